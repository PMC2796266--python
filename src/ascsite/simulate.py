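"""Self-contained synthetic fixtures: toy template structures and labelled
families with planted specificity-determining positions (SDPs).

The generator emulates the shape of a real benchmark family: an otherwise
conserved active site (the planted signature columns) in which a small
subset of columns (the SDP columns) carries class-specific consensus
residues, surrounded by background columns subject to i.i.d. substitution
noise and sparse gaps.  The toy structure places the residues of the
signature columns within the distance cutoff of a pseudo-substrate het
group at the origin and everything else well outside it, so signature
extraction has an exact known answer.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._alphabet import AA20, ONE_TO_THREE
from .io import LabelledFamily, TemplateStructure, read_structure
from .site import ActiveSiteSelector

TEMPLATE_ID = "TEMPLATE"
HET_NAME = "SUB"


@dataclass
class FamilySpec:
    """Parameters of a planted-signal synthetic family.

    Defaults model a modest desk-scale benchmark family: three specificity
    classes of 20 members each over a 60-column alignment, an 8-residue
    active site containing two SDP columns, 5% per-column substitution
    noise and 2% gaps.
    """

    n_classes: int = 3
    n_per_class: int = 20
    msa_width: int = 60
    signature_columns: tuple[int, ...] = (7, 13, 22, 29, 35, 41, 48, 54)
    sdp_columns: tuple[int, ...] = (22, 41)
    noise: float = 0.05
    gap_rate: float = 0.02
    seed: int = 0
    two_chains: bool = False

    def __post_init__(self) -> None:
        self.signature_columns = tuple(sorted(self.signature_columns))
        self.sdp_columns = tuple(sorted(self.sdp_columns))
        cols = set(self.signature_columns) | set(self.sdp_columns)
        if any(not 0 <= c < self.msa_width for c in cols):
            raise ValueError("columns must lie within the MSA width")
        if not 0 <= self.noise < 1 or not 0 <= self.gap_rate < 1:
            raise ValueError("rates must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 sequences per class")

    @property
    def class_names(self) -> list[str]:
        return [f"class{i + 1}" for i in range(self.n_classes)]


@dataclass
class GroundTruth:
    """What the generator planted, for asserting recovery."""

    consensus: str
    signature_columns: tuple[int, ...]
    sdp_columns: tuple[int, ...]
    class_residues: dict[str, dict[int, str]]  # class -> column -> residue

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "signature_columns": list(self.signature_columns),
            "sdp_columns": list(self.sdp_columns),
            "class_residues": {
                c: {str(col): r for col, r in cols.items()}
                for c, cols in self.class_residues.items()
            },
        }


def _rng(spec: FamilySpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def make_family(spec: FamilySpec) -> tuple[LabelledFamily, GroundTruth]:
    """Generate a labelled family with planted SDPs; deterministic from seed.

    The template row is the ungapped consensus.  Class rows substitute their
    class residue at each SDP column, then receive i.i.d. substitution noise
    and gaps at non-SDP columns.
    """
    rng = _rng(spec, 1)
    aa = np.array(list(AA20))
    consensus = rng.choice(aa, size=spec.msa_width)

    class_residues: dict[str, dict[int, str]] = {c: {} for c in spec.class_names}
    for col in spec.sdp_columns:
        picks = rng.choice(aa, size=spec.n_classes, replace=False)
        for cname, r in zip(spec.class_names, picks):
            class_residues[cname][col] = str(r)

    non_sdp = np.array(
        [c for c in range(spec.msa_width) if c not in spec.sdp_columns]
    )
    ids = [TEMPLATE_ID]
    rows = ["".join(consensus)]
    labels: dict[str, str] = {}
    for cname in spec.class_names:
        for k in range(spec.n_per_class):
            row = consensus.copy()
            for col, r in class_residues[cname].items():
                row[col] = r
            # substitution noise outside SDP columns
            flip = non_sdp[rng.random(len(non_sdp)) < spec.noise]
            for col in flip:
                alternatives = [a for a in AA20 if a != row[col]]
                row[col] = alternatives[rng.integers(len(alternatives))]
            # sparse gaps, also only outside SDP columns
            gap = non_sdp[rng.random(len(non_sdp)) < spec.gap_rate]
            row[gap] = "-"
            sid = f"{cname}_{k:02d}"
            ids.append(sid)
            rows.append("".join(row))
            labels[sid] = cname

    # the generator produced the alignment itself, so every column is
    # maximally reliable on the 0-9 aligner scale
    family = LabelledFamily(ids=ids, rows=rows, labels=labels,
                            template_id=TEMPLATE_ID,
                            core_scores=np.full(spec.msa_width, 9.0))
    truth = GroundTruth(
        consensus="".join(consensus),
        signature_columns=spec.signature_columns,
        sdp_columns=spec.sdp_columns,
        class_residues=class_residues,
    )
    return family, truth


# ---------------------------------------------------------------------------
# toy structure
# ---------------------------------------------------------------------------

def _sphere_points(n: int, radius: float) -> np.ndarray:
    """n points spread on a sphere (golden-spiral layout)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return radius * np.stack(
        [np.cos(theta) * np.sin(phi),
         np.sin(theta) * np.sin(phi),
         np.cos(phi)], axis=1,
    )


def toy_structure_pdb_text(spec: FamilySpec,
                           consensus: str | None = None) -> str:
    """PDB text of a toy template matching the family's consensus.

    Each residue carries a single CA atom.  Residues of the planted
    signature columns sit on a 4.5 Å sphere around the pseudo-substrate
    (het group ``SUB``, four atoms near the origin); all other residues
    lie at least 10 Å away.
    """
    site_cols = list(spec.signature_columns)
    if len(site_cols) > 60:
        raise ValueError(
            f"{len(site_cols)} site residues cannot be packed within the "
            f"cutoff sphere"
        )
    if consensus is None:
        consensus, _ = _consensus_of(spec)
    n = spec.msa_width
    site_xyz = _sphere_points(max(len(site_cols), 1), radius=4.5)
    coords = np.zeros((n, 3))
    site_iter = iter(site_xyz)
    far = 0
    for col in range(n):
        if col in spec.signature_columns:
            coords[col] = next(site_iter)
        else:
            coords[col] = (14.0 + 1.8 * far, 6.0, -4.0)
            far += 1

    chain_of = ["A"] * n
    number_of = list(range(1, n + 1))
    if spec.two_chains:
        half = n // 2
        for col in range(half, n):
            chain_of[col] = "B"
            number_of[col] = col - half + 1

    lines = []
    serial = 1
    for col in range(n):
        res3 = ONE_TO_THREE[consensus[col]]
        x, y, z = coords[col]
        lines.append(
            f"ATOM  {serial:>5d}  CA  {res3:>3s} {chain_of[col]:1s}"
            f"{number_of[col]:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           C"
        )
        serial += 1
    # pseudo-substrate: 4 atoms in a small tetrahedron at the origin
    sub = 0.8 * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3)
    for i, (x, y, z) in enumerate(sub, start=1):
        lines.append(
            f"HETATM{serial:>5d}  C{i:<2d} {HET_NAME:>3s} "
            f"{chain_of[-1] if not spec.two_chains else 'B':1s}"
            f"{900:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _consensus_of(spec: FamilySpec) -> tuple[str, GroundTruth]:
    family, truth = make_family(spec)
    return truth.consensus, truth


def make_toy_structure(
    spec: FamilySpec,
) -> tuple[TemplateStructure, ActiveSiteSelector]:
    """Build the toy structure and its site selector via the PDB reader.

    Writing the structure as PDB text and reading it back guarantees the
    fixture exercises the same parsing path as user-supplied structures.
    """
    consensus, _ = _consensus_of(spec)
    text = toy_structure_pdb_text(spec, consensus=consensus)
    with tempfile.NamedTemporaryFile(
        "w", suffix=".pdb", delete=False
    ) as fh:
        fh.write(text)
        path = fh.name
    try:
        structure = read_structure(path)
    finally:
        Path(path).unlink(missing_ok=True)
    return structure, ActiveSiteSelector.het_group(HET_NAME)


def make_fixture(spec: FamilySpec):
    """Family, ground truth, structure and selector in one call."""
    family, truth = make_family(spec)
    structure, selector = make_toy_structure(spec)
    return family, truth, structure, selector
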
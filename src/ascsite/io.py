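"""Readers and writers for every external artifact.

Structures are plain-text PDB (ATOM/HETATM/TER records; everything else is
ignored), alignments are aligned FASTA (Clustal and Stockholm accepted via
conversion on read), labels are two-column TSV, substitution matrices come
from Biopython's canonical copies or NCBI-style text files, and trained
models round-trip through JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._alphabet import AA20, THREE_TO_ONE, WATER_NAMES


class FormatError(ValueError):
    """Raised when an input artifact cannot be parsed or is inconsistent."""


class EmptyResultError(ValueError):
    """Raised when a pipeline stage legitimately produces nothing
    (e.g. no residues within the cutoff, no trainable sequences)."""


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue (or het component): author numbering taken verbatim."""

    chain: str
    number: int
    icode: str
    name: str  # 3-letter residue name
    atoms: tuple[tuple[str, float, float, float], ...]

    @property
    def identifier(self) -> str:
        """User-facing id, e.g. ``A:LEU91`` (insertion code appended)."""
        return f"{self.chain}:{self.name}{self.number}{self.icode.strip()}"

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [
            (x, y, z)
            for (name, x, y, z) in self.atoms
            if not heavy_only or not name.strip().startswith("H")
        ]
        if not pts:  # hydrogen-only residue: fall back to all atoms
            pts = [(x, y, z) for (_, x, y, z) in self.atoms]
        return np.asarray(pts, dtype=float)


@dataclass
class TemplateStructure:
    """Parsed template structure: polymer residues, het groups, sequences.

    ``sequence_per_chain`` maps each chain id to its 1-letter sequence
    (non-standard residues as ``X``); ``residue_index`` gives, per chain,
    the polymer residues in file order so that ``sequence_per_chain[c][i]``
    describes ``residue_index[c][i]``.
    """

    chains: list[str]
    residues: list[Residue]
    het_groups: list[Residue]
    sequence_per_chain: dict[str, str]
    residue_index: dict[str, list[Residue]]

    @property
    def concatenated_sequence(self) -> str:
        """Chain sequences joined in file order (multi-chain templates)."""
        return "".join(self.sequence_per_chain[c] for c in self.chains)

    @property
    def concatenated_residues(self) -> list[Residue]:
        out: list[Residue] = []
        for c in self.chains:
            out.extend(self.residue_index[c])
        return out


def _three_to_one(name: str) -> str:
    return THREE_TO_ONE.get(name.strip().upper(), "X")


def read_structure(path: str | Path) -> TemplateStructure:
    """Parse a PDB file into a :class:`TemplateStructure`.

    Only ATOM/HETATM/TER records are interpreted.  Residues on ATOM records
    are polymer residues; HETATM groups (excluding waters) are collected as
    het groups.  Author residue numbering, including insertion codes, is
    preserved verbatim.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"structure {path} contains no models")
    model = st[0]

    chains: list[str] = []
    residues: list[Residue] = []
    het_groups: list[Residue] = []
    sequence_per_chain: dict[str, str] = {}
    residue_index: dict[str, list[Residue]] = {}

    for chain in model:
        cid = chain.name
        seq_chars: list[str] = []
        polymer: list[Residue] = []
        for res in chain:
            atoms = tuple(
                (at.name, at.pos.x, at.pos.y, at.pos.z) for at in res
            )
            if not atoms:
                continue
            xyz = np.array([a[1:] for a in atoms], dtype=float)
            if not np.isfinite(xyz).all():
                raise FormatError(
                    f"non-finite coordinates in residue "
                    f"{cid}:{res.name}{res.seqid.num}"
                )
            rec = Residue(
                chain=cid,
                number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=res.name.strip(),
                atoms=atoms,
            )
            is_het = res.het_flag == "H"
            if is_het:
                if rec.name.upper() not in WATER_NAMES:
                    het_groups.append(rec)
            else:
                polymer.append(rec)
                seq_chars.append(_three_to_one(rec.name))
        if polymer:
            if cid not in chains:
                chains.append(cid)
            sequence_per_chain[cid] = sequence_per_chain.get(cid, "") + "".join(seq_chars)
            residue_index.setdefault(cid, []).extend(polymer)
            residues.extend(polymer)

    if not residues and not het_groups:
        raise FormatError(f"structure {path} is empty (no atoms parsed)")
    return TemplateStructure(
        chains=chains,
        residues=residues,
        het_groups=het_groups,
        sequence_per_chain=sequence_per_chain,
        residue_index=residue_index,
    )


def write_structure_pdb(structure: TemplateStructure, path: str | Path) -> None:
    """Write a structure back out as minimal PDB text (ATOM/HETATM/END)."""
    Path(path).write_text(structure_to_pdb_text(structure))


def structure_to_pdb_text(structure: TemplateStructure) -> str:
    lines: list[str] = []
    serial = 1
    for res in structure.concatenated_residues:
        for (name, x, y, z) in res.atoms:
            lines.append(_pdb_atom_line("ATOM", serial, name, res, x, y, z))
            serial += 1
    for res in structure.het_groups:
        for (name, x, y, z) in res.atoms:
            lines.append(_pdb_atom_line("HETATM", serial, name, res, x, y, z))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_atom_line(record: str, serial: int, atom: str, res: Residue,
                   x: float, y: float, z: float) -> str:
    name = atom if len(atom) == 4 else f" {atom:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} "
        f"{res.chain:1s}{res.number:>4d}{res.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.strip()[0]:>2s}"
    )


# ---------------------------------------------------------------------------
# alignments and labels
# ---------------------------------------------------------------------------

@dataclass
class LabelledFamily:
    """An aligned enzyme family with (partial) specificity labels.

    ``labels[id]`` is the class of a labelled row; unlabelled rows (e.g. the
    template, or prediction targets) are absent from ``labels``.
    ``core_scores`` holds optional per-column alignment-reliability scores
    on the 0-9 scale of consistency-based aligners.
    """

    ids: list[str]
    rows: list[str]
    labels: dict[str, str]
    template_id: str | None = None
    core_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            bad = [i for i, r in zip(self.ids, self.rows)
                   if len(r) != len(self.rows[0])]
            raise FormatError(f"ragged alignment; offending ids: {bad}")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        if self.template_id is not None and self.template_id not in self.ids:
            raise ValueError(
                f"template id {self.template_id!r} not in alignment"
            )
        if self.core_scores is not None:
            self.core_scores = np.asarray(self.core_scores, dtype=float)
            if self.core_scores.shape != (self.width,):
                raise ValueError("core_scores length must equal MSA width")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def labelled_ids(self) -> list[str]:
        return [i for i in self.ids if i in self.labels]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, keep_ids: list[str]) -> "LabelledFamily":
        keep = set(keep_ids)
        ids = [i for i in self.ids if i in keep]
        rows = [r for i, r in zip(self.ids, self.rows) if i in keep]
        labels = {i: c for i, c in self.labels.items() if i in keep}
        return LabelledFamily(
            ids=ids, rows=rows, labels=labels,
            template_id=self.template_id if self.template_id in keep else None,
            core_scores=self.core_scores,
        )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>class`` table; ``#`` starts a comment line."""
    labels: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}:{ln}: expected 'id<TAB>class', got {line!r}"
            )
        labels[parts[0].strip()] = parts[1].strip()
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{i}\t{c}\n" for i, c in labels.items())
    )


def read_alignment(
    path: str | Path,
    labels_path: str | Path | None = None,
    template_id: str | None = None,
    fmt: str = "fasta",
) -> LabelledFamily:
    """Read an aligned FASTA (or Clustal/Stockholm) plus optional labels.

    Label ids missing from the alignment produce a warning and are skipped;
    alignment rows without a label are retained unlabelled.
    """
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise FormatError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]

    labels: dict[str, str] = {}
    if labels_path is not None:
        raw = read_labels(labels_path)
        known = set(ids)
        for i, c in raw.items():
            if i not in known:
                warnings.warn(
                    f"label id {i!r} not present in alignment; skipped",
                    stacklevel=2,
                )
            else:
                labels[i] = c
    return LabelledFamily(
        ids=ids, rows=rows, labels=labels, template_id=template_id
    )


def write_alignment(family: LabelledFamily, path: str | Path,
                    width: int = 60) -> None:
    """Write the family as aligned FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for i, row in zip(family.ids, family.rows):
            fh.write(f">{i}\n")
            for start in range(0, len(row), width):
                fh.write(row[start:start + width] + "\n")


def read_core_scores(path: str | Path) -> np.ndarray:
    """Read per-column reliability scores: one number per line or one row."""
    text = Path(path).read_text().split()
    return np.asarray([float(v) for v in text], dtype=float)


# ---------------------------------------------------------------------------
# substitution / similarity matrices
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """A symmetric residue-pair score or probability matrix."""

    alphabet: str
    values: np.ndarray
    name: str = ""
    #: set by the PSD projection step (see kernels module)
    psd_certified: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.alphabet)
        if len(set(self.alphabet)) != n:
            raise FormatError(f"duplicate letters in alphabet {self.alphabet!r}")
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"alphabet of size {n}"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise FormatError(f"matrix {self.name or '<anonymous>'} is not symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.alphabet.index(a), self.alphabet.index(b)])

    def reordered(self, alphabet: str) -> "SubstitutionMatrix":
        """Return a copy with rows/columns in the given letter order."""
        missing = [c for c in alphabet if c not in self.alphabet]
        if missing:
            raise FormatError(
                f"matrix {self.name!r} lacks residues: {missing}"
            )
        idx = [self.alphabet.index(c) for c in alphabet]
        return SubstitutionMatrix(
            alphabet=alphabet,
            values=self.values[np.ix_(idx, idx)],
            name=self.name,
            psd_certified=self.psd_certified,
        )


#: bundled matrix names -> Biopython substitution_matrices names
_BUNDLED = {"BLOSUM62": "BLOSUM62", "MCLA720101": "MCLACHLAN"}


def load_matrix(name_or_path: str | Path) -> SubstitutionMatrix:
    """Load a bundled matrix by name or parse an NCBI-style matrix file.

    Bundled names: ``BLOSUM62`` (half-bit log-odds) and ``MCLA720101``
    (the McLachlan 1972 chemical similarity matrix from AAindex).  Matrices
    are restricted/reordered to the 20 standard amino acids.
    """
    key = str(name_or_path)
    if key in _BUNDLED:
        m = substitution_matrices.load(_BUNDLED[key])
        letters = [c for c in m.alphabet if c in AA20]
        idx = [m.alphabet.index(c) for c in letters]
        values = np.asarray(m)[np.ix_(idx, idx)]
        sub = SubstitutionMatrix("".join(letters), values, name=key)
        return sub.reordered(AA20)
    return _parse_matrix_file(Path(name_or_path))


def _parse_matrix_file(path: Path) -> SubstitutionMatrix:
    """Parse a whitespace-separated matrix with an alphabet header row.

    Rows may carry a leading letter (NCBI style); ``#`` lines are comments.
    """
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty matrix file {path}")
    header = lines[0].split()
    alphabet = "".join(header)
    n = len(header)
    values = np.zeros((n, n))
    body = lines[1:]
    if len(body) < n:
        raise FormatError(f"{path}: expected {n} matrix rows, found {len(body)}")
    for i, ln in enumerate(body[:n]):
        parts = ln.split()
        if parts and parts[0] == header[i]:
            parts = parts[1:]
        if len(parts) != n:
            raise FormatError(
                f"{path}: row {i + 1} has {len(parts)} values, expected {n}"
            )
        values[i] = [float(v) for v in parts]
    return SubstitutionMatrix(alphabet, values, name=str(path))


def load_wold_table() -> dict[str, tuple[float, float, float]]:
    """Load the 3-descriptor z-scale table bundled with the package."""
    path = Path(__file__).parent / "data" / "wold_z3.tsv"
    table: dict[str, tuple[float, float, float]] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        aa, z1, z2, z3 = line.split("\t")
        table[aa] = (float(z1), float(z2), float(z3))
    missing = [c for c in AA20 if c not in table]
    if missing:
        raise FormatError(f"z-scale table lacks residues {missing}")
    return table


def load_background_frequencies() -> dict[str, float]:
    """Load the bundled Robinson-Robinson amino-acid background frequencies."""
    path = Path(__file__).parent / "data" / "background_frequencies.tsv"
    freqs: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        aa, f = line.split("\t")
        freqs[aa] = float(f)
    total = sum(freqs.values())
    return {a: f / total for a, f in freqs.items()}


# ---------------------------------------------------------------------------
# signature / definition / report serialization
# ---------------------------------------------------------------------------

def write_signatures_tsv(signature_set, path: str | Path) -> None:
    """Write a signature set: header of position ids, then id/signature rows."""
    header = "\t".join(p.residue_id for p in signature_set.definition.positions)
    with open(path, "w") as fh:
        fh.write(f"# positions:\t{header}\n")
        for i, sig in zip(signature_set.ids, signature_set.signatures):
            fh.write(f"{i}\t{sig}\n")


def definition_to_dict(definition) -> dict:
    return {
        "cutoff_angstrom": definition.cutoff_used,
        "core_min": definition.core_min_used,
        "positions": [
            {
                "residue_id": p.residue_id,
                "msa_column": p.column,
                "min_distance_angstrom": round(p.distance, 4),
                "core_score": p.core_score,
            }
            for p in definition.positions
        ],
    }


def write_definition_json(definition, path: str | Path) -> None:
    Path(path).write_text(json.dumps(definition_to_dict(definition), indent=2))


def definition_from_dict(payload: dict):
    from .site import SignatureDefinition, SignaturePosition

    return SignatureDefinition(
        positions=[
            SignaturePosition(
                residue_id=p["residue_id"],
                column=int(p["msa_column"]),
                distance=float(p["min_distance_angstrom"]),
                core_score=float(p["core_score"]),
            )
            for p in payload["positions"]
        ],
        cutoff_used=float(payload["cutoff_angstrom"]),
        core_min_used=float(payload["core_min"]),
    )


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~ascsite.svm.AscClassifier` to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path):
    from .svm import AscClassifier

    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != 1:
        raise FormatError(
            f"unsupported model file version {version!r} (expected 1)"
        )
    return AscClassifier.from_dict(payload)
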
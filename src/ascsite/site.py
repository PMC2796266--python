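"""From template structure + family MSA to per-sequence active-site signatures.

The pipeline: filter family members by identity to the template, pick the
most diverse representatives per class for a guide alignment, resolve the
active site (bound het group, named residue, or explicit coordinates),
extract the template residues lining the site (distance cutoff, per-column
reliability threshold), and map those residues along the MSA to obtain a
signature string for every sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import AA20, GAP, NULL_IDX, encode_rows
from .cv import identity_matrix, pairwise_identity
from .io import (
    EmptyResultError,
    LabelledFamily,
    Residue,
    SubstitutionMatrix,
    TemplateStructure,
    load_matrix,
)


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActiveSiteSelector:
    """Marks the active site by het-group name, residue id, or coordinates."""

    mode: str  # "het_group" | "residue" | "coordinates"
    het_name: str | None = None
    residue_id: str | None = None  # "CHAIN:NUMBER" or "CHAIN:NAMENUMBER"
    points: np.ndarray | None = None

    @classmethod
    def het_group(cls, name: str) -> "ActiveSiteSelector":
        return cls(mode="het_group", het_name=name)

    @classmethod
    def residue(cls, identifier: str) -> "ActiveSiteSelector":
        return cls(mode="residue", residue_id=identifier)

    @classmethod
    def coordinates(cls, points) -> "ActiveSiteSelector":
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(pts) == 0:
            raise ValueError("coordinate selector needs at least one point")
        return cls(mode="coordinates", points=pts)


def _is_ion(res: Residue) -> bool:
    """Monoatomic het groups (metal ions etc.) never define the site."""
    return len(res.atoms) == 1


def _match_residue(res: Residue, identifier: str) -> bool:
    chain, _, rest = identifier.partition(":")
    if res.chain != chain:
        return False
    rest = rest.strip().upper()
    name_num = f"{res.name}{res.number}{res.icode}".upper()
    return rest == name_num or rest == f"{res.number}{res.icode}".upper()


def site_atoms(structure: TemplateStructure,
               selector: ActiveSiteSelector) -> np.ndarray:
    """Resolve the selector to an (n, 3) array of site coordinates.

    A het-group name matches all of its copies (e.g. in both chains of a
    dimer); waters and monoatomic ions are never considered.
    """
    if selector.mode == "coordinates":
        return selector.points.copy()
    if selector.mode == "het_group":
        hits = [
            h for h in structure.het_groups
            if h.name.upper() == selector.het_name.upper() and not _is_ion(h)
        ]
        if not hits:
            available = sorted({
                h.name for h in structure.het_groups if not _is_ion(h)
            })
            raise ValueError(
                f"het group {selector.het_name!r} not found; "
                f"available: {available or 'none'}"
            )
        return np.vstack([h.coords() for h in hits])
    if selector.mode == "residue":
        hits = [
            r for r in structure.residues
            if _match_residue(r, selector.residue_id)
        ]
        if not hits:
            available = [r.identifier for r in structure.residues]
            raise ValueError(
                f"residue {selector.residue_id!r} not found; "
                f"available residues: {available[:20]}"
                f"{'...' if len(available) > 20 else ''}"
            )
        return np.vstack([r.coords() for r in hits])
    raise ValueError(f"unknown selector mode {selector.mode!r}")


def _selector_residues(structure: TemplateStructure,
                       selector: ActiveSiteSelector) -> set[int]:
    """Indices (into concatenated residues) of residues the selector names."""
    if selector.mode != "residue":
        return set()
    return {
        i for i, r in enumerate(structure.concatenated_residues)
        if _match_residue(r, selector.residue_id)
    }


# ---------------------------------------------------------------------------
# family preprocessing
# ---------------------------------------------------------------------------

def filter_by_template_identity(family: LabelledFamily,
                                min_identity: float = 0.20) -> LabelledFamily:
    """Drop rows whose identity to the template row is below the threshold.

    The template row itself is always retained.
    """
    if not 0 <= min_identity <= 1:
        raise ValueError("min_identity must lie in [0, 1]")
    if family.template_id is None:
        raise ValueError("family has no template id")
    template_row = family.row(family.template_id)
    keep = [
        i for i in family.ids
        if i == family.template_id
        or pairwise_identity(family.row(i), template_row) >= min_identity
    ]
    result = family.subset(keep)
    if not result.labelled_ids:
        raise EmptyResultError(
            "no trainable sequences after template-identity filter"
        )
    return result


def select_guide_sequences(family: LabelledFamily,
                           n_per_class: int = 5) -> list[str]:
    """Greedy maximin pick of the most diverse members of each class.

    Per class: seed with the sequence of lowest mean identity to its class,
    then repeatedly add the sequence whose minimum distance (1 - identity)
    to the chosen set is largest.  Ties break lexicographically by id, so
    the result is deterministic.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    chosen: list[str] = []
    for cls in family.classes:
        members = sorted(i for i in family.labelled_ids
                         if family.labels[i] == cls)
        if not members:
            raise ValueError(f"class {cls!r} has no sequences")
        rows = [family.row(i) for i in members]
        ident = identity_matrix(rows)
        dist = 1.0 - ident
        if len(members) <= n_per_class:
            chosen.extend(members)
            continue
        mean_ident = (ident.sum(axis=1) - 1.0) / (len(members) - 1)
        picked = [int(np.argmin(mean_ident))]  # argmin takes first = lexicographic
        while len(picked) < n_per_class:
            min_d = dist[:, picked].min(axis=1)
            min_d[picked] = -np.inf
            picked.append(int(np.argmax(min_d)))
        chosen.extend(members[i] for i in sorted(picked))
    return chosen


# ---------------------------------------------------------------------------
# template <-> MSA mapping
# ---------------------------------------------------------------------------

def template_column_map(structure: TemplateStructure,
                        family: LabelledFamily,
                        max_mismatch: float = 0.05) -> list[tuple[Residue, int]]:
    """Pair each template residue with its MSA column.

    The template's MSA row, with gaps removed, must equal the concatenated
    chain sequences (chains in file order); up to ``max_mismatch`` of the
    residues may disagree (e.g. non-standard residues read as ``X``).
    """
    if family.template_id is None:
        raise ValueError("family has no template id")
    row = family.row(family.template_id)
    residues = structure.concatenated_residues
    seq = structure.concatenated_sequence
    columns = [c for c, ch in enumerate(row) if ch != GAP]
    ungapped = "".join(row[c] for c in columns)
    if len(ungapped) != len(seq):
        raise ValueError(
            f"template MSA row has {len(ungapped)} residues but the "
            f"structure has {len(seq)}; cannot map structure to alignment"
        )
    mismatches = sum(1 for a, b in zip(ungapped, seq)
                     if a != b and "X" not in (a, b))
    if len(seq) and mismatches / len(seq) > max_mismatch:
        raise ValueError(
            f"template sequence mismatch: {mismatches}/{len(seq)} residues "
            f"differ between the MSA row and the structure"
        )
    return list(zip(residues, columns))


# ---------------------------------------------------------------------------
# CORE-score proxy
# ---------------------------------------------------------------------------

def core_score_proxy(family: LabelledFamily,
                     matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """Per-column conservation proxy on the 0-9 reliability scale.

    When no aligner-produced reliability scores are supplied, each column is
    scored by the mean pairwise BLOSUM62 score of its residue pairs and the
    raw scores are affinely rescaled to [0, 9] over the MSA.  Columns with
    fewer than two residues take the minimum raw score; an MSA whose columns
    all score identically (e.g. perfectly conserved) maps every column to 9.
    """
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    m21 = np.full((21, 21), np.nan)
    order = [matrix.alphabet.index(c) for c in AA20]
    m21[:20, :20] = matrix.values[np.ix_(order, order)]
    codes = encode_rows(family.rows)
    n, width = codes.shape
    raw = np.empty(width)
    for col in range(width):
        col_codes = codes[:, col]
        res = col_codes[col_codes != NULL_IDX]
        if len(res) < 2:
            raw[col] = np.nan
            continue
        sub = m21[np.ix_(res, res)]
        iu = np.triu_indices(len(res), k=1)
        raw[col] = float(np.mean(sub[iu]))
    if np.isnan(raw).all():
        return np.full(width, 0.0)
    lo = np.nanmin(raw)
    hi = np.nanmax(raw)
    raw = np.where(np.isnan(raw), lo, raw)
    if hi - lo < 1e-12:
        return np.full(width, 9.0)
    return 9.0 * (raw - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# signature definition and extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignaturePosition:
    residue_id: str
    column: int
    distance: float
    core_score: float


@dataclass
class SignatureDefinition:
    """The ordered active-site positions (template residues + MSA columns)."""

    positions: list[SignaturePosition]
    cutoff_used: float
    core_min_used: float

    def __post_init__(self) -> None:
        cols = [p.column for p in self.positions]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("MSA columns must be strictly increasing")

    @property
    def columns(self) -> list[int]:
        return [p.column for p in self.positions]

    def __len__(self) -> int:
        return len(self.positions)


def extract_signature_positions(
    structure: TemplateStructure,
    selector: ActiveSiteSelector,
    family: LabelledFamily,
    cutoff: float = 6.0,
    core_min: float = 5.0,
) -> SignatureDefinition:
    """Template residues lining the active site, as MSA positions.

    A residue qualifies when the minimum distance between its heavy atoms
    and the site atoms is at most ``cutoff`` (Å) and its MSA column's
    reliability score is at least ``core_min``.  Residues that are
    themselves part of a residue selector are excluded.  Scores come from
    ``family.core_scores`` when present, otherwise from the conservation
    proxy.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    points = site_atoms(structure, selector)
    mapping = template_column_map(structure, family)
    excluded = _selector_residues(structure, selector)
    if family.core_scores is not None:
        core = np.asarray(family.core_scores, dtype=float)
    else:
        core = core_score_proxy(family)

    positions: list[SignaturePosition] = []
    for idx, (res, col) in enumerate(mapping):
        if idx in excluded:
            continue
        d = float(np.min(np.linalg.norm(
            res.coords()[:, None, :] - points[None, :, :], axis=2
        )))
        if d <= cutoff and core[col] >= core_min:
            positions.append(SignaturePosition(
                residue_id=res.identifier, column=col,
                distance=d, core_score=float(core[col]),
            ))
    positions.sort(key=lambda p: p.column)
    if not positions:
        raise EmptyResultError(
            f"no residues within {cutoff} Å of the site with column score "
            f">= {core_min}; try a larger cutoff or lower core_min"
        )
    return SignatureDefinition(positions=positions, cutoff_used=cutoff,
                               core_min_used=core_min)


@dataclass
class SignatureSet:
    """Per-sequence signatures at the definition's columns."""

    ids: list[str]
    signatures: list[str]
    labels: dict[str, str]
    definition: SignatureDefinition

    def __post_init__(self) -> None:
        n = len(self.definition)
        bad = [i for i, s in zip(self.ids, self.signatures) if len(s) != n]
        if bad:
            raise ValueError(
                f"signatures of wrong length for ids {bad}"
            )

    def signature(self, seq_id: str) -> str:
        return self.signatures[self.ids.index(seq_id)]

    def labelled_subset(self) -> tuple[list[str], list[str], list[str]]:
        ids = [i for i in self.ids if i in self.labels]
        return (ids, [self.signature(i) for i in ids],
                [self.labels[i] for i in ids])


def map_signatures(family: LabelledFamily,
                   definition: SignatureDefinition) -> SignatureSet:
    """Read each row's characters at the definition's columns."""
    width = family.width
    bad = [c for c in definition.columns if not 0 <= c < width]
    if bad:
        raise ValueError(f"definition columns {bad} outside MSA width {width}")
    cols = definition.columns
    return SignatureSet(
        ids=list(family.ids),
        signatures=["".join(r[c] for c in cols) for r in family.rows],
        labels=dict(family.labels),
        definition=definition,
    )


# ---------------------------------------------------------------------------
# sequence-to-profile alignment
# ---------------------------------------------------------------------------

def align_to_guide(
    guide: LabelledFamily,
    raw_sequence: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    min_template_identity: float = 0.20,
    matrix: SubstitutionMatrix | None = None,
    return_score: bool = False,
):
    """Globally align a raw sequence to the guide MSA's fixed columns.

    Scores are profile averages of BLOSUM62 (half-bit units) over each
    column's residues; gaps are affine (open 10, extend 1).  Guide columns
    are never merged or split: the result is the new row padded to the
    guide width, with sequence residues that fit no column dropped as
    insertions.  Deterministic (ties prefer match, then column-skip).

    Raises if the aligned row's identity to the template row falls below
    ``min_template_identity`` (mirroring the training-time prefilter).
    """
    if not guide.rows:
        raise ValueError("empty guide alignment")
    raw = raw_sequence.strip().upper().replace("-", "")
    if not raw:
        raise ValueError("empty query sequence")
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    m = matrix.reordered(AA20).values

    codes = encode_rows(guide.rows)
    width = codes.shape[1]
    # per-column average substitution score against each of the 20 residues
    profile = np.zeros((width, 21))
    for col in range(width):
        res = codes[:, col][codes[:, col] != NULL_IDX]
        if len(res):
            profile[col, :20] = m[res].mean(axis=0)
    q = encode_rows([raw])[0]
    n = len(q)

    NEG = -1e18
    # states: M[i][j] best score with column i matched to residue j,
    # D[i][j] column i skipped (gap in new row), I[i][j] residue j inserted
    M = np.full((width + 1, n + 1), NEG)
    D = np.full((width + 1, n + 1), NEG)
    I = np.full((width + 1, n + 1), NEG)
    ptr = np.zeros((3, width + 1, n + 1), dtype=np.int8)  # 0=M,1=D,2=I
    M[0, 0] = 0.0
    for i in range(1, width + 1):
        D[i, 0] = -(gap_open + gap_extend * (i - 1))
        ptr[1, i, 0] = 1 if i > 1 else 0
    for j in range(1, n + 1):
        I[0, j] = -(gap_open + gap_extend * (j - 1))
        ptr[2, 0, j] = 2 if j > 1 else 0
    for i in range(1, width + 1):
        s_col = profile[i - 1]
        for j in range(0, n + 1):
            if j > 0:
                s = s_col[q[j - 1]]
                cand = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
                k = int(np.argmax(cand))
                M[i, j] = cand[k] + s
                ptr[0, i, j] = k
            cand = (M[i - 1, j] - gap_open, D[i - 1, j] - gap_extend,
                    I[i - 1, j] - gap_open)
            k = int(np.argmax(cand))
            D[i, j] = cand[k]
            ptr[1, i, j] = k
            if j > 0:
                cand = (M[i, j - 1] - gap_open, D[i, j - 1] - gap_open,
                        I[i, j - 1] - gap_extend)
                k = int(np.argmax(cand))
                I[i, j] = cand[k]
                ptr[2, i, j] = k

    finals = (M[width, n], D[width, n], I[width, n])
    best_score = float(max(finals))
    state = int(np.argmax(finals))
    i, j = width, n
    row_chars = [GAP] * width
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == 0:
            row_chars[i - 1] = raw[j - 1]
            i, j = i - 1, j - 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = int(prev)
    aligned = "".join(row_chars)

    if guide.template_id is not None:
        ident = pairwise_identity(aligned, guide.row(guide.template_id))
        if ident < min_template_identity:
            raise ValueError(
                f"query aligns with identity {ident:.2f} to the template, "
                f"below the {min_template_identity:.2f} threshold"
            )
    if return_score:
        return aligned, best_score
    return aligned
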
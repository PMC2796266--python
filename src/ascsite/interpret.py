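"""Ranking active-site positions by their influence on the trained models.

Two complementary scores are available.  For kernels with an explicit
feature map (``string``, ``wold``) the primal weight vector ``w = sum_i
alpha_i y_i phi(x_i)`` is computed and each position is scored by the
Euclidean norm of its block of weights.  For any kernel, a position can be
scored by the outer-loop accuracy of a full nested cross-validation in
which the kernel sees only that single signature column; in the multiclass
setting this is done per class pair on that pair's data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._alphabet import GAP, UNKNOWN
from .cv import CvConfig, nested_cv
from .io import LabelledFamily
from .kernels import KernelSpec, encode_onehot, encode_wold
from .site import SignatureDefinition, SignatureSet
from .svm import AscClassifier, BinarySvm

PRIMAL_KERNELS = ("string", "wold")


@dataclass
class RankedPosition:
    residue_id: str
    column: int
    score: float
    score_kind: str


@dataclass
class PositionRanking:
    """Positions sorted by descending score (ties by MSA column)."""

    entries: list[RankedPosition]
    score_kind: str
    class_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (-e.score, e.column)
        )

    def top(self, n: int) -> list[RankedPosition]:
        return self.entries[:n]

    def rank_of_column(self, column: int) -> int:
        """1-based rank of an MSA column in this ranking."""
        for i, e in enumerate(self.entries, start=1):
            if e.column == column:
                return i
        raise KeyError(column)


# ---------------------------------------------------------------------------
# primal weights
# ---------------------------------------------------------------------------

def _feature_map(kernel_name: str):
    if kernel_name == "string":
        return lambda s: encode_onehot(s, dims=20), 20
    if kernel_name == "wold":
        return encode_wold, 3
    raise ValueError(
        f"kernel {kernel_name!r} has no explicit feature map; use "
        f"single_position_accuracy instead"
    )


def primal_weight_vector(model: BinarySvm) -> np.ndarray:
    """Recover ``w = sum_i alpha_i y_i phi(x_i)`` for a primal-representable kernel."""
    phi, _ = _feature_map(model.kernel.name)
    feats = np.stack([phi(s) for s in model.support_items])
    return model.dual_coef @ feats


def primal_weight_ranking(model: BinarySvm,
                          definition: SignatureDefinition) -> PositionRanking:
    """Score each signature position by the norm of its primal weight block."""
    _, block = _feature_map(model.kernel.name)
    w = primal_weight_vector(model)
    entries = []
    for i, pos in enumerate(definition.positions):
        chunk = w[i * block:(i + 1) * block]
        entries.append(RankedPosition(
            residue_id=pos.residue_id, column=pos.column,
            score=float(np.linalg.norm(chunk)),
            score_kind="primal_weight_norm",
        ))
    return PositionRanking(entries=entries, score_kind="primal_weight_norm",
                           class_pair=model.classes)


def primal_rankings(model: AscClassifier,
                    definition: SignatureDefinition) -> dict:
    """One primal-weight ranking per pairwise model of a fitted classifier."""
    return {
        pair: primal_weight_ranking(binary, definition)
        for pair, binary in model.pairwise_models_.items()
    }


# ---------------------------------------------------------------------------
# single-position restricted-kernel accuracy
# ---------------------------------------------------------------------------

def single_position_accuracy(
    signature_set: SignatureSet,
    family: LabelledFamily,
    position: int,
    spec: KernelSpec,
    config: CvConfig,
    class_pair: tuple[str, str] | None = None,
) -> float:
    """Outer-loop accuracy of a nested CV run restricted to one column.

    ``position`` indexes the signature definition.  With more than two
    classes, ``class_pair`` selects the pairwise subproblem to score.
    """
    if not 0 <= position < len(signature_set.definition):
        raise ValueError(
            f"position {position} outside the {len(signature_set.definition)}"
            f"-position definition"
        )
    ids, sigs, labels = signature_set.labelled_subset()
    if class_pair is not None:
        keep = [i for i, y in zip(ids, labels) if y in class_pair]
        sigs = [signature_set.signature(i) for i in keep]
        labels = [signature_set.labels[i] for i in keep]
        ids = keep
    if len(set(labels)) != 2 and class_pair is None and len(set(labels)) > 2:
        raise ValueError("more than 2 classes: pass class_pair")
    single = [s[position] for s in sigs]
    rows = [family.row(i) for i in ids]
    cfg = replace(config, kernels=(spec,))
    report = nested_cv(single, ids, dict(zip(ids, labels)), cfg,
                       identity_rows=rows)
    return report.accuracy


def accuracy_rankings(
    signature_set: SignatureSet,
    family: LabelledFamily,
    spec: KernelSpec,
    config: CvConfig,
) -> dict:
    """Single-position accuracy rankings, one per class pair."""
    from itertools import combinations

    classes = sorted(set(signature_set.labels.values()))
    out = {}
    for pair in combinations(classes, 2):
        entries = []
        for i, pos in enumerate(signature_set.definition.positions):
            acc = single_position_accuracy(
                signature_set, family, i, spec, config, class_pair=pair
            )
            entries.append(RankedPosition(
                residue_id=pos.residue_id, column=pos.column,
                score=float(acc), score_kind="single_position_accuracy",
            ))
        out[pair] = PositionRanking(
            entries=entries, score_kind="single_position_accuracy",
            class_pair=pair,
        )
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def residue_preferences(signature_set: SignatureSet) -> pd.DataFrame:
    """Most frequent residue per class at each signature position."""
    ids, sigs, labels = signature_set.labelled_subset()
    classes = sorted(set(labels))
    records = []
    for i, pos in enumerate(signature_set.definition.positions):
        rec = {"residue_id": pos.residue_id, "msa_column": pos.column}
        for c in classes:
            chars = [s[i] for s, y in zip(sigs, labels)
                     if y == c and s[i] not in (GAP, UNKNOWN)]
            if chars:
                values, counts = np.unique(chars, return_counts=True)
                rec[f"preferred_{c}"] = str(values[np.argmax(counts)])
            else:
                rec[f"preferred_{c}"] = "-"
        records.append(rec)
    return pd.DataFrame.from_records(records)


def ranking_report(
    rankings: dict,
    definition: SignatureDefinition,
    signature_set: SignatureSet | None = None,
) -> pd.DataFrame:
    """Join rankings with the definition's geometry and residue preferences.

    One row per signature position; one score column per class pair.
    An empty rankings dict yields a table with the definition columns only.
    """
    records = []
    for pos in definition.positions:
        rec = {
            "residue_id": pos.residue_id,
            "msa_column": pos.column,
            "min_distance_angstrom": round(pos.distance, 3),
            "core_score": round(pos.core_score, 3),
        }
        for pair, ranking in rankings.items():
            label = "score" if pair is None else f"score_{pair[0]}_vs_{pair[1]}"
            by_col = {e.column: e.score for e in ranking.entries}
            rec[label] = by_col.get(pos.column, np.nan)
        records.append(rec)
    table = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["residue_id", "msa_column",
                 "min_distance_angstrom", "core_score"]
    )
    if signature_set is not None and records:
        prefs = residue_preferences(signature_set)
        table = table.merge(prefs, on=["residue_id", "msa_column"], how="left")
    return table


def write_bfactor_pdb(structure, ranking: PositionRanking,
                      definition: SignatureDefinition, path) -> None:
    """Write the structure with position scores in the B-factor column.

    Residues outside the signature get B-factor 0; suitable for colouring
    the active site by importance in any structure viewer.
    """
    from .io import Residue, TemplateStructure, structure_to_pdb_text

    scores = {e.residue_id: e.score for e in ranking.entries}
    smax = max(scores.values()) if scores else 1.0
    lines = []
    serial = 1
    for res in structure.concatenated_residues + structure.het_groups:
        record = "ATOM" if res in structure.concatenated_residues else "HETATM"
        b = 0.0
        if res.identifier in scores and smax > 0:
            b = 99.99 * scores[res.identifier] / smax
        for (name, x, y, z) in res.atoms:
            aname = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"{record:<6s}{serial:>5d} {aname:<4s} {res.name:>3s} "
                f"{res.chain:1s}{res.number:>4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          "
                f"{name.strip()[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
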
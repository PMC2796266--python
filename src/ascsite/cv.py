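"""Similarity-controlled model evaluation.

Generalisation is estimated with a nested cross-validation whose outer loop
leaves one labelled sequence out and whose training pool is restricted to
sequences whose identity to the held-out sequence does not exceed the MTTSI
(maximum training-to-testing sequence identity).  Identity is computed over
all aligned residues of the full MSA rows.  The inner loop performs
stratified k-fold cross-validation over a grid of (kernel, C) candidates
and picks the candidate with the best inner accuracy; the winner is refit
on the whole retained pool and predicts the held-out point.  Performance is
summarized by class-averaged precision and recall and their harmonic mean,
the (macro) F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._alphabet import NULL_IDX, encode_rows
from .kernels import KernelSpec, gram
from .io import LabelledFamily

DEFAULT_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 16, 2))


# ---------------------------------------------------------------------------
# identity and the MTTSI filter
# ---------------------------------------------------------------------------

def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of mutually aligned residues that are identical.

    Counted over columns where both rows carry a residue (no gap); returns
    0 when the rows share no aligned residue columns.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"rows differ in width ({len(row_a)} vs {len(row_b)})"
        )
    a, b = encode_rows([row_a, row_b])
    both = (a != NULL_IDX) & (b != NULL_IDX)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum()) / denom


def identity_matrix(rows: list[str]) -> np.ndarray:
    """All pairwise identities of equal-width rows (symmetric, diag 1)."""
    codes = encode_rows(rows)
    n = len(rows)
    out = np.ones((n, n))
    informative = codes != NULL_IDX
    for i in range(n):
        both = informative[i][None, :] & informative
        denom = both.sum(axis=1)
        same = ((codes == codes[i][None, :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(denom > 0, same / np.maximum(denom, 1), 0.0)
    return out


def mttsi_filter(family: LabelledFamily, test_id: str, mttsi: float) -> list[str]:
    """Labelled ids whose identity to the held-out sequence is <= MTTSI."""
    if test_id not in family.ids:
        raise ValueError(f"test id {test_id!r} not in family")
    test_row = family.row(test_id)
    return [
        i for i in family.labelled_ids
        if i != test_id and pairwise_identity(family.row(i), test_row) <= mttsi
    ]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def macro_f(true: list[str], pred: list[str]) -> tuple[float, float, float]:
    """Class-averaged precision, recall, and their harmonic mean (F).

    Per-class precision is defined as 0 when the class is never predicted.
    Classes are those occurring among the true labels.
    """
    if len(true) != len(pred):
        raise ValueError("label vectors differ in length")
    if not true:
        raise ValueError("empty label vectors")
    classes = sorted(set(true))
    precisions, recalls = [], []
    for c in classes:
        tp = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    p = float(np.mean(precisions))
    r = float(np.mean(recalls))
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


# ---------------------------------------------------------------------------
# configuration and report containers
# ---------------------------------------------------------------------------

@dataclass
class CvConfig:
    """Nested-CV protocol parameters.

    ``kernels`` lists the candidate kernels considered during inner model
    selection (each with concrete parameters); ``c_grid`` is the soft-margin
    grid.  ``seed`` fixes the inner-fold shuffling.
    """

    mttsi: float = 1.0
    inner_folds: int = 5
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    kernels: tuple[KernelSpec, ...] = (KernelSpec("string"),)
    seed: int = 42
    inner_metric: str = "accuracy"  # or "macro_f"

    def __post_init__(self) -> None:
        if not 0 < self.mttsi <= 1:
            raise ValueError("mttsi must lie in (0, 1]")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValueError("C grid must be non-empty and positive")
        self.kernels = tuple(
            k if isinstance(k, KernelSpec) else KernelSpec(k)
            for k in self.kernels
        )
        if self.inner_metric not in ("accuracy", "macro_f"):
            raise ValueError("inner_metric must be 'accuracy' or 'macro_f'")


@dataclass
class CvPoint:
    id: str
    true: str
    pred: str | None
    chosen_C: float | None
    chosen_kernel: str | None
    train_size: int
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class CvReport:
    points: list[CvPoint]
    per_class: dict[str, tuple[float, float]]
    macro_precision: float
    macro_recall: float
    f_measure: float
    mttsi: float
    n_skipped: int

    @property
    def accuracy(self) -> float:
        scored = [p for p in self.points if not p.skipped]
        if not scored:
            return float("nan")
        return sum(p.pred == p.true for p in scored) / len(scored)

    def to_dict(self) -> dict:
        return {
            "mttsi": self.mttsi,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "f_measure": self.f_measure,
            "accuracy": self.accuracy,
            "n_points": len(self.points),
            "n_skipped": self.n_skipped,
            "per_class": {
                c: {"precision": p, "recall": r}
                for c, (p, r) in self.per_class.items()
            },
            "points": [
                {
                    "id": p.id, "true": p.true, "pred": p.pred,
                    "chosen_C": p.chosen_C, "chosen_kernel": p.chosen_kernel,
                    "train_size": p.train_size, "skipped": p.skipped,
                    "skip_reason": p.skip_reason,
                }
                for p in self.points
            ],
        }

    def to_tsv(self) -> str:
        lines = ["id\ttrue\tpredicted\tchosen_C\tchosen_kernel\ttrain_size\tskipped"]
        for p in self.points:
            lines.append(
                f"{p.id}\t{p.true}\t{p.pred or ''}\t{p.chosen_C or ''}\t"
                f"{p.chosen_kernel or ''}\t{p.train_size}\t{int(p.skipped)}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# one-vs-one fit/predict on precomputed Gram subsets
# ---------------------------------------------------------------------------

def _ovo_predict(
    gram_full: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    C: float,
) -> list[str]:
    """Train pairwise SVMs on ``train_idx`` and vote-predict ``test_idx``.

    Class pairs missing from the training set are skipped (their votes are
    omitted).  Voting and tie-breaking match :class:`ascsite.svm.AscClassifier`.
    """
    classes = sorted(set(y[train_idx]))
    votes = np.zeros((len(test_idx), len(classes)))
    support = np.zeros((len(test_idx), len(classes)))
    cls_index = {c: i for i, c in enumerate(classes)}
    y_train = y[train_idx]
    for a, b in combinations(classes, 2):
        sub = train_idx[(y_train == a) | (y_train == b)]
        y_num = np.where(y[sub] == b, 1, -1)
        if len(set(y_num)) < 2:
            continue
        svc = SVC(kernel="precomputed", C=C)
        svc.fit(gram_full[np.ix_(sub, sub)], y_num)
        d = svc.decision_function(gram_full[np.ix_(test_idx, sub)])
        for i, v in enumerate(np.atleast_1d(d)):
            winner = b if v > 0 else a
            votes[i, cls_index[winner]] += 1
            support[i, cls_index[winner]] += abs(v)
    out = []
    for v, s in zip(votes, support):
        best = np.flatnonzero(v == v.max())
        if len(best) > 1:
            sb = s[best]
            best = best[np.flatnonzero(sb == sb.max())]
        out.append(classes[best[0]])
    return out


def _inner_select(
    grams: dict[str, np.ndarray],
    y: np.ndarray,
    pool: np.ndarray,
    config: CvConfig,
) -> tuple[KernelSpec, float]:
    """Pick (kernel, C) by stratified k-fold accuracy on the retained pool.

    Ties go to the smallest C, then to kernel order as listed in the config.
    Pools too small to stratify fall back to the first kernel and the
    smallest C in the grid.
    """
    y_pool = y[pool]
    _, counts = np.unique(y_pool, return_counts=True)
    k = min(config.inner_folds, int(counts.min()))
    fallback = (config.kernels[0], min(config.c_grid))
    if k < 2 or len(counts) < 2:
        return fallback
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(len(pool)), y_pool))
    best = None  # (score, C, kernel_index)
    for ki, spec in enumerate(config.kernels):
        g = grams[spec.label()]
        for C in config.c_grid:
            scores = []
            for tr, te in folds:
                tr_idx, te_idx = pool[tr], pool[te]
                if len(set(y[tr_idx])) < 2:
                    continue
                pred = _ovo_predict(g, y, tr_idx, te_idx, C)
                true = list(y[te_idx])
                if config.inner_metric == "macro_f":
                    scores.append(macro_f(true, pred)[2])
                else:
                    scores.append(np.mean([p == t for p, t in zip(pred, true)]))
            if not scores:
                continue
            score = float(np.mean(scores))
            cand = (score, -C, -ki)
            if best is None or (score, -C, -ki) > best[0]:
                best = (cand, spec, C)
    if best is None:
        return fallback
    return best[1], best[2]


# ---------------------------------------------------------------------------
# the nested protocol
# ---------------------------------------------------------------------------

def nested_cv(
    items: list[str],
    ids: list[str],
    labels: dict[str, str],
    config: CvConfig,
    identity_rows: list[str] | None = None,
) -> CvReport:
    """Leave-one-out outer loop with MTTSI filtering and inner model selection.

    ``items`` are the objects the kernels see (signatures, or full MSA rows
    for the ``rbf_msa`` kernel); ``identity_rows`` are the full MSA rows used
    for the identity filter and default to ``items``.
    """
    if identity_rows is None:
        identity_rows = items
    if len(items) != len(ids) or len(identity_rows) != len(ids):
        raise ValueError("items, ids and identity_rows must align")
    labelled = [i for i, sid in enumerate(ids) if sid in labels]
    if len({labels[ids[i]] for i in labelled}) < 2:
        raise ValueError("need at least 2 classes among labelled sequences")

    y = np.array([labels.get(sid, "") for sid in ids], dtype=object)
    ident = identity_matrix(list(identity_rows))
    grams = {
        spec.label(): gram(list(ids), list(items), spec).values
        for spec in config.kernels
    }

    points: list[CvPoint] = []
    for i in labelled:
        pool = np.array(
            [j for j in labelled if j != i and ident[j, i] <= config.mttsi],
            dtype=int,
        )
        true = str(y[i])
        if len(pool) == 0 or len(set(y[pool])) < 2:
            reason = ("training pool empty after MTTSI filter"
                      if len(pool) == 0 else
                      "single class left after MTTSI filter")
            points.append(CvPoint(ids[i], true, None, None, None,
                                  len(pool), skipped=True, skip_reason=reason))
            continue
        spec, C = _inner_select(grams, y, pool, config)
        pred = _ovo_predict(grams[spec.label()], y, pool,
                            np.array([i]), C)[0]
        points.append(CvPoint(ids[i], true, str(pred), C, spec.label(),
                              len(pool)))

    return _report_from_points(points, config.mttsi)


def _report_from_points(points: list[CvPoint], mttsi: float) -> CvReport:
    scored = [p for p in points if not p.skipped]
    if scored:
        true = [p.true for p in scored]
        pred = [p.pred for p in scored]
        mp, mr, f = macro_f(true, pred)
        classes = sorted(set(true))
        per_class = {}
        for c in classes:
            tp = sum(1 for p in scored if p.true == c and p.pred == c)
            fp = sum(1 for p in scored if p.true != c and p.pred == c)
            fn = sum(1 for p in scored if p.true == c and p.pred != c)
            per_class[c] = (
                tp / (tp + fp) if tp + fp else 0.0,
                tp / (tp + fn) if tp + fn else 0.0,
            )
    else:
        mp = mr = f = float("nan")
        per_class = {}
    return CvReport(
        points=points, per_class=per_class,
        macro_precision=mp, macro_recall=mr, f_measure=f,
        mttsi=mttsi, n_skipped=sum(p.skipped for p in points),
    )


def nested_cv_signatures(signature_set, family: LabelledFamily,
                         config: CvConfig) -> CvReport:
    """Run the nested protocol on signatures, with identity on full rows."""
    ids = list(signature_set.ids)
    items = [signature_set.signature(i) for i in ids]
    rows = [family.row(i) for i in ids]
    return nested_cv(items, ids, signature_set.labels, config,
                     identity_rows=rows)


def loo_nn1(family: LabelledFamily, mttsi: float) -> CvReport:
    """1-NN baseline under the same leave-one-out MTTSI-filtered splits."""
    from .svm import NearestMismatchClassifier

    ids = family.labelled_ids
    ident = identity_matrix(family.rows)
    pos = {sid: family.ids.index(sid) for sid in family.ids}
    points: list[CvPoint] = []
    for sid in ids:
        pool = [
            j for j in ids
            if j != sid and ident[pos[j], pos[sid]] <= mttsi
        ]
        true = family.labels[sid]
        if not pool:
            points.append(CvPoint(sid, true, None, None, None, 0,
                                  skipped=True,
                                  skip_reason="training pool empty after MTTSI filter"))
            continue
        clf = NearestMismatchClassifier()
        clf.fit([family.row(j) for j in pool],
                [family.labels[j] for j in pool], ids=pool)
        pred = str(clf.predict([family.row(sid)])[0])
        points.append(CvPoint(sid, true, pred, None, "nn1", len(pool)))
    return _report_from_points(points, mttsi)


def benchmark(
    family: LabelledFamily,
    signature_set,
    config: CvConfig,
    msa_kernels: tuple[KernelSpec, ...] | None = None,
) -> dict:
    """Compare ASC, 1-NN and the full-MSA SVM on identical splits.

    Each classifier family is evaluated once per candidate kernel and the
    best F-measure is marked, mirroring a report-the-best-model protocol.
    """
    from dataclasses import replace

    width = family.width
    if msa_kernels is None:
        msa_kernels = default_rbf_specs(width)

    asc_reports = {
        spec.label(): nested_cv_signatures(
            signature_set, family, replace(config, kernels=(spec,))
        )
        for spec in config.kernels
    }
    msa_config = replace(config, kernels=tuple(msa_kernels))
    rows = [family.row(i) for i in signature_set.ids]
    msa_report = nested_cv(rows, list(signature_set.ids),
                           signature_set.labels, msa_config)
    nn_report = loo_nn1(family, config.mttsi)

    best_asc = max(asc_reports, key=lambda k: asc_reports[k].f_measure)
    return {
        "asc": asc_reports,
        "asc_best_kernel": best_asc,
        "asc_f": asc_reports[best_asc].f_measure,
        "msa": msa_report,
        "msa_f": msa_report.f_measure,
        "nn1": nn_report,
        "nn1_f": nn_report.f_measure,
    }


def default_rbf_specs(width: int) -> tuple[KernelSpec, ...]:
    """Candidate gamma values for the full-MSA RBF kernel, scaled so that
    typical squared distances (order of the alignment width) stay resolved."""
    return tuple(
        KernelSpec("rbf_msa", gamma=g / max(width, 1))
        for g in (0.25, 1.0, 4.0)
    )
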
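"""Kernel-SVM classifiers over active-site signatures, plus the 1-NN baseline.

The central estimator is :class:`AscClassifier`, a one-vs-one multiclass
soft-margin SVM whose inputs are signature strings (or full MSA rows for the
``rbf_msa`` kernel).  One binary SVM is trained per unordered class pair on
that pair's data only; at prediction time every pairwise model casts a vote
and the class with the most votes wins.  Ties are broken by the larger sum
of absolute decision values supporting a tied class, then lexicographically.

The binary subproblems are solved with libsvm (via scikit-learn's ``SVC`` on
a precomputed Gram matrix), an exact soft-margin dual solver; the dual
coefficients, bias and support identities are exposed so Karush-Kuhn-Tucker
conditions can be verified and models serialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._alphabet import encode_rows
from .kernels import KernelSpec, cross_gram, gram


@dataclass
class BinarySvm:
    """A trained soft-margin binary SVM in dual form.

    ``dual_coef[i]`` is ``alpha_i * y_i`` for support item ``i``; the
    decision value of an item ``x`` is ``sum_i dual_coef[i] * k(s_i, x) + bias``
    with positive values voting for ``classes[1]``.
    """

    classes: tuple[str, str]  # (negative, positive), lexicographic order
    support_ids: list[str]
    support_items: list[str]
    dual_coef: np.ndarray
    bias: float
    C: float
    kernel: KernelSpec

    def decision_values(self, items: list[str]) -> np.ndarray:
        k = cross_gram(self.support_items, list(items), self.kernel)
        return self.dual_coef @ k + self.bias

    def predict(self, items: list[str]) -> list[str]:
        d = self.decision_values(items)
        return [self.classes[1] if v > 0 else self.classes[0] for v in d]


def train_binary(
    items: list[str],
    ids: list[str],
    y: list[str],
    kernel: KernelSpec,
    C: float = 1.0,
    gram_values: np.ndarray | None = None,
) -> BinarySvm:
    """Solve one soft-margin dual SVM on a PSD kernel matrix.

    ``y`` holds exactly two distinct class names; the lexicographically
    smaller one is mapped to -1.  Deterministic for fixed inputs.
    """
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if C <= 0:
        raise ValueError("C must be positive")
    if gram_values is None:
        gram_values = gram(ids, items, kernel).values
    if np.allclose(gram_values, 0):
        raise ValueError("degenerate all-zero Gram matrix")
    y_num = np.array([1 if c == classes[1] else -1 for c in y])
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(gram_values, y_num)
    sup = svc.support_
    return BinarySvm(
        classes=(classes[0], classes[1]),
        support_ids=[ids[i] for i in sup],
        support_items=[items[i] for i in sup],
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        kernel=kernel,
    )


class AscClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-one multiclass kernel SVM on active-site signatures.

    Parameters
    ----------
    kernel : str
        One of ``string``, ``blosum``, ``chemical``, ``wold`` (signature
        scope) or ``rbf_msa`` (full-MSA scope).
    C : float
        Soft-margin regularization weight shared by all pairwise models.
    gamma : float, optional
        Width of the ``rbf_msa`` kernel; ignored otherwise.

    Attributes
    ----------
    classes_ : ndarray of class names (sorted).
    pairwise_models_ : dict mapping class pairs to :class:`BinarySvm`.
    """

    def __init__(self, kernel: str = "string", C: float = 1.0,
                 gamma: float | None = None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    # -- sklearn plumbing ---------------------------------------------------

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        return KernelSpec(self.kernel, gamma=self.gamma)

    def fit(self, X, y, ids: list[str] | None = None,
            require_pair_minimum: bool = True) -> "AscClassifier":
        """Train one binary SVM per unordered class pair.

        ``X`` is a sequence of equal-length signature strings (or MSA rows).
        ``require_pair_minimum`` enforces >= 2 members per class, the
        contract for standalone training; the cross-validation driver
        relaxes it for small inner folds.
        """
        X = list(X)
        y = list(map(str, y))
        if len(X) != len(y):
            raise ValueError("X and y differ in length")
        if ids is None:
            ids = [f"item{i}" for i in range(len(X))]
        ids = list(ids)
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to train")
        if require_pair_minimum:
            counts = {c: y.count(c) for c in classes}
            small = [c for c, n in counts.items() if n < 2]
            if small:
                raise ValueError(
                    f"classes with fewer than 2 labelled signatures: {small}"
                )
        spec = self._spec()
        full = gram(ids, X, spec).values
        self.classes_ = np.array(classes)
        self.pairwise_models_ = {}
        y_arr = np.array(y)
        for a, b in combinations(classes, 2):
            idx = np.flatnonzero((y_arr == a) | (y_arr == b))
            self.pairwise_models_[(a, b)] = train_binary(
                [X[i] for i in idx],
                [ids[i] for i in idx],
                [y[i] for i in idx],
                spec,
                C=self.C,
                gram_values=full[np.ix_(idx, idx)],
            )
        self.n_features_in_ = len(X[0]) if X else 0
        return self

    def _check_lengths(self, X: list[str]) -> None:
        for x in X:
            if len(x) != self.n_features_in_:
                raise ValueError(
                    f"item length {len(x)} does not match the model's "
                    f"signature length {self.n_features_in_}"
                )

    def vote_matrix(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (votes, support) arrays of shape (n_items, n_classes).

        ``votes`` counts pairwise wins per class; ``support`` accumulates
        the absolute decision values behind those wins (used only to break
        vote ties).
        """
        check_is_fitted(self, "pairwise_models_")
        X = list(X)
        self._check_lengths(X)
        n, k = len(X), len(self.classes_)
        cls_index = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((n, k))
        support = np.zeros((n, k))
        for (a, b), model in self.pairwise_models_.items():
            d = model.decision_values(X)
            for i, v in enumerate(d):
                winner = b if v > 0 else a
                votes[i, cls_index[winner]] += 1
                support[i, cls_index[winner]] += abs(v)
        return votes, support

    def predict(self, X) -> np.ndarray:
        """Majority vote over pairwise models with deterministic tie-breaks."""
        votes, support = self.vote_matrix(X)
        out = []
        for v, s in zip(votes, support):
            best = np.flatnonzero(v == v.max())
            if len(best) > 1:
                sb = s[best]
                best = best[np.flatnonzero(sb == sb.max())]
            # classes_ is sorted, so the first index is the lexicographic tie-break
            out.append(self.classes_[best[0]])
        return np.array(out)

    def predict_with_votes(self, X):
        votes, _ = self.vote_matrix(X)
        return self.predict(X), votes

    # -- serialization ------------------------------------------------------

    def attach_metadata(self, definition=None, guide=None) -> "AscClassifier":
        """Attach the signature definition and guide alignment needed to
        predict raw (unaligned) sequences; both are serialized with the model."""
        if definition is not None:
            self.definition_ = definition
        if guide is not None:
            self.guide_ = guide
        return self

    def predict_raw(self, sequences: list[str]):
        """Align raw sequences to the stored guide MSA and predict.

        Requires ``attach_metadata`` (or a model file) to have supplied the
        guide alignment and signature definition.
        """
        from .site import align_to_guide

        if getattr(self, "guide_", None) is None or \
                getattr(self, "definition_", None) is None:
            raise ValueError(
                "model carries no guide alignment / signature definition; "
                "predict on pre-extracted signatures instead"
            )
        cols = self.definition_.columns
        sigs = []
        for seq in sequences:
            row = align_to_guide(self.guide_, seq)
            sigs.append("".join(row[c] for c in cols))
        return self.predict(sigs), sigs

    def to_dict(self) -> dict:
        check_is_fitted(self, "pairwise_models_")
        spec = self._spec()
        out = self._core_dict(spec)
        if getattr(self, "definition_", None) is not None:
            from .io import definition_to_dict

            out["definition"] = definition_to_dict(self.definition_)
        if getattr(self, "guide_", None) is not None:
            g = self.guide_
            out["guide"] = {
                "ids": list(g.ids),
                "rows": list(g.rows),
                "template_id": g.template_id,
            }
        return out

    def _core_dict(self, spec: KernelSpec) -> dict:
        return {
            "format_version": 1,
            "kernel": {"name": spec.name, "gamma": spec.gamma},
            "C": self.C,
            "classes": list(self.classes_),
            "signature_length": self.n_features_in_,
            "pairwise": [
                {
                    "classes": list(m.classes),
                    "support_ids": m.support_ids,
                    "support_items": m.support_items,
                    "dual_coef": [float(v) for v in m.dual_coef],
                    "bias": m.bias,
                }
                for m in self.pairwise_models_.values()
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AscClassifier":
        model = cls._from_core_dict(payload)
        if "definition" in payload:
            from .io import definition_from_dict

            model.definition_ = definition_from_dict(payload["definition"])
        if "guide" in payload:
            from .io import LabelledFamily

            g = payload["guide"]
            model.guide_ = LabelledFamily(
                ids=list(g["ids"]), rows=list(g["rows"]), labels={},
                template_id=g.get("template_id"),
            )
        return model

    @classmethod
    def _from_core_dict(cls, payload: dict) -> "AscClassifier":
        spec = KernelSpec(payload["kernel"]["name"],
                          gamma=payload["kernel"].get("gamma"))
        model = cls(kernel=spec.name, C=payload["C"], gamma=spec.gamma)
        model.classes_ = np.array(payload["classes"])
        model.n_features_in_ = payload["signature_length"]
        model.pairwise_models_ = {}
        for m in payload["pairwise"]:
            a, b = m["classes"]
            model.pairwise_models_[(a, b)] = BinarySvm(
                classes=(a, b),
                support_ids=list(m["support_ids"]),
                support_items=list(m["support_items"]),
                dual_coef=np.asarray(m["dual_coef"], dtype=float),
                bias=float(m["bias"]),
                C=payload["C"],
                kernel=spec,
            )
        return model


def train_multiclass(signature_set, spec: KernelSpec, C: float = 1.0) -> AscClassifier:
    """Train an :class:`AscClassifier` from a signature set (thin wrapper)."""
    ids = [i for i in signature_set.ids if i in signature_set.labels]
    items = [signature_set.signature(i) for i in ids]
    y = [signature_set.labels[i] for i in ids]
    clf = AscClassifier(kernel=spec.name, C=C, gamma=spec.gamma)
    clf.fit(items, y, ids=ids)
    return clf


class NearestMismatchClassifier(BaseEstimator, ClassifierMixin):
    """1-nearest-neighbour baseline on full MSA rows.

    The distance between two enzymes is the number of mismatching columns
    of their aligned sequences: columns where both rows are gapped are
    skipped, a gap against a residue counts as a mismatch.  Ties are broken
    by the smaller mismatch count, then by lexicographic training id.
    """

    def __init__(self):
        pass

    def fit(self, X, y, ids: list[str] | None = None) -> "NearestMismatchClassifier":
        X = list(X)
        y = list(map(str, y))
        if not X:
            raise ValueError("no labelled training rows")
        if ids is None:
            ids = [f"item{i}" for i in range(len(X))]
        # store in lexicographic-id order so argmin resolves ties by id
        order = sorted(range(len(X)), key=lambda i: ids[i])
        self.ids_ = [ids[i] for i in order]
        self.rows_ = [X[i] for i in order]
        self.y_ = [y[i] for i in order]
        # raw characters, not the kernel encoding: 'X' is a symbol here and
        # only counts as a match against another 'X'
        self.chars_ = np.array([list(r) for r in self.rows_])
        self.classes_ = np.unique(self.y_)
        return self

    def mismatch_counts(self, row: str) -> np.ndarray:
        check_is_fitted(self, "chars_")
        if len(row) != self.chars_.shape[1]:
            raise ValueError("row width does not match training rows")
        c = np.array(list(row))
        both_gap = (self.chars_ == "-") & (c[None, :] == "-")
        return ((self.chars_ != c[None, :]) & ~both_gap).sum(axis=1)

    def predict(self, X) -> np.ndarray:
        return np.array([self.y_[int(np.argmin(self.mismatch_counts(r)))]
                         for r in X])


def nn1_predict(rows: list[str], ids: list[str], labels: dict[str, str],
                test_row: str) -> str:
    """Predict the label of ``test_row`` by nearest mismatch distance."""
    train = [(i, r) for i, r in zip(ids, rows) if i in labels]
    if not train:
        raise ValueError("no labelled training rows")
    clf = NearestMismatchClassifier()
    clf.fit([r for _, r in train], [labels[i] for i, _ in train],
            ids=[i for i, _ in train])
    return str(clf.predict([test_row])[0])
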
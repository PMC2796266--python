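"""Signature encodings and kernel functions.

Four kernels operate on active-site signatures (equal-length strings over
the amino-acid alphabet plus gap/``X``):

* ``string`` — counts exactly matching, informative symbols.
* ``blosum`` — sums, over aligned positions, the joint substitution
  probability recovered from the BLOSUM62 log-odds matrix.
* ``chemical`` — the same positionwise construction with the McLachlan
  chemical similarity matrix (AAindex MCLA720101).
* ``wold`` — the dot product of the signatures embedded with the
  3-descriptor z-scales (hydrophobicity, size, electronic properties);
  gaps embed as three zeros.

A fifth kernel, ``rbf_msa``, is a Gaussian kernel on one-hot encoded full
MSA rows and serves as the whole-alignment comparator.  All signature
kernels are positive semi-definite by construction: the substitution
matrices are projected onto the PSD cone (eigenvalue clipping) before use
and carry a certificate; string and Wold kernels are explicit dot products.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._alphabet import AA20, NULL_IDX, encode, encode_rows
from .io import SubstitutionMatrix, load_background_frequencies, load_matrix, load_wold_table

SIGNATURE_KERNELS = ("string", "blosum", "chemical", "wold")
ALL_KERNELS = SIGNATURE_KERNELS + ("rbf_msa",)


@dataclass(frozen=True)
class KernelSpec:
    """A kernel choice plus its parameters.

    ``rbf_msa`` operates on full MSA rows (scope ``full_msa``); all other
    kernels operate on extracted signatures (scope ``signature``).
    """

    name: str
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ALL_KERNELS:
            raise ValueError(
                f"unknown kernel {self.name!r}; choose from {ALL_KERNELS}"
            )
        if self.name == "rbf_msa" and self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @property
    def scope(self) -> str:
        return "full_msa" if self.name == "rbf_msa" else "signature"

    def label(self) -> str:
        if self.name == "rbf_msa" and self.gamma is not None:
            return f"rbf_msa(gamma={self.gamma:g})"
        return self.name


@dataclass
class GramMatrix:
    ids: list[str]
    values: np.ndarray
    kernel: KernelSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("Gram matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("Gram matrix is not symmetric")


# ---------------------------------------------------------------------------
# matrix preparation
# ---------------------------------------------------------------------------

def psd_project(matrix: SubstitutionMatrix, tol: float = 1e-6,
                renormalize: bool = False) -> SubstitutionMatrix:
    """Clip negative eigenvalues to zero and certify the result as PSD.

    Matrices within ``-tol`` of PSD are certified unchanged.  ``renormalize``
    rescales a probability matrix so its entries again sum to 1 after
    clipping.
    """
    vals = matrix.values
    w, v = np.linalg.eigh(vals)
    if w.min() >= -tol:
        out = vals
    else:
        w_clipped = np.clip(w, 0.0, None)
        out = (v * w_clipped) @ v.T
        out = (out + out.T) / 2.0
        if renormalize and out.sum() > 0:
            out = out / out.sum()
    result = SubstitutionMatrix(
        alphabet=matrix.alphabet, values=out, name=matrix.name
    )
    result.psd_certified = True
    return result


def blosum_to_substitution_probabilities(
    log_odds: SubstitutionMatrix,
    backgrounds: dict[str, float] | None = None,
    scale: float = 2.0,
) -> SubstitutionMatrix:
    """Invert a log-odds matrix to joint substitution probabilities.

    BLOSUM matrices are published as log-odds ``B(a,b) = s*log2(q(a,b) /
    (p(a)p(b)))`` rounded to integers (``s = 2`` for the half-bit BLOSUM62).
    This recovers ``q(a,b) = p(a) p(b) 2^(B(a,b)/s)``, renormalizes the
    entries to sum to one, and projects onto the PSD cone so the positionwise
    substitution kernel is a valid Mercer kernel.
    """
    if backgrounds is None:
        backgrounds = load_background_frequencies()
    p = np.array([backgrounds[a] for a in log_odds.alphabet], dtype=float)
    if (p <= 0).any():
        raise ValueError("background frequencies must be positive")
    p = p / p.sum()
    q = np.outer(p, p) * np.power(2.0, log_odds.values / scale)
    q = (q + q.T) / 2.0
    q = q / q.sum()
    out = SubstitutionMatrix(log_odds.alphabet, q, name=f"{log_odds.name}:probabilities")
    return psd_project(out, renormalize=True)


@lru_cache(maxsize=None)
def _prepared_q(kind: str) -> SubstitutionMatrix:
    if kind == "blosum":
        return blosum_to_substitution_probabilities(load_matrix("BLOSUM62"))
    if kind == "chemical":
        return psd_project(load_matrix("MCLA720101"))
    raise ValueError(kind)


def _q21(q: SubstitutionMatrix) -> np.ndarray:
    """Extend a 20x20 residue matrix with a zero row/col for gap/unknown."""
    if not q.psd_certified:
        raise ValueError(
            f"matrix {q.name!r} lacks a PSD certificate; run psd_project first"
        )
    m = q.reordered(AA20).values
    out = np.zeros((21, 21))
    out[:20, :20] = m
    return out


@lru_cache(maxsize=None)
def _wold21() -> np.ndarray:
    """(21, 3) descriptor table; row 20 (gap/X) is all zeros."""
    table = load_wold_table()
    out = np.zeros((21, 3))
    for i, aa in enumerate(AA20):
        out[i] = table[aa]
    return out


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------

def encode_wold(signature: str) -> np.ndarray:
    """Embed a signature as the concatenation of (z1, z2, z3) per position.

    Gaps and unknown residues are encoded by three zeros.
    """
    codes = encode(signature)
    return _wold21()[codes].ravel()


def encode_onehot(signature: str, dims: int = 20) -> np.ndarray:
    """Per-position one-hot embedding; gap/X rows are all-zero when
    ``dims == 20`` and occupy their own channel when ``dims == 21``."""
    codes = encode(signature)
    out = np.zeros((len(codes), dims))
    for i, c in enumerate(codes):
        if c < dims:
            out[i, c] = 1.0
    return out.ravel()


# ---------------------------------------------------------------------------
# pairwise kernels
# ---------------------------------------------------------------------------

def _check_equal(s1: str, s2: str) -> None:
    if len(s1) != len(s2):
        raise ValueError(
            f"signatures differ in length ({len(s1)} vs {len(s2)})"
        )


def kernel_string(s1: str, s2: str) -> float:
    """Count positions with identical informative symbols (gap/X excluded)."""
    _check_equal(s1, s2)
    c1, c2 = encode(s1), encode(s2)
    return float(np.sum((c1 == c2) & (c1 != NULL_IDX)))


def kernel_substitution(s1: str, s2: str, q: SubstitutionMatrix) -> float:
    """Sum PSD-certified substitution-matrix values over aligned positions.

    Positions where either symbol is a gap or ``X`` contribute zero (their
    indicator embedding is the zero vector).
    """
    _check_equal(s1, s2)
    q21 = _q21(q)
    c1, c2 = encode(s1), encode(s2)
    return float(q21[c1, c2].sum())


def kernel_blosum(s1: str, s2: str) -> float:
    """Substitution kernel with the BLOSUM62-derived probability matrix."""
    return kernel_substitution(s1, s2, _prepared_q("blosum"))


def kernel_chemical(s1: str, s2: str) -> float:
    """Substitution kernel with the PSD-projected McLachlan matrix."""
    return kernel_substitution(s1, s2, _prepared_q("chemical"))


def kernel_wold(s1: str, s2: str) -> float:
    """Dot product of the z-scale embeddings of two signatures."""
    _check_equal(s1, s2)
    return float(encode_wold(s1) @ encode_wold(s2))


def kernel_rbf_msa(row1: str, row2: str, gamma: float) -> float:
    """Gaussian kernel on one-hot encoded full MSA rows.

    Each column is embedded one-hot over the 21 symbols {20 residues, gap}
    (``X`` shares the gap channel), so the squared distance is twice the
    number of differing columns.
    """
    _check_equal(row1, row2)
    c1, c2 = encode(row1), encode(row2)
    d2 = 2.0 * float(np.sum(c1 != c2))
    return float(np.exp(-gamma * d2))


def kernel_function(spec: KernelSpec):
    """Return the pairwise kernel ``k(a, b)`` for a spec."""
    if spec.name == "string":
        return kernel_string
    if spec.name == "blosum":
        return kernel_blosum
    if spec.name == "chemical":
        return kernel_chemical
    if spec.name == "wold":
        return kernel_wold
    if spec.name == "rbf_msa":
        if spec.gamma is None:
            raise ValueError("rbf_msa kernel requires gamma")
        return lambda a, b: kernel_rbf_msa(a, b, spec.gamma)
    raise ValueError(spec.name)


# ---------------------------------------------------------------------------
# vectorized Gram computation
# ---------------------------------------------------------------------------

def cross_gram(items_a: list[str], items_b: list[str],
               spec: KernelSpec) -> np.ndarray:
    """Kernel matrix between two item lists (rows: a, columns: b)."""
    if not items_a or not items_b:
        return np.zeros((len(items_a), len(items_b)))
    ca = encode_rows(list(items_a))
    cb = encode_rows(list(items_b))
    if ca.shape[1] != cb.shape[1]:
        raise ValueError("item sets differ in width")

    if spec.name == "string":
        ea = _onehot_matrix(ca)
        eb = _onehot_matrix(cb)
        return ea @ eb.T
    if spec.name in ("blosum", "chemical"):
        q21 = _q21(_prepared_q(spec.name))
        out = np.zeros((len(ca), len(cb)))
        for col in range(ca.shape[1]):
            out += q21[np.ix_(ca[:, col], cb[:, col])]
        return out
    if spec.name == "wold":
        wa = _wold21()[ca].reshape(len(ca), -1)
        wb = _wold21()[cb].reshape(len(cb), -1)
        return wa @ wb.T
    if spec.name == "rbf_msa":
        if spec.gamma is None:
            raise ValueError("rbf_msa kernel requires gamma")
        ham = (ca[:, None, :] != cb[None, :, :]).sum(axis=2)
        return np.exp(-spec.gamma * 2.0 * ham)
    raise ValueError(spec.name)


def _onehot_matrix(codes: np.ndarray) -> np.ndarray:
    n, width = codes.shape
    out = np.zeros((n, width * 20))
    rows, cols = np.nonzero(codes != NULL_IDX)
    out[rows, cols * 20 + codes[rows, cols]] = 1.0
    return out


def gram(ids: list[str], items: list[str], spec: KernelSpec) -> GramMatrix:
    """Symmetric kernel matrix over a list of signatures or MSA rows."""
    if len(ids) != len(items):
        raise ValueError("ids and items differ in length")
    try:
        values = cross_gram(items, items, spec)
    except ValueError as exc:
        raise ValueError(f"kernel failed on items {ids}: {exc}") from exc
    values = (values + values.T) / 2.0
    return GramMatrix(ids=list(ids), values=values, kernel=spec)
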
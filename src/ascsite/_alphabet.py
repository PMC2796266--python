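"""Amino-acid alphabet and integer encodings shared across the package.

Signatures and MSA rows are strings over the 20 standard one-letter amino
acid codes plus ``-`` (gap) and ``X`` (unknown residue).  For numerical work
they are encoded as ``int8`` arrays with residues at 0..19 in alphabetical
order and both ``-`` and ``X`` mapped to the sentinel index 20: neither
carries evidence, and every kernel and identity computation treats them as
contributing nothing.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"
#: sentinel index for gap/unknown in encoded arrays
NULL_IDX: int = 20

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AA20):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord(GAP)] = NULL_IDX
_CODE[ord(UNKNOWN)] = NULL_IDX
_CODE[ord("x")] = NULL_IDX

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: het-group names never treated as part of the active site
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as an int8 array (residues 0..19, gap/X -> 20).

    Raises
    ------
    ValueError
        If the string contains a character outside the legal alphabet;
        the message names the first offending position.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(
            f"illegal character {seq[pos]!r} at position {pos}; "
            f"legal symbols are the 20 amino acids, '-' and 'X'"
        )
    return codes


def encode_rows(rows: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, width) int8 matrix."""
    if not rows:
        return np.zeros((0, 0), dtype=np.int8)
    width = len(rows[0])
    out = np.empty((len(rows), width), dtype=np.int8)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"row {i} has length {len(row)}, expected {width}"
            )
        out[i] = encode(row)
    return out
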
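"""Shared amino-acid alphabet constants and integer encoding."""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"  # ambiguous residue; never matches a fixed motif position
GAP = "-"

#: residues legal in an unaligned sequence
SEQ_ALPHABET = frozenset(AA20 + UNKNOWN)
#: residues legal in an alignment row
ALN_ALPHABET = frozenset(AA20 + UNKNOWN + GAP)

N_CODES = 21  # 20 residues + X
X_CODE = 20

_INDEX = {aa: i for i, aa in enumerate(AA20)}
_INDEX[UNKNOWN] = X_CODE

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _aa, _i in _INDEX.items():
    _LOOKUP[ord(_aa)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 codes (0-19 residues, 20 = X).

    Raises ValueError naming the first illegal character (1-based position).
    """
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LOOKUP[np.minimum(raw, 127)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"illegal residue {residues[pos]!r} at position {pos + 1}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join((AA20 + UNKNOWN)[c] for c in codes)
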
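"""Amino-acid alphabet and symbol normalization.

The 20 canonical residues are encoded 0..19 in alphabetical one-letter
order; ``MISSING`` (gap ``-``, ``?`` and ``X``) is encoded 20.  Ambiguity
and non-standard codes (B, Z, J, U, O) are mapped to MISSING with a
logged warning.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_STATES: int = 20
MISSING: int = 20
MISSING_SYMBOLS = frozenset("-?X")
AMBIGUOUS_SYMBOLS = frozenset("BZJUO")

_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# symbol -> code lookup over the full byte range; -1 marks illegal symbols
_LUT = np.full(256, -1, dtype=np.int16)
for _aa, _i in _CODE_OF.items():
    _LUT[ord(_aa)] = _i
    _LUT[ord(_aa.lower())] = _i
for _s in MISSING_SYMBOLS:
    _LUT[ord(_s)] = MISSING
_LUT[ord("x")] = MISSING
for _s in AMBIGUOUS_SYMBOLS:
    _LUT[ord(_s)] = MISSING
    _LUT[ord(_s.lower())] = MISSING


def encode_sequence(seq: str, *, where: str = "") -> np.ndarray:
    """Encode a residue string to a uint8 code vector.

    Raises :class:`~biasdiag.errors.FormatError` naming the offending
    position for any symbol outside the normalized alphabet.
    """
    from .errors import FormatError

    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LUT[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        col = int(bad[0])
        raise FormatError(
            f"illegal residue character {seq[col]!r} at column {col + 1}"
            + (f" in {where}" if where else "")
        )
    ambiguous = [c for c in set(seq.upper()) & AMBIGUOUS_SYMBOLS]
    if ambiguous:
        logger.warning(
            "ambiguity codes %s mapped to MISSING%s",
            sorted(ambiguous),
            f" in {where}" if where else "",
        )
    return codes.astype(np.uint8)


def decode_row(row: np.ndarray, missing_char: str = "-") -> str:
    """Decode a code vector back to a residue string."""
    table = AMINO_ACIDS + missing_char
    return "".join(table[c] for c in row)
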
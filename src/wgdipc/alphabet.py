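"""Canonical amino-acid alphabet and dipeptide index space.

The 20 standard residues are fixed in alphabetical one-letter order so that
feature indices and column names are reproducible across runs and tools.
An ordered residue pair (a, b) maps to column ``20 * idx(a) + idx(b)``;
gapped pairs share the same 400-name space as adjacent pairs.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
DIPEPTIDES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
DIPEPTIDE_TO_INDEX: dict[str, int] = {d: i for i, d in enumerate(DIPEPTIDES)}
N_DIPEPTIDES: int = len(DIPEPTIDES)  # 400

# byte -> residue code lookup; -1 marks a non-canonical character
_CODE_LUT = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_TO_INDEX.items():
    _CODE_LUT[ord(_aa)] = _i


def encode_residues(sequence: str) -> np.ndarray:
    """Map a validated sequence to integer residue codes in [0, 20).

    Raises
    ------
    ValueError
        If the sequence contains a character outside the canonical alphabet.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"non-canonical residue {bad!r} in sequence")
    return codes


def dipeptide_index(pair: str) -> int:
    """Column index of an ordered residue pair such as ``'AC'``."""
    try:
        return DIPEPTIDE_TO_INDEX[pair.upper()]
    except KeyError:
        raise ValueError(f"not a canonical dipeptide: {pair!r}") from None
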
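"""Alphabets and index maps shared across the package.

Substrate side: the 20 standard amino acids plus ``x`` (unknown / chain
terminus padding), 21 symbols.  Domain side: the 20 amino acids plus the
alignment gap ``~``, 21 symbols.  All matrices in the package use these
fixed orders, with the phosphosite window spanning offsets −7..+7.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, in fixed alphabetical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Substrate alphabet: amino acids followed by the unknown symbol 'x'.
SUBSTRATE_ALPHABET: str = AMINO_ACIDS + "x"

#: Internal gap symbol for aligned catalytic domains ('-' is accepted on input).
GAP: str = "~"

#: Domain alphabet: amino acids followed by the gap symbol.
DOMAIN_ALPHABET: str = AMINO_ACIDS + GAP

N_SUBSTRATE: int = len(SUBSTRATE_ALPHABET)  # 21
N_DOMAIN: int = len(DOMAIN_ALPHABET)  # 21

#: Offset labels of a phosphosite region; the acceptor sits at offset 0.
OFFSETS: tuple[int, ...] = tuple(range(-7, 8))
N_OFFSETS: int = len(OFFSETS)  # 15
REGION_LENGTH: int = 15

#: Residues that can accept a phosphate (the window center).
ACCEPTORS: str = "STY"

SUBSTRATE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SUBSTRATE_ALPHABET)}
DOMAIN_INDEX: dict[str, int] = {c: i for i, c in enumerate(DOMAIN_ALPHABET)}
GAP_CODE: int = DOMAIN_INDEX[GAP]
X_CODE: int = SUBSTRATE_INDEX["x"]

#: FASTA ambiguity codes that map to 'x' on the substrate side.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BZUOXJ")


def offset_to_col(offset: int) -> int:
    """Map an offset label in −7..+7 to a 0-based matrix column."""
    if not -7 <= offset <= 7:
        raise ValueError(f"offset {offset} outside -7..+7")
    return offset + 7


def col_to_offset(col: int) -> int:
    """Map a 0-based matrix column to its offset label."""
    if not 0 <= col < N_OFFSETS:
        raise ValueError(f"column {col} outside 0..14")
    return col - 7


def encode_substrate(symbols: str) -> np.ndarray:
    """Encode a substrate-alphabet string as integer codes."""
    try:
        return np.fromiter(
            (SUBSTRATE_INDEX[c] for c in symbols), dtype=np.intp, count=len(symbols)
        )
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"symbol {exc.args[0]!r} not in substrate alphabet") from None


def encode_domain(symbols: str) -> np.ndarray:
    """Encode a gapped domain string as integer codes ('-' aliases to '~')."""
    try:
        return np.fromiter(
            (DOMAIN_INDEX[GAP if c == "-" else c] for c in symbols),
            dtype=np.intp,
            count=len(symbols),
        )
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in domain alphabet") from None
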
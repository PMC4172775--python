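"""Kozak coordinate conventions.

Positions are numbered the way the motif literature numbers them: +1 is the A
of the ATG start codon, upstream bases count -1, -2, ... and there is no
position 0.  A window spanning ``upstream`` bases of 5'UTR, the start codon
and ``downstream`` CDS bases therefore covers positions
``-upstream .. -1, +1 .. +3+downstream``.
"""

from __future__ import annotations

from typing import Sequence

START_CODON_POSITIONS: tuple[int, int, int] = (1, 2, 3)


def window_positions(upstream: int = 9, downstream: int = 3) -> tuple[int, ...]:
    """Ordered Kozak positions of an extraction window (default -9..-1, +1..+6)."""
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    return tuple(range(-upstream, 0)) + tuple(range(1, 4 + downstream))


def position_index(position: int, upstream: int = 9) -> int:
    """0-based index of a Kozak position within a window string."""
    if position == 0:
        raise ValueError("there is no Kozak position 0")
    if position < 0:
        idx = position + upstream
        if idx < 0:
            raise ValueError(f"position {position} outside a window with upstream={upstream}")
        return idx
    return upstream + position - 1


def parse_position_list(text: str) -> tuple[int, ...]:
    """Parse a comma-separated position list such as ``-4,-3,-2,-1,+4,+5``."""
    out = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        out.append(int(tok))
    if 0 in out:
        raise ValueError("there is no Kozak position 0")
    return tuple(out)


def is_contiguous(positions: Sequence[int]) -> bool:
    """True when the positions form a gap-free run in Kozak numbering (0 skipped)."""
    ordered = sorted(positions)
    for a, b in zip(ordered, ordered[1:]):
        step = b - a
        if a < 0 < b:
            step -= 1  # numbering jumps -1 -> +1
        if step != 1:
            return False
    return True
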
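"""Extraction of translation-initiation-site (TIS) windows from transcripts.

The window covers ``upstream`` bases of 5'UTR, the annotated start codon and
``downstream`` CDS bases after it (default -9..+6, a 15-mer).  A transcript
whose annotation cannot yield a clean full-length ATG window is *rejected*,
not silently dropped: rejections are data and carry a reason, so downstream
counts always balance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .io import TranscriptRecord

UNAMBIGUOUS = frozenset("ACGT")


class RejectionReason(str, enum.Enum):
    NONE = "none"
    SHORT_UTR = "short_utr"
    SHORT_CDS_TAIL = "short_cds_tail"
    NON_ATG_START = "non_atg_start"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True)
class TISWindow:
    """One transcript's initiation context.

    ``window`` is the extracted nucleotide string (full length only when
    ``accepted``); index ``upstream`` holds the A of the start codon.
    """

    transcript_id: str
    window: str
    accepted: bool
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.accepted != (self.rejection_reason is RejectionReason.NONE):
            raise ValueError("rejection_reason must be 'none' iff accepted")

    def variable_subsequence(self, positions: tuple[int, ...], upstream: int = 9) -> str:
        """Bases of this window at the given Kozak positions, in the given order."""
        from .positions import position_index

        return "".join(self.window[position_index(p, upstream)] for p in positions)


def extract_tis_window(
    record: "TranscriptRecord", upstream: int = 9, downstream: int = 3
) -> TISWindow:
    """Extract the -upstream..+(3+downstream) context around a transcript's start codon.

    Rejection checks apply in a fixed precedence: insufficient 5'UTR, then
    insufficient CDS tail, then a non-ATG annotated codon, then any IUPAC
    ambiguity code inside the window.  Ambiguity outside the window never
    matters.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    seq = record.sequence
    start = record.cds_start  # 0-based index of the A of the annotated codon

    def reject(reason: RejectionReason, window: str = "") -> TISWindow:
        return TISWindow(record.id, window, accepted=False, rejection_reason=reason)

    if start < upstream:
        return reject(RejectionReason.SHORT_UTR)
    if len(seq) - start < 3 + downstream:
        return reject(RejectionReason.SHORT_CDS_TAIL)
    window = seq[start - upstream : start + 3 + downstream]
    if window[upstream : upstream + 3] != "ATG":
        return reject(RejectionReason.NON_ATG_START, window)
    if not UNAMBIGUOUS.issuperset(window):
        return reject(RejectionReason.AMBIGUOUS_BASE, window)
    return TISWindow(record.id, window, accepted=True)


def window_tally(windows) -> dict[str, int]:
    """Count windows by status; keys are 'accepted' plus each rejection reason seen."""
    out: dict[str, int] = {"accepted": 0}
    for w in windows:
        if w.accepted:
            out["accepted"] += 1
        else:
            key = w.rejection_reason.value
            out[key] = out.get(key, 0) + 1
    return out
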
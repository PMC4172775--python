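"""Comparative scoring of initiation contexts and transcriptome breakdown.

A sequence over the *variable* positions (the significant context positions
minus the invariant ATG; six positions -4..-1, +4, +5 in zebrafish) is scored
by summing, position by position, the population frequency (in percent) of the
base it carries.  The score therefore rewards sequences built from the bases
the transcriptome itself favours; its maximum is attained by the string of
per-position modal bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .positions import START_CODON_POSITIONS, position_index
from .profile import PositionFrequencyMatrix
from .windows import TISWindow

DEFAULT_VARIABLE_POSITIONS = (-4, -3, -2, -1, 4, 5)


@dataclass(frozen=True)
class VariablePositionSet:
    """Ordered Kozak positions used for scoring; never the ATG itself."""

    positions: tuple[int, ...] = DEFAULT_VARIABLE_POSITIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if any(p in START_CODON_POSITIONS or p == 0 for p in self.positions):
            raise ValueError("variable positions exclude the start codon (+1..+3) and 0")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate positions")

    @property
    def k(self) -> int:
        return len(self.positions)

    def render_with_atg(self, variable_seq: str) -> str:
        """Interleave ATG into a variable-position string for display.

        ``AAACGC`` over positions (-4,-3,-2,-1,+4,+5) renders as ``AAACATGGC``.
        """
        if len(variable_seq) != self.k:
            raise ValueError("sequence length does not match position set")
        by_pos = dict(zip(self.positions, variable_seq))
        out = []
        for p in sorted(set(self.positions) | set(START_CODON_POSITIONS)):
            out.append({1: "A", 2: "T", 3: "G"}.get(p) or by_pos[p])
        return "".join(out)


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def score_sequence(
    seq: str,
    pfm: PositionFrequencyMatrix,
    positions: VariablePositionSet | Sequence[int] = DEFAULT_VARIABLE_POSITIONS,
    scale: str = "exact_percent",
) -> float:
    """Frequency-sum comparative score of a variable-position sequence.

    ``integer_percent`` rounds each percent half-up before summing, which is
    how scores read off a printed integer frequency table add up.
    """
    vps = positions if isinstance(positions, VariablePositionSet) else VariablePositionSet(tuple(positions))
    if len(seq) != vps.k:
        raise ValueError(f"sequence length {len(seq)} != {vps.k} variable positions")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over A/C/G/T")
    if scale not in ("exact_percent", "integer_percent"):
        raise ValueError(f"unknown scale {scale!r}")
    total = 0.0
    for p, base in zip(vps.positions, seq):
        pct = pfm.percent(p, base)
        total += _round_half_up(pct) if scale == "integer_percent" else pct
    return total


def enumerate_possible(
    positions: VariablePositionSet | Sequence[int] | int, materialize: bool = False
):
    """Number (and optionally lexicographic list) of possible variable sequences."""
    if isinstance(positions, int):
        k = positions
    elif isinstance(positions, VariablePositionSet):
        k = positions.k
    else:
        k = VariablePositionSet(tuple(positions)).k
    count = 4**k
    if not materialize:
        return count
    from itertools import product

    return count, ["".join(t) for t in product("ACGT", repeat=k)]


@dataclass(frozen=True)
class ScoredSequence:
    """One distinct variable-position sequence observed in the window set."""

    sequence: str          # variable positions only, e.g. "AAACGC"
    rendered: str          # with ATG interleaved, e.g. "AAACATGGC"
    score: float
    count: int
    rel_freq: float


def tabulate_observed(
    windows: Iterable[TISWindow],
    positions: VariablePositionSet | Sequence[int] = DEFAULT_VARIABLE_POSITIONS,
    pfm: PositionFrequencyMatrix | None = None,
    upstream: int = 9,
    scale: str = "exact_percent",
) -> list[ScoredSequence]:
    """Tally and score every distinct variable-position sequence observed.

    Sorted by descending count, ties by descending score, then alphabetically
    — a deterministic ranking suitable for export.
    """
    vps = positions if isinstance(positions, VariablePositionSet) else VariablePositionSet(tuple(positions))
    accepted = [w for w in windows if getattr(w, "accepted", True)]
    if not accepted:
        raise ValueError("no accepted windows")
    if pfm is None:
        pfm = PositionFrequencyMatrix.from_windows(accepted, upstream=upstream)
    counts: dict[str, int] = {}
    for w in accepted:
        s = getattr(w, "window", w)
        var = "".join(s[position_index(p, upstream)] for p in vps.positions)
        counts[var] = counts.get(var, 0) + 1
    n = len(accepted)
    tally = [
        ScoredSequence(
            sequence=var,
            rendered=vps.render_with_atg(var),
            score=score_sequence(var, pfm, vps, scale=scale),
            count=c,
            rel_freq=c / n,
        )
        for var, c in counts.items()
    ]
    tally.sort(key=lambda s: (-s.count, -s.score, s.sequence))
    return tally


@dataclass(frozen=True)
class TranscriptomeBreakdown:
    """Distribution summary of the observed initiation sequences."""

    n_windows: int
    n_possible: int
    n_observed: int
    n_rare: int            # distinct sequences with rel_freq <= rare threshold
    top_cover_count: int   # fewest top sequences whose cumulative rel_freq >= 0.5
    top_decile_cover: float  # cumulative rel_freq of the top ceil(10% of observed)


def breakdown(
    tally: Sequence[ScoredSequence],
    positions: VariablePositionSet | Sequence[int] = DEFAULT_VARIABLE_POSITIONS,
    rare_threshold: float = 0.001,
) -> TranscriptomeBreakdown:
    if not tally:
        raise ValueError("empty tally")
    vps = positions if isinstance(positions, VariablePositionSet) else VariablePositionSet(tuple(positions))
    n_windows = sum(s.count for s in tally)
    rel = np.array([s.count for s in tally], dtype=float) / n_windows
    cum = np.cumsum(rel)  # tally is already rank-ordered
    top_cover_count = int(np.searchsorted(cum, 0.5 - 1e-12) + 1)
    n_decile = math.ceil(0.10 * len(tally))
    return TranscriptomeBreakdown(
        n_windows=n_windows,
        n_possible=4**vps.k,
        n_observed=len(tally),
        n_rare=int((rel <= rare_threshold + 1e-15).sum()),
        top_cover_count=top_cover_count,
        top_decile_cover=float(cum[n_decile - 1]),
    )


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of frequency = a * exp(b * score) in log space.

    ``points`` holds one (median score, occurrence count) pair per frequency
    group — the distinct sequences sharing an occurrence count.
    """

    a: float
    b: float
    points: tuple[tuple[float, float], ...]
    r_squared_log: float

    def predict(self, score: float) -> float:
        return self.a * math.exp(self.b * score)


def fit_score_frequency(tally: Sequence[ScoredSequence]) -> ExponentialFit:
    """Fit the score-vs-frequency exponential trend over frequency groups.

    Distinct sequences are grouped by raw occurrence count; each group
    contributes (median score, count).  The fit is ordinary least squares of
    log(count) on median score.
    """
    groups: dict[int, list[float]] = {}
    for s in tally:
        groups.setdefault(s.count, []).append(s.score)
    if len(groups) < 2:
        raise ValueError("insufficient frequency groups")
    points = tuple(
        (float(np.median(scores)), float(count))
        for count, scores in sorted(groups.items())
    )
    x = np.array([p[0] for p in points])
    y = np.log([p[1] for p in points])
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return ExponentialFit(a=float(np.exp(log_a)), b=float(b), points=points, r_squared_log=r2)


def write_ranked_list(tally: Sequence[ScoredSequence], path) -> None:
    """Ranked-list export: sequence, variable_sequence, score, count, rel_freq, rank."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "sequence": [s.rendered for s in tally],
            "variable_sequence": [s.sequence for s in tally],
            "score": [s.score for s in tally],
            "count": [s.count for s in tally],
            "rel_freq": [s.rel_freq for s in tally],
            "rank": range(1, len(tally) + 1),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
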
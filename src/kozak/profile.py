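"""Position frequency matrices, positional selection tests and consensus calling.

The neutral expectation at every position is an even 25:25:25:25 base
composition, the genome-wide background reported for the broad neighbourhood
of vertebrate transcription start sites.  Two tests are used against it:

* a 3-df Pearson chi-square per position (is the whole composition skewed?),
  used to flag positions under selection;
* a one-sided exact binomial on the modal base (is the most prevalent base
  above 25%?), used when calling a consensus letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
from scipy import stats

from .positions import START_CODON_POSITIONS, position_index, window_positions

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_START_BASE = {1: "A", 2: "T", 3: "G"}


class PositionFrequencyMatrix:
    """Per-position base counts and exact percent frequencies over aligned windows.

    ``counts`` has shape ``(len(positions), 4)`` in A, C, G, T order and sums
    to ``n`` at every position.  Percents are kept exact; rounding to the
    integers shown in published frequency tables happens only on export.
    """

    def __init__(self, positions: Sequence[int], counts, n: int | float):
        self.positions = tuple(int(p) for p in positions)
        self.counts = np.asarray(counts, dtype=float)
        self.n = n
        if self.counts.shape != (len(self.positions), 4):
            raise ValueError("counts must be (n_positions, 4)")
        if n <= 0:
            raise ValueError("n must be positive")
        if not np.allclose(self.counts.sum(axis=1), n, rtol=0, atol=1e-6):
            raise ValueError("counts at every position must sum to n")
        self._index = {p: i for i, p in enumerate(self.positions)}

    # -- construction -------------------------------------------------------
    @classmethod
    def from_windows(cls, windows: Iterable, upstream: int = 9) -> "PositionFrequencyMatrix":
        """Tally accepted windows (TISWindow objects or plain strings)."""
        ws = list(windows)
        if any(not getattr(w, "accepted", True) for w in ws):
            raise ValueError("only accepted windows can enter a frequency matrix")
        strings = [getattr(w, "window", w) for w in ws]
        if not strings:
            raise ValueError("no accepted windows")
        length = len(strings[0])
        if any(len(s) != length for s in strings):
            raise ValueError("all windows must have the same length")
        arr = np.frombuffer("".join(strings).encode(), dtype=np.uint8).reshape(len(strings), length)
        counts = np.zeros((length, 4), dtype=float)
        for b, j in _BASE_INDEX.items():
            counts[:, j] = (arr == ord(b)).sum(axis=0)
        if not np.all(counts.sum(axis=1) == len(strings)):
            raise ValueError("windows contain non-ACGT characters")
        downstream = length - upstream - 3
        return cls(window_positions(upstream, downstream), counts, len(strings))

    @classmethod
    def from_probabilities(
        cls, pwm: Mapping[int, Sequence[float]], n: int | float = 10_000
    ) -> "PositionFrequencyMatrix":
        """Expected-count matrix of a generative PWM (start codon filled as ATG).

        Counts are the exact expectations ``n * p`` and may be fractional.
        Useful for deterministic scoring against a known composition.
        """
        all_pos = sorted(set(pwm) | set(START_CODON_POSITIONS))
        counts = np.zeros((len(all_pos), 4), dtype=float)
        for i, p in enumerate(all_pos):
            if p in START_CODON_POSITIONS:
                counts[i, _BASE_INDEX[_START_BASE[p]]] = n
            else:
                vec = np.asarray(pwm[p], dtype=float)
                if vec.shape != (4,) or vec.min() < 0 or abs(vec.sum() - 1) > 1e-12:
                    raise ValueError(f"position {p}: probabilities must be a 4-vector summing to 1")
                counts[i] = vec * n
        return cls(all_pos, counts, n)

    # -- accessors -----------------------------------------------------------
    @property
    def percents(self) -> np.ndarray:
        return self.counts / self.n * 100.0

    def row(self, position: int) -> np.ndarray:
        try:
            return self.counts[self._index[position]]
        except KeyError:
            raise KeyError(f"position {position} not in matrix") from None

    def percent(self, position: int, base: str) -> float:
        return float(self.row(position)[_BASE_INDEX[base]] / self.n * 100.0)

    def modal_base(self, position: int) -> str:
        """Most frequent base at a position; ties break alphabetically."""
        return BASES[int(np.argmax(self.row(position)))]

    # -- export --------------------------------------------------------------
    def to_frame(self, integer_percents: bool = False):
        import pandas as pd

        vals = self.percents.T
        if integer_percents:
            vals = np.floor(vals + 0.5)
        return pd.DataFrame(vals, index=list(BASES), columns=list(self.positions))

    def to_tsv(self, path, integer_percents: bool = False) -> None:
        self.to_frame(integer_percents).to_csv(path, sep="\t", index_label="base")

    def to_json(self, path=None) -> str:
        payload = {
            "positions": list(self.positions),
            "n": self.n,
            "counts": {b: self.counts[:, j].tolist() for b, j in _BASE_INDEX.items()},
            "percents": {b: self.percents[:, j].tolist() for b, j in _BASE_INDEX.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PositionFrequencyMatrix":
        with open(path) as fh:
            payload = json.load(fh)
        counts = np.column_stack([payload["counts"][b] for b in BASES])
        return cls(payload["positions"], counts, payload["n"])


def build_pfm(windows: Iterable, upstream: int = 9) -> PositionFrequencyMatrix:
    """Build a :class:`PositionFrequencyMatrix` from accepted windows."""
    ws = [w for w in windows]
    accepted = [w for w in ws if getattr(w, "accepted", True)]
    if not accepted:
        raise ValueError("no accepted windows")
    return PositionFrequencyMatrix.from_windows(accepted, upstream=upstream)


# ---------------------------------------------------------------------------
# Positional bias


@dataclass(frozen=True)
class PositionalBiasResult:
    """Chi-square (3 df) of one position's composition against 25:25:25:25."""

    position: int
    statistic: float
    p_value: float
    significant: bool


def positional_chi_square(
    pfm: PositionFrequencyMatrix, position: int, alpha: float = 0.03
) -> PositionalBiasResult:
    """Pearson chi-square of observed counts vs the even expectation n/4.

    No continuity correction; the p-value is the chi-square upper tail at
    3 degrees of freedom.
    """
    obs = pfm.row(position)
    expected = pfm.n / 4.0
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=3))
    return PositionalBiasResult(position, statistic, p_value, p_value < alpha)


def positional_bias(pfm: PositionFrequencyMatrix, alpha: float = 0.03) -> list[PositionalBiasResult]:
    return [positional_chi_square(pfm, p, alpha=alpha) for p in pfm.positions]


def significant_positions(
    results: Iterable[PositionalBiasResult], alpha: float = 0.03
) -> tuple[int, ...]:
    """Positions with p < alpha, in genomic order; the ATG positions always count."""
    results = list(results)
    flagged = {r.position for r in results if r.p_value < alpha}
    flagged.update(r.position for r in results if r.position in START_CODON_POSITIONS)
    return tuple(sorted(flagged))


# ---------------------------------------------------------------------------
# Consensus


@dataclass(frozen=True)
class ConsensusCall:
    """Per-position consensus letters and the Table-style rendered string.

    A position gets a letter only when its modal base is significantly above
    the 25% background; the letter is lowercased when the runner-up base is
    within ``near_tie_margin`` percent points of the modal base.  ``rendered``
    spans the maximal contiguous run of lettered positions containing ATG.
    """

    letters: dict[int, str] = field(default_factory=dict)
    rules: dict[int, str] = field(default_factory=dict)
    rendered: str = ""


def _modal_significance(counts: np.ndarray, n: int | float, mode: str, alpha: float) -> bool:
    modal = int(np.argmax(counts))
    k = counts[modal]
    if mode == "binomial":
        # One-sided exact binomial: P(X >= k) under p=0.25.
        p = float(stats.binom.sf(np.ceil(k) - 1, int(round(n)), 0.25))
        return p < alpha
    if mode == "chi_square":
        expected = n / 4.0
        statistic = float(((counts - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(statistic, df=3))
        return p < alpha and k / n > 0.25
    raise ValueError(f"unknown consensus mode {mode!r}")


def call_consensus(
    pfm: PositionFrequencyMatrix,
    alpha: float = 0.05,
    near_tie_margin: float = 5.0,
    mode: str = "binomial",
) -> ConsensusCall:
    letters: dict[int, str] = {}
    rules: dict[int, str] = {}
    for p in pfm.positions:
        if p in START_CODON_POSITIONS:
            letters[p] = _START_BASE[p]
            rules[p] = "fixed_start_codon"
            continue
        counts = pfm.row(p)
        if not _modal_significance(counts, pfm.n, mode, alpha):
            rules[p] = "not_significant"
            continue
        order = np.argsort(counts)[::-1]
        modal_pct = counts[order[0]] / pfm.n * 100.0
        runner_pct = counts[order[1]] / pfm.n * 100.0
        letter = BASES[int(order[0])]
        if modal_pct - runner_pct <= near_tie_margin:
            letters[p] = letter.lower()
            rules[p] = "near_tie"
        else:
            letters[p] = letter
            rules[p] = "dominant"
    rendered = _render_block(pfm.positions, letters)
    return ConsensusCall(letters=letters, rules=rules, rendered=rendered)


def _render_block(positions: Sequence[int], letters: Mapping[int, str]) -> str:
    """Maximal contiguous lettered run containing the start codon."""
    ordered = sorted(positions)
    anchor = ordered.index(1)
    lo = anchor
    while lo > 0 and ordered[lo - 1] in letters:
        lo -= 1
    hi = anchor + 2  # +3 is in the window whenever +1 is
    while hi + 1 < len(ordered) and ordered[hi + 1] in letters:
        hi += 1
    return "".join(letters[p] for p in ordered[lo : hi + 1])
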
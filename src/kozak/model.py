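"""Model/Results interface over the full initiation-context analysis.

``KozakContextModel`` holds the data (accepted windows plus rejection
accounting); ``fit`` runs the positional chi-square screen, the consensus
call, the comparative-score tabulation, the transcriptome breakdown and the
score-frequency exponential trend, returning a ``KozakContextResults`` with a
``summary()`` table in the style of a regression results printout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from . import io as kio
from .positions import START_CODON_POSITIONS
from .profile import (
    BASES,
    ConsensusCall,
    PositionFrequencyMatrix,
    PositionalBiasResult,
    build_pfm,
    call_consensus,
    positional_bias,
    significant_positions,
)
from .scoring import (
    DEFAULT_VARIABLE_POSITIONS,
    ExponentialFit,
    ScoredSequence,
    TranscriptomeBreakdown,
    VariablePositionSet,
    breakdown,
    fit_score_frequency,
    score_sequence,
    tabulate_observed,
)
from .windows import TISWindow, extract_tis_window, window_tally


class KozakContextModel:
    """Initiation-context model over a set of extracted TIS windows.

    Parameters
    ----------
    windows
        TIS windows (accepted and rejected); rejected windows only feed the
        accounting, never the statistics.
    upstream, downstream
        Window geometry in bases around the start codon (default -9..+6).
    variable_positions
        Positions used for comparative scoring; defaults to the six zebrafish
        variable positions -4..-1, +4, +5.
    """

    def __init__(
        self,
        windows: Iterable[TISWindow],
        upstream: int = 9,
        downstream: int = 3,
        variable_positions: Sequence[int] = DEFAULT_VARIABLE_POSITIONS,
    ):
        self.windows = list(windows)
        self.upstream = upstream
        self.downstream = downstream
        self.variable_positions = (
            variable_positions
            if isinstance(variable_positions, VariablePositionSet)
            else VariablePositionSet(tuple(variable_positions))
        )
        self.accepted = [w for w in self.windows if w.accepted]
        if not self.accepted:
            raise ValueError("no accepted windows")
        self.tally_by_status = window_tally(self.windows)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_transcripts(
        cls, records: Iterable[kio.TranscriptRecord], upstream: int = 9,
        downstream: int = 3, **kw
    ) -> "KozakContextModel":
        windows = [extract_tis_window(r, upstream, downstream) for r in records]
        return cls(windows, upstream=upstream, downstream=downstream, **kw)

    @classmethod
    def from_files(
        cls, path, format: str, gff=None, bed=None, upstream: int = 9,
        downstream: int = 3, **kw
    ) -> "KozakContextModel":
        report = kio.read_transcripts(path, format, gff=gff, bed=bed)
        model = cls.from_transcripts(report.records, upstream, downstream, **kw)
        model.load_report = report
        return model

    @property
    def nobs(self) -> int:
        return len(self.accepted)

    def fit(
        self,
        alpha_flag: float = 0.03,
        alpha_consensus: float = 0.05,
        consensus_mode: str = "binomial",
        near_tie_margin: float = 5.0,
        scale: str = "exact_percent",
        rare_threshold: float = 0.001,
    ) -> "KozakContextResults":
        pfm = build_pfm(self.accepted, upstream=self.upstream)
        bias = positional_bias(pfm, alpha=alpha_flag)
        sig = significant_positions(bias, alpha=alpha_flag)
        consensus = call_consensus(
            pfm, alpha=alpha_consensus, near_tie_margin=near_tie_margin, mode=consensus_mode
        )
        tally = tabulate_observed(
            self.accepted, self.variable_positions, pfm=pfm,
            upstream=self.upstream, scale=scale,
        )
        bdown = breakdown(tally, self.variable_positions, rare_threshold=rare_threshold)
        try:
            score_fit = fit_score_frequency(tally)
        except ValueError:
            score_fit = None  # fewer than two frequency groups
        return KozakContextResults(
            model=self,
            pfm=pfm,
            bias=tuple(bias),
            significant=sig,
            consensus=consensus,
            tally=tuple(tally),
            breakdown=bdown,
            score_fit=score_fit,
            alpha_flag=alpha_flag,
            alpha_consensus=alpha_consensus,
            scale=scale,
        )


@dataclass
class KozakContextResults:
    """Fitted initiation-context profile with diagnostics."""

    model: KozakContextModel
    pfm: PositionFrequencyMatrix
    bias: tuple[PositionalBiasResult, ...]
    significant: tuple[int, ...]
    consensus: ConsensusCall
    tally: tuple[ScoredSequence, ...]
    breakdown: TranscriptomeBreakdown
    score_fit: ExponentialFit | None
    alpha_flag: float
    alpha_consensus: float
    scale: str

    def score(self, seq: str, scale: str | None = None) -> float:
        """Comparative score of a variable-position sequence under this profile."""
        return score_sequence(
            seq, self.pfm, self.model.variable_positions, scale=scale or self.scale
        )

    def top_sequences(self, n: int = 10) -> tuple[ScoredSequence, ...]:
        return self.tally[:n]

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Kozak initiation-context profile")
        add("=" * 64)
        add(f"windows (accepted)       {self.model.nobs}")
        for status, count in sorted(self.model.tally_by_status.items()):
            if status != "accepted" and count:
                add(f"rejected: {status:<15}{count}")
        add(f"consensus                {self.consensus.rendered}")
        add(f"significant positions    {', '.join(_fmt_pos(p) for p in self.significant)}"
            f"  (alpha={self.alpha_flag})")
        add("")
        add(f"{'pos':>4} {'A%':>7} {'C%':>7} {'G%':>7} {'T%':>7} "
            f"{'chi2(3)':>9} {'p':>10} {'sig':>4} {'cons':>5}")
        by_pos = {r.position: r for r in self.bias}
        pct = self.pfm.percents
        for i, p in enumerate(self.pfm.positions):
            r = by_pos[p]
            letter = self.consensus.letters.get(p, ".")
            add(
                f"{_fmt_pos(p):>4} "
                + " ".join(f"{pct[i, j]:7.2f}" for j in range(4))
                + f" {r.statistic:9.1f} {r.p_value:10.3g} "
                + f"{'*' if r.significant or p in START_CODON_POSITIONS else '':>4} {letter:>5}"
            )
        add("")
        b = self.breakdown
        add(f"distinct sequences       {b.n_observed} of {b.n_possible} possible")
        add(f"rare (<=0.1%)            {b.n_rare}")
        add(f"top sequences for 50%    {b.top_cover_count}")
        add(f"top decile coverage      {b.top_decile_cover:.3f}")
        if self.score_fit is not None:
            f = self.score_fit
            add(f"freq ~ a*exp(b*score)    a={f.a:.4g}  b={f.b:.4g}  R2(log)={f.r_squared_log:.3f}")
        if self.tally:
            t = self.tally[0]
            add(f"most frequent            {t.rendered}  score={t.score:g}  "
                f"count={t.count} ({t.rel_freq:.2%})")
        return "\n".join(lines)


def _fmt_pos(p: int) -> str:
    return f"+{p}" if p > 0 else str(p)
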
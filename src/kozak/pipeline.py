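"""One-command pipeline: extract -> profile -> score -> breakdown -> fit.

Writes plain TSV/JSON reports plus a run manifest (package version, config
hash, per-stage record counts).  Outputs carry no timestamps, so identical
configuration and inputs reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as kio
from .model import KozakContextModel
from .scoring import DEFAULT_VARIABLE_POSITIONS, write_ranked_list

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str = ""
    input_format: str = "tsv"
    gff: str | None = None
    bed: str | None = None
    upstream: int = 9
    downstream: int = 3
    alpha_flag: float = 0.03
    alpha_consensus: float = 0.05
    consensus_mode: str = "binomial"
    near_tie_margin: float = 5.0
    variable_positions: tuple[int, ...] = DEFAULT_VARIABLE_POSITIONS
    scale: str = "exact_percent"
    rare_threshold: float = 0.001
    out_dir: str = "kozak_out"

    def __post_init__(self) -> None:
        for name in ("alpha_flag", "alpha_consensus", "rare_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("extract")
        report = kio.read_transcripts(
            config.input_path, config.input_format, gff=config.gff, bed=config.bed
        )
        model = KozakContextModel.from_transcripts(
            report.records,
            upstream=config.upstream,
            downstream=config.downstream,
            variable_positions=config.variable_positions,
        )
        kio.write_windows_tsv(model.windows, out / "windows.tsv")

        stage("profile")
        results = model.fit(
            alpha_flag=config.alpha_flag,
            alpha_consensus=config.alpha_consensus,
            consensus_mode=config.consensus_mode,
            near_tie_margin=config.near_tie_margin,
            scale=config.scale,
            rare_threshold=config.rare_threshold,
        )
        results.pfm.to_tsv(out / "matrix.tsv")
        results.pfm.to_json(out / "matrix.json")
        with open(out / "bias.tsv", "w") as fh:
            fh.write("position\tstatistic\tp_value\tsignificant\n")
            for r in results.bias:
                fh.write(f"{r.position}\t{r.statistic:.10g}\t{r.p_value:.10g}\t{r.significant}\n")
        with open(out / "consensus.json", "w") as fh:
            json.dump(
                {
                    "rendered": results.consensus.rendered,
                    "letters": {str(p): l for p, l in sorted(results.consensus.letters.items())},
                    "rules": {str(p): r for p, r in sorted(results.consensus.rules.items())},
                    "significant_positions": list(results.significant),
                },
                fh, indent=2,
            )
            fh.write("\n")

        stage("score")
        write_ranked_list(results.tally, out / "ranked.tsv")

        stage("breakdown")
        with open(out / "breakdown.json", "w") as fh:
            json.dump(dataclasses.asdict(results.breakdown), fh, indent=2)
            fh.write("\n")

        stage("fit")
        fit_payload = (
            None
            if results.score_fit is None
            else {
                "a": results.score_fit.a,
                "b": results.score_fit.b,
                "r_squared_log": results.score_fit.r_squared_log,
                "points": [list(p) for p in results.score_fit.points],
            }
        )
        with open(out / "fit.json", "w") as fh:
            json.dump(fit_payload, fh, indent=2)
            fh.write("\n")
    except Exception as exc:  # annotate which stage died, then re-raise
        raise RuntimeError(f"pipeline failed at stage {_current_stage(exc)}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "counts": {
            "input_records": len(report.records),
            "skipped_on_load": report.n_skipped,
            **model.tally_by_status,
            "distinct_sequences": results.breakdown.n_observed,
        },
        "consensus": results.consensus.rendered,
        "significant_positions": list(results.significant),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _current_stage(exc: Exception) -> str:
    # best-effort stage attribution from the traceback's module names
    import traceback

    for frame in reversed(traceback.extract_tb(exc.__traceback__)):
        name = Path(frame.filename).stem
        if name in ("io", "windows"):
            return "extract"
        if name == "profile":
            return "profile"
        if name == "scoring":
            return "score"
    return "unknown"
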
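"""Synthetic RefSeq-like transcriptomes with a configurable initiation context.

Each transcript is a 5'UTR, an ATG-initiated CDS and a 3'UTR sampled from a
uniform (configurable) background, with position-specific base probabilities
injected into the -9..-1 and +4..+6 context from a position weight matrix
(PWM).  The generator returns both the records and a per-transcript truth
object, so every downstream stage — extraction, matrix building, testing,
tabulation — can be checked against known ground truth without any external
data.

The ``zebrafish_like_pwm`` preset places the published zebrafish modal
percents (35, 62, 39, 36, 46, 42) on A, A, A, C at -4..-1 and G, C at +4, +5,
spreading the remainder evenly over the other three bases; every other
position, including +6 (for which no modal percent is published), is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np

from .io import TranscriptRecord
from .profile import BASES
from .windows import RejectionReason

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)

PWM_POSITIONS = tuple(range(-9, 0)) + (4, 5, 6)


def _validate_probvec(name: str, vec) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (4,) or arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities must be a non-negative 4-vector summing to 1")
    return arr


def uniform_pwm() -> dict[int, np.ndarray]:
    return {p: np.full(4, 0.25) for p in PWM_POSITIONS}


def zebrafish_like_pwm() -> dict[int, np.ndarray]:
    """PWM preset reproducing the zebrafish context's modal frequencies."""
    pwm = uniform_pwm()
    modal = {-4: ("A", 0.35), -3: ("A", 0.62), -2: ("A", 0.39),
             -1: ("C", 0.36), 4: ("G", 0.46), 5: ("C", 0.42)}
    for pos, (base, p) in modal.items():
        vec = np.full(4, (1.0 - p) / 3.0)
        vec[BASES.index(base)] = p
        pwm[pos] = vec
    return pwm


PWM_PRESETS = {"uniform": uniform_pwm, "zebrafish": zebrafish_like_pwm}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic transcriptome.

    Lengths are sampled uniformly over inclusive ranges; ``cds_codons`` counts
    codons including the ATG and the +4..+6 codon.  A single global seed
    drives one reproducible stream; each transcript gets a deterministic
    substream so changing ``n_transcripts`` never reshuffles earlier records.
    """

    n_transcripts: int = 1000
    pwm: Mapping[int, Sequence[float]] = field(default_factory=zebrafish_like_pwm)
    utr5_length: tuple[int, int] = (9, 120)
    cds_codons: tuple[int, int] = (30, 300)
    utr3_length: tuple[int, int] = (20, 200)
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        self.pwm = {int(p): _validate_probvec(f"pwm[{p}]", v) for p, v in self.pwm.items()}
        missing = set(PWM_POSITIONS) - set(self.pwm)
        if missing:
            raise ValueError(f"pwm missing positions {sorted(missing)}")
        self.background = _validate_probvec("background", self.background)
        for name in ("utr5_length", "cds_codons", "utr3_length"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        if self.cds_codons[0] < 2:
            raise ValueError("cds_codons must be >= 2 (ATG plus the +4..+6 codon)")


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    window: str              # the realised -9..+6 context (truncated if UTR < 9)
    utr5_length: int
    cds_length: int          # in bases
    utr3_length: int
    accepted: bool           # expected outcome of default 15-mer extraction
    rejection_reason: RejectionReason


@dataclass(frozen=True)
class SyntheticTruth:
    transcripts: tuple[TranscriptTruth, ...]
    pwm: dict[int, tuple[float, ...]]

    def accepted_windows(self) -> list[str]:
        return [t.window for t in self.transcripts if t.accepted]

    def to_json(self, path) -> None:
        payload = {
            "pwm": {str(p): list(v) for p, v in self.pwm.items()},
            "transcripts": [
                {
                    "transcript_id": t.transcript_id,
                    "window": t.window,
                    "utr5_length": t.utr5_length,
                    "cds_length": t.cds_length,
                    "utr3_length": t.utr3_length,
                    "accepted": t.accepted,
                    "rejection_reason": t.rejection_reason.value,
                }
                for t in self.transcripts
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _sample_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    if n == 0:
        return ""
    return _BASE_ARR[rng.choice(4, size=n, p=probs)].tobytes().decode()


def generate_transcriptome(
    config: GeneratorConfig,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Sample a synthetic transcriptome and its ground truth."""
    records: list[TranscriptRecord] = []
    truths: list[TranscriptTruth] = []
    base_seed = config.seed % (2**31)
    for i in range(config.n_transcripts):
        rng = np.random.default_rng([base_seed, i])
        utr5_len = int(rng.integers(config.utr5_length[0], config.utr5_length[1] + 1))
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        utr3_len = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))

        upstream_ctx = "".join(
            _sample_bases(rng, 1, config.pwm[p]) for p in range(-9, 0)
        )
        second_codon = "".join(_sample_bases(rng, 1, config.pwm[p]) for p in (4, 5, 6))

        n_up = min(9, utr5_len)
        utr5 = _sample_bases(rng, utr5_len - n_up, config.background)
        utr5 += upstream_ctx[9 - n_up :]
        cds = "ATG" + second_codon + _sample_bases(rng, 3 * (n_codons - 2), config.background)
        utr3 = _sample_bases(rng, utr3_len, config.background)

        tid = f"NM_SYN{i + 1:06d}"
        records.append(
            TranscriptRecord(tid, utr5 + cds + utr3, cds_start=utr5_len, source_format="tsv")
        )
        window = upstream_ctx[9 - n_up :] + cds[:6]
        if utr5_len < 9:
            accepted, reason = False, RejectionReason.SHORT_UTR
        else:
            accepted, reason = True, RejectionReason.NONE
        truths.append(
            TranscriptTruth(tid, window, utr5_len, 3 * n_codons, utr3_len, accepted, reason)
        )
    truth = SyntheticTruth(
        transcripts=tuple(truths),
        pwm={p: tuple(v) for p, v in config.pwm.items()},
    )
    return records, truth


def sample_windows(
    pwm: Mapping[int, Sequence[float]], n: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Vectorised sampler of full 15-mer windows straight from a PWM.

    Equivalent to generating transcripts and extracting, minus the background
    sequence; intended for statistical experiments at large n.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = []
    for p in tuple(range(-9, 0)) + (1, 2, 3) + (4, 5, 6):
        if p in (1, 2, 3):
            ch = {1: "A", 2: "T", 3: "G"}[p]
            cols.append(np.full(n, ord(ch), dtype=np.uint8))
        else:
            probs = _validate_probvec(f"pwm[{p}]", pwm[p])
            cols.append(_BASE_ARR[rng.choice(4, size=n, p=probs)])
    arr = np.column_stack(cols)
    return [row.tobytes().decode() for row in arr]


# ---------------------------------------------------------------------------
# Writers (all readable by kozak.io.read_transcripts)


def write_tsv(records: Sequence[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# transcript_id\tsequence\tcds_start (1-based first base of start codon)\n")
        for r in records:
            fh.write(f"{r.id}\t{r.sequence}\t{r.cds_start + 1}\n")


def write_fasta_gff(records: Sequence[TranscriptRecord], fasta_path, gff_path) -> None:
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            # CDS runs from the start codon to the end of the coding part; for
            # windowing only its start matters, so extend to sequence end.
            fh.write(
                f"{r.id}\tkozak_sim\tCDS\t{r.cds_start + 1}\t{len(r.sequence)}\t.\t+\t0\t"
                f"ID=cds-{r.id}\n"
            )


def write_genbank(records: Sequence[TranscriptRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    seq_records = []
    for r in records:
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.id,
            name=r.id[:16],
            description="synthetic mRNA",
            annotations={"molecule_type": "mRNA", "date": "01-JAN-2000"},
        )
        rec.features.append(
            SeqFeature(FeatureLocation(r.cds_start, len(r.sequence), strand=1), type="CDS")
        )
        seq_records.append(rec)
    from Bio import SeqIO

    SeqIO.write(seq_records, str(path), "genbank")
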
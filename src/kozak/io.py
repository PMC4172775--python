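"""Readers and writers for annotated mRNA records and extracted windows.

Supported inputs
----------------
``tsv``
    ``transcript_id<TAB>sequence<TAB>cds_start`` with ``#`` comment header;
    ``cds_start`` is 1-based (the first base of the start codon).
``fasta+gff``
    Transcript FASTA plus a GFF3 whose CDS features use the transcript id as
    seqid (1-based inclusive coordinates, strand-aware).
``fasta+bed``
    Transcript FASTA plus BED6 (0-based half-open, strand-aware); the interval
    is the CDS span on each transcript.
``genbank``
    GenBank flat files with CDS features.

All coordinates are normalised to a single internal convention: a 0-based
offset of the first base of the start codon on the sense strand.  Minus-strand
CDS annotations are handled by reverse-complementing the stored sequence, so
every :class:`TranscriptRecord` is conceptually an mRNA read 5'->3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

from .windows import TISWindow, RejectionReason

logger = logging.getLogger(__name__)

FORMATS = ("tsv", "fasta+gff", "fasta+bed", "genbank")

# Full IUPAC nucleotide alphabet accepted on input; windows themselves must be
# unambiguous, which extraction enforces.
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA sequence with a resolved start-codon offset (0-based, sense strand)."""

    id: str
    sequence: str
    cds_start: int
    source_format: str = "tsv"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(f"{self.id}: non-nucleotide characters {sorted(bad)}")
        if not 0 <= self.cds_start < len(seq):
            raise ValueError(
                f"{self.id}: cds_start {self.cds_start} outside sequence of length {len(seq)}"
            )


@dataclass
class LoadReport:
    """Records that loaded plus per-file accounting of what was skipped."""

    records: list[TranscriptRecord] = field(default_factory=list)
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def skip(self, message: str) -> None:
        self.n_skipped += 1
        self.messages.append(message)
        logger.warning("%s", message)


def read_transcripts(path, format: str, gff=None, bed=None) -> LoadReport:
    """Read annotated mRNA records from ``path`` in the declared format.

    ``gff``/``bed`` name the companion annotation file for the ``fasta+gff``
    and ``fasta+bed`` formats.  Malformed records are skipped and counted on
    the returned :class:`LoadReport`, never dropped silently; an unreadable
    file raises.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+gff":
        if gff is None:
            raise ValueError("fasta+gff requires a gff= companion file")
        return _read_fasta_annot(path, Path(gff), kind="gff")
    if bed is None:
        raise ValueError("fasta+bed requires a bed= companion file")
    return _read_fasta_annot(path, Path(bed), kind="bed")


def _read_tsv(path: Path) -> LoadReport:
    report = LoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                report.skip(f"{path}:{lineno}: expected 3 tab-separated fields")
                continue
            tid, seq, start = parts
            try:
                cds_start = int(start) - 1  # file is 1-based
                record = TranscriptRecord(tid, seq, cds_start, source_format="tsv")
            except ValueError as exc:
                report.skip(f"{path}:{lineno}: {exc}")
                continue
            report.records.append(record)
    return report


def _read_genbank(path: Path) -> LoadReport:
    report = LoadReport()
    for rec in SeqIO.parse(str(path), "genbank"):
        cds = [f for f in rec.features if f.type == "CDS"]
        if not cds:
            report.skip(f"{rec.id}: no CDS feature")
            continue
        loc = cds[0].location
        seq = str(rec.seq)
        if loc.strand == -1:
            seq = str(Seq(seq).reverse_complement())
            cds_start = len(seq) - int(loc.end)
        else:
            cds_start = int(loc.start)
        try:
            record = TranscriptRecord(rec.id, seq, cds_start, source_format="genbank")
        except ValueError as exc:
            report.skip(f"{rec.id}: {exc}")
            continue
        report.records.append(record)
    return report


def _cds_spans_from_gff(annot: Path) -> dict[str, tuple[int, int, str]]:
    """seqid -> (min start, max end, strand) over CDS features, 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(annot),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    spans: dict[str, tuple[int, int, str]] = {}
    for feat in db.features_of_type("CDS"):
        start0, end0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        prev = spans.get(feat.seqid)
        if prev is None:
            spans[feat.seqid] = (start0, end0, feat.strand or "+")
        else:
            spans[feat.seqid] = (min(prev[0], start0), max(prev[1], end0), prev[2])
    return spans


def _cds_spans_from_bed(annot: Path) -> dict[str, tuple[int, int, str]]:
    import pandas as pd

    bed = pd.read_csv(
        annot,
        sep="\t",
        comment="#",
        header=None,
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "strand": str},
    )
    spans: dict[str, tuple[int, int, str]] = {}
    for row in bed.itertuples(index=False):
        prev = spans.get(row.chrom)
        if prev is None:
            spans[row.chrom] = (row.start, row.end, row.strand)
        else:
            spans[row.chrom] = (min(prev[0], row.start), max(prev[1], row.end), prev[2])
    return spans


def _read_fasta_annot(fasta: Path, annot: Path, kind: str) -> LoadReport:
    if not annot.exists():
        raise FileNotFoundError(annot)
    spans = _cds_spans_from_gff(annot) if kind == "gff" else _cds_spans_from_bed(annot)
    fmt = "fasta+gff" if kind == "gff" else "fasta+bed"
    report = LoadReport()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        span = spans.get(rec.id)
        if span is None:
            report.skip(f"{rec.id}: no CDS annotation in {annot.name}")
            continue
        start0, end0, strand = span
        seq = str(rec.seq)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
            cds_start = len(seq) - end0
        else:
            cds_start = start0
        try:
            record = TranscriptRecord(rec.id, seq, cds_start, source_format=fmt)
        except ValueError as exc:
            report.skip(f"{rec.id}: {exc}")
            continue
        report.records.append(record)
    return report


# ---------------------------------------------------------------------------
# Window table I/O


def write_windows_tsv(windows: Iterable[TISWindow], path) -> None:
    """`transcript_id<TAB>window<TAB>status` with a comment header."""
    with open(path, "w") as fh:
        fh.write("# transcript_id\twindow\tstatus\n")
        for w in windows:
            status = "accepted" if w.accepted else w.rejection_reason.value
            fh.write(f"{w.transcript_id}\t{w.window}\t{status}\n")


def read_windows_tsv(path) -> list[TISWindow]:
    out: list[TISWindow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, window, status = line.split("\t")
            if status == "accepted":
                out.append(TISWindow(tid, window, accepted=True))
            else:
                out.append(
                    TISWindow(tid, window, accepted=False,
                              rejection_reason=RejectionReason(status))
                )
    return out
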
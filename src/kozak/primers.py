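"""Expression-construct forward-primer design.

A reporter fusion that tests an initiation context in vivo is assembled as

    promoter + linker + upstream_context(6 nt, positions -6..-1) + ATG
             + second_codon(3 nt, positions +4..+6) + reporter_tail

where the reporter tail is the reporter CDS from its second codon onward.
The implied 9-mer context (last four upstream bases, ATG, first two bases of
the second codon) is emitted alongside for cross-checking against a scored
initiation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

_ACGT = frozenset("ACGT")

SP6_PROMOTER = "ATTTAGGTGACACTATAG"
EGFP_CODON2_TAIL = "GTGAGCAAGGGCGAGGAG"

#: Part sets of the five SP6-driven eGFP fusion constructs used to compare
#: zebrafish initiation contexts (most frequent, rarest, a middle scorer, one
#: absent from the transcriptome, and the canonical Kozak context).
EGFP_CONSTRUCT_PARTS: dict[str, dict[str, str]] = {
    name: {
        "promoter": SP6_PROMOTER,
        "linker": "AA",
        "upstream_context": ctx,
        "second_codon": codon,
        "reporter_tail": EGFP_CODON2_TAIL,
    }
    for name, (ctx, codon) in {
        "frequent": ("GCAAAC", "GCG"),
        "rare": ("CTTTCT", "CTC"),
        "middle": ("GCAGTC", "GAG"),
        "worst": ("CGTTGT", "CTG"),
        "kozak": ("GCCACC", "GCG"),
    }.items()
}


@dataclass(frozen=True)
class ConstructDesign:
    promoter: str
    linker: str
    upstream_context: str
    second_codon: str
    reporter_tail: str
    primer: str
    kozak_9mer: str


def _check(name: str, value: str, length: int | None = None, allow_empty: bool = False) -> str:
    value = value.upper()
    if not value and not allow_empty:
        raise ValueError(f"{name} must be non-empty")
    if set(value) - _ACGT:
        raise ValueError(f"{name} must be over A/C/G/T")
    if length is not None and len(value) != length:
        raise ValueError(f"{name} must have length {length}, got {len(value)}")
    return value


def design_expression_primer(
    promoter: str,
    linker: str,
    upstream_context: str,
    second_codon: str,
    reporter_tail: str,
) -> ConstructDesign:
    """Assemble the forward primer placing a chosen context before a reporter."""
    promoter = _check("promoter", promoter, allow_empty=True)
    linker = _check("linker", linker, allow_empty=True)
    upstream_context = _check("upstream_context", upstream_context, length=6)
    second_codon = _check("second_codon", second_codon, length=3)
    reporter_tail = _check("reporter_tail", reporter_tail)
    primer = promoter + linker + upstream_context + "ATG" + second_codon + reporter_tail
    kozak_9mer = upstream_context[-4:] + "ATG" + second_codon[:2]
    return ConstructDesign(
        promoter=promoter,
        linker=linker,
        upstream_context=upstream_context,
        second_codon=second_codon,
        reporter_tail=reporter_tail,
        primer=primer,
        kozak_9mer=kozak_9mer,
    )
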
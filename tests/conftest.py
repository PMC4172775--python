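import numpy as np
import pytest

from kozak import (
    GeneratorConfig,
    PositionFrequencyMatrix,
    generate_transcriptome,
    zebrafish_like_pwm,
)


@pytest.fixture(scope="session")
def zebra_pwm():
    return zebrafish_like_pwm()


@pytest.fixture(scope="session")
def zebra_pfm(zebra_pwm):
    """Deterministic expected-count matrix of the zebrafish-like preset."""
    return PositionFrequencyMatrix.from_probabilities(zebra_pwm, n=10_000)


@pytest.fixture(scope="session")
def small_transcriptome():
    """200 synthetic transcripts with their ground truth (all-accepted regime)."""
    config = GeneratorConfig(n_transcripts=200, seed=11)
    return generate_transcriptome(config)


def make_window_strings(variable_seqs, upstream_pad="CCCCC", tail="C"):
    """Build full 15-mer windows from 6-mers over positions -4..-1, +4, +5."""
    out = []
    for s in variable_seqs:
        assert len(s) == 6
        out.append(upstream_pad + s[:4] + "ATG" + s[4:6] + tail)
    return out
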
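"""Frequency matrices, the positional chi-square screen and consensus calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kozak import (
    PositionFrequencyMatrix,
    build_pfm,
    call_consensus,
    positional_chi_square,
    significant_positions,
    zebrafish_like_pwm,
)
from kozak.profile import PositionalBiasResult

from conftest import make_window_strings


def pfm_from_counts(counts_by_pos, n):
    """Small helper: a matrix over positions (-2,-1,+1..+3) with given counts."""
    positions = sorted(counts_by_pos) + [1, 2, 3]
    rows = [counts_by_pos[p] for p in sorted(counts_by_pos)]
    rows += [[n, 0, 0, 0], [0, 0, 0, n], [0, 0, n, 0]]
    return PositionFrequencyMatrix(positions, rows, n)


# ---------------------------------------------------------------------------
# matrix construction


def test_degenerate_window_set_gives_100_percent():
    pfm = build_pfm(["CCCCCCCCCATGGCT"] * 4)
    assert pfm.n == 4
    assert pfm.percent(-1, "C") == 100.0
    assert pfm.percent(-1, "A") == 0.0


def test_manual_tally_at_minus_one():
    windows = make_window_strings(["AAAAGC", "AAAAGC", "AAACGC"])  # -1 in {A,A,C}
    pfm = build_pfm(windows)
    assert pfm.percent(-1, "A") == pytest.approx(200 / 3)
    assert pfm.percent(-1, "C") == pytest.approx(100 / 3)
    assert pfm.percent(-1, "G") == 0.0
    # start codon columns are pure by construction
    for pos, base in [(1, "A"), (2, "T"), (3, "G")]:
        assert pfm.percent(pos, base) == 100.0


def test_percent_columns_sum_to_100(small_transcriptome):
    from kozak import extract_tis_window

    records, _ = small_transcriptome
    pfm = build_pfm([extract_tis_window(r) for r in records])
    assert np.allclose(pfm.percents.sum(axis=1), 100.0, atol=1e-9)


def test_empty_or_rejected_input_errors():
    from kozak import RejectionReason, TISWindow

    with pytest.raises(ValueError, match="no accepted windows"):
        build_pfm([])
    rejected = TISWindow("x", "", accepted=False,
                         rejection_reason=RejectionReason.SHORT_UTR)
    with pytest.raises(ValueError, match="no accepted windows"):
        build_pfm([rejected])


def test_matrix_json_roundtrip(tmp_path, zebra_pfm):
    path = tmp_path / "m.json"
    zebra_pfm.to_json(path)
    back = PositionFrequencyMatrix.from_json(path)
    assert back.positions == zebra_pfm.positions
    assert np.allclose(back.counts, zebra_pfm.counts)


# ---------------------------------------------------------------------------
# chi-square screen


def _chi2_sf_df3_oracle(x):
    """Upper tail of chi-square(3) via the closed form erfc + exp (independent
    of scipy): P(X>x) = erfc(sqrt(x/2)) + sqrt(2x/pi) * exp(-x/2)."""
    return math.erfc(math.sqrt(x / 2)) + math.sqrt(2 * x / math.pi) * math.exp(-x / 2)


@pytest.mark.parametrize(
    "counts,n,stat",
    [
        ((25, 25, 25, 25), 100, 0.0),
        ((40, 20, 20, 20), 100, 12.0),
        ((10, 0, 0, 0), 10, 30.0),
    ],
)
def test_chi_square_statistic_and_tail(counts, n, stat):
    pfm = pfm_from_counts({-1: list(counts)}, n)
    res = positional_chi_square(pfm, -1)
    assert res.statistic == pytest.approx(stat, abs=1e-12)
    expected_p = 1.0 if stat == 0 else _chi2_sf_df3_oracle(stat)
    assert res.p_value == pytest.approx(expected_p, rel=1e-10)
    assert 0 < res.p_value <= 1


def test_chi_square_frozen_values():
    pfm = pfm_from_counts({-1: [40, 20, 20, 20]}, 100)
    assert positional_chi_square(pfm, -1).p_value == pytest.approx(7.383160505e-3, rel=1e-6)
    pfm = pfm_from_counts({-1: [10, 0, 0, 0]}, 10)
    assert positional_chi_square(pfm, -1).p_value == pytest.approx(1.380057031e-6, rel=1e-6)


def test_unknown_position_errors(zebra_pfm):
    with pytest.raises(KeyError):
        positional_chi_square(zebra_pfm, -42)


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.integers(0, 200), min_size=4, max_size=4), st.integers(0, 3))
def test_chi_square_monotone_in_modal_count(counts, donor):
    """Shifting one count from any base onto the modal base never lowers chi2."""
    if sum(counts) == 0:
        counts[0] = 4
    n = sum(counts)
    modal = int(np.argmax(counts))
    if donor == modal or counts[donor] == 0:
        donor = next((i for i in range(4) if i != modal and counts[i] > 0), None)
        if donor is None:
            return
    shifted = list(counts)
    shifted[modal] += 1
    shifted[donor] -= 1
    s0 = positional_chi_square(pfm_from_counts({-1: counts}, n), -1).statistic
    s1 = positional_chi_square(pfm_from_counts({-1: shifted}, n), -1).statistic
    assert s1 >= s0 - 1e-9


def test_significant_positions_threshold_semantics():
    results = [
        PositionalBiasResult(-5, 1.0, 0.50, False),
        PositionalBiasResult(-4, 11.0, 0.01, True),
        PositionalBiasResult(1, 0.0, 1.0, False),
        PositionalBiasResult(2, 0.0, 1.0, False),
        PositionalBiasResult(3, 0.0, 1.0, False),
    ]
    assert significant_positions(results, alpha=0.03) == (-4, 1, 2, 3)


def test_null_matrix_flags_only_start_codon():
    pfm = PositionFrequencyMatrix.from_probabilities(
        {p: [0.25] * 4 for p in list(range(-9, 0)) + [4, 5, 6]}, n=1000
    )
    from kozak import positional_bias

    sig = significant_positions(positional_bias(pfm, alpha=0.03), alpha=0.03)
    assert sig == (1, 2, 3)


# ---------------------------------------------------------------------------
# consensus


def _exact_binom_upper_tail(k, n, p_num=1, p_den=4):
    """Exact rational P(X >= k) for X ~ Binomial(n, p_num/p_den)."""
    q_num = p_den - p_num
    total = sum(
        math.comb(n, i) * p_num**i * q_num ** (n - i) for i in range(k, n + 1)
    )
    return float(Fraction(total, p_den**n))


def test_binomial_consensus_threshold_matches_exact_tail():
    # 300/1000 at 30% is significantly above the 25% background...
    p_300 = _exact_binom_upper_tail(300, 1000)
    assert p_300 == pytest.approx(1.9359032e-4, rel=1e-5)
    pfm = pfm_from_counts({-1: [300, 240, 230, 230]}, 1000)
    assert call_consensus(pfm, alpha=0.05).letters[-1] == "A"
    # ...while 260/1000 is not (exact tail ~0.24)
    assert _exact_binom_upper_tail(260, 1000) > 0.2
    pfm = pfm_from_counts({-1: [260, 250, 245, 245]}, 1000)
    assert -1 not in call_consensus(pfm, alpha=0.05).letters


def test_near_tie_lowercase():
    pfm = pfm_from_counts({-1: [400, 380, 120, 100]}, 1000)
    call = call_consensus(pfm, alpha=0.05, near_tie_margin=5.0)
    assert call.letters[-1] == "a"
    assert call.rules[-1] == "near_tie"
    # widen the gap past the margin: uppercase
    pfm = pfm_from_counts({-1: [400, 340, 160, 100]}, 1000)
    call = call_consensus(pfm, alpha=0.05, near_tie_margin=5.0)
    assert call.letters[-1] == "A"
    assert call.rules[-1] == "dominant"


def test_consensus_renders_contiguous_block():
    pwm = {p: [0.25] * 4 for p in list(range(-9, 0)) + [4, 5, 6]}
    for p in (-4, -3, -2, -1):
        pwm[p] = [1.0, 0.0, 0.0, 0.0]  # pure A
    pfm = PositionFrequencyMatrix.from_probabilities(pwm, n=1000)
    call = call_consensus(pfm)
    assert call.rendered == "AAAAATG"
    assert all(call.letters[p] == "A" for p in (-4, -3, -2, -1))


def test_consensus_block_never_spans_a_gap():
    pwm = {p: [0.25] * 4 for p in list(range(-9, 0)) + [4, 5, 6]}
    pwm[-6] = [1.0, 0.0, 0.0, 0.0]  # significant but isolated from the ATG
    pwm[4] = [0.0, 0.0, 1.0, 0.0]
    pfm = PositionFrequencyMatrix.from_probabilities(pwm, n=1000)
    call = call_consensus(pfm)
    assert call.rendered == "ATGG"
    assert -6 in call.letters  # lettered, just outside the rendered block


def test_chi_square_consensus_mode_requires_modal_above_background():
    # heavy depletion of A: chi-square fires but the modal base is barely above 25%
    pfm = pfm_from_counts({-1: [10, 340, 330, 320]}, 1000)
    assert -1 not in call_consensus(pfm, mode="chi_square", alpha=0.05).letters or \
        call_consensus(pfm, mode="chi_square", alpha=0.05).letters[-1] == "c"
    pfm = pfm_from_counts({-1: [500, 200, 150, 150]}, 1000)
    assert call_consensus(pfm, mode="chi_square", alpha=0.05).letters[-1] == "A"


def test_order_invariance_of_matrix_and_consensus():
    rng = np.random.default_rng(0)
    windows = make_window_strings(
        ["".join(rng.choice(list("ACGT"), 6)) for _ in range(300)]
    )
    shuffled = list(windows)
    rng.shuffle(shuffled)
    a, b = build_pfm(windows), build_pfm(shuffled)
    assert np.array_equal(a.counts, b.counts)
    assert call_consensus(a) == call_consensus(b)


def test_preset_consensus_recovery(zebra_pwm):
    """12,000 windows from the zebrafish-like preset recover its modal letters."""
    from kozak import sample_windows

    windows = sample_windows(zebra_pwm, 12_000, seed=123)
    call = call_consensus(build_pfm(windows))
    assert "AAACATGGC" in call.rendered
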
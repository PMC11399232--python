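"""Early-warning statistics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bifurcell.ews import (
    kendall_tau,
    kolmogorov_complexity,
    lempel_ziv_complexity,
    roc_evaluate,
    rolling_statistics,
    sample_entropy,
)


# ----------------------------------------------------------------------
# independent oracles

def sampen_oracle(x, m=2, r=None):
    """Direct double-loop transcription of the SampEn definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x)
    nt = n - m  # number of (m+1)-templates; m-templates use the same range
    A = B = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -np.log(A / B)


def auc_oracle(scores, labels):
    """Pairwise Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ----------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(30)) == pytest.approx(0.0)

    def test_alternating_series_matches_oracle(self):
        x = np.array([1.0, -1.0] * 10)
        assert sample_entropy(x, r=0.5) == pytest.approx(
            sampen_oracle(x, r=0.5), nan_ok=True)

    @given(st.integers(0, 2**31 - 1), st.integers(8, 30))
    def test_equals_double_loop_oracle_on_random_series(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        got = sample_entropy(x)
        want = sampen_oracle(x)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want)

    def test_all_small_binary_sequences(self):
        # exhaustive over binary sequences of length 8
        for code in range(2**8):
            x = np.array([(code >> k) & 1 for k in range(8)], dtype=float)
            got = sample_entropy(x, r=0.5)
            want = sampen_oracle(x, r=0.5)
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), m=2)


class TestLempelZiv:
    def test_hand_parsed_alternating(self):
        # 0101010101 parses as 0 | 1 | 01010101 -> 3 phrases
        assert lempel_ziv_complexity(np.array([0, 1] * 5)) == 3

    def test_constant_sequence_minimal(self):
        # 0 | 000...0 -> phrase count 2 (trailing-phrase convention)
        assert lempel_ziv_complexity(np.zeros(20, dtype=int)) == 2

    def test_random_sequence_normalized_near_one(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert kolmogorov_complexity(x) == pytest.approx(1.0, abs=0.2)

    def test_periodic_less_complex_than_random(self):
        rng = np.random.default_rng(1)
        periodic = np.tile([0.0, 1.0, 2.0, 3.0], 50)
        random = rng.standard_normal(200)
        assert kolmogorov_complexity(periodic) < kolmogorov_complexity(random)


class TestKendallTau:
    def test_monotone_limits(self):
        assert kendall_tau(np.arange(10.0)).kendall_tau == pytest.approx(1.0)
        assert kendall_tau(-np.arange(10.0)).kendall_tau == pytest.approx(-1.0)

    def test_small_example(self):
        # values (1, 3, 2): 2 concordant, 1 discordant of 3 pairs
        assert kendall_tau(np.array([1.0, 3.0, 2.0])).kendall_tau == pytest.approx(1 / 3)

    def test_all_tied_is_zero(self):
        assert kendall_tau(np.ones(10)).kendall_tau == 0.0

    def test_nan_entries_ignored(self):
        v = np.array([1.0, np.nan, 2.0, 3.0])
        assert kendall_tau(v).kendall_tau == pytest.approx(1.0)


class TestRollingStatistics:
    def test_window_count_and_first_window_variance(self):
        # N = 16, fraction 0.25 -> w = 4; first window [1, 2, 3, 4]
        x = np.concatenate([[1.0, 2.0, 3.0, 4.0],
                            np.random.default_rng(0).standard_normal(12)])
        ews = rolling_statistics(x, 0.25)
        assert ews.window == 4
        assert len(ews.variance) == 16 - 4 + 1
        assert ews.variance[0] == pytest.approx(5 / 3)

    def test_white_noise_limits(self):
        # averaged over independent realizations: variance -> 1, AC1 -> 0
        rng = np.random.default_rng(1)
        vars_, acs = [], []
        for _ in range(20):
            ews = rolling_statistics(rng.standard_normal(200), 0.25)
            vars_.append(np.nanmean(ews.variance))
            acs.append(np.nanmean(ews.ac1))
        assert np.mean(vars_) == pytest.approx(1.0, abs=0.1)
        assert abs(np.mean(acs)) < 0.1

    def test_ar1_autocorrelation_recovered(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        x = np.empty(1200)
        x[0] = 0.0
        for t in range(1, len(x)):
            x[t] = rho * x[t - 1] + rng.standard_normal()
        ews = rolling_statistics(x, 0.25)  # window 300
        assert np.mean(ews.ac1) == pytest.approx(rho, abs=0.1)

    def test_constant_window_ac1_missing(self):
        x = np.concatenate([np.ones(8), np.random.default_rng(3).standard_normal(8)])
        ews = rolling_statistics(x, 0.5)
        assert np.isnan(ews.ac1[0])


class TestROC:
    def test_perfect_separation(self):
        res = roc_evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)
        assert res.n_predictions == 4

    def test_small_example_auc(self):
        # scores 0.9+, 0.8-, 0.7+, 0.1-: 3 of 4 pairs concordant
        res = roc_evaluate([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)

    @given(st.integers(0, 2**31 - 1), st.integers(4, 40))
    def test_auc_equals_mann_whitney_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(n).round(1)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        res = roc_evaluate(scores, labels)
        assert res.auc == pytest.approx(auc_oracle(scores, labels))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        res = roc_evaluate(rng.standard_normal(4000), rng.integers(0, 2, 4000))
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_evaluate([0.1, 0.2], [1, 1])
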
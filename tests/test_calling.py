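"""The five-node caller: thresholds, per-node tests, orchestration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cnatree as ct
from cnatree.calling import (CallingParams, FALLBACK_THRESHOLDS, classify_odd,
                             detect_even_gains, het_thresholds, resolve_loh,
                             weighted_alpha)
from cnatree.calling import test_loh as loh_decision
from cnatree.calling import test_parity as parity_decision
from cnatree.dip import DipCalibration

CAL = DipCalibration(n_sim=400, seed=44)


def params(**kw):
    kw.setdefault("dip_calibration", CAL)
    return CallingParams(**kw)


class TestHetThresholds:
    def three_cluster_baf(self, seed=0, n=6000):
        rng = np.random.default_rng(seed)
        comp = rng.choice(3, size=n, p=[0.35, 0.3, 0.35])
        centre = np.array([0.02, 0.5, 0.98])[comp]
        return np.clip(centre + rng.normal(0, 0.04, n), 0, 1)

    def test_brackets_the_heterozygous_cluster(self):
        th = het_thresholds(self.three_cluster_baf(), params())
        assert 0.05 < th.low < 0.4
        assert 0.6 < th.high < 0.95

    def test_symmetry(self):
        baf = self.three_cluster_baf(seed=1)
        baf = np.concatenate([baf, 1 - baf])  # enforce mirror symmetry
        th = het_thresholds(baf, params())
        assert th.low == pytest.approx(1 - th.high, abs=0.02)

    def test_all_homozygous_falls_back(self):
        rng = np.random.default_rng(2)
        baf = np.clip(np.concatenate([rng.normal(0.01, 0.01, 3000),
                                      rng.normal(0.99, 0.01, 3000)]), 0, 1)
        with pytest.warns(UserWarning):
            th = het_thresholds(baf, params())
        assert (th.low, th.high) == FALLBACK_THRESHOLDS


class TestWeightedAlpha:
    def test_printed_example(self):
        levels = weighted_alpha([100, 300, 600], 0.05, 3)
        assert levels == pytest.approx([0.1 * 0.05 / 3, 0.3 * 0.05 / 3,
                                        0.6 * 0.05 / 3])

    def test_single_segment_single_test(self):
        assert weighted_alpha([500], 0.05, 1)[0] == pytest.approx(0.05)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=40),
           st.floats(0.001, 0.2), st.integers(1, 10))
    @settings(max_examples=60, deadline=None)
    def test_budget_identity(self, sizes, alpha, m):
        """Weighted Bonferroni budget: M * sum(alpha_i) == alpha exactly."""
        levels = weighted_alpha(sizes, alpha, m)
        assert m * levels.sum() == pytest.approx(alpha, rel=1e-12)

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            weighted_alpha([100, 0], 0.05, 5)


class TestLohNode:
    def test_no_hets_is_loh(self):
        # exact tail: 0.7^50 ~ 1.8e-8 <= 1e-4
        assert loh_decision(0, 50, 0.3, 1e-4)

    def test_rate_matching_segment_is_not_loh(self):
        assert not loh_decision(30, 100, 0.3, 0.05)

    def test_moderate_depletion_insufficient(self):
        # closed-form lower tail of Binomial(30, 0.3) at 10 is ~0.73
        tail = sum(math.comb(30, k) * 0.3**k * 0.7**(30 - k) for k in range(11))
        assert tail > 0.5
        assert not loh_decision(10, 30, 0.3, 0.001)

    def test_agrees_with_closed_form_tail(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 120))
            h = int(rng.integers(0, n + 1))
            rate = float(rng.uniform(0.1, 0.6))
            level = float(rng.uniform(1e-5, 0.1))
            tail = sum(math.comb(n, k) * rate**k * (1 - rate)**(n - k)
                       for k in range(h + 1))
            assert loh_decision(h, n, rate, level) == (tail <= level)


class TestParityNode:
    def test_background_like_segment_is_even(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(0.5, 0.04, 120)
        bg = rng.normal(0.5, 0.04, 2000)
        assert parity_decision(seg, bg, 0.01, params()) == "even"

    def test_bimodal_segment_is_odd(self):
        """Three-copy segment at purity ~0.6: BAF bands at 0.35/0.65."""
        rng = np.random.default_rng(1)
        seg = 0.5 + rng.choice([-1, 1], 150) * 0.15 + rng.normal(0, 0.04, 150)
        bg = rng.normal(0.5, 0.04, 2000)
        assert parity_decision(seg, bg, 0.01, params()) == "odd"

    def test_shifted_unimodal_fold_is_odd_via_rank_sum(self):
        """Widened symmetric spread: dip stays quiet, rank-sum fires."""
        rng = np.random.default_rng(2)
        seg = 0.5 + rng.normal(0, 0.09, 200)
        bg = rng.normal(0.5, 0.04, 2000)
        assert parity_decision(seg, bg, 0.01, params()) == "odd"

    def test_too_few_hets_defaults_even(self):
        assert parity_decision(np.full(4, 0.2), np.full(100, 0.5), 0.05,
                           params()) == "even"


class TestGainNode:
    def test_all_equal_medians_flag_nothing(self):
        assert detect_even_gains([0.0, 0.0, 0.0, 0.0], 0.05) == set()

    def test_printed_outlier_example(self):
        medians = [0.01, -0.02, 0.00, 0.03, 0.58]
        flagged = detect_even_gains(medians, 0.05)
        assert flagged == {4}
        # closed-form check of the Grubbs decision at alpha 0.05, N=5
        vals = np.asarray(medians)
        g = (vals.max() - vals.mean()) / vals.std(ddof=1)
        t = stats.t.ppf(1 - 0.05 / 5, 3)
        crit = 4 / np.sqrt(5) * np.sqrt(t * t / (3 + t * t))
        assert g > crit

    def test_iterative_flagging_terminates(self):
        rng = np.random.default_rng(3)
        medians = np.concatenate([rng.normal(0, 0.01, 12), [0.6, 0.8]])
        flagged = detect_even_gains(medians, 0.01)
        assert flagged == {12, 13}

    def test_standardized_mode_handles_uneven_sizes(self):
        """A noisy small-segment median is not an outlier once standardized."""
        rng = np.random.default_rng(4)
        sizes = np.array([1000] * 10 + [12])
        sigma = 0.15
        medians = rng.normal(0, 1.2533 * sigma / np.sqrt(sizes))
        medians[-1] = 0.14  # ~ +2 standard errors for n=12, huge on raw scale
        flagged = detect_even_gains(medians, 0.05, sizes=sizes, noise_scale=sigma)
        assert flagged == set()


class TestFinalNodes:
    rng = np.random.default_rng(5)
    neutral = rng.normal(0.0, 0.15, 2000)

    def test_equivalent_segment_is_cnloh(self):
        seg = self.rng.normal(0.0, 0.15, 300)
        assert classify_odd(seg, self.neutral, 0.1, 0.01) == "CNLOH"

    def test_strong_loss_and_gain(self):
        seg_lo = self.rng.normal(-0.5, 0.15, 300)
        seg_hi = self.rng.normal(0.4, 0.15, 300)
        assert classify_odd(seg_lo, self.neutral, 0.1, 0.01) == "Loss"
        assert classify_odd(seg_hi, self.neutral, 0.1, 0.01) == "Gain"

    def test_loh_resolution(self):
        assert resolve_loh(self.rng.normal(0.0, 0.15, 300), self.neutral,
                           0.01) == "CNLOH"
        assert resolve_loh(self.rng.normal(-0.8, 0.15, 300), self.neutral,
                           0.01) == "Loss"
        assert resolve_loh(self.rng.normal(0.6, 0.15, 300), self.neutral,
                           0.01) == "Gain"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            classify_odd(np.zeros(50), np.array([]), 0.1, 0.05)
        with pytest.raises(ValueError):
            resolve_loh(np.zeros(50), np.array([]), 0.05)


class TestCallSample:
    def test_null_genome_all_neutral(self, null_track):
        _, track = null_track
        result = ct.call_track(track, params())
        assert all(c.state == "Neutral" for c in result.calls)

    def test_states_partition_segments(self, aberrant_track):
        _, track, _ = aberrant_track
        result = ct.call_track(track, params())
        assert len(result.calls) == len(result.segmentation)
        from collections import Counter
        counts = Counter(c.state for c in result.calls)
        assert sum(counts.values()) == len(result.calls)
        assert set(counts) <= {"Loss", "Neutral", "Gain", "CNLOH"}

    def test_truth_states_recovered_at_their_loci(self, aberrant_track):
        cfg, track, _ = aberrant_track
        result = ct.call_track(track, params())
        called = ct.marker_states(result.calls, len(track))
        truth = ct.truth_marker_states(cfg)
        for state in ("Loss", "Gain", "CNLOH"):
            at_truth = called[truth == state]
            assert (at_truth == state).mean() > 0.9

    def test_cnloh_invariant(self, aberrant_track):
        """CNLOH calls arise only via the LOH or odd-parity branches."""
        _, track, _ = aberrant_track
        result = ct.call_track(track, params())
        for c in result.calls:
            if c.state == "CNLOH":
                assert c.loh_flag or c.parity == "odd"

    def test_determinism(self, aberrant_track):
        _, track, _ = aberrant_track
        r1 = ct.call_track(track, params())
        r2 = ct.call_track(track, params())
        assert [(c.state, c.start, c.end) for c in r1.calls] == \
               [(c.state, c.start, c.end) for c in r2.calls]
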
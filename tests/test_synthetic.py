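"""Synthetic paired-recording generator: ground truth, determinism, statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synapsync import (
    DriveParams,
    KernelParams,
    PairScenario,
    RingTable,
    calibrate_q_follow,
    cross_correlation,
    css_slope,
    default_ring_table,
    effective_css,
    generate_convergent_trace,
    generate_pair,
    sample_synapse_pair,
    stream_correlation,
)


class TestEffectiveCss:
    def test_identical_streams(self):
        assert effective_css(0.01, 1.0) == pytest.approx(1.0)

    def test_no_release(self):
        assert effective_css(0.5, 0.0) == 0.0

    def test_closed_form_value(self):
        # q(1-p)/(1-pq) at p=0.01, q=0.8
        assert effective_css(0.01, 0.8) == pytest.approx(0.798, abs=5e-4)

    def test_against_monte_carlo_oracle(self):
        """Brute-force correlation of two thinned Bernoulli streams."""
        p, q, n = 0.01, 0.8, 2_000_000
        rng = np.random.default_rng(99)
        master = rng.random(n) < p
        x = master & (rng.random(n) < q)
        y = master & (rng.random(n) < q)
        mc = np.corrcoef(x, y)[0, 1]
        se = (1 - mc**2) / np.sqrt(n)
        assert abs(effective_css(p, q) - mc) < 3 * max(se, 1e-4)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            effective_css(1.2, 0.5)

    @given(st.floats(0.001, 0.999), st.floats(0.0, 1.0))
    def test_reduces_to_stream_correlation_without_async(self, p, q):
        assert stream_correlation(p, q, 0.0) == pytest.approx(
            effective_css(p, q), rel=1e-9, abs=1e-12
        )


class TestCalibration:
    @given(st.floats(0.0, 0.9), st.floats(0.05, 0.5), st.floats(0.0, 0.01))
    def test_roundtrip(self, target, p, r):
        try:
            q = calibrate_q_follow(target, p, r)
        except ValueError:
            return  # unattainable targets are rejected, not silently clipped
        assert stream_correlation(p, q, r) == pytest.approx(target, abs=1e-9)

    def test_unattainable_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_q_follow(0.9, 0.1, 0.1)

    def test_zero_target(self):
        assert calibrate_q_follow(0.0, 0.1, 0.01) == 0.0


class TestDefaultRingTable:
    def test_documented_anatomy(self):
        t = default_ring_table()
        assert t.gamma == pytest.approx(32.3)
        assert t.r0 == pytest.approx(40.0)
        assert len(t) >= 4
        assert np.all((t.p_shared >= 0) & (t.p_shared <= 1))
        assert np.all(np.diff(t.n_r) > 0)  # counts grow with ring area
        assert np.all(np.diff(t.p_shared) < 0)  # sharing falls with distance

    def test_slope_in_open_unit_interval(self):
        assert 0.0 < css_slope(default_ring_table()) < 1.0


class TestStreamStatistics:
    def test_event_rate(self):
        d = DriveParams(p_master=0.1, q_follow=0.8, r_async=0.005)
        n = 500_000
        x, _ = sample_synapse_pair(d, n, seed=5)
        rate = d.p_master * d.q_follow + d.r_async
        se = np.sqrt(rate / n)
        assert abs(x.mean() - rate) < 3 * se

    def test_pair_correlation_matches_dial(self):
        d = DriveParams(p_master=0.1, q_follow=0.8, r_async=0.0)
        n = 1_000_000
        x, y = sample_synapse_pair(d, n, seed=6)
        r = np.corrcoef(x, y)[0, 1]
        se = (1 - r**2) / np.sqrt(n)
        assert abs(r - effective_css(0.1, 0.8)) < 3 * se


def short_scenario(**kwargs):
    defaults = dict(duration=10.0, seed=0)
    defaults.update(kwargs)
    return PairScenario(**defaults)


class TestGeneratePair:
    def test_seed_determinism(self):
        a1, b1, g1 = generate_pair(short_scenario(seed=3, target_css=0.5))
        a2, b2, g2 = generate_pair(short_scenario(seed=3, target_css=0.5))
        assert np.array_equal(a1.samples, a2.samples)
        assert np.array_equal(b1.samples, b2.samples)
        assert g1 == g2
        a3, _, _ = generate_pair(short_scenario(seed=4, target_css=0.5))
        assert not np.array_equal(a1.samples, a3.samples)

    def test_perfect_synchrony_identity(self):
        """All contacts shared, q=1, no noise, no async: identical traces."""
        table = RingTable(r=[10.0, 30.0], n_r=[5.0, 8.0], p_shared=[1.0, 1.0])
        sc = PairScenario(
            ring_table=table,
            drive=DriveParams(p_master=0.1, q_follow=1.0, r_async=0.0),
            noise_sd=0.0,
            duration=10.0,
            seed=2,
            target_css=1.0,
        )
        a, b, gt = generate_pair(sc)
        assert gt == pytest.approx(1.0)
        assert np.array_equal(a.samples, b.samples)
        cc = cross_correlation(a, b, max_lag=50.0)
        assert cc.peak == pytest.approx(1.0, abs=1e-9)
        assert cc.peak_lag == 0.0

    def test_independent_pair_uncorrelated(self):
        sc = short_scenario(
            duration=30.0,
            drive=DriveParams(p_master=0.1, q_follow=0.0, r_async=0.02),
            target_css=None,
            seed=8,
        )
        a, b, gt = generate_pair(sc)
        assert gt == 0.0
        cc = cross_correlation(a, b, max_lag=20.0)
        assert abs(cc.peak) < 0.05
        # stream-level null bound: 3/sqrt(n_bins)
        d = DriveParams(p_master=0.1, q_follow=0.0, r_async=0.02)
        x, y = sample_synapse_pair(d, 300_000, seed=8)
        assert abs(np.corrcoef(x, y)[0, 1]) < 3 / np.sqrt(300_000)

    def test_peak_cc_monotone_in_target(self):
        """At fixed seed/wiring, the measured peak grows with the dial.

        The zero level is generated from purely asynchronous release (with
        q = 0 and no asynchronous floor there would be no events at all);
        the other levels use the calibrated follow probability.
        """
        null_sc = PairScenario(
            drive=DriveParams(p_master=0.1, q_follow=0.0, r_async=0.02),
            duration=20.0,
            seed=11,
            noise_sd=0.5,
        )
        a, b, gt = generate_pair(null_sc)
        assert gt == 0.0
        peaks = [cross_correlation(a, b, max_lag=50.0).peak]
        for target in (0.25, 0.5, 0.75, 1.0):
            sc = PairScenario(
                drive=DriveParams(p_master=0.1, q_follow=0.85, r_async=0.0),
                duration=20.0,
                seed=11,
                target_css=target,
                noise_sd=0.5,
            )
            a, b, _ = generate_pair(sc)
            peaks.append(cross_correlation(a, b, max_lag=50.0).peak)
        assert all(p1 < p2 for p1, p2 in zip(peaks, peaks[1:]))

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_pair(short_scenario(duration=0.05, target_css=0.5))

    def test_invalid_scenarios(self):
        with pytest.raises(ValueError):
            PairScenario(target_css=1.5)
        with pytest.raises(ValueError):
            PairScenario(noise_sd=-1.0)
        with pytest.raises(ValueError):
            KernelParams(amplitude=-8.0, tau_rise=3.0, tau_decay=2.0)
        with pytest.raises(ValueError):
            DriveParams(p_master=1.5)


class TestConvergentTrace:
    def test_coherent_summation_is_quadratic(self):
        """q=1, 10 synapses/RBC, no noise: variance exactly 100x the 1-synapse case."""
        kwargs = dict(
            drive=DriveParams(p_master=0.1, q_follow=1.0, r_async=0.0),
            noise_sd=0.0,
            duration=10.0,
            seed=5,
        )
        v1 = np.var(generate_convergent_trace(PairScenario(**kwargs), 1).samples)
        v10 = np.var(generate_convergent_trace(PairScenario(**kwargs), 10).samples)
        assert v10 / v1 == pytest.approx(100.0, rel=1e-9)

    def test_incoherent_summation_is_linear(self):
        """Independent synapses at matched rate: variance ratio ~ synapse count."""
        kwargs = dict(
            drive=DriveParams(p_master=0.1, q_follow=0.0, r_async=0.08),
            noise_sd=0.0,
            duration=30.0,
        )
        v1 = np.var(
            generate_convergent_trace(PairScenario(seed=21, **kwargs), 1).samples
        )
        v10 = np.var(
            generate_convergent_trace(PairScenario(seed=22, **kwargs), 10).samples
        )
        assert v10 / v1 == pytest.approx(10.0, rel=0.15)

    def test_single_synapse_matches_pair_member_scale(self):
        sc = short_scenario(seed=9, target_css=0.8, duration=20.0)
        single = generate_convergent_trace(sc, 1)
        a, _, _ = generate_pair(sc)
        assert np.var(single.samples) == pytest.approx(np.var(a.samples), rel=0.2)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            generate_convergent_trace(short_scenario(target_css=0.5), 0)
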
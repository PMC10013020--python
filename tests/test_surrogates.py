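"""Surrogate engines: preservation contracts, reproducibility, null behavior."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram

import ppmir
from ppmir import (
    EstimatorConfig,
    IntervalSeries,
    SurrogateConfig,
    embed_at_events,
    intervals,
    local_permutation,
    surrogate_iaaft,
    surrogate_jodi,
    surrogate_mir_values,
    surrogate_shuffle,
)


def interval_series_strategy():
    return st.lists(
        st.floats(min_value=0.05, max_value=3.0, allow_nan=False),
        min_size=8,
        max_size=60,
    ).map(lambda w: IntervalSeries(0.0, w))


@pytest.fixture(scope="module")
def ar_intervals():
    """Serially correlated heartbeat-like interval series."""
    s = ppmir.simulate_hdig(n_events=400, seed=77)
    return intervals(s)


def lag_acf(w, lag):
    z = w - w.mean()
    return float(np.dot(z[:-lag], z[lag:]) / np.dot(z, z))


class TestShuffle:
    @given(interval_series_strategy())
    @settings(max_examples=30, deadline=None)
    def test_multiset_and_duration_preserved(self, iv):
        s = surrogate_shuffle(iv, seed=1)
        np.testing.assert_array_equal(np.sort(s.intervals), np.sort(iv.intervals))
        assert s.intervals.sum() == pytest.approx(iv.intervals.sum(), rel=1e-12)
        assert s.start_time == iv.start_time

    def test_seeded(self, ar_intervals):
        a = surrogate_shuffle(ar_intervals, seed=5)
        b = surrogate_shuffle(ar_intervals, seed=5)
        np.testing.assert_array_equal(a.intervals, b.intervals)


class TestIAAFT:
    def test_amplitudes_exact(self, ar_intervals):
        s = surrogate_iaaft(ar_intervals, seed=3)
        np.testing.assert_array_equal(
            np.sort(s.intervals), np.sort(ar_intervals.intervals)
        )

    def test_spectrum_closer_than_shuffle(self, ar_intervals):
        w = ar_intervals.intervals
        _, p0 = periodogram(w)

        def mse(surr):
            _, p = periodogram(surr.intervals)
            return np.mean((p - p0) ** 2)

        mses_iaaft = [mse(surrogate_iaaft(ar_intervals, seed=s)) for s in range(5)]
        mses_shuf = [mse(surrogate_shuffle(ar_intervals, seed=s)) for s in range(5)]
        assert np.mean(mses_iaaft) < np.mean(mses_shuf)

    def test_seeds_differ_with_same_amplitudes(self, ar_intervals):
        a = surrogate_iaaft(ar_intervals, seed=1)
        b = surrogate_iaaft(ar_intervals, seed=2)
        assert not np.array_equal(a.intervals, b.intervals)
        np.testing.assert_array_equal(np.sort(a.intervals), np.sort(b.intervals))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            surrogate_iaaft(IntervalSeries(0.0, [1.0] * 5), seed=0)


class TestJODI:
    def test_is_permutation(self, ar_intervals):
        s = surrogate_jodi(ar_intervals, seed=4)
        np.testing.assert_array_equal(
            np.sort(s.intervals), np.sort(ar_intervals.intervals)
        )

    def test_lag1_autocorrelation_match(self, ar_intervals):
        s = surrogate_jodi(ar_intervals, seed=4)
        assert abs(lag_acf(s.intervals, 1) - lag_acf(ar_intervals.intervals, 1)) < 0.05

    def test_seeded(self, ar_intervals):
        a = surrogate_jodi(ar_intervals, seed=9)
        b = surrogate_jodi(ar_intervals, seed=9)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_differs_from_original_order(self, ar_intervals):
        s = surrogate_jodi(ar_intervals, seed=4)
        assert not np.array_equal(s.intervals, ar_intervals.intervals)


class TestLocalPermutationOp:
    @pytest.fixture
    def joint_set(self, sim2_pair):
        x, y = sim2_pair
        joint, _ = embed_at_events(x, y, 2)
        return joint

    def test_target_blocks_bit_identical(self, joint_set):
        out = local_permutation(joint_set, n_perm_neighbors=10, seed=1)
        np.testing.assert_array_equal(out.samples[:, :2], joint_set.samples[:, :2])

    def test_source_block_multiset_preserved(self, joint_set):
        out = local_permutation(joint_set, n_perm_neighbors=10, seed=1)
        orig = joint_set.samples[:, 2:]
        perm = out.samples[:, 2:]
        np.testing.assert_allclose(
            np.sort(orig, axis=0), np.sort(perm, axis=0), rtol=0, atol=0
        )
        assert not np.array_equal(orig, perm)

    def test_no_self_assignment(self, joint_set):
        out = local_permutation(joint_set, n_perm_neighbors=10, seed=2)
        same = np.all(out.samples[:, 2:] == joint_set.samples[:, 2:], axis=1)
        # rows with duplicated source blocks can coincide; the assignment
        # itself avoids identity, so coincidences must be rare
        assert same.mean() < 0.05

    def test_requires_joint_scope(self, sim2_pair):
        x, y = sim2_pair
        _, marg = embed_at_events(x, y, 2)
        with pytest.raises(ValueError):
            local_permutation(marg, seed=0)


class TestSurrogateMIRValues:
    def test_returns_m_seeded_values(self, sim2_pair):
        x, y = sim2_pair
        cfg = EstimatorConfig(seed=1)
        scfg = SurrogateConfig(M=7, seed=2)
        v1 = surrogate_mir_values(x, y, cfg, scfg)
        v2 = surrogate_mir_values(x, y, cfg, scfg)
        assert v1.shape == (7,)
        np.testing.assert_array_equal(v1, v2)

    @pytest.mark.parametrize("method", ["shuffle", "iaaft", "jodi"])
    def test_interval_engines_reproducible(self, sim2_pair, method):
        x, y = sim2_pair
        cfg = EstimatorConfig(seed=1)
        scfg = SurrogateConfig(method=method, M=3, seed=2)
        np.testing.assert_array_equal(
            surrogate_mir_values(x, y, cfg, scfg),
            surrogate_mir_values(x, y, cfg, scfg),
        )

    def test_local_permutation_reduces_ter(self, sim2_pair):
        """Replacing source histories under the conditional-independence null
        must lower the TER on strongly coupled data."""
        x, y = sim2_pair
        cfg = EstimatorConfig(l=1, seed=3)
        orig = ppmir.mir(x, y, cfg).mir
        vals = surrogate_mir_values(x, y, cfg, SurrogateConfig(M=20, seed=4))
        assert np.median(vals) < orig

    def test_local_permutation_median_above_shuffle(self, sim2_pair):
        """The conditional null retains target/source-history structure, so
        its surrogate MIR sits above the fully destructive shuffle's."""
        x, y = sim2_pair
        cfg = EstimatorConfig(l=1, seed=3)
        lp = surrogate_mir_values(x, y, cfg, SurrogateConfig(M=20, seed=4))
        sh = surrogate_mir_values(
            x, y, cfg, SurrogateConfig(method="shuffle", M=20, seed=4)
        )
        assert np.median(lp) > np.median(sh)

    def test_local_permutation_not_anticonservative(self):
        """On uncoupled pairs the engine must not inflate detections."""
        hits = []
        for r in range(25):
            x = ppmir.simulate_renewal("exponential", 300, seed=4000 + r)
            y = ppmir.simulate_renewal("exponential", 300, seed=8000 + r, t0=0.37)
            est = ppmir.cmir(
                x, y, EstimatorConfig(l=1, seed=r), SurrogateConfig(M=20, seed=r)
            )
            hits.append(est.significant)
        assert np.mean(hits) <= 0.2

    def test_apply_to_both_differs_from_source(self, sim2_pair):
        x, y = sim2_pair
        cfg = EstimatorConfig(seed=1)
        v_src = surrogate_mir_values(
            x, y, cfg, SurrogateConfig(method="shuffle", M=3, seed=2)
        )
        v_both = surrogate_mir_values(
            x, y, cfg, SurrogateConfig(method="shuffle", M=3, seed=2, apply_to="both")
        )
        assert not np.array_equal(v_src, v_both)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SurrogateConfig(method="twin")
        with pytest.raises(ValueError):
            SurrogateConfig(M=0)
        with pytest.raises(ValueError):
            SurrogateConfig(apply_to="neither")
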
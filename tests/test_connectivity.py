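"""Preprocessing, wavelet correlation, Fisher-z and local thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectopharm.connectivity import (
    AssociationMatrix,
    TimeSeriesMatrix,
    coverage_exclude,
    drop_initial_volumes,
    effective_df,
    fisher_z,
    highpass_filter,
    local_threshold,
    n_usable_coefficients,
    regress_nuisance,
    wavelet_correlation,
)
from connectopharm.modwt import boundary_width, min_length, modwt_detail


def _ts(values, tr=2.0):
    return TimeSeriesMatrix(np.asarray(values, dtype=float), tr_seconds=tr)


class TestVolumeTrimming:
    def test_145_to_140(self, rng):
        ts = _ts(rng.standard_normal((4, 145)))
        out = drop_initial_volumes(ts, 5)
        assert out.n_volumes == 140
        assert np.array_equal(out.values, ts.values[:, 5:])
        assert out.node_labels == ts.node_labels

    def test_k_zero_identity(self, rng):
        ts = _ts(rng.standard_normal((3, 20)))
        assert np.array_equal(drop_initial_volumes(ts, 0).values, ts.values)

    def test_dropping_everything_rejected(self, rng):
        ts = _ts(rng.standard_normal((3, 20)))
        with pytest.raises(ValueError):
            drop_initial_volumes(ts, 20)


class TestHighpass:
    def test_constant_becomes_zero(self):
        out = highpass_filter(_ts(np.full((2, 200), 7.0)))
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_passband_sinusoid_retained(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = highpass_filter(_ts(x[None, :]), cutoff_hz=0.01)
        assert out.values.std() == pytest.approx(x.std(), rel=0.05)

    def test_drift_attenuated(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.004 * t)
        out = highpass_filter(_ts(x[None, :]), cutoff_hz=0.01)
        assert out.values.std() <= 0.2 * x.std()

    def test_cutoff_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_filter(_ts(rng.standard_normal((2, 50))), cutoff_hz=0.3)


class TestNuisanceRegression:
    def test_signal_equal_to_regressor_vanishes(self, rng):
        reg = rng.standard_normal((100, 1))
        out = regress_nuisance(_ts(reg.T), reg)
        assert np.abs(out.values).max() < 1e-10

    def test_zero_regressors_demean_only(self, rng):
        x = rng.standard_normal((3, 50)) + 5.0
        out = regress_nuisance(_ts(x), np.zeros((50, 2)))
        assert np.allclose(out.values, x - x.mean(axis=1, keepdims=True), atol=1e-10)

    def test_residual_orthogonal_to_regressors(self, rng):
        reg = rng.standard_normal((200, 3))
        signal = 2.0 * reg[:, 0] + rng.standard_normal(200)
        out = regress_nuisance(_ts(signal[None, :]), reg)
        for k in range(3):
            c = reg[:, k] - reg[:, k].mean()
            assert abs(np.corrcoef(out.values[0], c)[0, 1]) < 1e-10

    def test_rank_deficient_warns(self, rng):
        reg = np.repeat(rng.standard_normal((60, 1)), 2, axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_nuisance(_ts(rng.standard_normal((2, 60))), reg)


class TestModwt:
    def test_boundary_width_db4_scale3(self):
        # (2^3 - 1) * (8 - 1) = 49 circularity-affected coefficients
        assert boundary_width("db4", 3) == 49
        assert n_usable_coefficients(140, 3) == 91

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match=str(min_length("db4", 3))):
            modwt_detail(np.zeros(30), 3)

    def test_one_level_energy_preservation(self, rng):
        # ||W1||^2 + ||V1||^2 = ||x||^2 for the rescaled filter pair
        from connectopharm.modwt import _circular_filter, _filters

        x = rng.standard_normal(256)
        h, g = _filters("db4")
        w1 = _circular_filter(x[None, :], h, 1)
        v1 = _circular_filter(x[None, :], g, 1)
        assert np.sum(w1**2) + np.sum(v1**2) == pytest.approx(np.sum(x**2), rel=1e-10)


class TestWaveletCorrelation:
    def test_duplicated_series_r_one(self, rng):
        x = rng.standard_normal(140)
        ts = _ts(np.vstack([x, x]))
        r = wavelet_correlation(ts, scale=3).values
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_series_r_minus_one(self, rng):
        x = rng.standard_normal(140)
        r = wavelet_correlation(_ts(np.vstack([x, -x])), scale=3).values
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.standard_normal((3, 140))
        r1 = wavelet_correlation(_ts(x), scale=3).values
        y = x * np.array([[2.0], [0.5], [7.0]]) + np.array([[1.0], [-3.0], [0.0]])
        r2 = wavelet_correlation(_ts(y), scale=3).values
        assert np.allclose(r1, r2, atol=1e-10)

    def test_null_calibration_small(self, rng):
        bound = 2.58 / np.sqrt(effective_df(140, 3))
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            r = wavelet_correlation(_ts(rng.standard_normal((2, 140))), 3).values[0, 1]
            hits += abs(r) < bound
        assert hits / n_rep >= 0.98

    def test_short_series_error_names_minimum(self, rng):
        with pytest.raises(ValueError, match="need at least"):
            wavelet_correlation(_ts(rng.standard_normal((2, 40))), scale=3)


class TestFisherZ:
    def test_zero_maps_to_zero_and_oracle_value(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        z = fisher_z(AssociationMatrix(r)).values
        assert z[0, 1] == 0.0
        # atanh(0.5) by series: sum r^(2k+1)/(2k+1)
        series = sum(0.5 ** (2 * k + 1) / (2 * k + 1) for k in range(60))
        assert z[0, 2] == pytest.approx(series, abs=1e-12)
        assert z[0, 2] == pytest.approx(0.54931, abs=1e-5)
        assert np.all(np.diag(z) == 0)

    @pytest.mark.parametrize("r", np.round(np.arange(0.1, 1.0, 0.1), 1))
    def test_odd_symmetry(self, r):
        m_pos = np.array([[1.0, r], [r, 1.0]])
        m_neg = np.array([[1.0, -r], [-r, 1.0]])
        zp = fisher_z(AssociationMatrix(m_pos)).values[0, 1]
        zn = fisher_z(AssociationMatrix(m_neg)).values[0, 1]
        assert zp == -zn

    def test_clipping_at_unity_warns(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="clip"):
            z = fisher_z(AssociationMatrix(m))
        assert np.isfinite(z.values).all()

    @given(
        st.lists(
            st.floats(min_value=-0.999, max_value=0.999), min_size=2, max_size=8, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotonic(self, rs):
        rs = sorted(rs)
        zs = [
            fisher_z(AssociationMatrix(np.array([[1.0, r], [r, 1.0]]))).values[0, 1]
            for r in rs
        ]
        assert all(a < b for a, b in zip(zs, zs[1:]))


class TestCoverage:
    def test_rule_application(self):
        valid = np.ones((20, 3), dtype=bool)
        valid[:12, 0] = False  # invalid in 12 subjects -> dropped
        valid[:9, 1] = False  # invalid in 9 subjects -> kept
        assert coverage_exclude(valid, min_subjects=10) == [1, 2]

    def test_all_valid_identity(self):
        valid = np.ones((5, 4), dtype=bool)
        assert coverage_exclude(valid) == [0, 1, 2, 3]

    def test_dropping_all_nodes_rejected(self):
        valid = np.zeros((12, 2), dtype=bool)
        with pytest.raises(ValueError, match="every node"):
            coverage_exclude(valid, min_subjects=10)


class TestLocalThreshold:
    def test_worked_example_mst(self, four_node_assoc):
        g = local_threshold(four_node_assoc, 0.5)
        assert g.edges.tolist() == [[0, 1], [0, 2], [0, 3]]

    def test_worked_example_second_round_trim(self, four_node_assoc):
        g = local_threshold(four_node_assoc, 4 / 6)
        assert g.edges.tolist() == [[0, 1], [0, 2], [0, 3], [2, 3]]

    def test_exact_density_and_connectedness(self, rng):
        for _ in range(10):
            n = 50
            m = rng.standard_normal((n, n))
            m = np.clip((m + m.T) / 6, -0.99, 0.99)
            np.fill_diagonal(m, 1.0)
            a = AssociationMatrix(m)
            for d in (0.05, 0.06, 0.1, 0.3):
                g = local_threshold(a, d)
                assert g.n_edges == round(d * n * (n - 1) / 2)
                assert g.is_connected()

    def test_density_below_tree_rejected(self, four_node_assoc):
        with pytest.raises(ValueError, match="spanning-tree"):
            local_threshold(four_node_assoc, 0.1)

    def test_fisher_z_ordering_invariance(self, rng):
        # thresholding is rank-based, so r and fisher-z give identical graphs
        m = rng.standard_normal((30, 30))
        m = np.clip((m + m.T) / 6, -0.99, 0.99)
        np.fill_diagonal(m, 1.0)
        a = AssociationMatrix(m)
        g_r = local_threshold(a, 0.2)
        g_z = local_threshold(fisher_z(a), 0.2)
        assert np.array_equal(g_r.edges, g_z.edges)
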
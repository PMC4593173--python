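"""Tests for MVAR estimation, order selection, PDC and flow aggregation."""

import numpy as np
import pandas as pd
import pytest

from ssvepflow import (
    SignalSegment,
    aggregate_flows,
    band_average,
    fit_mvar,
    generate_var_fixture,
    pdc_spectrum,
    segment_flows,
    select_order_aic,
)
from ssvepflow.pdc import FlowSummary, MVARModel, SingularityError, mvar_aic

VAR2_A1 = np.array([[0.5, 0.1, 0.0], [0.3, 0.4, 0.0], [0.0, 0.2, 0.3]])
VAR2_A2 = np.array([[-0.2, 0.0, 0.0], [0.0, -0.1, 0.1], [0.1, 0.0, -0.2]])


@pytest.fixture(scope="module")
def var2_segment():
    return generate_var_fixture([VAR2_A1, VAR2_A2], 1.0, 3000, seed=8)


class TestFitMvar:
    def test_recovers_known_var2_within_3_se(self, var2_segment):
        model = fit_mvar(var2_segment, 2, demean=False)
        truth = np.stack([VAR2_A1, VAR2_A2])
        # asymptotic standard errors from the regressor covariance
        x = var2_segment.data.T
        n, N = x.shape
        Z = np.concatenate([x[2 - r : n - r] for r in (1, 2)], axis=1)
        zinv = np.linalg.inv(Z.T @ Z)
        for i in range(N):
            se = np.sqrt(model.sigma[i, i] * np.diag(zinv)).reshape(2, N)
            assert np.all(np.abs(model.coefs[:, i, :] - truth[:, i, :]) < 3.5 * se)

    def test_matches_brute_force_normal_equations(self, var2_segment):
        """Per-channel solve of the normal equations Z'Z b = Z'y is an
        independent route to the same least-squares estimate."""
        model = fit_mvar(var2_segment, 3, demean=False)
        x = var2_segment.data.T
        n, N = x.shape
        Z = np.concatenate([x[3 - r : n - r] for r in (1, 2, 3)], axis=1)
        for i in range(N):
            b = np.linalg.solve(Z.T @ Z, Z.T @ x[3:, i])
            assert model.coefs[:, i, :].ravel() == pytest.approx(b, abs=1e-10)

    def test_matches_statsmodels_var(self, var2_segment):
        sm = pytest.importorskip("statsmodels.tsa.api")
        res = sm.VAR(var2_segment.data.T).fit(2, trend="n")
        model = fit_mvar(var2_segment, 2, demean=False)
        assert model.coefs == pytest.approx(res.coefs, abs=1e-8)

    def test_residuals_orthogonal_to_regressors(self, var2_segment):
        model = fit_mvar(var2_segment, 2)
        x = var2_segment.data.T - var2_segment.data.T.mean(axis=0)
        n = x.shape[0]
        Z = np.concatenate([x[2 - r : n - r] for r in (1, 2)], axis=1)
        B = model.coefs.transpose(1, 0, 2).reshape(3, -1).T
        resid = x[2:] - Z @ B
        assert np.abs(Z.T @ resid).max() < 1e-7 * np.abs(Z).max() * n

    def test_white_noise_coefficients_small(self, rng):
        x = rng.normal(size=(4, 3000))
        model = fit_mvar(SignalSegment(x, 1000.0, tuple("abcd")), 2)
        # each coefficient's se is ~ 1/sqrt(n); allow 4 sigma
        assert np.abs(model.coefs).max() < 4.0 / np.sqrt(3000 - 2)

    def test_rank_deficiency_names_channels(self):
        x = np.zeros((2, 500))
        x[0] = np.arange(500) * 0.0
        seg = SignalSegment(x + 0.0, 1000.0, ("flat1", "flat2"))
        with pytest.raises(SingularityError, match="flat1"):
            fit_mvar(seg, 2)


@pytest.fixture(scope="module")
def var6_segment():
    # bivariate VAR(6) with strong lag-6 structure
    A = [np.zeros((2, 2)) for _ in range(6)]
    A[0] = np.array([[0.3, 0.0], [0.2, 0.3]])
    A[5] = np.array([[0.35, 0.0], [0.25, 0.3]])
    return generate_var_fixture(A, 1.0, 3000, seed=9)


class TestOrderSelection:
    def test_recovers_order_6_within_search_range(self, var6_segment):
        sel = select_order_aic(var6_segment, 5, 20)
        assert sel.order == 6

    def test_result_clamped_to_range_with_full_curve(self, var2_segment):
        sel = select_order_aic(var2_segment, 5, 20)
        assert 5 <= sel.order <= 20
        assert len(sel.aic) == len(sel.orders) == 16

    def test_ties_resolve_to_smallest(self):
        # construct a degenerate tie by monkey-free means: argmin picks first
        orders = np.arange(5, 8)
        aic = np.array([1.0, 1.0, 2.0])
        assert orders[int(np.argmin(aic))] == 5


class TestPDCSpectrum:
    def test_diagonal_model_has_zero_offdiagonal_pdc(self):
        coefs = np.stack([np.diag([0.5, -0.3, 0.2])])
        model = MVARModel(coefs, np.eye(3), ("a", "b", "c"), 1000)
        spec = pdc_spectrum(model, fs=1000.0)
        off = ~np.eye(3, dtype=bool)
        assert np.all(spec.values[off] == 0)

    def test_normalization_sums_to_one_per_source(self, var2_segment):
        model = fit_mvar(var2_segment, 2)
        spec = pdc_spectrum(model, fs=var2_segment.fs)
        colsums = (spec.values**2).sum(axis=0)
        assert np.allclose(colsums, 1.0, atol=1e-10)
        assert spec.values.min() >= 0 and spec.values.max() <= 1

    def test_bivariate_closed_form(self):
        """For x2 driven by x1 with lag-1 coefficient c, PDC from 1 to 2 has
        the closed form |c z| / sqrt(|1 - a z|^2 + |c z|^2)."""
        a, c = 0.4, 0.5
        coefs = np.array([[[a, 0.0], [c, 0.3]]])
        model = MVARModel(coefs, np.eye(2), ("x1", "x2"), 1000)
        freqs = np.arange(1.0, 500.0)
        spec = pdc_spectrum(model, freqs, fs=1000.0)
        z = np.exp(-2j * np.pi * freqs / 1000.0)
        expected = np.abs(-c * z) / np.sqrt(np.abs(1 - a * z) ** 2 + np.abs(c * z) ** 2)
        assert spec.values[1, 0, :] == pytest.approx(expected, abs=1e-12)
        assert np.all(spec.values[0, 1, :] == 0)


class TestBandAverage:
    def _flat_spectrum(self, value=0.25):
        freqs = np.arange(1.0, 500.0)
        values = np.full((2, 2, freqs.size), value)
        from ssvepflow.pdc import PDCSpectrum

        return PDCSpectrum(freqs, values, ("a", "b"))

    def test_constant_spectrum_averages_to_constant(self):
        flows = band_average(self._flat_spectrum(0.25), (6, 92))
        assert np.all(flows.to_numpy() == pytest.approx(0.25))

    def test_monotonicity(self, var2_segment):
        model = fit_mvar(var2_segment, 2)
        spec = pdc_spectrum(model, fs=var2_segment.fs)
        from ssvepflow.pdc import PDCSpectrum

        bigger = PDCSpectrum(spec.freqs, np.minimum(spec.values + 0.1, 1.0), spec.labels)
        assert np.all(
            band_average(bigger, (6, 92)).to_numpy()
            >= band_average(spec, (6, 92)).to_numpy()
        )

    def test_agrees_with_quadrature_oracle(self, var2_segment):
        model = fit_mvar(var2_segment, 2)
        spec = pdc_spectrum(model, fs=var2_segment.fs)
        flows = band_average(spec, (6, 92))
        mask = (spec.freqs >= 6) & (spec.freqs <= 92)
        f = spec.freqs[mask]
        oracle = np.trapezoid(spec.values[:, :, mask], f, axis=2) / (f[-1] - f[0])
        # trapezoid and arithmetic mean agree on the default 1 Hz grid
        assert flows.to_numpy() == pytest.approx(oracle, abs=2e-3)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="does not intersect"):
            band_average(self._flat_spectrum(), (600, 700))


class TestAggregateFlows:
    GROUPS = {"VC": ["V1_L", "V1_R", "V2_L", "V2_R"], "FA": ["FrA_L", "FrA_R"]}
    LABELS = ["V1_L", "V1_R", "V2_L", "V2_R", "FrA_L", "FrA_R"]

    def test_all_ones_counts_ordered_pairs(self):
        mat = pd.DataFrame(np.ones((6, 6)), index=self.LABELS, columns=self.LABELS)
        s = aggregate_flows(mat, self.GROUPS)
        assert (s.vc_to_fa, s.fa_to_vc, s.within_fa, s.within_vc) == (8, 8, 2, 12)

    def test_zero_matrix_gives_zero_flows(self):
        mat = pd.DataFrame(np.zeros((6, 6)), index=self.LABELS, columns=self.LABELS)
        s = aggregate_flows(mat, self.GROUPS)
        assert s == FlowSummary(0, 0, 0, 0)

    def test_missing_label_is_lookup_error(self):
        mat = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(KeyError, match="V1_L"):
            aggregate_flows(mat, self.GROUPS)

    def test_overlapping_groups_rejected(self):
        mat = pd.DataFrame(np.ones((6, 6)), index=self.LABELS, columns=self.LABELS)
        groups = {"VC": ["V1_L", "FrA_L"], "FA": ["FrA_L", "FrA_R"]}
        with pytest.raises(ValueError, match="overlap"):
            aggregate_flows(mat, groups)

    def test_permutation_symmetry(self, rng):
        mat = rng.uniform(0, 1, (6, 6))
        df = pd.DataFrame(mat, index=self.LABELS, columns=self.LABELS)
        perm = list(reversed(self.LABELS))
        df_perm = df.loc[perm, perm]
        assert aggregate_flows(df, self.GROUPS) == aggregate_flows(df_perm, self.GROUPS)


class TestDirectionRecovery:
    GROUPS = TestAggregateFlows.GROUPS

    def test_planted_coupling_ordered_in_95_of_100_seeds(self):
        """Unidirectional x1 -> x2 coupling must order the band-averaged
        flows in at least 95 of 100 seeded realisations at n = 3000."""
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        wins = 0
        for seed in range(100):
            seg = generate_var_fixture([A], 1.0, 3000, seed=seed)
            model = fit_mvar(seg, 5)
            flows = band_average(pdc_spectrum(model, fs=seg.fs), (6, 92))
            if flows.at["ch2", "ch1"] > flows.at["ch1", "ch2"]:
                wins += 1
        assert wins >= 95

    def test_planted_vc_to_fa_structure_in_study_montage(self):
        from ssvepflow.synthetic_data import (
            ELECTRODE_LABELS,
            _electrode_var_coefficients,
        )

        seg = generate_var_fixture(
            _electrode_var_coefficients(0.30), 1.0, 3000, seed=3,
            labels=ELECTRODE_LABELS,
        )
        summary, _, _ = segment_flows(seg, self.GROUPS, (6, 92), order=5)
        assert summary.vc_to_fa > summary.fa_to_vc
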
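"""NRF derivation, stimulus-component selection, magnitudes, age trends."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from nrfage.nrf import (NRF, NRFConfig, component_betas, derive_components,
                        nrf_magnitude, select_stimulus_components, unit_normalize,
                        weekly_age_trend)

CFG = NRFConfig()


class TestUnitNormalize:
    def test_constant_row(self):
        x, keep = unit_normalize(np.full((1, 4), 2.0))
        np.testing.assert_allclose(x, 0.5)
        assert keep.all()

    def test_rows_have_unit_norm(self):
        x, _ = unit_normalize(np.random.default_rng(0).normal(size=(6, 40)))
        np.testing.assert_allclose(np.linalg.norm(x, axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self):
        row = np.random.default_rng(1).normal(size=(1, 30))
        a, _ = unit_normalize(row)
        b, _ = unit_normalize(10.0 * row)
        np.testing.assert_allclose(a, b)

    def test_zero_row_excluded_with_warning(self):
        x = np.vstack([np.ones(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="all-zero"):
            out, keep = unit_normalize(x)
        assert out.shape == (1, 5)
        assert list(keep) == [True, False]


class TestDeriveComponents:
    def test_rank_one_matrix(self):
        wave = np.sin(np.linspace(0, 2 * np.pi, 100))
        x = np.outer([1.0, 2.0, -0.5], wave)
        cs = derive_components(x, NRFConfig(center=False))
        assert cs.components.shape[0] == 1
        assert cs.cumulative_variance_pct == pytest.approx(100.0)

    def test_components_orthonormal(self):
        x = np.random.default_rng(2).normal(size=(20, 80))
        cs = derive_components(x, CFG)
        gram = cs.components @ cs.components.T
        np.testing.assert_allclose(gram, np.eye(cs.components.shape[0]), atol=1e-8)

    def test_retained_variance_exceeds_threshold(self):
        x = np.random.default_rng(3).normal(size=(15, 60))
        cs = derive_components(x, CFG)
        assert cs.cumulative_variance_pct > CFG.variance_threshold_pct

    def test_two_orthogonal_waveforms_recovered(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 200)
        u = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        loads = rng.normal(size=(30, 2))
        x = loads @ u + 0.01 * rng.normal(size=(30, 200))
        cs = derive_components(x, CFG)
        angles = subspace_angles(cs.components[:2].T, u.T)
        assert np.degrees(angles).max() < 5.0

    def test_dominant_deflection_negative(self):
        x = np.random.default_rng(5).normal(size=(10, 50))
        cs = derive_components(x, CFG)
        for comp in cs.components:
            assert comp[np.argmax(np.abs(comp))] <= 0


class TestSelection:
    def _scenario(self, rng, n=15, s=200, stim_locked=True):
        t = np.linspace(0, 1, s)
        u_shared = np.sin(2 * np.pi * t) / np.linalg.norm(np.sin(2 * np.pi * t))
        u_stim = np.cos(2 * np.pi * t) / np.linalg.norm(np.cos(2 * np.pi * t))
        a = rng.normal(1.0, 0.3, n)
        b = rng.normal(1.0, 0.1, n) if stim_locked else np.zeros(n)
        stim = np.outer(a, u_shared) + np.outer(b, u_stim)
        rest = np.outer(a, u_shared)
        return stim, rest, u_stim

    def test_injected_component_selected_with_correct_betas(self):
        rng = np.random.default_rng(6)
        stim, rest, u_stim = self._scenario(rng)
        cs = derive_components(np.vstack([stim, rest]), CFG)
        nrfs, b_stim, b_rest = select_stimulus_components(cs, stim, rest, CFG,
                                                          modality="visual")
        assert len(nrfs) >= 1
        j = max(range(cs.components.shape[0]),
                key=lambda k: abs(cs.components[k] @ u_stim))
        assert any(n.component_index == j for n in nrfs)
        sign = np.sign(cs.components[j] @ u_stim)
        assert sign * b_stim[:, j].mean() == pytest.approx(1.0, abs=0.1)
        assert b_rest[:, j].mean() == pytest.approx(0.0, abs=0.1)

    def test_identical_conditions_select_nothing(self):
        rng = np.random.default_rng(7)
        stim, rest, _ = self._scenario(rng, stim_locked=False)
        cs = derive_components(np.vstack([stim, rest]), CFG)
        nrfs, *_ = select_stimulus_components(cs, stim, rest, CFG)
        assert nrfs == []

    def test_null_selection_rate_near_alpha(self):
        """Absent component: per-run selection of a pure-noise component stays
        within alpha + 0.02 over 200 seeded runs."""
        rng = np.random.default_rng(8)
        hits = 0
        t = np.linspace(0, 1, 120)
        u = np.sin(2 * np.pi * t) / np.linalg.norm(np.sin(2 * np.pi * t))
        for _ in range(200):
            stim = np.outer(rng.normal(1, 0.3, 12), u) + 0.05 * rng.normal(size=(12, 120))
            rest = np.outer(rng.normal(1, 0.3, 12), u) + 0.05 * rng.normal(size=(12, 120))
            cs = derive_components(np.vstack([stim, rest]), CFG)
            nrfs, *_ = select_stimulus_components(cs, stim, rest, CFG)
            if any(n.component_index == 0 for n in nrfs):
                hits += 1
        assert hits / 200 <= CFG.selection_alpha + 0.02

    def test_too_few_recordings_error(self):
        cs = derive_components(np.random.default_rng(9).normal(size=(4, 30)), CFG)
        with pytest.raises(ValueError):
            select_stimulus_components(cs, np.ones((2, 30)), np.zeros((2, 30)), CFG)

    def test_component_betas_recover_loadings(self):
        rng = np.random.default_rng(10)
        comps = np.linalg.qr(rng.normal(size=(50, 3)))[0].T
        loads = rng.normal(size=(8, 3))
        y = loads @ comps + 0.7  # constant offset absorbed by the intercept
        np.testing.assert_allclose(component_betas(comps, y), loads, atol=1e-9)


def _make_nrf(window=(0.0, 1.0), sfreq=500.0):
    n = int((window[1] - window[0]) * sfreq)
    t = np.arange(n) / sfreq
    wave = np.sin(2 * np.pi * 3 * t)
    wave /= np.linalg.norm(wave)
    return NRF("visual", 0, window, wave, 50.0, 5.0, 0.001)


class TestMagnitude:
    def test_exact_recovery_noiseless(self):
        nrf = _make_nrf()
        m = nrf_magnitude(3.0 * nrf.waveform, nrf, 500.0, CFG)
        assert m.beta == pytest.approx(3.0, abs=1e-9)
        assert m.applied_shift_s == 0.0

    def test_orthogonal_nuisance_leaves_slope(self):
        """Regression step in isolation (jitter disabled): a nuisance
        orthogonal to the centered NRF leaves the slope at exactly 1."""
        nrf = _make_nrf()
        n = nrf.waveform.size
        t = np.arange(n) / 500.0
        nuisance = np.cos(2 * np.pi * 3 * t)  # orthogonal, zero-mean
        x = nrf.waveform - nrf.waveform.mean()
        y = nrf.waveform + 0.8 * nuisance
        beta_oracle = x @ (y - y.mean()) / (x @ x)  # normal-equation oracle
        cfg = NRFConfig(magnitude_jitter_s=1e-6)  # k_max = 0: pure regression
        m = nrf_magnitude(y, nrf, 500.0, cfg)
        assert m.applied_shift_s == 0.0
        assert m.beta == pytest.approx(beta_oracle, abs=1e-9)
        assert m.beta == pytest.approx(1.0, abs=1e-6)

    def test_delayed_response_recovered_after_alignment(self):
        nrf = _make_nrf()
        delayed = np.roll(nrf.waveform, int(0.03 * 500))
        m = nrf_magnitude(delayed, nrf, 500.0, CFG)
        assert m.applied_shift_s == pytest.approx(-0.03, abs=1 / 500)
        assert m.beta == pytest.approx(1.0, rel=0.05)

    def test_scaling_linearity(self):
        nrf = _make_nrf()
        rng = np.random.default_rng(11)
        y = nrf.waveform + 0.1 * rng.normal(size=nrf.waveform.size)
        b1 = nrf_magnitude(y, nrf, 500.0, CFG).beta
        b5 = nrf_magnitude(5.0 * y, nrf, 500.0, CFG).beta
        assert b5 == pytest.approx(5.0 * b1, rel=1e-12)

    def test_windowed_nrf_zero_padded(self):
        nrf = _make_nrf(window=(0.1, 0.5))
        response = np.zeros(500)
        a = int(0.1 * 500)
        response[a:a + nrf.waveform.size] = 2.0 * nrf.waveform
        m = nrf_magnitude(response, nrf, 500.0, CFG)
        assert m.beta == pytest.approx(2.0, abs=1e-9)

    def test_degenerate_nrf_errors(self):
        nrf = _make_nrf()
        nrf.waveform = np.ones_like(nrf.waveform)
        with pytest.raises(ValueError, match="degenerate"):
            nrf_magnitude(np.ones(500), nrf, 500.0, CFG)


class TestWeeklyTrend:
    def test_exact_linear_trend(self):
        pma_days = np.repeat([7 * 30, 7 * 31, 7 * 32, 7 * 33], 3)
        betas = 2.0 * np.floor(pma_days / 7)
        trend = weekly_age_trend(betas, pma_days)
        assert trend.slope_per_week == pytest.approx(2.0)
        assert trend.p_value < 1e-6

    def test_too_few_weeks_error(self):
        with pytest.raises(ValueError):
            weekly_age_trend(np.ones(4), np.array([210, 210, 217, 217]))

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(12)
        pma_days = rng.integers(196, 280, 60)
        betas = rng.normal(size=60)
        trend = weekly_age_trend(betas, pma_days)
        assert abs(trend.slope_per_week) < 0.5

    def test_slow_wave_magnitudes_decline_with_age(self, default_study):
        """End-to-end generative check: in the default synthetic study, each
        modality's leading (slow-wave) NRF has a negative weekly slope."""
        for modality, res in default_study.modalities.items():
            lead = [t for t in res.trends if t.nrf_name.endswith("nrf1")]
            assert lead and lead[0].slope_per_week < 0
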
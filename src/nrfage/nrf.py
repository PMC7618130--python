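"""Neurodynamic response functions: derivation, selection, magnitudes.

Recording-specific stimulus and rest averages (unit-normalised so morphology,
not amplitude, drives the decomposition) are stacked and decomposed by PCA
over the time dimension. The smallest component set explaining more than 95%
of the variance is retained; each retained component is regressed (jointly,
with an intercept) onto the raw stimulus and rest averages, and components
whose per-recording stimulus betas differ from the rest betas in a two-sided
paired t-test at alpha = 0.05 become NRFs. A recording's NRF magnitude is the
slope of a simple linear regression of the Woody-aligned broadband response
on the NRF — the evoked-potential analogue of a voxelwise haemodynamic
response function beta. No multiple-comparison correction is applied
anywhere in this module; trend p-values are a guide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from nrfage.alignment import woody_align


@dataclass(frozen=True)
class NRFConfig:
    variance_threshold_pct: float = 95.0
    selection_alpha: float = 0.05
    center: bool = True  # mean-center across recordings before PCA
    magnitude_band_hz: tuple[float, float] = (0.1, 30.0)
    magnitude_jitter_s: float = 0.05
    magnitude_window_s: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold_pct <= 100:
            raise ValueError("variance_threshold_pct must be in (0, 100]")
        if not 0 < self.selection_alpha < 1:
            raise ValueError("selection_alpha must be in (0, 1)")


@dataclass
class NRF:
    """A characteristic unit-scale evoked waveform."""

    modality: str
    component_index: int
    time_window_s: tuple[float, float]
    waveform: np.ndarray
    variance_explained_pct: float
    selection_t: float
    selection_p: float

    @property
    def name(self) -> str:
        return f"{self.modality}_nrf{self.component_index + 1}"


@dataclass
class NRFMagnitude:
    recording_id: str
    nrf_name: str
    beta: float  # microvolts per unit NRF
    applied_shift_s: float


@dataclass
class AgeTrend:
    nrf_name: str
    weeks: np.ndarray
    weekly_means: np.ndarray
    intercept: float
    slope_per_week: float
    p_value: float


def unit_normalize(averages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each row to unit Euclidean norm over the entire time window.

    Returns ``(normalized, keep_mask)``; all-zero rows are excluded with a
    warning (their mask entry is False).
    """
    x = np.asarray(averages, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    keep = norms > 0
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} all-zero rows from normalization")
    return x[keep] / norms[keep, None], keep


@dataclass
class ComponentSet:
    components: np.ndarray  # retained, k x samples, orthonormal rows
    variance_explained_pct: np.ndarray  # per retained component
    cumulative_variance_pct: float
    n_total: int


def derive_components(normalized: np.ndarray, cfg: NRFConfig = NRFConfig()) -> ComponentSet:
    """PCA over the time dimension; retain the smallest set of leading
    components whose cumulative explained variance exceeds the threshold.

    Component signs are fixed so the largest-|amplitude| sample is negative,
    matching the negative polarity of the dominant evoked deflections.
    """
    x = np.asarray(normalized, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for a decomposition")
    if cfg.center:
        x = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("degenerate input: zero variance")
    pct = 100.0 * var / total
    cum = np.cumsum(pct)
    k = int(np.searchsorted(cum, cfg.variance_threshold_pct, side="right")) + 1
    k = min(k, pct.size)
    comps = vt[:k].copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] > 0:
            row *= -1.0
    return ComponentSet(comps, pct[:k], float(cum[k - 1]), pct.size)


def component_betas(components: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Joint multiple regression (with intercept) of all retained components
    onto each raw response row; returns recordings x components betas."""
    comps = np.asarray(components, dtype=float)
    y = np.asarray(responses, dtype=float)
    design = np.column_stack([np.ones(comps.shape[1]), comps.T])
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return coef[1:].T


def select_stimulus_components(componentset: ComponentSet, stim_raw: np.ndarray,
                               rest_raw: np.ndarray, cfg: NRFConfig = NRFConfig(), *,
                               modality: str = "", time_window_s: tuple[float, float] = (0.0, 1.0),
                               ) -> tuple[list[NRF], np.ndarray, np.ndarray]:
    """Keep components whose stimulus betas differ from rest betas.

    Per recording and condition the retained components are jointly fitted to
    the non-normalised average; per component, a two-sided paired t-test
    compares stimulus and rest betas, and components with p < alpha become
    NRFs. Zero-variance (or otherwise undefined) tests are non-significant.
    Returns ``(nrfs, stim_betas, rest_betas)``.
    """
    stim_raw = np.asarray(stim_raw, dtype=float)
    rest_raw = np.asarray(rest_raw, dtype=float)
    if stim_raw.shape != rest_raw.shape:
        raise ValueError("stimulus and rest rows must be matched")
    if stim_raw.shape[0] < 3:
        raise ValueError("need at least 3 paired recordings for selection")
    comps = componentset.components
    b_stim = component_betas(comps, stim_raw)
    b_rest = component_betas(comps, rest_raw)
    nrfs: list[NRF] = []
    for j in range(comps.shape[0]):
        diff = b_stim[:, j] - b_rest[:, j]
        # paired differences at floating-point noise level count as zero
        # variance (the t statistic is scale-invariant, so rounding error
        # would otherwise masquerade as a real effect)
        scale = max(np.std(b_stim[:, j]), np.std(b_rest[:, j]),
                    np.abs(b_stim[:, j]).max(), 1e-300)
        if np.std(diff, ddof=1) <= 1e-8 * scale:
            t_j, p_j = 0.0, 1.0
        else:
            t_j, p_j = stats.ttest_rel(b_stim[:, j], b_rest[:, j])
        if np.isnan(p_j):
            t_j, p_j = 0.0, 1.0
        if p_j < cfg.selection_alpha:
            nrfs.append(NRF(modality, j, time_window_s, comps[j].copy(),
                            float(componentset.variance_explained_pct[j]),
                            float(t_j), float(p_j)))
    return nrfs, b_stim, b_rest


def nrf_magnitude(response: np.ndarray, nrf: NRF, sfreq: float,
                  cfg: NRFConfig = NRFConfig(), *, recording_id: str = "") -> NRFMagnitude:
    """Slope of the Woody-aligned broadband response regressed on the NRF.

    The response covers the full magnitude window (0-1 s post-stimulus); the
    NRF is zero-padded outside its own analysis window for alignment, and the
    regression (simple OLS with intercept) runs over the NRF's window only.
    """
    response = np.asarray(response, dtype=float)
    w0, w1 = cfg.magnitude_window_s
    n_full = int(round((w1 - w0) * sfreq))
    if response.size != n_full:
        raise ValueError(f"response must cover the {w0}-{w1} s window ({n_full} samples)")
    a = int(round((nrf.time_window_s[0] - w0) * sfreq))
    b = a + nrf.waveform.size
    if a < 0 or b > n_full:
        raise ValueError("NRF window outside the magnitude window")
    template = np.zeros(n_full)
    template[a:b] = nrf.waveform
    x = nrf.waveform
    if np.std(x) == 0:
        raise ValueError("degenerate NRF: zero variance")
    shift, aligned, _ = woody_align(response, template, sfreq, cfg.magnitude_jitter_s)
    y = aligned[a:b]
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean()) / (xc @ xc))
    return NRFMagnitude(recording_id, nrf.name, beta, shift)


def weekly_age_trend(betas: np.ndarray, pma_days: np.ndarray,
                     nrf_name: str = "") -> AgeTrend:
    """OLS of the weekly-averaged NRF magnitudes on integer PMA week."""
    betas = np.asarray(betas, dtype=float)
    weeks_all = np.floor(np.asarray(pma_days, dtype=float) / 7.0).astype(int)
    weeks = np.unique(weeks_all)
    if weeks.size < 3:
        raise ValueError("need at least 3 distinct PMA weeks")
    means = np.array([betas[weeks_all == w].mean() for w in weeks])
    model = sm.OLS(means, sm.add_constant(weeks.astype(float))).fit()
    return AgeTrend(nrf_name, weeks, means, float(model.params[0]),
                    float(model.params[1]), float(model.pvalues[1]))
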
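"""Age-weighted grand averaging and Woody-filter latency alignment.

Each recording's evoked average is compared against an age-weighted grand
average of its PMA neighbours (Gaussian weights, FWHM 27 days, zero beyond
28 days) and temporally shifted to it by a Woody filter: the integer-sample
lag within +/-0.05 s that maximises the Pearson correlation with the
template. Rest averages receive the same treatment so that stimulus/rest
contrasts stay fair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AlignmentConfig:
    fwhm_days: float = 27.0
    zero_weight_beyond_days: float = 28.0
    max_jitter_s: float = 0.05
    n_refinement_passes: int = 2
    include_self: bool = True  # a recording contributes to its own template

    def __post_init__(self) -> None:
        if self.fwhm_days <= 0 or self.max_jitter_s <= 0:
            raise ValueError("fwhm_days and max_jitter_s must be > 0")
        if self.zero_weight_beyond_days < self.fwhm_days / 2:
            raise ValueError("zero-weight cutoff must be >= fwhm/2")
        if self.n_refinement_passes < 1:
            raise ValueError("need at least one alignment pass")


def age_weights(target_pma_days: float, all_pma_days: np.ndarray,
                cfg: AlignmentConfig = AlignmentConfig()) -> np.ndarray:
    """Gaussian PMA-distance weights: 1 at zero difference, 0 beyond cutoff."""
    delta = np.abs(np.asarray(all_pma_days, dtype=float) - target_pma_days)
    sigma = cfg.fwhm_days * FWHM_TO_SIGMA
    w = np.exp(-(delta**2) / (2.0 * sigma**2))
    w[delta > cfg.zero_weight_beyond_days] = 0.0
    return w


def age_weighted_average(averages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Sum of weight-scaled recording averages divided by the weight sum."""
    weights = np.asarray(weights, dtype=float)
    if not np.any(weights > 0):
        raise ValueError("no neighbours in age window (all weights zero)")
    return weights @ np.asarray(averages, dtype=float) / weights.sum()


def woody_align(signal: np.ndarray, template: np.ndarray, sfreq: float,
                max_jitter_s: float = 0.05,
                window: slice | None = None) -> tuple[float, np.ndarray, float]:
    """Align ``signal`` to ``template`` by a bounded integer-sample shift.

    Returns ``(shift_s, aligned, correlation)`` where the shift maximises the
    Pearson correlation between the template and the lagged signal within
    ``window`` (whole trace by default). The aligned trace is the signal
    shifted by that lag with nearest-value edge fill; ties prefer the
    smaller |lag|, so the returned correlation never falls below lag 0's.
    """
    signal = np.asarray(signal, dtype=float)
    template = np.asarray(template, dtype=float)
    if signal.shape != template.shape:
        raise ValueError("signal and template must share the sampling grid")
    if window is None:
        window = slice(0, signal.size)
    n_win = window.stop - window.start
    if n_win < 3:
        raise ValueError("correlation window shorter than 3 samples")

    k_max = int(np.floor(max_jitter_s * sfreq))
    pad = np.pad(signal, k_max, mode="edge")
    lags = np.arange(-k_max, k_max + 1)
    # lagged[k][i] = signal[i - k]
    shifted = np.stack([pad[k_max - k: k_max - k + signal.size][window] for k in lags])
    t = template[window]
    tc = t - t.mean()
    sc = shifted - shifted.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, sc @ tc / denom, 0.0)
    # argmax with ties broken toward |lag| = 0
    order = np.lexsort((np.abs(lags), -corr))
    best = order[0]
    k = int(lags[best])
    aligned = pad[k_max - k: k_max - k + signal.size]
    return k / sfreq, aligned, float(corr[best])


@dataclass
class AlignmentResult:
    """Aligned stimulus/rest averages and the shifts applied to them."""

    aligned_stim: np.ndarray  # recordings x samples
    aligned_rest: np.ndarray
    templates: np.ndarray  # per-recording age-weighted template
    shift_stim_s: np.ndarray
    shift_rest_s: np.ndarray
    correlation: np.ndarray  # stimulus-template correlation at the chosen lag


def build_age_templates(stim_averages: np.ndarray, rest_averages: np.ndarray,
                        pma_days: np.ndarray, sfreq: float,
                        cfg: AlignmentConfig = AlignmentConfig()) -> AlignmentResult:
    """Woody-filter every recording's averages to its age-weighted template.

    Refinement passes rebuild the templates from the aligned stimulus
    averages and re-derive each recording's shift from its original average,
    so shifts never compound across passes.
    """
    stim = np.asarray(stim_averages, dtype=float)
    rest = np.asarray(rest_averages, dtype=float)
    pma_days = np.asarray(pma_days, dtype=float)
    n = stim.shape[0]
    aligned = stim.copy()
    shifts = np.zeros(n)
    corrs = np.zeros(n)
    templates = np.empty_like(stim)
    for _ in range(cfg.n_refinement_passes):
        prev = shifts.copy()
        for i in range(n):
            w = age_weights(pma_days[i], pma_days, cfg)
            if not cfg.include_self:
                w[i] = 0.0
            templates[i] = age_weighted_average(aligned, w)
        for i in range(n):
            shifts[i], aligned[i], corrs[i] = woody_align(
                stim[i], templates[i], sfreq, cfg.max_jitter_s)
        if np.array_equal(prev, shifts):
            break
    shift_rest = np.zeros(n)
    aligned_rest = rest.copy()
    for i in range(n):
        shift_rest[i], aligned_rest[i], _ = woody_align(
            rest[i], templates[i], sfreq, cfg.max_jitter_s)
    return AlignmentResult(aligned, aligned_rest, templates, shifts, shift_rest, corrs)
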
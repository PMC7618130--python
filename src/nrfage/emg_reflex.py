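"""EMG reflex-withdrawal quantification and (brain) age correlations.

The EMG channel is band-pass filtered 10-500 Hz (Hamming windowed-sinc FIR,
cutoffs 8.75 and 562.5 Hz) with zero-phase notch filters at k*50 Hz
(k = 1..10), epoched from 5 s before the heel lance to 15 s after, and
rectified. Reflex start/end come from an envelope-threshold detector
(moving-average smoothing, baseline mean + k*SD threshold with a sustain
requirement); every constant is exposed in config because the detector is a
documented reconstruction, not a published algorithm. Reflex amplitude and
duration are then correlated one-tailed (negative direction — responses
refine with maturity) with PMA, brain age, and the adjusted brain-age gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import filtfilt, iirnotch

from nrfage.preprocess import FilterSpec, apply_fir
from nrfage.synthetic import Recording


@dataclass(frozen=True)
class EMGConfig:
    bandpass_hz: tuple[float, float] = (10.0, 500.0)
    bandpass_cutoffs_hz: tuple[float, float] = (8.75, 562.5)
    notch_base_hz: float = 50.0
    notch_harmonics: int = 10
    notch_q: float = 30.0
    epoch_window_s: tuple[float, float] = (-5.0, 15.0)
    smoothing_window_s: float = 0.05
    threshold_k_sd: float = 3.0
    min_onset_sustain_s: float = 0.1
    max_onset_latency_s: float = 2.0
    offset_quiet_fraction: float = 0.9  # tolerated re-crossings in the offset window
    baseline_screen_mult: float = 5.0
    baseline_screen_sustain_s: float = 0.2

    def __post_init__(self) -> None:
        if self.epoch_window_s[0] >= 0 or self.epoch_window_s[1] <= 0:
            raise ValueError("epoch window must bracket the lance at t=0")


@dataclass
class ReflexMeasure:
    recording_id: str
    detected: bool
    start_s: float = np.nan
    end_s: float = np.nan
    amplitude_uv: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s if self.detected else np.nan


@dataclass
class CorrelationResult:
    metric: str  # amplitude_uv | duration_s
    age_variable: str  # pma_weeks | brain_age_weeks | adjusted_gap_weeks
    r: float
    p_one_tailed: float
    n: int


def preprocess_emg(recording: Recording, cfg: EMGConfig = EMGConfig()
                   ) -> tuple[np.ndarray, np.ndarray] | None:
    """Filter, epoch around the lance, and rectify the EMG channel.

    Returns ``(times, rectified)`` or None when the recording has no EMG
    channel or no lance event.
    """
    if "EMG" not in recording.channels or not recording.events_of("lance"):
        return None
    fs = recording.sfreq_hz
    if cfg.bandpass_cutoffs_hz[1] >= fs / 2:
        raise ValueError("bandpass upper cutoff at or above Nyquist")
    x = recording.get_channel("EMG").astype(float)
    spec = FilterSpec("bandpass", cfg.bandpass_hz, cfg.bandpass_cutoffs_hz)
    x = apply_fir(x, spec, fs)
    for k in range(1, cfg.notch_harmonics + 1):
        f0 = k * cfg.notch_base_hz
        if f0 >= fs / 2:
            break
        b, a = iirnotch(f0, cfg.notch_q, fs=fs)
        x = filtfilt(b, a, x)
    lance = recording.events_of("lance")[0].onset_s
    w0, w1 = cfg.epoch_window_s
    i0 = int(round((lance + w0) * fs))
    n = int(round((w1 - w0) * fs))
    if i0 < 0 or i0 + n > x.size:
        return None
    times = w0 + np.arange(n) / fs
    return times, np.abs(x[i0:i0 + n])


def _envelope(rectified: np.ndarray, sfreq: float, window_s: float) -> np.ndarray:
    n = max(int(round(window_s * sfreq)), 1)
    kernel = np.ones(n) / n
    return np.convolve(rectified, kernel, mode="same")


def _sustained_onsets(above: np.ndarray, n_sustain: int) -> np.ndarray:
    """Indices where ``above`` stays True for at least ``n_sustain`` samples."""
    if n_sustain <= 1:
        return np.flatnonzero(above)
    run = np.convolve(above.astype(int), np.ones(n_sustain, int), mode="valid")
    return np.flatnonzero(run == n_sustain)


def detect_reflex(times: np.ndarray, rectified: np.ndarray, sfreq: float,
                  cfg: EMGConfig = EMGConfig(), *, recording_id: str = "") -> ReflexMeasure:
    """Envelope-threshold reflex detection on a rectified lance epoch.

    Start: first post-stimulus time where the smoothed envelope exceeds
    baseline mean + k*SD, sustained for ``min_onset_sustain_s`` and within
    ``max_onset_latency_s``. End: first subsequent time the envelope stays
    below the threshold for twice the sustain window, tolerating brief noise
    re-crossings (``offset_quiet_fraction``); epoch end if never.
    Amplitude: mean rectified value between start and end.
    """
    env = _envelope(rectified, sfreq, cfg.smoothing_window_s)
    baseline = env[times < 0]
    mu0, sd0 = baseline.mean(), baseline.std()
    thr = mu0 + cfg.threshold_k_sd * sd0
    n_sustain = max(int(round(cfg.min_onset_sustain_s * sfreq)), 1)

    post = (times >= 0) & (times <= cfg.max_onset_latency_s)
    search = np.flatnonzero(post)
    onsets = _sustained_onsets(env[search] > thr, n_sustain)
    if onsets.size == 0:
        return ReflexMeasure(recording_id, detected=False)
    start_idx = search[onsets[0]]

    below = env[start_idx:] < thr
    n_off = 2 * n_sustain
    if below.size >= n_off:
        frac = np.convolve(below.astype(int), np.ones(n_off, int), mode="valid") / n_off
        offs = np.flatnonzero(below[: frac.size] & (frac >= cfg.offset_quiet_fraction))
    else:
        offs = np.array([], int)
    end_idx = start_idx + offs[0] if offs.size else rectified.size - 1
    amp = float(rectified[start_idx:end_idx + 1].mean())
    return ReflexMeasure(recording_id, True, float(times[start_idx]),
                         float(times[end_idx]), amp)


def baseline_movement_screen(times: np.ndarray, rectified: np.ndarray, sfreq: float,
                             cfg: EMGConfig = EMGConfig()) -> bool:
    """Automated proxy for the visual baseline screen: reject (False) when
    the baseline envelope exceeds a multiple of its own median for a
    sustained period."""
    env = _envelope(rectified, sfreq, cfg.smoothing_window_s)
    baseline = env[times < 0]
    thr = cfg.baseline_screen_mult * np.median(baseline)
    n_sustain = max(int(round(cfg.baseline_screen_sustain_s * sfreq)), 1)
    return _sustained_onsets(baseline > thr, n_sustain).size == 0


def measures_table(measures: list[ReflexMeasure]) -> pd.DataFrame:
    return pd.DataFrame([{"recording_id": m.recording_id, "detected": m.detected,
                          "start_s": m.start_s, "end_s": m.end_s,
                          "duration_s": m.duration_s, "amplitude_uv": m.amplitude_uv}
                         for m in measures])


def correlate_with_age(measures: pd.DataFrame, predictions: pd.DataFrame,
                       ) -> list[CorrelationResult]:
    """Pearson r with one-tailed p (alternative: negative) for each of
    {amplitude, duration} x {PMA, brain age, adjusted gap}."""
    merged = measures[measures["detected"]].merge(predictions, on="recording_id")
    if len(merged) < 4:
        raise ValueError("need at least 4 paired observations")
    out = []
    for metric in ("amplitude_uv", "duration_s"):
        for age_var in ("pma_weeks", "brain_age_weeks", "adjusted_gap_weeks"):
            if age_var not in merged.columns:
                continue
            x = merged[metric].to_numpy(float)
            y = merged[age_var].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                out.append(CorrelationResult(metric, age_var, np.nan, np.nan, len(merged)))
                continue
            res = stats.pearsonr(x, y, alternative="less")
            out.append(CorrelationResult(metric, age_var, float(res.statistic),
                                         float(res.pvalue), len(merged)))
    return out
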
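"""EEG preprocessing: FIR filtering, epoching, artifact rejection, inclusion.

Filters are Hamming windowed-sinc FIR designs applied single-pass with
group-delay compensation (zero phase, -6 dB at the stated cutoff). The
broadband analysis branch is 0.1-30 Hz; the NRF-derivation branch adds a
12 Hz low-pass. Epochs span 1 s before to 1 s after stimulus onset
(half-open, exactly 2*sfreq samples), are baseline corrected to
[-0.5, 0) s, and are rejected when the pre-stimulus amplitude exceeds
+/-150 uV. A stimulus modality with fewer than five clean epochs is
excluded; a recording is dropped only when every stimulus modality is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import firwin, oaconvolve

from nrfage.synthetic import Event, Recording

STIMULUS_KINDS = ("visual", "tactile")


@dataclass(frozen=True)
class FilterSpec:
    """Hamming windowed-sinc FIR filter, specified by band edges.

    ``cutoff_hz`` is the -6 dB point; the transition width used for the
    Hamming design rule is twice the cutoff-to-passband-edge distance.
    """

    kind: str  # lowpass | highpass | bandpass
    passband_edge_hz: float | tuple[float, float]
    cutoff_hz: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    @property
    def transition_width_hz(self) -> float:
        edges = np.atleast_1d(self.passband_edge_hz).astype(float)
        cuts = np.atleast_1d(self.cutoff_hz).astype(float)
        return float(np.min(2.0 * np.abs(cuts - edges)))


#: the three EEG filters of the analysis
HIGHPASS_01 = FilterSpec("highpass", 0.1, 0.05)
LOWPASS_30 = FilterSpec("lowpass", 30.0, 33.75)
LOWPASS_12 = FilterSpec("lowpass", 12.0, 13.5)


@lru_cache(maxsize=32)
def _design_cached(kind: str, passband: tuple, cutoff: tuple, sfreq: float) -> np.ndarray:
    nyq = sfreq / 2.0
    if max(cutoff) >= nyq:
        raise ValueError(f"cutoff {max(cutoff)} Hz >= Nyquist {nyq} Hz")
    trans = FilterSpec(kind, passband if len(passband) > 1 else passband[0],
                       cutoff if len(cutoff) > 1 else cutoff[0]).transition_width_hz
    # Hamming window design rule: transition width ~ 3.3 / N (normalized)
    n_taps = int(np.ceil(3.3 * sfreq / trans))
    n_taps += 1 - n_taps % 2  # odd length -> type-I linear phase
    pass_zero = kind == "lowpass"
    cut = list(cutoff) if len(cutoff) > 1 else cutoff[0]
    return firwin(n_taps, cut, window="hamming", pass_zero=pass_zero, fs=sfreq)


def design_fir(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Return the FIR taps for ``spec`` at sampling rate ``sfreq``."""
    passband = tuple(np.atleast_1d(spec.passband_edge_hz).astype(float))
    cutoff = tuple(np.atleast_1d(spec.cutoff_hz).astype(float))
    return _design_cached(spec.kind, passband, cutoff, float(sfreq))


def apply_fir(signal: np.ndarray, spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Filter along the last axis, zero-phase via group-delay compensation."""
    taps = design_fir(spec, sfreq)
    x = np.asarray(signal, dtype=float)
    delay = (taps.size - 1) // 2
    if x.ndim == 1:
        y = oaconvolve(x, taps, mode="full")
        return y[delay:delay + x.size]
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = oaconvolve(x[i], taps, mode="full")[delay:delay + x.shape[-1]]
    return out


@dataclass(frozen=True)
class PreprocessConfig:
    epoch_window_s: tuple[float, float] = (-1.0, 1.0)
    baseline_window_s: tuple[float, float] = (-0.5, 0.0)
    reject_window_s: tuple[float, float] = (-1.0, 0.0)
    reject_ampl_uv: float = 150.0
    min_clean_epochs: int = 5
    rest_pad_count: int = 10
    rest_pad_interval_s: float = 10.0
    rest_pad_trigger_max: int = 5

    def __post_init__(self) -> None:
        w0, w1 = self.epoch_window_s
        for name in ("baseline_window_s", "reject_window_s"):
            a, b = getattr(self, name)
            if not (w0 <= a < b <= w1):
                raise ValueError(f"{name} must lie within the epoch window")
        if self.reject_ampl_uv <= 0 or self.min_clean_epochs <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class EpochSet:
    """Trials x samples matrix for one recording/modality/channel."""

    recording_id: str
    infant_id: str
    pma_days: int
    modality: str
    channel: str
    sfreq_hz: float
    data: np.ndarray  # trials x samples, microvolts
    times: np.ndarray  # seconds, stimulus at 0
    kept: np.ndarray  # bool mask over trials
    reject_reason: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.kept.size or len(self.reject_reason) != self.kept.size:
            raise ValueError("mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def window_indices(self, window_s: tuple[float, float]) -> slice:
        """Half-open sample slice for a time window relative to stimulus."""
        t0 = self.times[0]
        a = int(round((window_s[0] - t0) * self.sfreq_hz))
        b = int(round((window_s[1] - t0) * self.sfreq_hz))
        if a < 0 or b > self.times.size:
            raise ValueError(f"window {window_s} outside epoch")
        return slice(a, b)


def epoch_and_baseline(recording: Recording, kind: str, channel: str,
                       cfg: PreprocessConfig, *, signal: np.ndarray | None = None) -> EpochSet:
    """Extract baseline-corrected epochs around all events of ``kind``.

    ``signal`` may supply a pre-filtered version of the channel (the caller
    owns the filter-branch choice); it defaults to the raw channel data.
    Events too close to the recording edge are flagged "unepochable".
    """
    x = recording.get_channel(channel) if signal is None else np.asarray(signal, dtype=float)
    fs = recording.sfreq_hz
    w0, w1 = cfg.epoch_window_s
    n_samp = int(round((w1 - w0) * fs))
    times = w0 + np.arange(n_samp) / fs
    b = slice(int(round((cfg.baseline_window_s[0] - w0) * fs)),
              int(round((cfg.baseline_window_s[1] - w0) * fs)))

    events = sorted(recording.events_of(kind), key=lambda e: e.onset_s)
    if not events:
        warnings.warn(f"no {kind!r} events in {recording.session_id}")
        return EpochSet(recording.session_id, recording.infant_id, recording.pma_days,
                        kind, channel, fs, np.empty((0, n_samp)), times,
                        np.zeros(0, bool), [])

    data = np.zeros((len(events), n_samp))
    kept = np.ones(len(events), bool)
    reasons = [""] * len(events)
    for i, ev in enumerate(events):
        i0 = int(round(ev.onset_s * fs)) + int(round(w0 * fs))
        if i0 < 0 or i0 + n_samp > x.size:
            kept[i] = False
            reasons[i] = "unepochable"
            continue
        ep = x[i0:i0 + n_samp].astype(float)
        data[i] = ep - ep[b].mean()
    return EpochSet(recording.session_id, recording.infant_id, recording.pma_days,
                    kind, channel, fs, data, times, kept, reasons)


def reject_artifacts(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Reject trials whose |amplitude| in the pre-stimulus window exceeds the
    threshold (strict inequality: a trial at exactly 150 uV is kept)."""
    if epochs.n_trials == 0:
        return epochs
    win = epochs.window_indices(cfg.reject_window_s)
    peak = np.abs(epochs.data[:, win]).max(axis=1)
    kept = epochs.kept.copy()
    reasons = list(epochs.reject_reason)
    for i in np.flatnonzero(kept & (peak > cfg.reject_ampl_uv)):
        kept[i] = False
        reasons[i] = "amplitude"
    return replace(epochs, kept=kept, reject_reason=reasons)


def enforce_inclusion(epochsets: list[EpochSet], cfg: PreprocessConfig) -> pd.DataFrame:
    """Recording-level inclusion report after artifact rejection.

    A stimulus modality is excluded when fewer than ``min_clean_epochs``
    clean trials remain; a recording is excluded only when all of its
    stimulus modalities are.
    """
    rows = []
    for es in epochsets:
        rows.append({"recording": es.recording_id, "modality": es.modality,
                     "n_total": es.n_trials, "n_rejected": es.n_trials - es.n_kept,
                     "n_clean": es.n_kept,
                     "included": es.n_kept >= cfg.min_clean_epochs})
    report = pd.DataFrame(rows)
    stim = report[report.modality.isin(STIMULUS_KINDS)]
    rec_ok = stim.groupby("recording")["included"].any()
    report["recording_included"] = report["recording"].map(rec_ok).fillna(False).astype(bool)
    return report


def pad_resting_events(recording: Recording, cfg: PreprocessConfig) -> Recording:
    """Top up sparse rest annotations.

    When five or fewer rest events exist, ten new ones are added at 10 s
    intervals before the first annotated rest event (clipped to the
    epochable range); otherwise the recording is returned unchanged.
    """
    rests = recording.events_of("rest")
    if not rests:
        raise ValueError(f"{recording.session_id} has no rest events to pad from")
    if len(rests) > cfg.rest_pad_trigger_max:
        return recording
    first = min(e.onset_s for e in rests)
    min_onset = -cfg.epoch_window_s[0]  # earliest epochable onset
    new = [Event("rest", first - k * cfg.rest_pad_interval_s)
           for k in range(1, cfg.rest_pad_count + 1)]
    fitting = [e for e in new if e.onset_s >= min_onset]
    if len(fitting) < len(new):
        warnings.warn(f"{recording.session_id}: only {len(fitting)} of "
                      f"{cfg.rest_pad_count} padded rest events fit before t=0")
    return recording.with_events(list(recording.events) + fitting)
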
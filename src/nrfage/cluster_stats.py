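"""Cluster-based permutation test for stimulus-vs-rest evoked activity.

Sample-wise paired t statistics are thresholded at the 97.5th percentile of
the t distribution with n-1 degrees of freedom; adjacent supra-threshold
samples of the same sign form clusters whose summed-t mass is compared
against a permutation null of per-recording condition swaps (sign flips of
the paired difference), using the maximum |mass| per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: fixed analysis windows (seconds post-stimulus) used to trim responses
#: before NRF derivation — around the significant clusters of each modality
ANALYSIS_WINDOWS_S = {"visual": (0.1, 1.0), "tactile": (0.0, 0.3)}


@dataclass(frozen=True)
class ClusterConfig:
    alpha: float = 0.05
    t_percentile: float = 97.5
    n_permutations: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_series: np.ndarray
    threshold_t: float
    n_permutations: int = 0

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def samplewise_paired_t(stim: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Per-sample paired t with df = n-1; zero-variance nonzero differences
    give +/-inf (always supra-threshold)."""
    stim = np.asarray(stim, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if stim.shape != rest.shape:
        raise ValueError("stimulus and rest matrices must be matched")
    n = stim.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired recordings")
    d = stim - rest
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    t[(sd == 0) & (mean > 0)] = np.inf
    t[(sd == 0) & (mean < 0)] = -np.inf
    return t


def find_clusters(t_series: np.ndarray, threshold_t: float) -> list[tuple[int, int, float]]:
    """Maximal sign-homogeneous runs of supra-threshold samples.

    Returns ``(start, stop, mass)`` index tuples (half-open), ordered by
    start; mass is the signed sum of t within the run.
    """
    if threshold_t <= 0:
        raise ValueError("threshold_t must be > 0")
    t = np.asarray(t_series, dtype=float)
    out: list[tuple[int, int, float]] = []
    for sign in (1.0, -1.0):
        above = (sign * t > threshold_t).astype(np.int8)
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above, [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            out.append((int(a), int(b), float(t[a:b].sum())))
    return sorted(out)


def _max_cluster_mass(t_row: np.ndarray, threshold: float) -> float:
    best = 0.0
    for _, _, mass in find_clusters(t_row, threshold):
        best = max(best, abs(mass))
    return best


def _null_t_matrix(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t-series for many sign-flip permutations at once.

    Sign flips leave the per-sample sum of squares unchanged, so each
    permutation's t follows from its flipped mean alone.
    """
    n = d.shape[0]
    ss = (d**2).sum(axis=0)  # invariant under sign flips
    mean = signs @ d / n
    var = np.maximum(ss - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zv = var == 0
    t[zv & (mean > 0)] = np.inf
    t[zv & (mean < 0)] = -np.inf
    t[zv & (mean == 0)] = 0.0
    return t


def permutation_test(stim: np.ndarray, rest: np.ndarray,
                     cfg: ClusterConfig = ClusterConfig(), *,
                     sfreq: float = 1.0, t_start: float = 0.0,
                     rng: np.random.Generator | None = None) -> ClusterResult:
    """Cluster-based permutation test of stimulus vs rest responses.

    Cluster p-values carry the +1 correction:
    ``p = (1 + #{null >= |mass|}) / (1 + n_permutations)``.
    """
    stim = np.asarray(stim, dtype=float)
    rest = np.asarray(rest, dtype=float)
    t_obs = samplewise_paired_t(stim, rest)
    n = stim.shape[0]
    threshold = float(stats.t.ppf(cfg.t_percentile / 100.0, df=n - 1))
    observed = find_clusters(t_obs, threshold)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    d = stim - rest
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, n))
    t_null = _null_t_matrix(d, signs)
    null_max = np.array([_max_cluster_mass(row, threshold) for row in t_null])

    clusters = []
    for a, b, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + cfg.n_permutations)
        clusters.append(Cluster(t_start + a / sfreq, t_start + b / sfreq, mass, p))
    return ClusterResult(clusters, t_obs, threshold, cfg.n_permutations)


def trim_to_analysis_window(waveforms: np.ndarray, modality: str, sfreq: float,
                            t_start: float = 0.0,
                            windows: dict[str, tuple[float, float]] = ANALYSIS_WINDOWS_S,
                            ) -> tuple[np.ndarray, tuple[float, float]]:
    """Trim post-stimulus waveforms to the modality's NRF analysis window."""
    if modality not in windows:
        raise ValueError(f"unknown modality {modality!r}")
    w0, w1 = windows[modality]
    x = np.asarray(waveforms, dtype=float)
    a = int(round((w0 - t_start) * sfreq))
    b = int(round((w1 - t_start) * sfreq))
    if a < 0 or b > x.shape[-1]:
        raise ValueError(f"analysis window {w0}-{w1} s outside the epoch")
    return x[..., a:b], (w0, w1)
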
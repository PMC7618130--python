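"""Brain-age prediction from NRF magnitudes.

A linear epsilon-insensitive support vector regression (epsilon = 0.15
weeks, box constraint C = 1, L1 soft margin) maps per-recording NRF
magnitudes to PMA. Performance is assessed with leave-one-infant-out (LOIO)
cross-validation so repeated sessions of one infant never span train and
test, percentile-bootstrap confidence intervals on the MAE, and a one-tailed
permutation test whose permutations move PMA label blocks between whole
infants (exchangeability blocks for the repeated-measures structure). A null
model predicting the LOIO mean PMA provides the reference; the brain-age gap
(prediction - PMA) is PMA-adjusted by taking the residuals of gap ~ PMA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

FEATURE_PREFIXES = ("visual", "tactile")


@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "linear"
    epsilon: float = 0.15  # insensitivity tube, weeks
    box_constraint: float = 1.0
    standardize_features: bool = True
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.box_constraint <= 0:
            raise ValueError("epsilon and box_constraint must be > 0")


@dataclass
class FeatureTable:
    """One row per recording; feature columns are NRF magnitudes."""

    df: pd.DataFrame  # recording_id, infant_id, pma_weeks + features
    feature_cols: list[str]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df[self.feature_cols].isna()

    def restrict(self, modality: str) -> "FeatureTable":
        cols = [c for c in self.feature_cols if c.startswith(modality)]
        if not cols:
            raise ValueError(f"no {modality!r} feature columns")
        keep = ["recording_id", "infant_id", "pma_weeks"] + cols
        return FeatureTable(self.df[keep].copy(), cols)


def assemble_features(magnitudes: pd.DataFrame) -> FeatureTable:
    """Pivot a tidy magnitude table (recording_id, infant_id, pma_days,
    modality, nrf_name, beta) into a wide per-recording feature table.

    Recordings lacking a modality keep NaN features here; imputation with
    training-fold column means happens inside each CV fold.
    """
    required = {"recording_id", "infant_id", "pma_days", "nrf_name", "beta"}
    if not required.issubset(magnitudes.columns):
        raise ValueError(f"magnitude table needs columns {sorted(required)}")
    if magnitudes["infant_id"].nunique() < 2:
        raise ValueError("need at least 2 infants")
    wide = magnitudes.pivot_table(index=["recording_id", "infant_id", "pma_days"],
                                  columns="nrf_name", values="beta").reset_index()
    wide.columns.name = None
    feature_cols = sorted(c for c in wide.columns
                          if isinstance(c, str) and c.startswith(FEATURE_PREFIXES))
    if not feature_cols:
        raise ValueError("no NRF feature columns found")
    for c in feature_cols:
        if wide[c].isna().all():
            raise ValueError(f"feature column {c!r} is missing for every recording")
    wide["pma_weeks"] = wide["pma_days"] / 7.0
    cols = ["recording_id", "infant_id", "pma_weeks"] + feature_cols
    return FeatureTable(wide[cols].copy(), feature_cols)


class SVRModel:
    """Linear SVR with (optional) training-fold standardization and
    training-fold mean imputation of missing features."""

    def __init__(self, cfg: SVRConfig = SVRConfig()):
        self.cfg = cfg

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SVRModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 distinct response values")
        self.impute_ = np.nanmean(x, axis=0)
        if np.isnan(self.impute_).any():
            raise ValueError("a feature column is missing in the whole training fold")
        x = self._fill(x)
        if self.cfg.standardize_features:
            self.mean_ = x.mean(axis=0)
            sd = x.std(axis=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(x.shape[1])
            self.sd_ = np.ones(x.shape[1])
        self.svr_ = SVR(kernel=self.cfg.kernel, C=self.cfg.box_constraint,
                        epsilon=self.cfg.epsilon, tol=self.cfg.tol)
        self.svr_.fit((x - self.mean_) / self.sd_, y)
        return self

    def _fill(self, x: np.ndarray) -> np.ndarray:
        x = np.array(x, dtype=float)
        nan = np.isnan(x)
        if nan.any():
            x[nan] = np.broadcast_to(self.impute_, x.shape)[nan]
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = self._fill(np.asarray(x, dtype=float))
        return self.svr_.predict((x - self.mean_) / self.sd_)


def fit_svr(table: FeatureTable, cfg: SVRConfig = SVRConfig()) -> SVRModel:
    x = table.df[table.feature_cols].to_numpy(float)
    y = table.df["pma_weeks"].to_numpy(float)
    return SVRModel(cfg).fit(x, y)


def loio_cv(table: FeatureTable, cfg: SVRConfig = SVRConfig(),
            y: np.ndarray | None = None) -> pd.DataFrame:
    """Leave-one-infant-out predictions for every recording.

    ``y`` optionally overrides the PMA response (used by the block
    permutation test); fold structure is unchanged by row order.
    """
    df = table.df.reset_index(drop=True)
    infants = np.sort(df["infant_id"].unique())
    if infants.size < 3:
        raise ValueError("need at least 3 infants for leave-one-infant-out CV")
    x = df[table.feature_cols].to_numpy(float)
    y = df["pma_weeks"].to_numpy(float) if y is None else np.asarray(y, dtype=float)
    pred = np.empty(len(df))
    null_pred = np.empty(len(df))
    for infant in infants:
        test = (df["infant_id"] == infant).to_numpy()
        train = ~test
        assert not (set(df.loc[test, "infant_id"]) & set(df.loc[train, "infant_id"]))
        model = SVRModel(cfg).fit(x[train], y[train])
        pred[test] = model.predict(x[test])
        null_pred[test] = y[train].mean()
    out = df[["recording_id", "infant_id", "pma_weeks"]].copy()
    out["pma_weeks"] = y
    out["brain_age_weeks"] = pred
    out["null_pred_weeks"] = null_pred
    out["gap_weeks"] = pred - y
    return out


def adjust_gap(predictions: pd.DataFrame) -> pd.DataFrame:
    """Add the PMA-adjusted gap: residuals of OLS gap ~ PMA (zero mean,
    exactly uncorrelated with PMA). Constant PMA degrades to centering."""
    df = predictions.copy()
    if len(df) < 3:
        raise ValueError("need at least 3 recordings to adjust the gap")
    pma = df["pma_weeks"].to_numpy(float)
    gap = df["gap_weeks"].to_numpy(float)
    pc = pma - pma.mean()
    if np.all(pc == 0):
        df["adjusted_gap_weeks"] = gap - gap.mean()
        return df
    slope = pc @ (gap - gap.mean()) / (pc @ pc)
    intercept = gap.mean() - slope * pma.mean()
    df["adjusted_gap_weeks"] = gap - (intercept + slope * pma)
    return df


@dataclass
class ModelEvaluation:
    mae_weeks: float
    ci95: tuple[float, float]
    p_permutation: float
    null_mae_weeks: float
    mean_abs_difference_vs_null: float
    diff_ci95: tuple[float, float]
    p_diff: float
    n_recordings: int
    n_permutations: int
    n_bootstrap: int

    def to_dict(self) -> dict:
        return {"mae_weeks": self.mae_weeks, "ci95": list(self.ci95),
                "p_permutation": self.p_permutation,
                "null_mae_weeks": self.null_mae_weeks,
                "mean_abs_difference_vs_null": self.mean_abs_difference_vs_null,
                "diff_ci95": list(self.diff_ci95), "p_diff": self.p_diff,
                "n_recordings": self.n_recordings,
                "n_permutations": self.n_permutations,
                "n_bootstrap": self.n_bootstrap}


def permute_blocks(infant_ids: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Permute PMA label vectors across whole infants.

    Whole label blocks are exchanged between infants with equal session
    counts (groups of one keep their labels), preserving the within-infant
    dependence structure.
    """
    infant_ids = np.asarray(infant_ids)
    y = np.asarray(y, dtype=float)
    out = y.copy()
    infants, counts = np.unique(infant_ids, return_counts=True)
    for c in np.unique(counts):
        group = infants[counts == c]
        if group.size < 2:
            continue
        perm = rng.permutation(group.size)
        blocks = [y[infant_ids == inf] for inf in group]
        for dst, src in enumerate(perm):
            out[infant_ids == group[dst]] = blocks[src]
    return out


def evaluate(predictions: pd.DataFrame, table: FeatureTable,
             cfg: SVRConfig = SVRConfig(), *, n_bootstrap: int = 10_000,
             n_permutations: int = 1000, seed: int | None = None) -> ModelEvaluation:
    """MAE with bootstrap CI, block-permutation p, and null-model contrast.

    The permutation p is one-tailed (smaller MAE is better) with the +1
    correction; each permutation reassigns whole infants' PMA blocks and
    reruns the full LOIO CV. The null model predicts the LOIO mean PMA; the
    paired contrast of absolute errors gets a bootstrap CI and a one-tailed
    sign-flip permutation p.
    """
    if n_permutations < 20:
        warnings.warn("fewer than 20 permutations: p-value resolution is very coarse")
    rng = np.random.default_rng(seed)
    y = predictions["pma_weeks"].to_numpy(float)
    err = np.abs(predictions["brain_age_weeks"].to_numpy(float) - y)
    err_null = np.abs(predictions["null_pred_weeks"].to_numpy(float) - y)
    n = err.size
    mae = float(err.mean())
    null_mae = float(err_null.mean())

    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boot = err[idx].mean(axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    infant_ids = table.df["infant_id"].to_numpy()
    y_table = table.df["pma_weeks"].to_numpy(float)
    worse = 0
    for _ in range(n_permutations):
        y_perm = permute_blocks(infant_ids, y_table, rng)
        perm_pred = loio_cv(table, cfg, y=y_perm)
        perm_mae = np.abs(perm_pred["brain_age_weeks"] - perm_pred["pma_weeks"]).mean()
        if perm_mae <= mae:
            worse += 1
    p_perm = (1.0 + worse) / (1.0 + n_permutations)

    diff = err_null - err  # positive where the model beats the null
    boot_diff = diff[idx].mean(axis=1)
    diff_ci = (float(np.percentile(boot_diff, 2.5)), float(np.percentile(boot_diff, 97.5)))
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    null_means = (signs * diff).mean(axis=1)
    p_diff = (1.0 + np.sum(null_means >= diff.mean())) / (1.0 + n_permutations)

    return ModelEvaluation(mae, ci, float(p_perm), null_mae, float(diff.mean()),
                           diff_ci, float(p_diff), n, n_permutations, n_bootstrap)
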
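"""End-to-end orchestration: simulate -> preprocess -> align -> cluster ->
NRF -> magnitudes -> brain age -> EMG -> report.

`derive_study` is the library entry point operating on in-memory recordings;
`run_pipeline` adds file I/O, a run manifest with checksums, and stage
logging for the command-line workflow.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nrfage import alignment, brain_age, cluster_stats, emg_reflex, nrf, preprocess, synthetic
from nrfage.alignment import AlignmentConfig, build_age_templates
from nrfage.brain_age import FeatureTable, SVRConfig, adjust_gap, assemble_features, evaluate, loio_cv
from nrfage.cluster_stats import ClusterConfig, permutation_test, trim_to_analysis_window
from nrfage.emg_reflex import EMGConfig, baseline_movement_screen, correlate_with_age, detect_reflex, measures_table, preprocess_emg
from nrfage.nrf import NRFConfig, derive_components, nrf_magnitude, select_stimulus_components, unit_normalize, weekly_age_trend
from nrfage.preprocess import (HIGHPASS_01, LOWPASS_12, LOWPASS_30, EpochSet,
                               PreprocessConfig, apply_fir, enforce_inclusion,
                               epoch_and_baseline, pad_resting_events, reject_artifacts)
from nrfage.synthetic import MODALITY_CHANNELS, CohortSpec, Recording, generate_cohort

logger = logging.getLogger("nrfage")

POST_STIM_WINDOW_S = (0.0, 1.0)


# --------------------------------------------------------------------------
# Per-recording preprocessing across the two filter branches
# --------------------------------------------------------------------------

@dataclass
class RecordingBranches:
    """Epoch sets for one recording/modality in both filter branches."""

    stim_bb: EpochSet  # broadband 0.1-30 Hz (magnitude / brain-age branch)
    stim_nrf: EpochSet  # + 12 Hz low-pass (NRF-derivation branch)
    rest_bb: EpochSet
    rest_nrf: EpochSet


def preprocess_recording(rec: Recording, cfg: PreprocessConfig
                         ) -> dict[str, RecordingBranches]:
    """Filter, epoch, baseline-correct and artifact-reject one recording.

    Rejection masks are computed on the broadband branch and shared with the
    NRF branch so both branches keep identical trial sets.
    """
    rec = pad_resting_events(rec, cfg)
    out: dict[str, RecordingBranches] = {}
    for modality, channel in MODALITY_CHANNELS.items():
        raw = rec.get_channel(channel).astype(float)
        bb = apply_fir(apply_fir(raw, HIGHPASS_01, rec.sfreq_hz), LOWPASS_30, rec.sfreq_hz)
        nb = apply_fir(bb, LOWPASS_12, rec.sfreq_hz)
        sets = {}
        for kind in (modality, "rest"):
            e_bb = reject_artifacts(epoch_and_baseline(rec, kind, channel, cfg, signal=bb), cfg)
            e_nrf = epoch_and_baseline(rec, kind, channel, cfg, signal=nb)
            e_nrf = dataclasses.replace(e_nrf, kept=e_bb.kept.copy(),
                                        reject_reason=list(e_bb.reject_reason))
            sets[kind] = (e_bb, e_nrf)
        out[modality] = RecordingBranches(sets[modality][0], sets[modality][1],
                                          sets["rest"][0], sets["rest"][1])
    return out


def _post_stim_average(es: EpochSet) -> np.ndarray:
    """Kept-trial average over the 0-1 s post-stimulus window."""
    win = es.window_indices(POST_STIM_WINDOW_S)
    return es.kept_data()[:, win].mean(axis=0)


# --------------------------------------------------------------------------
# Study-level results
# --------------------------------------------------------------------------

@dataclass
class ModalityResult:
    modality: str
    recording_ids: list[str]
    alignment: alignment.AlignmentResult
    cluster: cluster_stats.ClusterResult
    components: nrf.ComponentSet
    nrfs: list[nrf.NRF]
    trends: list[nrf.AgeTrend]


@dataclass
class StudyResult:
    inclusion: pd.DataFrame
    modalities: dict[str, ModalityResult]
    magnitudes: pd.DataFrame
    features: FeatureTable
    predictions: pd.DataFrame
    evaluation: brain_age.ModelEvaluation
    emg_measures: pd.DataFrame
    emg_correlations: list[emg_reflex.CorrelationResult]


def derive_study(recordings: list[Recording], *,
                 pre_cfg: PreprocessConfig = PreprocessConfig(),
                 align_cfg: AlignmentConfig = AlignmentConfig(),
                 cluster_cfg: ClusterConfig = ClusterConfig(),
                 nrf_cfg: NRFConfig = NRFConfig(),
                 svr_cfg: SVRConfig = SVRConfig(),
                 emg_cfg: EMGConfig = EMGConfig(),
                 model_variant: str = "combined",
                 n_permutations_model: int = 1000,
                 n_bootstrap: int = 10_000,
                 run_emg: bool = True,
                 seed: int | None = None) -> StudyResult:
    """Run the full analysis on a cohort of recordings."""
    rng = np.random.default_rng(seed)
    sfreq = recordings[0].sfreq_hz

    logger.info("preprocessing %d recordings", len(recordings))
    branches = {rec.session_id: preprocess_recording(rec, pre_cfg) for rec in recordings}
    rec_by_id = {rec.session_id: rec for rec in recordings}

    all_sets = [b[m].stim_bb for b in branches.values() for m in MODALITY_CHANNELS]
    inclusion = enforce_inclusion(all_sets, pre_cfg)
    included = {(r.recording, r.modality) for r in inclusion.itertuples() if r.included}

    modality_results: dict[str, ModalityResult] = {}
    mag_rows = []
    for modality in MODALITY_CHANNELS:
        ids = [rid for rid in branches if (rid, modality) in included
               and branches[rid][modality].rest_bb.n_kept > 0]
        if len(ids) < 3:
            logger.warning("modality %s: only %d usable recordings; skipped", modality, len(ids))
            continue
        pma = np.array([rec_by_id[r].pma_days for r in ids], dtype=float)
        stim_avg = np.stack([_post_stim_average(branches[r][modality].stim_nrf) for r in ids])
        rest_avg = np.stack([_post_stim_average(branches[r][modality].rest_nrf) for r in ids])
        stim_bb_avg = np.stack([_post_stim_average(branches[r][modality].stim_bb) for r in ids])

        logger.info("modality %s: aligning %d recordings", modality, len(ids))
        aligned = build_age_templates(stim_avg, rest_avg, pma, sfreq, align_cfg)

        cluster = permutation_test(aligned.aligned_stim, aligned.aligned_rest,
                                   cluster_cfg, sfreq=sfreq, t_start=0.0,
                                   rng=np.random.default_rng(rng.integers(2**31)))

        stim_trim, window = trim_to_analysis_window(aligned.aligned_stim, modality, sfreq)
        rest_trim, _ = trim_to_analysis_window(aligned.aligned_rest, modality, sfreq)
        stacked, _ = unit_normalize(np.vstack([stim_trim, rest_trim]))
        comps = derive_components(stacked, nrf_cfg)
        nrfs, _, _ = select_stimulus_components(comps, stim_trim, rest_trim, nrf_cfg,
                                                modality=modality, time_window_s=window)
        logger.info("modality %s: %d/%d components selected as NRFs",
                    modality, len(nrfs), comps.components.shape[0])

        trends = []
        for one in nrfs:
            betas = []
            for i, rid in enumerate(ids):
                m = nrf_magnitude(stim_bb_avg[i], one, sfreq, nrf_cfg, recording_id=rid)
                betas.append(m.beta)
                mag_rows.append({"recording_id": rid, "infant_id": rec_by_id[rid].infant_id,
                                 "pma_days": rec_by_id[rid].pma_days, "modality": modality,
                                 "nrf_name": one.name, "beta": m.beta,
                                 "applied_shift_s": m.applied_shift_s})
            try:
                trends.append(weekly_age_trend(np.array(betas), pma, one.name))
            except ValueError:
                pass
        modality_results[modality] = ModalityResult(modality, ids, aligned, cluster,
                                                    comps, nrfs, trends)

    magnitudes = pd.DataFrame(mag_rows)
    if magnitudes.empty:
        raise RuntimeError("no NRFs were selected in any modality")
    features = assemble_features(magnitudes)
    if model_variant != "combined":
        features = features.restrict(model_variant)

    logger.info("brain age: LOIO CV over %d infants", features.df["infant_id"].nunique())
    predictions = loio_cv(features, svr_cfg)
    predictions = adjust_gap(predictions)
    evaluation = evaluate(predictions, features, svr_cfg, n_bootstrap=n_bootstrap,
                          n_permutations=n_permutations_model,
                          seed=int(rng.integers(2**31)))

    emg_measures = pd.DataFrame(columns=["recording_id", "detected", "start_s",
                                         "end_s", "duration_s", "amplitude_uv"])
    correlations: list[emg_reflex.CorrelationResult] = []
    if run_emg:
        measures = []
        for rec in recordings:
            prep = preprocess_emg(rec, emg_cfg)
            if prep is None:
                continue
            times, rectified = prep
            if not baseline_movement_screen(times, rectified, rec.sfreq_hz, emg_cfg):
                continue
            measures.append(detect_reflex(times, rectified, rec.sfreq_hz, emg_cfg,
                                          recording_id=rec.session_id))
        if measures:
            emg_measures = measures_table(measures)
            try:
                correlations = correlate_with_age(emg_measures, predictions)
            except ValueError:
                logger.warning("too few detected reflexes for correlations")

    return StudyResult(inclusion, modality_results, magnitudes, features,
                       predictions, evaluation, emg_measures, correlations)


# --------------------------------------------------------------------------
# Config / manifest / file-based pipeline
# --------------------------------------------------------------------------

_TUPLE_FIELDS = True  # configs use tuples; YAML stores lists


def _coerce(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        default = f.default
        if isinstance(default, tuple) and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = CohortSpec()
    preprocess: PreprocessConfig = PreprocessConfig()
    alignment: AlignmentConfig = AlignmentConfig()
    cluster: ClusterConfig = ClusterConfig()
    nrf: NRFConfig = NRFConfig()
    svr: SVRConfig = SVRConfig()
    emg: EMGConfig = EMGConfig()
    model_variant: str = "combined"  # combined | visual | tactile
    n_permutations_model: int = 1000
    n_bootstrap: int = 10_000
    run_emg: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)

        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        Path(path).write_text(yaml.safe_dump(listify(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sub = {"cohort": CohortSpec, "preprocess": PreprocessConfig,
               "alignment": AlignmentConfig, "cluster": ClusterConfig,
               "nrf": NRFConfig, "svr": SVRConfig, "emg": EMGConfig}
        kwargs = {}
        for k, v in d.items():
            if k in sub:
                if k == "cohort" and isinstance(v.get("sessions_per_infant"), list):
                    v["sessions_per_infant"] = tuple(v["sessions_per_infant"])
                kwargs[k] = _coerce(sub[k], v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict[str, str], t0: float) -> None:
        self.stages[name] = {"outputs": outputs, "seconds": round(time.time() - t0, 3)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write all stage outputs under out_dir."""
    from nrfage import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    manifest = RunManifest(_sha256(cfg_path), __version__)

    t0 = time.time()
    recordings, truth = generate_cohort(config.cohort)
    truth.to_json(out / "ground_truth.json")
    manifest.add_stage("simulate", {"ground_truth.json": _sha256(out / "ground_truth.json")}, t0)

    t0 = time.time()
    result = derive_study(
        recordings, pre_cfg=config.preprocess, align_cfg=config.alignment,
        cluster_cfg=config.cluster, nrf_cfg=config.nrf, svr_cfg=config.svr,
        emg_cfg=config.emg, model_variant=config.model_variant,
        n_permutations_model=config.n_permutations_model,
        n_bootstrap=config.n_bootstrap, run_emg=config.run_emg, seed=config.seed)

    outputs = {}
    result.inclusion.to_csv(out / "qc_inclusion.csv", index=False)
    outputs["qc_inclusion.csv"] = _sha256(out / "qc_inclusion.csv")

    shift_rows, nrf_rows, cluster_json = [], [], {}
    for m, res in result.modalities.items():
        for i, rid in enumerate(res.recording_ids):
            shift_rows.append({"recording_id": rid, "modality": m,
                               "shift_s": res.alignment.shift_stim_s[i],
                               "correlation": res.alignment.correlation[i]})
        for one in res.nrfs:
            t = one.time_window_s[0] + np.arange(one.waveform.size) / recordings[0].sfreq_hz
            for ti, amp in zip(t, one.waveform):
                nrf_rows.append({"nrf_name": one.name, "time_s": ti, "amplitude": amp})
        cluster_json[m] = {"threshold_t": res.cluster.threshold_t,
                           "clusters": [dataclasses.asdict(c) for c in res.cluster.clusters]}
    pd.DataFrame(shift_rows).to_csv(out / "alignment_shifts.csv", index=False)
    pd.DataFrame(nrf_rows).to_csv(out / "nrf_waveforms.csv", index=False)
    (out / "clusters.json").write_text(json.dumps(cluster_json, indent=1))
    result.magnitudes.to_csv(out / "nrf_magnitudes.csv", index=False)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    (out / "evaluation.json").write_text(json.dumps(result.evaluation.to_dict(), indent=1))
    result.emg_measures.to_csv(out / "emg_measures.csv", index=False)
    (out / "emg_correlations.json").write_text(json.dumps(
        [dataclasses.asdict(c) for c in result.emg_correlations], indent=1))
    for name in ("alignment_shifts.csv", "nrf_waveforms.csv", "clusters.json",
                 "nrf_magnitudes.csv", "predictions.csv", "evaluation.json",
                 "emg_measures.csv", "emg_correlations.json"):
        outputs[name] = _sha256(out / name)
    manifest.add_stage("analysis", outputs, t0)
    manifest.to_json(out / "manifest.json")
    return manifest


def make_report(out_dir: str | Path) -> Path:
    """Render a markdown report with figures from a completed run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# Sensory-evoked brain age report", ""]

    def section(title, path, plot):
        if not (out / path).exists():
            lines.append(f"## {title}\n\n_{path} missing; section omitted._\n")
            return
        fig_name = plot()
        lines.append(f"## {title}\n\n![{title}](figures/{fig_name})\n")

    def plot_nrfs():
        df = pd.read_csv(out / "nrf_waveforms.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        for name, g in df.groupby("nrf_name"):
            ax.plot(g["time_s"], g["amplitude"], label=name)
        ax.set(xlabel="time post-stimulus (s)", ylabel="unit amplitude")
        ax.legend(fontsize=7)
        fig.savefig(fig_dir / "nrfs.png", dpi=110)
        plt.close(fig)
        return "nrfs.png"

    def plot_magnitudes():
        df = pd.read_csv(out / "nrf_magnitudes.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        for name, g in df.groupby("nrf_name"):
            ax.scatter(g["pma_days"] / 7.0, g["beta"], s=8, label=name)
        ax.set(xlabel="PMA (weeks)", ylabel="NRF magnitude (uV)")
        ax.legend(fontsize=7)
        fig.savefig(fig_dir / "magnitudes.png", dpi=110)
        plt.close(fig)
        return "magnitudes.png"

    def plot_predictions():
        df = pd.read_csv(out / "predictions.csv")
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(df["pma_weeks"], df["brain_age_weeks"], s=12)
        lim = [df["pma_weeks"].min() - 1, df["pma_weeks"].max() + 1]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set(xlabel="PMA (weeks)", ylabel="brain age (weeks)")
        fig.savefig(fig_dir / "predictions.png", dpi=110)
        plt.close(fig)
        return "predictions.png"

    def plot_shifts():
        df = pd.read_csv(out / "alignment_shifts.csv")
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.hist(df["shift_s"], bins=21)
        ax.set(xlabel="applied Woody shift (s)", ylabel="recordings")
        fig.savefig(fig_dir / "shifts.png", dpi=110)
        plt.close(fig)
        return "shifts.png"

    def plot_emg():
        df = pd.read_csv(out / "emg_measures.csv")
        pred = pd.read_csv(out / "predictions.csv")
        merged = df[df["detected"]].merge(pred, on="recording_id")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(merged["brain_age_weeks"], merged["amplitude_uv"], s=12)
        ax.set(xlabel="brain age (weeks)", ylabel="reflex amplitude (uV)")
        fig.savefig(fig_dir / "emg.png", dpi=110)
        plt.close(fig)
        return "emg.png"

    section("Aligned responses and Woody shifts", "alignment_shifts.csv", plot_shifts)
    section("Neurodynamic response functions", "nrf_waveforms.csv", plot_nrfs)
    section("NRF magnitudes vs PMA", "nrf_magnitudes.csv", plot_magnitudes)
    section("Brain age predictions", "predictions.csv", plot_predictions)
    emg_df = out / "emg_measures.csv"
    if emg_df.exists() and not pd.read_csv(emg_df).empty:
        section("EMG reflex correlates", "emg_measures.csv", plot_emg)
    else:
        lines.append("## EMG reflex correlates\n\n_EMG stage disabled or empty; section omitted._\n")

    if (out / "evaluation.json").exists():
        ev = json.loads((out / "evaluation.json").read_text())
        lines.append(f"Model MAE: {ev['mae_weeks']:.2f} weeks "
                     f"(95% CI {ev['ci95'][0]:.2f}-{ev['ci95'][1]:.2f}), "
                     f"permutation p = {ev['p_permutation']:.4g}; "
                     f"null-model MAE {ev['null_mae_weeks']:.2f} weeks.")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
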
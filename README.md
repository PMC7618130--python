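# nrfage

Sensory-evoked-potential **brain age** for preterm infants.

Between 28 and 40 weeks post-menstrual age (PMA) the morphology of
visual- and tactile-evoked EEG potentials changes dramatically: a
high-amplitude slow wave dominates in the youngest infants and disappears
with maturation, while higher-frequency evoked components shift in latency.
`nrfage` turns this maturational signal into a quantitative model:

1. **Neurodynamic response functions (NRFs)** — characteristic evoked
   waveforms derived by PCA from unit-normalised, latency-aligned
   (Woody-filtered), age-weighted recording averages, with the evoked window
   located by a cluster-based permutation test of stimulus vs resting-state
   activity.
2. **NRF magnitudes** — per-recording slope coefficients β from regressing
   each NRF onto the broadband (0.1–30 Hz) evoked average, the EEG analogue
   of a voxelwise haemodynamic-response β.
3. **Brain age** — linear ε-insensitive support vector regression
   (ε = 0.15 wk, C = 1) from the NRF magnitudes to PMA, evaluated with
   leave-one-infant-out cross-validation, bootstrap CIs on the MAE, and a
   one-tailed permutation test over infant-level exchangeability blocks.
   The **brain-age gap** (prediction − PMA) is PMA-adjusted by taking the
   residuals of gap ~ PMA.
4. **Biological validity check** — amplitude and duration of the EMG-recorded
   reflex withdrawal to a clinically required heel lance, correlated
   (one-tailed, negative) with PMA, brain age, and the adjusted gap.

Because cot-side infant EEG cannot be redistributed, the package ships a
**synthetic-cohort generator** with known ground truth (age-dependent slow
wave, latency-shifting fast component, 1/f background, per-recording latency
jitter, per-infant maturity offsets, maturity-dependent EMG reflex bursts).
Every stage of the pipeline is exercised and validated end to end against
that ground truth. It is aimed at researchers in developmental
neurophysiology who want a tested, reusable reference implementation of this
analysis for their own cohorts or for simulation studies.

## Worked example

```python
from nrfage import CohortSpec
from nrfage.synthetic import generate_cohort
from nrfage.pipeline import derive_study

spec = CohortSpec(n_infants=30, snr=2.0, seed=7)
recordings, truth = generate_cohort(spec)
result = derive_study(recordings, n_permutations_model=99,
                      n_bootstrap=2000, seed=7)

for modality, res in result.modalities.items():
    sig = res.cluster.significant()
    print(f"{modality}: {len(res.nrfs)} NRFs; evoked window "
          f"{sig[0].start_s:.2f}-{sig[0].end_s:.2f} s (p = {sig[0].p_value:.3f})")

ev = result.evaluation
print(f"brain age MAE {ev.mae_weeks:.2f} wk "
      f"(95% CI {ev.ci95[0]:.2f}-{ev.ci95[1]:.2f}), "
      f"null {ev.null_mae_weeks:.2f} wk, permutation p = {ev.p_permutation:.3f}")

amp = next(c for c in result.emg_correlations
           if c.metric == "amplitude_uv" and c.age_variable == "brain_age_weeks")
print(f"reflex amplitude vs brain age: r = {amp.r:.2f}, "
      f"one-tailed p = {amp.p_one_tailed:.4f} (n = {amp.n})")
```

prints (about one minute on a laptop):

```
visual: 10 NRFs; evoked window 0.12-0.67 s (p = 0.001)
tactile: 6 NRFs; evoked window 0.04-0.30 s (p = 0.001)
brain age MAE 1.35 wk (95% CI 1.13-1.57), null 2.61 wk, permutation p = 0.010
reflex amplitude vs brain age: r = -0.92, one-tailed p = 0.0000 (n = 48)
```

Reading the numbers: the cluster test localises evoked activity where the
generator injected it; the SVR predicts PMA with a 1.35-week mean absolute
error, clearly beating the leave-one-infant-out mean-age null model
(2.61 weeks) at the smallest p attainable with 99 block permutations; and
the simulated reflex withdrawal, which shrinks with true neural maturity,
is strongly anticorrelated with the predicted brain age.

## Command line

```sh
nrfage simulate --out cohort/ --seed 1          # write a synthetic cohort
nrfage run-all  --out run/    --seed 1          # full pipeline on a fresh cohort
nrfage run-all  --out run/ --model visual       # single-modality model variant
nrfage report   run/                            # markdown report with figures
```

All constants of the analysis (filter edges, ±150 µV rejection threshold,
27-day FWHM age weighting, 0.05 s Woody jitter, 95% PCA variance threshold,
ε/C, permutation and bootstrap counts) are named keys in the YAML config
(`PipelineConfig.to_yaml` / `from_yaml`).

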
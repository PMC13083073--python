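# plvnet

Event-related EEG phase-coherence analysis for Parkinsonian cognitive
decline: wavelet phase-locking connectivity over a predefined electrode-pair
set, graph-theoretic network characterization, and L1-regularized
classification with resampling-based validation — driven by a synthetic
phase-coupled oddball cohort generator, so every stage is testable without
clinical recordings.

## The problem

Visual-oddball EEG studies of Parkinson's disease dementia (PDD), Parkinson's
disease with mild cognitive impairment (PD-MCI) and dementia with Lewy bodies
(DLB) report weakened stimulus-locked low-frequency phase synchronization
between frontal and temporo-parietal sites relative to healthy controls.
`plvnet` implements that analysis chain end to end:

1. **Preprocessing** — zero-phase 0.01–60 Hz Butterworth filtering, polyphase
   resampling to 256 Hz, epoching (−3..+3 s for delta, −1..+1 s for theta),
   amplitude-threshold artifact rejection, and a spherical-spline current
   source density (CSD) transform (spline order m = 4, Legendre degree 10,
   λ = 10⁻⁵) to attenuate volume conduction.
2. **Connectivity** — a Gabor-normalized complex Morlet bank (3 cycles,
   σ_t = 3/(2πf), 30 log-spaced bins per band; delta 1–3.5 Hz, theta 4–7 Hz)
   yields instantaneous phases φ(f, t); for each electrode pair the
   phase-locking value

   PLV(f, t) = | N⁻¹ Σ_trials exp(j(φ_y − φ_x)) |

   is averaged over bins and the post-stimulus window (0–600 ms delta,
   0–300 ms theta) across a fixed set of 40 fronto-temporal /
   fronto-parietal / centro-parietal / temporo-occipital pairs
   (20 inter-, 10 left-, 10 right-hemispheric).
3. **Networks** — subject PLV matrices thresholded at 10% density; global and
   local efficiency (mean inverse shortest-path length with 1/PLV edge
   lengths), weighted clustering C and path length L, and small-worldness
   σ = (C/C_rand)/(L/L_rand) against 100 degree-matched Maslov–Sneppen nulls.
4. **Statistics** — Welch planned contrasts with Hedges' g and BCa bootstrap
   CIs, coherence→MMSE / coherence→error-score regressions with an age
   covariate (standardized β), Benjamini–Hochberg FDR, and a 3-D coherence
   embedding over the most discriminative pairs.
5. **Classification** — LASSO logistic regression along a glmnet-style λ
   path with 10-fold cross-validation (λ_min / λ_1se, binomial deviance),
   Bolasso stability selection (100 resamples, 85% retention), pooled
   out-of-fold ROC/AUC with bootstrap CIs, confusion metrics, and
   label-permutation tests (p = M⁻¹ Σ[θᵢ ≥ Θ]).

The synthetic generator plants von Mises phase coupling with concentration
κ, giving the closed-form expected PLV I₁(κ)/I₀(κ) — an analytic oracle for
the entire stack — and emulates the study conditions: a 30-channel 10–20
montage, four groups of 24/20/18/11 subjects, ~14–20 artifact-free target
trials each, reduced coupling on six designated fronto-temporal/parietal
pairs in patient-like groups, and MMSE/error scores linear in subject
coherence.

## Worked example

```python
import numpy as np
from plvnet.synth import CohortSpec, CouplingSpec, generate_cohort
from plvnet.pipeline import connectivity_table, feature_matrix
from plvnet.classify import lasso_cv, roc_auc

cohort = CohortSpec(group_sizes={"HC": 24, "PDD": 18}, rng_seed=11)
epochs, covariates = generate_cohort(cohort, CouplingSpec(band="theta"))
table = connectivity_table(epochs, "theta", apply_preprocess=False)

gm = table.pivot_table(index="pair", columns="group", values="plv", aggfunc="mean")
print((gm["HC"] - gm["PDD"]).sort_values(ascending=False).head(6).round(3))

feats = feature_matrix(table, "theta")
names = [c for c in feats.columns if c not in ("subject", "group")]
fit = lasso_cv(feats[names].to_numpy(), (feats["group"] == "PDD").to_numpy(int),
               rng=1, feature_names=names)
print("K =", fit.k_min, "AUC =", round(roc_auc(fit.oof_scores,
      (feats["group"] == "PDD").to_numpy(int), n_boot=200, rng=2).auc, 3))
```

prints

```
pair
F3-T8     0.353
F3-TP8    0.315
F4-T7     0.278
F3-O2     0.230
F4-P8     0.196
F3-P8     0.170
dtype: float64
K = 8 AUC = 0.995
```

The six largest HC−PDD coherence differences are exactly the six pairs the
generator weakened (the planted effect is confined to them), and the
cross-validated classifier separates the groups nearly perfectly at this
effect size; with the effect switched off the same pipeline returns AUC ≈ 0.5.

## Command line

Each stage is a subcommand over one YAML config; runs with the same config
and seed are byte-identical:

```bash
plvnet simulate  --config config.yaml --out run/
plvnet connect   --config config.yaml --out run/ --indir run/epochs --preprocessed
plvnet network   --config config.yaml --out run/ --indir run/epochs
plvnet stats     --config config.yaml --out run/ --indir run/ --covariates run/covariates.csv
plvnet classify  --config config.yaml --out run/ --indir run/
plvnet report    --config config.yaml --out run/ --indir run/
```

`plvnet preprocess` applies artifact rejection + CSD to epoch archives;
BrainVision/EDF+ recordings are read through `mne`
(`plvnet.epochs.read_epochs`).

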
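# epiclone

Stochastic clonal dynamics and cell-cycle inference for squamous epithelial
homeostasis, built around the **single-progenitor (SP) model** of basal-layer
maintenance in mouse esophagus and interfollicular epidermis.

## The problem

Adult squamous epithelia shed cells from their surface and replace them by
division in the basal layer. Competing models describe the dividing cells:
one equipotent progenitor population (SP), a stem-cell/committed-progenitor
hierarchy (SC-CP), or two independent stem-cell pools cycling at different
rates (2xSC). Two transgenic assays discriminate them:

* **H2B-GFP dilution** — a stable histone-GFP fusion halves per division, so
  intensity histograms over a chase report the division rate λ and whether
  one or several populations cycle (modality of the histogram).
* **Lineage tracing** — sparsely labelled basal cells grow into clones whose
  basal-cell size distributions over months constrain the fate parameters.

In the SP model a progenitor divides after a (non-exponential) cycle-time
draw, producing PP / PD / DD daughter pairs with probabilities r / 1−2r / r;
differentiating basal cells (D) exit the basal layer at the stratification
rate Γ. Homeostasis ties the progenitor fraction ρ of the basal layer to the
other rates:

    Γ = ρ λ / (1 − ρ)

This package provides, for users of such data (quantitative tissue
biologists and modellers):

* exact non-Markovian event-driven Monte Carlo of SP, SC-CP and 2xSC clones
  and of H2B-GFP dilution, with exponential / shifted-gamma / deterministic
  cycle-time laws and stationary-renewal initial phases (numba-compiled);
* H2B-GFP analysis: normalization, Silverman's critical-bandwidth bootstrap
  and Hartigan's dip tests of unimodality, division-rate estimation
  (log2-slope and simulation-fit), gamma cycle-shape fitting, and
  label-retaining-cell quantification;
* maximum-likelihood inference of (r, ρ) from binned clone-size
  distributions with λ and the cycle law fixed, profile-likelihood 95% CIs,
  goodness of fit (R²_T, S_T) and CI-coverage counts;
* clone-population statistics: per-animal timecourses, the neutral-drift
  scaling collapse P(size ≥ x·mean) → e^(−x), sister-fate correlation
  (4r − 1 in the balanced case);
* synthetic-data generators emulating both experimental designs, with
  presets for the five tissues with published estimates
  (`esophagus-lrig1`, `esophagus-ahyfp`, `paw`, `ear`, `dorsum`).

## Worked example

The `analysis/` scripts run the whole study end to end on synthetic data
generated at the esophageal estimates (λ = 2.9/week, r = 0.10, ρ = 0.65,
min cycle 0.5 d):

```sh
python analysis/01_generate_datasets.py
python analysis/02_dilution_analysis.py
python analysis/03_clone_dynamics.py
python analysis/04_fit_clone_model.py
```

which prints (abridged):

```
esophageal clone table: 1258 surviving clones (10d: 327, 30d: 322, 84d: 307, 180d: 302)
esophagus-lrig1: lambda = 2.88/week (95% CI 2.83-2.92; nominal 2.9); keratinocyte
  LRC fraction at 18 d = 0.0000; all per-animal histograms unimodal: True
dorsum: lambda = 1.17/week (95% CI 1.12-1.23; nominal 1.2); ...
max |tail - exp(-x)| per time point: {'10d': 0.337, '30d': 0.185, '84d': 0.131, '180d': 0.059}
r    = 0.089  (95% CI 0.081-0.113)
rho  = 63.8% (95% CI 59-72%)
Gamma = 5.1/week (homeostatic identity)
goodness of fit: R2_T = 0.95, S_T = 2.0
model inside the 95% CI of the observed proportions in 27/28 (time, size) cells
```

Reading this: the chase recovers the division rate it was generated at
(2.88 vs 2.9/week); single-population dilution histograms stay unimodal and
contain no keratinocyte label-retaining cells; clone-size distributions
drift toward the exponential scaling form at late times; and the grid-search
MLE recovers the fate parameters (r ≈ 0.09 vs 0.10, ρ ≈ 64% vs 65%) with the
stratification rate following from the homeostatic identity. The `epiclone`
console script exposes the same steps (`epiclone synth`, `fit-clones`,
`fit-dilution`, `test-modality`, `simulate-clones`, `simulate-dilution`,
`summarize-clones`) for file-based pipelines.

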
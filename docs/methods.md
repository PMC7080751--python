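# Methods

## Models

**Single-progenitor (SP) model.** All dividing basal cells are equivalent.
A progenitor divides after a waiting time drawn from a cycle-time law with
mean 7/λ days (λ in /week); the daughter pair is PP with probability r, PD
with 1−2r, DD with r (0 ≤ r ≤ 0.5). Differentiating basal cells (D) are
post-mitotic and stratify — leave the basal layer — after an exponential
wait at rate Γ. Suprabasal cells optionally shed at rate μ (off by default:
the analyses here never constrain μ, so suprabasal counts accumulate and are
compared only qualitatively). Homeostasis of the basal layer forces
Γ = ρλ/(1−ρ), where ρ is the progenitor fraction of basal cells; the
package's `SPParams.homeostatic` constructor enforces the identity to
relative precision 1e−9, and the inference eliminates Γ through it.
Expected progenitor number per progenitor-derived clone is exactly 1 at all
times (critical branching), which the test suite asserts by Monte Carlo for
every cycle-time family.

**Cycle-time laws.** Exponential (Markovian), shifted gamma
(t_min + Gamma(k, s) with s = (mean − t_min)/k, so the mean is exact for
every shape), and deterministic (k → ∞ limit). The shift rather than a
truncation implements the refractory minimum t_min because it keeps the
mean constraint analytic. Cells present at labelling or chase start are
caught mid-cycle: their residual time to first division is drawn from the
stationary-renewal residual-life law with density (1 − F(u))/mean, sampled
as U × L with L length-biased (for the shifted gamma, a
Gamma(k)/Gamma(k+1) mixture). For exponential cycles this reduces to
memorylessness; getting it right matters precisely for the narrow gamma
laws the data favour.

**Hierarchy models.** SC-CP: stem cells divide 4× slower than progenitors by
default, with balanced stem fates (SS/S+P/PP at r_s/1−2r_s/r_s) feeding a
progenitor pool whose fates are skewed toward differentiation by δ
(PP: r_p(1−δ), PD: 1−2r_p, DD: r_p(1+δ)); the stem→progenitor flux balances
the skew. 2xSC: two independent SP processes with separate rates mixed at
labelling fractions. Published parameterisations of these models are not
reproduced here; the structures exist to generate contrast scenarios (e.g.
the dilution bimodality a 4×-separated two-population model predicts), and
every parameter is overridable.

**Simulation engine.** Exact event-driven Monte Carlo: each cell carries a
pending event time drawn at birth; events are processed in time order with
no discretisation. Per-clone cell lists are small, so the next event is
found by linear scan; the loops are numba-compiled and seeded per call,
which makes ensembles deterministic in a single integer seed and lets the
likelihood grid reuse common random numbers. A Gillespie implementation of
the Markovian special case is kept in the test suite as an independent
cross-check of the event queue.

## H2B-GFP dilution analysis

Intensities are normalized so the mean keratinocyte intensity at chase time
0 is 1; CD45+ leukocyte records are rescaled but excluded from every
statistic (they serve as label-retention references). Every division halves
the parent's label into both daughters (an optional beta-distributed
asymmetric partition exists behind a flag but is off: dilution is by
division only).

*Modality.* Silverman's test finds, by bisection, the smallest Gaussian-KDE
bandwidth giving a unimodal density, then draws variance-rescaled smoothed
bootstrap resamples and reports the fraction with >1 mode at that bandwidth.
This variant is conservative: its empirical type-I error at nominal
α = 0.05 is below 0.10 (asserted over seeded null runs in the tests), so
unimodality calls err toward not rejecting. Hartigan's dip statistic is
implemented from the classic modal-interval algorithm and validated in the
tests against an exact linear-programming oracle; its p-values come from a
simulated uniform null at the observed n. Tests are run on log
intensities pooled per animal, with a per-field option (between-field
illumination offsets can manufacture bimodality, which the generator can
reproduce on demand).

*Division rate.* The default `log2_slope` estimator regresses per-field mean
log2 keratinocyte intensity on chase time (weeks), weighting by cell count;
λ̂ = −slope, with a percentile bootstrap over fields within time points for
the CI. It carries a small downward bias at finite Γ — differentiating
basal cells hold frozen label for ~1/Γ before stratifying — of order 2% for
esophagus and ~4% for the slowest tissue (dorsum) at the 0/7/12/18-day
design, well inside the bootstrap CI; the `simulation_fit` estimator
(grid over λ, matching simulated histograms by binned likelihood) is the
bias-free reference and the two are cross-checked in the tests.

*Cycle shape.* With λ fixed, a (shape, t_min) grid is scored by the binned
negative log-likelihood of observed log intensities under simulated
histograms (30 equal-width bins spanning the pooled data, simulated bin
probabilities floored at 1/(2·n_sim) and renormalized; bin count fixed for
determinism). Besides the grid minimiser, a *conservative* solution — the
smallest shape within the χ²(1) 95% tolerance (1.92 log-units) of the
minimum — is reported and is the shape recommended for downstream
inference, so cycle-time regularity is never overstated. The tolerance rule
is a package choice; no published value exists for it. The width of the
time-0 intensity law is estimated from the time-0 data and absorbed into
the simulated initial intensities, which also soaks up static multiplicative
measurement spread.

*Label-retaining cells.* An LRC is a cell brighter than `fold_threshold` ×
the one-division level (0.5 after normalization) at a chase time where the
population has divided ≥2 times; fractions are reported separately for
keratinocytes and leukocytes. The threshold is a quantitative proxy for
what is a visual call in imaging practice.

## Clone-size inference

Surviving clones (≥1 basal cell) are binned by basal size into 1..6 and 7+;
seven categories per time point mirror how such distributions are reported.
With λ and the cycle law fixed from dilution data — the constraint that
breaks the r–λ degeneracy of clone data alone — the (r, ρ) likelihood is
multinomial over bins, summed over time points, with simulated probabilities
from ensembles at each grid point (Γ eliminated by homeostasis; a
non-homeostatic mode with free Γ exists behind a flag). Clones are pooled
across animals within a time point. The MLE is the grid argmax with local
quadratic sub-grid refinement of each profile; 95% CIs are profile-
likelihood intervals at the χ²(1) threshold with linear interpolation
between grid points, flagged when they hit the grid edge. Goodness of fit:
per time point, R² = 1 − RSS/TSS over bin frequencies in percent and
S = √(RSS/n_bins) in percentage points (an RMS-residual definition, chosen
because no formula for S is published); R²_T and S_T are unweighted means
over time points. CI coverage counts (time, size) cells whose observed
proportion ±1.96 SE (SE of a proportion) contains the prediction; its
calibration under multinomial resampling is pinned to an exact binomial
enumeration oracle in the tests (Wald intervals dip slightly below 95% for
small-probability bins).

## Synthetic data generation

The generators define the study conditions. Lineage design: cohorts of
3/3/6/4 animals at 10/30/84/180 days, ~300 surviving clones per time point
(targets 300/315/302/305), labelling efficiency 1/301 basal cells,
basal-representative initial cells (a labelled cell is a progenitor with
probability ρ). Enough clones are initiated per animal that surviving
counts match the target in expectation (survival estimated from a pilot
ensemble), and each record carries the induction effort so clone density
per induced cell is reconstructable. Chase design: chases 0/7/12/18 days,
3/3/3/2 animals, 5 fields × 130 cells per animal, 3% leukocytes, lognormal
between-field offsets (CV 0.10), lognormal measurement noise (CV 0.20),
lognormal initial intensities (CV 0.40). The intensity widths were set to
reproduce the roughly two-fold interquartile spread real time-0 histograms
show; narrower choices leave the discrete division-count structure
resolvable at 18 days, which a single-population tissue does not exhibit.
The default gamma shape is k = 8 with the tissue's published minimum cycle
time — a narrow law consistent with the reported homogeneity of cycle
periods; no published shape value exists, and the shape remains a free
parameter of `fit_cycle_shape`.

What the generators deliberately omit: multicolour reporter structure and
per-colour induction variability, clone merging (induction is sparse),
between-animal parameter heterogeneity (an optional per-animal λ jitter
exists, default off), spatial neighbour interactions, image segmentation
artefacts, and tissue growth or wounding. Passing tests therefore
demonstrate that the *inference machinery* recovers known truth under the
stated designs, not that real tissues obey the SP model.

## Numerical choices and problem sizes

Rates are stored in /week and durations in days (single conversion constant
7). Likelihood floors are 1/(2·n_sim) with renormalization. The analysis
scripts and the reproduction script run the grid search at ~20,000 clones
per grid point on a grid of r ∈ 0.03..0.25 (step 0.01) × ρ ∈ 0.30..0.95
(step 0.05), a desk-scale setting chosen so a full run completes in minutes
on one CPU; production-scale ensembles of 100,000 clones per point are the
`mle_grid_search` default. Dilution recoveries use ≥2,000 basal cells per
chase time. Seeds: every entry point takes one integer seed; internal
streams are spawned from it via `SeedSequence`, and simulation kernels are
seeded explicitly so grid points share common random numbers.

## Known limitations

Profile-likelihood CIs inherit Monte-Carlo roughness from finite ensembles;
below ~10,000 clones per grid point they can run slightly narrow. The
log2-slope λ estimator's finite-Γ bias (above) is documented rather than
corrected. The dip test's null is simulated from the uniform distribution,
the standard but conservative calibration choice. ρ is weakly identified by
clone sizes alone (its likelihood profile is shallow on the large-ρ side),
which the wide published bounds reflect; recovery tests treat the published
CI as the acceptance region. Suprabasal counts are bookkeeping only unless
a shedding rate is supplied.
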
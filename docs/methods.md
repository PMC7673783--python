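# Methods

This note documents the statistical machinery in `dielaccess`: the models
and their assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, numerical choices, and known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Event preparation

**Independence filter.** Camera triggers arrive in bursts; within each
(site, species) stream, an event is kept iff it falls at least
`quiet_minutes` (default 30) after the previously *kept* event. The first
event of a stream is always kept and a gap of exactly the quiet period
counts as independent. Comparing against the last kept (rather than last
raw) event makes the filter idempotent and order-stable; both properties
are tested.

**Clock → circle.** The circular coordinate is local clock time,
2π·(seconds since midnight)/86400. Sunrise/sunset enter only through the
nocturnal window (below); times are not sun-anchored.

**Detection histories.** For occupancy modelling, each deployment (one grid
cell in one survey year) is one *site*; cells surveyed in multiple years are
separate sites, keyed back to the cell for later year-averaging. Deployment
windows are cut into consecutive `occasion_days`-day occasions (default 14);
a trailing partial occasion of ≥ 7 days is kept, shorter ones dropped (the
source protocol leaves this unstated; it is configurable). Occasions outside
a deployment are missing, not zero.

**Species rules.** Taxon merges (the two duiker species → "duiker") apply
*before* the minimum-detection threshold (< 50 independent records removes a
species); named exclusions (elephant, hippopotamus — unrealistic prey for
large carnivores) are dropped outright. Guild pooling concatenates member
species' event times, so species are implicitly weighted by detection counts.

## 2. Human occupancy and zonation

Single-season, single-species occupancy model: site i is used with
probability Ψ_i, detection on occasion j given use has probability p_ij,
both logit-linear in covariates (categoricals dummy-coded with first-level
reference; TN and SAV standardised). The likelihood multiplies the usual
zero-inflated Bernoulli site terms with missing occasions skipped.
Optimisation is L-BFGS-B on the coefficients from a zero start plus random
restarts (default 10 at the top level; GOF bootstrap refits use 2 — the
structures refit inside GOF are simple and effectively unimodal, and 10×
restarts across a thousand bootstrap datasets buys nothing but runtime).

**Model selection** is the conventional two-stage AICc search: all candidate
detection structures with constant Ψ first, then all occupancy structures on
the stage-1 winner; AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = sites, models
with n ≤ K+1 flagged and excluded, and the ΔAICc < 2 set reported. Zone
classification always uses the single lowest-AICc model.

**Goodness of fit** is a parametric bootstrap of a chi-square statistic on
detection-history frequencies: sites are cohorted by identical (Ψ, p,
missingness) profiles; within a cohort the observed frequency of each
realised history is compared to its model probability times the cohort
size, a pooled cell absorbs the never-observed histories, and expected
cells under 0.5 are pooled upward. The bootstrap simulates data from the
fit, refits, and recomputes the statistic; p is the fraction of bootstrap
statistics ≥ observed, and ĉ = observed/mean(bootstrap). The exact
cohorting of the classical statistic is underdetermined for
covariate-rich models; this construction is one defensible reading and is
calibration-tested (p-values uniform under self-simulation).

**Conditional occupancy** is the posterior probability of use given the
history: 1 for any site with a detection, Ψq/(Ψq+1−Ψ) with q = Π(1−p_ij)
for all-zero sites. Per-cell values average a cell's site-years; the
threshold is their mean (or a fixed value); a cell is "high" human use iff
strictly above the threshold (ties → low). The sensitivity analysis
re-classifies at threshold ± 0.1 and re-runs all randomization tests.

## 3. Diel activity estimation

Activity curves are von Mises KDEs on a 512-point grid over [0, 2π),
renormalised so the periodic trapezoid integral is exactly 1.

**Bandwidth.** The kernel concentration is the Taylor (2008) plug-in

    κ_b = [3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²)]^(2/5) · adjust

with κ̂ the ML concentration (A(κ)=R̄ inverted by Best–Fisher start plus
Newton, capped at 500). This is the rule shipped with the standard overlap
estimators. A tempting simplification, κ_b = κ̂, is wrong for diel data: a
bimodal crepuscular curve has R̄ ≈ 0, so κ̂ ≈ 0 and the "estimate" is the
uniform density regardless of n; the plug-in's n^(2/5) factor restores
structure. `adjust` multiplies κ_b: 0.8 for the small-sample overlap
estimator Δ̂₁, 1.0 for Δ̂₄ and everywhere else.

**Fast path.** Point estimates use the exact kernel sum. Bootstrap
ensembles use linear binning onto the grid plus FFT circular convolution
with the kernel — O(n + G log G) per replicate instead of O(nG) — which is
what makes 10,000-replicate ensembles routine; the two paths agree to
~1e-3 sup-norm at typical sizes (tested). Parametric resampling inverts the
grid CDF; each replicate re-estimates its own bandwidth. The ensemble mean
does **not** converge to the source curve (resample-and-refit smooths
twice, an O(bandwidth) bias), only to its double-smoothed version; tests
assert the correct Monte-Carlo convergence statement.

## 4. Zone comparisons

**Nocturnal window**: sunset + 2 h to sunrise − 2 h, by default 20:06 →
03:41 (sunrise 05:41, sunset 18:06 at the survey median date), duration
7 h 35 min. Nocturnality is the activity-curve integral over that wrapping
arc, computed with quadrature weights that interpolate the grid density at
4096 arc points (exact for flat densities: 7.5833/24 = 0.3160).

**Randomization test.** Statistic: the overlap Δ̂ of the two zone curves
(estimator chosen by min n, as below). Null: fit a KDE to the pooled
sample, draw paired samples of the original sizes from it, recompute Δ̂;
p = (#{null Δ̂ ≤ observed} + 1)/(n_reps + 1). Type-I error is
calibration-tested to [0.03, 0.07] at α = 0.05.

**Nocturnality difference.** Δnoct = noct(high) − noct(low); paired
parametric ensembles give a percentile CI; significant iff the CI excludes
0. Positive = more nocturnal under high human use.

**Overlap coefficient.** Δ̂₁ integrates min(f̂_a, f̂_b) on the grid
(adjust 0.8); Δ̂₄ is the average of clipped density ratios evaluated at the
observed points (adjust 1.0, ratio denominators floored at 1e-12). The
estimator switches on min(n_a, n_b): Δ̂₁ below 75, Δ̂₄ at and above
(75 itself is unassigned by the convention "Δ₁ if N < 75, Δ₄ if N > 75";
the large-sample estimator is used at the boundary). CIs are bias-corrected
(BC, no acceleration) percentile intervals from paired nonparametric
resampling; zone difference is declared when the two zones' CIs do not
overlap.

## 5. Prey access (PAUC)

Prey curves are stacked into proportional contributions
p_s(t) = w_s f̂_s(t)/Σ w f̂, so Σ_s p_s(t) = 1 at every grid point. Default
weights are equal (each prey KDE integrates to 1 before stacking), which
makes PAUC a pure temporal-accessibility measure; detection-count weighting
is available (`prey_weights: detections`) since the source convention is
ambiguous. Then

    PAUC_s = 100 · ∫ p_s(t) f̂_pred(t) dt   (Σ_s PAUC_s = 100 exactly),
    ΔPAUC_s = PAUC_s(high) − PAUC_s(low)    (Σ_s ΔPAUC_s = 0 exactly),

both identities holding per bootstrap replicate by construction (tested to
1e-6). Bootstrapping is model-level (each zone-specific curve re-fit from
parametric resamples each replicate; chunked so memory stays flat), with
percentile CIs. Leopard's prey list excludes buffalo; lion and spotted
hyena take all 11 prey. Access diversity compares the variance of the 11
PAUC values between zones with the Fligner–Killeen test (scipy's asymptotic
implementation, flagged as asymptotic in the output; with n = 11 per group
the asymptotic p is an approximation). Lower variance = more even access =
higher effective prey diversity.

No multiple-testing correction is applied across the 14 per-species tests;
raw p-values are reported (and the run manifest says so).

## 6. The synthetic world

The generator emulates a West-African dry-season camera survey:

* **Human occupancy**: 204 cells × 10 two-week occasions; Ψ bimodal near
  the extremes (≈0.10 in national parks, ≈0.90 in hunting concessions,
  MGMT split 50/50, mean Ψ ≈ 0.5) — matching the reported shape of human
  occupancy in such systems; detection p ≈ 0.25 with a year effect and a
  savanna-cover effect. True z, Ψ, p are retained for recovery tests.
* **Diel activity**: 3 carnivores (nocturnal-crepuscular; spotted hyena
  ~6× the detections of lion or leopard), 11 ungulates (mostly
  diurnal-crepuscular; aardvark nocturnal), humans strongly diurnal
  (~80% of detections between sunrise and sunset). Counts span 110–1400
  per species per zone pair.
* **Zone shifts**: the high-zone mixture reweights the low-zone components
  by an exponential tilt, bisected until the nocturnal-window mass moves by
  the stated delta (tolerance 0.005): reedbuck +0.123, duiker +0.074,
  bushbuck +0.069, warthog +0.045, kob −0.053, aardvark −0.150, lion +0.12,
  hyena +0.04, leopard −0.05, buffalo +0.03, others 0. Component shapes are
  untouched, so a shift is reachable only within the span of the components'
  own nocturnal masses (else a specification error).
* **Timestamps** are ISO clock times on synthetic January–June dates; only
  time of day is meaningful.

What it does **not** emulate: spatial autocorrelation or animal movement,
camera-level detection physics (distance, trigger sensitivity), seasonal or
lunar modulation of activity, observation error in species ID, and any
dependence between a species' abundance and its diel shape. A green
recovery test therefore establishes estimator correctness under clean
sampling assumptions, not robustness to those field realities.

Per-operation RNG streams are derived from the master seed via CRC-tagged
`SeedSequence`s, so adding a stage never perturbs another stage's draws and
the full pipeline is bit-reproducible under a fixed seed (hash-tested).

## 7. Sizes, budgets, defaults

Defaults follow the analysis conventions: 30-min quiet period, 14-day
occasions, < 50-detection species cutoff, 512-point grid, 10,000 bootstrap
replicates, 1000 randomization repetitions, 1000 GOF bootstraps, α = 0.05,
threshold offsets ± 0.1. The test suite and acceptance script shrink only
*replicate counts* for runtime (e.g. GOF calibration at 200 × 200; pipeline
integration runs at n_boot 150–2000), never thresholds or generator
parameters; conservation identities are n_boot-independent, and the
calibration/recovery experiments state their sizes in their docstrings.

## 8. Known limitations

* Nocturnality of a KDE is a smoothed functional: point estimates are
  biased toward the uniform value (≈ 0.316) by O(bandwidth²) and the
  parametric bootstrap slightly understates sampling variance; measured
  coverage of a +0.10 built-in shift is ≈ 0.95 at n = 800/zone.
* Zone misclassification (conditional occupancy is 1 for any cell with a
  human detection) attenuates all zone contrasts toward zero; the
  end-to-end recovery tests therefore check sign and significance, not
  magnitude.
* The asymptotic Fligner–Killeen p-value with 11 values per group is an
  approximation; a permutation variant is not implemented.
* Multi-season (colonisation/extinction) occupancy, sun-anchored time
  transforms, alternative kernels and cross-validated bandwidths are out of
  scope by design.
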
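# dielaccess

Tools for asking how human presence reshapes the *temporal* niche of
wildlife, and what that does to predators' access to their prey, from
camera-trap data.

The package targets the standard savanna camera-grid design: a survey of
grid cells yields timestamped detections of humans, large carnivores and
ungulates. It then answers, in order:

1. **Where are humans?** Single-season, single-species occupancy models with
   imperfect detection (detection histories in 2-week occasions) estimate
   human site use Ψ per cell; conditional (latent) occupancy is thresholded
   at its mean to classify cells into **low** and **high** human-use zones.
2. **Who changed their schedule?** Each species' diel activity is a circular
   density over the 24-h clock, estimated by von Mises kernel density.
   Zone differences are tested with a bootstrapped randomization test
   (statistic: the coefficient of overlapping Δ of the two zone curves,
   null curves drawn from the pooled sample's KDE), and **nocturnality** —
   the area under the activity curve between 2 h after sunset and 2 h
   before sunrise — is compared with parametric-bootstrap CIs.
3. **What does it mean for predators?** Besides predator-vs-pooled-prey
   overlap Δ (Δ̂₁ for min *n* < 75, Δ̂₄ otherwise, with bias-corrected
   bootstrap CIs), the package computes a community-level prey-access
   metric: prey curves are stacked into proportional contributions
   p_s(t) with Σ_s p_s(t) = 1, and

       PAUC_s = 100 · ∫ p_s(t) · f_pred(t) dt

   is the percent of the area under the predator's activity curve
   attributable to prey *s* (Σ_s PAUC_s = 100). ΔPAUC_s = PAUC_s(high) −
   PAUC_s(low) measures how human presence redistributes predator access
   across the prey community (Σ_s ΔPAUC_s = 0), with bootstrap CIs, and a
   Fligner–Killeen test compares the evenness of access between zones.

A synthetic-data module generates the whole world with known ground truth —
occupancy/detection parameters, per-species von Mises mixtures, and stated
zone shifts in nocturnality — so every estimator in the chain is testable
without field data.

## Worked example

```python
from dielaccess import (PipelineConfig, run_pipeline)

cfg = PipelineConfig(seed=7, n_boot=200, n_reps=100, n_boot_gof=50)
bundle = run_pipeline(cfg)          # simulates the reference scenario and
                                    # runs every stage
print(bundle.zones.n_high, bundle.zones.n_low, round(bundle.zones.threshold, 3))
print(bundle.nocturnality[bundle.nocturnality.species_or_guild == "reedbuck"])
```

prints (seed 7):

```
90 114 0.496
  species_or_guild  prop_low  prop_high     delta   ci_low   ci_high  significant
8         reedbuck  0.394104   0.462881  0.068777  ...      ...       True
```

i.e. the occupancy model split the 204 cells into 90 high- and 114 low-use
cells at a mean-occupancy threshold of 0.50, and reedbuck — generated with a +0.123 nocturnality
shift in high-use zones — is estimated 6.9 percentage points more nocturnal
where humans are common (attenuated by zone misclassification and kernel
smoothing), with a bootstrap CI excluding 0. The same bundle carries the
model-selection and GOF tables, per-species randomization tests, zone-level
predator–prey Δ, and the PAUC/ΔPAUC and access-diversity tables; in this
run lion and spotted hyena gain significant access to reedbuck (ΔPAUC > 0)
and lose access to kob (ΔPAUC < 0), matching the generator's built-in
shifts.

A command line mirrors the stages:

```bash
dielaccess simulate --seed 7 --out scenario/     # write synthetic CSVs
dielaccess run --seed 7 --out results/           # full pipeline
dielaccess sensitivity --seed 7 --out results/   # threshold ±0.1 re-tests
```

Real data enter through two CSVs (set `use_reference_scenario: false` in a
YAML config): a detection table `site_id,species,timestamp[,year,...]` and a
deployment table `site_id,year,start_date,end_date[,covariates...]`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on the reference scenario under the
given seed — occupancy model selection and goodness of fit, zone
classification, all diel comparisons, overlap, PAUC/ΔPAUC, the
Fligner–Killeen tests and the threshold sensitivity analysis — writes the
result tables under `results/pipeline_outputs/`, and emits the target JSON
to `--out`.

## Layout

```
src/dielaccess/
  synthetic.py    ground-truth generators (histories, diel mixtures, scenario)
  events.py       CSV I/O, 30-min independence filter, detection histories,
                  species filters, guild pooling
  occupancy.py    occupancy likelihood, AICc two-stage selection, bootstrap
                  GOF and c-hat, conditional occupancy, zone classification
  density.py      von Mises KDE (Taylor plug-in bandwidth), bootstrap engine
  comparison.py   nocturnal window, randomization test, nocturnality, Δ overlap
  prey_access.py  stacked prey composition, PAUC, ΔPAUC, access diversity
  pipeline.py     orchestration, manifest, threshold sensitivity
  cli.py          click front end
```

See `docs/methods.md` for the statistical details and the design decisions.
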
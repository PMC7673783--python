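"""End-to-end orchestration: data -> zones -> diel analyses -> prey access.

Stages, in order: read (or simulate) detection events; quiet-period
independence filter; species filters (merges, exclusions, minimum
detections); human occupancy modelling with two-stage AICc selection and
parametric-bootstrap goodness of fit; low/high zone classification from
cell-averaged conditional occupancy; per-species and guild randomization
tests; nocturnality differences with bootstrap CIs; predator-vs-pooled-prey
overlap (Delta) per zone with bias-corrected CIs; PAUC / delta-PAUC per
predator; Fligner-Killeen prey-access diversity test.  A run manifest
(seeds, config hash, stage log) makes runs reproducible.

No multiple-testing correction is applied across the per-species tests: raw
per-test p-values are reported, as is conventional for this analysis, and
the output notes this.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, events as ev, occupancy as occ, prey_access as pa
from .density import DielSample
from .synthetic import _child_seed, make_reference_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML via ``from_yaml``."""

    # inputs: either CSV paths or the built-in synthetic scenario
    events_csv: str | None = None
    deployments_csv: str | None = None
    use_reference_scenario: bool = True

    # guilds and prey lists
    carnivores: tuple = ("lion", "leopard", "spotted_hyena")
    ungulates: tuple = ("buffalo", "roan_antelope", "hartebeest", "waterbuck", "kob",
                        "reedbuck", "bushbuck", "aardvark", "warthog", "oribi", "duiker")
    human_label: str = "human"
    #: predator -> prey exclusions (leopard never takes buffalo)
    prey_exclusions: dict = field(default_factory=lambda: {"leopard": ("buffalo",)})

    # event preparation
    quiet_minutes: float = 30.0
    min_detections: int = 50
    species_exclusions: tuple = ("elephant", "hippopotamus")
    species_merges: dict = field(default_factory=lambda: {
        "red_flanked_duiker": "duiker", "common_duiker": "duiker"})

    # occupancy
    occasion_days: int = 14
    p_covariates: tuple = ("SAV", "YR", "TN", "CAM", "MGMT", "SITE")
    psi_covariates: tuple = ("MGMT", "YR", "SITE")
    n_boot_gof: int = 1000
    threshold_rule: str = "mean"
    fixed_threshold: float | None = None
    fit_restarts: int = 10

    # temporal analyses
    sunrise: str = "05:41"
    sunset: str = "18:06"
    buffer_hours: float = 2.0
    n_reps: int = 1000
    n_boot: int = 10_000
    prey_weights: str = "equal"
    min_sample: int = 10
    alpha: float = 0.05
    sensitivity_offsets: tuple = (-0.1, +0.1)

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    zones: occ.ZoneAssignment
    selection: occ.ModelSelectionResult
    gof: occ.GOFResult
    comparisons: pd.DataFrame
    nocturnality: pd.DataFrame
    overlap: pd.DataFrame
    pauc: pd.DataFrame
    delta_pauc: pd.DataFrame
    diversity: pd.DataFrame
    manifest: dict
    events: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.zones.table.to_csv(out / "zones.csv")
        self.selection.stage1_table.to_csv(out / "model_selection_detection.csv", index=False)
        self.selection.stage2_table.to_csv(out / "model_selection_occupancy.csv", index=False)
        self.comparisons.to_csv(out / "randomization_tests.csv", index=False)
        self.nocturnality.to_csv(out / "nocturnality.csv", index=False)
        self.overlap.to_csv(out / "overlap.csv", index=False)
        self.pauc.to_csv(out / "pauc.csv", index=False)
        self.delta_pauc.to_csv(out / "delta_pauc.csv", index=False)
        self.diversity.to_csv(out / "access_diversity.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def result_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.zones.table, self.comparisons, self.nocturnality,
                   self.overlap, self.pauc, self.delta_pauc, self.diversity):
            h.update(df.round(10).to_csv().encode())
        return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(manifest, name):
    manifest["stages"].append({"stage": name, "t": time.time()})
    logger.info("stage: %s", name)


def prepare_events(config: PipelineConfig):
    """Load or simulate events and the human detection-history set."""
    if config.use_reference_scenario:
        events, history, truth = make_reference_scenario(seed=config.seed)
        return events, history, truth
    if not config.events_csv or not config.deployments_csv:
        raise ValueError("events_csv and deployments_csv required when not simulating")
    events, _ = ev.read_detections(config.events_csv)
    deployments = pd.read_csv(config.deployments_csv)
    filtered = ev.filter_independent_events(events, config.quiet_minutes)
    history = ev.build_detection_history(
        filtered, deployments, config.human_label, occasion_days=config.occasion_days
    )
    return events, history, None


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full analysis; see module docstring for the stage order."""
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "seed": config.seed, "stages": []}
    window = comparison.make_nocturnal_window(config.sunrise, config.sunset, config.buffer_hours)
    seed = config.seed

    _stage(manifest, "prepare_events")
    events, history, truth = prepare_events(config)

    _stage(manifest, "independence_filter")
    try:
        events = ev.filter_independent_events(events, config.quiet_minutes)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("independence_filter", exc) from exc

    _stage(manifest, "species_filters")
    wildlife = events[events["species"] != config.human_label]
    humans = events[events["species"] == config.human_label]
    wildlife, filter_report = ev.apply_species_filters(
        wildlife, min_detections=config.min_detections,
        exclusions=config.species_exclusions, merges=config.species_merges,
    )
    events = pd.concat([wildlife, humans], ignore_index=True)
    manifest["species_filter_report"] = filter_report

    _stage(manifest, "occupancy_selection")
    try:
        selection = occ.aicc_model_selection(
            history,
            p_covariates=config.p_covariates,
            psi_covariates=config.psi_covariates,
            restarts=min(config.fit_restarts, 3),
            seed=_child_seed(seed, "selection"),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("occupancy_selection", exc) from exc
    best = selection.best_fit
    manifest["naive_occupancy"] = history.naive_occupancy()

    _stage(manifest, "goodness_of_fit")
    gof = occ.goodness_of_fit(best, n_boot=config.n_boot_gof, seed=_child_seed(seed, "gof"))

    _stage(manifest, "classify_zones")
    zones = occ.classify_zones(best, threshold_rule=config.threshold_rule,
                               fixed_value=config.fixed_threshold)
    manifest["zone_threshold"] = zones.threshold
    manifest["n_high"] = zones.n_high
    manifest["n_low"] = zones.n_low

    _stage(manifest, "attach_zones")
    events = ev.attach_zones(events, zones.zone_of_cell)
    events = events.dropna(subset=["zone"])

    comparisons, nocturnality, overlap, pauc, dpauc, diversity = diel_analyses(
        events, config, window, seed, manifest
    )

    manifest["note"] = ("per-species p-values are raw (no multiple-testing "
                        "correction), matching standard reporting for this analysis")
    if truth is not None:
        manifest["synthetic_truth_seed"] = truth["seed"]
    return ResultBundle(
        zones=zones, selection=selection, gof=gof, comparisons=comparisons,
        nocturnality=nocturnality, overlap=overlap, pauc=pauc, delta_pauc=dpauc,
        diversity=diversity, manifest=manifest, events=events,
    )


def _guilds_present(events, config: PipelineConfig):
    present = set(events["species"])
    return {
        "carnivores": [s for s in config.carnivores if s in present],
        "ungulates": [s for s in config.ungulates if s in present],
    }


def _zone_sample(events, name, members, zone):
    s = ev.pool_guild(events, members, zone)
    return DielSample(name=name, zone=zone, times=s.times)


def randomization_stage(events, config: PipelineConfig, seed) -> pd.DataFrame:
    """Per-species and per-guild randomization tests between zones."""
    guilds = _guilds_present(events, config)
    species_present = guilds["carnivores"] + guilds["ungulates"]
    rows = []
    targets = [(sp, [sp]) for sp in species_present] + list(guilds.items())
    for name, members in targets:
        lo = _zone_sample(events, name, members, "low")
        hi = _zone_sample(events, name, members, "high")
        if min(lo.n, hi.n) < config.min_sample:
            logger.warning("skipping %s: n_low=%d n_high=%d below floor", name, lo.n, hi.n)
            continue
        r = comparison.randomization_test(lo, hi, n_reps=config.n_reps,
                                          seed=_child_seed(seed, f"rand:{name}"))
        rows.append({"species_or_guild": name, "statistic": r.statistic,
                     "p_value": r.p_value, "n_low": r.n_low, "n_high": r.n_high,
                     "n_reps": r.n_reps, "significant": r.p_value < config.alpha})
    return pd.DataFrame(rows)


def diel_analyses(events, config: PipelineConfig, window, seed, manifest):
    """Stages downstream of zone assignment."""
    guilds = _guilds_present(events, config)
    species_present = guilds["carnivores"] + guilds["ungulates"]

    def zone_sample(name, members, zone):
        return _zone_sample(events, name, members, zone)

    _stage(manifest, "randomization_tests")
    comparisons = randomization_stage(events, config, seed)

    _stage(manifest, "nocturnality")
    noct_rows = []
    targets = [(sp, [sp]) for sp in species_present] + list(guilds.items())
    for name, members in targets:
        lo = zone_sample(name, members, "low")
        hi = zone_sample(name, members, "high")
        if min(lo.n, hi.n) < config.min_sample:
            continue
        n = comparison.nocturnality_difference(
            lo, hi, window, n_boot=config.n_boot, seed=_child_seed(seed, f"noct:{name}"),
            min_sample=config.min_sample,
        )
        noct_rows.append({"species_or_guild": name, "prop_low": n.prop_low,
                          "prop_high": n.prop_high, "delta": n.delta,
                          "ci_low": n.ci95[0], "ci_high": n.ci95[1],
                          "significant": n.significant})
    nocturnality = pd.DataFrame(noct_rows)

    _stage(manifest, "predator_prey_overlap")
    overlap_rows = []
    for pred in guilds["carnivores"]:
        prey_list = [s for s in guilds["ungulates"]
                     if s not in config.prey_exclusions.get(pred, ())]
        for zone in ("low", "high"):
            p_s = zone_sample(pred, [pred], zone)
            q_s = zone_sample(f"prey_of_{pred}", prey_list, zone)
            if min(p_s.n, q_s.n) < config.min_sample:
                continue
            o = comparison.overlap_ci(p_s, q_s, n_boot=config.n_boot,
                                      seed=_child_seed(seed, f"ovl:{pred}:{zone}"))
            overlap_rows.append({"predator": pred, "zone": zone, "delta": o.delta_hat,
                                 "estimator": o.estimator, "min_n": o.min_n,
                                 "ci_low": o.ci95[0], "ci_high": o.ci95[1]})
    overlap = pd.DataFrame(overlap_rows)
    if not overlap.empty:
        sig = {}
        for pred, grp in overlap.groupby("predator"):
            if len(grp) == 2:
                lo_row = grp[grp["zone"] == "low"].iloc[0]
                hi_row = grp[grp["zone"] == "high"].iloc[0]
                sig[pred] = bool(lo_row["ci_high"] < hi_row["ci_low"]
                                 or hi_row["ci_high"] < lo_row["ci_low"])
        overlap["zones_differ"] = overlap["predator"].map(sig)

    _stage(manifest, "prey_access")
    pauc_rows, dpauc_tabs, div_rows = [], [], []
    for pred in guilds["carnivores"]:
        prey_list = [s for s in guilds["ungulates"]
                     if s not in config.prey_exclusions.get(pred, ())]
        try:
            pred_samples = {z: zone_sample(pred, [pred], z) for z in ("low", "high")}
            prey_samples = {s: {z: zone_sample(s, [s], z) for z in ("low", "high")}
                            for s in prey_list}
            res = pa.delta_pauc(pred_samples, prey_samples, n_boot=config.n_boot,
                                seed=_child_seed(seed, f"pauc:{pred}"),
                                weights=config.prey_weights, min_sample=config.min_sample)
        except Exception as exc:  # noqa: BLE001
            raise StageFailure(f"prey_access:{pred}", exc) from exc
        for z, series in (("low", res.pauc_low), ("high", res.pauc_high)):
            for s, v in series.items():
                pauc_rows.append({"predator": pred, "zone": z, "prey": s, "pauc": v})
        dpauc_tabs.append(res.table)
        d = pa.access_diversity_test(res.pauc_low.to_numpy(), res.pauc_high.to_numpy(),
                                     alpha=config.alpha, predator=pred)
        div_rows.append({"predator": pred, "fk_statistic": d.fk_statistic,
                         "p_value": d.p_value, "interpretation": d.interpretation,
                         "var_low": d.var_low, "var_high": d.var_high,
                         "method": d.method})
    pauc = pd.DataFrame(pauc_rows)
    dpauc = pd.concat(dpauc_tabs, ignore_index=True) if dpauc_tabs else pd.DataFrame()
    diversity = pd.DataFrame(div_rows)
    return comparisons, nocturnality, overlap, pauc, dpauc, diversity


def threshold_sensitivity(config: PipelineConfig, bundle: ResultBundle,
                          offsets=None) -> pd.DataFrame:
    """Re-run the per-species/guild randomization tests at shifted zone
    thresholds and report significance stability.

    For each offset, cells are re-classified at (base threshold + offset)
    with the same fitted occupancy model; offsets yielding an empty zone are
    flagged and skipped.  Offset 0.0 reproduces the base run.
    """
    offsets = list(config.sensitivity_offsets if offsets is None else offsets)
    best = bundle.selection.best_fit
    base = bundle.comparisons[["species_or_guild", "p_value", "significant"]].copy()
    base["offset"] = 0.0
    rows = [base]
    raw_events = bundle.events.drop(columns=["zone"])
    for off in offsets:
        thr = bundle.zones.threshold + off
        if not (0.0 < thr < 1.0):
            logger.warning("offset %+0.2f puts threshold outside (0,1); skipped", off)
            continue
        z = occ.classify_zones(best, threshold_rule="fixed", fixed_value=thr)
        if z.n_high == 0 or z.n_low == 0:
            logger.warning("offset %+0.2f empties a zone; skipped", off)
            continue
        events_off = ev.attach_zones(raw_events, z.zone_of_cell).dropna(subset=["zone"])
        comp = randomization_stage(events_off, config, config.seed)
        comp = comp[["species_or_guild", "p_value", "significant"]].copy()
        comp["offset"] = off
        rows.append(comp)
    table = pd.concat(rows, ignore_index=True)
    stability = table.groupby("species_or_guild")["significant"].agg(["all", "any"])
    stable = (stability["all"] | ~stability["any"]).rename("stable")
    return table.merge(stable, on="species_or_guild")
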
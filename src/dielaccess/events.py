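"""Reading, validating and preparing camera-trap detection events.

Covers: CSV ingestion with schema validation, the quiet-period independence
filter applied per camera station and species, conversion of clock times to
circular coordinates, assembly of occupancy detection histories from
deployments, the species filtering rules (minimum detections, exclusions,
taxon merges), and pooling of species into guild-level diel samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import TWO_PI, DielSample

MANDATORY_COLUMNS = ("site_id", "species", "timestamp")
SECONDS_PER_DAY = 86400.0


class FormatError(ValueError):
    """Raised when an input table is structurally unusable."""


@dataclass
class ReadReport:
    n_rows: int
    n_rejected: int
    rejected_indices: list = field(default_factory=list)


def read_detections(path, column_map: dict | None = None, max_bad_fraction: float = 0.01):
    """Read a detection-event CSV into a validated events table.

    Parameters
    ----------
    column_map : optional mapping from the file's column names to the
        canonical names (site_id, species, timestamp, year, camera_type, zone).
    max_bad_fraction : abort if more than this fraction of rows has an
        unparseable timestamp; below it, bad rows are dropped and counted.

    Returns
    -------
    (events, report) : the validated DataFrame and a ReadReport with the
        count of rejected rows.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"detection table is missing mandatory column(s): {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() | df["species"].isna() | (df["species"].astype(str).str.len() == 0)
    n_bad = int(bad.sum())
    if len(df) and n_bad / len(df) > max_bad_fraction:
        raise FormatError(
            f"{n_bad}/{len(df)} rows rejected (unparseable timestamp or empty "
            f"species), above the {max_bad_fraction:.0%} abort threshold"
        )
    report = ReadReport(n_rows=len(df), n_rejected=n_bad, rejected_indices=list(df.index[bad]))
    events = df.loc[~bad].copy()
    events["timestamp"] = ts[~bad]
    if "year" not in events.columns:
        events["year"] = events["timestamp"].dt.year
    return events.reset_index(drop=True), report


def filter_independent_events(events: pd.DataFrame, quiet_minutes: float = 30.0) -> pd.DataFrame:
    """Thin detection events to independent records with a quiet period.

    Within each (site_id, species) stream ordered by time, an event is kept
    iff it falls at least ``quiet_minutes`` after the previously *kept* event;
    the first event of a stream is always kept and a gap of exactly
    ``quiet_minutes`` counts as independent.  The filter is idempotent.
    """
    if quiet_minutes < 0:
        raise ValueError("quiet_minutes must be nonnegative")
    if events.empty:
        return events.copy()
    quiet = pd.Timedelta(minutes=quiet_minutes)
    ordered = events.sort_values(["site_id", "species", "timestamp"], kind="mergesort")
    keep = np.zeros(len(ordered), dtype=bool)
    ts = ordered["timestamp"].to_numpy()
    group_ids = pd.factorize(
        ordered["site_id"].astype(str) + "\x00" + ordered["species"].astype(str)
    )[0]
    last_kept = None
    last_group = -1
    for k in range(len(ordered)):
        if group_ids[k] != last_group or ts[k] - last_kept >= quiet:
            keep[k] = True
            last_kept = ts[k]
            last_group = group_ids[k]
    return ordered.loc[keep].reset_index(drop=True)


def clock_to_radians(timestamps) -> np.ndarray | float:
    """Map local clock time-of-day to radians in [0, 2pi): midnight -> 0, noon -> pi."""
    scalar = not hasattr(timestamps, "__len__") or isinstance(timestamps, str)
    ts = pd.to_datetime(pd.Series([timestamps] if scalar else timestamps))
    secs = ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second + ts.dt.microsecond / 1e6
    rad = (TWO_PI * secs / SECONDS_PER_DAY).to_numpy() % TWO_PI
    return float(rad[0]) if scalar else rad


def hours_to_radians(hours: float) -> float:
    """Clock hours (0-24) to radians in [0, 2pi)."""
    return (hours % 24.0) * TWO_PI / 24.0


def build_detection_history(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
    occasion_days: int = 14,
    min_partial_days: int = 7,
):
    """Assemble a site x occasion detection history for one species.

    Each deployment row (a grid cell surveyed in one year) is one *site*:
    cells surveyed in multiple years are separate sites, keyed back to their
    grid cell through ``cell_key``.  Deployment windows are sliced into
    consecutive ``occasion_days``-day occasions from start_date; a trailing
    partial occasion of at least ``min_partial_days`` days is kept, shorter
    ones are dropped.  Occasions beyond a deployment's end are missing (NaN),
    not zero.

    Returns an ``occupancy.DetectionHistorySet``.
    """
    from .occupancy import DetectionHistorySet

    dep = deployments.copy()
    dep["start_date"] = pd.to_datetime(dep["start_date"])
    dep["end_date"] = pd.to_datetime(dep["end_date"])
    if (dep["end_date"] < dep["start_date"]).any():
        raise FormatError("deployment with end_date before start_date")

    sp_events = events[events["species"] == species]
    dep_keys = set(zip(dep["site_id"], dep["year"]))
    ev_keys = set(zip(sp_events["site_id"], sp_events["year"]))
    orphans = ev_keys - dep_keys
    if orphans:
        raise FormatError(f"events of '{species}' at site-years with no deployment: {sorted(orphans)[:5]}")

    durations = (dep["end_date"] - dep["start_date"]).dt.days
    n_occ_full = durations // occasion_days
    partial = durations % occasion_days
    n_occ = (n_occ_full + (partial >= min_partial_days)).astype(int)
    j_max = int(n_occ.max())

    y = np.full((len(dep), j_max), np.nan)
    site_ids = []
    for i, row in enumerate(dep.itertuples(index=False)):
        site_ids.append(f"{row.site_id}::{row.year}")
        ji = n_occ.iloc[i]
        y[i, :ji] = 0.0
        ev = sp_events[(sp_events["site_id"] == row.site_id) & (sp_events["year"] == row.year)]
        if len(ev):
            offset_days = (ev["timestamp"] - row.start_date).dt.total_seconds() / 86400.0
            occ_idx = np.floor(offset_days / occasion_days).astype(int)
            occ_idx = occ_idx[(occ_idx >= 0) & (occ_idx < ji)]
            y[i, np.unique(occ_idx)] = 1.0

    covariate_cols = [c for c in dep.columns if c not in ("site_id", "year", "start_date", "end_date")]
    site_cov = dep[covariate_cols].copy()
    site_cov["YR"] = dep["year"].astype(str)
    site_cov.index = pd.Index(site_ids, name="site")
    return DetectionHistorySet(
        y=y,
        site_covariates=site_cov,
        cell_key=np.asarray(dep["site_id"].astype(str)),
        site_ids=np.asarray(site_ids),
    )


def apply_species_filters(
    events: pd.DataFrame,
    min_detections: int = 50,
    exclusions: tuple = (),
    merges: dict | None = None,
):
    """Apply the analysis species filters to an (independence-filtered) table.

    Order matters: merges (e.g. the two duiker species into 'duiker') are
    applied before the detection-count threshold, exclusions (e.g. elephant,
    hippopotamus) are dropped outright, and any species with fewer than
    ``min_detections`` records (strictly fewer) is removed.

    Returns (filtered_events, report) where report maps each removed species
    to the reason ('excluded' or 'below_min_detections:<n>').
    """
    out = events.copy()
    report: dict[str, str] = {}
    if merges:
        out["species"] = out["species"].replace(merges)
        for old in merges:
            if old in set(events["species"]):
                report[old] = f"merged_into:{merges[old]}"
    for sp in exclusions:
        if sp in set(out["species"]):
            report[sp] = "excluded"
    out = out[~out["species"].isin(set(exclusions))]
    counts = out["species"].value_counts()
    small = counts[counts < min_detections]
    for sp, k in small.items():
        report[sp] = f"below_min_detections:{k}"
    out = out[~out["species"].isin(set(small.index))]
    return out.reset_index(drop=True), report


def species_sample(events: pd.DataFrame, species: str, zone: str | None = None) -> DielSample:
    """Extract one species' diel sample (radian times) in one zone."""
    sel = events["species"] == species
    if zone is not None:
        sel &= events["zone"] == zone
    sub = events[sel]
    return DielSample(name=species, zone=zone or "all", times=clock_to_radians(sub["timestamp"]))


def pool_guild(events: pd.DataFrame, members: list[str], zone: str | None = None) -> DielSample:
    """Pool member species' events into one guild-level diel sample.

    Species are implicitly weighted by their detection counts: the pooled
    sample is the concatenation of all members' radian event times in the
    zone.
    """
    if not members:
        raise ValueError("members must be non-empty")
    sel = events["species"].isin(members)
    if zone is not None:
        sel &= events["zone"] == zone
    sub = events[sel]
    if sub.empty:
        raise ValueError(f"no events for guild members {members} in zone {zone!r}")
    name = "+".join(members) if len(members) <= 3 else f"guild[{len(members)}]"
    return DielSample(name=name, zone=zone or "all", times=clock_to_radians(sub["timestamp"]))


def attach_zones(events: pd.DataFrame, zone_of_cell: dict) -> pd.DataFrame:
    """Label each event with the human-use zone of its grid cell."""
    out = events.copy()
    out["zone"] = out["site_id"].map(zone_of_cell)
    return out
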
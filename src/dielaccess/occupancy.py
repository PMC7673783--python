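"""Single-season, single-species occupancy models with imperfect detection.

The model: each site i is occupied with probability psi_i (logit-linear in
site covariates); given occupancy, each survey occasion j yields a detection
with probability p_ij (logit-linear in site and/or occasion covariates).
The likelihood for site i's binary history y_i. (missing occasions skipped) is

    L_i = psi_i * prod_j p_ij^y_ij (1-p_ij)^(1-y_ij)  +  (1-psi_i) * I(y_i. == 0)

Model selection follows a two-stage AICc search (detection structure first
with constant occupancy, then occupancy structure with the best detection
structure), goodness of fit uses a parametric bootstrap of a chi-square
statistic over detection-history frequencies cohorted by covariate profile,
and sites are classified into low/high human-use zones by thresholding the
cell-averaged conditional (latent) occupancy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

#: covariates treated as continuous and standardised; everything else is
#: dummy-coded with the first level as reference
CONTINUOUS_COVARIATES = ("TN", "SAV")


class FitError(RuntimeError):
    """Raised when the occupancy likelihood cannot be maximised."""


@dataclass
class DetectionHistorySet:
    """Site x occasion binary-with-missing detection data plus covariates."""

    y: np.ndarray  # (n_sites, n_occasions), entries 0/1/NaN
    site_covariates: pd.DataFrame
    cell_key: np.ndarray
    site_ids: np.ndarray | None = None
    occasion_covariates: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        vals = self.y[~np.isnan(self.y)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detection histories must be binary (0/1) or missing")
        if len(self.site_covariates) != self.n_sites:
            raise ValueError("site covariates do not match the number of sites")
        if self.site_ids is None:
            self.site_ids = np.array([f"site{i}" for i in range(self.n_sites)])

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def detected(self) -> np.ndarray:
        """Boolean: site has at least one detection."""
        return np.nansum(self.y, axis=1) > 0

    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection (no correction)."""
        return float(self.detected.mean())


@dataclass
class OccupancyFit:
    psi_formula: tuple
    p_formula: tuple
    beta_psi: np.ndarray
    beta_p: np.ndarray
    loglik: float
    n_sites: int
    site_psi: np.ndarray
    site_p: np.ndarray  # (n_sites, n_occasions)
    history: DetectionHistorySet = field(repr=False, default=None)
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.beta_psi) + len(self.beta_p)

    def aicc(self) -> float:
        return aicc(self.loglik, self.K, self.n_sites)


@dataclass
class GOFResult:
    chisq_obs: float
    boot_chisq: np.ndarray
    p_value: float
    c_hat: float
    n_failed: int = 0


@dataclass
class ZoneAssignment:
    """Per-grid-cell human-use class from thresholded conditional occupancy."""

    table: pd.DataFrame  # index cell_id, columns mean_conditional_psi, zone
    threshold: float

    @property
    def zone_of_cell(self) -> dict:
        return self.table["zone"].to_dict()

    @property
    def n_high(self) -> int:
        return int((self.table["zone"] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.table["zone"] == "low").sum())


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2K + 2K(K+1)/(n-K-1); undefined (inf) if n <= K+1."""
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _design_matrix(cov: pd.DataFrame, formula: tuple | list) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded categoricals (first level reference) +
    standardised continuous covariates, in formula order."""
    n = len(cov)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in formula:
        if term not in cov.columns:
            raise KeyError(f"covariate '{term}' not found")
        x = cov[term]
        if term in CONTINUOUS_COVARIATES or pd.api.types.is_numeric_dtype(x):
            v = x.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
            names.append(term)
        else:
            levels = sorted(x.astype(str).unique())
            for lev in levels[1:]:
                cols.append((x.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def _p_design(history: DetectionHistorySet, p_formula) -> np.ndarray:
    """Detection design as (n_sites*n_occasions, K_p); site covariates are
    broadcast across occasions, occasion covariates override when present."""
    n, J = history.y.shape
    site_terms = [t for t in p_formula if t not in history.occasion_covariates]
    X_site, _ = _design_matrix(history.site_covariates, site_terms)
    X = np.repeat(X_site, J, axis=0)
    for t in p_formula:
        if t in history.occasion_covariates:
            v = np.asarray(history.occasion_covariates[t], dtype=float).reshape(n * J)
            sd = np.nanstd(v)
            v = (v - np.nanmean(v)) / sd if sd > 0 else v - np.nanmean(v)
            X = np.column_stack([X, np.nan_to_num(v)])
    return X


def _negloglik_factory(history: DetectionHistorySet, X_psi, X_p):
    y = history.y
    n, J = y.shape
    obs = ~np.isnan(y)
    y0 = np.nan_to_num(y)
    all_zero = ~history.detected
    k_psi = X_psi.shape[1]

    def negloglik(beta: np.ndarray) -> float:
        # clip away from {0,1} so log terms stay finite at extreme coefficients
        psi = np.clip(expit(X_psi @ beta[:k_psi]), 1e-12, 1.0 - 1e-12)
        eta_p = (X_p @ beta[k_psi:]).reshape(n, J)
        # log detection-history probability given occupancy, missing skipped
        with np.errstate(over="ignore"):
            log_p = -np.logaddexp(0.0, -eta_p)
            log_q = -np.logaddexp(0.0, eta_p)
        ll_det = np.where(obs, y0 * log_p + (1.0 - y0) * log_q, 0.0).sum(axis=1)
        occ_term = np.log(psi) + ll_det
        site_ll = np.where(
            all_zero,
            np.logaddexp(occ_term, np.log1p(-psi)),
            occ_term,
        )
        return -site_ll.sum()

    return negloglik


def fit_occupancy(
    history: DetectionHistorySet,
    psi_formula=(),
    p_formula=(),
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
) -> OccupancyFit:
    """Maximum-likelihood fit of the single-season occupancy model.

    ``psi_formula`` and ``p_formula`` are sequences of covariate names; the
    empty sequence is the constant (intercept-only) structure.  Optimisation
    is quasi-Newton (L-BFGS-B) on the logit-scale coefficients from a zero
    start plus ``restarts`` random restarts, keeping the best optimum.
    """
    if history.n_occasions < 1:
        raise ValueError("need at least one occasion")
    X_psi, _ = _design_matrix(history.site_covariates, tuple(psi_formula))
    X_p = _p_design(history, tuple(p_formula))
    nll = _negloglik_factory(history, X_psi, X_p)
    k = X_psi.shape[1] + X_p.shape[1]

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [rng.normal(scale=1.5, size=k) for _ in range(max(restarts - 1, 0))]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 500, "ftol": tol})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("occupancy likelihood optimisation failed")
    beta = best.x
    k_psi = X_psi.shape[1]
    site_psi = expit(X_psi @ beta[:k_psi])
    site_p = expit((X_p @ beta[k_psi:]).reshape(history.y.shape))
    fit = OccupancyFit(
        psi_formula=tuple(psi_formula),
        p_formula=tuple(p_formula),
        beta_psi=beta[:k_psi],
        beta_p=beta[k_psi:],
        loglik=-float(best.fun),
        n_sites=history.n_sites,
        site_psi=site_psi,
        site_p=site_p,
        history=history,
        converged=bool(best.success),
    )
    if not best.success:
        logger.warning("optimiser reported non-convergence: %s", best.message)
    return fit


def _powerset(items) -> list[tuple]:
    items = list(items)
    return [
        tuple(c) for r in range(len(items) + 1) for c in itertools.combinations(items, r)
    ]


def _selection_table(history, candidates, restarts, seed) -> tuple[pd.DataFrame, dict]:
    rows, fits = [], {}
    for i, (psi_f, p_f) in enumerate(candidates):
        try:
            fit = fit_occupancy(history, psi_f, p_f, restarts=restarts, seed=seed + i)
        except (FitError, KeyError) as exc:
            logger.warning("model psi=%s p=%s failed: %s", psi_f, p_f, exc)
            continue
        a = fit.aicc()
        if not np.isfinite(a):
            logger.warning("model psi=%s p=%s: AICc undefined (n <= K+1), excluded", psi_f, p_f)
            continue
        model_id = f"psi({'+'.join(psi_f) or '.'})p({'+'.join(p_f) or '.'})"
        fits[model_id] = fit
        rows.append({"model": model_id, "psi_formula": psi_f, "p_formula": p_f,
                     "K": fit.K, "loglik": fit.loglik, "AICc": a})
    if not rows:
        raise FitError("no candidate model could be fit")
    tab = pd.DataFrame(rows).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    tab["deltaAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    rel = np.exp(-0.5 * tab["deltaAICc"])
    tab["weight"] = rel / rel.sum()
    return tab, fits


@dataclass
class ModelSelectionResult:
    stage1_table: pd.DataFrame  # detection structures, constant occupancy
    stage2_table: pd.DataFrame  # occupancy structures, best detection structure
    best_fit: OccupancyFit

    @property
    def competing(self) -> pd.DataFrame:
        """Stage-2 models with deltaAICc < 2."""
        return self.stage2_table[self.stage2_table["deltaAICc"] < 2.0]


def aicc_model_selection(
    history: DetectionHistorySet,
    p_covariate_sets=None,
    psi_covariate_sets=None,
    p_covariates=("SAV", "YR", "TN", "CAM", "MGMT", "SITE"),
    psi_covariates=("MGMT", "YR", "SITE"),
    restarts: int = 3,
    seed: int = 0,
) -> ModelSelectionResult:
    """Two-stage AICc model selection.

    Stage 1 fits every candidate detection structure while holding occupancy
    constant and ranks by AICc; stage 2 fixes the stage-1 best detection
    structure and fits every candidate occupancy structure.  Candidate sets
    default to all combinations of the available covariates.  Classification
    downstream uses the single lowest-AICc stage-2 model.
    """
    if p_covariate_sets is None:
        avail = [c for c in p_covariates
                 if c in history.site_covariates.columns or c in history.occasion_covariates]
        p_covariate_sets = _powerset(avail)
    if psi_covariate_sets is None:
        avail = [c for c in psi_covariates if c in history.site_covariates.columns]
        psi_covariate_sets = _powerset(avail)

    stage1, _ = _selection_table(
        history, [((), tuple(pf)) for pf in p_covariate_sets], restarts, seed
    )
    best_p = stage1["p_formula"].iloc[0]
    stage2, fits2 = _selection_table(
        history, [(tuple(sf), best_p) for sf in psi_covariate_sets], restarts, seed + 1000
    )
    return ModelSelectionResult(
        stage1_table=stage1, stage2_table=stage2, best_fit=fits2[stage2["model"].iloc[0]]
    )


# ---------------------------------------------------------------------------
# goodness of fit


def _history_chisq(fit: OccupancyFit, y: np.ndarray, min_expected: float = 0.5) -> float:
    """Chi-square over detection-history frequencies, cohorted by covariate
    profile (identical psi_i, p_i rows and missingness pattern); expected
    cells below ``min_expected`` are pooled within cohort."""
    obs_mask = ~np.isnan(y)
    y0 = np.nan_to_num(y).astype(int)
    psi, p = fit.site_psi, fit.site_p

    profile = [
        (round(psi[i], 12),) + tuple(np.round(p[i][obs_mask[i]], 12)) + tuple(obs_mask[i])
        for i in range(len(y))
    ]
    codes, _ = pd.factorize(pd.Series(profile))
    chisq = 0.0
    for c in np.unique(codes):
        idx = np.where(codes == c)[0]
        i0 = idx[0]
        m = obs_mask[i0]
        pj = p[i0][m]
        psi_i = psi[i0]
        hists = [tuple(y0[i][m]) for i in idx]
        uniq = sorted(set(hists))
        o = np.array([hists.count(h) for h in uniq], dtype=float)
        e = np.empty(len(uniq))
        for k, h in enumerate(uniq):
            hv = np.array(h, dtype=float)
            p_det = np.prod(pj**hv * (1 - pj) ** (1 - hv))
            prob = psi_i * p_det + (0.0 if hv.any() else (1.0 - psi_i))
            e[k] = len(idx) * prob
        # unobserved histories enter as a single pooled zero-count cell
        e_miss = max(len(idx) - e.sum(), 0.0)
        o = np.append(o, 0.0)
        e = np.append(e, e_miss)
        # pool small expected cells (ascending) into the last cell
        order = np.argsort(e)
        o, e = o[order], e[order]
        while len(e) > 1 and e[0] < min_expected:
            e[1] += e[0]
            o[1] += o[0]
            o, e = o[1:], e[1:]
        ok = e > 0
        chisq += float((((o - e) ** 2) / np.where(ok, e, 1.0))[ok].sum())
    return chisq


def simulate_from_fit(fit: OccupancyFit, rng: np.random.Generator) -> np.ndarray:
    """Parametric simulation of a detection-history matrix from a fit,
    preserving the observed missingness pattern."""
    y = fit.history.y
    z = rng.random(fit.n_sites) < fit.site_psi
    det = (rng.random(y.shape) < fit.site_p) & z[:, None]
    sim = det.astype(float)
    sim[np.isnan(y)] = np.nan
    return sim


def goodness_of_fit(
    fit: OccupancyFit,
    n_boot: int = 1000,
    seed: int = 0,
    restarts: int = 2,
    max_failure_fraction: float = 0.10,
) -> GOFResult:
    """Parametric-bootstrap chi-square goodness of fit and the c-hat statistic.

    Simulates ``n_boot`` datasets from the fitted model, refits the same
    structure to each and recomputes the chi-square; the p-value is the
    proportion of bootstrap statistics >= the observed one and
    c-hat = chisq_obs / mean(bootstrap chisq).
    """
    rng = np.random.default_rng(seed)
    chisq_obs = _history_chisq(fit, fit.history.y)
    boot = []
    n_failed = 0
    for b in range(n_boot):
        sim_y = simulate_from_fit(fit, rng)
        sim_hist = DetectionHistorySet(
            y=sim_y,
            site_covariates=fit.history.site_covariates,
            cell_key=fit.history.cell_key,
            site_ids=fit.history.site_ids,
            occasion_covariates=fit.history.occasion_covariates,
        )
        try:
            refit = fit_occupancy(
                sim_hist, fit.psi_formula, fit.p_formula,
                restarts=restarts, seed=int(rng.integers(2**31 - 1)),
            )
            boot.append(_history_chisq(refit, sim_y))
        except (FitError, FloatingPointError):
            n_failed += 1
    if n_boot and n_failed / n_boot > max_failure_fraction:
        raise FitError(f"{n_failed}/{n_boot} bootstrap refits failed")
    boot = np.asarray(boot)
    p = float((boot >= chisq_obs).mean()) if len(boot) else np.nan
    c_hat = float(chisq_obs / boot.mean()) if len(boot) and boot.mean() > 0 else np.nan
    return GOFResult(chisq_obs=chisq_obs, boot_chisq=boot, p_value=p, c_hat=c_hat, n_failed=n_failed)


def conditional_occupancy(fit: OccupancyFit) -> np.ndarray:
    """Posterior (latent) probability each site is used, given its history.

    Sites with a detection have probability exactly 1; an all-zero site has
    psi*q / (psi*q + 1 - psi) with q the probability of detecting nothing
    across its observed occasions.
    """
    y = fit.history.y
    obs = ~np.isnan(y)
    log_q = np.where(obs, np.log1p(-np.clip(fit.site_p, 0.0, 1.0 - 1e-15)), 0.0).sum(axis=1)
    q = np.exp(log_q)
    psi = fit.site_psi
    cond = psi * q / (psi * q + (1.0 - psi))
    cond[fit.history.detected] = 1.0
    return cond


def classify_zones(
    fit: OccupancyFit,
    threshold_rule: str = "mean",
    fixed_value: float | None = None,
    cell_key: np.ndarray | None = None,
) -> ZoneAssignment:
    """Classify grid cells into low/high human-use zones.

    Conditional occupancy is averaged across each cell's site-years; the
    threshold is the mean of those per-cell values (rule="mean") or a fixed
    value (rule="fixed").  A cell is 'high' iff its value is strictly greater
    than the threshold (ties are 'low').
    """
    cond = conditional_occupancy(fit)
    cells = np.asarray(cell_key if cell_key is not None else fit.history.cell_key)
    per_cell = pd.Series(cond).groupby(pd.Series(cells)).mean()
    if threshold_rule == "mean":
        threshold = float(per_cell.mean())
    elif threshold_rule == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold rule requires fixed_value")
        threshold = float(fixed_value)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    table = pd.DataFrame({
        "mean_conditional_psi": per_cell,
        "zone": np.where(per_cell > threshold, "high", "low"),
    })
    table.index.name = "cell_id"
    return ZoneAssignment(table=table, threshold=threshold)
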
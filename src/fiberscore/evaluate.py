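"""Survival evaluation: horizon ROC, risk stratification, Cox hazard
ratios, time-dependent AUC, concordance, nomogram and calibration.

The horizon ROC uses the cumulative/dynamic definition: at horizon t,
cases are patients with an observed event by t, controls are patients
still at risk beyond t, and censoring before t is handled with inverse
probability of censoring weights (IPCW) from the Kaplan-Meier estimate of
the censoring distribution. The optimal cutoff maximizes the Youden index
(sensitivity + specificity - 1) and is meant to be frozen on the training
cohort before being applied elsewhere. The integrated AUC (iAUC) weights
the time-dependent AUC curve by the estimated event-time density over the
grid (Riemann sum). No multiple-testing correction is applied anywhere;
reported p-values are raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex


class EvaluationError(ValueError):
    """Raised when a metric is undefined for the given data."""


# --------------------------------------------------------------------------
# IPCW machinery
# --------------------------------------------------------------------------

def censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate G(t) of the censoring distribution."""
    km = KaplanMeierFitter()
    km.fit(np.asarray(time, float), 1 - np.asarray(event, int))
    return km


def _G_at(km: KaplanMeierFitter, t: np.ndarray, left: bool = False) -> np.ndarray:
    t = np.asarray(t, float)
    if left:
        t = np.maximum(t - 1e-9, 0.0)
    return km.survival_function_at_times(t).to_numpy(float)


def _ipcw_case_control(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float,
    km: KaplanMeierFitter | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(case scores, case weights, control scores, control weights) at horizon."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if km is None:
        km = censoring_survival(time, event)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any() or not controls.any():
        raise EvaluationError(f"no cases or no controls at horizon {horizon}")
    g_cases = _G_at(km, time[cases], left=True)
    g_ctrl = float(_G_at(km, np.array([horizon]))[0])
    g_cases = np.clip(g_cases, 1e-8, None)
    g_ctrl = max(g_ctrl, 1e-8)
    w_cases = 1.0 / g_cases
    w_ctrl = np.full(controls.sum(), 1.0 / g_ctrl)
    return scores[cases], w_cases, scores[controls], w_ctrl


def _weighted_auc(sc: np.ndarray, wc: np.ndarray, sn: np.ndarray, wn: np.ndarray) -> float:
    """P(case score > control score) with ties counted half, weighted."""
    order = np.argsort(sn, kind="stable")
    sn, wn = sn[order], wn[order]
    cum = np.concatenate([[0.0], np.cumsum(wn)])
    total_n = cum[-1]
    below = cum[np.searchsorted(sn, sc, side="left")]
    upto = cum[np.searchsorted(sn, sc, side="right")]
    ties = upto - below
    numer = float(np.sum(wc * (below + 0.5 * ties)))
    return numer / (float(np.sum(wc)) * total_n)


# --------------------------------------------------------------------------
# horizon ROC with Youden cutoff
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    horizon_months: float


def _youden_cutoff(
    sc: np.ndarray, wc: np.ndarray, sn: np.ndarray, wn: np.ndarray
) -> tuple[float, float, float, float]:
    """Cutoff maximizing sensitivity + specificity - 1; ties -> lower cutoff.

    A patient is called high-risk when score >= cutoff.
    """
    thresholds = np.unique(np.concatenate([sc, sn]))
    total_c, total_n = float(np.sum(wc)), float(np.sum(wn))
    best = (-np.inf, np.inf, 0.0, 0.0)  # (youden, cutoff, sens, spec)
    for c in thresholds:
        sens = float(np.sum(wc[sc >= c])) / total_c
        spec = float(np.sum(wn[sn < c])) / total_n
        youden = sens + spec - 1.0
        if youden > best[0] + 1e-12 or (abs(youden - best[0]) <= 1e-12 and c < best[1]):
            best = (youden, float(c), sens, spec)
    _, cutoff, sens, spec = best
    acc = (float(np.sum(wc[sc >= cutoff])) + float(np.sum(wn[sn < cutoff]))) / (total_c + total_n)
    return cutoff, sens, spec, acc


def roc_at_horizon(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 60.0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> RocResult:
    """Cumulative/dynamic IPCW ROC at a fixed horizon with bootstrap CI."""
    sc, wc, sn, wn = _ipcw_case_control(scores, time, event, horizon)
    auc = _weighted_auc(sc, wc, sn, wn)
    cutoff, sens, spec, acc = _youden_cutoff(sc, wc, sn, wn)

    lo = hi = auc
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = len(scores)
        reps = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            try:
                b = _ipcw_case_control(np.asarray(scores)[idx], np.asarray(time)[idx],
                                       np.asarray(event)[idx], horizon)
                reps.append(_weighted_auc(*b))
            except EvaluationError:
                continue
        if reps:
            lo, hi = np.percentile(reps, [2.5, 97.5])
            lo, hi = min(float(lo), auc), max(float(hi), auc)
    return RocResult(auc=float(auc), ci_lower=float(lo), ci_upper=float(hi),
                     cutoff=cutoff, sensitivity=sens, specificity=spec,
                     accuracy=acc, horizon_months=float(horizon))


# --------------------------------------------------------------------------
# KM stratification and log-rank
# --------------------------------------------------------------------------

@dataclass
class StratificationResult:
    km_low: pd.DataFrame        # columns: time, survival, ci_lower, ci_upper
    km_high: pd.DataFrame
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_lower: float
    hr_ci_upper: float
    n_low: int
    n_high: int


def _km_table(time: np.ndarray, event: np.ndarray, label: str) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event, label=label)
    ci = km.confidence_interval_survival_function_
    return pd.DataFrame({
        "time": km.survival_function_.index.to_numpy(float),
        "survival": km.survival_function_[label].to_numpy(float),
        "ci_lower": ci.iloc[:, 0].to_numpy(float),
        "ci_upper": ci.iloc[:, 1].to_numpy(float),
    })


def stratify_and_km(
    scores: np.ndarray, cutoff: float, time: np.ndarray, event: np.ndarray
) -> StratificationResult:
    """Split at a (training-derived) cutoff; KM curves, log-rank, group HR.

    High risk is score >= cutoff. Greenwood confidence bands come with the
    product-limit estimates.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    high = scores >= cutoff
    if high.all() or (~high).all():
        raise EvaluationError("cutoff assigns every patient to one group")
    if event.sum() == 0:
        raise EvaluationError("no events in either group; log-rank undefined")
    lr = logrank_test(time[~high], time[high], event[~high], event[high])
    data = pd.DataFrame({"high": high.astype(float), "dfs_months": time, "event": event})
    cph = CoxPHFitter()
    cph.fit(data, duration_col="dfs_months", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    lo, hi = float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1]))
    return StratificationResult(
        km_low=_km_table(time[~high], event[~high], "low"),
        km_high=_km_table(time[high], event[high], "high"),
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr, hr_ci_lower=lo, hr_ci_upper=hi,
        n_low=int((~high).sum()), n_high=int(high.sum()),
    )


# --------------------------------------------------------------------------
# Cox regression reporting
# --------------------------------------------------------------------------

@dataclass
class HazardResult:
    covariate: str
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float      # likelihood-ratio test
    n_events: int
    adjusted_for: tuple[str, ...] = ()


def cox_regression(
    df: pd.DataFrame,
    covariates: tuple[str, ...],
    time_col: str = "dfs_months",
    event_col: str = "event",
    mode: str = "univariate",
) -> list[HazardResult]:
    """Cox hazard ratios with Wald CIs and likelihood-ratio p-values.

    ``univariate`` fits each covariate alone; ``multivariate`` fits all
    jointly, and each covariate's p-value compares the full model with the
    model dropping that covariate.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    n_events = int(df[event_col].sum())
    if mode == "multivariate" and n_events < 5 * len(covariates):
        warnings.warn(f"{n_events} events for {len(covariates)} covariates "
                      "(< 5 events per covariate)")
    sub = df[list(covariates)].astype(float)
    if np.linalg.matrix_rank(np.c_[np.ones(len(sub)), sub.to_numpy()]) <= len(covariates):
        raise EvaluationError("collinear covariates in Cox regression")

    def _fit(cols: list[str]) -> CoxPHFitter:
        data = df[cols + [time_col, event_col]].copy()
        data[cols] = data[cols].astype(float)
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except Exception as exc:
            raise EvaluationError(f"Cox fit failed for {cols}: {exc}") from exc
        return cph

    results = []
    if mode == "univariate":
        for cov in covariates:
            cph = _fit([cov])
            null_ll = _fit_null_loglik(df, time_col, event_col)
            lr = 2.0 * (cph.log_likelihood_ - null_ll)
            from scipy.stats import chi2
            p = float(chi2.sf(max(lr, 0.0), 1))
            ci = cph.confidence_intervals_
            results.append(HazardResult(
                covariate=cov, hr=float(np.exp(cph.params_[cov])),
                ci_lower=float(np.exp(ci.loc[cov].iloc[0])),
                ci_upper=float(np.exp(ci.loc[cov].iloc[1])),
                p_value=p, n_events=n_events))
    else:
        full = _fit(list(covariates))
        from scipy.stats import chi2
        for cov in covariates:
            rest = [c for c in covariates if c != cov]
            ll_reduced = (_fit(rest).log_likelihood_ if rest
                          else _fit_null_loglik(df, time_col, event_col))
            lr = 2.0 * (full.log_likelihood_ - ll_reduced)
            p = float(chi2.sf(max(lr, 0.0), 1))
            ci = full.confidence_intervals_
            results.append(HazardResult(
                covariate=cov, hr=float(np.exp(full.params_[cov])),
                ci_lower=float(np.exp(ci.loc[cov].iloc[0])),
                ci_upper=float(np.exp(ci.loc[cov].iloc[1])),
                p_value=p, n_events=n_events,
                adjusted_for=tuple(rest)))
    return results


def _fit_null_loglik(df: pd.DataFrame, time_col: str, event_col: str) -> float:
    from .scoring import efron_partial_loglik
    return efron_partial_loglik(np.zeros(len(df)), df[time_col].to_numpy(float),
                                df[event_col].to_numpy(int))


# --------------------------------------------------------------------------
# time-dependent AUC and iAUC
# --------------------------------------------------------------------------

def time_dependent_auc(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray, time_grid: np.ndarray
) -> tuple[np.ndarray, float]:
    """Cumulative/dynamic AUC(t) on a grid and the event-density-weighted iAUC.

    iAUC weights are the Kaplan-Meier increments of the event-time
    distribution over the grid intervals, normalized to sum to one.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    grid = np.asarray(time_grid, float)
    if grid.min() <= 0 or grid.max() >= time.max():
        raise EvaluationError("time grid must lie within the observed follow-up range")
    km_c = censoring_survival(time, event)
    aucs = np.empty(len(grid))
    for k, t in enumerate(grid):
        sc, wc, sn, wn = _ipcw_case_control(scores, time, event, t, km=km_c)
        aucs[k] = _weighted_auc(sc, wc, sn, wn)
    km_e = KaplanMeierFitter().fit(time, event)
    F = 1.0 - km_e.survival_function_at_times(grid).to_numpy(float)
    dF = np.diff(np.concatenate([[0.0], F]))
    if dF.sum() <= 0:
        raise EvaluationError("no event mass on the time grid")
    w = dF / dF.sum()
    return aucs, float(np.sum(aucs * w))


# --------------------------------------------------------------------------
# concordance
# --------------------------------------------------------------------------

def concordance_index(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Harrell's C with a percentile bootstrap CI.

    Usable pairs are (i, j) with t_i < t_j and event_i = 1; score ties
    count one half. Higher scores must indicate higher risk.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    scores = np.asarray(scores, float)
    if event.sum() == 0:
        raise EvaluationError("no comparable pairs (no events)")
    c = float(_lifelines_cindex(time, -scores, event))
    lo = hi = c
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, len(time), len(time))
            if event[idx].sum() == 0:
                continue
            reps.append(float(_lifelines_cindex(time[idx], -scores[idx], event[idx])))
        if reps:
            lo, hi = np.percentile(reps, [2.5, 97.5])
            lo, hi = min(float(lo), c), max(float(hi), c)
    return c, lo, hi


# --------------------------------------------------------------------------
# nomogram, calibration, score-to-survival curves
# --------------------------------------------------------------------------

@dataclass
class NomogramSpec:
    covariates: tuple[str, ...]
    point_maps: dict[str, pd.DataFrame]   # per covariate: value -> points (0..100 max)
    total_points_map: pd.DataFrame        # total points -> S(t) at each horizon
    horizons: tuple[float, ...]
    c_index: float
    c_index_ci: tuple[float, float]


@dataclass
class CalibrationReport:
    horizon: float
    bins: pd.DataFrame   # predicted mean, observed KM, ci per risk-quantile bin
    mean_abs_error: float


def build_nomogram(
    df: pd.DataFrame,
    covariates: tuple[str, ...],
    time_col: str = "dfs_months",
    event_col: str = "event",
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0),
    n_bins: int = 4,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> tuple[NomogramSpec, CalibrationReport]:
    """Nomogram point mappings plus a calibration report at the last horizon.

    Points per covariate are proportional to |beta x range| rescaled so the
    widest covariate spans 100; survival maps use the Breslow baseline of
    the fitted Cox model. Calibration compares predicted survival with the
    KM-observed survival in predicted-risk quantile bins.
    """
    time = df[time_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    if max(horizons) >= time[event == 1].max():
        raise EvaluationError("horizon beyond the last observed event time")
    data = df[list(covariates)].astype(float).copy()
    data[time_col] = time
    data[event_col] = event
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    cph.fit(data, duration_col=time_col, event_col=event_col)
    beta = cph.params_.reindex(list(covariates)).to_numpy(float)

    ranges = {c: (float(df[c].min()), float(df[c].max())) for c in covariates}
    spans = np.array([abs(b) * (ranges[c][1] - ranges[c][0])
                      for b, c in zip(beta, covariates)])
    if spans.max() <= 0:
        raise EvaluationError("all covariates have zero prognostic span")
    scale = 100.0 / spans.max()

    point_maps = {}
    for b, c in zip(beta, covariates):
        lo, hi = ranges[c]
        grid = np.unique(df[c].to_numpy(float)) if df[c].nunique() <= 12 else \
            np.linspace(lo, hi, 25)
        # points grow with risk: anchor at the low-risk end of the covariate
        anchor = lo if b >= 0 else hi
        pts = np.abs(b) * np.abs(grid - anchor) * scale
        point_maps[c] = pd.DataFrame({"value": grid, "points": pts})

    # total points -> survival: linear predictor eta = total/scale + eta_min
    eta = (df[list(covariates)].to_numpy(float) @ beta)
    eta_min = float(np.sum([min(b * ranges[c][0], b * ranges[c][1])
                            for b, c in zip(beta, covariates)]))
    baseline = cph.baseline_survival_
    total_grid = np.linspace(0.0, spans.sum() * scale, 41)
    rows = {"total_points": total_grid}
    centered_shift = float(np.mean(eta))  # lifelines baseline is at covariate means
    for h in horizons:
        s0 = float(baseline.iloc[(baseline.index <= h).sum() - 1, 0]) \
            if (baseline.index <= h).any() else 1.0
        etas = total_grid / scale + eta_min
        rows[f"survival_{int(h)}m"] = s0 ** np.exp(etas - centered_shift)
    total_map = pd.DataFrame(rows)

    c, lo_c, hi_c = concordance_index(eta, time, event,
                                      bootstrap_reps=bootstrap_reps, seed=seed)
    spec = NomogramSpec(
        covariates=tuple(covariates), point_maps=point_maps,
        total_points_map=total_map, horizons=tuple(horizons),
        c_index=c, c_index_ci=(lo_c, hi_c),
    )

    h = max(horizons)
    pred = _predict_survival(cph, df[list(covariates)].astype(float), h)
    order = np.argsort(-pred)  # high risk first
    bins_idx = np.array_split(order, n_bins)
    rng = np.random.default_rng(seed)
    rows_cal = []
    for bi, idx in enumerate(bins_idx):
        km = KaplanMeierFitter().fit(time[idx], event[idx])
        obs = float(km.survival_function_at_times([h]).iloc[0])
        boots = []
        for _ in range(bootstrap_reps):
            bs = rng.choice(idx, len(idx), replace=True)
            kmb = KaplanMeierFitter().fit(time[bs], event[bs])
            boots.append(float(kmb.survival_function_at_times([h]).iloc[0]))
        lo_o, hi_o = (np.percentile(boots, [2.5, 97.5]) if boots else (obs, obs))
        rows_cal.append({"bin": bi, "n": len(idx),
                         "predicted": float(np.mean(pred[idx])),
                         "observed": obs,
                         "observed_ci_lower": float(lo_o),
                         "observed_ci_upper": float(hi_o)})
    cal = pd.DataFrame(rows_cal)
    report = CalibrationReport(
        horizon=h, bins=cal,
        mean_abs_error=float(np.mean(np.abs(cal["predicted"] - cal["observed"]))),
    )
    return spec, report


def _predict_survival(cph: CoxPHFitter, X: pd.DataFrame, horizon: float) -> np.ndarray:
    sf = cph.predict_survival_function(X, times=[horizon])
    return sf.iloc[0].to_numpy(float)


def score_to_dfs_curve(
    score_grid: np.ndarray,
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 60.0,
) -> pd.DataFrame:
    """Predicted S(horizon | score) over a score grid from a univariate Cox fit.

    S(h | s) = S0(h)^exp(beta s); strictly decreasing in the score when the
    fitted beta is positive.
    """
    data = pd.DataFrame({"score": np.asarray(scores, float),
                         "dfs_months": np.asarray(time, float),
                         "event": np.asarray(event, int)})
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    cph.fit(data, duration_col="dfs_months", event_col="event")
    sf = cph.predict_survival_function(pd.DataFrame({"score": np.asarray(score_grid, float)}),
                                       times=[horizon])
    return pd.DataFrame({"score": np.asarray(score_grid, float),
                         "dfs_probability": sf.iloc[0].to_numpy(float)})


# --------------------------------------------------------------------------
# subgroup driver
# --------------------------------------------------------------------------

def subgroup_report(
    df: pd.DataFrame,
    group_vars: tuple[str, ...],
    score_cols: tuple[str, ...],
    cutoffs: dict[str, float],
    horizon: float = 60.0,
    time_col: str = "dfs_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-subgroup hazard ratio and horizon AUC for each score, long format.

    ``cutoffs`` maps score column -> training-cohort Youden cutoff. Empty
    subgroups or subgroups without events are skipped with a warning.
    """
    rows = []
    for var in group_vars:
        for level in pd.unique(df[var]):
            sub = df[df[var] == level]
            if len(sub) == 0 or sub[event_col].sum() == 0:
                warnings.warn(f"subgroup {var}={level}: no patients or no events; skipped")
                continue
            t = sub[time_col].to_numpy(float)
            e = sub[event_col].to_numpy(int)
            for score in score_cols:
                s = sub[score].to_numpy(float)
                try:
                    auc = roc_at_horizon(s, t, e, horizon=horizon, bootstrap_reps=0).auc
                except EvaluationError:
                    auc = np.nan
                try:
                    strat = stratify_and_km(s, cutoffs[score], t, e)
                    hr = strat.hazard_ratio
                except EvaluationError:
                    hr = np.nan
                rows.append({"group_var": var, "level": level, "score": score,
                             "n": len(sub), "n_events": int(e.sum()),
                             "hr": hr, "auc": auc})
    return pd.DataFrame(rows)
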
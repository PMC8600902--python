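"""Prognostic score construction.

Four model kinds, all linear in their inputs:

* ``tcmf`` — L1-penalized (LASSO) Cox partial-likelihood regression over
  the standardized 142-feature matrix; the penalty is chosen by k-fold
  cross-validated partial likelihood (Verweij-van Houwelingen criterion),
  by default with the one-standard-error rule. The score is the linear
  combination of the selected features weighted by their coefficients.
* ``tacs`` — L2-penalized (ridge) Cox regression over the eight binary
  collagen-architecture indicators; all eight coefficients are retained,
  the penalty chosen by cross-validated partial likelihood.
* ``cli`` — unpenalized Cox regression over indicator contrasts of the
  clinical covariates (reference level = first listed level of each).
* ``combined`` — the relative weight of each component score is its
  coefficient in a multivariate Cox fit over the component scores; the
  combined score is the weighted sum.

Ties are handled with the Efron approximation throughout. Fitting is
deterministic given the data and seed (cross-validation folds are seeded
and stratified by the event indicator).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .cohort import CLINICAL_LEVELS, TACS_COLUMNS
from .pipeline import NormalizationParams

log = logging.getLogger("fiberscore")

MODEL_FORMAT_VERSION = 1


class FitError(RuntimeError):
    """Raised on non-convergence or separation during model fitting."""


@dataclass
class ScoreModel:
    """A fitted linear risk score.

    ``score(x) = sum_i beta_i x_i`` over the selected feature columns; for
    combined models the inputs are the named component score columns and
    the coefficients are the Cox-derived relative weights.
    """

    kind: str  # tcmf | tacs | cli | combined
    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    normalization: NormalizationParams | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per selected feature required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.kind not in ("tcmf", "tacs", "cli", "combined"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def is_empty(self) -> bool:
        return len(self.feature_names) == 0

    def score(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor for each row; 0 for an empty model.

        Clinical models accept either pre-encoded contrast columns or a raw
        cohort table with the categorical covariates.
        """
        if self.is_empty:
            return np.zeros(len(df))
        if self.kind == "cli" and any(n not in df.columns for n in self.feature_names):
            df = encode_clinical(df)
        X = df[list(self.feature_names)].to_numpy(float)
        return X @ self.coefficients


def write_score_model(model: ScoreModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "feature_names": list(model.feature_names),
        "coefficients": [float(c) for c in model.coefficients],
        "normalization": model.normalization.to_dict() if model.normalization else None,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_score_model(path: str | Path) -> ScoreModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    norm = payload.get("normalization")
    return ScoreModel(
        kind=payload["kind"],
        feature_names=tuple(payload["feature_names"]),
        coefficients=np.asarray(payload["coefficients"], float),
        normalization=NormalizationParams.from_dict(norm) if norm else None,
        metadata=payload.get("metadata", {}),
    )


# --------------------------------------------------------------------------
# Efron partial log-likelihood (used for cross-validation scoring)
# --------------------------------------------------------------------------

def efron_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with the Efron tie correction."""
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, e, h = time[order], event[order], eta[order]
    exp_h = np.exp(h)
    # risk-set sums via suffix cumulative sums over ascending times
    suffix = np.concatenate([np.cumsum(exp_h[::-1])[::-1], [0.0]])
    ll = 0.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        death_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(death_idx)
        if d > 0:
            risk_sum = suffix[i]
            tie_sum = float(np.sum(exp_h[death_idx]))
            ll += float(np.sum(h[death_idx]))
            for ell in range(d):
                ll -= np.log(risk_sum - (ell / d) * tie_sum)
        i = j
    return float(ll)


def _cv_partial_loglik(
    fit_at_alphas, X: np.ndarray, time: np.ndarray, event: np.ndarray,
    alphas: np.ndarray, folds: int, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Verweij-van Houwelingen cross-validated partial likelihood per alpha.

    `fit_at_alphas(X, y, alphas)` must return a coefficient matrix of shape
    (n_features, n_alphas). The CV contribution of a fold is
    ll(beta; all data) - ll(beta; training part).
    """
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    contribs = np.zeros((folds, len(alphas)))
    for f, (tr, _te) in enumerate(skf.split(X, event)):
        coefs = fit_at_alphas(X[tr], y[tr], alphas)  # (p, n_alphas)
        for a in range(len(alphas)):
            beta = coefs[:, a]
            ll_all = efron_partial_loglik(X @ beta, time, event)
            ll_tr = efron_partial_loglik(X[tr] @ beta, time[tr], event[tr])
            contribs[f, a] = ll_all - ll_tr
    mean = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(folds)
    return mean, se


# --------------------------------------------------------------------------
# LASSO-Cox
# --------------------------------------------------------------------------

def fit_lasso_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cv_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    lambda_rule: str = "1se",
    seed: int = 0,
    normalization: NormalizationParams | None = None,
) -> ScoreModel:
    """Feature selection and weighting by L1-penalized Cox regression.

    ``X`` must already be standardized (the fitter does not rescale).
    Returns a model holding the nonzero-coefficient features; an empty
    model (with a warning) if the chosen penalty zeroes everything.
    """
    if lambda_rule not in ("1se", "min"):
        raise ValueError("lambda_rule must be '1se' or 'min'")
    if int(np.sum(event)) < 2:
        raise FitError("need at least two observed events to fit")
    Xv = X.to_numpy(float)
    if np.isnan(Xv).any():
        raise FitError("missing values in the feature matrix")
    y = Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=60, alpha_min_ratio=0.01,
                                  normalize=False, fit_baseline_model=False)
    try:
        path.fit(Xv, y)
    except Exception as exc:  # pragma: no cover - surfaced as FitError
        raise FitError(f"LASSO-Cox path fit failed: {exc}") from exc
    alphas = np.asarray(path.alphas_) if lambda_grid is None else np.asarray(lambda_grid, float)

    def fit_at(Xtr, ytr, alphas_):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas_, normalize=False,
                                   fit_baseline_model=False)
        m.fit(Xtr, ytr)
        # coxnet may drop leading alphas it considers redundant; align by value
        coefs = np.zeros((Xtr.shape[1], len(alphas_)))
        fitted = {round(float(a), 12): i for i, a in enumerate(m.alphas_)}
        for i, a in enumerate(alphas_):
            j = fitted.get(round(float(a), 12))
            if j is not None:
                coefs[:, i] = m.coef_[:, j]
            elif fitted:
                # nearest fitted alpha as fallback
                jj = int(np.argmin(np.abs(np.asarray(m.alphas_) - a)))
                coefs[:, i] = m.coef_[:, jj]
        return coefs

    mean_cvpl, se_cvpl = _cv_partial_loglik(fit_at, Xv, np.asarray(time, float),
                                            np.asarray(event, int), alphas, cv_folds, seed)
    best = int(np.argmax(mean_cvpl))
    if lambda_rule == "min":
        chosen = best
    else:
        threshold = mean_cvpl[best] - se_cvpl[best]
        # alphas descend; the 1-SE rule takes the largest (sparsest) penalty
        # whose CV likelihood is within one SE of the optimum
        ok = np.nonzero(mean_cvpl >= threshold)[0]
        chosen = int(ok[0]) if len(ok) else best

    full = fit_at(Xv, y, alphas)
    beta = full[:, chosen]
    nonzero = np.nonzero(beta)[0]
    if len(nonzero) == 0:
        warnings.warn("LASSO-Cox selected no features at the chosen penalty")
    model = ScoreModel(
        kind="tcmf",
        feature_names=tuple(X.columns[i] for i in nonzero),
        coefficients=beta[nonzero],
        normalization=normalization,
        metadata={
            "lambda": float(alphas[chosen]),
            "lambda_rule": lambda_rule,
            "cv_folds": cv_folds,
            "seed": seed,
            "n_candidates": int(X.shape[1]),
        },
    )
    log.info("LASSO-Cox: %d/%d features at lambda=%.5g (%s rule)",
             len(nonzero), X.shape[1], alphas[chosen], lambda_rule)
    return model


def lasso_path_n_selected(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(alphas, number of nonzero coefficients) along the regularization path."""
    y = Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))
    m = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=60, alpha_min_ratio=0.01,
                               normalize=False, fit_baseline_model=False)
    m.fit(X.to_numpy(float), y)
    return np.asarray(m.alphas_), (np.abs(m.coef_) > 0).sum(axis=0)


# --------------------------------------------------------------------------
# ridge-Cox over the eight architecture indicators
# --------------------------------------------------------------------------

def fit_ridge_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    penalty: float | None = None,
    penalty_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> ScoreModel:
    """L2-penalized Cox fit retaining all input columns.

    With ``penalty=None`` the ridge strength is chosen by cross-validated
    partial likelihood over a log-spaced grid. Constant columns are flagged
    (their coefficients are defined but shrunk to zero by the penalty).
    """
    Xv = X.to_numpy(float)
    for c in X.columns:
        if X[c].nunique() <= 1:
            warnings.warn(f"constant indicator column {c!r}")
    tv = np.asarray(time, float)
    ev = np.asarray(event, int)
    y = Surv.from_arrays(event=ev.astype(bool), time=tv)

    if penalty is None:
        grid = (np.logspace(-2, 3, 11) if penalty_grid is None
                else np.asarray(penalty_grid, float))

        def fit_at(Xtr, ytr, alphas_):
            coefs = np.zeros((Xtr.shape[1], len(alphas_)))
            for i, a in enumerate(alphas_):
                m = CoxPHSurvivalAnalysis(alpha=float(a), ties="efron")
                m.fit(Xtr, ytr)
                coefs[:, i] = m.coef_
            return coefs

        mean_cvpl, _ = _cv_partial_loglik(fit_at, Xv, tv, ev, grid, cv_folds, seed)
        penalty = float(grid[int(np.argmax(mean_cvpl))])

    m = CoxPHSurvivalAnalysis(alpha=float(penalty), ties="efron")
    try:
        m.fit(Xv, y)
    except Exception as exc:
        raise FitError(f"ridge-Cox fit failed: {exc}") from exc
    return ScoreModel(
        kind="tacs",
        feature_names=tuple(X.columns),
        coefficients=np.asarray(m.coef_, float),
        metadata={"penalty": float(penalty), "cv_folds": cv_folds, "seed": seed},
    )


def fit_tacs_score(table_df: pd.DataFrame, time, event, **kwargs) -> ScoreModel:
    """Ridge-Cox over the tacs_1..tacs_8 indicator columns of a cohort table."""
    return fit_ridge_cox(table_df[list(TACS_COLUMNS)], time, event, **kwargs)


# --------------------------------------------------------------------------
# clinical Cox model
# --------------------------------------------------------------------------

def encode_clinical(df: pd.DataFrame, columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Indicator contrasts for the categorical clinical covariates.

    The reference level of each covariate is the first level listed in the
    schema (e.g. age <=50, luminal A, T<=2cm, N0, stage I, G1, therapy no);
    indicator columns are named ``column:level``.
    """
    columns = columns or tuple(c for c in CLINICAL_LEVELS if c in df.columns)
    out = {}
    for col in columns:
        levels = CLINICAL_LEVELS[col]
        observed = set(df[col].astype(str))
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)} in clinical column {col!r}")
        for level in levels[1:]:
            out[f"{col}:{level}"] = (df[col].astype(str) == level).astype(float)
    return pd.DataFrame(out, index=df.index)


#: Clinical inputs of the prognostic clinical model.
CLI_MODEL_COLUMNS = (
    "age_group", "subtype", "tumor_size", "nodal_status",
    "grade", "stage", "chemotherapy", "radiation_therapy",
)


def fit_cli_cox(
    df: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    columns: tuple[str, ...] = CLI_MODEL_COLUMNS,
) -> ScoreModel:
    """Unpenalized Cox regression over encoded clinical risk factors."""
    X = encode_clinical(df, tuple(c for c in columns if c in df.columns))
    X = X.loc[:, X.nunique() > 1]  # drop unobserved contrasts
    if X.shape[1] == 0:
        warnings.warn("no varying clinical contrasts; clinical score is constant 0")
        return ScoreModel(kind="cli", feature_names=(), coefficients=np.array([]))
    data = X.copy()
    data["dfs_months"] = np.asarray(time, float)
    data["event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="dfs_months", event_col="event")
    except Exception as exc:
        raise FitError(f"clinical Cox fit failed (separation/non-convergence?): {exc}") from exc
    beta = cph.params_.reindex(X.columns).to_numpy(float)
    return ScoreModel(
        kind="cli",
        feature_names=tuple(X.columns),
        coefficients=beta,
        metadata={"columns": list(columns)},
    )


# --------------------------------------------------------------------------
# score combination
# --------------------------------------------------------------------------

def combine_scores(
    df: pd.DataFrame,
    component_cols: tuple[str, ...],
    time: np.ndarray,
    event: np.ndarray,
) -> ScoreModel:
    """Cox-derived relative weights of component scores.

    The weights are the coefficients of a multivariate Cox fit over the
    component score columns; the combined score is their weighted sum.
    """
    X = df[list(component_cols)].astype(float)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[-1] <= 0 or sv[0] / max(sv[-1], 1e-300) > 1e6:
        warnings.warn("component scores are (nearly) collinear; weights are unstable")
    data = X.copy()
    data["dfs_months"] = np.asarray(time, float)
    data["event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="dfs_months", event_col="event")
    except Exception as exc:
        raise FitError(f"combination Cox fit failed: {exc}") from exc
    weights = cph.params_.reindex(list(component_cols)).to_numpy(float)
    return ScoreModel(
        kind="combined",
        feature_names=tuple(component_cols),
        coefficients=weights,
        metadata={"components": list(component_cols)},
    )
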
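"""Fitting and AICc selection of the community-analogue vital-rate models.

Three roles are fitted per functional group x treatment:

* persistence — Bernoulli GLM with logit link (statsmodels);
* expansion — Gaussian with mean and SD each linear in the covariates,
  estimated by joint maximum likelihood (scipy optimiser, analytic gradient);
* colonisation — the same heteroscedastic Gaussian machinery on colonist log
  covers, with abundance covariates only (no dependence on resident cover).

For each role the candidate set is the base model plus every model obtained
by dropping any combination of the selectable terms: 2^5 = 32 candidates for
persistence and expansion, 2^3 = 8 for colonisation (for the Gaussian roles
the mean and SD sub-models share one term subset).  Selection keeps models
within two AICc units of the minimum and returns the lowest-AICc candidate
that passes a biological-plausibility screen; ties go to fewer parameters,
then to the canonical term ordering.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .params import (COLONISATION_TERMS, GROWTH_TERMS, SELECTABLE,
                     SIGMA_FLOOR, VitalRateParams)
from .survey import TransitionDataset

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


class SelectionError(RuntimeError):
    """No plausible candidate model exists."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_candidates(role: str) -> list[tuple[str, ...]]:
    """All term subsets for a role, in a deterministic order.

    Subsets are ordered by size then by position in the canonical term order,
    so the first entry is always the intercept-only model and the last the
    base (full) model.
    """
    try:
        terms = SELECTABLE[role]
    except KeyError:
        raise ValueError(f"unknown role {role!r}") from None
    subsets = []
    for r in range(len(terms) + 1):
        subsets.extend(itertools.combinations(terms, r))
    return subsets


@dataclass
class CandidateModel:
    """One fitted candidate: role, included terms, and fit summary."""

    role: str
    terms: tuple[str, ...]
    params: dict = field(default_factory=dict)       # term -> estimate
    se: dict = field(default_factory=dict)           # term -> std. error
    sd_params: dict = field(default_factory=dict)    # SD sub-model (Gaussian)
    sd_se: dict = field(default_factory=dict)
    loglik: float = np.nan
    k: int = 0
    n: int = 0
    aicc: float = np.inf
    converged: bool = False
    flagged: bool = False
    flag_reason: str = ""
    plausible: bool | None = None

    @property
    def usable(self) -> bool:
        return self.converged and not self.flagged and np.isfinite(self.aicc)


def _design(df: pd.DataFrame, terms, all_terms, xcol: str | None):
    cols = []
    for t in all_terms:
        if t == "1":
            cols.append(np.ones(len(df)))
        elif t in terms:
            if t == "x":
                cols.append(df[xcol].to_numpy(float))
            elif t == "x2":
                cols.append(df[xcol].to_numpy(float) ** 2)
            else:
                cols.append(df[t].to_numpy(float))
    used = ["1"] + [t for t in all_terms if t in terms and t != "1"]
    return np.column_stack(cols), used


def fit_persistence(dataset: TransitionDataset | pd.DataFrame,
                    terms=SELECTABLE["persistence"]) -> CandidateModel:
    """Logit-link Bernoulli model of annual persistence."""
    df = dataset.persistence if isinstance(dataset, TransitionDataset) \
        else dataset
    cand = CandidateModel(role="persistence", terms=tuple(terms))
    y = df["persisted"].to_numpy(float)
    cand.n = len(df)
    if cand.n == 0 or y.min() == y.max():
        cand.flagged = True
        cand.flag_reason = ("separation: all responses identical "
                            "(infinite intercept)") if cand.n else \
            "empty dataset"
        cand.converged = cand.n > 0
        return cand
    X, used = _design(df, terms, GROWTH_TERMS, "x")
    cand.k = X.shape[1]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            cand.flagged, cand.flag_reason = True, f"fit failed: {exc}"
            return cand
    cand.converged = bool(fit.converged)
    cand.params = dict(zip(used, fit.params))
    cand.se = dict(zip(used, fit.bse))
    cand.loglik = float(fit.llf)
    sep = any("separat" in str(w.message).lower() for w in caught)
    if sep or np.max(np.abs(fit.params)) > 25 or np.max(fit.bse) > 1e3:
        cand.flagged = True
        cand.flag_reason = "possible separation (infinite coefficient)"
    if cand.converged and cand.n - cand.k - 1 > 0:
        cand.aicc = aicc(cand.loglik, cand.k, cand.n)
    elif cand.converged:
        cand.flagged, cand.flag_reason = True, "AICc undefined (n <= k+1)"
    return cand


def _hetero_nll_grad(theta, X, y, p):
    bmu, bsd = theta[:p], theta[p:]
    mu = X @ bmu
    sraw = X @ bsd
    s = np.maximum(sraw, SIGMA_FLOOR)
    r = y - mu
    nll = float(np.sum(np.log(s) + 0.5 * (r / s) ** 2) + 0.5 * len(y) * _LOG2PI)
    gmu = -X.T @ (r / s**2)
    active = (sraw > SIGMA_FLOOR).astype(float)
    gsd = X.T @ ((1.0 / s - r**2 / s**3) * active)
    return nll, np.concatenate([gmu, gsd])


def _fit_hetero_gaussian(role, df, terms, all_terms, ycol, xcol):
    """Joint ML for a Gaussian with linear mean and linear SD sub-models."""
    cand = CandidateModel(role=role, terms=tuple(terms))
    cand.n = len(df)
    if cand.n == 0:
        cand.flagged, cand.flag_reason = True, "empty dataset"
        return cand
    y = df[ycol].to_numpy(float)
    X, used = _design(df, terms, all_terms, xcol)
    p = X.shape[1]
    cand.k = 2 * p
    if cand.n < cand.k + 2:
        cand.flagged, cand.flag_reason = True, "AICc undefined (n <= k+1)"
        return cand
    # start from OLS mean + homoscedastic residual SD
    bmu0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ bmu0
    bsd0 = np.zeros(p)
    bsd0[0] = max(float(np.std(resid)), 10 * SIGMA_FLOOR)
    theta0 = np.concatenate([bmu0, bsd0])
    res = minimize(_hetero_nll_grad, theta0, args=(X, y, p), jac=True,
                   method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-7})
    grad_ok = np.linalg.norm(np.asarray(res.jac), np.inf) < 1e-3 * max(
        1.0, abs(res.fun))
    cand.converged = bool(res.success) or grad_ok  # precision loss near optimum
    if not np.isfinite(res.fun):
        cand.flagged, cand.flag_reason = True, "non-finite likelihood"
        return cand
    cand.loglik = -float(res.fun)
    bmu, bsd = res.x[:p], res.x[p:]
    cov = _observed_info_cov(res.x, X, y, p)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)) if cov is not None \
        else np.full(2 * p, np.nan)
    cand.params = dict(zip(used, bmu))
    cand.se = dict(zip(used, se[:p]))
    cand.sd_params = dict(zip(used, bsd))
    cand.sd_se = dict(zip(used, se[p:]))
    if not cand.converged:
        cand.flagged, cand.flag_reason = True, \
            f"optimiser did not converge: {res.message}"
    else:
        cand.aicc = aicc(cand.loglik, cand.k, cand.n)
    return cand


def _observed_info_cov(theta, X, y, p):
    """Covariance from a finite-difference observed information matrix."""
    m = len(theta)
    H = np.empty((m, m))
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(m):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _hetero_nll_grad(tp, X, y, p)
        _, gm = _hetero_nll_grad(tm, X, y, p)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def fit_expansion(dataset: TransitionDataset | pd.DataFrame,
                  terms=SELECTABLE["expansion"]) -> CandidateModel:
    """Heteroscedastic Gaussian model of next year's log cover."""
    df = dataset.expansion if isinstance(dataset, TransitionDataset) \
        else dataset
    return _fit_hetero_gaussian("expansion", df, terms, GROWTH_TERMS,
                                "y", "x")


def fit_colonisation(dataset: TransitionDataset | pd.DataFrame,
                     terms=SELECTABLE["colonisation"]) -> CandidateModel:
    """Heteroscedastic Gaussian model of colonist log cover."""
    df = dataset.colonisation if isinstance(dataset, TransitionDataset) \
        else dataset
    if len(df) == 0:
        raise ValueError("no colonisation events in dataset")
    return _fit_hetero_gaussian("colonisation", df, terms,
                                COLONISATION_TERMS, "y", None)


def colonisation_fallback(dataset: TransitionDataset) -> CandidateModel:
    """Intercept-only colonist-size model for cells too sparse to select.

    With fewer than four colonisation events AICc is undefined for every
    candidate; the sample mean/SD (SD floored at 0.1 on the log scale) is
    the only defensible estimate.  With no events at all the model is
    irrelevant (the colonisation rate is zero) and placeholder moments are
    returned.
    """
    df = dataset.colonisation if isinstance(dataset, TransitionDataset) \
        else dataset
    cand = CandidateModel(role="colonisation", terms=(), converged=True,
                          n=len(df), k=2)
    if len(df) == 0:
        cand.params = {"1": 0.0}
        cand.sd_params = {"1": 1.0}
    else:
        y = df["y"].to_numpy(float)
        cand.params = {"1": float(np.mean(y))}
        cand.sd_params = {"1": max(float(np.std(y)), 0.1)}
        cand.loglik = float(np.sum(
            -np.log(cand.sd_params["1"]) - 0.5 * _LOG2PI
            - 0.5 * ((y - cand.params["1"]) / cand.sd_params["1"]) ** 2))
    cand.flag_reason = "fallback: too few colonisation events for selection"
    return cand


_FITTERS = {"persistence": fit_persistence, "expansion": fit_expansion,
            "colonisation": fit_colonisation}


def fit_all_candidates(dataset: TransitionDataset,
                       role: str) -> list[CandidateModel]:
    """Fit every candidate term subset for one role."""
    return [_FITTERS[role](dataset, terms)
            for terms in enumerate_candidates(role)]


def _order_key(cand: CandidateModel):
    canon = SELECTABLE[cand.role]
    return (cand.aicc, cand.k, tuple(canon.index(t) for t in cand.terms))


def select_model(candidates: list[CandidateModel],
                 plausibility_oracle=None) -> CandidateModel:
    """AICc selection with a plausibility screen.

    Candidates within two AICc units of the minimum are considered in order
    of (AICc, parameter count, canonical term order); the first one the
    oracle accepts wins.  If none in the window is plausible the window is
    widened to all candidates with a logged warning.
    """
    usable = sorted((c for c in candidates if c.usable), key=_order_key)
    if not usable:
        raise SelectionError("no converged, unflagged candidate")
    best = usable[0].aicc
    window = [c for c in usable if c.aicc - best <= 2.0]
    if plausibility_oracle is None:
        return window[0]
    for c in window:
        c.plausible = bool(plausibility_oracle(c))
        if c.plausible:
            return c
    logger.warning("no plausible model within 2 AICc units of the minimum; "
                   "widening to the full candidate set")
    for c in usable:
        if c.plausible is None:
            c.plausible = bool(plausibility_oracle(c))
        if c.plausible:
            return c
    raise SelectionError("no biologically plausible candidate model")


def params_from_models(persistence: CandidateModel,
                       expansion: CandidateModel,
                       colonisation: CandidateModel,
                       col_rate: float = 1.0) -> VitalRateParams:
    """Assemble a VitalRateParams from three selected fits.

    Terms excluded from a selected model carry a zero coefficient, so the
    restricted model's predictions are reproduced exactly.
    """
    def vec(d, order):
        return np.array([d.get(t, 0.0) for t in order])
    return VitalRateParams(
        persistence=vec(persistence.params, GROWTH_TERMS),
        expansion_mean=vec(expansion.params, GROWTH_TERMS),
        expansion_sd=vec(expansion.sd_params, GROWTH_TERMS),
        colonisation_mean=vec(colonisation.params, COLONISATION_TERMS),
        colonisation_sd=vec(colonisation.sd_params, COLONISATION_TERMS),
        col_rate=col_rate)


# ---------------------------------------------------------------------------
# Flat CSV export / import of fitted coefficients.  The same schema can
# ingest externally published coefficient tables to rebuild the IPMs
# without refitting (columns: group, treatment, role, term, estimate, se).
# ---------------------------------------------------------------------------

_ROLE_ORDERS = {
    "persistence": GROWTH_TERMS,
    "expansion_mean": GROWTH_TERMS,
    "expansion_sd": GROWTH_TERMS,
    "colonisation_mean": COLONISATION_TERMS,
    "colonisation_sd": COLONISATION_TERMS,
}


def params_to_frame(params_by_gt: dict) -> pd.DataFrame:
    """Flatten {(group, treatment): VitalRateParams} to a tidy coefficient
    table (zero rows included so the table fully specifies the model)."""
    rows = []
    for (group, treatment), p in sorted(params_by_gt.items()):
        for role, order in _ROLE_ORDERS.items():
            vec = getattr(p, role)
            for term, est in zip(order, vec):
                rows.append(dict(group=group, treatment=treatment, role=role,
                                 term=term, estimate=est, se=np.nan))
        rows.append(dict(group=group, treatment=treatment, role="col_rate",
                         term="rate", estimate=p.col_rate, se=np.nan))
    return pd.DataFrame(rows)


def params_from_frame(df: pd.DataFrame) -> dict:
    """Inverse of :func:`params_to_frame`; missing terms default to zero."""
    out = {}
    for (group, treatment), sub in df.groupby(["group", "treatment"]):
        kw = {}
        for role, order in _ROLE_ORDERS.items():
            vec = np.zeros(len(order))
            rsub = sub[sub["role"] == role]
            for _, row in rsub.iterrows():
                vec[order.index(row["term"])] = row["estimate"]
            kw[role] = vec
        rate = sub.loc[sub["role"] == "col_rate", "estimate"]
        out[(group, treatment)] = VitalRateParams(
            col_rate=float(rate.iloc[0]) if len(rate) else 1.0, **kw)
    return out
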
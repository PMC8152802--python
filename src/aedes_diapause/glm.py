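"""Logistic diapause-probability model with AIC-based predictor selection.

The response is the per-egg diapause indicator over viable eggs (success =
embryonated unhatched, failure = hatched), modelled as

    logit p = b0 + b1 * week + b2 * width + b3 * week * width [+ year terms]

with week of collection (x1), egg width in um (x2), their product and a
categorical year effect as candidate predictors.  Fitting is by maximum
likelihood via iteratively reweighted least squares (IRLS), and candidate
formulas are ranked by AIC = 2k - 2 logLik.  Predictors are left in
natural units so coefficients read directly against field scales.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import EggRecord, EggStatus
from .morphometrics import summarize_reps

__all__ = [
    "GlmFit",
    "build_design",
    "fit_logistic",
    "select_by_aic",
    "predict_diapause",
    "CANDIDATE_TERMS",
]

logger = logging.getLogger(__name__)

CANDIDATE_TERMS = ("x1", "x2", "year", "x1:x2")

MAX_ITER = 100
LL_RTOL = 1e-8
#: |linear predictor| beyond which fitted probabilities are numerically 0/1
SEPARATION_ETA = 25.0


def build_design(records: Iterable[EggRecord]) -> pd.DataFrame:
    """Per-egg design rows: viable eggs with morphometry only.

    Columns: ``y`` (1 = embryonated unhatched, 0 = hatched), ``x1`` week of
    collection, ``x2`` mean egg width (um), ``year`` (ISO week-year, as a
    categorical level).
    """
    rows = []
    n_total = n_viable = 0
    for r in records:
        n_total += 1
        if not r.is_viable:
            continue
        n_viable += 1
        m = summarize_reps(r)
        if m is None:
            continue
        rows.append(
            {
                "y": 1 if r.status is EggStatus.EMBRYONATED_UNHATCHED else 0,
                "x1": float(r.iso_week),
                "x2": m.width_um,
                "year": str(r.iso_year),
            }
        )
    logger.info(
        "design: %d eggs, %d viable, %d with morphometry", n_total, n_viable, len(rows)
    )
    if not rows:
        raise ValueError("no viable eggs with morphometry: cannot build design")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlmFit:
    terms: tuple[str, ...]
    column_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    log_likelihood: float
    aic: float
    n: int
    n_iter: int
    converged: bool
    separation: bool
    year_levels: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def coef(self, name: str) -> float:
        return self.coefficients[self.column_names.index(name)]


def _design_matrix(
    design: pd.DataFrame, terms: Sequence[str], year_levels: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(len(design))]
    names = ["intercept"]
    if "x1" in terms:
        cols.append(design["x1"].to_numpy(float))
        names.append("x1")
    if "x2" in terms:
        cols.append(design["x2"].to_numpy(float))
        names.append("x2")
    if "year" in terms:
        for lvl in year_levels[1:]:  # first level is the reference
            cols.append((design["year"].astype(str) == lvl).to_numpy(float))
            names.append(f"year[{lvl}]")
    if "x1:x2" in terms:
        cols.append(design["x1"].to_numpy(float) * design["x2"].to_numpy(float))
        names.append("x1:x2")
    return np.column_stack(cols), tuple(names)


def _check_hierarchy(terms: Sequence[str]) -> None:
    if "x1:x2" in terms and not ({"x1", "x2"} <= set(terms)):
        raise ValueError("x1:x2 requires both main effects x1 and x2")
    unknown = set(terms) - set(CANDIDATE_TERMS)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")


def fit_logistic(
    design: pd.DataFrame,
    terms: Sequence[str] = ("x1", "x2", "x1:x2"),
    weights: np.ndarray | None = None,
) -> GlmFit:
    """Maximum-likelihood logistic fit by IRLS.

    ``design`` must have columns y (0/1), x1, x2 and (if the ``year`` term
    is used) year.  ``weights`` are optional frequency weights, making a
    grouped-binomial fit equivalent to the expanded Bernoulli one.
    Convergence is declared when the relative log-likelihood change drops
    below 1e-8 (at most 100 iterations); non-convergence and quasi-complete
    separation are flagged on the result, never silently ignored.
    """
    terms = tuple(terms)
    _check_hierarchy(terms)
    y = design["y"].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be 0/1")
    year_levels = (
        tuple(sorted(design["year"].astype(str).unique())) if "year" in terms else ()
    )
    X, names = _design_matrix(design, terms, year_levels)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"singular design; collinear column(s): {bad}")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        wt = np.clip(w * p * (1.0 - p), 1e-12, None)
        # Newton step on the weighted normal equations
        XtW = X.T * wt
        step = np.linalg.solve(XtW @ X, X.T @ (w * (y - p)))
        beta = beta + step
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        score_max = float(np.max(np.abs(X.T @ (w * (y - p)))))
        # require both a stationary likelihood and vanishing score, so the
        # estimating equations hold to numerical precision (unless the fit
        # is drifting to infinity under separation)
        if abs(ll - ll_old) <= LL_RTOL * (abs(ll) + 0.1) and (
            score_max < 1e-8 * max(1.0, float(np.sum(w)))
            or np.max(np.abs(eta)) >= SEPARATION_ETA
        ):
            converged = True
            break
        ll_old = ll

    eta_raw = X @ beta
    separation = bool(np.max(np.abs(eta_raw)) > SEPARATION_ETA)
    p = 1.0 / (1.0 + np.exp(-np.clip(eta_raw, -35, 35)))
    wt = np.clip(w * p * (1.0 - p), 1e-12, None)
    fisher = (X.T * wt) @ X
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    ll = float(np.sum(w * (y * np.log(np.clip(p, 1e-300, 1))
                           + (1 - y) * np.log(np.clip(1 - p, 1e-300, 1)))))
    k = X.shape[1]
    fit = GlmFit(
        terms=terms,
        column_names=names,
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in se),
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n=int(np.sum(w)),
        n_iter=n_iter,
        converged=converged,
        separation=separation,
        year_levels=year_levels,
    )
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", MAX_ITER)
    if separation:
        logger.warning("quasi-complete separation detected (|eta| > %g)", SEPARATION_ETA)
    return fit


def _hierarchical_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    seen: list[tuple[str, ...]] = []
    pool = [t for t in CANDIDATE_TERMS if t in set(candidates)]
    for r in range(len(pool) + 1):
        for comb in itertools.combinations(pool, r):
            if "x1:x2" in comb and not ({"x1", "x2"} <= set(comb)):
                continue
            if comb not in seen:
                seen.append(comb)
    return seen


def select_by_aic(
    design: pd.DataFrame,
    candidate_terms: Sequence[str] = CANDIDATE_TERMS,
) -> tuple[GlmFit, pd.DataFrame]:
    """Exhaustive AIC ranking over hierarchical subsets of the candidates.

    Every subset of ``candidate_terms`` that respects marginality (the
    week-by-width product only together with both main effects) is fitted,
    including the intercept-only model.  Non-converged candidates are
    excluded with a warning.  Returns the minimum-AIC fit and the full
    ranking table (formula, k, logLik, AIC, dAIC).
    """
    subsets = _hierarchical_subsets(tuple(dict.fromkeys(candidate_terms)))
    if len(subsets) < 2:
        raise ValueError("need at least two candidate formulas")
    fits: list[GlmFit] = []
    for terms in subsets:
        f = fit_logistic(design, terms)
        if not f.converged:
            warnings.warn(f"candidate {terms or ('1',)} did not converge; excluded")
            continue
        fits.append(f)
    if not fits:
        raise ValueError("no candidate converged")
    fits.sort(key=lambda f: f.aic)
    best = fits[0]
    table = pd.DataFrame(
        {
            "formula": [" + ".join(f.terms) or "1" for f in fits],
            "k": [f.k for f in fits],
            "logLik": [f.log_likelihood for f in fits],
            "AIC": [f.aic for f in fits],
            "dAIC": [f.aic - best.aic for f in fits],
        }
    )
    return best, table


def predict_diapause(
    fit: GlmFit,
    week: float,
    width_um: float,
    year: str | int | None = None,
) -> float:
    """Predicted diapause probability, strictly inside (0, 1).

    ``year`` must be a level seen at fit time when the model has a year
    effect.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    eta = fit.coef("intercept")
    if "x1" in fit.terms:
        eta += fit.coef("x1") * week
    if "x2" in fit.terms:
        eta += fit.coef("x2") * width_um
    if "x1:x2" in fit.terms:
        eta += fit.coef("x1:x2") * week * width_um
    if "year" in fit.terms:
        if year is None:
            raise ValueError("model has a year effect: pass year=")
        lvl = str(year)
        if lvl not in fit.year_levels:
            raise ValueError(f"year level {lvl!r} unseen in training {fit.year_levels}")
        if lvl != fit.year_levels[0]:
            eta += fit.coef(f"year[{lvl}]")
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return float(np.clip(p, 1e-15, 1 - 1e-15))
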
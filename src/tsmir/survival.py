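"""Median-difference survival risk score and Cox screening.

The signature is built in four steps:

1. Each candidate gene is screened with a univariate Cox
   proportional-hazards fit of overall survival on its expression.
2. Genes with Wald p < alpha join the signature: coefficient > 0 into
   C+ (higher expression, higher death hazard), coefficient < 0 into
   C-.
3. Each sample's risk score is RS = U - D, where U is the median
   expression of the C+ genes and D the median of the C- genes in that
   sample. Medians make the score robust to single outlying genes and
   to the exact signature size.
4. RS values are binned into equally spaced (equal-width) levels over
   the observed range, and survival association is tested by a Cox fit
   on the level as a single numeric covariate, reporting one hazard
   ratio per one-level increase.

The single-covariate Cox fitter is implemented here directly (Newton-
Raphson on the Breslow partial likelihood with step halving) because
the screening step fits thousands of genes and only ever needs one
covariate; `lifelines` remains the general-purpose alternative and is
used for Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .containers import CoxFit, ExprMatrix, RiskScores, Signature, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "univariate_cox",
    "cox_screen",
    "build_signature",
    "compute_risk_scores",
    "bin_risk_levels",
    "survival_association",
    "km_curves",
    "breslow_partial_loglik",
]

_SCORE_TOL = 1e-8
_MAX_ITER = 100


def _prepare(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="mergesort")
    t, xv, d = time[order], x[order], event[order].astype(bool)
    # Breslow ties: every event at time t uses the full risk set {t_j >= t},
    # which starts at the first index of the tied block.
    first = np.searchsorted(t, t, side="left")
    return t, xv, d, first


def _loglik_score_info(beta: float, xv, d, first):
    w = np.exp(beta * xv)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]
    f = first[d]
    r0, r1, r2 = s0[f], s1[f], s2[f]
    loglik = float(np.sum(beta * xv[d] - np.log(r0)))
    score = float(np.sum(xv[d] - r1 / r0))
    info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
    return loglik, score, info


def breslow_partial_loglik(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of a single covariate at ``beta``."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _, xv, d, first = _prepare(x, time, event)
    return _loglik_score_info(beta, xv, d, first)[0]


def univariate_cox(x: np.ndarray, survival: SurvivalTable) -> CoxFit:
    """Cox proportional-hazards fit for one continuous covariate.

    Newton-Raphson with step halving on the Breslow partial likelihood;
    convergence when |score| < 1e-8 (at most 100 iterations). Returns
    the log hazard ratio, its standard error, a two-sided Wald p-value
    and the event count; the 95% CI is exp(coef +/- 1.96 se).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(survival.table):
        raise ValueError("covariate length does not match survival table")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("covariate is constant; hazard ratio undefined")
    n_events = survival.n_events
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")

    _, xv, d, first = _prepare(x, survival.time, survival.event)
    beta = 0.0
    loglik, score, info = _loglik_score_info(beta, xv, d, first)
    converged = False
    for _ in range(_MAX_ITER):
        if abs(score) < _SCORE_TOL:
            converged = True
            break
        step = score / info if info > 0 else np.sign(score)
        # step-halve until the partial likelihood does not decrease
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_score_info(new_beta, xv, d, first)
            if new_ll >= loglik - 1e-12:
                break
            step *= 0.5
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
    else:
        if abs(score) < _SCORE_TOL:
            converged = True
    # monotone partial likelihood (perfect separation): the score decays
    # to zero with the curvature, so "convergence" at vanishing
    # information is divergence to +/- infinity, not a finite MLE
    if converged and info < 1e-6 * max(1.0, np.var(x)) * n_events:
        converged = False
    if not converged:
        warnings.warn(
            f"Cox fit did not converge (|score|={abs(score):.2e})", RuntimeWarning,
            stacklevel=2,
        )
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(float(beta), se, p, n=len(x), n_events=n_events,
                  converged=converged)


def cox_screen(expr: ExprMatrix, survival: SurvivalTable) -> dict[str, CoxFit]:
    """Univariate Cox fit per gene over a common cohort.

    Expression columns are aligned to the survival table's samples.
    Constant genes are skipped with a warning.
    """
    cols = [s for s in survival.sample_ids if s in set(expr.sample_ids)]
    if len(cols) != len(survival.sample_ids):
        raise ValueError("survival table contains samples absent from expression")
    sub = expr.values[cols]
    fits: dict[str, CoxFit] = {}
    n_skipped = 0
    for gene, row in sub.iterrows():
        xv = row.to_numpy(dtype=float)
        if np.ptp(xv) == 0.0:
            n_skipped += 1
            continue
        fits[gene] = univariate_cox(xv, survival)
    if n_skipped:
        logger.warning("skipped %d constant genes in Cox screen", n_skipped)
    return fits


def build_signature(gene_fits: dict[str, CoxFit], alpha: float = 0.05) -> Signature:
    """Split significantly survival-associated genes by coefficient sign.

    Gene -> C+ iff p < alpha and coef > 0; C- iff p < alpha and
    coef < 0. A significant gene with coefficient exactly 0 has no
    defined direction and is dropped with a warning.
    """
    c_plus, c_minus = [], []
    for gene in sorted(gene_fits):
        fit = gene_fits[gene]
        if fit.p >= alpha:
            continue
        if fit.coef > 0:
            c_plus.append(gene)
        elif fit.coef < 0:
            c_minus.append(gene)
        else:
            warnings.warn(
                f"gene {gene} significant with zero coefficient; dropped",
                RuntimeWarning, stacklevel=2,
            )
    logger.info("signature: %d C+ genes, %d C- genes", len(c_plus), len(c_minus))
    return Signature(c_plus, c_minus)


def compute_risk_scores(
    expr: ExprMatrix,
    sig: Signature,
    missing: str = "drop",
) -> RiskScores:
    """Median-difference risk score per sample: RS = U - D.

    U is the per-sample median expression over the C+ genes and D the
    median over the C- genes. When several probesets map to one
    signature gene the caller should have collapsed them (per-sample
    median) beforehand. Signature genes absent from the matrix are
    dropped from their group (``missing='drop'``, with a logged count;
    necessary across array platforms) or raise (``missing='raise'``).
    An empty group contributes a median of 0, with a prominent warning.
    """
    if len(sig) == 0:
        raise ValueError("signature has no genes")

    def _present(genes: list[str], label: str) -> list[str]:
        have = [g for g in genes if g in expr.values.index]
        lost = len(genes) - len(have)
        if lost:
            if missing == "raise":
                raise KeyError(f"{lost} {label} genes missing from expression")
            logger.warning("dropped %d missing %s genes", lost, label)
        return have

    cp = _present(sig.c_plus, "C+")
    cm = _present(sig.c_minus, "C-")
    if not cp and not cm:
        raise ValueError("no signature genes present in expression matrix")

    def _median(genes: list[str], label: str) -> np.ndarray:
        if not genes:
            warnings.warn(
                f"{label} group empty after filtering; its median set to 0 — "
                "risk scores are one-sided", RuntimeWarning, stacklevel=3,
            )
            return np.zeros(len(expr.sample_ids))
        return expr.values.loc[genes].median(axis=0).to_numpy(dtype=float)

    u = _median(cp, "C+")
    d = _median(cm, "C-")
    table = pd.DataFrame(
        {"u": u, "d": d, "rs": u - d}, index=pd.Index(expr.sample_ids, name="sample_id")
    )
    return RiskScores(table)


def bin_risk_levels(scores: RiskScores, n_levels: int = 4) -> RiskScores:
    """Assign each sample to one of ``n_levels`` equally spaced
    (equal-width) risk levels over the observed RS range.

    Level k covers [min + (k-1)w, min + kw) with w = range / n_levels;
    the last bin is right-closed so the maximum falls in level
    ``n_levels``. When all RS are identical the output is a single
    degenerate level with a warning. Equal-width (not quantile) binning
    keeps the level scale linear in RS; group sizes may be unequal.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    rs = scores.rs
    lo, hi = float(rs.min()), float(rs.max())
    table = scores.table.copy()
    if hi == lo:
        warnings.warn("all risk scores identical; single degenerate level",
                      RuntimeWarning, stacklevel=2)
        table["level"] = 1
        return RiskScores(table, n_levels=n_levels)
    w = (hi - lo) / n_levels
    level = np.floor((rs - lo) / w).astype(int) + 1
    level = np.clip(level, 1, n_levels)
    table["level"] = level
    return RiskScores(table, n_levels=n_levels)


def survival_association(
    levels: np.ndarray,
    survival: SurvivalTable,
    categorical: bool = False,
) -> CoxFit | dict[int, CoxFit]:
    """Cox association between risk level and overall survival.

    By default the level enters as a single numeric covariate (ordinal
    trend), so the hazard ratio is per one-level increase — one HR per
    dataset. ``categorical=True`` instead returns one fit per non-
    reference level using indicator covariates against level 1.
    """
    levels = np.asarray(levels, dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need at least 2 distinct levels")
    if not categorical:
        return univariate_cox(levels, survival)
    ref = levels.min()
    out: dict[int, CoxFit] = {}
    for lev in sorted(np.unique(levels)):
        if lev == ref:
            continue
        mask = np.isin(levels, (ref, lev))
        sub = SurvivalTable(survival.table.loc[mask])
        out[int(lev)] = univariate_cox((levels[mask] == lev).astype(float), sub)
    return out


def km_curves(
    levels: np.ndarray, survival: SurvivalTable
) -> dict[int, pd.DataFrame]:
    """Kaplan-Meier survival curve per risk level.

    Returns, per level, a step function as a DataFrame with columns
    ``time`` and ``survival`` (product-limit estimate S(t)); the first
    row is (0, 1).
    """
    levels = np.asarray(levels)
    out: dict[int, pd.DataFrame] = {}
    for lev in sorted(np.unique(levels)):
        mask = levels == lev
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[mask], survival.event[mask])
        sf = kmf.survival_function_
        out[int(lev)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out
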
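"""Regression and cognition statistics.

Implements the statistical layer of the pipeline: cognition composite
scores (means of test z-scores), tolerance/VIF collinearity diagnostics,
blockwise backward/forward stepwise OLS regression with forced second-block
predictors, the hierarchical age + age^2 model with an R^2-change F test,
and a leave-one-out cross-validated coefficient of determination on the
percent scale with an uncentred denominator:

    R2_cv = 100 * (1 - sum_i (y_i - yhat_i)^2 / sum_i y_i^2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "StepwiseStep",
    "composite_score",
    "collinearity",
    "fit_ols",
    "stepwise_blockwise",
    "hierarchical_quadratic",
    "cv_r2_score",
    "loocv_r2",
]

TOLERANCE_THRESHOLD = 0.2  # flag predictors whose tolerance falls below this


@dataclass
class RegressionResult:
    """One fitted OLS model (always with an intercept)."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    std_betas: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    p_model: float
    n: int
    tolerance: dict[str, float] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    fitted: np.ndarray | None = None
    y: np.ndarray | None = None


@dataclass
class StepwiseStep:
    """One model in a stepwise sequence, with the action that produced it."""

    action: str                 # "start" | "remove" | "add" | "enter_block2"
    predictor: str | None
    p_at_action: float | None
    model: RegressionResult
    delta_r2: float | None = None
    f_change: float | None = None
    p_change: float | None = None


def composite_score(
    table: pd.DataFrame, components: Sequence[str], domain: str
) -> pd.Series:
    """Mean of component z-scores per subject, stored under ``domain``.

    Subjects missing any component get a missing composite (with a warning);
    no silent imputation.
    """
    missing_cols = [c for c in components if c not in table.columns]
    if missing_cols:
        raise KeyError(f"components not in table: {missing_cols}")
    sub = table[list(components)]
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} subject(s) missing a component of "
            f"{domain!r}; composite left missing",
            stacklevel=2,
        )
    out = sub.mean(axis=1)
    out[incomplete] = np.nan
    out.name = domain
    return out


def collinearity(X: pd.DataFrame) -> pd.DataFrame:
    """Tolerance and VIF per predictor.

    Each predictor is regressed on all the others; tolerance = 1 - R^2 of
    that regression, VIF = 1 / tolerance. Predictors with tolerance below
    0.2 are flagged; exact collinearity yields tolerance 0 and a singularity
    flag.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than predictors")
    rows = []
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(float))
        target = X[col].to_numpy(float)
        res = sm.OLS(target, others).fit()
        r2 = min(max(float(res.rsquared), 0.0), 1.0)
        tol = 1.0 - r2
        singular = tol < 1e-10
        if singular:
            tol = 0.0
        rows.append({
            "predictor": col,
            "tolerance": tol,
            "vif": np.inf if tol == 0 else 1.0 / tol,
            "flagged": tol < TOLERANCE_THRESHOLD,
            "singular": singular,
        })
    return pd.DataFrame(rows).set_index("predictor")


def _safe_p(p: float) -> float:
    # an exact fit gives 0/0 t statistics; treat an undefined partial p as 1
    return 1.0 if not np.isfinite(p) else float(p)


def fit_ols(y: pd.Series | np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """OLS with intercept, raw and standardized coefficients, VIF/tolerance."""
    yv = np.asarray(y, dtype=float)
    names = tuple(X.columns)
    Xv = X.to_numpy(float)
    n = yv.size
    if n <= Xv.shape[1] + 1:
        raise ValueError(
            f"need more rows ({n}) than predictors + 1 ({Xv.shape[1] + 1})"
        )
    design = sm.add_constant(Xv, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(yv, design).fit()
    sy = yv.std(ddof=1)
    betas = {}
    for k, name in enumerate(names):
        sx = Xv[:, k].std(ddof=1)
        betas[name] = float(res.params[k + 1] * sx / sy) if sy > 0 else np.nan
    pvals = {name: _safe_p(res.pvalues[k + 1]) for k, name in enumerate(names)}
    tol: dict[str, float] = {}
    vif: dict[str, float] = {}
    if len(names) >= 2:
        diag = collinearity(X)
        tol = diag["tolerance"].to_dict()
        vif = diag["vif"].to_dict()
    elif len(names) == 1:
        tol = {names[0]: 1.0}
        vif = {names[0]: 1.0}
    fvalue = float(res.fvalue) if np.isfinite(res.fvalue) else np.inf
    return RegressionResult(
        predictors=names,
        coefficients={name: float(res.params[k + 1]) for k, name in enumerate(names)},
        std_betas=betas,
        pvalues=pvals,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=fvalue,
        df=(int(res.df_model), int(res.df_resid)),
        p_model=0.0 if not np.isfinite(res.f_pvalue) and fvalue == np.inf
        else _safe_p(res.f_pvalue),
        n=n,
        tolerance=tol,
        vif=vif,
        fitted=np.asarray(res.fittedvalues),
        y=yv,
    )


def _f_change(prev: RegressionResult, cur: RegressionResult) -> tuple[float, float, float]:
    """(delta R2, F-change, p) between two nested models (cur = larger)."""
    small, big = (prev, cur) if len(cur.predictors) >= len(prev.predictors) else (cur, prev)
    dk = len(big.predictors) - len(small.predictors)
    d_r2 = big.r2 - small.r2
    if dk == 0:
        return d_r2, np.nan, np.nan
    df2 = big.n - len(big.predictors) - 1
    denom = (1.0 - big.r2) / df2
    if denom <= 0:
        return d_r2, np.inf, 0.0
    f = (d_r2 / dk) / denom
    from scipy.stats import f as fdist

    p = float(fdist.sf(f, dk, df2))
    return d_r2, float(f), p


def stepwise_blockwise(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    block1: Sequence[str],
    block2: Sequence[str] = (),
    direction: str = "backward",
    p_remove: float = 0.10,
    p_enter: float = 0.05,
    block2_entry: str = "before",
) -> list[StepwiseStep]:
    """Blockwise stepwise OLS over ``block1`` with ``block2`` forced.

    Backward: start from all block-1 predictors (plus the forced block-2
    predictors), repeatedly drop the block-1 predictor with the largest
    partial-F p-value above ``p_remove``. Forward: repeatedly add the
    eligible block-1 predictor with the smallest partial-F p-value below
    ``p_enter``. Block-2 predictors are never removed. With
    ``block2_entry="before"`` (default) the forced predictors are in the
    working model throughout selection; ``"after"`` runs block-1 selection
    alone first and enters block 2 at the end.

    Returns the full model sequence with delta-R^2 and F-change between
    consecutive models.
    """
    block1 = list(block1)
    block2 = list(block2)
    if direction not in ("backward", "forward"):
        raise ValueError(f"direction must be backward|forward, got {direction!r}")
    if not block1 and not block2:
        raise ValueError("empty predictor sets")
    missing = [c for c in block1 + block2 if c not in X.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")

    forced_during = block2 if block2_entry == "before" else []
    steps: list[StepwiseStep] = []

    def fit(cols: Sequence[str]) -> RegressionResult:
        return fit_ols(y, X[list(cols)])

    if direction == "backward":
        current = list(block1)
        model = fit(forced_during + current)
        steps.append(StepwiseStep("start", None, None, model))
        while current:
            # candidate with the largest removable p; undefined p counts as 1
            # and ties break toward the smallest |standardized beta|
            cand = max(
                current,
                key=lambda c: (model.pvalues[c], -abs(model.std_betas[c])
                               if np.isfinite(model.std_betas[c]) else 0.0),
            )
            if model.pvalues[cand] <= p_remove:
                break
            current.remove(cand)
            if not current and not forced_during:
                steps.append(StepwiseStep("remove", cand, model.pvalues[cand], model))
                warnings.warn("all predictors removed; last model retained", stacklevel=2)
                break
            new_model = fit(forced_during + current)
            steps.append(StepwiseStep("remove", cand, model.pvalues[cand], new_model))
            model = new_model
    else:
        current = []
        if forced_during:
            model = fit(forced_during)
            steps.append(StepwiseStep("start", None, None, model))
        else:
            model = None
        while True:
            remaining = [c for c in block1 if c not in current]
            if not remaining:
                break
            trial = {c: fit(forced_during + current + [c]) for c in remaining}
            best = min(remaining, key=lambda c: trial[c].pvalues[c])
            if trial[best].pvalues[best] >= p_enter:
                break
            current.append(best)
            model = trial[best]
            steps.append(StepwiseStep("add", best, model.pvalues[best], model))
        if model is None:
            # nothing entered and nothing forced: fall back to the best single
            # candidate model so the caller still sees a fitted sequence
            warnings.warn("no predictor met the entry criterion", stacklevel=2)
            model = fit(block1[:1])
            steps.append(StepwiseStep("start", None, None, model))

    if block2 and block2_entry == "after":
        new_model = fit(list(model.predictors) + block2)
        steps.append(StepwiseStep("enter_block2", ",".join(block2), None, new_model))
        model = new_model

    for prev, cur in zip(steps, steps[1:]):
        d_r2, f, p = _f_change(prev.model, cur.model)
        cur.delta_r2, cur.f_change, cur.p_change = d_r2, f, p
    return steps


def hierarchical_quadratic(age: np.ndarray, y: np.ndarray) -> list[StepwiseStep]:
    """Hierarchical model: block 1 y ~ age, block 2 y ~ age + age^2.

    Reports delta-R^2 and the F-change test for the added quadratic term.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(age) == 0:
        raise ValueError("age vector is constant")
    X = pd.DataFrame({"age": age, "age_sq": age**2})
    m1 = fit_ols(y, X[["age"]])
    m2 = fit_ols(y, X)
    steps = [
        StepwiseStep("start", None, None, m1),
        StepwiseStep("add", "age_sq", m2.pvalues["age_sq"], m2),
    ]
    d_r2, f, p = _f_change(m1, m2)
    steps[1].delta_r2, steps[1].f_change, steps[1].p_change = d_r2, f, p
    return steps


def cv_r2_score(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated R^2 on the percent scale, uncentred denominator."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    denom = float(np.sum(y**2))
    if denom == 0:
        raise ValueError("sum of squared measurements is zero")
    return 100.0 * (1.0 - float(np.sum((y - y_pred) ** 2)) / denom)


def loocv_r2(X: pd.DataFrame, y: pd.Series | np.ndarray) -> float:
    """Leave-one-out cross-validated R^2 (percent) of an OLS model."""
    yv = np.asarray(y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n = yv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    preds = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        design = sm.add_constant(Xv[keep], has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular design when leaving out fold {i}")
        res = sm.OLS(yv[keep], design).fit()
        preds[i] = res.params[0] + Xv[i] @ res.params[1:]
    return cv_r2_score(yv, preds)
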
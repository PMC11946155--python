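"""Stepwise multiple regression linking prestimulus EEG measures to ERP
components and behaviour.

The procedure is classical forward-entry / backward-removal stepwise
selection: at each step the candidate with the smallest entry p-value joins
the model if that p-value is at most ``p_enter``; afterwards any included
predictor whose p-value exceeds ``p_remove`` is dropped (largest first); the
loop runs to a fixed point.  Coefficients are reported as standardized betas
(identical t statistics to the unstandardized fit).  No multiple-testing
correction is applied -- the linkage analysis is exploratory by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StepRecord", "RegressionResult", "stepwise_regress", "run_linkage_suite"]


@dataclass
class StepRecord:
    step: int
    action: str  # 'enter' | 'remove'
    predictor: str
    p_value: float


@dataclass
class RegressionResult:
    dependent: str
    predictors: list[str]
    beta: dict
    t: dict
    p: dict
    r_squared: float
    n: int
    trace: list[StepRecord] = field(default_factory=list)

    def significant(self) -> bool:
        return len(self.predictors) > 0


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (coef, t, p, r2, dof) for the slopes."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    m = Xd.shape[1]
    xtx = Xd.T @ Xd
    cond = np.linalg.cond(xtx)
    if cond > 1e8:
        warnings.warn("near-collinear predictors; using pseudo-inverse", RuntimeWarning)
        xtx_inv = np.linalg.pinv(xtx)
    else:
        xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (Xd.T @ y)
    resid = y - Xd @ coef
    dof = n - m
    if dof <= 0:
        raise ValueError("not enough cases for the model size")
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return coef[1:], t[1:], p[1:], r2, dof


def stepwise_regress(X: pd.DataFrame, y, p_enter: float = 0.05,
                     p_remove: float = 0.10, dependent: str = "y",
                     max_steps: int = 200) -> RegressionResult:
    """Forward-entry / backward-removal stepwise regression.

    ``X`` is a cases x predictors DataFrame; ``y`` a 1-D array-like.
    Standardized betas are computed from the z-scored fit of the final model;
    t and p come from the same fit (they are invariant to the scaling).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, float)
    n, k = Xv.shape
    if np.any(~np.isfinite(Xv)) or np.any(~np.isfinite(yv)):
        raise ValueError("missing or non-finite values in the regression inputs")
    if n <= k + 2:
        warnings.warn("few cases relative to candidate predictors", RuntimeWarning)

    included: list[int] = []
    trace: list[StepRecord] = []
    step = 0
    changed = True
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    while changed and step < max_steps:
        changed = False
        # forward entry (skipped once the model is numerically perfect)
        best_j, best_p = None, np.inf
        saturated = False
        if included:
            coef, _, _, r2_cur, _ = _ols(Xv[:, included], yv)
            saturated = r2_cur >= 1.0 - 1e-12
        for j in range(k) if not saturated else []:
            if j in included:
                continue
            cols = included + [j]
            try:
                _, _, pvals, _, _ = _ols(Xv[:, cols], yv)
            except ValueError:
                continue
            pj = pvals[-1]
            if np.isfinite(pj) and pj < best_p:
                best_p, best_j = pj, j
        if best_j is not None and best_p <= p_enter:
            included.append(best_j)
            step += 1
            trace.append(StepRecord(step, "enter", names[best_j], float(best_p)))
            changed = True
        # backward removal
        while included:
            _, _, pvals, _, _ = _ols(Xv[:, included], yv)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                j = included.pop(worst)
                step += 1
                trace.append(StepRecord(step, "remove", names[j], float(pvals[worst])))
                changed = True
            else:
                break

    if included:
        coef, t, p, r2, _ = _ols(Xv[:, included], yv)
        sx = Xv[:, included].std(axis=0, ddof=1)
        sy = yv.std(ddof=1)
        beta = coef * sx / sy if sy > 0 else np.zeros_like(coef)
        sel_names = [names[j] for j in included]
        return RegressionResult(
            dependent=dependent, predictors=sel_names,
            beta=dict(zip(sel_names, beta.tolist())),
            t=dict(zip(sel_names, t.tolist())),
            p=dict(zip(sel_names, p.tolist())),
            r_squared=r2, n=n, trace=trace,
        )
    return RegressionResult(dependent=dependent, predictors=[], beta={}, t={},
                            p={}, r_squared=0.0, n=n, trace=trace)


def run_linkage_suite(predictors: pd.DataFrame, erp_go: pd.DataFrame,
                      erp_nogo: pd.DataFrame, behaviour: pd.DataFrame,
                      p_enter: float = 0.05, p_remove: float = 0.10):
    """Primary and secondary stepwise regression suites.

    Primary: every behavioural measure and every (Go and No-Go) ERP component
    amplitude is regressed on the prestimulus predictor table (oscillation
    component amplitudes plus pink and white noise amplitudes at 1 Hz).
    Secondary: each behavioural measure is regressed on the *EEG-affected*
    ERP components (those whose primary regression selected at least one
    predictor).  All tables must be indexed by participant and aligned.

    Returns ``(primary, secondary)`` lists of :class:`RegressionResult`.
    """
    for tbl, label in ((erp_go, "erp_go"), (erp_nogo, "erp_nogo"),
                       (behaviour, "behaviour")):
        if not tbl.index.equals(predictors.index):
            raise ValueError(f"{label} participants not aligned with predictors")

    primary: list[RegressionResult] = []
    dep_tables = [("behaviour", behaviour), ("go", erp_go), ("nogo", erp_nogo)]
    for label, tbl in dep_tables:
        for col in tbl.columns:
            res = stepwise_regress(predictors, tbl[col].to_numpy(float),
                                   p_enter=p_enter, p_remove=p_remove,
                                   dependent=f"{label}:{col}")
            primary.append(res)

    affected = []
    for res in primary:
        label, _, col = res.dependent.partition(":")
        if label in ("go", "nogo") and res.significant():
            tbl = erp_go if label == "go" else erp_nogo
            affected.append((res.dependent, tbl[col].to_numpy(float)))
    secondary: list[RegressionResult] = []
    if affected:
        X2 = pd.DataFrame({name: vals for name, vals in affected},
                          index=predictors.index)
        for col in behaviour.columns:
            res = stepwise_regress(X2, behaviour[col].to_numpy(float),
                                   p_enter=p_enter, p_remove=p_remove,
                                   dependent=f"behaviour:{col}")
            secondary.append(res)
    return primary, secondary
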
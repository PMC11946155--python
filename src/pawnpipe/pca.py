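"""Covariance-matrix PCA with Varimax and Promax rotation for EEG components.

Two uses in the pipeline share this machinery:

* frequency PCA (f-PCA): cases are participant x channel, variables are the
  31 one-hertz bins (0-30 Hz) of the noise-free oscillation amplitude
  spectra; all components are extracted and rotated obliquely with Promax;
* temporal PCA (t-PCA): cases are participant x channel for one condition,
  variables are the 300 time points (-100..498 ms at 2 ms) of the mean ERP;
  all components are extracted and rotated with Kaiser-normalized Varimax.

Loadings are kept on the covariance (microvolt) scale, so the "scaled factor
loadings" plotted in this literature are simply the rotated loadings here.
Components are sign-flipped so the loading at each component's absolute peak
is positive; negative-going deflections then come out with negative scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSolution",
    "half_sample",
    "pca_covariance",
    "varimax",
    "varimax_criterion",
    "promax",
    "rotate_solution",
    "select_components",
    "component_amplitude",
]


def half_sample(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Retain every second sample (1000 Hz -> 500 Hz), no extra filtering.

    The ERP is already low-passed far below the new Nyquist frequency, so
    plain decimation is alias-free.
    """
    x = np.asarray(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(None, None, 2)
    return x[tuple(sl)]


@dataclass
class FactorSolution:
    """Unrotated + rotated PCA solution on one case matrix."""

    loadings: np.ndarray  # p x k, eigenvector * sqrt(eigenvalue), uV units
    scores: np.ndarray  # n x k standardized component scores
    eigenvalues: np.ndarray
    explained_pct: np.ndarray  # unrotated, per component
    total_variance: float  # trace of the covariance matrix
    variable_values: np.ndarray  # frequency bins (Hz) or time points (ms)
    case_meta: pd.DataFrame | None = None
    # rotation results
    method: str = "none"  # 'none' | 'varimax' | 'promax'
    rotated_loadings: np.ndarray | None = None  # orthogonal: rotated; oblique: pattern
    structure: np.ndarray | None = None
    phi: np.ndarray | None = None
    rotation_matrix: np.ndarray | None = None
    rotated_scores: np.ndarray | None = None
    rotated_explained_pct: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def active_loadings(self) -> np.ndarray:
        return self.loadings if self.rotated_loadings is None else self.rotated_loadings

    @property
    def active_scores(self) -> np.ndarray:
        return self.scores if self.rotated_scores is None else self.rotated_scores

    @property
    def active_explained_pct(self) -> np.ndarray:
        return (self.explained_pct if self.rotated_explained_pct is None
                else self.rotated_explained_pct)

    def peak_variable(self, comp: int) -> float:
        load = self.active_loadings[:, comp]
        return float(self.variable_values[int(np.argmax(np.abs(load)))])


def pca_covariance(X: np.ndarray, variable_values: np.ndarray | None = None,
                   case_meta: pd.DataFrame | None = None) -> FactorSolution:
    """Eigendecomposition of the variables' covariance matrix; all components kept.

    Loadings are eigenvectors scaled by the square root of their eigenvalue
    (data units); scores are the centred data projected on unit eigenvectors
    and standardized to unit variance.  Zero (or numerically negative)
    eigenvalues are retained with zero scores and flagged.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if variable_values is None:
        variable_values = np.arange(p, dtype=float)
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(evals < 0, 0.0, evals)
    total = float(evals.sum())
    loadings = evecs * np.sqrt(evals)[None, :]
    keep = evals > 1e-12 * max(total, 1.0)
    inv_sd = np.zeros_like(evals)
    inv_sd[keep] = 1.0 / np.sqrt(evals[keep])
    scores = (Xc @ evecs) * inv_sd[None, :]
    flags = {"n_zero_eigenvalues": int(np.sum(evals <= 1e-12 * max(total, 1.0)))}
    return FactorSolution(
        loadings=loadings, scores=scores, eigenvalues=evals,
        explained_pct=100.0 * evals / total if total > 0 else np.zeros(p),
        total_variance=total, variable_values=np.asarray(variable_values, float),
        case_meta=case_meta, flags=flags,
    )


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over components of the variance of squared loadings."""
    L2 = L**2
    return float(np.sum(L2.var(axis=0)))


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-7, max_iter: int = 500):
    """Varimax rotation (pairwise-equivalent SVD algorithm).

    Rows are rescaled to unit communality during rotation when
    ``kaiser_normalize`` and rescaled back afterwards.  Iterates until the
    relative improvement of the criterion falls below ``tol``; a
    non-convergence warning is issued at ``max_iter`` and the best iterate is
    returned.  Returns ``(rotated_loadings, rotation_matrix, converged)``.
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    if k < 2:
        return L.copy(), np.eye(k), True
    h = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        hs = np.where(h > 0, h, 1.0)
        Ln = L / hs[:, None]
    else:
        hs = np.ones(p)
        Ln = L
    R = np.eye(k)
    d = 0.0
    converged = False
    for _ in range(max_iter):
        LR = Ln @ R
        Q = LR**3 - LR @ np.diag(np.sum(LR**2, axis=0)) / p
        u, s, vt = np.linalg.svd(Ln.T @ Q)
        R = u @ vt
        d_new = float(s.sum())
        if d_new <= d * (1.0 + tol):
            converged = True
            break
        d = d_new
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate", RuntimeWarning)
    rotated = (Ln @ R) * hs[:, None]
    return rotated, R, converged


def promax(loadings: np.ndarray, kappa: float = 3.0, kaiser_normalize: bool = True,
           tol: float = 1e-7, max_iter: int = 500):
    """Promax oblique rotation: Procrustes fit of a Varimax solution to a powered target.

    The target is ``sign(l) * |l| ** kappa`` of the (row-normalized) Varimax
    loadings.  Returns ``(pattern, structure, phi, transform, flags)`` where
    ``transform`` maps unrotated loadings to the pattern and ``phi`` is the
    factor correlation matrix with unit diagonal.  If the intermediate matrix
    is singular the Varimax solution is returned with ``phi = I`` and a flag.
    """
    V, R, converged = varimax(loadings, kaiser_normalize=kaiser_normalize,
                              tol=tol, max_iter=max_iter)
    h = np.sqrt(np.sum(V**2, axis=1))
    hs = np.where(h > 0, h, 1.0)
    Vn = V / hs[:, None]
    target = (np.sign(Vn) * np.abs(Vn) ** kappa) * hs[:, None]
    flags = {"varimax_converged": converged, "promax_fallback": False}
    # components whose powered target carries no mass (noise/zero-variance
    # factors in an all-components extraction) are left at their Varimax
    # orientation: obliquely fitting them is numerically arbitrary and lets
    # them rotate into genuine factors.
    norms = np.linalg.norm(target, axis=0)
    degenerate = norms < 0.25 * norms.max() if norms.max() > 0 else norms >= 0
    flags["n_degenerate_promax"] = int(degenerate.sum())
    k = V.shape[1]
    active = np.flatnonzero(~degenerate)
    try:
        # oblique Procrustes fit restricted to the active factors; frozen
        # (degenerate) factors keep their Varimax columns and stay
        # uncorrelated with everything else.
        U_a, *_ = np.linalg.lstsq(V[:, active], target[:, active], rcond=None)
        d = np.diag(np.linalg.inv(U_a.T @ U_a))
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive normalisation")
        U_a = U_a * np.sqrt(d)[None, :]
        U = np.eye(k)
        U[np.ix_(active, active)] = U_a
        pattern = V.copy()
        pattern[:, active] = V[:, active] @ U_a
        phi = np.eye(k)
        phi[np.ix_(active, active)] = np.linalg.inv(U_a.T @ U_a)
        transform = R @ U
    except np.linalg.LinAlgError:
        flags["promax_fallback"] = True
        pattern = V
        phi = np.eye(V.shape[1])
        transform = R
    structure = pattern @ phi
    return pattern, structure, phi, transform, flags


def _sign_fix(solution: FactorSolution):
    """Flip each component so its peak loading is positive (scores follow)."""
    L = solution.rotated_loadings
    peaks = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[peaks, np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    solution.rotated_loadings = L * signs
    if solution.rotated_scores is not None:
        solution.rotated_scores = solution.rotated_scores * signs
    if solution.structure is not None:
        solution.structure = solution.structure * signs
    if solution.phi is not None:
        solution.phi = solution.phi * np.outer(signs, signs)
    if solution.rotation_matrix is not None:
        solution.rotation_matrix = solution.rotation_matrix * signs[None, :]


def rotate_solution(solution: FactorSolution, method: str = "varimax",
                    kappa: float = 3.0, kaiser_normalize: bool = True,
                    tol: float = 1e-7, max_iter: int = 500) -> FactorSolution:
    """Rotate an unrotated solution in place and attach rotated variance shares.

    Post-rotation explained variance uses per-component sums of squared
    loadings over the total variance (structure loadings for the oblique
    case, where variance attribution is not unique).
    """
    if method == "varimax":
        rotated, R, converged = varimax(solution.loadings, kaiser_normalize,
                                        tol, max_iter)
        solution.rotated_loadings = rotated
        solution.rotation_matrix = R
        solution.rotated_scores = solution.scores @ R
        solution.structure = None
        solution.phi = None
        ss = np.sum(rotated**2, axis=0)
        solution.flags["varimax_converged"] = converged
    elif method == "promax":
        pattern, structure, phi, transform, flags = promax(
            solution.loadings, kappa, kaiser_normalize, tol, max_iter)
        solution.rotated_loadings = pattern
        solution.structure = structure
        solution.phi = phi
        solution.rotation_matrix = transform
        try:
            solution.rotated_scores = solution.scores @ np.linalg.inv(transform.T)
        except np.linalg.LinAlgError:
            solution.rotated_scores = solution.scores @ transform
        # oblique variance attribution: pattern x structure products partition
        # the total variance exactly (sum over components = trace of the
        # covariance), unlike structure sums of squares which double-count
        # shared variance between correlated factors.
        ss = np.sum(pattern * structure, axis=0)
        ss = np.clip(ss, 0.0, None)
        solution.flags.update(flags)
    else:
        raise ValueError("method must be 'varimax' or 'promax'")
    solution.method = method
    solution.rotated_explained_pct = 100.0 * ss / solution.total_variance
    _sign_fix(solution)
    return solution


def select_components(solution: FactorSolution, min_variance_pct: float = 1.5) -> list[int]:
    """Indices of components whose rotated variance share meets the cutoff,
    in descending-variance order.  An empty selection is allowed (flagged)."""
    pct = solution.active_explained_pct
    idx = [int(i) for i in np.argsort(pct)[::-1] if pct[i] >= min_variance_pct]
    solution.flags["empty_selection"] = len(idx) == 0
    return idx


def component_amplitude(solution: FactorSolution, components: list[int],
                        case_meta: pd.DataFrame | None = None,
                        mode: str = "mean_amplitude") -> pd.DataFrame:
    """Per-participant global mean component amplitudes in microvolts.

    For each case the component amplitude is the standardized factor score
    times the scaled loading at the component's peak variable (the signed
    value at the loading's absolute maximum -- identical for both modes once
    the peak-positive sign convention is applied).  Per participant the
    global mean is taken over channels (and any further metadata columns).

    Returns a DataFrame indexed by participant with one column per component,
    named by the component's peak variable.
    """
    if mode not in ("mean_amplitude", "peak_amplitude"):
        raise ValueError("mode must be 'mean_amplitude' or 'peak_amplitude'")
    meta = case_meta if case_meta is not None else solution.case_meta
    if meta is None:
        raise ValueError("case metadata with a 'participant' column is required")
    L = solution.active_loadings
    F = solution.active_scores
    k = L.shape[1]
    cols = {}
    for c in components:
        if not 0 <= c < k:
            raise ValueError(f"unknown component index {c}")
        peak = int(np.argmax(np.abs(L[:, c])))
        name = f"comp_{solution.variable_values[peak]:g}"
        while name in cols:  # two components peaking at the same variable
            name += "b"
        cols[name] = F[:, c] * L[peak, c]
    df = pd.DataFrame(cols)
    df["participant"] = meta["participant"].to_numpy()
    return df.groupby("participant").mean()
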
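"""Constrained pink + white noise decomposition of EEG power spectra.

The model: observed prestimulus power at integer frequency f is

    S(f) = p / f  +  w  +  osc(f),      osc(f) >= 0,

with pink noise power exactly proportional to 1/f and white noise flat.  The
fit returns the (p, w) that maximize the total extracted noise power over the
2-24 Hz fit range subject to p >= 0, w >= 0 and p/f + w <= S(f) at every bin
-- i.e. the *maximal* noise consistent with non-negative oscillation power
everywhere in the range.  With x = 1/f this is a two-variable linear program
whose optimum lies at a vertex of the feasible polygon; vertices are
enumerated exactly (every line through two spectrum points in (x, S) space,
plus the axis-aligned candidates), so no iterative solver is involved.

The non-negativity constraint is the point of the construction: a free-
exponent aperiodic fit (provided as :func:`aperiodic_baseline_demo`) can
exceed the observed power at some frequencies and then yields physically
impossible negative oscillation power after subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseFit",
    "fit_pink_white",
    "extend_noise",
    "subtract_noise",
    "aperiodic_baseline_demo",
]

_FEAS_EPS = 1e-9


@dataclass
class NoiseFit:
    """Result of the constrained pink/white fit on one power spectrum."""

    pink_coeff: float  # p: pink power at 1 Hz (uV^2); PN power at f is p/f
    white_level: float  # w: white power per bin (uV^2)
    fit_freqs: np.ndarray  # integer bins the fit used
    residuals: np.ndarray  # S(f) - p/f - w on the fit range
    support: np.ndarray  # bins where the residual is numerically zero
    objective: float  # total extracted noise power over the fit range

    @property
    def pink_amplitude_at_1hz(self) -> float:
        return float(np.sqrt(self.pink_coeff))

    @property
    def white_amplitude(self) -> float:
        return float(np.sqrt(self.white_level))


def _fit_range(freqs: np.ndarray, power: np.ndarray, fit_lo: float, fit_hi: float):
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    sel = (freqs >= fit_lo - 1e-9) & (freqs <= fit_hi + 1e-9)
    f = freqs[sel]
    s = power[sel]
    if f.size == 0:
        raise ValueError("empty fit range")
    if np.any(s < 0):
        raise ValueError("power spectrum must be non-negative on the fit range")
    if np.any(f <= 0):
        raise ValueError("fit range must exclude 0 Hz (1/f undefined)")
    return f, s


def fit_pink_white(power: np.ndarray, freqs: np.ndarray | None = None,
                   fit_lo: float = 2.0, fit_hi: float = 24.0) -> NoiseFit:
    """Maximal-valid-noise fit of p/f + w to a power spectrum.

    ``power`` holds per-bin power (uV^2); ``freqs`` defaults to 0..len-1 Hz.
    Solves ``max p * sum(1/f) + w * m  s.t.  p, w >= 0, p/f + w <= S(f)``
    by exact vertex enumeration.  Ties in the objective are broken toward the
    larger white level.
    """
    if freqs is None:
        freqs = np.arange(len(power), dtype=float)
    f, s = _fit_range(freqs, power, fit_lo, fit_hi)
    x = 1.0 / f
    m = f.size
    sum_x = x.sum()
    scale = max(float(s.max()), 1.0)
    atol = _FEAS_EPS * scale

    # candidate vertices
    cand_p = [0.0, float(np.min(s * f))]
    cand_w = [float(np.min(s)), 0.0]
    if m >= 2:
        i, j = np.triu_indices(m, k=1)
        dx = x[i] - x[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            p_ij = (s[i] - s[j]) / dx
        w_ij = s[i] - p_ij * x[i]
        ok = np.isfinite(p_ij)
        cand_p += list(p_ij[ok])
        cand_w += list(w_ij[ok])
    cand_p = np.asarray(cand_p)
    cand_w = np.asarray(cand_w)

    # clip tiny negatives, then enforce feasibility against every constraint
    cand_p = np.where((cand_p < 0) & (cand_p > -atol), 0.0, cand_p)
    cand_w = np.where((cand_w < 0) & (cand_w > -atol), 0.0, cand_w)
    nonneg = (cand_p >= 0) & (cand_w >= 0)
    slack = s[None, :] - cand_p[:, None] * x[None, :] - cand_w[:, None]
    feasible = nonneg & (slack.min(axis=1) >= -atol)
    if not np.any(feasible):  # all-zero spectrum etc.
        cand_p, cand_w = np.array([0.0]), np.array([0.0])
        feasible = np.array([True])
    cand_p, cand_w = cand_p[feasible], cand_w[feasible]

    obj = cand_p * sum_x + cand_w * m
    best = obj.max()
    tied = obj >= best - 1e-12 * max(best, 1.0)
    k = np.flatnonzero(tied)[np.argmax(cand_w[tied])]
    p, w = float(cand_p[k]), float(cand_w[k])

    resid = s - p * x - w
    support = f[np.abs(resid) <= max(atol, 1e-12)]
    return NoiseFit(pink_coeff=p, white_level=w, fit_freqs=f,
                    residuals=resid, support=support,
                    objective=float(p * sum_x + w * m))


def extend_noise(fit: NoiseFit, lo: float = 1.0, hi: float = 30.0):
    """Evaluate the fitted PN and WN spectra on integer bins [lo, hi].

    Returns ``(freqs, pn_power, wn_power)``; amplitudes are the square roots.
    """
    if lo < 1:
        raise ValueError("extension must start at >= 1 Hz (1/f undefined at 0)")
    freqs = np.arange(np.ceil(lo), np.floor(hi) + 1, dtype=float)
    pn = fit.pink_coeff / freqs
    wn = np.full_like(freqs, fit.white_level)
    return freqs, pn, wn


def subtract_noise(observed_amplitude: np.ndarray, fit: NoiseFit,
                   freqs: np.ndarray | None = None,
                   domain: str = "power"):
    """Remove the fitted noise from an observed amplitude spectrum.

    In the default power domain the oscillation power is
    ``max(S^2 - p/f - w, 0)`` and the oscillation amplitude its square root.
    Inside the fit range the clipping can only absorb numerical epsilon (the
    fit guarantees non-negative residuals there); outside it (1 Hz and above
    the fit ceiling) clipping may genuinely activate and clipped bins are
    counted.  Bins at 0 Hz (or below 1 Hz) are returned as zero.

    Returns ``(osc_amplitude, n_clipped_outside)``.
    """
    obs = np.asarray(observed_amplitude, float)
    if freqs is None:
        freqs = np.arange(len(obs), dtype=float)
    freqs = np.asarray(freqs, float)
    if freqs.shape != obs.shape:
        raise ValueError("freqs and observed spectrum must align")
    if domain not in ("power", "amplitude"):
        raise ValueError("domain must be 'power' or 'amplitude'")

    in_fit = (freqs >= fit.fit_freqs.min() - 1e-9) & (freqs <= fit.fit_freqs.max() + 1e-9)
    usable = freqs >= 1.0 - 1e-9
    noise_power = np.zeros_like(obs)
    noise_power[usable] = fit.pink_coeff / freqs[usable] + fit.white_level

    if domain == "power":
        raw = obs**2 - noise_power
        osc = np.sqrt(np.clip(raw, 0.0, None))
    else:
        raw = obs - np.sqrt(noise_power)
        osc = np.clip(raw, 0.0, None)
    osc[~usable] = 0.0
    clip_tol = _FEAS_EPS * max(float(np.max(obs**2, initial=0.0)), 1.0)
    clipped = usable & (raw < -clip_tol)
    n_clipped_outside = int(np.sum(clipped & ~in_fit))
    return osc, n_clipped_outside


def aperiodic_baseline_demo(power: np.ndarray, freqs: np.ndarray | None = None,
                            fit_lo: float = 2.0, fit_hi: float = 24.0):
    """Unconstrained near-pink baseline fit and its negative-residual count.

    Fits ``log S = log a - chi * log f`` by ordinary least squares over the
    fit range (a free aperiodic exponent, no validity constraint) and
    subtracts it from the observed power.  Returns
    ``(a, chi, n_negative_bins, residuals)``.  On bump-dominated spectra the
    baseline exceeds the observation at some bins, which is exactly the
    negative-oscillation pathology the constrained fit is built to avoid.
    """
    if freqs is None:
        freqs = np.arange(len(power), dtype=float)
    f, s = _fit_range(freqs, power, fit_lo, fit_hi)
    pos = s > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive bins for the log-log fit")
    coef = np.polyfit(np.log(f[pos]), np.log(s[pos]), 1)
    chi = -float(coef[0])
    a = float(np.exp(coef[1]))
    baseline = a * f ** (-chi)
    resid = s - baseline
    tol = _FEAS_EPS * max(float(s.max()), 1.0)
    n_negative = int(np.sum(resid < -tol))
    return a, chi, n_negative, resid
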
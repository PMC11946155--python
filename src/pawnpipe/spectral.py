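"""Single-sided amplitude spectra of prestimulus epochs at 1-Hz resolution.

Each 500-sample prestimulus segment is de-meaned, tapered with a 10%
split-cosine-bell window, zero-padded to 1000 points and Fourier-transformed;
amplitudes are corrected for the original (unpadded) length and for the
taper's coherent gain, so a pure integer-Hz tone of amplitude A recovers A at
its bin.  Spectra are averaged on the amplitude (uV) scale within
participant, channel and condition, and the Go/No-Go means are pooled for the
noise fit.

Calibration notes
-----------------
For *tones* the correction above is exact.  For *Gaussian broadband noise*
two extra factors relate a mean amplitude bin to the underlying one-sided PSD:
the equivalent noise bandwidth of the window (bin width times
``mean(w^2)/mean(w)^2``), and the Rayleigh factor pi/4 incurred by averaging
amplitudes rather than powers across epochs.  :func:`noise_psd_from_mean_amplitude`
applies both, and is what parameter-recovery studies use to compare fitted
noise levels with generator ground truth.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "taper_window",
    "coherent_gain",
    "enbw_hz",
    "amplitude_spectrum",
    "mean_spectra",
    "pooled_spectrum",
    "noise_psd_from_mean_amplitude",
]


def taper_window(n: int, taper_fraction: float = 0.10) -> np.ndarray:
    """Split-cosine-bell window: cosine ramps over n*fraction/2 samples per end.

    Ramp samples follow ``0.5 * (1 - cos(pi * (i + 0.5) / m))`` (midpoint
    sampling), which makes the window mean exactly ``1 - fraction/2`` when
    ``n * fraction / 2`` is an integer.  ``taper_fraction = 1`` gives a full
    Hanning-type window.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < taper_fraction <= 1:
        raise ValueError("taper_fraction must lie in (0, 1]")
    m = int(round(n * taper_fraction / 2.0))
    w = np.ones(n)
    if m > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def coherent_gain(n: int, taper_fraction: float = 0.10) -> float:
    return float(taper_window(n, taper_fraction).mean())


def enbw_hz(n: int, fs: float, taper_fraction: float = 0.10) -> float:
    """Equivalent noise bandwidth of the taper in Hz (includes the fs/n bin width)."""
    w = taper_window(n, taper_fraction)
    return fs * float(np.sum(w**2)) / float(np.sum(w)) ** 2


def amplitude_spectrum(x: np.ndarray, fs: float = 1000.0, pad_to: int = 1000,
                       taper_fraction: float = 0.10, fmax_hz: float = 30.0,
                       image_correction: bool = True):
    """Corrected single-sided amplitude spectrum of the trailing axis.

    Returns ``(freqs, amplitudes)`` with bin spacing ``fs / pad_to`` and bins
    kept up to ``fmax_hz`` inclusive.  The base correction divides
    ``2|X[k]|`` by the original (unpadded) length ``n`` (the zero-padding
    correction) and by the taper's coherent gain.  The mean is removed before
    tapering, so DC content is discarded.

    With ``image_correction`` (default) the negative-frequency image leaking
    through the taper's transform is removed exactly: a real tone at bin k
    contributes ``X[k] = (z W(0) + conj(z) W(2 f_k)) / 2`` with ``z`` the
    complex tone amplitude and ``W`` the taper transform, so ``|z|`` is
    recovered by inverting that R-linear map.  This makes integer-Hz tone
    calibration exact irrespective of phase; for broadband noise the change
    is second order in ``W(2f_k)/W(0)`` (below 0.1%).
    """
    x = np.asarray(x, float)
    n = x.shape[-1]
    if n > pad_to:
        raise ValueError("epoch longer than pad_to")
    if n < 4:
        raise ValueError("epoch too short")
    w = taper_window(n, taper_fraction)
    xc = x - x.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(xc * w, n=pad_to, axis=-1)
    freqs = np.fft.rfftfreq(pad_to, 1.0 / fs)
    keep = freqs <= fmax_hz + 1e-9
    Xk = X[..., keep]
    n_keep = int(keep.sum())
    w0 = float(w.sum())
    if image_correction:
        # taper transform at twice each retained bin frequency
        Wfull = np.fft.fft(w, n=pad_to)
        idx2 = (2 * np.arange(n_keep)) % pad_to
        W2 = Wfull[idx2]
        denom = w0**2 - np.abs(W2) ** 2
        denom[0] = 1.0  # DC handled separately below
        z = 2.0 * (w0 * Xk - W2 * np.conj(Xk)) / denom
        amp = np.abs(z)
        amp[..., 0] = np.abs(Xk[..., 0]) / w0  # DC: zeroed epochs anyway
    else:
        cg = w0 / n
        amp = np.abs(Xk) / n
        amp[..., 1:] *= 2.0
        amp /= cg
    return freqs[keep], amp


def mean_spectra(spectra: np.ndarray, axis: int = 0) -> np.ndarray:
    """Arithmetic mean of amplitude spectra along ``axis`` (e.g. over epochs)."""
    spectra = np.asarray(spectra, float)
    if spectra.shape[axis] == 0:
        raise ValueError("cannot average an empty set of spectra")
    return spectra.mean(axis=axis)


def pooled_spectrum(go_mean: np.ndarray, nogo_mean: np.ndarray) -> np.ndarray:
    """Pooled condition spectrum: mean of the Go-mean and No-Go-mean spectra."""
    return 0.5 * (np.asarray(go_mean, float) + np.asarray(nogo_mean, float))


def expected_mean_amplitude(freqs_out: np.ndarray, psd_freqs: np.ndarray,
                            psd: np.ndarray, n: int, fs: float,
                            taper_fraction: float = 0.10) -> np.ndarray:
    """Expected epoch-averaged amplitude bins for a Gaussian process.

    Propagates a one-sided PSD (given on the fine grid ``psd_freqs``)
    through the windowed, padded DFT: the bin power is the PSD convolved
    with the taper's power kernel ``(|W(f_k - f)|^2 + |W(f_k + f)|^2) / 2``,
    and averaging amplitudes across epochs contributes the Rayleigh factor
    ``sqrt(pi / 4)``.  This is the correct oracle for narrowband processes,
    for which spectral leakage visibly smears the raw PSD.
    """
    freqs_out = np.asarray(freqs_out, float)
    psd_freqs = np.asarray(psd_freqs, float)
    psd = np.asarray(psd, float)
    w = taper_window(n, taper_fraction)
    cg = w.mean()
    t = np.arange(n) / fs
    df = np.gradient(psd_freqs)
    out = np.empty_like(freqs_out)
    for i, fk in enumerate(freqs_out):
        wm = np.abs(np.exp(-2j * np.pi * (fk - psd_freqs)[:, None] * t[None, :]) @ w) ** 2
        wp = np.abs(np.exp(-2j * np.pi * (fk + psd_freqs)[:, None] * t[None, :]) @ w) ** 2
        e_x2 = np.sum(psd * 0.5 * (wm + wp) * df)
        out[i] = np.sqrt((np.pi / 4.0) * (4.0 / (n**2 * cg**2)) * e_x2)
    return out


def noise_psd_from_mean_amplitude(amp: np.ndarray, n: int, fs: float,
                                  taper_fraction: float = 0.10) -> np.ndarray:
    """Convert epoch-averaged amplitude bins of Gaussian noise to PSD (uV^2/Hz).

    ``(mean amplitude)^2`` underestimates mean power by pi/4 for Rayleigh-
    distributed bin amplitudes, and a power bin integrates the PSD over the
    window's equivalent noise bandwidth (times 2 for the single-sided
    amplitude convention), hence::

        PSD = amp^2 * (4 / pi) / (2 * ENBW)
    """
    amp = np.asarray(amp, float)
    return amp**2 * (4.0 / np.pi) / (2.0 * enbw_hz(n, fs, taper_fraction))
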
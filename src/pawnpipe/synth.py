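"""Synthetic multichannel EEG sessions for an equiprobable auditory Go/No-Go task.

Every downstream stage of the pipeline (filtering, epoching, spectral
estimation, pink/white-noise fitting, component PCA, behaviour, linkage
regression) is exercised against recordings produced here, so the generator
carries an explicit ground truth: per-channel pink-noise (power ~ 1/f) and
white-noise (flat power) levels, a set of band-limited oscillations, a set of
Gaussian-windowed ERP deflections inserted at stimulus onsets, behavioural
rates, and a list of couplings that tie single-trial prestimulus amplitudes to
single-trial ERP template scale.

The signal model is additive::

    x_c(t) = sum_b w_bc s_b(t)  +  pink_c(t)  +  white_c(t)  +  ERP_c(t)

where ``s_b`` is a band-limited Gaussian process (narrowband-shaped noise with
a slowly varying envelope), and pink/white noise are independent per channel.
All randomness derives from a single master seed through a documented
derivation scheme, so sessions and cohorts are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_NAMES_30",
    "SessionConfig",
    "OscillationBand",
    "ErpComponent",
    "Coupling",
    "GroundTruth",
    "Recording",
    "Session",
    "CohortConfig",
    "derive_rng",
    "generate_pink_noise",
    "generate_white_noise",
    "generate_band_noise",
    "generate_events",
    "generate_session",
    "participant_truth",
    "coupling_reference",
    "generate_cohort",
    "default_ground_truth",
    "expected_noise_psd",
    "expected_oscillation_psd",
    "generate_oscillation_spectra",
    "generate_erp_case_matrix",
]

#: The 30 scalp sites of a standard extended 10-20 montage, in the usual
#: anterior-to-posterior order.
CHANNEL_NAMES_30 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz",
    "FC4", "FT8", "T7", "C3", "Cz", "C4", "T8", "TP7", "CP3", "CPz",
    "CP4", "TP8", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]


# --------------------------------------------------------------------------
# seed derivation
# --------------------------------------------------------------------------

def _key_code(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode()) & 0x7FFFFFFF


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """Derive an independent generator from ``master_seed`` and a key path.

    Keys may be ints (e.g. a participant index) or short strings naming a
    stage ("pink", "events", ...).  The same (seed, keys) pair always yields
    the same stream, and distinct key paths yield statistically independent
    streams via :class:`numpy.random.SeedSequence`.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_code(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# configuration / ground truth types
# --------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Task-structure parameters of one recording session."""

    n_channels: int = 30
    fs: float = 1000.0
    soa_ms: float = 1100.0
    n_go_per_block: int = 75
    n_nogo_per_block: int = 75
    n_blocks: int = 2
    lead_in_s: float = 2.0
    block_gap_s: float = 3.0
    tail_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        soa_samples = self.soa_ms * self.fs / 1000.0
        if abs(soa_samples - round(soa_samples)) > 1e-9:
            raise ValueError("soa_ms * fs must be an integer number of samples")
        for name in ("n_channels", "n_go_per_block", "n_nogo_per_block", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa_ms * self.fs / 1000.0))

    @property
    def trials_per_block(self) -> int:
        return self.n_go_per_block + self.n_nogo_per_block

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.n_blocks

    @property
    def n_samples(self) -> int:
        block = self.trials_per_block * self.soa_samples
        total_s = self.lead_in_s + self.tail_s + self.block_gap_s * (self.n_blocks - 1)
        return int(round(total_s * self.fs)) + block * self.n_blocks

    def channel_names(self) -> list[str]:
        if self.n_channels == 30:
            return list(CHANNEL_NAMES_30)
        return [f"ch{i + 1:02d}" for i in range(self.n_channels)]


@dataclass
class OscillationBand:
    """A band-limited oscillation: Gaussian spectral profile, per-channel weights.

    ``bandwidth_hz`` is the full width at half maximum of the spectral
    envelope; ``rms_uv`` is the RMS amplitude of the unit-topography source.
    """

    name: str
    centre_hz: float
    bandwidth_hz: float
    rms_uv: float
    topography: np.ndarray | None = None

    def __post_init__(self):
        if self.rms_uv < 0:
            raise ValueError("rms_uv must be >= 0")


@dataclass
class ErpComponent:
    """One Gaussian-windowed ERP deflection inserted at stimulus onset."""

    name: str
    condition: str  # 'go' | 'nogo'
    latency_ms: float
    width_ms: float  # FWHM of the Gaussian envelope
    amplitude_uv: float  # peak magnitude, >= 0
    polarity: int  # +1 or -1
    topography: np.ndarray | None = None

    def __post_init__(self):
        if self.amplitude_uv < 0:
            raise ValueError("amplitude_uv must be >= 0")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.condition not in ("go", "nogo"):
            raise ValueError("condition must be 'go' or 'nogo'")


@dataclass
class Coupling:
    """Link between a prestimulus source and an ERP component amplitude.

    ``source`` is an oscillation band name or ``"pink"``.  ``sign`` is the
    sign of the induced dependence of the *signed* ERP amplitude on the
    source; for a negative-polarity component a negative sign therefore means
    "larger source -> more negative (larger magnitude) deflection".
    """

    source: str
    target: str  # ERP component name
    target_condition: str  # 'go' | 'nogo'
    sign: int
    strength: float

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("coupling sign must be +1 or -1")


@dataclass
class GroundTruth:
    """Complete generative description of one participant's session."""

    pink_power_at_1hz: np.ndarray  # uV^2/Hz per channel
    white_power: np.ndarray  # uV^2/Hz per channel
    bands: list[OscillationBand] = field(default_factory=list)
    erp_components: list[ErpComponent] = field(default_factory=list)
    couplings: list[Coupling] = field(default_factory=list)
    rt_mean_ms: float = 340.0
    rt_sd_ms: float = 80.0
    omission_rate: float = 0.04
    commission_rate: float = 0.06

    def __post_init__(self):
        self.pink_power_at_1hz = np.atleast_1d(np.asarray(self.pink_power_at_1hz, float))
        self.white_power = np.atleast_1d(np.asarray(self.white_power, float))
        if np.any(self.pink_power_at_1hz < 0) or np.any(self.white_power < 0):
            raise ValueError("noise powers must be >= 0")
        for r in (self.omission_rate, self.commission_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        names = {b.name for b in self.bands} | {"pink"}
        comps = {(c.condition, c.name) for c in self.erp_components}
        for cp in self.couplings:
            if cp.source not in names:
                raise ValueError(f"coupling source {cp.source!r} names no band")
            if (cp.target_condition, cp.target) not in comps:
                raise ValueError(
                    f"coupling target {cp.target_condition}/{cp.target!r} names no ERP component"
                )

    def band(self, name: str) -> OscillationBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class Recording:
    """Continuous multichannel voltage data (channels x samples, uV)."""

    data: np.ndarray
    fs: float
    channel_names: list[str]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Session:
    """A generated session: recording, event table, truth, and internals.

    ``internals`` exposes generator-side quantities used by recovery tests:
    per-trial standardized source amplitudes and per-trial ERP template
    scales.  ``parts`` (if requested) holds the additive signal constituents.
    """

    recording: Recording
    events: pd.DataFrame
    truth: GroundTruth
    config: SessionConfig
    internals: dict = field(default_factory=dict)
    parts: dict | None = None


@dataclass
class CohortConfig:
    """Cohort of synthetic participants; one participant = one session."""

    n_participants: int = 47
    jitter_sigma: float = 0.2  # SD of log-normal amplitude jitter (log scale)
    session: SessionConfig = field(default_factory=SessionConfig)


# --------------------------------------------------------------------------
# elementary noise generators
# --------------------------------------------------------------------------

def generate_pink_noise(n_samples: int, fs: float, power_at_1hz, seed) -> np.ndarray:
    """Zero-mean pink noise with one-sided PSD ``power_at_1hz / f``.

    Synthesis is by frequency-domain shaping: spectral amplitude proportional
    to f**-0.5 with independent uniform random phases, followed by an inverse
    real FFT.  ``power_at_1hz`` may be a scalar or a per-channel vector; the
    result is (n_samples,) or (n_channels, n_samples).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    power = np.atleast_1d(np.asarray(power_at_1hz, float))
    if np.any(power < 0):
        raise ValueError("power_at_1hz must be >= 0")
    scalar = np.isscalar(power_at_1hz) or np.ndim(power_at_1hz) == 0
    rng = _as_rng(seed)

    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mag = np.zeros_like(freqs)
    mag[1:] = np.sqrt(fs * n_samples / (2.0 * freqs[1:]))  # unit power_at_1hz
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(power.size, freqs.size))
    spec = mag[None, :] * np.exp(1j * phases)
    spec[:, 0] = 0.0
    if n_samples % 2 == 0:
        spec[:, -1] = 0.0  # drop the (negligible) Nyquist term to keep x real
    x = np.fft.irfft(spec, n=n_samples, axis=1) * np.sqrt(power)[:, None]
    return x[0] if scalar else x


def generate_white_noise(n_samples: int, fs: float, power, seed) -> np.ndarray:
    """White noise with one-sided PSD ``power`` (variance = power * fs / 2)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = np.atleast_1d(np.asarray(power, float))
    if np.any(p < 0):
        raise ValueError("power must be >= 0")
    scalar = np.isscalar(power) or np.ndim(power) == 0
    rng = _as_rng(seed)
    sd = np.sqrt(p * fs / 2.0)
    x = rng.standard_normal((p.size, n_samples)) * sd[:, None]
    return x[0] if scalar else x


def generate_band_noise(
    n_samples: int, fs: float, centre_hz: float, bandwidth_hz: float, rms_uv: float, seed
) -> np.ndarray:
    """Band-limited Gaussian process with Gaussian spectral envelope.

    The one-sided PSD is ``rms_uv**2 * g(f) / integral(g)`` with
    ``g(f) = exp(-(f - centre)^2 / (2 sigma^2))`` and
    ``sigma = bandwidth / 2.3548`` (FWHM convention), so the total variance is
    ``rms_uv**2``.  Spectral coefficients are complex Gaussian, which yields
    the slowly varying random envelope characteristic of narrowband EEG.
    """
    if rms_uv < 0:
        raise ValueError("rms_uv must be >= 0")
    rng = _as_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    sigma = bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-0.5 * ((freqs - centre_hz) / sigma) ** 2)
    df = fs / n_samples
    denom = g.sum() * df
    if denom <= 0:
        return np.zeros(n_samples)
    psd = rms_uv**2 * g / denom
    scale = np.sqrt(psd * fs * n_samples / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spec = scale * z / np.sqrt(2.0)
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n=n_samples)


# --------------------------------------------------------------------------
# expected spectra (ground truth for spectral-domain checks)
# --------------------------------------------------------------------------

def expected_noise_psd(truth: GroundTruth, freqs: np.ndarray) -> np.ndarray:
    """Channel-mean one-sided noise PSD p/f + w at ``freqs`` (uV^2/Hz)."""
    freqs = np.asarray(freqs, float)
    p = float(np.mean(truth.pink_power_at_1hz))
    w = float(np.mean(truth.white_power))
    out = np.full_like(freqs, w, dtype=float)
    nz = freqs > 0
    out[nz] += p / freqs[nz]
    return out


def expected_oscillation_psd(truth: GroundTruth, freqs: np.ndarray,
                             channel: int | None = None) -> np.ndarray:
    """One-sided PSD contributed by the oscillation bands at ``freqs``."""
    freqs = np.asarray(freqs, float)
    out = np.zeros_like(freqs, dtype=float)
    for b in truth.bands:
        sigma = b.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        g = np.exp(-0.5 * ((freqs - b.centre_hz) / sigma) ** 2)
        # normalisation matches generate_band_noise on a long record
        norm = sigma * np.sqrt(2.0 * np.pi)
        if b.topography is None:
            wgt = 1.0
        else:
            topo = np.atleast_1d(b.topography)
            wgt = float(topo[channel] ** 2) if channel is not None else float(np.mean(topo**2))
        out += wgt * b.rms_uv**2 * g / norm
    return out


# --------------------------------------------------------------------------
# event table / behaviour
# --------------------------------------------------------------------------

def generate_events(config: SessionConfig, truth: GroundTruth, rng) -> pd.DataFrame:
    """Shuffled Go/No-Go stimulus sequence with responses.

    Returns a frame with one row per stimulus: ``onset_sample``, ``code``
    ('go'/'nogo'), ``rt_ms`` (NaN when no press occurred) and ``block``.
    Go RTs are normal(rt_mean, rt_sd) truncated to [100, 1000] ms; omissions
    and No-Go commissions occur independently at the configured rates.
    """
    rng = _as_rng(rng)
    fs, soa = config.fs, config.soa_samples
    rows = []
    block_len = config.trials_per_block * soa
    for b in range(config.n_blocks):
        codes = np.array(["go"] * config.n_go_per_block + ["nogo"] * config.n_nogo_per_block)
        rng.shuffle(codes)
        start = int(round(config.lead_in_s * fs)) + b * (block_len + int(round(config.block_gap_s * fs)))
        for k, code in enumerate(codes):
            rows.append((start + k * soa, code, b))
    ev = pd.DataFrame(rows, columns=["onset_sample", "code", "block"])

    def _draw_rt(n):
        # normal truncated to [100, 1000] ms by rejection
        out = np.empty(n)
        remaining = np.arange(n)
        while remaining.size:
            draw = rng.normal(truth.rt_mean_ms, truth.rt_sd_ms, remaining.size)
            ok = (draw >= 100.0) & (draw <= 1000.0)
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        return out

    rt = np.full(len(ev), np.nan)
    is_go = (ev["code"] == "go").to_numpy()
    n_go = int(is_go.sum())
    responded = rng.random(n_go) >= truth.omission_rate
    go_rt = np.full(n_go, np.nan)
    go_rt[responded] = _draw_rt(int(responded.sum()))
    rt[is_go] = go_rt
    n_nogo = int((~is_go).sum())
    commit = rng.random(n_nogo) < truth.commission_rate
    nogo_rt = np.full(n_nogo, np.nan)
    nogo_rt[commit] = _draw_rt(int(commit.sum()))
    rt[~is_go] = nogo_rt
    ev["rt_ms"] = rt
    return ev


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------

def _default_topography(n_channels: int, centre_frac: float, spread: float = 0.30,
                        floor: float = 0.4) -> np.ndarray:
    """Smooth positive per-channel weight profile (stand-in for scalp maps)."""
    idx = np.arange(n_channels)
    c = centre_frac * max(n_channels - 1, 1)
    w = floor + (1.0 - floor) * np.exp(-0.5 * ((idx - c) / (spread * max(n_channels, 1))) ** 2)
    return w


def _band_topo(b: OscillationBand, n_channels: int) -> np.ndarray:
    if b.topography is not None:
        topo = np.atleast_1d(np.asarray(b.topography, float))
        if topo.size != n_channels:
            raise ValueError(f"band {b.name}: topography length != n_channels")
        return topo
    return np.ones(n_channels)

def _erp_topo(c: ErpComponent, n_channels: int) -> np.ndarray:
    if c.topography is not None:
        topo = np.atleast_1d(np.asarray(c.topography, float))
        if topo.size != n_channels:
            raise ValueError(f"component {c.name}: topography length != n_channels")
        return topo
    return np.ones(n_channels)


def _erp_template(comp: ErpComponent, fs: float) -> tuple[np.ndarray, int]:
    """Gaussian deflection sampled from latency - 4 sigma to latency + 4 sigma.

    Returns (waveform with unit peak, offset in samples from stimulus onset).
    """
    sigma_ms = comp.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t0 = comp.latency_ms - 4.0 * sigma_ms
    t1 = comp.latency_ms + 4.0 * sigma_ms
    n0 = int(np.floor(t0 * fs / 1000.0))
    n1 = int(np.ceil(t1 * fs / 1000.0))
    t = np.arange(n0, n1 + 1) * 1000.0 / fs
    wave = np.exp(-0.5 * ((t - comp.latency_ms) / sigma_ms) ** 2)
    return wave, n0


def _trial_source_amplitudes(session_sources: dict, pink: np.ndarray,
                             onsets: np.ndarray, pre_samples: int) -> dict:
    """Per-trial RMS amplitude of each coupling source on [-pre, 0) windows."""
    out = {}
    for name, series in session_sources.items():
        segs = np.stack([series[o - pre_samples:o] for o in onsets])
        out[name] = np.sqrt(np.mean(segs**2, axis=1))
    segs = np.stack([pink[:, o - pre_samples:o] for o in onsets])  # trials x ch x t
    out["pink"] = np.sqrt(np.mean(segs**2, axis=(1, 2)))
    return out


def generate_session(config: SessionConfig, truth: GroundTruth, seed: int | None = None,
                     coupling_reference: dict | None = None,
                     keep_parts: bool = False) -> Session:
    """Generate one complete session.

    The recording is the sample-for-sample sum of band oscillations, pink
    noise, white noise, and stimulus-locked ERP templates.  For every
    coupling, the template amplitude of the target component on trial k is
    scaled by ``1 + sign * polarity * strength * z_k`` where ``z_k`` is the
    standardized prestimulus amplitude of the source on that trial (the
    ``polarity`` factor makes ``sign`` the sign of the induced dependence of
    the signed component amplitude).  ``coupling_reference`` supplies the
    standardization constants ``{source: (mean, sd)}``; cohort-level
    references (see :func:`coupling_reference`) make couplings operate across
    participants as well as across trials.  Without a reference, sources are
    standardized within the session.
    """
    if seed is None:
        seed = config.seed
    C = config.n_channels
    if truth.pink_power_at_1hz.size == 1:
        truth = replace(truth, pink_power_at_1hz=np.full(C, float(truth.pink_power_at_1hz[0])))
    if truth.white_power.size == 1:
        truth = replace(truth, white_power=np.full(C, float(truth.white_power[0])))
    if truth.pink_power_at_1hz.size != C or truth.white_power.size != C:
        raise ValueError("noise power vectors must match n_channels")
    n = config.n_samples

    pink = generate_pink_noise(n, config.fs, truth.pink_power_at_1hz, derive_rng(seed, "pink"))
    white = generate_white_noise(n, config.fs, truth.white_power, derive_rng(seed, "white"))
    pink = np.atleast_2d(pink)
    white = np.atleast_2d(white)

    osc = np.zeros((C, n))
    sources: dict[str, np.ndarray] = {}
    for b in truth.bands:
        src = generate_band_noise(n, config.fs, b.centre_hz, b.bandwidth_hz, 1.0,
                                  derive_rng(seed, "band", b.name))
        topo = _band_topo(b, C)
        osc += np.outer(topo * b.rms_uv, src)
        sources[b.name] = src * b.rms_uv

    events = generate_events(config, truth, derive_rng(seed, "events"))
    onsets = events["onset_sample"].to_numpy()

    pre = int(round(0.5 * config.fs))
    amps = _trial_source_amplitudes(sources, pink, onsets, pre)
    zscores = {}
    for name, a in amps.items():
        if coupling_reference is not None and name in coupling_reference:
            mu, sd = coupling_reference[name]
        else:
            mu, sd = float(np.mean(a)), float(np.std(a))
        zscores[name] = (a - mu) / sd if sd > 0 else np.zeros_like(a)

    # per-trial, per-component template scales
    comp_scales = {}
    for comp in truth.erp_components:
        scale = np.ones(len(events))
        for cp in truth.couplings:
            if cp.target == comp.name and cp.target_condition == comp.condition:
                scale = scale + cp.sign * comp.polarity * cp.strength * zscores[cp.source]
        comp_scales[(comp.condition, comp.name)] = scale

    erp = np.zeros((C, n))
    codes = events["code"].to_numpy()
    for comp in truth.erp_components:
        wave, n0 = _erp_template(comp, config.fs)
        topo = _erp_topo(comp, C)
        amp_vec = comp.amplitude_uv * comp.polarity * topo
        scale = comp_scales[(comp.condition, comp.name)]
        for k, onset in enumerate(onsets):
            if codes[k] != comp.condition:
                continue
            lo = onset + n0
            hi = lo + wave.size
            if lo < 0 or hi > n:
                continue
            erp[:, lo:hi] += np.outer(amp_vec * scale[k], wave)

    data = osc + pink + white + erp
    rec = Recording(data=data, fs=config.fs, channel_names=config.channel_names())
    internals = {
        "source_amplitudes": amps,
        "source_z": zscores,
        "component_scales": comp_scales,
    }
    parts = None
    if keep_parts:
        parts = {"oscillations": osc, "pink": pink, "white": white, "erp": erp}
    return Session(recording=rec, events=events, truth=truth, config=config,
                   internals=internals, parts=parts)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _lognormal_scale(rng, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma)))


def participant_truth(base: GroundTruth, rng, jitter_sigma: float = 0.2) -> GroundTruth:
    """Per-participant ground truth: log-normal jitter on all amplitudes.

    Amplitude-like quantities (band RMS, ERP peak) are multiplied by
    independent log-normal factors with median 1; power-like quantities (pink
    and white levels) by the squared factor, so that amplitude jitter is
    log-normal(0, sigma) throughout.
    """
    rng = _as_rng(rng)
    pink = base.pink_power_at_1hz * _lognormal_scale(rng, jitter_sigma) ** 2
    white = base.white_power * _lognormal_scale(rng, jitter_sigma) ** 2
    bands = [replace(b, rms_uv=b.rms_uv * _lognormal_scale(rng, jitter_sigma))
             for b in base.bands]
    comps = [replace(c, amplitude_uv=c.amplitude_uv * _lognormal_scale(rng, jitter_sigma))
             for c in base.erp_components]
    return replace(base, pink_power_at_1hz=pink, white_power=white,
                   bands=bands, erp_components=comps)


def coupling_reference(base: GroundTruth, config: SessionConfig, seed: int,
                       jitter_sigma: float = 0.2, n_windows: int = 256) -> dict:
    """Cohort-level standardization constants for each coupling source.

    Simulates ``n_windows`` prestimulus-length windows of each source process
    at its nominal amplitude, measures the window RMS distribution, and folds
    in the analytic moments of the log-normal participant jitter.  Returns
    ``{source_name: (mean, sd)}`` of the per-trial source amplitude across
    trials *and* participants, so that the induced couplings vary between
    participants (which is what the across-participant linkage regressions
    measure).
    """
    rng = derive_rng(seed, "coupling-ref")
    pre = int(round(0.5 * config.fs))
    n = n_windows * pre
    ea = float(np.exp(0.5 * jitter_sigma**2))  # E[lognormal]
    ea2 = float(np.exp(2.0 * jitter_sigma**2))  # E[lognormal^2]
    out = {}
    sources = {cp.source for cp in base.couplings}
    for name in sources:
        if name == "pink":
            p0 = float(np.mean(base.pink_power_at_1hz))
            series = generate_pink_noise(n, config.fs, p0, rng)
        else:
            b = base.band(name)
            series = generate_band_noise(n, config.fs, b.centre_hz, b.bandwidth_hz,
                                         b.rms_uv, rng)
        r = np.sqrt(np.mean(series.reshape(n_windows, pre) ** 2, axis=1))
        m1, m2 = float(np.mean(r)), float(np.mean(r**2))
        mu = ea * m1
        var = ea2 * m2 - mu**2
        out[name] = (mu, float(np.sqrt(max(var, 0.0))))
    return out


def generate_cohort(cohort: CohortConfig, base: GroundTruth, seed: int,
                    keep_parts: bool = False):
    """Yield ``(participant_index, Session)`` pairs for a whole cohort.

    Sessions are yielded lazily (they are large); each participant draws an
    independent jittered truth and an independent session stream, all derived
    from ``seed``.
    """
    ref = coupling_reference(base, cohort.session, seed, cohort.jitter_sigma) \
        if base.couplings else None
    for i in range(cohort.n_participants):
        truth_i = participant_truth(base, derive_rng(seed, "jitter", i), cohort.jitter_sigma)
        sess = generate_session(cohort.session, truth_i,
                                seed=_key_code(seed) ^ (1000003 * (i + 1)) & 0x7FFFFFFF,
                                coupling_reference=ref, keep_parts=keep_parts)
        yield i, sess


# --------------------------------------------------------------------------
# default study ground truth
# --------------------------------------------------------------------------

def default_ground_truth(n_channels: int = 30) -> GroundTruth:
    """The default study conditions.

    Five oscillation bands with the canonical peak frequencies of
    delta/theta (2 Hz), theta/alpha (8 Hz), alpha (10 Hz), alpha/beta
    (15 Hz) and beta (25 Hz); pink noise with a vertex-weighted topography;
    Go ERP components N1b, N1c, N2c, P3b, SW1 and No-Go components N1b, N1c,
    P2/N2b, N2c/eP3a, lP3a, SW1; and five couplings (alpha -> Go P3b direct,
    beta -> Go N2c and Go SW1 inverse, pink -> No-Go N1b inverse and
    No-Go N1c direct) at strength 0.5.
    """
    C = n_channels
    pink = 10.0 * _default_topography(C, 0.50, spread=0.35, floor=0.6)
    white = 0.30 * _default_topography(C, 0.30, spread=0.45, floor=0.7)
    bands = [
        OscillationBand("DT", 2.0, 2.0, 2.5, _default_topography(C, 0.35)),
        OscillationBand("TA", 8.0, 1.8, 2.0, _default_topography(C, 0.25)),
        OscillationBand("A1", 10.0, 1.8, 3.5, _default_topography(C, 0.92)),
        OscillationBand("AB", 15.0, 4.0, 1.8, _default_topography(C, 0.75)),
        OscillationBand("B1", 25.0, 6.0, 1.5, _default_topography(C, 0.50)),
    ]
    erp = [
        ErpComponent("N1b", "go", 95.0, 45.0, 8.0, -1, _default_topography(C, 0.40)),
        ErpComponent("N1c", "go", 160.0, 60.0, 5.0, -1, _default_topography(C, 0.55, 0.18)),
        ErpComponent("N2c", "go", 240.0, 70.0, 6.0, -1, _default_topography(C, 0.48)),
        ErpComponent("P3b", "go", 350.0, 110.0, 12.0, +1, _default_topography(C, 0.80)),
        ErpComponent("SW1", "go", 460.0, 120.0, 6.0, +1, _default_topography(C, 0.65)),
        ErpComponent("N1b", "nogo", 95.0, 45.0, 8.0, -1, _default_topography(C, 0.40)),
        ErpComponent("N1c", "nogo", 160.0, 60.0, 5.0, -1, _default_topography(C, 0.55, 0.18)),
        ErpComponent("P2N2b", "nogo", 215.0, 60.0, 5.0, -1, _default_topography(C, 0.35)),
        ErpComponent("N2cP3a", "nogo", 290.0, 80.0, 8.0, +1, _default_topography(C, 0.50)),
        ErpComponent("lP3a", "nogo", 380.0, 100.0, 7.0, +1, _default_topography(C, 0.55)),
        ErpComponent("SW1", "nogo", 470.0, 120.0, 5.0, +1, _default_topography(C, 0.60)),
    ]
    couplings = [
        Coupling("A1", "P3b", "go", +1, 0.5),
        Coupling("B1", "N2c", "go", -1, 0.5),
        Coupling("B1", "SW1", "go", -1, 0.5),
        Coupling("pink", "N1b", "nogo", -1, 0.5),
        Coupling("pink", "N1c", "nogo", +1, 0.5),
    ]
    return GroundTruth(pink_power_at_1hz=pink, white_power=white, bands=bands,
                       erp_components=erp, couplings=couplings)


# --------------------------------------------------------------------------
# spectra-level and ERP-level case generators (component-recovery studies)
# --------------------------------------------------------------------------

def generate_oscillation_spectra(n_participants: int, n_channels: int,
                                 bands: list[OscillationBand], seed: int,
                                 freqs: np.ndarray | None = None,
                                 noise_sd_uv: float = 0.15,
                                 jitter_sigma: float = 0.2):
    """Synthetic noise-free oscillation amplitude spectra, case-matrix form.

    Builds the matrix a frequency PCA consumes directly: one row per
    participant x channel, one column per 1-Hz bin.  Each band contributes a
    Gaussian amplitude profile times its topography times a per-participant
    log-normal amplitude factor; independent half-normal measurement noise of
    scale ``noise_sd_uv`` is added (spectra are non-negative).

    Returns ``(X, meta, amp_factors)`` where ``meta`` is a DataFrame with
    participant/channel per row and ``amp_factors`` is the
    (n_participants x n_bands) matrix of planted amplitude factors.
    """
    rng = _as_rng(seed)
    if freqs is None:
        freqs = np.arange(31.0)
    B = len(bands)
    factors = np.exp(rng.normal(0.0, jitter_sigma, size=(n_participants, B)))
    profiles = np.zeros((B, freqs.size))
    topos = np.zeros((B, n_channels))
    for j, b in enumerate(bands):
        sigma = b.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        profiles[j] = b.rms_uv * np.exp(-0.5 * ((freqs - b.centre_hz) / sigma) ** 2)
        topos[j] = _band_topo(b, n_channels)
    rows, meta = [], []
    for i in range(n_participants):
        base = np.einsum("b,bc,bf->cf", factors[i], topos, profiles)
        noise = np.abs(rng.normal(0.0, noise_sd_uv, size=base.shape))
        rows.append(base + noise)
        meta.extend((i, c) for c in range(n_channels))
    X = np.vstack(rows)
    meta = pd.DataFrame(meta, columns=["participant", "channel"])
    return X, meta, factors


def generate_erp_case_matrix(n_participants: int, n_channels: int,
                             components: list[ErpComponent], seed: int,
                             times_ms: np.ndarray | None = None,
                             noise_sd_uv: float = 0.5,
                             jitter_sigma: float = 0.2):
    """Synthetic mean-ERP case matrix (participant x channel rows, time columns).

    Each planted component contributes a Gaussian deflection at its latency,
    scaled by polarity, topography, and a per-participant log-normal factor;
    smooth Gaussian noise (white noise low-passed by a moving average) of SD
    ``noise_sd_uv`` models residual EEG left in the trial-averaged ERP.
    """
    rng = _as_rng(seed)
    if times_ms is None:
        times_ms = np.arange(-100, 500, 2.0)
    K = len(components)
    factors = np.exp(rng.normal(0.0, jitter_sigma, size=(n_participants, K)))
    waves = np.zeros((K, times_ms.size))
    topos = np.zeros((K, n_channels))
    for j, c in enumerate(components):
        sig = c.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        waves[j] = c.polarity * c.amplitude_uv * np.exp(-0.5 * ((times_ms - c.latency_ms) / sig) ** 2)
        topos[j] = _erp_topo(c, n_channels)
    rows, meta = [], []
    kernel = np.ones(8) / 8.0
    for i in range(n_participants):
        base = np.einsum("k,kc,kt->ct", factors[i], topos, waves)
        noise = rng.normal(0.0, noise_sd_uv * np.sqrt(kernel.size),
                           size=(n_channels, times_ms.size + kernel.size - 1))
        noise = np.apply_along_axis(np.convolve, 1, noise, kernel, "valid")
        rows.append(base + noise)
        meta.extend((i, c) for c in range(n_channels))
    X = np.vstack(rows)
    meta = pd.DataFrame(meta, columns=["participant", "channel"])
    return X, meta, factors
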
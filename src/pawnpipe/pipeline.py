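"""End-to-end orchestration: simulate -> preprocess -> spectra -> noise ->
f-PCA -> t-PCA -> behaviour -> linkage regressions.

Two entry styles are provided.  The file-based stages (``stage_*`` and
:func:`run_all`) exchange all data through documented CSV/JSON/binary files,
so each stage can be re-run in isolation on the previous stage's outputs and
reproduces the orchestrated run bit for bit.  The in-memory API
(:func:`process_participant`, :func:`run_cohort`) drives the same operations
without touching disk and is what the recovery studies use.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .behaviour import summarize_behaviour
from .noise import fit_pink_white, subtract_noise
from .pca import (FactorSolution, component_amplitude, pca_covariance,
                  rotate_solution, select_components)
from .preprocess import (bandpass_filter, classify_trials, extract_epochs,
                         filter_gain, match_epoch_counts, reject_artifacts)
from .regression import RegressionResult, run_linkage_suite
from .spectral import amplitude_spectrum, pooled_spectrum
from .synth import (CohortConfig, Coupling, ErpComponent, GroundTruth,
                    OscillationBand, Session, SessionConfig,
                    default_ground_truth, derive_rng, generate_cohort)

logger = logging.getLogger("pawnpipe")

__all__ = [
    "AnalysisParams", "ParticipantResult", "CohortResult",
    "load_config", "process_participant", "run_cohort", "run_all",
    "linkage_recovery_study", "noise_recovery_study",
]

__version__ = "0.1.0"


# --------------------------------------------------------------------------
# parameters / configuration
# --------------------------------------------------------------------------

@dataclass
class AnalysisParams:
    """All analysis-stage knobs with the study defaults."""

    filter_lo: float = 0.1
    filter_hi: float = 30.0
    filter_order: int = 8
    extreme_uv: float = 125.0
    jump_uv: float = 50.0
    flat_uv: float = 0.05
    flat_win_ms: float = 100.0
    min_trials: int = 50
    rt_window_ms: tuple = (100.0, 500.0)
    taper_fraction: float = 0.10
    pad_to: int = 1000
    fmax_hz: float = 30.0
    fit_lo: float = 2.0
    fit_hi: float = 24.0
    extend_lo: float = 1.0
    extend_hi: float = 30.0
    variance_cutoff_pct: float = 1.5
    kappa: float = 3.0
    erp_window_ms: tuple = (-100.0, 500.0)
    erp_step_ms: float = 2.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    compensate_filter: bool = False
    varimax_tol: float = 1e-7
    varimax_max_iter: int = 500

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown analysis parameters: {sorted(extra)}")
        kwargs = dict(d)
        for key in ("rt_window_ms", "erp_window_ms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _truth_from_dict(d: dict | None, n_channels: int) -> GroundTruth:
    base = default_ground_truth(n_channels)
    if not d:
        return base
    kwargs = {}
    if "pink_power_at_1hz" in d:
        v = d["pink_power_at_1hz"]
        kwargs["pink_power_at_1hz"] = np.full(n_channels, float(v)) if np.isscalar(v) \
            else np.asarray(v, float)
    else:
        kwargs["pink_power_at_1hz"] = base.pink_power_at_1hz
    if "white_power" in d:
        v = d["white_power"]
        kwargs["white_power"] = np.full(n_channels, float(v)) if np.isscalar(v) \
            else np.asarray(v, float)
    else:
        kwargs["white_power"] = base.white_power
    kwargs["bands"] = [OscillationBand(**b) for b in d["bands"]] if "bands" in d else base.bands
    kwargs["erp_components"] = ([ErpComponent(**c) for c in d["erp_components"]]
                                if "erp_components" in d else base.erp_components)
    kwargs["couplings"] = ([Coupling(**c) for c in d["couplings"]]
                           if "couplings" in d else base.couplings)
    for key in ("rt_mean_ms", "rt_sd_ms", "omission_rate", "commission_rate"):
        kwargs[key] = d.get(key, getattr(base, key))
    return GroundTruth(**kwargs)


def load_config(path):
    """Parse a YAML run configuration into (CohortConfig, GroundTruth, AnalysisParams)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    session = SessionConfig(**raw.get("session", {}))
    cohort_d = raw.get("cohort", {})
    cohort = CohortConfig(n_participants=cohort_d.get("n_participants", 47),
                          jitter_sigma=cohort_d.get("jitter_sigma", 0.2),
                          session=session)
    truth = _truth_from_dict(raw.get("truth"), session.n_channels)
    params = AnalysisParams.from_dict(raw.get("analysis", {}))
    return cohort, truth, params


# --------------------------------------------------------------------------
# per-participant analysis (in memory)
# --------------------------------------------------------------------------

@dataclass
class ParticipantResult:
    participant: int
    excluded: bool
    behaviour: dict
    counts: dict
    freqs: np.ndarray | None = None
    spectrum_go: np.ndarray | None = None  # channels x bins, mean amplitude
    spectrum_nogo: np.ndarray | None = None
    spectrum_pooled: np.ndarray | None = None
    pink_coeff: np.ndarray | None = None  # per channel (spectrum-power units)
    white_level: np.ndarray | None = None
    clipped_bins: np.ndarray | None = None
    oscillation: np.ndarray | None = None  # channels x bins, amplitude
    erp_times_ms: np.ndarray | None = None
    erp_go: np.ndarray | None = None  # channels x time
    erp_nogo: np.ndarray | None = None


def _prestim_spectra(epochs, params: AnalysisParams):
    pre = epochs.times_ms < -1e-9
    seg = epochs.data[:, :, pre]
    freqs, amp = amplitude_spectrum(seg, fs=epochs.fs, pad_to=params.pad_to,
                                    taper_fraction=params.taper_fraction,
                                    fmax_hz=params.fmax_hz)
    mean_amp = amp.mean(axis=0)
    if params.compensate_filter:
        gain = filter_gain(freqs[1:], params.filter_lo, params.filter_hi,
                           params.filter_order, epochs.fs)
        mean_amp[:, 1:] /= np.clip(gain, 1e-3, None)
    return freqs, mean_amp


def _mean_erp(epochs, params: AnalysisParams):
    lo, hi = params.erp_window_ms
    mask = (epochs.times_ms >= lo - 1e-9) & (epochs.times_ms < hi - 1e-9)
    step = int(round(params.erp_step_ms * epochs.fs / 1000.0))
    erp = epochs.data[:, :, mask].mean(axis=0)[:, ::step]
    times = epochs.times_ms[mask][::step]
    return times, erp


def process_participant(session: Session, params: AnalysisParams,
                        participant: int = 0, seed: int = 0) -> ParticipantResult:
    """Run the within-participant chain on one session.

    Filtering, validity classification, epoching, artifact rejection, epoch
    count matching, prestimulus spectra (mean amplitude per channel and
    condition plus the pooled Go/No-Go mean), the constrained pink/white fit
    per channel, noise-free oscillation spectra, mean Go and No-Go ERPs, and
    the behavioural summary.
    """
    cfg = session.config
    filtered = bandpass_filter(session.recording, params.filter_lo,
                               params.filter_hi, params.filter_order)
    events = classify_trials(session.events, cfg.soa_ms, cfg.fs, params.rt_window_ms)
    epochs = extract_epochs(filtered, events)
    epochs = reject_artifacts(epochs, params.extreme_uv, params.jump_uv,
                              params.flat_uv, params.flat_win_ms)
    go = epochs.subset(np.flatnonzero(epochs.condition == "go"))
    nogo = epochs.subset(np.flatnonzero(epochs.condition == "nogo"))
    go_m, nogo_m, excluded = match_epoch_counts(
        go, nogo, params.min_trials, derive_rng(seed, "match", participant))
    behaviour = summarize_behaviour(events, params.rt_window_ms).as_dict()
    counts = {
        "n_trials": epochs.n_trials,
        "accepted_go": int(go_m.accepted.sum()),
        "accepted_nogo": int(nogo_m.accepted.sum()),
        **{f"rejected_{k}": v for k, v in epochs.rejection_counts().items()
           if k != "none"},
    }
    res = ParticipantResult(participant=participant, excluded=excluded,
                            behaviour=behaviour, counts=counts)
    if excluded:
        return res

    go_acc = go_m.subset(np.flatnonzero(go_m.accepted))
    nogo_acc = nogo_m.subset(np.flatnonzero(nogo_m.accepted))
    freqs, spec_go = _prestim_spectra(go_acc, params)
    _, spec_nogo = _prestim_spectra(nogo_acc, params)
    pooled = pooled_spectrum(spec_go, spec_nogo)

    C = pooled.shape[0]
    p = np.zeros(C)
    w = np.zeros(C)
    clipped = np.zeros(C, int)
    osc = np.zeros_like(pooled)
    for c in range(C):
        fit = fit_pink_white(pooled[c] ** 2, freqs, params.fit_lo, params.fit_hi)
        p[c], w[c] = fit.pink_coeff, fit.white_level
        osc[c], clipped[c] = subtract_noise(pooled[c], fit, freqs)
    res.freqs = freqs
    res.spectrum_go, res.spectrum_nogo, res.spectrum_pooled = spec_go, spec_nogo, pooled
    res.pink_coeff, res.white_level, res.clipped_bins = p, w, clipped
    res.oscillation = osc
    res.erp_times_ms, res.erp_go = _mean_erp(go_acc, params)
    _, res.erp_nogo = _mean_erp(nogo_acc, params)
    return res


# --------------------------------------------------------------------------
# cohort-level analysis (in memory)
# --------------------------------------------------------------------------

@dataclass
class CohortResult:
    participants: list
    excluded: list
    counts: pd.DataFrame
    behaviour: pd.DataFrame
    noise_params: pd.DataFrame
    fpca: FactorSolution | None = None
    fpca_selected: list = field(default_factory=list)
    predictors: pd.DataFrame | None = None
    tpca: dict = field(default_factory=dict)
    tpca_selected: dict = field(default_factory=dict)
    erp_amplitudes: dict = field(default_factory=dict)
    primary: list = field(default_factory=list)
    secondary: list = field(default_factory=list)
    fpca_ratio: float = float("nan")
    tpca_ratio: float = float("nan")
    truths: list = field(default_factory=list)


def _case_matrix(results: list[ParticipantResult], attr: str):
    rows, meta = [], []
    for r in results:
        arr = getattr(r, attr)
        rows.append(arr)
        meta.extend((r.participant, c) for c in range(arr.shape[0]))
    X = np.vstack(rows)
    return X, pd.DataFrame(meta, columns=["participant", "channel"])


def analyse_cohort(results: list[ParticipantResult], params: AnalysisParams,
                   freqs: np.ndarray, erp_times: np.ndarray) -> CohortResult:
    """Group-level stages on a list of processed participants."""
    included = [r for r in results if not r.excluded]
    excluded = [r.participant for r in results if r.excluded]
    behaviour = pd.DataFrame([r.behaviour for r in results],
                             index=[r.participant for r in results])
    behaviour.index.name = "participant"
    counts = pd.DataFrame([{"participant": r.participant, "excluded": r.excluded,
                            **r.counts} for r in results]).set_index("participant")
    noise_rows = []
    for r in included:
        for c in range(len(r.pink_coeff)):
            noise_rows.append({"participant": r.participant, "channel": c,
                               "pink_coeff": r.pink_coeff[c],
                               "white_level": r.white_level[c],
                               "clipped_bins": int(r.clipped_bins[c])})
    noise_params = pd.DataFrame(noise_rows)
    out = CohortResult(participants=[r.participant for r in included],
                       excluded=excluded, counts=counts,
                       behaviour=behaviour.loc[[r.participant for r in included]],
                       noise_params=noise_params)
    if not included:
        return out

    # ---- frequency PCA on the noise-free oscillation spectra (pooled Go/No-Go)
    X, meta = _case_matrix(included, "oscillation")
    fpca = pca_covariance(X, variable_values=freqs, case_meta=meta)
    rotate_solution(fpca, method="promax", kappa=params.kappa)
    sel = select_components(fpca, params.variance_cutoff_pct)
    out.fpca, out.fpca_selected = fpca, sel
    out.fpca_ratio = X.shape[0] / X.shape[1]

    osc_amp = component_amplitude(fpca, sel, meta, mode="mean_amplitude")
    osc_amp.columns = [c.replace("comp_", "osc") + "Hz" for c in osc_amp.columns]
    pn = pd.Series({r.participant: float(np.mean(np.sqrt(r.pink_coeff)))
                    for r in included}, name="PN_1Hz")
    wn = pd.Series({r.participant: float(np.mean(np.sqrt(r.white_level)))
                    for r in included}, name="WN")
    predictors = osc_amp.copy()
    predictors["PN_1Hz"] = pn
    predictors["WN"] = wn
    out.predictors = predictors

    # ---- temporal PCAs, one per condition
    for cond, attr in (("go", "erp_go"), ("nogo", "erp_nogo")):
        Xe, meta_e = _case_matrix(included, attr)
        tp = pca_covariance(Xe, variable_values=erp_times, case_meta=meta_e)
        rotate_solution(tp, method="varimax", tol=params.varimax_tol,
                        max_iter=params.varimax_max_iter)
        sel_t = select_components(tp, params.variance_cutoff_pct)
        out.tpca[cond] = tp
        out.tpca_selected[cond] = sel_t
        amp = component_amplitude(tp, sel_t, meta_e, mode="peak_amplitude")
        amp.columns = [c.replace("comp_", "T") + "ms" for c in amp.columns]
        out.erp_amplitudes[cond] = amp
        out.tpca_ratio = Xe.shape[0] / Xe.shape[1]

    out.primary, out.secondary = run_linkage_suite(
        out.predictors, out.erp_amplitudes["go"], out.erp_amplitudes["nogo"],
        out.behaviour, params.p_enter, params.p_remove)
    return out


def run_cohort(cohort: CohortConfig, truth: GroundTruth, params: AnalysisParams,
               seed: int) -> CohortResult:
    """Generate and analyse a whole synthetic cohort in memory."""
    results = []
    freqs = erp_times = None
    truths = []
    for i, sess in generate_cohort(cohort, truth, seed):
        r = process_participant(sess, params, participant=i, seed=seed)
        results.append(r)
        truths.append(sess.truth)
        if not r.excluded and freqs is None:
            freqs, erp_times = r.freqs, r.erp_times_ms
        logger.info("participant %d: excluded=%s accepted go/nogo = %s/%s",
                    i, r.excluded, r.counts.get("accepted_go"),
                    r.counts.get("accepted_nogo"))
    out = analyse_cohort(results, params, freqs, erp_times)
    out.truths = truths
    return out


# --------------------------------------------------------------------------
# file-based stages
# --------------------------------------------------------------------------

def _pdirs(root) -> list[Path]:
    return sorted(Path(root, "participants").glob("p*"))


def stage_simulate(cohort: CohortConfig, truth: GroundTruth, out_dir, seed: int):
    """Write per-participant recordings (binary + JSON) and event tables (TSV)."""
    out = Path(out_dir)
    for i, sess in generate_cohort(cohort, truth, seed):
        d = out / "participants" / f"p{i:03d}"
        pio.save_recording(d, sess.recording)
        pio.save_events(d / "events.tsv", sess.events)
    (out / "session.json").write_text(json.dumps(
        {"session": asdict(cohort.session),
         "n_participants": cohort.n_participants, "seed": seed}, indent=1))


def stage_preprocess(run_dir, params: AnalysisParams, seed: int):
    """Filter, epoch, classify, reject, and match counts for every participant."""
    run = Path(run_dir)
    session_meta = json.loads((run / "session.json").read_text())
    soa_ms = session_meta["session"]["soa_ms"]
    summary = []
    for d in _pdirs(run):
        i = int(d.name[1:])
        rec = pio.load_recording(d)
        events = pio.load_events(d / "events.tsv")
        filtered = bandpass_filter(rec, params.filter_lo, params.filter_hi,
                                   params.filter_order)
        events = classify_trials(events, soa_ms, rec.fs, params.rt_window_ms)
        epochs = extract_epochs(filtered, events)
        epochs = reject_artifacts(epochs, params.extreme_uv, params.jump_uv,
                                  params.flat_uv, params.flat_win_ms)
        go = epochs.subset(np.flatnonzero(epochs.condition == "go"))
        nogo = epochs.subset(np.flatnonzero(epochs.condition == "nogo"))
        go_m, nogo_m, excluded = match_epoch_counts(
            go, nogo, params.min_trials, derive_rng(seed, "match", i))
        pio.save_epochs(d, go_m.subset(np.flatnonzero(go_m.accepted)), "epochs_go")
        pio.save_epochs(d, nogo_m.subset(np.flatnonzero(nogo_m.accepted)), "epochs_nogo")
        row = {"participant": i, "excluded": excluded,
               "accepted_go": int(go_m.accepted.sum()),
               "accepted_nogo": int(nogo_m.accepted.sum())}
        row.update({f"rejected_{k}": v for k, v in epochs.rejection_counts().items()
                    if k != "none"})
        summary.append(row)
    pd.DataFrame(summary).to_csv(run / "rejection_summary.csv", index=False)


def stage_spectra(run_dir, params: AnalysisParams):
    """Prestimulus mean amplitude spectra per participant/channel/condition (long CSV)."""
    run = Path(run_dir)
    rows = []
    for d in _pdirs(run):
        i = int(d.name[1:])
        summary = pd.read_csv(run / "rejection_summary.csv").set_index("participant")
        if bool(summary.loc[i, "excluded"]):
            continue
        specs = {}
        for cond in ("go", "nogo"):
            ep = pio.load_epochs(d, f"epochs_{cond}")
            freqs, amp = _prestim_spectra(ep, params)
            specs[cond] = amp
        specs["pooled"] = pooled_spectrum(specs["go"], specs["nogo"])
        for cond, amp in specs.items():
            for c in range(amp.shape[0]):
                for k, f in enumerate(freqs):
                    rows.append((i, c, cond, f, amp[c, k]))
    df = pd.DataFrame(rows, columns=["participant", "channel", "condition",
                                     "freq_hz", "amplitude_uv"])
    df.to_csv(run / "spectra.csv", index=False)


def stage_noise(run_dir, params: AnalysisParams):
    """Constrained pink/white fits and oscillation spectra from spectra.csv."""
    run = Path(run_dir)
    df = pd.read_csv(run / "spectra.csv")
    pooled = df[df["condition"] == "pooled"]
    noise_rows, osc_rows = [], []
    for (i, c), grp in pooled.groupby(["participant", "channel"]):
        grp = grp.sort_values("freq_hz")
        freqs = grp["freq_hz"].to_numpy()
        amp = grp["amplitude_uv"].to_numpy()
        fit = fit_pink_white(amp**2, freqs, params.fit_lo, params.fit_hi)
        osc, clipped = subtract_noise(amp, fit, freqs)
        noise_rows.append({"participant": i, "channel": c,
                           "pink_coeff": fit.pink_coeff,
                           "white_level": fit.white_level,
                           "support": ";".join(f"{f:g}" for f in fit.support),
                           "clipped_bins": clipped})
        osc_rows.extend((i, c, f, a) for f, a in zip(freqs, osc))
    pd.DataFrame(noise_rows).to_csv(run / "noise_params.csv", index=False)
    pd.DataFrame(osc_rows, columns=["participant", "channel", "freq_hz",
                                    "amplitude_uv"]).to_csv(
        run / "oscillation.csv", index=False)


def _write_solution(out_dir: Path, sol: FactorSolution, selected: list[int],
                    amplitudes: pd.DataFrame):
    out_dir.mkdir(parents=True, exist_ok=True)
    L = sol.active_loadings
    pd.DataFrame(L, index=pd.Index(sol.variable_values, name="variable")).to_csv(
        out_dir / "loadings.csv")
    scores = pd.DataFrame(sol.active_scores)
    scores.insert(0, "participant", sol.case_meta["participant"].to_numpy())
    scores.insert(1, "channel", sol.case_meta["channel"].to_numpy())
    scores.to_csv(out_dir / "scores.csv", index=False)
    sel_rows = [{"component": c, "peak_variable": sol.peak_variable(c),
                 "variance_pct": sol.active_explained_pct[c]} for c in selected]
    pd.DataFrame(sel_rows).to_csv(out_dir / "selection.csv", index=False)
    amplitudes.to_csv(out_dir / "amplitudes.csv")


def stage_fpca(run_dir, params: AnalysisParams):
    run = Path(run_dir)
    df = pd.read_csv(run / "oscillation.csv")
    wide = df.pivot_table(index=["participant", "channel"], columns="freq_hz",
                          values="amplitude_uv", sort=True)
    meta = wide.index.to_frame(index=False)
    X = wide.to_numpy()
    sol = pca_covariance(X, variable_values=wide.columns.to_numpy(float),
                         case_meta=meta)
    rotate_solution(sol, method="promax", kappa=params.kappa)
    sel = select_components(sol, params.variance_cutoff_pct)
    amp = component_amplitude(sol, sel, meta, mode="mean_amplitude")
    amp.columns = [c.replace("comp_", "osc") + "Hz" for c in amp.columns]
    _write_solution(run / "fpca", sol, sel, amp)


def stage_tpca(run_dir, params: AnalysisParams, condition: str):
    run = Path(run_dir)
    rows, meta = [], []
    summary = pd.read_csv(run / "rejection_summary.csv").set_index("participant")
    times = None
    for d in _pdirs(run):
        i = int(d.name[1:])
        if bool(summary.loc[i, "excluded"]):
            continue
        ep = pio.load_epochs(d, f"epochs_{condition}")
        times, erp = _mean_erp(ep, params)
        rows.append(erp)
        meta.extend((i, c) for c in range(erp.shape[0]))
    X = np.vstack(rows)
    meta = pd.DataFrame(meta, columns=["participant", "channel"])
    sol = pca_covariance(X, variable_values=times, case_meta=meta)
    rotate_solution(sol, method="varimax", tol=params.varimax_tol,
                    max_iter=params.varimax_max_iter)
    sel = select_components(sol, params.variance_cutoff_pct)
    amp = component_amplitude(sol, sel, meta, mode="peak_amplitude")
    amp.columns = [c.replace("comp_", "T") + "ms" for c in amp.columns]
    _write_solution(run / f"tpca_{condition}", sol, sel, amp)


def stage_behaviour(run_dir, params: AnalysisParams):
    run = Path(run_dir)
    rows = []
    for d in _pdirs(run):
        i = int(d.name[1:])
        ev = pio.load_events(d / "events.tsv")
        rows.append({"participant": i,
                     **summarize_behaviour(ev, params.rt_window_ms).as_dict()})
    pd.DataFrame(rows).set_index("participant").to_csv(run / "behaviour.csv")


def _results_frame(results: list[RegressionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        if not res.predictors:
            rows.append({"dependent": res.dependent, "predictor": "",
                         "beta": np.nan, "t": np.nan, "p": np.nan,
                         "r_squared": res.r_squared, "n": res.n})
        for name in res.predictors:
            rows.append({"dependent": res.dependent, "predictor": name,
                         "beta": res.beta[name], "t": res.t[name],
                         "p": res.p[name], "r_squared": res.r_squared,
                         "n": res.n})
    return pd.DataFrame(rows)


def _trace_frame(results: list[RegressionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for rec in res.trace:
            rows.append({"dependent": res.dependent, "step": rec.step,
                         "action": rec.action, "predictor": rec.predictor,
                         "p_value": rec.p_value})
    return pd.DataFrame(rows, columns=["dependent", "step", "action",
                                       "predictor", "p_value"])


def stage_regress(run_dir, params: AnalysisParams):
    run = Path(run_dir)
    predictors = pd.read_csv(run / "fpca" / "amplitudes.csv").set_index("participant")
    noise = pd.read_csv(run / "noise_params.csv")
    pn = noise.groupby("participant")["pink_coeff"].apply(
        lambda s: float(np.mean(np.sqrt(s))))
    wn = noise.groupby("participant")["white_level"].apply(
        lambda s: float(np.mean(np.sqrt(s))))
    predictors["PN_1Hz"] = pn
    predictors["WN"] = wn
    erp_go = pd.read_csv(run / "tpca_go" / "amplitudes.csv").set_index("participant")
    erp_nogo = pd.read_csv(run / "tpca_nogo" / "amplitudes.csv").set_index("participant")
    behaviour = pd.read_csv(run / "behaviour.csv").set_index("participant")
    behaviour = behaviour.loc[predictors.index]
    primary, secondary = run_linkage_suite(predictors, erp_go, erp_nogo,
                                           behaviour, params.p_enter,
                                           params.p_remove)
    out = run / "regressions"
    out.mkdir(exist_ok=True)
    _results_frame(primary).to_csv(out / "primary.csv", index=False)
    _results_frame(secondary).to_csv(out / "secondary.csv", index=False)
    _trace_frame(primary + secondary).to_csv(out / "trace.csv", index=False)


STAGES = ["simulate", "preprocess", "spectra", "noise", "fpca",
          "tpca_go", "tpca_nogo", "behaviour", "regress"]


def run_all(config_path, out_dir, seed: int) -> dict:
    """Execute every stage in order; write a reproducibility manifest and report.

    Any stage failure aborts with the failing stage named; outputs produced
    so far stay on disk next to a FAILED marker.
    """
    cohort, truth, params = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_fns = {
        "simulate": lambda: stage_simulate(cohort, truth, out, seed),
        "preprocess": lambda: stage_preprocess(out, params, seed),
        "spectra": lambda: stage_spectra(out, params),
        "noise": lambda: stage_noise(out, params),
        "fpca": lambda: stage_fpca(out, params),
        "tpca_go": lambda: stage_tpca(out, params, "go"),
        "tpca_nogo": lambda: stage_tpca(out, params, "nogo"),
        "behaviour": lambda: stage_behaviour(out, params),
        "regress": lambda: stage_regress(out, params),
    }
    for name in STAGES:
        logger.info("stage %s ...", name)
        try:
            stage_fns[name]()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc

    digests = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.suffix in (".csv", ".tsv", ".json", ".bin"):
            digests[str(path.relative_to(out))] = pio.sha256_file(path)
    manifest = {
        "config": str(config_path),
        "master_seed": seed,
        "stage_order": STAGES,
        "stage_seeds": {"simulate": seed, "preprocess_match": seed},
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 2),
        "digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _write_report(out)
    return manifest


def _write_report(run_dir: Path):
    run = Path(run_dir)
    lines = ["pawnpipe run report", "==================="]
    summary = pd.read_csv(run / "rejection_summary.csv")
    lines.append(f"participants: {len(summary)}; excluded: {int(summary['excluded'].sum())}")
    lines.append(f"accepted trials (go): {summary['accepted_go'].tolist()}")
    for name in ("fpca", "tpca_go", "tpca_nogo"):
        sel = pd.read_csv(run / name / "selection.csv")
        if len(sel):
            peaks = ", ".join(f"{v:g}" for v in sel["peak_variable"])
            lines.append(f"{name}: {len(sel)} components (peaks: {peaks}); "
                         f"variance sum {sel['variance_pct'].sum():.1f}%")
        else:
            lines.append(f"{name}: no components met the variance cutoff")
    prim = pd.read_csv(run / "regressions" / "primary.csv")
    sig = prim[prim["predictor"].fillna("") != ""]
    lines.append(f"significant primary regressions: {sig['dependent'].nunique()}")
    for _, row in sig.iterrows():
        lines.append(f"  {row['dependent']} <- {row['predictor']} "
                     f"(beta={row['beta']:.2f}, p={row['p']:.3f})")
    (run / "report.txt").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# recovery studies
# --------------------------------------------------------------------------

def study_cohort_config(n_participants: int = 47, n_channels: int = 10,
                        n_blocks: int = 1) -> CohortConfig:
    """Cohort configuration used by the linkage recovery study.

    Task timing and trial counts per block follow the study conditions
    (1100 ms onset asynchrony, 75 Go + 75 No-Go shuffled per block); channel
    count and block count are reduced to keep a 20-cohort simulation within
    a desktop compute budget, which leaves the across-participant linkage
    statistics intact.
    """
    sess = SessionConfig(n_channels=n_channels, n_blocks=n_blocks)
    return CohortConfig(n_participants=n_participants, session=sess)


def study_params() -> AnalysisParams:
    """Analysis parameters for the recovery studies: inclusion threshold
    scaled to the single-block trial budget, 4 ms ERP grid and a capped
    Varimax iteration budget to keep 20-cohort simulations fast."""
    return AnalysisParams(min_trials=30, erp_step_ms=4.0, varimax_max_iter=200)


def _match_predictor(columns, source: str, truth: GroundTruth) -> str | None:
    if source == "pink":
        return "PN_1Hz" if "PN_1Hz" in columns else None
    centre = truth.band(source).centre_hz
    best, best_d = None, 1.5
    for col in columns:
        if col.startswith("osc") and col.endswith("Hz"):
            try:
                f = float(col[3:-2].rstrip("b"))
            except ValueError:
                continue
            if abs(f - centre) < best_d:
                best, best_d = col, abs(f - centre)
    return best


def _match_dependent(columns, comp: ErpComponent, tol_ms: float = 30.0) -> str | None:
    best, best_d = None, tol_ms
    for col in columns:
        if col.startswith("T") and col.endswith("ms"):
            try:
                t = float(col[1:-2].rstrip("b"))
            except ValueError:
                continue
            if abs(t - comp.latency_ms) < best_d:
                best, best_d = col, abs(t - comp.latency_ms)
    return best


def linkage_recovery_study(n_seeds: int = 20, seed0: int = 0,
                           cohort: CohortConfig | None = None,
                           truth: GroundTruth | None = None,
                           params: AnalysisParams | None = None) -> pd.DataFrame:
    """End-to-end recovery of the planted prestimulus -> ERP couplings.

    For each cohort seed the full pipeline runs on a fresh synthetic cohort;
    each planted coupling is scored as recovered when the stepwise regression
    for the matched ERP component selects the matched predictor with the
    planted sign.  Returns one row per (seed, coupling).
    """
    cohort = cohort or study_cohort_config()
    truth = truth if truth is not None else default_ground_truth(cohort.session.n_channels)
    params = params or study_params()
    rows = []
    for s in range(n_seeds):
        res = run_cohort(cohort, truth, params, seed=seed0 + 1000 + s)
        by_dep = {r.dependent: r for r in res.primary}
        for cp in truth.couplings:
            comp = next(c for c in truth.erp_components
                        if c.name == cp.target and c.condition == cp.target_condition)
            pred_col = _match_predictor(res.predictors.columns, cp.source, truth)
            dep_col = _match_dependent(
                res.erp_amplitudes[cp.target_condition].columns, comp)
            recovered = False
            beta = np.nan
            if pred_col is not None and dep_col is not None:
                r = by_dep.get(f"{cp.target_condition}:{dep_col}")
                if r is not None and pred_col in r.predictors:
                    beta = r.beta[pred_col]
                    recovered = np.sign(beta) == cp.sign
            rows.append({"seed": s, "source": cp.source, "target": cp.target,
                         "condition": cp.target_condition, "sign": cp.sign,
                         "predictor": pred_col, "dependent": dep_col,
                         "beta": beta, "recovered": recovered})
    return pd.DataFrame(rows)


def noise_recovery_study(n_seeds: int = 20, seed0: int = 0,
                         pink_power: float = 10.0, white_power: float = 0.3,
                         n_channels: int = 6, n_blocks: int = 4) -> pd.DataFrame:
    """Recovery of known pink/white noise levels through the full chain.

    Sessions carry oscillation bumps confined to 6-20 Hz (so the flanks of
    the 2-24 Hz fit range are pure noise), flat topographies, and no ERP
    couplings.  The pooled prestimulus spectrum is averaged across channels,
    fitted, and the fitted levels are converted back to PSD units (Rayleigh
    and noise-bandwidth corrections, plus the analysis-filter compensation)
    for comparison with the generator truth.  Returns per-seed relative
    errors of p and w.
    """
    from .spectral import noise_psd_from_mean_amplitude
    from .synth import generate_session

    sess_cfg = SessionConfig(n_channels=n_channels, n_blocks=n_blocks)
    bands = [
        OscillationBand("theta", 7.0, 2.0, 2.0),
        OscillationBand("alpha", 10.5, 2.0, 3.5),
        OscillationBand("beta", 16.0, 4.0, 1.8),
    ]
    truth = GroundTruth(pink_power_at_1hz=np.full(n_channels, pink_power),
                        white_power=np.full(n_channels, white_power),
                        bands=bands, erp_components=[], couplings=[])
    params = replace(study_params(), compensate_filter=True)
    rows = []
    for s in range(n_seeds):
        session = generate_session(sess_cfg, truth, seed=seed0 + 2000 + s)
        r = process_participant(session, params, participant=0, seed=seed0 + s)
        mean_amp = r.spectrum_pooled.mean(axis=0)
        fit = fit_pink_white(mean_amp**2, r.freqs, params.fit_lo, params.fit_hi)
        n_pre = int(round(0.5 * sess_cfg.fs))
        conv = noise_psd_from_mean_amplitude(1.0, n_pre, sess_cfg.fs,
                                             params.taper_fraction)
        p_hat = fit.pink_coeff * conv
        w_hat = fit.white_level * conv
        rows.append({"seed": s, "p_true": pink_power, "w_true": white_power,
                     "p_hat": p_hat, "w_hat": w_hat,
                     "p_rel_err": (p_hat - pink_power) / pink_power,
                     "w_rel_err": (w_hat - white_power) / white_power})
    return pd.DataFrame(rows)
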
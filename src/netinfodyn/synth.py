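"""Synthetic data: benchmark VAR networks and physiological-like recordings.

Two families of generators live here.

1. *Benchmark VAR networks* (:class:`VarSpec`, :func:`simulate_var`,
   :func:`benchmark_preset`, :func:`oracle_measures`): linear Gaussian
   processes with a known coupling topology, used to validate every
   estimator in the package against ground truth.

2. *Raw recordings* (:func:`synth_recording`): multi-rate signals that
   emulate a wearable-sensor session — an ECG with template-matchable
   QRS deflections whose beat-to-beat intervals are modulated by the
   respiratory phase (respiratory sinus arrhythmia), a sinusoid-plus-
   noise respiration belt signal, a blood-volume-pulse waveform whose
   steepest-rise point trails each R peak by a controllable pulse
   arrival time (PAT), and a single-channel EEG built from band-limited
   noise with slowly varying band amplitude envelopes.  Every generated
   quantity that a downstream stage must recover (beat times, per-beat
   PAT, band envelopes) is stored as ground truth.

The recording generator aims at dynamical, not morphological, realism:
QRS complexes are stylized spikes, not P-QRS-T waveforms, and the EEG is
stationary band noise.  That is exactly what the preprocessing chain
needs to be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import signal as sps

from . import infodyn, varss
from .varss import VarModel

__all__ = [
    "VarSpec",
    "RawRecording",
    "simulate_var",
    "benchmark_preset",
    "oracle_measures",
    "synth_recording",
    "render_bvp",
    "write_recording",
    "read_recording",
    "PRESET_NAMES",
    "NODE_LABELS",
    "STATES",
]

NODE_LABELS = ["RR", "RESP", "PAT", "delta", "theta", "alpha", "beta"]
STATES = ("REST", "MA", "SG")
PRESET_NAMES = ("independent", "chain3", "paperlike7")

BURN_IN = 500  # transient discard for spectral radius <= 0.95


# ---------------------------------------------------------------------------
# VAR benchmark networks
# ---------------------------------------------------------------------------


@dataclass
class VarSpec:
    """A ground-truth VAR network: coefficients, innovations, topology.

    ``A[l][j, i]`` couples source ``i`` (lag ``l+1``) into target ``j``;
    the directed link ``i -> j`` is *true* iff some lag block has a
    nonzero ``(j, i)`` entry.  The spec must describe a stable process
    (companion spectral radius < 1) with a symmetric positive-definite
    innovation covariance.
    """

    M: int
    m: int
    A: list[NDArray[np.float64]]
    Sigma: NDArray[np.float64]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if not self.labels:
            self.labels = [f"X{j + 1}" for j in range(self.M)]
        eigvals = np.linalg.eigvalsh(self.Sigma)
        if np.min(eigvals) <= 0:
            raise ValueError("Sigma must be positive definite")

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(varss.companion_matrix(self.A)))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    @property
    def truth_adjacency(self) -> NDArray[np.bool_]:
        """Boolean ``(M, M)``: entry ``[i, j]`` true iff a directed link i -> j
        exists at any lag.  The diagonal carries no meaning."""
        adj = np.zeros((self.M, self.M), dtype=bool)
        for a in self.A:
            adj |= a.T != 0
        return adj

    def to_model(self) -> VarModel:
        return VarModel(m=self.m, M=self.M, A=[a.copy() for a in self.A],
                        Sigma=self.Sigma.copy())


def simulate_var(spec: VarSpec, n_samples: int, seed: int) -> NDArray[np.float64]:
    """Simulate ``n_samples`` of the VAR process with Gaussian innovations.

    A burn-in of ``BURN_IN`` samples is generated and discarded so the
    returned segment is (effectively) a draw from the stationary
    distribution.  Identical ``(spec, n_samples, seed)`` give identical
    output.

    Raises
    ------
    ValueError
        If the spec is unstable (with the offending spectral radius) or
        ``n_samples <= spec.m``.
    """
    if not spec.is_stable:
        raise ValueError(
            f"unstable VAR spec: companion spectral radius "
            f"{spec.spectral_radius:.4f} >= 1"
        )
    if n_samples <= spec.m:
        raise ValueError("n_samples must exceed the model order")
    rng = np.random.default_rng(seed)
    M, m = spec.M, spec.m
    total = n_samples + BURN_IN
    L = np.linalg.cholesky(spec.Sigma)
    innov = rng.standard_normal((total, M)) @ L.T
    X = np.zeros((total, M))
    A = spec.A
    for n in range(total):
        x = innov[n].copy()
        for lag in range(1, min(m, n) + 1):
            x += A[lag - 1] @ X[n - lag]
        X[n] = x
    return X[BURN_IN:].T.copy()


def _preset_independent() -> VarSpec:
    coefs = [0.9, 0.8, 0.7, 0.5, 0.4, 0.3, 0.2]
    A = [np.diag(coefs)]
    return VarSpec(M=7, m=1, A=A, Sigma=np.eye(7), labels=list(NODE_LABELS))


def _preset_chain3() -> VarSpec:
    A = [np.array([[0.5, 0.0, 0.0],
                   [0.4, 0.5, 0.0],
                   [0.0, 0.4, 0.5]])]
    return VarSpec(M=3, m=1, A=A, Sigma=np.eye(3), labels=["X1", "X2", "X3"])


def _preset_paperlike7() -> VarSpec:
    # rows = targets, cols = sources; indices follow NODE_LABELS
    # peripheral core: RESP <-> RR, RR -> PAT, RESP -> PAT
    # two brain-to-peripheral links: delta -> RR, beta -> RESP
    # self-couplings decrease RR > RESP > PAT > bands so storage follows suit
    RR, RESP, PAT, D, TH, AL, BE = range(7)
    A1 = np.zeros((7, 7))
    A1[RR, RR] = 0.60
    A1[RR, RESP] = 0.40
    A1[RR, D] = 0.30
    A1[RESP, RESP] = 0.55
    A1[RESP, RR] = 0.30
    A1[RESP, BE] = 0.30
    A1[PAT, PAT] = 0.30
    A1[PAT, RR] = 0.30
    A1[PAT, RESP] = 0.30
    A1[D, D] = 0.30
    A1[TH, TH] = 0.25
    A1[AL, AL] = 0.20
    A1[BE, BE] = 0.30
    return VarSpec(M=7, m=1, A=[A1], Sigma=np.eye(7), labels=list(NODE_LABELS))


def benchmark_preset(name: str, seed: int = 0) -> VarSpec:
    """Return a named benchmark network.

    * ``independent`` — 7 uncoupled AR(1) nodes (null topology);
    * ``chain3``      — X1 -> X2 -> X3, the mediation testbed;
    * ``paperlike7``  — 7 nodes labelled like the physiological network,
      with bidirectional cardiorespiratory coupling, cardiac drive of the
      pulse arrival time, and two weak brain-to-peripheral links; the
      self-couplings encode the storage ordering RR > RESP > PAT > bands.

    ``seed`` is accepted for interface uniformity; the presets are fixed.
    """
    if name == "independent":
        return _preset_independent()
    if name == "chain3":
        return _preset_chain3()
    if name == "paperlike7":
        return _preset_paperlike7()
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def oracle_measures(
    spec: VarSpec, n_oracle: int = 100_000, seed: int = 0, lags: int = 20
) -> infodyn.InfoMeasures:
    """Brute-force information measures from one long realization.

    Every partial variance is estimated by ordinary least squares of the
    target's present on the designated past lag set over an
    ``n_oracle``-sample realization, then the log-ratio formulas are
    applied.  This is the estimator-independent reference for the
    state-space backend: it converges to the model-implied values as
    ``n_oracle`` grows.

    ``lags`` sets the regression depth (default 20, never below the
    spec order): reduced lag sets of a VAR network need a deep past to
    approximate their steady-state prediction error, because removing
    processes destroys the finite-order Markov property.
    """
    min_n = max(lags, spec.m) * spec.M + spec.m + 10
    if n_oracle < min_n:
        raise ValueError(f"n_oracle={n_oracle} too small to invert the design")
    X = simulate_var(spec, n_oracle, seed)
    partials = infodyn.regression_partial_variances(X, spec.m, lags=lags)
    return infodyn.measures_from_partials(
        partials, labels=spec.labels, backend="oracle", m=spec.m, n_samples=n_oracle
    )


# ---------------------------------------------------------------------------
# Raw physiological-like recordings
# ---------------------------------------------------------------------------

ECG_FS = 250.0
RESP_FS = 25.0
BVP_FS = 64.0
EEG_FS = 256.0

EEG_BANDS = {"delta": (0.5, 3.0), "theta": (3.0, 8.0),
             "alpha": (8.0, 12.0), "beta": (12.0, 25.0)}


@dataclass
class RawRecording:
    """A per-subject multi-rate signal bundle with optional ground truth.

    Channels carry their native sampling rates (ECG 250 Hz, respiration
    25 Hz, BVP 64 Hz, EEG 256 Hz).  ``truth`` holds generator-side beat
    times (s), per-beat PAT (s), and per-band amplitude envelopes for
    synthetic recordings; it is empty for real data.
    """

    ecg: NDArray[np.float64]
    resp: NDArray[np.float64]
    bvp: NDArray[np.float64]
    eeg: NDArray[np.float64]
    state: str
    subject_id: str = "S00"
    rates: dict = field(default_factory=lambda: {
        "ecg": ECG_FS, "resp": RESP_FS, "bvp": BVP_FS, "eeg": EEG_FS})
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("all sampling rates must be positive")

    @property
    def duration(self) -> float:
        return len(self.ecg) / self.rates["ecg"]


def _raised_cosine_spike(fs: float, width_s: float = 0.04) -> NDArray[np.float64]:
    """QRS surrogate: a raised-cosine spike of the given width, amplitude 1.

    The length is forced odd so the maximum falls on a single sample,
    which keeps beat placement and template alignment unambiguous.
    """
    n = max(3, int(round(width_s * fs)) // 2 * 2 + 1)
    t = np.arange(n) / (n - 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _add_at(signal_arr: NDArray, idx: int, template: NDArray) -> None:
    """Add ``template`` into ``signal_arr`` starting at ``idx``, clipped to bounds."""
    lo = max(idx, 0)
    hi = min(idx + len(template), len(signal_arr))
    if hi > lo:
        signal_arr[lo:hi] += template[lo - idx: hi - idx]


BVP_RISE_S = 0.08   # systolic upstroke duration
BVP_FALL_S = 0.30   # diastolic decay duration


def _pulse_waveform(tau: NDArray[np.float64]) -> NDArray[np.float64]:
    """Analytic blood-pulse shape: raised-cosine upstroke, cosine decay.

    ``tau`` is time from pulse onset (s); the steepest rise sits at
    ``BVP_RISE_S / 2`` exactly, which defines the pulse-arrival fiducial.
    """
    w = np.zeros_like(tau)
    rise = (tau >= 0) & (tau < BVP_RISE_S)
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * tau[rise] / BVP_RISE_S))
    fall = (tau >= BVP_RISE_S) & (tau <= BVP_RISE_S + BVP_FALL_S)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (tau[fall] - BVP_RISE_S) / BVP_FALL_S))
    return w


def render_bvp(
    beat_times: NDArray[np.float64],
    pats: NDArray[np.float64],
    duration: float,
    fs: float = BVP_FS,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> NDArray[np.float64]:
    """Render a BVP signal with one pulse per beat at the prescribed PATs.

    The analytic pulse waveform is evaluated at the sample times with a
    *continuous* onset, so the steepest-rise point of each pulse occurs
    exactly ``pats[k]`` seconds after ``beat_times[k]`` — the stored
    per-beat PAT is realized in the signal, not rounded to the grid.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    bvp = rng.standard_normal(n) * noise_sd
    width = BVP_RISE_S + BVP_FALL_S
    for t_beat, pat in zip(beat_times, pats):
        onset = t_beat + pat - BVP_RISE_S / 2.0
        i0 = max(0, int(np.ceil(onset * fs)))
        i1 = min(n, int(np.floor((onset + width) * fs)) + 1)
        if i1 <= i0:
            continue
        tau = np.arange(i0, i1) / fs - onset
        bvp[i0:i1] += _pulse_waveform(tau)
    return bvp


def _band_limited_noise(rng, n, fs, low, high):
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    sos = sps.butter(4, [max(low, 0.1) / nyq, min(high, nyq * 0.95) / nyq],
                     btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_log_envelope(rng, n_seconds, mean=1.0, rho=0.95, sd=0.25):
    """Positive, slowly varying envelope: exponentiated AR(1) at 1 Hz."""
    z = np.zeros(n_seconds)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    z[0] = rng.standard_normal() * sd
    for k in range(1, n_seconds):
        z[k] = rho * z[k - 1] + rng.standard_normal() * innov_sd
    return mean * np.exp(z - 0.5 * sd**2)


def synth_recording(
    duration: float = 490.0,
    state: str = "REST",
    subject_id: str = "S00",
    seed: int = 0,
    rr_mean: float = 0.8,
    rr_jitter_sd: float = 0.02,
    rsa_gain: float = 0.08,
    resp_rate_hz: float = 0.25,
    resp_noise_sd: float = 0.05,
    pat_base: float = 0.25,
    pat_variation: float = 0.03,
    pat_noise_sd: float = 0.003,
    ecg_noise_sd: float = 0.05,
    band_envelope_sd: float = 0.25,
    band_envelopes: dict[str, NDArray[np.float64]] | None = None,
) -> RawRecording:
    """Generate a multi-rate recording emulating one wearable session.

    Mechanisms, in generation order:

    * respiration: ``sin(2*pi*f_resp*t)`` plus white noise at 25 Hz;
    * beat times: ``RR_n = rr_mean * (1 + rsa_gain * sin(phi_resp(t_n)))
      + jitter`` — respiratory sinus arrhythmia as pure phase coupling;
    * ECG at 250 Hz: a 40 ms raised-cosine spike of amplitude 1 per beat
      on baseline noise (SD ``ecg_noise_sd``);
    * per-beat PAT: ``pat_base + pat_variation * sin(phi_resp)`` plus
      noise; the BVP places each pulse's steepest rise accordingly;
    * EEG at 256 Hz: sum over the four canonical bands of band-limited
      noise scaled by a slowly varying positive envelope (log-AR(1) at
      1 Hz, linearly interpolated), unless explicit 1 Hz envelopes are
      supplied via ``band_envelopes``.

    Ground truth (beat times, per-beat RR and PAT, respiration phase at
    beats, band envelopes) is stored in ``truth``.
    """
    if duration < 360.0:
        raise ValueError("duration must be >= 360 s to allow analysis-window offsets")
    if rr_mean <= 0 or resp_rate_hz <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)

    # respiration (25 Hz)
    n_resp = int(round(duration * RESP_FS))
    t_resp = np.arange(n_resp) / RESP_FS
    resp_clean = np.sin(2.0 * np.pi * resp_rate_hz * t_resp)
    resp = resp_clean + rng.standard_normal(n_resp) * resp_noise_sd

    # beat times with RSA phase coupling
    beat_times = []
    rr_truth = []
    resp_phase_at_beats = []
    t = 0.5  # first beat after a short lead-in
    while True:
        phase = 2.0 * np.pi * resp_rate_hz * t
        rr = rr_mean * (1.0 + rsa_gain * np.sin(phase)) + rng.standard_normal() * rr_jitter_sd
        rr = max(rr, 0.3)
        t_next = t + rr
        if t_next > duration - 0.05:
            break
        beat_times.append(t)
        rr_truth.append(rr)
        resp_phase_at_beats.append(phase)
        t = t_next
    beat_times = np.array(beat_times)
    rr_truth = np.array(rr_truth)
    resp_phase_at_beats = np.array(resp_phase_at_beats)

    # ECG (250 Hz)
    n_ecg = int(round(duration * ECG_FS))
    ecg = rng.standard_normal(n_ecg) * ecg_noise_sd
    spike = _raised_cosine_spike(ECG_FS)
    peak_off = int(np.argmax(spike))
    for tb in beat_times:
        _add_at(ecg, int(round(tb * ECG_FS)) - peak_off, spike)

    # per-beat PAT and BVP (64 Hz)
    pats = (pat_base
            + pat_variation * np.sin(resp_phase_at_beats)
            + rng.standard_normal(len(beat_times)) * pat_noise_sd)
    pats = np.clip(pats, 0.05, 0.55)
    bvp = render_bvp(beat_times, pats, duration, seed=int(rng.integers(2**31)))

    # EEG (256 Hz): four band-limited components with 1 Hz envelopes
    n_eeg = int(round(duration * EEG_FS))
    t_eeg = np.arange(n_eeg) / EEG_FS
    n_sec = int(np.ceil(duration))
    envelopes = {}
    eeg = np.zeros(n_eeg)
    for band, (lo, hi) in EEG_BANDS.items():
        if band_envelopes is not None and band in band_envelopes:
            env_1hz = np.asarray(band_envelopes[band], dtype=float)
            if len(env_1hz) < n_sec:
                raise ValueError(f"envelope for {band} shorter than the record")
        else:
            env_1hz = _ar1_log_envelope(rng, n_sec, sd=band_envelope_sd)
        env = np.interp(t_eeg, np.arange(len(env_1hz)), env_1hz)
        carrier = _band_limited_noise(rng, n_eeg, EEG_FS, lo, hi)
        eeg += env * carrier
        envelopes[band] = env_1hz

    truth = {
        "beat_times": beat_times,
        "rr": rr_truth,
        "pat": pats,
        "resp_phase_at_beats": resp_phase_at_beats,
        "band_envelopes": envelopes,
        "resp_rate_hz": resp_rate_hz,
    }
    return RawRecording(ecg=ecg, resp=resp, bvp=bvp, eeg=eeg, state=state,
                        subject_id=subject_id, truth=truth)


# ---------------------------------------------------------------------------
# Disk layout: one CSV per channel + manifest.json (+ truth.json)
# ---------------------------------------------------------------------------


def write_recording(rec: RawRecording, out_dir: str | Path) -> Path:
    """Write a recording as per-channel ``time_s,value`` CSVs plus a manifest.

    Returns the manifest path.  Ground truth, when present, goes to
    ``truth.json`` beside the channel files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = {}
    for name in ("ecg", "resp", "bvp", "eeg"):
        x = getattr(rec, name)
        fs = rec.rates[name]
        fname = f"{name}.csv"
        pd.DataFrame({"time_s": np.arange(len(x)) / fs, "value": x}).to_csv(
            out / fname, index=False, float_format="%.6g")
        channels[name] = fname
    manifest = {
        "subject_id": rec.subject_id,
        "state": rec.state,
        "channels": channels,
        "rates_hz": rec.rates,
    }
    if rec.truth:
        truth_ser = {
            k: (v.tolist() if isinstance(v, np.ndarray) else
                {kk: vv.tolist() for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in rec.truth.items()
        }
        (out / "truth.json").write_text(json.dumps(truth_ser))
        manifest["truth"] = "truth.json"
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_recording(manifest_path: str | Path) -> RawRecording:
    """Load a recording from its ``manifest.json``."""
    mpath = Path(manifest_path)
    man = json.loads(mpath.read_text())
    base = mpath.parent
    data = {}
    for name, fname in man["channels"].items():
        df = pd.read_csv(base / fname)
        data[name] = df["value"].to_numpy(dtype=float)
    truth = {}
    if man.get("truth"):
        raw = json.loads((base / man["truth"]).read_text())
        for k, v in raw.items():
            if isinstance(v, list):
                truth[k] = np.asarray(v, dtype=float)
            elif isinstance(v, dict):
                truth[k] = {kk: np.asarray(vv, dtype=float) for kk, vv in v.items()}
            else:
                truth[k] = v
    return RawRecording(
        ecg=data["ecg"], resp=data["resp"], bvp=data["bvp"], eeg=data["eeg"],
        state=man["state"], subject_id=man["subject_id"],
        rates={k: float(v) for k, v in man["rates_hz"].items()},
        truth=truth,
    )
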
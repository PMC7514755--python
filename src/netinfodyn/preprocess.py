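"""From raw multi-rate signals to the synchronous 7 x 300 network matrix.

The chain mirrors standard practice in short-term network-physiology
studies:

* band-pass the ECG (1-20 Hz half-power, zero phase) and detect R peaks
  by normalized cross-correlation with a data-derived QRS template;
* derive per-beat series: RR intervals, respiration sampled at the R
  peaks, and pulse arrival times (PAT = R peak to the steepest-rise
  point of the blood volume pulse);
* spline-resample the three peripheral series onto the integer-second
  grid (1 Hz);
* compute EEG band powers (delta, theta, alpha, beta) from 2 s
  periodogram epochs with 50% overlap, one value per second;
* cut a 300-sample analysis window at a state-dependent offset, screen
  it for gross nonstationarity, and standardize each row to zero mean
  and unit variance (1/N convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import signal as sps
from scipy import stats as sst
from scipy.interpolate import CubicSpline

from .synth import EEG_BANDS, NODE_LABELS, STATES, RawRecording

__all__ = [
    "BeatSeries",
    "NetworkSeries",
    "NoBeatsError",
    "PulseDetectionError",
    "filter_ecg",
    "detect_r_peaks",
    "beat_rr",
    "resp_at_beats",
    "compute_pat",
    "resample_1hz",
    "eeg_band_power",
    "select_window",
    "check_stationarity",
    "standardize",
    "preprocess_recording",
]

WINDOW_LEN = 300          # analysis window, samples at 1 Hz
OFFSET_REST = 180.0       # s after record start for resting windows
OFFSET_TASK = 60.0        # s after task onset (configurable 60-120)
PAT_SEARCH_MAX = 0.6      # s, upper cap of the per-beat pulse search window
REFRACTORY = 0.25         # s, minimum R-R spacing enforced in detection


logger = logging.getLogger(__name__)


class NoBeatsError(RuntimeError):
    """The R-peak detector found no candidate beats."""


class PulseDetectionError(RuntimeError):
    """Too many beats without an acceptable blood pulse."""


@dataclass
class BeatSeries:
    """Per-beat quantities anchored at R-peak times.

    ``rr[k]`` is the interval closed by ``times[k]`` (the RR value is
    attributed to the second peak of each pair, when the interval is
    known).  All arrays share length.
    """

    times: NDArray[np.float64]
    rr: NDArray[np.float64]
    resp_at_beat: NDArray[np.float64] | None = None
    pat: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")
        for arr in (self.resp_at_beat, self.pat):
            if arr is not None and len(arr) != len(self.times):
                raise ValueError("beat-series arrays must share length")
        if self.pat is not None and np.any(
            (self.pat <= 0) | (self.pat >= self.rr)
        ):
            raise ValueError("each PAT must lie in (0, RR)")


@dataclass
class NetworkSeries:
    """The M x N synchronous 1 Hz matrix of node series.

    Rows follow the fixed order RR, RESP, PAT, delta, theta, alpha,
    beta.  ``t`` records the absolute timestamps (s) of the columns.
    """

    X: NDArray[np.float64]
    labels: list[str]
    state: str
    t: NDArray[np.float64] | None = None
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("network series contains non-finite values")
        if self.standardized:
            mu = np.abs(self.X.mean(axis=1)).max()
            dv = np.abs(self.X.var(axis=1) - 1.0).max()
            if mu > 1e-10 or dv > 1e-10:
                raise ValueError("standardized flag set but rows are not standardized")

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X.T, columns=self.labels)
        df.insert(0, "t", self.t if self.t is not None else np.arange(self.N))
        return df


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------


def filter_ecg(ecg: NDArray[np.float64], fs: float) -> NDArray[np.float64]:
    """Zero-phase 1-20 Hz band-pass (half-power corners, 4th-order design).

    Removes baseline wander below 1 Hz and high-frequency noise above
    20 Hz while preserving R-peak timing (forward-backward filtering).
    """
    if fs <= 40.0:
        raise ValueError(f"sampling rate {fs} Hz too low for a 20 Hz corner")
    sos = sps.butter(4, [1.0, 20.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ecg, dtype=float))


def _provisional_peaks(x: NDArray[np.float64], fs: float) -> NDArray[np.int_]:
    thr = 0.6 * np.percentile(np.abs(x), 95)
    if thr <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(x, height=thr, distance=max(1, int(REFRACTORY * fs)))
    return peaks


def detect_r_peaks(ecg_filtered: NDArray[np.float64], fs: float) -> NDArray[np.float64]:
    """Template-matching R-peak detection; returns peak times in seconds.

    A provisional amplitude-threshold pass (0.6 x 95th percentile of the
    rectified signal, 250 ms refractory) seeds a QRS template: the mean
    of +/-60 ms segments around the 20 largest provisional peaks.  The
    normalized cross-correlation of the template with the signal is then
    thresholded at 0.6, local maxima are taken with the same refractory
    spacing, and each R time is placed at the maximum of the aligned
    template.

    Raises
    ------
    NoBeatsError
        If no provisional or matched beats are found.
    """
    x = np.asarray(ecg_filtered, dtype=float)
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    prov = _provisional_peaks(x, fs)
    if len(prov) == 0:
        raise NoBeatsError("no candidate beats above the amplitude threshold")

    half = int(round(0.06 * fs))
    prov = prov[(prov >= half) & (prov < len(x) - half)]
    if len(prov) == 0:
        raise NoBeatsError("no candidate beats away from the record edges")
    best = prov[np.argsort(x[prov])[::-1][:20]]
    template = np.mean([x[p - half: p + half + 1] for p in best], axis=0)
    t0 = template - template.mean()
    t_norm = np.linalg.norm(t0)
    if t_norm == 0:
        raise NoBeatsError("degenerate (constant) QRS template")
    t0 /= t_norm
    w = len(t0)

    # normalized cross-correlation against each sliding window
    num = np.correlate(x, t0, mode="valid")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    win_sum = c1[w:] - c1[:-w]
    win_sq = c2[w:] - c2[:-w]
    win_var = np.maximum(win_sq - win_sum**2 / w, 1e-30)
    ncc = num / np.sqrt(win_var)

    cand, _ = sps.find_peaks(ncc, height=0.6, distance=max(1, int(REFRACTORY * fs)))
    if len(cand) == 0:
        raise NoBeatsError("no beats matched the QRS template")
    r_idx = cand + int(np.argmax(template))
    # shape match alone is not specific: band-limited noise can correlate
    # well with a smooth template, so the aligned sample must also clear
    # the amplitude threshold of the provisional pass
    thr = 0.6 * np.percentile(np.abs(x), 95)
    r_idx = r_idx[x[r_idx] >= thr]
    if len(r_idx) == 0:
        raise NoBeatsError("no beats matched the QRS template above threshold")
    return r_idx / fs


def beat_rr(
    peaks: NDArray[np.float64],
    plausibility: tuple[float, float] = (0.7, 1.3),
    running_median_beats: int = 11,
) -> BeatSeries:
    """RR intervals from R-peak times, with automated ectopic handling.

    ``rr[k] = times[k+1] - times[k]``, attributed to the closing peak.
    An interval outside ``plausibility x running-median`` is treated as
    an artifact: two consecutive implausibly short intervals whose sum is
    plausible are merged (a false peak split one beat), and any remaining
    out-of-band interval is bridged by linear interpolation of the RR
    value over neighbouring beats (a missed or ectopic beat).
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form RR intervals")
    lo, hi = plausibility

    # pass 1: merge false-peak splits
    times = list(peaks)
    changed = True
    while changed:
        changed = False
        rr = np.diff(times)
        if len(rr) < 3:
            break
        med = _running_median(rr, running_median_beats)
        k = 0
        while k < len(rr) - 1:
            if rr[k] < lo * med[k] and rr[k + 1] < lo * med[k + 1]:
                merged = rr[k] + rr[k + 1]
                if lo * med[k] <= merged <= hi * med[k]:
                    del times[k + 1]  # drop the spurious middle peak
                    changed = True
                    break
            k += 1

    times = np.asarray(times)
    rr = np.diff(times)
    med = _running_median(rr, running_median_beats)
    bad = (rr < lo * med) | (rr > hi * med)
    if np.any(bad) and np.any(~bad):
        idx = np.arange(len(rr))
        rr = rr.copy()
        rr[bad] = np.interp(idx[bad], idx[~bad], rr[~bad])
    return BeatSeries(times=times[1:], rr=rr)


def _running_median(x: NDArray[np.float64], width: int) -> NDArray[np.float64]:
    if len(x) == 0:
        return x
    half = width // 2
    out = np.empty_like(x)
    for k in range(len(x)):
        lo = max(0, k - half)
        hi = min(len(x), k + half + 1)
        out[k] = np.median(x[lo:hi])
    return out


# ---------------------------------------------------------------------------
# Respiration and BVP
# ---------------------------------------------------------------------------


def resp_at_beats(
    resp: NDArray[np.float64], fs: float, peaks: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Respiration value at the sample nearest each R-peak time."""
    resp = np.asarray(resp, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    idx = np.round(peaks * fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= len(resp)):
        raise ValueError("R peak outside the respiration signal span")
    return resp[idx]


def compute_pat(
    peaks: NDArray[np.float64],
    bvp: NDArray[np.float64],
    fs: float,
    w_max: float = PAT_SEARCH_MAX,
    max_missing_frac: float = 0.2,
) -> NDArray[np.float64]:
    """Per-beat pulse arrival time from the BVP maximum-derivative point.

    For each R peak the search window extends from the peak to
    ``min(next RR, w_max)`` seconds after it; the PAT is the time of the
    largest first difference of the BVP in that window, minus the peak
    time.  Beats whose window shows no usable upstroke (maximum first
    difference not clearly above the record's background) are marked
    missing and bridged by interpolation over beat index.

    Raises
    ------
    PulseDetectionError
        If more than ``max_missing_frac`` of beats lack a pulse.
    """
    peaks = np.asarray(peaks, dtype=float)
    bvp = np.asarray(bvp, dtype=float)
    d = np.diff(bvp)
    n_b = len(peaks)
    raw = np.full(n_b, np.nan)
    strength = np.zeros(n_b)
    for k, p in enumerate(peaks):
        nxt = peaks[k + 1] - p if k + 1 < n_b else w_max
        w = min(nxt, w_max)
        i0 = int(np.floor(p * fs)) + 1
        i1 = min(int(np.floor((p + w) * fs)), len(d))
        if i1 <= i0:
            continue
        seg = d[i0:i1]
        j = int(np.argmax(seg))
        strength[k] = seg[j]
        # first-difference d[i] approximates the slope at (i + 1/2) / fs
        raw[k] = (i0 + j + 0.5) / fs - p

    pos = strength[strength > 0]
    floor_val = 0.25 * np.median(pos) if len(pos) else np.inf
    ok = (strength > 0) & (strength >= floor_val) & ~np.isnan(raw)
    if np.mean(~ok) > max_missing_frac:
        raise PulseDetectionError(
            f"{int(np.sum(~ok))}/{n_b} beats without an acceptable pulse"
        )
    pat = raw.copy()
    if np.any(~ok):
        idx = np.arange(n_b)
        pat[~ok] = np.interp(idx[~ok], idx[ok], raw[ok])
    return pat


# ---------------------------------------------------------------------------
# Resampling and EEG band power
# ---------------------------------------------------------------------------


def resample_1hz(
    times: NDArray[np.float64],
    values: NDArray[np.float64],
    grid: NDArray[np.float64] | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Cubic-spline interpolation of a beat-time series onto a 1 Hz grid.

    When ``grid`` is omitted it is the integer seconds inside the
    beat-time span.  Requesting points outside the span raises (the
    spline would extrapolate).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 beats for cubic-spline resampling")
    if np.mean(np.diff(times)) > 1.0:
        warnings.warn("mean beat rate below 1 Hz: 1 Hz grid oversamples the beats")
    if grid is None:
        grid = np.arange(np.ceil(times[0]), np.floor(times[-1]) + 1.0)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or grid[0] < times[0] - 1e-9 or grid[-1] > times[-1] + 1e-9:
        raise ValueError("evaluation grid outside the beat-time span")
    cs = CubicSpline(times, values)
    return grid, cs(grid)


def eeg_band_power(
    eeg: NDArray[np.float64],
    fs: float,
    bands: dict[str, tuple[float, float]] = EEG_BANDS,
    epoch_s: float = 2.0,
    hop_s: float = 1.0,
) -> tuple[NDArray[np.float64], dict[str, NDArray[np.float64]]]:
    """Band-power time series from overlapping periodogram epochs.

    Each ``epoch_s``-second epoch (hop ``hop_s``) is mean-detrended and
    its rectangular-window periodogram summed over the frequency bins
    whose centre lies in each band's half-open range ``[low, high)``.
    A record of duration D seconds yields ``floor(D) - 1`` values per
    band, timestamped at the epoch centres (1, 2, ..., D-1 s).
    """
    eeg = np.asarray(eeg, dtype=float)
    if fs < 64.0:
        raise ValueError("EEG sampling rate must be >= 64 Hz")
    n_epoch = int(round(epoch_s * fs))
    hop = int(round(hop_s * fs))
    if len(eeg) < n_epoch:
        raise ValueError("signal shorter than one epoch")
    freqs = np.fft.rfftfreq(n_epoch, d=1.0 / fs)
    masks = {b: (freqs >= lo) & (freqs < hi) for b, (lo, hi) in bands.items()}
    n_out = (len(eeg) - n_epoch) // hop + 1
    t = np.empty(n_out)
    out = {b: np.empty(n_out) for b in bands}
    for k in range(n_out):
        seg = eeg[k * hop: k * hop + n_epoch]
        f, pxx = sps.periodogram(seg, fs=fs, window="boxcar", detrend="constant")
        for b in bands:
            out[b][k] = np.sum(pxx[masks[b]])
        t[k] = (k * hop + n_epoch / 2.0) / fs
    return t, out


# ---------------------------------------------------------------------------
# Window selection, stationarity, standardization
# ---------------------------------------------------------------------------


def select_window(
    df: pd.DataFrame,
    state: str,
    offset_task: float = OFFSET_TASK,
    offset_rest: float = OFFSET_REST,
    window_len: int = WINDOW_LEN,
) -> NetworkSeries:
    """Cut the 300-sample analysis window from a 1 Hz multichannel table.

    ``df`` must have a ``t`` column (absolute seconds) plus one column
    per node.  Resting windows start ``offset_rest`` (default 180 s)
    after the record start; task windows start ``offset_task`` (default
    60 s, configurable up to 120 s) after the task onset, taken as t=0
    of the record.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if not 0.0 <= offset_task:
        raise ValueError("offset_task must be nonnegative")
    offset = offset_rest if state == "REST" else offset_task
    sel = df[df["t"] >= offset].head(window_len)
    if len(sel) < window_len:
        raise ValueError(
            f"insufficient length: {len(sel)} samples at offset {offset} s, "
            f"need {window_len}"
        )
    labels = [c for c in df.columns if c != "t"]
    return NetworkSeries(
        X=sel[labels].to_numpy(dtype=float).T,
        labels=labels,
        state=state,
        t=sel["t"].to_numpy(dtype=float),
        standardized=False,
    )


@dataclass
class StationarityResult:
    passed: bool
    n_rejections: int
    n_tests: int
    details: list = field(default_factory=list)


def check_stationarity(
    series: NDArray[np.float64],
    n_sub: int = 10,
    sub_len: int = 50,
    alpha: float = 0.05,
    max_rejections: int = 3,
    seed: int = 0,
) -> StationarityResult:
    """Restricted weak-sense stationarity screen over random subwindows.

    ``n_sub`` random subwindows of ``sub_len`` samples are each compared
    against the pooled remainder of the series with a two-sided Welch
    t-test on the mean and a two-sided variance-ratio F-test (two tests
    per subwindow).  The series fails when more than ``max_rejections``
    of the ``2 * n_sub`` tests reject at level ``alpha``.

    The default ``max_rejections = 3`` is Monte-Carlo calibrated: the
    subwindows overlap, so the 20 tests are positively dependent and the
    rejection count is overdispersed relative to a binomial — allowing 3
    rejections keeps the false-alarm rate on iid Gaussian series near 5%
    while a step of 3 SD or a 4-SD linear trend still fails essentially
    always.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_sub and len(x) < sub_len + 2:
        raise ValueError("series too short for the subwindow scheme")
    if np.var(x) == 0:
        raise ValueError("degenerate (zero-variance) series")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(x) - sub_len + 1, size=n_sub)
    n_rej = 0
    details = []
    for s in starts:
        sub = x[s: s + sub_len]
        rest = np.concatenate([x[:s], x[s + sub_len:]])
        _, p_mean = sst.ttest_ind(sub, rest, equal_var=False)
        v1, v2 = np.var(sub, ddof=1), np.var(rest, ddof=1)
        F = v1 / v2
        d1, d2 = len(sub) - 1, len(rest) - 1
        p_var = 2.0 * min(sst.f.cdf(F, d1, d2), sst.f.sf(F, d1, d2))
        n_rej += int(p_mean < alpha) + int(p_var < alpha)
        details.append({"start": int(s), "p_mean": float(p_mean), "p_var": float(p_var)})
    return StationarityResult(
        passed=n_rej <= max_rejections,
        n_rejections=n_rej,
        n_tests=2 * n_sub,
        details=details,
    )


def standardize(net: NetworkSeries) -> NetworkSeries:
    """Reduce each row to zero mean and unit variance (1/N convention)."""
    X = net.X
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # ddof=0
    if np.any(sd == 0):
        bad = [net.labels[i] for i in np.where(sd.ravel() == 0)[0]]
        raise ValueError(f"constant row(s): {bad}")
    return NetworkSeries(
        X=(X - mu) / sd,
        labels=list(net.labels),
        state=net.state,
        t=None if net.t is None else net.t.copy(),
        standardized=True,
        meta=dict(net.meta),
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def preprocess_recording(
    rec: RawRecording,
    offset_task: float = OFFSET_TASK,
    offset_rest: float = OFFSET_REST,
    window_len: int = WINDOW_LEN,
    stationarity_seed: int = 0,
) -> NetworkSeries:
    """Run the whole preprocessing chain on one recording.

    Returns the standardized :class:`NetworkSeries`; diagnostics (beat
    count, stationarity flags, detected order of operations constants)
    land in ``meta``.  A stationarity failure logs a warning and flags
    the row but does not abort the analysis.
    """
    fs_ecg = rec.rates["ecg"]
    ecg_f = filter_ecg(rec.ecg, fs_ecg)
    peaks = detect_r_peaks(ecg_f, fs_ecg)
    beats = beat_rr(peaks)
    resp_b = resp_at_beats(rec.resp, rec.rates["resp"], beats.times)
    pat_b = compute_pat(peaks, rec.bvp, rec.rates["bvp"])[1:]  # align to closing peaks

    grid, rr_1hz = resample_1hz(beats.times, beats.rr)
    _, resp_1hz = resample_1hz(beats.times, resp_b, grid)
    _, pat_1hz = resample_1hz(beats.times, pat_b, grid)
    t_band, bands = eeg_band_power(rec.eeg, rec.rates["eeg"])

    # crop everything to the common integer-second timestamps
    common = np.intersect1d(grid, t_band)
    gi = np.searchsorted(grid, common)
    bi = np.searchsorted(t_band, common)
    df = pd.DataFrame({
        "t": common,
        "RR": rr_1hz[gi],
        "RESP": resp_1hz[gi],
        "PAT": pat_1hz[gi],
        **{b: bands[b][bi] for b in ("delta", "theta", "alpha", "beta")},
    })
    net = select_window(df, rec.state, offset_task=offset_task,
                        offset_rest=offset_rest, window_len=window_len)

    flags = {}
    for row, label in zip(net.X, net.labels):
        res = check_stationarity(row, seed=stationarity_seed)
        flags[label] = res.passed
        if not res.passed:
            logger.warning(
                "%s/%s: row %s failed the stationarity screen (%d/%d rejections)",
                rec.subject_id, rec.state, label, res.n_rejections, res.n_tests,
            )
    net.meta.update({
        "subject_id": rec.subject_id,
        "n_beats": len(beats.times),
        "stationarity": flags,
        "offsets": {"rest": offset_rest, "task": offset_task},
    })
    out = standardize(net)
    return out


def _expected_labels() -> list[str]:
    return list(NODE_LABELS)
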
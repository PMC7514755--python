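"""End-to-end orchestration: recordings -> measures -> consensus tables.

A *study* is a set of subjects, each with one recording per mental
state (REST — resting wakefulness, MA — mental arithmetic, SG — serious
game).  For every subject-state window the pipeline extracts the
7 x 300 network matrix, decomposes it into per-node information
measures, runs the link F-tests, and finally aggregates per-state
median tables and consensus graphs across subjects.

Everything is driven by a :class:`StudyConfig`; all artifacts are plain
CSV/JSON with a provenance sidecar, and identical (config, seed) reruns
produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import infodyn, inference, preprocess, synth, varss

__all__ = [
    "StudyConfig",
    "StageError",
    "SubjectStateResult",
    "StudyResult",
    "generate_study",
    "run_subject",
    "run_study",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """All tunables of the study pipeline with their default protocol values."""

    states: tuple[str, ...] = synth.STATES
    window_len: int = 300
    offset_rest: float = 180.0
    offset_task: float = 60.0
    max_order: int = 12
    order: int | None = None          # fixed VAR order; None = AIC per window
    alpha: float = 0.05
    consensus_thin: int = 7
    consensus_thick: int = 12
    backend: str = "state-space"
    fdr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len <= 0 or self.max_order <= 0 or not (0 < self.alpha < 1):
            raise ValueError("config fields out of range")
        if not 0 < self.consensus_thin <= self.consensus_thick:
            raise ValueError("consensus thresholds must satisfy 0 < thin <= thick")
        if self.backend not in ("state-space", "regression"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a config from JSON or YAML."""
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if "states" in d:
            d["states"] = tuple(d["states"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubjectStateResult:
    subject_id: str
    state: str
    network: preprocess.NetworkSeries
    measures: infodyn.InfoMeasures
    graph: inference.SubjectGraph
    order: int
    stable: bool


@dataclass
class StudyResult:
    per_subject: dict[str, dict[str, SubjectStateResult]]
    medians: dict[str, pd.DataFrame]               # measure -> states x nodes table
    consensus: dict[str, inference.ConsensusGraph]  # state -> graph
    excluded: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Synthetic study generation
# ---------------------------------------------------------------------------

STATE_PARAMS = {
    # mild state-dependent parameter shifts: faster breathing and heart
    # rate with weaker RSA under task load, mimicking autonomic arousal
    "REST": {"duration": 500.0, "resp_rate_hz": 0.25, "rr_mean": 0.85, "rsa_gain": 0.10},
    "MA": {"duration": 380.0, "resp_rate_hz": 0.30, "rr_mean": 0.75, "rsa_gain": 0.06},
    "SG": {"duration": 380.0, "resp_rate_hz": 0.28, "rr_mean": 0.80, "rsa_gain": 0.08},
}


def generate_study(
    out_dir: str | Path,
    n_subjects: int = 18,
    seed: int = 0,
    states: tuple[str, ...] = synth.STATES,
) -> list[Path]:
    """Generate a full synthetic study on disk; returns subject manifests.

    Layout: ``<out>/sub-XX/<STATE>/manifest.json`` per recording plus a
    subject-level ``subject.json`` mapping states to recordings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifests = []
    for s in range(n_subjects):
        sid = f"sub-{s + 1:02d}"
        sdir = out / sid
        state_map = {}
        for state in states:
            params = dict(STATE_PARAMS[state])
            rec = synth.synth_recording(
                state=state, subject_id=sid,
                seed=int(rng.integers(2**31)), **params,
            )
            mpath = synth.write_recording(rec, sdir / state)
            state_map[state] = str(Path(state) / "manifest.json")
        subj_manifest = sdir / "subject.json"
        subj_manifest.write_text(json.dumps(
            {"subject_id": sid, "states": state_map}, indent=1))
        manifests.append(subj_manifest)
    return manifests


# ---------------------------------------------------------------------------
# Per-subject pipeline
# ---------------------------------------------------------------------------


def _load_channels(manifest_path: Path) -> tuple[dict, dict, str, str]:
    man = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    chans = {}
    for name, fname in man.get("channels", {}).items():
        f = base / fname
        if f.exists():
            chans[name] = pd.read_csv(f)["value"].to_numpy(dtype=float)
    rates = {k: float(v) for k, v in man.get("rates_hz", {}).items()}
    return chans, rates, man.get("state", ""), man.get("subject_id", "")


def _process_state(
    chans: dict,
    rates: dict,
    state: str,
    subject_id: str,
    config: StudyConfig,
    partial_dir: Path | None = None,
) -> SubjectStateResult:
    partials: dict[str, pd.DataFrame] = {}
    stage = "load"

    def fail(exc: Exception):
        if partial_dir is not None:
            partial_dir.mkdir(parents=True, exist_ok=True)
            for name, df in partials.items():
                df.to_csv(partial_dir / f"partial_{name}.csv", index=False)
        raise StageError(stage, exc)

    try:
        stage = "filter_ecg"
        if "ecg" not in chans:
            raise KeyError("channel 'ecg' missing")
        ecg_f = preprocess.filter_ecg(chans["ecg"], rates["ecg"])
        stage = "detect_r_peaks"
        peaks = preprocess.detect_r_peaks(ecg_f, rates["ecg"])
        stage = "beat_rr"
        beats = preprocess.beat_rr(peaks)
        partials["rr"] = pd.DataFrame({"t": beats.times, "rr": beats.rr})
        stage = "resp_at_beats"
        if "resp" not in chans:
            raise KeyError("channel 'resp' missing")
        resp_b = preprocess.resp_at_beats(chans["resp"], rates["resp"], beats.times)
        partials["resp"] = pd.DataFrame({"t": beats.times, "resp": resp_b})
        stage = "eeg_band_power"
        if "eeg" not in chans:
            raise KeyError("channel 'eeg' missing")
        t_band, bands = preprocess.eeg_band_power(chans["eeg"], rates["eeg"])
        partials["bands"] = pd.DataFrame({"t": t_band, **bands})
        stage = "compute_pat"
        if "bvp" not in chans:
            raise KeyError("channel 'bvp' missing")
        pat_b = preprocess.compute_pat(peaks, chans["bvp"], rates["bvp"])[1:]
        stage = "resample_1hz"
        grid, rr_1hz = preprocess.resample_1hz(beats.times, beats.rr)
        _, resp_1hz = preprocess.resample_1hz(beats.times, resp_b, grid)
        _, pat_1hz = preprocess.resample_1hz(beats.times, pat_b, grid)
        stage = "select_window"
        common = np.intersect1d(grid, t_band)
        gi = np.searchsorted(grid, common)
        bi = np.searchsorted(t_band, common)
        df = pd.DataFrame({
            "t": common,
            "RR": rr_1hz[gi], "RESP": resp_1hz[gi], "PAT": pat_1hz[gi],
            **{b: bands[b][bi] for b in ("delta", "theta", "alpha", "beta")},
        })
        net = preprocess.select_window(
            df, state, offset_task=config.offset_task,
            offset_rest=config.offset_rest, window_len=config.window_len)
        stage = "stationarity"
        flags = {}
        for row, label in zip(net.X, net.labels):
            res = preprocess.check_stationarity(row, seed=config.seed)
            flags[label] = res.passed
            if not res.passed:
                logger.warning("%s/%s: row %s flagged nonstationary",
                               subject_id, state, label)
        stage = "standardize"
        net.meta.update({"subject_id": subject_id, "stationarity": flags,
                         "n_beats": len(beats.times)})
        net = preprocess.standardize(net)
        stage = "decompose"
        order = config.order or infodyn.select_order_with_fallback(
            net.X, config.max_order)
        fitted = varss.fit_var(net.X, order)
        stable = fitted.is_stable
        if not stable:
            logger.warning("%s/%s: unstable VAR fit (rho=%.4f); "
                           "subject flagged for exclusion from consensus",
                           subject_id, state, fitted.spectral_radius)
        measures = infodyn.decompose_network(
            net.X, m=order, labels=net.labels,
            backend=config.backend if stable else "regression")
        stage = "inference"
        graph = inference.subject_link_graph(
            net.X, m=order, alpha=config.alpha, labels=net.labels,
            fdr=config.fdr)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        fail(exc)
    return SubjectStateResult(
        subject_id=subject_id, state=state, network=net, measures=measures,
        graph=graph, order=order, stable=stable)


def run_subject(
    subject_manifest: str | Path,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, SubjectStateResult]:
    """Process every state of one subject; optionally write artifacts.

    On a stage failure the error names the stage and any partial 1 Hz
    series already extracted are preserved under the output directory.
    """
    config = config or StudyConfig()
    spath = Path(subject_manifest)
    man = json.loads(spath.read_text())
    sid = man["subject_id"]
    results = {}
    for state, rel in man["states"].items():
        if state not in config.states:
            continue
        t0 = time.perf_counter()
        chans, rates, state_m, _ = _load_channels(spath.parent / rel)
        pdir = None if out_dir is None else Path(out_dir) / sid / state
        res = _process_state(chans, rates, state_m or state, sid, config,
                             partial_dir=pdir)
        results[state] = res
        logger.info("%s/%s done in %.2f s (order %d)", sid, state,
                    time.perf_counter() - t0, res.order)
        if out_dir is not None:
            _write_state_result(res, Path(out_dir) / sid / state, config)
    return results


def _write_state_result(res: SubjectStateResult, d: Path, config: StudyConfig) -> None:
    d.mkdir(parents=True, exist_ok=True)
    res.network.to_frame().to_csv(d / "network.csv", index=False,
                                  float_format="%.10g")
    res.measures.to_frame(res.subject_id, res.state).to_csv(
        d / "measures.csv", index=False, float_format="%.10g")
    res.measures.tcond_frame().to_csv(d / "tcond.csv", float_format="%.10g")
    res.graph.edges_frame().to_csv(d / "links.csv", index=False,
                                   float_format="%.10g")
    sidecar = {
        "subject_id": res.subject_id,
        "state": res.state,
        "order": res.order,
        "stable": res.stable,
        "backend": res.measures.backend,
        "stationarity": res.network.meta.get("stationarity", {}),
        "config_hash": config.config_hash,
        "seed": config.seed,
    }
    (d / "provenance.json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Study level
# ---------------------------------------------------------------------------


def run_study(
    subject_manifests: list[str | Path],
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Process all subjects and aggregate medians and consensus topology.

    Subject-state windows whose fitted VAR is unstable are excluded from
    the consensus graphs (their identity is logged and recorded) but
    still appear in the per-subject tables.
    """
    config = config or StudyConfig()
    if not subject_manifests:
        raise ValueError("need at least one subject")
    per_subject: dict[str, dict[str, SubjectStateResult]] = {}
    for mpath in subject_manifests:
        res = run_subject(mpath, config, out_dir=out_dir)
        sid = next(iter(res.values())).subject_id if res else str(mpath)
        per_subject[sid] = res

    medians: dict[str, pd.DataFrame] = {}
    consensus: dict[str, inference.ConsensusGraph] = {}
    excluded: list[tuple[str, str]] = []
    labels = synth.NODE_LABELS
    for measure in ("S", "N", "T"):
        rows = {}
        for state in config.states:
            vals = [getattr(r[state].measures, measure)
                    for r in per_subject.values() if state in r]
            rows[state] = np.median(vals, axis=0)
        medians[measure] = pd.DataFrame.from_dict(
            rows, orient="index", columns=labels)
    for state in config.states:
        graphs, meas = [], []
        for sid, r in per_subject.items():
            if state not in r:
                continue
            if not r[state].stable:
                excluded.append((sid, state))
                continue
            graphs.append(r[state].graph)
            meas.append(r[state].measures)
        consensus[state] = inference.consensus_graph(
            graphs, meas, thin=config.consensus_thin,
            thick=config.consensus_thick)
    if excluded:
        logger.warning("excluded from consensus (unstable fits): %s", excluded)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure, df in medians.items():
            df.to_csv(out / f"median_{measure}.csv", float_format="%.10g")
        for state, cg in consensus.items():
            cg.edges_frame().to_csv(out / f"consensus_{state}.csv", index=False)
            gjson = {
                "nodes": [{"id": lab,
                           "mean_T": None if cg.node_mean_T is None
                           else float(cg.node_mean_T[k])}
                          for k, lab in enumerate(cg.labels)],
                "edges": cg.edges_frame().to_dict(orient="records"),
                "n_subjects": cg.n_subjects,
                "thresholds": {"thin": cg.thin, "thick": cg.thick},
            }
            (out / f"consensus_{state}.json").write_text(json.dumps(gjson, indent=1))
        (out / "study_provenance.json").write_text(json.dumps({
            "config": config.to_dict(), "config_hash": config.config_hash,
            "n_subjects": len(per_subject),
            "excluded_from_consensus": excluded,
        }, indent=1, default=str))
    return StudyResult(per_subject=per_subject, medians=medians,
                       consensus=consensus, excluded=excluded)
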
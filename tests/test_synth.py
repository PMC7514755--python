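"""Benchmark-network simulation, presets, the OLS oracle, and recordings."""

import json

import numpy as np
import pytest
from scipy import linalg as sla

from netinfodyn import synth
from netinfodyn.synth import (
    RawRecording,
    VarSpec,
    benchmark_preset,
    oracle_measures,
    read_recording,
    render_bvp,
    simulate_var,
    synth_recording,
    write_recording,
)


class TestSimulateVar:
    def test_ar1_stationary_variance(self):
        spec = VarSpec(M=1, m=1, A=[np.array([[0.9]])], Sigma=np.eye(1))
        x = simulate_var(spec, 100_000, seed=0)
        expected = 1.0 / (1.0 - 0.81)
        assert np.var(x) == pytest.approx(expected, rel=0.05)

    def test_white_noise_has_no_autocorrelation(self):
        spec = VarSpec(M=2, m=1, A=[np.zeros((2, 2))], Sigma=np.eye(2))
        n = 50_000
        x = simulate_var(spec, n, seed=2)
        for row in x:
            r1 = np.corrcoef(row[:-1], row[1:])[0, 1]
            assert abs(r1) < 3.0 / np.sqrt(n)

    def test_bivariate_covariance_matches_lyapunov(self):
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        spec = VarSpec(M=2, m=1, A=[A], Sigma=np.eye(2))
        x = simulate_var(spec, 200_000, seed=2)
        truth = sla.solve_discrete_lyapunov(A, np.eye(2))
        sample = np.cov(x)
        assert np.allclose(sample, truth, rtol=0.05)
        # lagged cross-correlation X1 -> X2 must be positive and large
        r = np.corrcoef(x[0, :-1], x[1, 1:])[0, 1]
        assert r > 0.3

    def test_identical_seed_bit_identical(self, paperlike_spec):
        a = simulate_var(paperlike_spec, 500, seed=7)
        b = simulate_var(paperlike_spec, 500, seed=7)
        c = simulate_var(paperlike_spec, 500, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_unstable_spec_rejected_with_diagnostic(self):
        spec = VarSpec(M=1, m=1, A=[np.array([[1.01]])], Sigma=np.eye(1))
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_var(spec, 100, seed=0)

    def test_too_few_samples_rejected(self, chain3_spec):
        with pytest.raises(ValueError):
            simulate_var(chain3_spec, 1, seed=0)


class TestPresets:
    def test_independent_has_no_links(self, independent_spec):
        adj = independent_spec.truth_adjacency
        np.fill_diagonal(adj, False)
        assert not adj.any()

    def test_chain3_has_exactly_the_two_chain_links(self, chain3_spec):
        adj = chain3_spec.truth_adjacency
        np.fill_diagonal(adj, False)
        links = set(zip(*np.where(adj)))
        assert links == {(0, 1), (1, 2)}

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            benchmark_preset("nope")

    def test_all_presets_stable(self):
        for name in synth.PRESET_NAMES:
            assert benchmark_preset(name).is_stable

    def test_paperlike_storage_ordering(self, paperlike_spec):
        """The preset encodes peripheral > brain storage: RR > RESP > PAT > bands."""
        meas = oracle_measures(paperlike_spec, n_oracle=100_000, seed=11)
        s = dict(zip(meas.labels, meas.S))
        assert s["RR"] > s["RESP"] > s["PAT"]
        assert s["PAT"] > max(s["delta"], s["theta"], s["alpha"], s["beta"])


class TestOracle:
    def test_independent_transfers_vanish(self, independent_spec):
        meas = oracle_measures(independent_spec, n_oracle=100_000, seed=5)
        off = meas.Tcond[~np.eye(7, dtype=bool)]
        assert np.nanmax(off) < 0.01

    def test_ar1_storage_closed_form(self):
        spec = VarSpec(M=1, m=1, A=[np.array([[0.9]])], Sigma=np.eye(1))
        meas = oracle_measures(spec, n_oracle=100_000, seed=6)
        assert meas.S[0] == pytest.approx(0.5 * np.log(1 / 0.19), abs=0.02)

    def test_chain3_mediated_transfer_is_null(self, chain3_oracle):
        assert chain3_oracle.Tcond[0, 2] < 0.01        # 1 -> 3 | 2: mediated
        assert chain3_oracle.Tcond[0, 1] > 0.05        # 1 -> 2 | 3: direct
        assert chain3_oracle.Tcond[1, 2] > 0.05        # 2 -> 3 | 1: direct

    def test_oracle_satisfies_decomposition_invariants(self, paperlike_spec):
        meas = oracle_measures(paperlike_spec, n_oracle=100_000, seed=7)
        assert np.max(np.abs(meas.H - (meas.S + meas.T + meas.N))) < 1e-6
        assert np.min(meas.S) >= -0.01
        assert np.min(meas.T) >= -0.01

    def test_independent_transfer_shrinks_with_sample_size(self, independent_spec):
        def max_transfer(n, seed):
            m = oracle_measures(independent_spec, n_oracle=n, seed=seed)
            return np.nanmax(m.Tcond)

        small = np.mean([max_transfer(20_000, s) for s in (0, 1, 2)])
        large = np.mean([max_transfer(80_000, s) for s in (0, 1, 2)])
        assert large < small

    def test_oracle_too_small_rejected(self, paperlike_spec):
        with pytest.raises(ValueError, match="too small"):
            oracle_measures(paperlike_spec, n_oracle=50, seed=0)


class TestSynthRecording:
    def test_beat_count_matches_mean_rate(self):
        rec = synth_recording(duration=400.0, state="REST", seed=0, rr_mean=0.8)
        n_expected = 400.0 / 0.8
        assert abs(len(rec.truth["beat_times"]) - n_expected) < 10

    def test_rsa_off_decouples_rr_from_respiration(self):
        rec = synth_recording(duration=400.0, state="REST", seed=1, rsa_gain=0.0)
        rr = rec.truth["rr"]
        drive = np.sin(rec.truth["resp_phase_at_beats"])
        assert abs(np.corrcoef(rr, drive)[0, 1]) < 0.1
        # variance is jitter only
        assert np.std(rr) == pytest.approx(0.02, rel=0.2)

    def test_constant_pat_is_exact(self):
        rec = synth_recording(duration=400.0, state="REST", seed=2,
                              pat_variation=0.0, pat_noise_sd=0.0)
        assert np.all(rec.truth["pat"] == 0.25)

    def test_same_seed_reproducible(self):
        a = synth_recording(duration=400.0, state="MA", seed=3)
        b = synth_recording(duration=400.0, state="MA", seed=3)
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.bvp, b.bvp)
        assert np.array_equal(a.eeg, b.eeg)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="360"):
            synth_recording(duration=100.0, state="REST", seed=0)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            synth_recording(duration=400.0, state="WALK", seed=0)

    def test_render_bvp_places_pulse_per_beat(self):
        beats = np.array([1.0, 2.0, 3.0])
        pats = np.array([0.25, 0.25, 0.25])
        bvp = render_bvp(beats, pats, duration=5.0, noise_sd=0.0, seed=0)
        d = np.diff(bvp)
        for tb in beats:
            i0 = int((tb + 0.1) * 64)
            i1 = int((tb + 0.5) * 64)
            j = np.argmax(d[i0:i1]) + i0
            assert ((j + 0.5) / 64.0 - tb) == pytest.approx(0.25, abs=1.0 / 64)


class TestRecordingIO:
    def test_roundtrip_preserves_channels_and_truth(self, tmp_path):
        rec = synth_recording(duration=400.0, state="SG", subject_id="S07", seed=4)
        mpath = write_recording(rec, tmp_path / "rec")
        back = read_recording(mpath)
        assert back.state == "SG" and back.subject_id == "S07"
        assert back.rates == rec.rates
        for ch in ("ecg", "resp", "bvp", "eeg"):
            orig, rt = getattr(rec, ch), getattr(back, ch)
            assert len(orig) == len(rt)
            scale = max(1.0, np.max(np.abs(orig)))
            assert np.max(np.abs(orig - rt)) < 1e-4 * scale
        assert np.allclose(back.truth["beat_times"], rec.truth["beat_times"])
        assert np.allclose(back.truth["pat"], rec.truth["pat"])

    def test_manifest_layout(self, tmp_path):
        rec = synth_recording(duration=400.0, state="REST", seed=5)
        mpath = write_recording(rec, tmp_path / "rec")
        man = json.loads(mpath.read_text())
        assert set(man["channels"]) == {"ecg", "resp", "bvp", "eeg"}
        assert man["rates_hz"]["ecg"] == 250.0
        assert (tmp_path / "rec" / "truth.json").exists()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            RawRecording(ecg=np.zeros(10), resp=np.zeros(10), bvp=np.zeros(10),
                         eeg=np.zeros(10), state="REST",
                         rates={"ecg": -1.0, "resp": 25.0, "bvp": 64.0,
                                "eeg": 256.0})
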
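"""Shared fixtures: benchmark specs and one default synthetic recording.

Expensive artifacts (recordings, long oracle realizations) are session
scoped so the whole suite pays for them once.
"""

import logging

import numpy as np
import pytest

from netinfodyn import preprocess, synth

logging.getLogger("netinfodyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def independent_spec():
    return synth.benchmark_preset("independent")


@pytest.fixture(scope="session")
def chain3_spec():
    return synth.benchmark_preset("chain3")


@pytest.fixture(scope="session")
def paperlike_spec():
    return synth.benchmark_preset("paperlike7")


@pytest.fixture(scope="session")
def default_recording():
    """One resting recording at default (study) parameters."""
    return synth.synth_recording(state="REST", seed=42)


@pytest.fixture(scope="session")
def default_peaks(default_recording):
    ecg_f = preprocess.filter_ecg(default_recording.ecg,
                                  default_recording.rates["ecg"])
    return preprocess.detect_r_peaks(ecg_f, default_recording.rates["ecg"])


@pytest.fixture(scope="session")
def default_network(default_recording):
    return preprocess.preprocess_recording(default_recording)


@pytest.fixture(scope="session")
def chain3_oracle(chain3_spec):
    return synth.oracle_measures(chain3_spec, n_oracle=100_000, seed=3)


def matched_fraction(detected: np.ndarray, truth: np.ndarray, tol: float):
    """(sensitivity, precision) of event detection within +/- tol seconds."""
    d = np.abs(detected[:, None] - truth[None, :])
    sens = float(np.mean(d.min(axis=0) <= tol))
    prec = float(np.mean(d.min(axis=1) <= tol))
    return sens, prec


@pytest.fixture(scope="session")
def match_events():
    return matched_fraction
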
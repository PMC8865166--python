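import numpy as np
import pytest

from drivestress.simulate import SessionConfig, sample_rr_train, synthesize_ecg


@pytest.fixture(scope="session")
def clean_session_beats():
    """A 60 s noise-free-morphology beat train with physiological HRV."""
    cfg = SessionConfig(baseline_hr=70.0, hrv_sd=3.0, rsa_amplitude=2.0)
    return cfg, sample_rr_train(cfg, None, duration=60.0, rng=11)


@pytest.fixture(scope="session")
def clean_ecg(clean_session_beats):
    cfg, beats = clean_session_beats
    times, signal = synthesize_ecg(beats, ecg_fs=500.0, noise_sd=0.0, duration=60.0)
    return beats, times, signal


def pair_beats(detected, truth, tol=0.05):
    """Nearest-neighbour pairing of detected vs true beats at +/-tol seconds.

    Returns (true positives, sensitivity, positive predictivity).
    """
    truth = np.asarray(truth)
    used = set()
    tp = 0
    for d in np.asarray(detected):
        j = int(np.argmin(np.abs(truth - d)))
        if abs(truth[j] - d) <= tol and j not in used:
            tp += 1
            used.add(j)
    sens = tp / len(truth) if len(truth) else 0.0
    ppv = tp / len(detected) if len(detected) else 0.0
    return tp, sens, ppv
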
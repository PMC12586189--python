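import numpy as np
import pytest

import resphrv as rv


@pytest.fixture
def mouse_resp():
    return rv.RespParams()


@pytest.fixture
def mouse_cardiac():
    return rv.CardiacParams()


@pytest.fixture(scope="session")
def freely_moving_session():
    """One rendered photostimulation session (ECG + pleth), seed 7."""
    schedule = rv.photostim_schedule()
    recording, truth = rv.build_session(schedule, seed=7)
    return recording, truth


def interior(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Events away from the recording edges, where detector baselines
    (rolling medians/maxima) are fully supported."""
    times = np.asarray(times, dtype=float)
    return times[(times >= lo) & (times <= hi)]


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy nearest matching of detected to true event times.

    Returns (n_matched, timing errors of matches, n_extra).
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    errors = []
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        k = int(np.argmin(d))
        if d[k] <= tol:
            used[k] = True
            errors.append(detected[k] - t)
    n_matched = len(errors)
    return n_matched, np.asarray(errors), int(detected.size - n_matched)
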
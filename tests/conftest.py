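import numpy as np
import pytest

import homebase as hb


@pytest.fixture(scope="session")
def room():
    return hb.default_room()


@pytest.fixture(scope="session")
def td_session(room):
    """One seeded TD-archetype session (trajectory + ground truth)."""
    return hb.simulate_session(hb.td_params(), room, seed=11, session_id="td_fix")


@pytest.fixture(scope="session")
def ntd_session(room):
    return hb.simulate_session(hb.ntd_params(), room, seed=12, session_id="ntd_fix")


@pytest.fixture(scope="session")
def td_result(room, td_session):
    traj, _ = td_session
    return hb.analyze_session(traj, room, hb.RunConfig(), group="TD")


@pytest.fixture(scope="session")
def no_maps_config():
    return hb.RunConfig(compute_maps=False)


def ring_oracle(d, r_in, r_out):
    """Independent brute-force two-threshold state machine (the test
    oracle for the ring algorithm): sequential scan, strict inequalities."""
    state = "OUT"
    start = None
    visits = []
    for i, x in enumerate(d):
        if state == "OUT" and x < r_in:
            state, start = "IN", i
        elif state == "IN" and x > r_out:
            visits.append((start, i, True))
            state = "OUT"
    if state == "IN":
        visits.append((start, len(d) - 1, False))
    return visits


@pytest.fixture(scope="session")
def random_walk_series():
    """Seeded random-walk distance series used for oracle-equivalence checks."""
    rng = np.random.default_rng(42)

    def make(n=300, scale=12.0, start=100.0):
        d = np.abs(start + np.cumsum(rng.normal(0.0, scale, n)))
        return d

    return make
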
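import numpy as np
import pandas as pd
import pytest

from epiquant.synth import EmbryoSimConfig, generate_embryo_tracks


def rect(r0, c0, r1, c1):
    """Axis-aligned rectangle polygon in (row, col) coordinates."""
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], float)


@pytest.fixture(scope="session")
def wt_tracks():
    """Small wild-type track table with its ground truth (jitter-free)."""
    cfg = EmbryoSimConfig(seed=7, genotype="wildtype",
                          n_divisions_per_embryo=4)
    return generate_embryo_tracks(cfg)


@pytest.fixture(scope="session")
def mutant_tracks():
    cfg = EmbryoSimConfig(seed=8, genotype="mutant",
                          n_divisions_per_embryo=4)
    return generate_embryo_tracks(cfg)


@pytest.fixture()
def simple_track_table():
    """Two-daughter single-division table built by hand.

    Mother sits at (10, 0) with the embryonic-region centre at the origin,
    daughter d1 ends nearer the centre (apical movement), d2 farther
    (basal movement).
    """
    rows = []

    def add(track, role, frame, x, y):
        rows.append({
            "embryo_id": "e0", "track_id": track, "role": role,
            "frame": frame, "t_min": 7.5 * frame, "x_um": x, "y_um": y,
            "centre_x_um": 0.0, "centre_y_um": 0.0, "division_id": "e0_d0",
            "genotype": "wildtype",
        })

    add("m", "mother", 0, 14.0, 0.0)
    add("m", "mother", 1, 10.0, 0.0)
    add("d1", "daughter_1", 2, 9.0, 1.0)
    add("d1", "daughter_1", 3, 5.0, 0.0)   # toward centre: apical
    add("d2", "daughter_2", 2, 11.0, -1.0)
    add("d2", "daughter_2", 3, 16.0, 0.0)  # away from centre: basal
    return pd.DataFrame(rows)
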
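import numpy as np
import pytest

import carthick as ct


@pytest.fixture(scope="session")
def knee():
    """Default three-bone knee phantom with its ground-truth thickness map."""
    vol, truth = ct.make_phantom(ct.default_knee_spec())
    return vol, truth


@pytest.fixture(scope="session")
def knee_volume(knee):
    return knee[0]


@pytest.fixture(scope="session")
def annulus3():
    """Calibration annulus with a 3.0 mm shell at 0.5 mm in-plane spacing."""
    return ct.annulus_phantom(3.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (n=400) with the default calibration, fixed seed."""
    spec = ct.CohortSpec(
        n_subjects=400, n_male=219, n_female=181, n_left=198, n_right=202, seed=7
    )
    return ct.make_cohort(spec)


def brute_force_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs oracle for the signed Euclidean distance field (tiny grids)."""
    sp = np.asarray(spacing, dtype=float)
    idx = np.indices(mask.shape).reshape(3, -1).T * sp
    inside = mask.reshape(-1)
    out = np.empty(inside.shape, dtype=float)
    pts_in = idx[inside]
    pts_out = idx[~inside]
    for i, (p, is_in) in enumerate(zip(idx, inside)):
        opposite = pts_out if is_in else pts_in
        d = np.sqrt(((opposite - p) ** 2).sum(axis=1)).min()
        out[i] = -d if is_in else d
    return out.reshape(mask.shape)
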
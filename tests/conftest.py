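import numpy as np
import pytest

from rootstress import (
    FIELD_BUSSCHER,
    FIELD_SURFACE,
    PACKED_BUSSCHER,
    PACKED_SURFACE,
    SyntheticConfig,
    generate_experiment,
    predict_qp,
    relative_elongation,
)


@pytest.fixture(scope="session")
def field_surface():
    return FIELD_SURFACE


@pytest.fixture(scope="session")
def packed_surface():
    return PACKED_SURFACE


@pytest.fixture(scope="session")
def field_busscher():
    return FIELD_BUSSCHER


@pytest.fixture(scope="session")
def packed_busscher():
    return PACKED_BUSSCHER


@pytest.fixture(scope="session")
def noise_free_table():
    """Default-design synthetic table with all noise switched off."""
    cfg = SyntheticConfig(seed=11, noise_re_sd=0.0, noise_qp_sd=0.0)
    return generate_experiment(cfg)


@pytest.fixture()
def busscher_grid():
    """Noise-free (BD, w, Qp) triples on a 6 x 5 grid from the Field power law."""
    bd, w = np.meshgrid(np.linspace(1.02, 1.42, 6), np.linspace(0.25, 0.45, 5))
    bd, w = bd.ravel(), w.ravel()
    return bd, w, predict_qp(FIELD_BUSSCHER, bd, w)


def surface_grid_obs(params, n_s=9, n_q=8, s_range=(50.0, 95.0), q_range=(0.3, 4.0)):
    """Noise-free observations of a surface on an n_s x n_q grid."""
    s, q = np.meshgrid(np.linspace(*s_range, n_s), np.linspace(*q_range, n_q))
    s, q = s.ravel(), q.ravel()
    return s, q, relative_elongation(params, q, s)
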
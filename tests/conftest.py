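import numpy as np
import pytest

from thermoseg import ClassParams, ScenarioConfig, generate_video


def small_polygon():
    return [(3.0, 8.0), (6.5, 12.5), (11.0, 11.0), (12.5, 6.0), (7.0, 3.5)]


@pytest.fixture
def small_cfg():
    """Desk-scale scenario: 16x16 px, shortened phases, full noise model."""
    return ScenarioConfig(n_rows=16, n_cols=16, t_bl=40.0, t_gap=5.0,
                          t_rec=60.0, tumor_polygon=small_polygon(), seed=7)


@pytest.fixture
def noiseless_cfg():
    """Deterministic limit: no noise, no heterogeneity, no oscillation."""
    params = {
        "healthy": ClassParams(t_base=33.5, t_base_sd=0.0, drop=4.0,
                               a=4.0, b=-0.12, a_rel_sd=0.0, b_rel_sd=0.0,
                               cardiac_amp=0.0, coherence_weight=0.1,
                               coherence_weight_sd=0.0),
        "tumor": ClassParams(t_base=32.5, t_base_sd=0.0, drop=4.0,
                             a=3.5, b=-0.02, a_rel_sd=0.0, b_rel_sd=0.0,
                             cardiac_amp=0.0, coherence_weight=0.9,
                             coherence_weight_sd=0.0),
    }
    return ScenarioConfig(n_rows=16, n_cols=16, t_bl=40.0, t_gap=5.0,
                          t_rec=60.0, tumor_polygon=small_polygon(),
                          class_params=params, noise_sd=0.0, slow_amp=0.0,
                          seed=3)


@pytest.fixture(scope="session")
def small_video_and_mask():
    cfg = ScenarioConfig(n_rows=16, n_cols=16, t_bl=40.0, t_gap=5.0,
                         t_rec=60.0, tumor_polygon=small_polygon(), seed=7)
    return generate_video(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
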
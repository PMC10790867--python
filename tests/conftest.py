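import numpy as np
import pytest

from oddbci import SimulationConfig, simulate_session
from oddbci import preprocess as prep
from oddbci.synthetic import condition_of


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_config():
    """Generator config with no artifacts and no rhythm modulation: plain
    spatially mixed 1/f background plus ERP templates."""
    return SimulationConfig(
        montage="scalp8", seed=7, blink_rate_per_min=0.0,
        muscle_rate_per_min=0.0, flatline_prob=0.0, nonstationarity_db=0.0)


@pytest.fixture(scope="session")
def small_session():
    """One short scalp session shared by read-only tests."""
    cfg = SimulationConfig(montage="scalp8", seed=21)
    rec, trials = simulate_session(cfg, 150)
    return cfg, rec, trials


@pytest.fixture(scope="session")
def cleaned_epochs(small_session):
    """ERP-band cleaned hit/miss epochs from the shared session."""
    _, rec, trials = small_session
    cleaned, asr, _ = prep.preprocess_recording(rec, band="erp")
    cond = condition_of(trials)
    keep = np.isin(cond, ["hit", "miss"])
    eps = prep.extract_epochs(cleaned, trials["onset_s"].to_numpy()[keep],
                              labels=cond[keep])
    return cleaned, eps


def random_spd(rng, n, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
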
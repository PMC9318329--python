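import pytest

from aminobalance import default_config, generate_cohort
from aminobalance.quantification import DialysisSession, UrineCollection


@pytest.fixture(scope="session")
def cohort():
    """Default-size synthetic cohort (59 dialysis patients, 33 controls)."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """Larger cohort for distribution-level checks."""
    return generate_cohort(default_config(seed=7, n_hd=2000, n_ctrl=800))


@pytest.fixture
def session_factory():
    def make(**kwargs):
        defaults = dict(
            v_dialysate=135.0, duration_h=4.0, n_per_week=3, uf_volume=2.0,
            weight_post=78.0,
        )
        defaults.update(kwargs)
        return DialysisSession(**defaults)

    return make


@pytest.fixture
def urine_factory():
    def make(**kwargs):
        defaults = dict(volume=1.0, panel={}, urea=0.0, protein=0.0)
        defaults.update(kwargs)
        return UrineCollection(**defaults)

    return make
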
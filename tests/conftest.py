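import numpy as np
import pytest

from gatedgsd.presets import make_design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_design():
    """Factory for a fast, small trial design (same structure as setting 1,
    shrunk for unit-test speed; loose futility thresholds so the stage-1
    event targets stay small)."""

    def factory(variant="gGSD", **overrides):
        kw = dict(
            n_total=160,
            enroll_duration=12.0,
            followup_duration=10.0,
            futility={
                "gamma": 0.2,
                "hr_alt": 0.7,
                "theta": {"F": 0.95, "S": 0.95},
            },
        )
        kw.update(overrides)
        return make_design(1, variant, **kw)

    return factory
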
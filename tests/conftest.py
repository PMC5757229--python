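import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import etpymodel as m

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return m.validate_config(m.default_config())


@pytest.fixture(scope="session")
def space():
    return m.enumerate_states()


@pytest.fixture(scope="session")
def base_results(cfg):
    return m.run_base_case(cfg)


def perturbed_config(seed: int) -> "m.ModelConfig":
    """A randomised but valid configuration, for conservation-style checks."""
    rng = np.random.default_rng(seed)
    cfg = m.default_config(seed=seed)
    cfg.cohort.ldl_mean = float(rng.uniform(100.0, 250.0))
    cfg.cohort.female_frac = float(rng.uniform(0.2, 0.8))
    cfg.target_10y_risk = float(rng.uniform(0.30, 0.70))
    cfg.risk_adjustment.pooled_rr = float(rng.uniform(3.0, 10.0))
    cfg.event_distribution = m.generate_event_distribution(int(rng.integers(1, 2**31)))
    cfg.efficacy.ldl_reduction_pct = float(rng.uniform(0.40, 0.6480))
    cfg.efficacy.ldl_reduction_ci = (0.0, 1.0)
    scale = float(rng.uniform(0.5, 2.0))
    cfg.costs.acute = {k: v * scale for k, v in cfg.costs.acute.items()}
    cfg.costs.post = {k: v * scale for k, v in cfg.costs.post.items()}
    cfg.discount.rate_costs = float(rng.uniform(0.0, 0.05))
    cfg.discount.rate_outcomes = float(rng.uniform(0.0, 0.05))
    cfg.revascularisation_rates = {
        "ecvd": float(rng.uniform(0.0, 0.2)),
        "acute_mi": float(rng.uniform(0.0, 0.6)),
        "post_mi": float(rng.uniform(0.0, 0.2)),
    }
    return m.validate_config(cfg)
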
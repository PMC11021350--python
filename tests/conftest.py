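import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from statetrace import _engine
from statetrace.cmr import StateTraceData
from statetrace.synthetic import SyntheticConfig, sample_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session", autouse=True)
def _compiled_kernels():
    """Pay JIT compilation once up front so individual tests time sanely."""
    _engine.warm_up()


@pytest.fixture(scope="session")
def small_dataset():
    """A small grid-layout synthetic dataset shared by pipeline tests."""
    return sample_dataset(
        SyntheticConfig(model="one_latent", n_participants=12, items_per_cell=3, seed=11)
    )


def monotone_state_trace(n_cond=5, with_backing=False, n_participants=8, seed=0):
    """Jointly monotone condition means (zero CMR misfit by construction)."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0.1, 0.9, size=n_cond))
    y = np.sort(rng.uniform(0.1, 0.9, size=n_cond))
    kwargs = {}
    if with_backing:
        noise_x = rng.normal(0, 1e-9, size=(n_participants, n_cond))
        noise_y = rng.normal(0, 1e-9, size=(n_participants, n_cond))
        xb = x + noise_x - noise_x.mean(axis=0)
        yb = y + noise_y - noise_y.mean(axis=0)
        kwargs = {"x_backing": xb, "y_backing": yb}
    return StateTraceData(
        condition_labels=[f"c{i}" for i in range(n_cond)],
        x_means=x,
        y_means=y,
        x_weights=np.ones(n_cond),
        y_weights=np.ones(n_cond),
        dv_names=("think", "feel"),
        **kwargs,
    )
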
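import numpy as np
import pytest

from kaedeflux import SimulationConfig, generate_cohort, simulate_axon
from kaedeflux.gradient_stats import fit_gradient_rate
from kaedeflux.pipeline import RunConfig, _axon_stats, quantify_axon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noise_free_config(**overrides) -> SimulationConfig:
    """Default kinetics rendered without any imaging noise or background."""
    base = dict(shot_noise=False, read_noise_sd=0.0, background=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


def recover_rate(stack, traces, run_config: RunConfig | None = None) -> float:
    """Full pipeline on one axon: ratio -> profile -> two-level OLS -> rate."""
    rc = run_config or RunConfig()
    profiles = quantify_axon(stack, traces, rc)
    points = _axon_stats(profiles, rc, stack.pixel_size_um)
    return fit_gradient_rate(points).rate


def cohort_rates(seed: int, n_plus: int = 10, n_minus: int = 6):
    """Simulated cohort at study defaults -> per-condition recovered rates."""
    manifest = generate_cohort(n_plus, n_minus, seed=seed)
    plus, minus = [], []
    for ax in manifest["axons"]:
        rate = recover_rate(ax["stack"], ax["traces"])
        (plus if ax["condition"] == "+UTR" else minus).append(rate)
    return np.array(plus), np.array(minus)


def rate_for_k_local(k_local: float, seed: int, noise_free: bool = False) -> float:
    """Recovered gradient rate for one axon with a planted synthesis rate."""
    cfg = (
        noise_free_config(k_local=k_local, rng_seed=seed)
        if noise_free
        else SimulationConfig(k_local=k_local, rng_seed=seed)
    )
    _, stack, traces = simulate_axon(cfg)
    return recover_rate(stack, traces)
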
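import numpy as np
import pandas as pd
import pytest

from yieldbayes import (GroupPosterior, ModelSpec, SamplerConfig,
                        MEASUREMENT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240327)


def make_measurements(yields_by_field, x0=0.0):
    """Small measurement table from {(field_id, group): [yields]}."""
    rows = []
    for i, ((fid, group), ys) in enumerate(yields_by_field.items()):
        for j, y in enumerate(ys):
            rows.append({
                "field_id": fid, "group": group,
                "x": x0 + 50.0 * i, "y": 5.0 * j,
                "area_m2": 86.6, "dry_yield_kg_ha": float(y),
            })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def make_posterior(mu_draws, sigma_draws=None):
    """GroupPosterior wrapping externally supplied draws (2 pseudo-chains)."""
    mu = np.asarray(mu_draws, dtype=float)
    if sigma_draws is None:
        sigma_draws = np.ones_like(mu)
    sigma = np.asarray(sigma_draws, dtype=float)
    n = (mu.size // 2) * 2
    mu2 = mu[:n].reshape(2, n // 2)
    sg2 = sigma[:n].reshape(2, n // 2)
    return GroupPosterior(
        mu=mu2, sigma=sg2, acceptance_rate=1.0,
        rhat={"mu": 1.0, "sigma": 1.0},
        ess={"mu": float(n), "sigma": float(n)},
        spec=ModelSpec(mu_loc=float(mu.mean()), mu_scale=1.0, sigma_scale=1.0),
        config=SamplerConfig(), n_obs=n)
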
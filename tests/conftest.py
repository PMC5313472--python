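import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from herdfap.dynamics import SurvivalParams
from herdfap.engine import ReproConstants
from herdfap.model import HerdModel, _bulk_operating_point
from herdfap.pricing import BulkOperatingPoint, build_price_function
from herdfap.synthetic import GeneratorConfig, simulate_herds


def geometric_gamma(cont: float, n_max: int = 8) -> dict:
    """Final-lactation distributions for a constant continuation probability."""
    out = {}
    for j in range(1, n_max):
        g, reach = {}, 1.0
        for l in range(j + 1, n_max):
            g[l] = reach * (1.0 - cont)
            reach *= cont
        g[n_max] = reach
        out[j] = g
    return out


@pytest.fixture(scope="session")
def sim():
    """One 80-cow herd over 3.5 years, with ground truth."""
    cfg = GeneratorConfig(n_herds=1, cows_per_herd=80, years=3.5, seed=2024)
    records, truth = simulate_herds(cfg)
    return records, truth


@pytest.fixture(scope="session")
def toy_model(sim):
    """A HerdModel assembled from generator truth (no fitting): fast and exact."""
    records, truth = sim
    from herdfap.io import derive_records

    return HerdModel(
        herd_id="H001",
        milk_curves=truth.milk_curves,
        scc_curves=truth.scc_curves,
        xi_milk={1: 0.3, 2: 0.3, 3: 0.3, "pooled": 0.3},
        xi_scc={1: 0.3, 2: 0.3, 3: 0.3, "pooled": 0.3},
        survival={pg: truth.survival[pg] for pg in ("1", "2", "3+")},
        gamma=geometric_gamma(0.65),
        lambda_milk=0.5,
        lambda_scc=0.2,
        bulk=_bulk_operating_point(derive_records(records)),
        scheme=build_price_function(),
        constants=ReproConstants(),
    )
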
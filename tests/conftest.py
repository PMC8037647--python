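import numpy as np
import pytest

from rdsearch.models import FieldContext, ThreeStateParams, TwoStateParams
from rdsearch.synthetic import GeneratorSpec, default_nu_grid, generate_dataset, make_benchmark


@pytest.fixture(scope="session")
def gsir_bench():
    """Noise-free 11-residue bundle with per-residue three-state truth."""
    datasets, truth, spec = make_benchmark("gsir", noise_sd=0.0, seed=0)
    return datasets, truth


@pytest.fixture(scope="session")
def gstr_bench():
    """Noise-free 11-residue bundle with shared rates (kex=844, kzb=9.8)."""
    datasets, truth, spec = make_benchmark("gstr", noise_sd=0.0, seed=0)
    return datasets, truth


@pytest.fixture()
def one_residue():
    """Single noise-free three-state residue at two fields."""
    p = ThreeStateParams(r20=2.0, kex=885.0, dw_fc=388.0, kzb=9.29, dw_bz=1440.0)
    spec = GeneratorSpec(residues={"Y177": p}, noise_sd=0.0, seed=0)
    datasets, truth = generate_dataset(spec)
    return datasets[0], p


def random_three_state(rng) -> ThreeStateParams:
    return ThreeStateParams(
        r20=rng.uniform(-2, 10), kex=rng.uniform(50, 2000),
        dw_fc=rng.uniform(1, 1500), kzb=rng.uniform(0, 50),
        dw_bz=rng.uniform(1, 1500),
    )
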
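"""Shared fixtures: small synthetic datasets and cached benchmark runs."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

import isoratio as ir

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> ir.SyntheticConfig:
    """A fast simulated experiment: 40 groups (20 shifted), 200 background."""
    return replace(ir.BENCHMARK_CONFIG, n_background=200, n_groups=40,
                   n_shifted=20, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> ir.SyntheticDataset:
    return ir.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run(small_config):
    """(results, recovery report, dataset) of the small config."""
    return ir.run_benchmark(small_config)


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard benchmark run (1500 background, 100 null + 100 shifted,
    CV 0.2, no interference, seed 17)."""
    return ir.run_benchmark(ir.BENCHMARK_CONFIG)


@pytest.fixture()
def two_group_design() -> ir.DesignSpec:
    """3 vs 3 samples, one condition factor."""
    table = pd.DataFrame({
        "sample": [f"s{i}" for i in range(6)],
        "channel": [str(126 + i) for i in range(6)],
        "condition": ["a"] * 3 + ["b"] * 3,
    })
    return ir.build_design(table, "~ condition")


def make_matrix(values, samples=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"r{i}" for i in range(arr.shape[0])],
                        columns=samples)
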
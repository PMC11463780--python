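"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from meltgp.covariance import HierarchySpec, HyperParams
from meltgp.datasets import ProteinDataset, read_long_table
from meltgp.scaling import apply_scaling
from meltgp.simulate import SimulationDesign, simulate_dataset

TEMPS10 = np.linspace(37.0, 67.0, 10)


def make_toy_table(
    n_ids=2, conditions=("Ctrl", "Trt"), replicates=("R1", "R2"),
    temps=TEMPS10, seed=0,
) -> pd.DataFrame:
    """Deterministic positive-abundance long table with smooth decay curves."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ids):
        for c in conditions:
            for r in replicates:
                base = 1e6 * rng.uniform(0.5, 2.0)
                for t in temps:
                    ab = base * (1.0 / (1.0 + np.exp((t - 50) / 4)) + 0.05)
                    ab *= 1.0 + 0.02 * rng.standard_normal()
                    rows.append((f"P{i}", c, r, t, ab))
    return pd.DataFrame(
        rows, columns=["id", "condition", "replicate", "temperature", "abundance"]
    )


def make_dataset(table: pd.DataFrame, ident: str = "P0", scaling="mean"):
    ds = read_long_table(table)[ident]
    return apply_scaling(ds, scaling)


def toy_theta(units, sigma2_f=0.005, **kw) -> HyperParams:
    params = dict(
        lambda1=15.0, lambda2=8.0, sigma2_h=0.05, sigma2_g=0.01, beta2=0.002
    )
    params.update(kw)
    return HyperParams(sigma2_f={u: sigma2_f for u in units}, **params)


@pytest.fixture
def toy_table():
    return make_toy_table()


@pytest.fixture
def toy_dataset(toy_table):
    return make_dataset(toy_table)


@pytest.fixture
def sim_small():
    """Ten simulated identifiers, half differential, ready for the pipeline."""
    design = SimulationDesign(
        n_identifiers=10, fraction_differential=0.5, seed=7
    )
    obs, truth = simulate_dataset(design)
    return design, obs, truth


@pytest.fixture
def three_condition_dataset():
    design = SimulationDesign(n_identifiers=1, n_conditions=3, seed=13)
    obs, _ = simulate_dataset(design)
    ds = read_long_table(obs, require_positive=False)["sim_0000"]
    return apply_scaling(ds, "none")
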
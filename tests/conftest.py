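"""Shared fixtures: tiny hand-built datasets and small simulated collections."""

from __future__ import annotations

import numpy as np
import pytest

from stemsig import (ExpressionDataset, SignatureCollection, SimulationConfig,
                     generate_collection)


def make_dataset(values, n_control, name="ds", genes=None):
    """ExpressionDataset from a raw matrix with the first n_control columns
    as the control arm."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionDataset(
        name=name,
        genes=genes,
        samples=samples,
        values=values,
        control_ids=samples[:n_control],
        test_ids=samples[n_control:],
    )


@pytest.fixture
def separated_6v6():
    """Cleanly separated 6v6 dataset: strong mean shift on half the genes."""
    rng = np.random.default_rng(42)
    values = rng.normal(7.0, 0.5, size=(200, 12))
    values[:100, 6:] += 3.0
    return make_dataset(values, n_control=6, name="sep6v6")


@pytest.fixture(scope="session")
def small_collection():
    """Small reference simulation shared by read-only tests."""
    config = SimulationConfig(
        n_genes=600,
        genotypes=(
            ("T1", 2, {"proliferation": 1.5, "emt": -1.5}),
            ("T2", 2, {"emt": 1.5}),
        ),
        modules={"proliferation": 40, "emt": 40},
        n_decoy_signatures=30,
        n_related_per_module=4,
        seed=11,
    )
    return generate_collection(config)
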
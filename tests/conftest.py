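"""Shared fixtures: small synthetic cohorts reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from plaqomics.blocks import MultiOmicsDataset, OmicsBlock
from plaqomics.preprocess import PreprocessParams, preprocess_dataset
from plaqomics.simulate import SimulationConfig, generate_multiomics

SMALL_BLOCKS = [("gene", 120, 0.0), ("protein", 80, 0.26), ("peptide", 100, 0.39)]


def make_cohort(seed: int, effect_size: float = 2.0, preprocess: bool = True):
    """Study-scale cohort (16 vs 26 samples) with desk-scale block sizes."""
    cfg = SimulationConfig(
        n_per_class=(16, 26),
        block_specs=SMALL_BLOCKS,
        n_informative=10,
        effect_size=effect_size,
        seed=seed,
    )
    data, truth = generate_multiomics(cfg)
    if preprocess:
        data, _ = preprocess_dataset(data, PreprocessParams(top_n_variance=None))
    return data, truth


@pytest.fixture(scope="session")
def cohort():
    """One preprocessed separable cohort shared by read-only tests."""
    return make_cohort(seed=11)


@pytest.fixture(scope="session")
def complete_two_block():
    """Tiny fully observed two-block dataset for exact-math tests."""
    cfg = SimulationConfig(
        n_per_class=(10, 12),
        block_specs=[("gene", 60, 0.0), ("protein", 40, 0.0)],
        n_informative=5,
        effect_size=2.0,
        seed=3,
    )
    data, truth = generate_multiomics(cfg)
    return data, truth


def block_from_array(arr, name="b", feature_prefix="f", sample_prefix="s"):
    """features x samples ndarray -> OmicsBlock with generated ids."""
    arr = np.asarray(arr, dtype=float)
    return OmicsBlock(
        name,
        pd.DataFrame(
            arr,
            index=[f"{feature_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
        ),
    )


def dataset_from_arrays(arrays: dict, labels, positive_label=None):
    """{name: features x samples array} + labels -> MultiOmicsDataset."""
    blocks = [block_from_array(a, name=n) for n, a in arrays.items()]
    sids = blocks[0].sample_ids
    return MultiOmicsDataset(
        blocks, pd.Series(list(labels), index=sids), positive_label=positive_label
    )
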
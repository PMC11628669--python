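"""Shared fixtures: small synthetic datasets and matrix builders."""

import numpy as np
import pandas as pd
import pytest

from karyorda import GenotypeMatrix, PredictorTable, SampleTable
from karyorda.simulate import SimConfig, simulate


def make_genotypes(values, karyotype_col=None, contig="chr1"):
    """GenotypeMatrix from a plain array, with auto ids and positions."""
    values = np.asarray(values)
    n, L = values.shape
    locus_map = pd.DataFrame({
        "locus_id": [f"L{j + 1}" for j in range(L)],
        "contig": contig,
        "position": np.arange(1, L + 1) * 1000,
    })
    return GenotypeMatrix(values, locus_map,
                          [f"S{i + 1}" for i in range(n)],
                          karyotype_col=karyotype_col)


def make_samples(n, populations=None, two_n=None):
    pops = populations if populations is not None else ["P1"] * n
    tn = two_n if two_n is not None else [72] * n
    return SampleTable(pd.DataFrame({
        "sample_id": [f"S{i + 1}" for i in range(n)],
        "population": pops,
        "species": "C_laevigata",
        "lat": np.linspace(36, 44, n),
        "lon": np.linspace(-8, 0, n),
        "two_n": tn,
    }))


def make_predictors(arrays: dict, classes: dict | None = None):
    n = len(next(iter(arrays.values())))
    t = pd.DataFrame({"sample_id": [f"S{i + 1}" for i in range(n)], **arrays})
    return PredictorTable(t, classes or {})


@pytest.fixture(scope="session")
def study_sim():
    """One full-size synthetic study (34 pops, 153 samples, 700 loci)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A compact dataset for faster pipeline-level tests."""
    sizes = (4, 3, 3, 3, 2, 2, 2, 1) * 2
    return simulate(SimConfig(
        n_pops=16, pop_sizes=sizes, n_neutral=120, n_adaptive=20, seed=5))
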
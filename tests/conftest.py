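import warnings

import numpy as np
import pandas as pd
import pytest

import fpdiv


@pytest.fixture(autouse=True)
def _quiet_pcoa_warnings():
    # negative-eigenvalue warnings from Gower PCoA are expected and noisy
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="PCoA produced")
        yield


@pytest.fixture
def three_species_traits():
    return fpdiv.TraitTable(
        pd.DataFrame(
            {"mass": [10.0, 20.0, 30.0], "diet": ["insect", "seed", "insect"]},
            index=["A", "B", "C"],
        ),
        {"mass": "continuous", "diet": "nominal"},
    )


@pytest.fixture
def small_tree():
    return fpdiv.read_newick("((A:1,B:1):1,C:2);")


def random_mixed_traits(rng, n_species, n_cont=2, n_ord=1, n_nom=1, missing=0.0):
    """Random mixed-type trait table, optionally with missing values."""
    species = [f"s{i}" for i in range(n_species)]
    data, types = {}, {}
    for j in range(n_cont):
        data[f"c{j}"] = rng.normal(size=n_species)
        types[f"c{j}"] = "continuous"
    for j in range(n_ord):
        data[f"o{j}"] = rng.integers(0, 5, n_species).astype(float)
        types[f"o{j}"] = "ordinal"
    for j in range(n_nom):
        data[f"n{j}"] = rng.choice(["x", "y", "z"], n_species)
        types[f"n{j}"] = "nominal"
    df = pd.DataFrame(data, index=species)
    if missing:
        for col in df.columns:
            mask = rng.random(n_species) < missing
            # never blank out everything
            if mask.all():
                mask[rng.integers(n_species)] = False
            df.loc[mask, col] = np.nan
    return fpdiv.TraitTable(df, types)


def random_community(rng, n_sites, n_species, p=0.4):
    m = (rng.random((n_sites, n_species)) < p).astype(int)
    # ensure invariants: each species somewhere, each site at least 2 species
    for j in range(n_species):
        if m[:, j].sum() == 0:
            m[rng.integers(n_sites), j] = 1
    for i in range(n_sites):
        while m[i].sum() < 2:
            m[i, rng.integers(n_species)] = 1
    return fpdiv.CommunityMatrix(
        pd.DataFrame(m, index=[f"site{i}" for i in range(n_sites)],
                     columns=[f"s{j}" for j in range(n_species)])
    )
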
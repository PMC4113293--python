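import numpy as np
import pandas as pd
import pytest

from streambeta import CommunityMatrix, SiteMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_cm():
    """Three sites, three taxa, hand-countable."""
    data = pd.DataFrame(
        [[3, 0, 2], [0, 5, 1], [4, 4, 0]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(data)


def random_community(rng, n_sites, n_taxa, lam=1.0):
    """Random integer community with every site non-empty."""
    counts = rng.poisson(lam, size=(n_sites, n_taxa))
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] += 1
    data = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    return CommunityMatrix(data)


@pytest.fixture
def two_region_cm(rng):
    cm = random_community(rng, 10, 12, lam=2.0)
    groups = {"north": cm.site_ids[:5], "south": cm.site_ids[5:]}
    return cm, groups


@pytest.fixture
def metadata_frame():
    regions = ["R1"] * 3 + ["R2"] * 3
    islands = ["North"] * 3 + ["South"] * 3
    rng = np.random.default_rng(5)
    table = pd.DataFrame(
        {
            "site_id": [f"{r}_s{i}" for i, r in enumerate(regions)],
            "region": regions,
            "island": islands,
            "depth": rng.uniform(0.1, 0.5, 6),
            "velocity": rng.uniform(0.1, 0.9, 6),
            "slope": rng.uniform(0.5, 5, 6),
            "canopy": rng.uniform(0, 100, 6),
            "substrate_index": rng.uniform(30, 200, 6),
            "macrophytes": rng.uniform(0, 40, 6),
            "chl_a": rng.uniform(0.1, 4, 6),
            "pfankuch_bottom": rng.uniform(20, 45, 6),
            "steepness": rng.uniform(5, 60, 6),
        }
    )
    return table
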
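import numpy as np
import pytest

from connstage.atlas import RegionAtlas
from connstage.connectome import CohortConnectomes, Connectome
from connstage.synthetic import SyntheticConfig, generate_cohort

import pandas as pd


def make_connectome(n, edges, gfa=None, adc=None, subject_id="s"):
    """Build a connectome from {(i, j): weight} dicts."""
    w = np.zeros((n, n))
    for (i, j), v in edges.items():
        w[i, j] = w[j, i] = v
    g = a = None
    if gfa is not None:
        g = np.zeros((n, n))
        for (i, j), v in gfa.items():
            g[i, j] = g[j, i] = v
    if adc is not None:
        a = np.zeros((n, n))
        for (i, j), v in adc.items():
            a[i, j] = a[j, i] = v
    return Connectome(w, gfa=g, adc=a, subject_id=subject_id)


def small_atlas(n):
    table = pd.DataFrame(
        {
            "region_id": range(n),
            "label": [f"r{i}" for i in range(n)],
            "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n)],
            "tissue_class": ["cortical"] * n,
        }
    )
    return RegionAtlas(table)


@pytest.fixture
def triangle_connectome():
    """3 nodes, w12=2, w13=3, w23=5 (0-based: (0,1)=2, (0,2)=3, (1,2)=5)."""
    return make_connectome(3, {(0, 1): 2.0, (0, 2): 3.0, (1, 2): 5.0})


@pytest.fixture(scope="session")
def small_synthetic():
    """A reduced synthetic cohort for fast integration-style unit tests."""
    config = SyntheticConfig(
        group_sizes={"HC": 14, "II": 8, "IIIa": 6, "IIIb": 6, "IIIc": 5},
        n_regions=30,
        seed=11,
    )
    return generate_cohort(config)


def random_connectome(rng, n, density=0.5, max_w=10):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.integers(1, max_w + 1, size=len(iu[0])).astype(float) * present
    w[iu] = vals
    return Connectome(w + w.T, subject_id="r")
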
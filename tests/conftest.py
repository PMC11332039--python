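import numpy as np
import pandas as pd
import pytest

from coralpopgen.synthetic_data import SimulationConfig, simulate_dataset
from coralpopgen.variants import GenotypeMatrix


def make_gm(dosages, contigs=None, positions=None, qual=None, sample_ids=None):
    """Small GenotypeMatrix builder for hand-written cases."""
    d = np.asarray(dosages, dtype=np.int8)
    n, s = d.shape
    return GenotypeMatrix(
        d,
        sample_ids or [f"s{i:02d}" for i in range(n)],
        np.asarray(contigs if contigs is not None else ["chr1"] * s, dtype=object),
        np.asarray(positions if positions is not None else np.arange(1, s + 1)),
        np.asarray(qual if qual is not None else np.full(s, 50.0)),
    )


@pytest.fixture(scope="session")
def small_survey():
    """Default-design survey (11 islands x 3 sites x 3 colonies, 3 species)
    at a modest locus count, shared across read-only tests."""
    cfg = SimulationConfig(n_sites_genomic=1200, n_clone_pairs=2, seed=42)
    gm, meta, env, truth = simulate_dataset(cfg)
    return cfg, gm, meta, env, truth


@pytest.fixture(scope="session")
def lineages(small_survey):
    _, _, meta, _, _ = small_survey
    return meta.set_index("sample_id")["lineage"]
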
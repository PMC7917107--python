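import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests import the oracles module

from heterosis.io_formats import TriadCountMatrix


@pytest.fixture
def toy_matrix() -> TriadCountMatrix:
    """2 features x 9 samples (3 genotypes x 3 replicates, stage S)."""
    samples = [f"{g}_S_r{i}" for g in ("P1", "F1", "P2") for i in (1, 2, 3)]
    counts = pd.DataFrame(
        [[10, 12, 11, 20, 22, 21, 30, 33, 31], [100, 90, 110, 100, 95, 105, 100, 98, 102]],
        index=["featA", "featB"],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "genotype": [s.split("_")[0] for s in samples],
            "stage": "S",
            "replicate": [int(s[-1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return TriadCountMatrix(counts=counts, sample_meta=meta)


def triad_from_means(
    mu_p1: float, mu_f1: float, mu_p2: float, n_features: int, n_reps: int,
    dispersion: float, seed: int, stage: str = "S",
) -> TriadCountMatrix:
    """NB matrix where every feature shares one planted mean triple."""
    rng = np.random.default_rng(seed)

    def draw(mu):
        if dispersion == 0:
            return rng.poisson(mu, size=(n_features, n_reps))
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu), size=(n_features, n_reps))

    blocks, names = [], []
    for g, mu in (("P1", mu_p1), ("F1", mu_f1), ("P2", mu_p2)):
        blocks.append(draw(mu))
        names += [f"{g}_{stage}_r{i + 1}" for i in range(n_reps)]
    counts = pd.DataFrame(
        np.hstack(blocks), index=[f"f{i}" for i in range(n_features)], columns=names
    )
    meta = pd.DataFrame(
        {
            "genotype": [s.split("_")[0] for s in names],
            "stage": stage,
            "replicate": [int(s.split("r")[-1]) for s in names],
        },
        index=pd.Index(names, name="sample"),
    )
    return TriadCountMatrix(counts=counts, sample_meta=meta)
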
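"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from admixscan.data import GenotypeMatrix
from admixscan.synthio import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Neutral dataset: 150 loci, 30+30 parents, 20 F1s, a little missingness."""
    cfg = SimulationConfig(
        n_loci=150, n_island=30, n_mainland=30, n_f1=20,
        missing_rate=0.03, seed=101, years=(2015, 2016, 2017),
        traits=("height", "conelets"),
    )
    return generate_dataset(cfg, annotate=True)


@pytest.fixture(scope="session")
def selected_dataset():
    """Dataset with complete selection (s=1) planted at ten diagnostic loci."""
    cfg = SimulationConfig(
        n_loci=300, n_island=40, n_mainland=40, n_f1=30,
        selected_loci=tuple(range(10)), s=1.0,
        missing_rate=0.02, seed=77, years=(2015, 2016),
        traits=("height",),
    )
    return generate_dataset(cfg, annotate=True)


def toy_matrix(codes, ancestry_labels=None, **kwargs):
    """Build a GenotypeMatrix from a nested list of codes (loci x individuals)."""
    codes = np.asarray(codes, dtype=np.int8)
    n_loci, n_ind = codes.shape
    inds = [f"s{j}" for j in range(n_ind)]
    ancestry = None
    if ancestry_labels is not None:
        ancestry = dict(zip(inds, ancestry_labels))
    return GenotypeMatrix(
        genotypes=codes,
        locus_ids=[f"chr1:{100 + i}" for i in range(n_loci)],
        individuals=inds,
        ancestry=ancestry,
        **kwargs,
    )
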
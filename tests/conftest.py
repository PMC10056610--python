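import io

import numpy as np
import pytest

import fibermir as fm


@pytest.fixture(scope="session")
def refs():
    """Ten synthetic mature references, lengths 21-24, Hamming-separated."""
    return fm.gen_reference(10, (21, 24), seed=11)


@pytest.fixture(scope="session")
def default_counts():
    design = fm.default_design(seed=42)
    counts, truth = fm.sim_mixture_counts(design)
    return design, counts, truth


@pytest.fixture()
def group_design(default_counts):
    design, counts, _ = default_counts
    return fm.GroupDesign(dict(zip(counts.columns, design.groups)))


def fastq_handle(text: str) -> io.StringIO:
    return io.StringIO(text)


@pytest.fixture(scope="session")
def nb_matrix():
    """A random NB count matrix with unequal library scales, 6 samples."""
    rng = np.random.default_rng(20240917)
    mu = rng.lognormal(3.5, 1.3, size=300)
    cols = []
    for f in [1.0, 1.3, 0.7, 2.0, 1.0, 0.9]:
        cols.append(rng.negative_binomial(n=10, p=1.0 / (1.0 + 0.1 * mu * f)))
    import pandas as pd

    return pd.DataFrame(
        np.vstack(cols).T,
        index=[f"g{i:03d}" for i in range(300)],
        columns=[f"s{j}" for j in range(6)],
    )
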
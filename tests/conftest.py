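import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import seedcourse as sc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def marker_grm22():
    """Near-diagonal GRM for 22 lines from ~100 effective independent loci."""
    markers = sc.simulate.simulate_markers(22, 100, seed=5)
    return sc.grm_vanraden(markers)


@pytest.fixture(scope="session")
def structured_grm22():
    """Family-structured relationship matrix (well-identified variances)."""
    return sc.simulate.structured_grm(22, n_families=5, relatedness=0.5)


@pytest.fixture(scope="session")
def design6():
    """Small complete design: 6 lines x 6 times x 2 locations x 2 reps."""
    return sc.StudyDesign(n_lines=6, missing_fraction=0.0)


@pytest.fixture(scope="session")
def null_counts(design6):
    """Counts with no time effects, no genetics, no latent factor."""
    truth = sc.simulate.make_truth(design6, 300, pattern_codes=["00000"],
                                   h2=0.0, seed=11, latent_fraction=0.0)
    cm, md = sc.simulate.simulate_counts(design6, truth, seed=12,
                                         line_sd=0.0, latent_sd=0.0)
    return cm


def random_count_matrix(n_tx=30, n_s=8, seed=0, lam=20.0):
    """Small Poisson count fixture with minimal metadata."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_tx, n_s)),
        index=[f"T{i}" for i in range(n_tx)],
        columns=[f"S{j}" for j in range(n_s)])
    md = pd.DataFrame({
        "line": [f"L{j % 2}" for j in range(n_s)],
        "location": ["S1"] * n_s,
        "replicate": [1 + (j // 2) % 2 for j in range(n_s)],
        "daa": [8 + 5 * (j % 3) for j in range(n_s)],
    }, index=counts.columns)
    return sc.CountMatrix(counts, md)
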
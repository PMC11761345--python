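import numpy as np
import pandas as pd
import pytest

from omicsimpute import FixtureSpec, OmicsMatrix, generate, golden_matrices


def make_matrix(rows, groups=None, sample_prefix="s", feature_prefix="f"):
    """Small helper: build an OmicsMatrix from a list of row lists."""
    arr = np.asarray(rows, dtype=float)
    frame = pd.DataFrame(
        arr,
        index=[f"{sample_prefix}{i + 1}" for i in range(arr.shape[0])],
        columns=[f"{feature_prefix}{j + 1}" for j in range(arr.shape[1])],
    )
    return OmicsMatrix(frame, groups)


@pytest.fixture
def golden():
    return golden_matrices()


@pytest.fixture
def correlated_matrix():
    """Strongly correlated positive matrix: one latent factor, small noise."""
    return generate(FixtureSpec(n_samples=30, n_features=10, n_latent=1,
                                noise_sd=0.05, marginal="linear", seed=7))


@pytest.fixture
def lognormal_matrix():
    """Skewed, omics-like complete matrix."""
    return generate(FixtureSpec(n_samples=25, n_features=8, noise_sd=0.2, seed=11))
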
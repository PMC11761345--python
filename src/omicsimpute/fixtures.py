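"""Synthetic omics-like matrices with controllable correlation structure.

The generator emulates the gross statistical shape of mass-spectrometry
feature tables: strictly positive intensities, right-skewed (lognormal-like)
marginals, and correlation induced by a small number of latent factors
(shared biology / shared platform response). It exists so every other part
of the package can be exercised deterministically without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import OmicsMatrix

__all__ = ["FixtureSpec", "generate", "golden_matrices"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complete matrix.

    Features are exponentiated linear functions of ``n_latent`` shared
    Gaussian factors plus feature-specific Gaussian noise of SD
    ``noise_sd`` (on the log scale), then floored at ``value_floor`` so
    every cell is strictly positive. ``groups`` partitions features into
    named blocks (labels cycled over features).
    """

    n_samples: int = 45
    n_features: int = 40
    n_latent: int = 3
    noise_sd: float = 0.25
    groups: tuple[str, ...] | None = None
    value_floor: float = 1e-6
    log_mean: float = 6.0
    marginal: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1 or self.n_latent < 1:
            raise ValueError("dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.value_floor <= 0:
            raise ValueError("value_floor must be > 0")
        if self.marginal not in ("lognormal", "linear"):
            raise ValueError("marginal must be 'lognormal' or 'linear'")


def generate(spec: FixtureSpec) -> OmicsMatrix:
    """Generate one complete positive matrix from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 13]))
    z = rng.normal(size=(spec.n_samples, spec.n_latent))
    # loadings bounded away from 0 so every feature is a strictly monotone
    # map of the latent signal when noise_sd == 0
    w = rng.uniform(0.5, 1.5, size=(spec.n_latent, spec.n_features))
    w *= rng.choice([-1.0, 1.0], size=w.shape)
    signal = spec.log_mean + z @ w / np.sqrt(spec.n_latent)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(scale=spec.noise_sd, size=signal.shape)
    if spec.marginal == "lognormal":
        values = np.exp(signal) + spec.value_floor
    else:
        # strictly positive linear-in-latents intensities: shift each feature
        # so its smallest value sits well above zero
        values = signal - signal.min(axis=0, keepdims=True) + spec.log_mean + spec.value_floor
    frame = pd.DataFrame(
        values,
        index=[f"sample_{i + 1}" for i in range(spec.n_samples)],
        columns=[f"feat_{j + 1}" for j in range(spec.n_features)],
    )
    groups = None
    if spec.groups is not None:
        labels = list(spec.groups)
        groups = {f: labels[j % len(labels)] for j, f in enumerate(frame.columns)}
    return OmicsMatrix(frame, groups)


def _mat(rows: list[list[float]], n_features: int | None = None) -> OmicsMatrix:
    arr = np.array(rows, dtype=float)
    frame = pd.DataFrame(
        arr,
        index=[f"s{i + 1}" for i in range(arr.shape[0])],
        columns=[f"f{j + 1}" for j in range(arr.shape[1])],
    )
    return OmicsMatrix(frame)


def golden_matrices() -> dict[str, OmicsMatrix]:
    """Hand-written matrices with known answers, keyed by scenario name."""
    nan = np.nan

    constant7 = _mat([[7.0] * 3 for _ in range(6)])

    # two identical rows, one of which lost a cell; two decoys far away
    knn_duplicates = _mat([
        [1.0, 2.0, 3.0],
        [1.0, 2.0, nan],
        [50.0, 60.0, 70.0],
        [55.0, 65.0, 75.0],
    ])

    # f2 = 2 * f1 exactly; one f2 cell hidden
    collinear = _mat([
        [1.0, 2.0],
        [2.0, 4.0],
        [3.0, 6.0],
        [4.0, 8.0],
        [5.0, 10.0],
        [6.0, nan],
        [7.0, 14.0],
        [8.0, 16.0],
    ])

    # every row and column has a missing cell; dropping the 90%-missing
    # column f4 exposes 9 complete rows of 3 features
    ladder_rows = []
    for i in range(10):
        row = [float(10 * i + j + 1) for j in range(4)]
        if i < 9:
            row[3] = nan
        ladder_rows.append(row)
    for j in range(3):
        ladder_rows[9][j] = nan
    ladder = _mat(ladder_rows)

    # 6 x 3, fully observed: exactly the 18-value eligibility boundary
    eligibility_boundary = _mat(
        [[float(i * 3 + j + 1) for j in range(3)] for i in range(6)]
    )
    below = eligibility_boundary.values.copy()
    below.iloc[0, 0] = nan
    eligibility_below = OmicsMatrix(below)

    return {
        "constant7": constant7,
        "knn_duplicates": knn_duplicates,
        "collinear": collinear,
        "ladder": ladder,
        "eligibility_boundary": eligibility_boundary,
        "eligibility_below": eligibility_below,
    }
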
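"""Simulation of the three canonical missingness mechanisms on a complete table.

Given a fully observed samples x features matrix, each simulator hides a
known budget of cells and returns both the masked matrix and the hidden
("holdout") true values, so that imputation error can be scored exactly.

* MCAR — every cell equally likely: rank one uniform draw per cell and mask
  the lowest ``round(threshold * n_cells)`` draws.
* MNAR — missingness depends on the (unobserved) value itself, emulating
  e.g. limit-of-detection censoring: per feature, draw L1 ~ logistic(0, 1)
  and L2 ~ uniform(0, 1), form L3 = L1 * L2, pick the most extreme L3 ranks
  (both tails), read off the L1 rank at each picked position, and mask the
  cell whose *measurement* rank equals that L1 rank. Because extreme
  products require extreme logistic draws, masked cells concentrate at the
  feature's value extremes.
* MAR — missingness depends on the *other* features in the sample: the same
  L1/L3 construction runs per sample across features, but ranks are taken
  on each cell's co-dependence score (the sum of the sample's other feature
  values, within the cell's feature group when groups are declared).

All three are pure functions of ``(matrix, threshold, seed)``: each
(mechanism, row-or-column, group) gets its own named RNG stream derived
from the seed, so masks are reproducible and independent of iteration
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import rankdata

from .data_model import OmicsMatrix
from .exceptions import BudgetError, CoDependenceError


def _require_complete(x: OmicsMatrix) -> None:
    if not x.is_complete():
        raise ValueError(
            f"simulators need a fully observed matrix; {x.n_missing} cells are missing"
        )

__all__ = [
    "Mechanism",
    "SimulatedDataset",
    "simulate_mcar",
    "simulate_mnar",
    "simulate_mar",
    "simulate",
]


class Mechanism(str, Enum):
    MCAR = "MCAR"
    MAR = "MAR"
    MNAR = "MNAR"


_MECH_CODE = {Mechanism.MCAR: 1, Mechanism.MNAR: 2, Mechanism.MAR: 3}


@dataclass(frozen=True)
class SimulatedDataset:
    """A masked copy of a complete matrix plus the values it hides.

    ``holdout`` lists ``(sample_index, feature_index, true_value)`` for every
    simulated-missing cell; ``masked`` equals the source matrix everywhere
    else.
    """

    masked: OmicsMatrix
    holdout: list[tuple[int, int, float]]
    mechanism: Mechanism
    threshold: float
    seed: int

    @property
    def holdout_truth(self) -> np.ndarray:
        return np.array([v for _, _, v in self.holdout], dtype=float)

    def holdout_predictions(self, imputed: OmicsMatrix) -> np.ndarray:
        arr = imputed.to_numpy()
        return np.array([arr[i, j] for i, j, _ in self.holdout], dtype=float)


def _budget(threshold: float, pool: int, what: str) -> int:
    """Round-half-away-from-zero cell budget; must leave at least one cell
    masked and at least one observed."""
    b = int(np.floor(threshold * pool + 0.5))
    if b < 1:
        raise BudgetError(
            f"threshold {threshold} masks 0 of {pool} {what} cells; raise the threshold"
        )
    if b >= pool:
        raise BudgetError(
            f"threshold {threshold} would mask all {pool} {what} cells; lower the threshold"
        )
    return b


def _check_preconditions(x: OmicsMatrix, threshold: float) -> None:
    _require_complete(x)
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")


def _stream(seed: int, mechanism: Mechanism, *idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _MECH_CODE[mechanism], *idx]))


def _ordinal_ranks(v: np.ndarray) -> np.ndarray:
    # ties broken by first occurrence in index order
    return rankdata(v, method="ordinal").astype(int)


def _extreme_positions(l3: np.ndarray, budget: int) -> np.ndarray:
    """Positions whose L3 rank is among the budgeted extremes.

    floor(budget/2) cells come from the highest ranks, the remainder from
    the lowest — the extra cell goes to the low tail, mimicking
    limit-of-detection loss.
    """
    n = len(l3)
    r3 = _ordinal_ranks(l3)
    n_high = budget // 2
    n_low = budget - n_high
    wanted = set(range(1, n_low + 1)) | set(range(n - n_high + 1, n + 1))
    return np.flatnonzero(np.isin(r3, list(wanted)))


def _finish(x: OmicsMatrix, mask: np.ndarray, mechanism: Mechanism,
            threshold: float, seed: int) -> SimulatedDataset:
    arr = x.to_numpy()
    holdout = [(int(i), int(j), float(arr[i, j])) for i, j in np.argwhere(mask)]
    masked_vals = x.values.copy()
    masked_arr = masked_vals.to_numpy()
    masked_arr[mask] = np.nan
    masked_vals.iloc[:, :] = masked_arr
    masked = OmicsMatrix(masked_vals, None if x.groups is None else dict(x.groups))
    return SimulatedDataset(masked, holdout, mechanism, threshold, int(seed))


def simulate_mcar(x: OmicsMatrix, threshold: float, seed: int) -> SimulatedDataset:
    """Mask ``round(threshold * n_cells)`` cells uniformly at random."""
    _check_preconditions(x, threshold)
    ns, nf = x.shape
    b = _budget(threshold, ns * nf, "matrix")
    rng = _stream(seed, Mechanism.MCAR, 0)
    draws = rng.uniform(0.0, 1.0, size=(ns, nf))
    ranks = _ordinal_ranks(draws.ravel()).reshape(ns, nf)
    mask = ranks <= b
    return _finish(x, mask, Mechanism.MCAR, threshold, seed)


def simulate_mnar(x: OmicsMatrix, threshold: float, seed: int) -> SimulatedDataset:
    """Mask value-dependent cells: per feature, ``round(threshold * n_samples)``
    cells drawn from both value extremes via the logistic-product construction."""
    _check_preconditions(x, threshold)
    ns, nf = x.shape
    b = _budget(threshold, ns, "per-feature")
    arr = x.to_numpy()
    mask = np.zeros((ns, nf), dtype=bool)
    for j in range(nf):
        rng = _stream(seed, Mechanism.MNAR, j)
        l1 = rng.logistic(loc=0.0, scale=1.0, size=ns)
        l2 = rng.uniform(0.0, 1.0, size=ns)
        l3 = l1 * l2
        positions = _extreme_positions(l3, b)
        r1 = _ordinal_ranks(l1)
        rdata = _ordinal_ranks(arr[:, j])
        target_ranks = r1[positions]
        mask[np.isin(rdata, target_ranks), j] = True
    return _finish(x, mask, Mechanism.MNAR, threshold, seed)


def simulate_mar(x: OmicsMatrix, threshold: float, seed: int,
                 groups: dict[str, str] | None = None) -> SimulatedDataset:
    """Mask cells according to the extremity of their co-dependence score.

    The co-dependence score of cell (i, j) is the sum of sample i's *other*
    feature values, restricted to feature j's group when groups are
    declared. Each (sample, group) block is processed independently with a
    per-group budget ``round(threshold * group_size)``, so the mask inside
    one group never depends on another group's values.
    """
    _check_preconditions(x, threshold)
    if groups is None:
        groups = x.groups
    ns, nf = x.shape
    arr = x.to_numpy()
    col_of = {f: j for j, f in enumerate(x.feature_ids)}
    if groups is None:
        blocks = {"__all__": list(range(nf))}
    else:
        blocks = {}
        for f in x.feature_ids:
            blocks.setdefault(groups[f], []).append(col_of[f])
    mask = np.zeros((ns, nf), dtype=bool)
    for g_idx, label in enumerate(sorted(blocks)):
        cols = np.array(blocks[label], dtype=int)
        m = len(cols)
        if m == 1:
            raise CoDependenceError(
                f"feature group {label!r} has a single feature; "
                "co-dependence is undefined"
            )
        b = _budget(threshold, m, f"per-sample group {label!r}")
        for i in range(ns):
            rng = _stream(seed, Mechanism.MAR, i, g_idx)
            l1 = rng.logistic(loc=0.0, scale=1.0, size=m)
            l2 = rng.uniform(0.0, 1.0, size=m)
            l3 = l1 * l2
            positions = _extreme_positions(l3, b)
            r1 = _ordinal_ranks(l1)
            codep = arr[i, cols].sum() - arr[i, cols]
            rcodep = _ordinal_ranks(codep)
            target_ranks = r1[positions]
            mask[i, cols[np.isin(rcodep, target_ranks)]] = True
    return _finish(x, mask, Mechanism.MAR, threshold, seed)


def simulate(x: OmicsMatrix, mechanism: Mechanism | str, threshold: float,
             seed: int) -> SimulatedDataset:
    """Dispatch to the mechanism-specific simulator."""
    mech = Mechanism(mechanism)
    if mech is Mechanism.MCAR:
        return simulate_mcar(x, threshold, seed)
    if mech is Mechanism.MNAR:
        return simulate_mnar(x, threshold, seed)
    return simulate_mar(x, threshold, seed)
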
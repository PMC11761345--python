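"""Distributional diagnostics: complete-case deletion vs imputation.

Imputation is worthwhile only if it leaves the data's distribution closer
to the (unknown) truth than simply deleting every sample and feature that
contains a missing value. This module quantifies the comparison with:

* pooled histograms of feature-z-scored values on shared bin edges,
* per-feature skewness and kurtosis (population moments; a normal feature
  has skewness 0 and kurtosis 3 — high skewness hints that values are
  missing preferentially at one abundance extreme, i.e. possibly MNAR),
* PCA in both orientations: samples as observations with features as
  variables, and features as observations with samples as variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .data_model import OmicsMatrix
from .exceptions import UndefinedMomentError

__all__ = [
    "skewness",
    "kurtosis",
    "complete_case",
    "PCAResult",
    "DiagnosticsReport",
    "compare_datasets",
]

#: |skewness| above this is flagged as possibly missing-not-at-random
SKEW_FLAG = 1.0


def _checked(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 3:
        raise UndefinedMomentError(f"need at least 3 values, got {arr.size}")
    if np.var(arr) == 0.0:
        raise UndefinedMomentError("zero variance; moment undefined")
    return arr


def skewness(v) -> float:
    """Third standardized moment m3 / m2^(3/2) (population estimator).

    Zero for symmetric data; positive when the right tail is long.
    """
    return float(stats.skew(_checked(v), bias=True))


def kurtosis(v) -> float:
    """Fourth standardized moment m4 / m2^2 (population, not excess).

    3 for a normal distribution; the minimum attainable value is 1.
    """
    return float(stats.kurtosis(_checked(v), fisher=False, bias=True))


def complete_case(m: OmicsMatrix) -> OmicsMatrix:
    """Delete every sample and every feature that contains a missing value."""
    mask = m.mask.to_numpy()
    keep_rows = ~mask.any(axis=1)
    keep_cols = ~mask.any(axis=0)
    return m.subset(samples=m.values.index[keep_rows],
                    features=m.values.columns[keep_cols])


@dataclass
class PCAResult:
    scores: pd.DataFrame          # observations x components
    loadings: pd.DataFrame        # variables x components
    variance_explained: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Scores @ loadings.T: the centered standardized matrix."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def _zscore_columns(frame: pd.DataFrame) -> pd.DataFrame:
    arr = frame.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=frame.index, columns=frame.columns)


def _pca(frame: pd.DataFrame) -> PCAResult:
    """Full-rank PCA on column-standardized data."""
    z = _zscore_columns(frame)
    n_comp = min(z.shape)
    model = PCA(n_components=n_comp)
    scores = model.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=frame.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_,
    )


def _moments_table(m: OmicsMatrix) -> pd.DataFrame:
    rows = {}
    for f in m.feature_ids:
        col = m.values[f].dropna().to_numpy()
        try:
            rows[f] = {"skewness": skewness(col), "kurtosis": kurtosis(col)}
        except UndefinedMomentError:
            rows[f] = {"skewness": np.nan, "kurtosis": np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


def _pooled_z(m: OmicsMatrix) -> np.ndarray:
    return _zscore_columns(m.values).to_numpy().ravel()


@dataclass
class DiagnosticsReport:
    """Distributional comparison of a complete-case matrix vs an imputed one."""

    bin_edges: np.ndarray
    cleaned_counts: np.ndarray
    imputed_counts: np.ndarray
    cleaned_moments: pd.DataFrame
    imputed_moments: pd.DataFrame
    pca_samples: PCAResult | None
    pca_features: PCAResult | None
    pca_samples_cleaned: PCAResult | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def pca_dict(p: PCAResult | None):
            if p is None:
                return None
            return {
                "scores": p.scores.round(6).to_dict(orient="index"),
                "loadings": p.loadings.round(6).to_dict(orient="index"),
                "variance_explained": [float(v) for v in p.variance_explained],
            }

        return {
            "histogram": {
                "bin_edges": [float(e) for e in self.bin_edges],
                "cleaned_counts": [int(c) for c in self.cleaned_counts],
                "imputed_counts": [int(c) for c in self.imputed_counts],
            },
            "cleaned_moments": self.cleaned_moments.round(6).to_dict(orient="index"),
            "imputed_moments": self.imputed_moments.round(6).to_dict(orient="index"),
            "pca_samples": pca_dict(self.pca_samples),
            "pca_features": pca_dict(self.pca_features),
            "pca_samples_cleaned": pca_dict(self.pca_samples_cleaned),
            "notes": self.notes,
        }


def compare_datasets(cleaned: OmicsMatrix, imputed: OmicsMatrix) -> DiagnosticsReport:
    """Build the full diagnostics report.

    ``cleaned`` is the complete-case deletion of the original data (see
    :func:`complete_case`); ``imputed`` the completed dataset. Histograms
    share Freedman-Diaconis bin edges computed on the pooled z-scores of
    both datasets so the two distributions are directly comparable. PCA is
    omitted (with a note) when the cleaned matrix is degenerate.
    """
    if not imputed.is_complete():
        raise ValueError("imputed matrix still contains missing cells")
    notes: list[str] = []

    z_clean = _pooled_z(cleaned) if cleaned.values.size else np.array([])
    z_imp = _pooled_z(imputed)
    pooled = np.concatenate([z_clean, z_imp])
    edges = np.histogram_bin_edges(pooled, bins="fd")
    clean_counts, _ = np.histogram(z_clean, bins=edges)
    imp_counts, _ = np.histogram(z_imp, bins=edges)

    cleaned_moments = (_moments_table(cleaned) if cleaned.values.size
                       else pd.DataFrame(columns=["skewness", "kurtosis"]))
    imputed_moments = _moments_table(imputed)

    flagged = imputed_moments.index[imputed_moments["skewness"].abs() > SKEW_FLAG]
    for f in flagged:
        notes.append(
            f"feature {f!r}: |skewness| = {abs(imputed_moments.loc[f, 'skewness']):.3f} > "
            f"{SKEW_FLAG:g}; strongly asymmetric distributions can indicate "
            "value-dependent (MNAR) missingness"
        )

    degenerate = cleaned.n_samples < 2 or cleaned.n_features < 2
    if degenerate:
        notes.append("complete-case matrix is degenerate (<2 rows or columns); PCA omitted")
        pca_samples = pca_features = pca_cleaned = None
    else:
        pca_samples = _pca(imputed.values)
        pca_features = _pca(imputed.values.T)
        pca_cleaned = _pca(cleaned.values)

    return DiagnosticsReport(
        bin_edges=edges,
        cleaned_counts=clean_counts,
        imputed_counts=imp_counts,
        cleaned_moments=cleaned_moments,
        imputed_moments=imputed_moments,
        pca_samples=pca_samples,
        pca_features=pca_features,
        pca_samples_cleaned=pca_cleaned,
        notes=notes,
    )
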
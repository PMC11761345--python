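"""Matplotlib renderings of a :class:`~omicsimpute.diagnostics.DiagnosticsReport`."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import DiagnosticsReport, PCAResult

__all__ = ["plot_report"]


def _histogram(report: DiagnosticsReport, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = report.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2
    width = edges[1] - edges[0]
    ax.bar(centers, report.cleaned_counts, width=width, alpha=0.5,
           label="complete-case deleted")
    ax.bar(centers, report.imputed_counts, width=width, alpha=0.5, label="imputed")
    ax.set_xlabel("feature z-score")
    ax.set_ylabel("count")
    ax.set_title("Pooled z-score distribution")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _moments_scatter(report: DiagnosticsReport, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for table, label, marker in (
        (report.cleaned_moments, "complete-case deleted", "o"),
        (report.imputed_moments, "imputed", "x"),
    ):
        if len(table):
            ax.scatter(table["skewness"], table["kurtosis"], marker=marker,
                       alpha=0.7, label=label)
            for name, row in table.iterrows():
                ax.annotate(str(name), (row["skewness"], row["kurtosis"]),
                            fontsize=6, alpha=0.6)
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.axhline(3.0, color="grey", lw=0.5)
    ax.set_xlabel("skewness")
    ax.set_ylabel("kurtosis")
    ax.set_title("Per-feature moments (normal reference: 0, 3)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _biplot(pca: PCAResult, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    s = pca.scores
    ax.scatter(s.iloc[:, 0], s.iloc[:, 1] if s.shape[1] > 1 else 0 * s.iloc[:, 0],
               alpha=0.7)
    for name in s.index:
        y = s.loc[name].iloc[1] if s.shape[1] > 1 else 0.0
        ax.annotate(str(name), (s.loc[name].iloc[0], y), fontsize=6, alpha=0.7)
    ve = pca.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_report(report: DiagnosticsReport, outdir: str | Path,
                fmt: str = "svg") -> list[Path]:
    """Write histogram, moments scatter, and the two PCA score plots.

    Returns the list of files written (PCA plots are skipped when the
    report carries no PCA, e.g. for a degenerate complete-case matrix).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / f"histogram.{fmt}"
    _histogram(report, p)
    written.append(p)

    p = outdir / f"moments.{fmt}"
    _moments_scatter(report, p)
    written.append(p)

    if report.pca_samples is not None:
        p = outdir / f"pca_samples.{fmt}"
        _biplot(report.pca_samples, "PCA of samples (features as variables)", p)
        written.append(p)
    if report.pca_features is not None:
        p = outdir / f"pca_features.{fmt}"
        _biplot(report.pca_features, "PCA of features (samples as variables)", p)
        written.append(p)
    return written
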
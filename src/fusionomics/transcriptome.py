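"""Expression-side gene sets and PCA coordinates.

Differentially expressed gene (DEG) sets are defined purely by the adjusted
p-value (FDR < alpha, default 0.05); the population (gene universe) for
hypergeometric testing is every gene whose mean raw count across all samples
is at least ``min_mean_count`` (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DEGRecord

__all__ = [
    "AnalysisConfig",
    "filter_degs",
    "define_population",
    "vst_like_transform",
    "pca_coordinates",
]


@dataclass(frozen=True)
class AnalysisConfig:
    fdr_alpha: float = 0.05
    min_mean_count: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1), got {self.fdr_alpha}")
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be non-negative")


def filter_degs(
    records: list[DEGRecord],
    config: AnalysisConfig = AnalysisConfig(),
    direction: str | None = None,
) -> set[str]:
    """Gene ids with padj present and strictly below the FDR threshold.

    ``direction`` optionally restricts to "up" (log2fc > 0) or "down";
    default keeps both directions, so overlaps are identifier-only.
    Missing padj counts as not significant.
    """
    out = set()
    for r in records:
        if r.padj is None or r.padj >= config.fdr_alpha:
            continue
        if direction == "up" and r.log2fc <= 0:
            continue
        if direction == "down" and r.log2fc >= 0:
            continue
        out.add(r.gene_id)
    return out


def define_population(
    counts: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> set[str]:
    """Genes with row-mean count >= min_mean_count (boundary inclusive)."""
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    means = counts.mean(axis=1)
    return set(counts.index[means >= config.min_mean_count])


def vst_like_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization followed by log2(x + 1).

    Size factors are the per-sample medians of count ratios to the geometric
    mean row, taken over genes with all-positive counts.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts; size factor undefined")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    log_geo_mean = np.log(mat[positive]).mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(np.log(mat[positive]) - log_geo_mean, axis=0))
    return pd.DataFrame(
        np.log2(mat / size_factors + 1.0), index=counts.index, columns=counts.columns
    )


def pca_coordinates(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (rows) onto principal components of mean-centered data.

    Returns (coordinates, variance_fractions).  The sign of each component is
    fixed so its largest-magnitude loading is positive, making coordinates
    deterministic across runs and BLAS builds.
    """
    X = matrix.to_numpy(dtype=float)
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(n_samples, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(n_samples, n_features)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # pin sign: largest-|loading| entry of each right-singular vector positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    coords = U[:, :n_components] * S[:n_components]
    total_var = (S**2).sum()
    fractions = np.zeros(n_components) if total_var == 0 else (S[:n_components] ** 2) / total_var
    return (
        pd.DataFrame(
            coords,
            index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        fractions,
    )
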
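"""Control-vs-case transcriptome divergence along a time course.

Three complementary views: PCA of the samples on the most variable genes,
per-time-point mean between-group Euclidean distance over all genes, and the
Pearson correlation between group-mean expression profiles per time point.
A rise-then-fall of the distance (mirrored by the correlation) localizes the
time point of greatest divergence between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix, SampleMetadata

__all__ = [
    "HeterogeneityReport",
    "pca_top_variable",
    "group_distance_by_time",
    "group_correlation_by_time",
    "heterogeneity_report",
]


@dataclass
class HeterogeneityReport:
    pca_coords: pd.DataFrame          # samples x components
    explained_variance: pd.Series     # fraction per component, non-increasing
    distance_by_time: pd.Series       # time_h -> mean between-group distance
    correlation_by_time: pd.Series    # time_h -> Pearson r of group means


def pca_top_variable(expr: ExpressionMatrix, n_top: int = 500,
                     k: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of the samples on the ``n_top`` genes with the highest standard
    deviation across samples.

    Genes are ranked by sample-wise SD (ties broken by gene id, lexicographic);
    the retained submatrix is centered per gene but not scaled (gene SD is the
    selection signal, so raw SD structure is kept). For determinism, each
    component is sign-flipped so its loading vector has a non-negative sum.
    Returns (scores, explained-variance fractions).
    """
    if expr.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_top > expr.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {expr.n_genes} genes")
    if k > min(expr.n_samples - 1, n_top):
        raise ValueError(f"k={k} exceeds min(n_samples - 1, n_top)")
    sds = expr.values.std(axis=1, ddof=1)
    order = sorted(expr.gene_ids, key=lambda g: (-sds[g], g))
    top = expr.values.loc[order[:n_top]]

    X = top.to_numpy().T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.where(pca.components_.sum(axis=1) < 0, -1.0, 1.0)
    scores = scores * flip
    coords = pd.DataFrame(scores, index=expr.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(k)])
    evr = pd.Series(pca.explained_variance_ratio_, index=coords.columns)
    return coords, evr


def _groups_by_time(expr: ExpressionMatrix, meta: SampleMetadata):
    meta.check_matches(expr)
    for t in meta.time_points:
        ctrl = [s for s in meta.samples(group="control", time_h=t) if s in expr.values.columns]
        case = [s for s in meta.samples(group="case", time_h=t) if s in expr.values.columns]
        if not ctrl or not case:
            raise ValueError(f"time point {t} lacks a control or case sample")
        yield t, ctrl, case


def group_distance_by_time(expr: ExpressionMatrix, meta: SampleMetadata) -> pd.Series:
    """Mean Euclidean distance over all control x case sample pairs per time
    point, computed over all genes on the matrix's own scale."""
    out = {}
    for t, ctrl, case in _groups_by_time(expr, meta):
        C = expr.values[ctrl].to_numpy()
        K = expr.values[case].to_numpy()
        d = np.sqrt(((C[:, :, None] - K[:, None, :]) ** 2).sum(axis=0))
        out[t] = float(d.mean())
    return pd.Series(out).sort_index()


def group_correlation_by_time(expr: ExpressionMatrix, meta: SampleMetadata) -> pd.Series:
    """Pearson r between the mean control and mean case profiles (all genes)
    at each time point; a zero-variance mean profile is an error."""
    if expr.n_genes < 3:
        raise ValueError("correlation needs at least 3 genes")
    out = {}
    for t, ctrl, case in _groups_by_time(expr, meta):
        c = expr.values[ctrl].mean(axis=1).to_numpy()
        k = expr.values[case].mean(axis=1).to_numpy()
        if np.std(c) == 0 or np.std(k) == 0:
            raise ValueError(f"zero-variance mean profile at time {t}: correlation undefined")
        out[t] = float(stats.pearsonr(c, k).statistic)
    return pd.Series(out).sort_index()


def heterogeneity_report(expr: ExpressionMatrix, meta: SampleMetadata,
                         n_top: int = 500, k: int = 2) -> HeterogeneityReport:
    n_top = min(n_top, expr.n_genes)
    coords, evr = pca_top_variable(expr, n_top=n_top, k=k)
    return HeterogeneityReport(
        pca_coords=coords,
        explained_variance=evr,
        distance_by_time=group_distance_by_time(expr, meta),
        correlation_by_time=group_correlation_by_time(expr, meta),
    )
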
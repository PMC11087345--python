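"""Immune-infiltration scoring, cell-type abundance and gene-cell correlation.

Generic, signature-driven stand-ins for the fixed-signature immune tools used
in the bulk-deconvolution literature: the immune score is a per-sample ssGSEA
score over a user-supplied immune gene list; cell-type abundance comes either
from marker-set ssGSEA scores or from non-negative least-squares deconvolution
of the bulk profile against a user-supplied reference signature matrix; and
gene-by-cell-type association uses Spearman correlation with average-linkage
clustering of the genes' correlation profiles. No fixed reference (LM22-style)
matrix ships with the package — signatures are always user inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from ._stats import two_group_test
from .enrichment import ssgsea_score
from .io_formats import ExpressionMatrix, GeneSetCollection, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "CellTypeScores",
    "GeneCellCorrelation",
    "immune_score",
    "group_test_by_time",
    "score_cell_types",
    "deconvolve",
    "gene_cell_correlation",
]


@dataclass
class SignatureMatrix:
    """Genes x cell types reference expression, linear scale, no all-zero column."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell-type names in signature")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature values must be >= 0")
        zero_cols = self.values.columns[(arr == 0).all(axis=0)]
        if len(zero_cols):
            raise ValueError(f"all-zero signature column(s): {list(zero_cols)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def index(self):
        return self.values.index

    @property
    def columns(self):
        return self.values.columns


@dataclass
class CellTypeScores:
    """Samples x cell types grid; ``mode`` is ``marker_ssgsea`` (free scores)
    or ``deconvolution`` (rows are proportions summing to 1, with per-sample
    residual norms)."""

    values: pd.DataFrame
    mode: str
    residuals: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("marker_ssgsea", "deconvolution"):
            raise ValueError(f"unknown mode {self.mode!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("cell-type scores must be finite")
        if self.mode == "deconvolution":
            if (arr < -1e-12).any():
                raise ValueError("deconvolution proportions must be >= 0")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("deconvolution rows must sum to 1")


@dataclass
class GeneCellCorrelation:
    rho: pd.DataFrame       # genes x cell types
    p: pd.DataFrame         # genes x cell types
    clusters: pd.Series     # gene -> cluster label (int), NaN rho rows excluded


def immune_score(expr: ExpressionMatrix, immune_signature,
                 alpha: float = 0.25, normalize: bool = False) -> pd.Series:
    """Per-sample ssGSEA score of the immune gene list — the degree of
    immune-cell infiltration of each sample."""
    return ssgsea_score(expr, immune_signature, alpha=alpha, normalize=normalize)


def group_test_by_time(scores: pd.Series, meta: SampleMetadata,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Normality-gated control-vs-case test of a per-sample score at each
    time point.

    Shapiro-Wilk at 0.05 in each group; t-test if both pass, otherwise
    Wilcoxon rank-sum; two-sided p, ``significant = p < alpha``. Returns a
    table with one row per time point, ascending.
    """
    rows = []
    for t in meta.time_points:
        ctrl = [s for s in meta.samples(group="control", time_h=t) if s in scores.index]
        case = [s for s in meta.samples(group="case", time_h=t) if s in scores.index]
        if len(ctrl) < 2 or len(case) < 2:
            raise ValueError(f"time point {t} has < 2 samples in a group")
        p, test = two_group_test(scores[ctrl].to_numpy(), scores[case].to_numpy())
        rows.append({"time_h": t, "n_control": len(ctrl), "n_case": len(case),
                     "test": test, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def score_cell_types(expr: ExpressionMatrix, markers: GeneSetCollection,
                     alpha: float = 0.25) -> CellTypeScores:
    """Marker-set ssGSEA score per sample and cell type (no cross-type
    normalization — scores are comparable within a cell type, not across)."""
    cols = {name: ssgsea_score(expr, members, alpha=alpha)
            for name, members in markers.items()}
    return CellTypeScores(values=pd.DataFrame(cols), mode="marker_ssgsea")


def deconvolve(bulk: ExpressionMatrix, signature: SignatureMatrix) -> CellTypeScores:
    """Cell-type proportions per bulk sample by non-negative least squares.

    Bulk is taken to linear scale; the fit runs over the genes shared with
    the signature, which must be full column rank there. Coefficients are
    non-negative by construction and renormalized to sum to 1; the residual
    norm of each fit is reported alongside.
    """
    linear = bulk.to_linear()
    shared = [g for g in signature.index if g in linear.values.index]
    k = len(signature.cell_types)
    if len(shared) < k:
        raise ValueError(f"only {len(shared)} shared genes for {k} cell types")
    S = signature.values.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(S)
    if rank < k:
        # small R diagonal entries localize dependent columns for the message
        r = np.linalg.qr(S)[1]
        dep = [signature.cell_types[i] for i in range(k)
               if abs(r[i, i]) < 1e-10 * abs(r[0, 0])] or signature.cell_types
        raise ValueError(f"signature is rank-deficient on shared genes "
                         f"(rank {rank} < {k}); collinear column(s): {dep}")
    B = linear.values.loc[shared].to_numpy(dtype=float)
    props, resid = [], []
    for j, sample in enumerate(linear.sample_ids):
        coef, rnorm = nnls(S, B[:, j])
        total = coef.sum()
        if total == 0:
            logger.warning("deconvolve: all-zero fit for sample %s; uniform fallback", sample)
            coef = np.full(k, 1.0 / k)
        else:
            coef = coef / total
        props.append(coef)
        resid.append(rnorm)
    values = pd.DataFrame(props, index=linear.sample_ids, columns=signature.cell_types)
    return CellTypeScores(values=values, mode="deconvolution",
                          residuals=pd.Series(resid, index=linear.sample_ids,
                                              name="residual_norm"))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho, n <= 10."""
    n = len(x)
    rx = stats.rankdata(x)
    perms = np.array(list(itertools.permutations(stats.rankdata(y))))
    rhos = np.array([stats.pearsonr(rx, p).statistic for p in perms])
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def gene_cell_correlation(expr: ExpressionMatrix, genes, scores: CellTypeScores,
                          n_clusters: int | None = None,
                          p_method: str = "t") -> GeneCellCorrelation:
    """Spearman correlation of each gene with each cell-type score, plus
    hierarchical clustering of the genes' correlation profiles.

    Correlations run over the samples shared between the matrix and the score
    grid (>= 5 required); ties get average ranks and p-values use the
    t-approximation (``p_method="exact"`` enumerates all rank permutations,
    n <= 10 only). A constant gene or score vector leaves rho/p as NaN. Genes
    are clustered by average linkage on ``1 - corr(rho rows)`` and cut into
    ``n_clusters`` groups (default 3, matching a three-stage gene grouping).
    """
    shared = [s for s in scores.values.index if s in expr.values.columns]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, found {len(shared)}")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {missing[:5]}")
    genes = list(dict.fromkeys(genes))
    E = expr.values.loc[genes, shared].to_numpy(dtype=float)
    C = scores.values.loc[shared].to_numpy(dtype=float)
    cell_types = list(scores.values.columns)
    n = len(shared)

    rho = np.full((len(genes), len(cell_types)), np.nan)
    pvals = np.full_like(rho, np.nan)
    rE = np.apply_along_axis(stats.rankdata, 1, E)
    rC = np.apply_along_axis(stats.rankdata, 0, C)
    for i in range(len(genes)):
        if np.ptp(E[i]) == 0:
            continue
        for j in range(len(cell_types)):
            if np.ptp(C[:, j]) == 0:
                continue
            r = float(stats.pearsonr(rE[i], rC[:, j]).statistic)
            rho[i, j] = r
            if p_method == "exact":
                if n > 10:
                    raise ValueError("exact Spearman p limited to n <= 10")
                pvals[i, j] = _spearman_exact_p(E[i], C[:, j], r)
            else:
                if abs(r) >= 1.0:
                    pvals[i, j] = np.finfo(float).tiny
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    pvals[i, j] = float(2 * stats.t.sf(abs(t), df=n - 2))

    rho_df = pd.DataFrame(rho, index=genes, columns=cell_types)
    p_df = pd.DataFrame(pvals, index=genes, columns=cell_types)

    if n_clusters is None:
        n_clusters = 3
    usable = rho_df.dropna(axis=0, how="any")
    usable = usable[usable.std(axis=1) > 0]
    clusters = pd.Series(np.nan, index=genes, name="cluster")
    if len(usable) >= 2 and len(cell_types) >= 2:
        corr = np.corrcoef(usable.to_numpy())
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = average(squareform(dist, checks=False))
        labels = fcluster(Z, t=min(n_clusters, len(usable)), criterion="maxclust")
        clusters.loc[usable.index] = labels
    elif len(usable) == 1:
        clusters.loc[usable.index] = 1
    return GeneCellCorrelation(rho=rho_df, p=p_df, clusters=clusters)
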
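"""Gene-set enrichment machinery.

Three statistics are implemented:

* :func:`ssgsea_score` — single-sample enrichment in the rank-weighted
  integral form: per sample, genes are ranked by expression and the score is
  the summed difference between the weighted in-set and unweighted out-of-set
  empirical CDFs walked down the ranking. Being rank-based, the score is
  invariant to any monotone transform of a sample's values.
* :func:`gsea_preranked` — classic running-sum enrichment score on a
  preranked list with a *gene-set permutation* null: the null distribution is
  built from random same-size gene sets drawn from the ranked universe, NES is
  the score divided by the mean magnitude of same-sign null scores, and the
  p-value uses the add-one form ``(b + 1) / (m + 1)`` so it is never zero.
* :func:`ora_test` — one-sided hypergeometric over-representation with
  Benjamini-Hochberg correction across the tested sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentTrajectory",
    "GseaResult",
    "ssgsea_score",
    "ssgsea_collection",
    "enrichment_trajectory",
    "gsea_preranked",
    "ora_test",
]


@dataclass
class EnrichmentTrajectory:
    """Per-sample and per-time-point enrichment of one gene set.

    ``per_time_score`` averages the case-sample scores at each design time
    point; ``peak_time_h`` is its argmax (ties broken toward the earliest
    time point).
    """

    gene_set_name: str
    per_sample_score: pd.Series
    per_time_score: pd.Series
    peak_time_h: float


@dataclass
class GseaResult:
    gene_set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: list[str] = field(default_factory=list)
    nes_defined: bool = True


def _ranked_order(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorting descending by value, ties broken by gene id."""
    return np.lexsort((ids, -values))


def _present_members(gene_set, gene_ids, context: str) -> list[str]:
    idx = set(gene_ids)
    present = [g for g in dict.fromkeys(gene_set) if g in idx]
    absent = len(dict.fromkeys(gene_set)) - len(present)
    if absent:
        logger.warning("%s: %d gene-set member(s) absent from matrix", context, absent)
    if len(present) < 2:
        raise ValueError(f"{context}: fewer than 2 gene-set members present")
    if len(present) == len(gene_ids):
        raise ValueError(f"{context}: gene set covers every gene (out-of-set CDF undefined)")
    return present


def ssgsea_score(expr: ExpressionMatrix, gene_set, alpha: float = 0.25,
                 normalize: bool = False) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` for every sample.

    Per sample: expression values get ascending average ranks ``r`` (the top
    gene has ``r = G``); walking genes in descending expression order (ties
    broken by gene id), the score is ``sum_i [P_in(i) - P_out(i)]`` where
    ``P_in`` accumulates ``r**alpha`` over in-set genes (normalized by the
    in-set total) and ``P_out`` accumulates counts of out-of-set genes
    (normalized by ``G - |set|``). With ``normalize=True`` scores are min-max
    scaled across the samples of the matrix.
    """
    gene_ids = np.asarray(expr.gene_ids)
    present = _present_members(gene_set, expr.gene_ids, "ssgsea")
    in_set = np.isin(gene_ids, present)
    G = len(gene_ids)
    k = int(in_set.sum())
    scores = {}
    vals = expr.values.to_numpy()
    for j, sample in enumerate(expr.sample_ids):
        col = vals[:, j]
        r = stats.rankdata(col)  # ascending average ranks; top gene = G
        order = _ranked_order(col, gene_ids)
        mask = in_set[order]
        w = np.where(mask, np.power(r[order], alpha), 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~mask) / (G - k)
        scores[sample] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, name="ssgsea")
    if normalize:
        lo, hi = out.min(), out.max()
        out = (out - lo) / (hi - lo) if hi > lo else out * 0.0
    return out


def ssgsea_collection(expr: ExpressionMatrix, sets: GeneSetCollection,
                      alpha: float = 0.25, normalize: bool = False) -> pd.DataFrame:
    """ssGSEA scores for every set in a collection: samples x sets."""
    cols = {name: ssgsea_score(expr, members, alpha=alpha, normalize=normalize)
            for name, members in sets.items()}
    return pd.DataFrame(cols)


def enrichment_trajectory(expr: ExpressionMatrix, meta: SampleMetadata, gene_set,
                          gene_set_name: str = "gene_set",
                          alpha: float = 0.25, normalize: bool = False,
                          group: str = "case") -> EnrichmentTrajectory:
    """Score one gene set per sample and summarize it over the time course.

    The per-time trajectory is the mean score over ``group`` samples (case by
    default) at each time point; its argmax defines the peak, with ties broken
    toward the earliest time point.
    """
    meta.check_matches(expr)
    per_sample = ssgsea_score(expr, gene_set, alpha=alpha, normalize=normalize)
    times = meta.time_points
    per_time = {}
    for t in times:
        ids = meta.samples(group=group, time_h=t)
        if not ids:
            raise ValueError(f"no {group} samples at time {t}")
        per_time[t] = float(per_sample[ids].mean())
    series = pd.Series(per_time).loc[times]
    peak = float(series.index[int(np.argmax(series.to_numpy()))])
    return EnrichmentTrajectory(
        gene_set_name=gene_set_name, per_sample_score=per_sample,
        per_time_score=series, peak_time_h=peak,
    )


def _running_sum_es(weights: np.ndarray, in_mask: np.ndarray, n_out: int):
    """Signed max-deviation enrichment score of one ranked membership vector.

    ``weights`` are the in-set increments (already in ranked order, zero for
    out-of-set genes); out-of-set genes decrement uniformly by ``1 / n_out``.
    Returns ``(es, extremum_position)`` where the position is the 0-based rank
    index at which the extremum is attained.
    """
    tot = weights.sum()
    if tot == 0:  # all in-set metrics are zero: fall back to uniform increments
        weights = in_mask.astype(float)
        tot = weights.sum()
    rs = np.cumsum(np.where(in_mask, weights / tot, -1.0 / n_out))
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min]:
        return float(rs[i_max]), i_max
    return float(rs[i_min]), i_min


def _null_es(w_ranked: np.ndarray, k: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized max-deviation ES for ``n_perm`` random k-subsets.

    Works from the sorted member positions of each random set: the running sum
    attains its maximum just after some hit and its minimum just before some
    hit, so only ``2k`` candidates per permutation need evaluating.
    """
    G = len(w_ranked)
    pos = np.argsort(rng.random((n_perm, G)), axis=1)[:, :k]
    pos.sort(axis=1)
    win = w_ranked[pos]
    cw = np.cumsum(win, axis=1)
    tot = cw[:, -1:].copy()
    zero_tot = tot[:, 0] == 0
    if zero_tot.any():  # uniform increments when a null set has all-zero weight
        cw[zero_tot] = np.arange(1, k + 1)[None, :]
        tot[zero_tot] = k
    miss = 1.0 / (G - k)
    j = np.arange(1, k + 1)[None, :]
    after = cw / tot - (pos + 1 - j) * miss
    before = np.concatenate([np.zeros((n_perm, 1)), cw[:, :-1]], axis=1) / tot \
        - (pos - j + 1) * miss
    pos_max = after.max(axis=1)
    neg_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def gsea_preranked(ranking: pd.Series, gene_set, n_perm: int = 1000,
                   weight: float = 1.0, seed: int = 0,
                   gene_set_name: str = "gene_set") -> GseaResult:
    """Preranked GSEA of one gene set with a gene-set permutation null.

    ``ranking`` maps gene id to a finite metric; genes are walked in
    descending metric order (ties broken by gene id). In-set steps increment
    by ``|metric|**weight`` normalized to the in-set total, out-of-set steps
    decrement by ``1 / (G - |set|)``; ES is the maximum deviation from zero.
    The null draws ``n_perm`` random same-size gene sets from the universe.
    NES divides ES by the mean magnitude of same-sign null scores; if no null
    shares the observed sign, NES is flagged undefined and p is reported as
    ``1 / (n_perm + 1)``.
    """
    vals = ranking.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("ranking metric contains non-finite values")
    ids = np.asarray(ranking.index, dtype=object)
    present = _present_members(gene_set, list(ids), "gsea_preranked")
    order = _ranked_order(vals, ids.astype(str))
    ranked_ids = ids[order]
    ranked_w = np.power(np.abs(vals[order]), weight)
    in_mask = np.isin(ranked_ids, present)
    k = int(in_mask.sum())
    G = len(ids)

    es, i_ext = _running_sum_es(np.where(in_mask, ranked_w, 0.0), in_mask, G - k)
    if es >= 0:
        leading = [g for g in ranked_ids[: i_ext + 1] if g in set(present)]
    else:
        leading = [g for g in ranked_ids[i_ext:] if g in set(present)]

    rng = np.random.default_rng(seed)
    null = _null_es(ranked_w, k, n_perm, rng)
    same_sign = null >= 0 if es >= 0 else null < 0
    m = int(same_sign.sum())
    if m == 0:
        warnings.warn(f"{gene_set_name}: no same-sign permutation scores; NES undefined")
        return GseaResult(gene_set_name=gene_set_name, es=es, nes=float("nan"),
                          p_value=1.0 / (n_perm + 1), n_permutations=n_perm,
                          leading_edge=leading, nes_defined=False)
    null_same = null[same_sign]
    nes = es / float(np.mean(np.abs(null_same)))
    b = int(np.sum(np.abs(null_same) >= abs(es)))
    p = (b + 1) / (m + 1)
    return GseaResult(gene_set_name=gene_set_name, es=es, nes=float(nes),
                      p_value=float(p), n_permutations=n_perm, leading_edge=leading)


def ora_test(hits, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Sets are intersected with the universe; the p-value is the one-sided
    upper tail ``P(X >= overlap)``; BH correction is applied across the tested
    sets. Returns a table sorted by p then set name with columns
    ``gene_set_name, overlap_count, set_size, universe_size, hits_in_universe,
    p_value, bh_q``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hits = [g for g in dict.fromkeys(hits) if g in uni]
    if not hits:
        raise ValueError("empty hit list (after intersecting with universe)")
    M, N = len(universe), len(hits)
    hit_set = set(hits)
    rows = []
    for name, members in sets.items():
        members_u = [g for g in members if g in uni]
        if not members_u:
            continue
        K = len(members_u)
        x = len(hit_set.intersection(members_u))
        p = float(stats.hypergeom.sf(x - 1, M, K, N))
        rows.append({"gene_set_name": name, "overlap_count": x, "set_size": K,
                     "universe_size": M, "hits_in_universe": N, "p_value": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["gene_set_name", "overlap_count", "set_size",
                                     "universe_size", "hits_in_universe",
                                     "p_value", "bh_q"])
    df = pd.DataFrame(rows)
    df["bh_q"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p_value", "gene_set_name"], kind="mergesort").reset_index(drop=True)
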
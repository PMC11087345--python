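"""Stage-specific gene calling with the Tau specificity index.

Given a two-group time course, the case time points are treated as the N
stages of the disease trajectory. Per gene, a representative linear-scale
expression ``X_i`` is the mean over case replicates at stage ``i``, and two
specificity indices are computed:

    tau_max = sum_i (1 - X_i / X_max) / (N - 1)
    tau_min = sum_i (1 - X_min / X_i) / (N - 1)

Both live in [0, 1]: 0 for a uniformly expressed gene, 1 for a gene expressed
in (tau_max), or depleted from (tau_min), exactly one stage. ``tau_max``
flags genes specifically HIGH at one stage, ``tau_min`` genes specifically
LOW at one stage; a gene's overall specificity is the larger of the two, and
genes at or above a threshold (0.8 by default) are called stage-specific.
The time course is split into a progression and a remission phase at the peak
of a pathway enrichment trajectory, and the called genes can be checked in an
independent dataset with per-time-point two-group tests.

Tau is computed on the LINEAR scale: the formulas divide expression levels,
which is meaningless for log-ratios, so log2 input is back-transformed first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import two_group_test
from .enrichment import EnrichmentTrajectory
from .io_formats import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "StageProfile",
    "StagePartition",
    "ValidationReport",
    "FLOOR_EPSILON",
    "build_stage_profile",
    "tau_index",
    "call_specific_genes",
    "partition_stages",
    "validate_stage_genes",
]

FLOOR_EPSILON = 1e-8

#: Columns of the Tau result table produced by :func:`tau_index`.
TAU_COLUMNS = ["gene_id", "tau_max", "tau_min", "tau",
               "specific", "assigned_stage", "direction"]


@dataclass
class StageProfile:
    """Genes x stages representative linear expression.

    ``values`` has one column per stage (case time points, ascending); rows
    are floored at :data:`FLOOR_EPSILON` so ``tau_min`` stays defined.
    ``zero_genes`` lists genes whose profile was all-zero before flooring
    (excluded from Tau); ``floored_genes`` lists genes with at least one
    floored stage.
    """

    values: pd.DataFrame
    stages: list[float]
    floored_genes: list[str] = field(default_factory=list)
    zero_genes: list[str] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass
class StagePartition:
    """Time points split at the enrichment peak: progression = stages at or
    before the peak (peak included), remission = stages after it."""

    peak_time_h: float
    progression_stages: list[float]
    remission_stages: list[float]


@dataclass
class ValidationReport:
    """Per-gene validation outcome on an independent dataset.

    ``per_gene`` holds one row per testable gene with per-time-point raw
    p-values, ``min_p``, ``changed`` (any raw p < alpha) and ``changed_bh``
    (any BH-corrected p < alpha, corrected across all gene x time tests).
    ``summary`` counts changed / unchanged genes per stage class.
    """

    per_gene: pd.DataFrame
    summary: pd.DataFrame
    not_testable: list[str]
    alpha: float


def build_stage_profile(expr: ExpressionMatrix, meta: SampleMetadata,
                        use_group: str = "case_only") -> StageProfile:
    """Mean linear expression over case replicates at every time point.

    Log2 input is back-transformed per sample before averaging (the profile
    is the mean of ``2**x``, not ``2**mean(x)``). Values are floored at
    :data:`FLOOR_EPSILON`; genes floored or entirely zero are recorded.
    """
    if use_group != "case_only":
        raise ValueError("only use_group='case_only' is supported")
    meta.check_matches(expr)
    linear = expr.to_linear()
    cols = {}
    for t in meta.time_points:
        ids = [s for s in meta.samples(group="case", time_h=t)
               if s in linear.values.columns]
        if not ids:
            raise ValueError(f"no case samples at stage {t}")
        cols[t] = linear.values[ids].mean(axis=1)
    values = pd.DataFrame(cols)
    zero = values.max(axis=1) == 0
    zero_genes = list(values.index[zero])
    floored = (values < FLOOR_EPSILON).any(axis=1) & ~zero
    floored_genes = list(values.index[floored])
    if floored_genes:
        logger.info("floored %d gene profile(s) at %g", len(floored_genes), FLOOR_EPSILON)
    values = values.clip(lower=FLOOR_EPSILON)
    return StageProfile(values=values, stages=list(values.columns),
                        floored_genes=floored_genes, zero_genes=zero_genes)


def tau_index(profile: StageProfile, threshold: float = 0.8) -> pd.DataFrame:
    """Tau specificity per gene of a stage profile.

    Returns one row per gene with ``tau_max``, ``tau_min``, their maximum
    ``tau``, the ``specific`` flag (``tau >= threshold``), the assigned stage
    (stage of ``X_max`` when ``tau_max >= tau_min``, else stage of ``X_min``;
    ties toward the earlier stage) and the direction (``up``/``down``
    accordingly). Genes whose profile was all-zero before flooring are
    excluded and logged.
    """
    if profile.n_stages < 2:
        raise ValueError("Tau needs at least 2 stages")
    values = profile.values
    if profile.zero_genes:
        logger.warning("excluding %d all-zero gene(s) from Tau", len(profile.zero_genes))
        values = values.drop(index=profile.zero_genes)
    X = values.to_numpy(dtype=float)
    N = profile.n_stages
    x_max = X.max(axis=1)
    x_min = X.min(axis=1)
    tau_max = (1.0 - X / x_max[:, None]).sum(axis=1) / (N - 1)
    tau_min = (1.0 - x_min[:, None] / X).sum(axis=1) / (N - 1)
    up = tau_max >= tau_min
    stages = np.asarray(profile.stages, dtype=float)
    stage_of_max = stages[X.argmax(axis=1)]
    stage_of_min = stages[X.argmin(axis=1)]
    tau = np.maximum(tau_max, tau_min)
    return pd.DataFrame({
        "gene_id": values.index,
        "tau_max": tau_max,
        "tau_min": tau_min,
        "tau": tau,
        "specific": tau >= threshold,
        "assigned_stage": np.where(up, stage_of_max, stage_of_min),
        "direction": np.where(up, "up", "down"),
    }).reset_index(drop=True)


def call_specific_genes(results: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Genes with ``tau >= threshold`` (boundary inclusive), sorted by
    descending tau then gene id."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = results[results["tau"] >= threshold].copy()
    out = out.sort_values(["tau", "gene_id"], ascending=[False, True], kind="mergesort")
    out["specific"] = True
    return out.reset_index(drop=True)


def partition_stages(traj: EnrichmentTrajectory) -> StagePartition:
    """Split the time course at the trajectory peak.

    Peak = argmax of the per-time score (ties toward the earliest time
    point); progression stages are those at or before the peak, remission
    those after. A peak at the final time point yields an empty remission
    phase with a warning.
    """
    scores = traj.per_time_score
    if len(scores) < 2:
        raise ValueError("partition needs at least 2 time points")
    times = [float(t) for t in scores.index]
    peak = times[int(np.argmax(scores.to_numpy()))]
    progression = [t for t in times if t <= peak]
    remission = [t for t in times if t > peak]
    if not remission:
        warnings.warn(f"enrichment peak at the final time point ({peak}): "
                      "remission phase is empty")
    return StagePartition(peak_time_h=peak, progression_stages=progression,
                          remission_stages=remission)


def stage_class(partition: StagePartition, stage: float) -> str:
    return "progression" if stage in partition.progression_stages else "remission"


def validate_stage_genes(genes: pd.DataFrame, val_expr: ExpressionMatrix,
                         val_meta: SampleMetadata, alpha: float = 0.05,
                         partition: StagePartition | None = None) -> ValidationReport:
    """Check called stage-specific genes in an independent dataset.

    Per gene and validation time point, control vs case are compared with a
    normality-gated two-group test (Shapiro-Wilk at 0.05 in both groups ->
    Student's t, else Wilcoxon rank-sum); ``changed`` means any raw p < alpha
    across the dataset's time points. BH-corrected calls (correction across
    all gene x time tests) are reported alongside. Genes absent from the
    validation matrix are recorded as not testable and excluded from counts.
    When a :class:`StagePartition` is given, summary counts are grouped by
    progression/remission class of the assigned stage, else by stage.
    """
    val_meta.check_matches(val_expr)
    times = val_meta.time_points
    for t in times:
        for grp in ("control", "case"):
            if len(val_meta.samples(group=grp, time_h=t)) < 2:
                raise ValueError(f"validation time {t} has < 2 {grp} samples")
    not_testable, rows, pvals = [], [], []
    for _, g in genes.iterrows():
        gid = g["gene_id"]
        if gid not in val_expr.values.index:
            not_testable.append(gid)
            continue
        row = {"gene_id": gid, "assigned_stage": g.get("assigned_stage", np.nan),
               "direction": g.get("direction", "")}
        gene_p = []
        for t in times:
            ctrl = val_expr.values.loc[gid, val_meta.samples(group="control", time_h=t)]
            case = val_expr.values.loc[gid, val_meta.samples(group="case", time_h=t)]
            p, _ = two_group_test(ctrl.to_numpy(), case.to_numpy())
            row[f"p_{t:g}h"] = p
            gene_p.append(p)
        row["min_p"] = min(gene_p)
        row["changed"] = row["min_p"] < alpha
        rows.append(row)
        pvals.extend(gene_p)
    per_gene = pd.DataFrame(rows)
    if len(per_gene):
        q = multipletests(np.asarray(pvals), method="fdr_bh")[1].reshape(len(per_gene), -1)
        per_gene["min_q"] = q.min(axis=1)
        per_gene["changed_bh"] = per_gene["min_q"] < alpha
        if partition is not None:
            per_gene["stage_class"] = [stage_class(partition, s)
                                       for s in per_gene["assigned_stage"]]
        else:
            per_gene["stage_class"] = per_gene["assigned_stage"].map(lambda s: f"{s:g}h")
        summary = (per_gene.groupby("stage_class")["changed"]
                   .agg(changed="sum", total="count").reset_index())
        summary["changed"] = summary["changed"].astype(int)
        summary["unchanged"] = summary["total"] - summary["changed"]
    else:
        per_gene = pd.DataFrame(columns=["gene_id", "assigned_stage", "direction",
                                         "min_p", "changed"])
        summary = pd.DataFrame(columns=["stage_class", "changed", "total", "unchanged"])
    return ValidationReport(per_gene=per_gene, summary=summary,
                            not_testable=not_testable, alpha=alpha)
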
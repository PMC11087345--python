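"""Synthetic two-group time-course expression data with planted ground truth.

The generator emulates a kainic-acid-style rodent epilepsy time course:
control and case groups sampled at 1, 6, 24, 72 and 240 h with a few
replicates each (the default design, 5 time points x 2 groups x 3 replicates,
mirrors a 30-sample microarray study). Ground truth is planted on the log2
scale:

* stage-specific genes — shifted up or down by a fixed log2 fold change in
  case samples at exactly one time point,
* a pathway whose genes share an additive activation following a unimodal
  (triangular in log-time) trajectory peaking at a chosen time point,
* an optional immune signature whose genes are shifted in case samples from
  an onset time point onward (a rise-and-stay trajectory),
* bulk mixtures of cell-type reference profiles with known proportions.

Effects are additive on the log2 scale (multiplicative on the linear scale),
so back-transformed values are always positive. Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleMetadata

__all__ = [
    "SyntheticConfig",
    "TruthTables",
    "generate_timecourse",
    "generate_mixtures",
    "random_signature",
]

DEFAULT_TIME_POINTS = (1.0, 6.0, 24.0, 72.0, 240.0)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic time-course study.

    ``n_specific_per_stage`` counts planted genes per direction: each stage
    receives that many "up" genes and that many "down" genes. ``seed`` fixes
    both the random design (which genes are planted) and the noise;
    ``noise_seed`` optionally redraws only the noise, which is how matched
    validation datasets (same planted genes, fresh measurements) are made.
    """

    n_genes: int = 2000
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS
    replicates: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.3
    n_specific_per_stage: int = 0
    specific_log2_fc: float = 3.0
    pathway_size: int = 0
    pathway_peak_time_h: float | None = None
    pathway_amplitude_log2: float = 1.5
    immune_size: int = 0
    immune_onset_time_h: float = 24.0
    immune_log2_shift: float = 1.5
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.time_points_h) < 2:
            raise ValueError("need at least two time points")
        if list(self.time_points_h) != sorted(self.time_points_h):
            raise ValueError("time_points_h must be increasing")
        if any(t <= 0 for t in self.time_points_h):
            raise ValueError("time points must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("baseline_log2_sd", "specific_log2_fc",
                     "pathway_amplitude_log2", "immune_log2_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be >= 0")
        n_planted = (2 * self.n_specific_per_stage * len(self.time_points_h)
                     + self.pathway_size + self.immune_size)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        if self.pathway_size > 0:
            if self.pathway_peak_time_h is None:
                object.__setattr__(self, "pathway_peak_time_h", 24.0)
            if self.pathway_peak_time_h not in self.time_points_h:
                raise ValueError("pathway_peak_time_h must be one of time_points_h")
        if self.immune_size > 0 and self.immune_onset_time_h not in self.time_points_h:
            raise ValueError("immune_onset_time_h must be one of time_points_h")


@dataclass
class TruthTables:
    """Planted ground truth emitted next to a synthetic dataset."""

    specific_genes: dict[str, tuple[float, str]]  # gene -> (stage time_h, "up"/"down")
    pathway_genes: list[str]
    pathway_trajectory: dict[float, float]  # time_h -> planted log2 activation
    immune_genes: list[str] = field(default_factory=list)
    true_proportions: pd.DataFrame | None = None  # samples x cell types

    def specific_table(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "stage_h": t, "direction": d}
            for g, (t, d) in self.specific_genes.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "stage_h", "direction"])


def pathway_activation(time_h: float, peak_h: float, amplitude: float,
                       half_width_ln: float = 2.0) -> float:
    """Triangular activation in log-time: ``amplitude`` at the peak, falling
    linearly in ``ln(time)`` to zero at ``half_width_ln`` natural-log units."""
    d = abs(math.log(time_h) - math.log(peak_h))
    return amplitude * max(0.0, 1.0 - d / half_width_ln)


def generate_timecourse(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, TruthTables]:
    """Simulate the two-group time course described by ``config``.

    Per-gene log2 baselines are drawn once from
    ``Normal(baseline_log2_mean, baseline_log2_sd)``; every sample adds iid
    ``Normal(0, noise_log2_sd)`` measurement noise; case samples additionally
    carry the planted effects. Returns a log2-scale matrix, its metadata and
    the :class:`TruthTables`.
    """
    design_rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(
        config.seed if config.noise_seed is None else config.noise_seed
    )
    times = list(config.time_points_h)
    n_stages = len(times)
    width = max(len(str(config.n_genes)), 4)
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    sample_rows = []
    for grp, tag in (("control", "C"), ("case", "KA")):
        for t in times:
            for r in range(1, config.replicates + 1):
                sample_rows.append(
                    {"sample_id": f"{tag}_{t:g}h_r{r}", "group": grp,
                     "time_h": float(t), "replicate": r}
                )
    meta_df = pd.DataFrame(sample_rows).set_index("sample_id")
    sample_ids = list(meta_df.index)

    baseline = design_rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                 size=config.n_genes)

    # planted gene assignment: up per stage, down per stage, pathway, immune
    n_spec = config.n_specific_per_stage
    n_planted = 2 * n_spec * n_stages + config.pathway_size + config.immune_size
    planted_idx = design_rng.choice(config.n_genes, size=n_planted, replace=False)
    cursor = 0
    specific: dict[str, tuple[float, str]] = {}
    effect = np.zeros((config.n_genes, len(sample_ids)))
    case_mask = (meta_df["group"] == "case").to_numpy()
    time_arr = meta_df["time_h"].to_numpy()

    for direction, sign in (("up", 1.0), ("down", -1.0)):
        for t in times:
            idx = planted_idx[cursor:cursor + n_spec]
            cursor += n_spec
            cols = case_mask & (time_arr == t)
            for gi in idx:
                specific[gene_ids[gi]] = (float(t), direction)
                effect[gi, cols] += sign * config.specific_log2_fc

    pathway_idx = planted_idx[cursor:cursor + config.pathway_size]
    cursor += config.pathway_size
    trajectory: dict[float, float] = {}
    if config.pathway_size > 0:
        for t in times:
            act = pathway_activation(t, config.pathway_peak_time_h,
                                     config.pathway_amplitude_log2)
            trajectory[float(t)] = act
            cols = case_mask & (time_arr == t)
            effect[np.ix_(pathway_idx, np.flatnonzero(cols))] += act

    immune_idx = planted_idx[cursor:cursor + config.immune_size]
    if config.immune_size > 0:
        cols = case_mask & (time_arr >= config.immune_onset_time_h)
        effect[np.ix_(immune_idx, np.flatnonzero(cols))] += config.immune_log2_shift

    noise = noise_rng.normal(0.0, config.noise_log2_sd,
                             size=(config.n_genes, len(sample_ids)))
    values = baseline[:, None] + effect + noise
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )
    truth = TruthTables(
        specific_genes=specific,
        pathway_genes=[gene_ids[i] for i in pathway_idx],
        pathway_trajectory=trajectory,
        immune_genes=[gene_ids[i] for i in immune_idx],
    )
    return expr, SampleMetadata(table=meta_df), truth


def generate_mixtures(signature, proportions: pd.DataFrame,
                      noise_log2_sd: float = 0.0, seed: int = 0) -> ExpressionMatrix:
    """Mix cell-type reference profiles into bulk samples.

    ``signature`` is a :class:`~stagespec.immune_infiltration.SignatureMatrix`
    (genes x cell types, linear scale); ``proportions`` is samples x cell
    types, each row non-negative and summing to 1. The bulk linear value is
    ``signature @ proportions`` per sample, multiplied by log-normal noise
    ``2**Normal(0, noise_log2_sd)`` per gene and sample.
    """
    sig = signature.values
    if list(proportions.columns) != list(sig.columns):
        raise ValueError(
            "proportions columns must match signature cell types "
            f"({list(proportions.columns)} vs {list(sig.columns)})"
        )
    arr = proportions.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion rows must sum to 1")
    bulk = sig.to_numpy() @ arr.T  # genes x samples
    rng = np.random.default_rng(seed)
    if noise_log2_sd > 0:
        bulk = bulk * np.power(2.0, rng.normal(0.0, noise_log2_sd, size=bulk.shape))
    df = pd.DataFrame(bulk, index=sig.index, columns=list(proportions.index))
    return ExpressionMatrix(values=df, scale="linear")


def random_signature(n_genes: int = 200, n_cell_types: int = 5, seed: int = 0,
                     n_markers_per_type: int = 20, marker_boost: float = 8.0):
    """Draw a well-conditioned synthetic cell-type reference signature.

    Each cell type gets ``n_markers_per_type`` disjoint marker genes whose
    reference expression is multiplied by ``marker_boost``, on top of shared
    log-normal background expression — enough structure for both marker-set
    scoring and least-squares deconvolution to be well posed.
    """
    from .immune_infiltration import SignatureMatrix

    if n_markers_per_type * n_cell_types > n_genes:
        raise ValueError("not enough genes for disjoint marker blocks")
    rng = np.random.default_rng(seed)
    width = max(len(str(n_genes)), 4)
    gene_ids = [f"SG{i:0{width}d}" for i in range(1, n_genes + 1)]
    cell_types = [f"celltype_{chr(ord('A') + k)}" for k in range(n_cell_types)]
    base = np.power(2.0, rng.normal(5.0, 1.0, size=(n_genes, n_cell_types)))
    markers: dict[str, list[str]] = {}
    order = rng.permutation(n_genes)
    for k, ct in enumerate(cell_types):
        block = order[k * n_markers_per_type:(k + 1) * n_markers_per_type]
        base[block, k] *= marker_boost
        markers[ct] = [gene_ids[i] for i in block]
    df = pd.DataFrame(base, index=gene_ids, columns=cell_types)
    return SignatureMatrix(values=df), markers
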
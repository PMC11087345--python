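import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagespec import (ExpressionMatrix, GeneSetCollection, SignatureMatrix,
                       SyntheticConfig, deconvolve, gene_cell_correlation,
                       generate_mixtures, generate_timecourse,
                       group_test_by_time, immune_score, random_signature,
                       score_cell_types)
from stagespec.immune_infiltration import CellTypeScores
from stagespec._stats import two_group_test
from conftest import make_meta


class TestImmuneScore:
    def test_shifted_signature_raises_case_scores_noiselessly(self):
        cfg = SyntheticConfig(n_genes=300, immune_size=30,
                              immune_onset_time_h=1.0, noise_log2_sd=0.0, seed=4)
        expr, meta, truth = generate_timecourse(cfg)
        score = immune_score(expr, truth.immune_genes)
        for t in meta.time_points:
            c = score[meta.samples(group="control", time_h=t)].mean()
            k = score[meta.samples(group="case", time_h=t)].mean()
            assert k > c

    def test_identical_columns_identical_scores(self):
        col = np.random.default_rng(0).normal(6, 1, 50)
        values = pd.DataFrame({"a": col, "b": col},
                              index=[f"g{i}" for i in range(50)])
        expr = ExpressionMatrix(values=values, scale="log2")
        s = immune_score(expr, ["g1", "g5", "g9"])
        assert s["a"] == s["b"]

    def test_rising_immune_trajectory_orders_p_values(self):
        """With the signature planted to rise from 24 h, shifted time points
        show far stronger group differences than the pre-onset ones."""
        cfg = SyntheticConfig(n_genes=800, immune_size=60, replicates=6,
                              immune_onset_time_h=24.0, seed=10)
        expr, meta, truth = generate_timecourse(cfg)
        score = immune_score(expr, truth.immune_genes)
        tests = group_test_by_time(score, meta).set_index("time_h")
        assert tests.loc[[24.0, 72.0, 240.0], "significant"].all()
        assert tests.loc[[24.0, 72.0, 240.0], "p_value"].max() \
            < tests.loc[[1.0, 6.0], "p_value"].min()


class TestGroupTestByTime:
    def test_single_sample_group_rejected(self):
        meta = make_meta([1.0], replicates=1)
        scores = pd.Series(1.0, index=meta.sample_ids)
        with pytest.raises(ValueError, match="< 2"):
            group_test_by_time(scores, meta)

    def test_null_false_positive_rate(self):
        """Exchangeable groups stay non-significant in >= 94% of simulations."""
        rng = np.random.default_rng(6)
        fp = sum(two_group_test(rng.normal(size=4), rng.normal(size=4))[0] < 0.05
                 for _ in range(500))
        assert fp / 500 <= 0.06

    def test_power_at_large_shift(self):
        """5 pooled-SD shift: near-certain detection at n=5 per group; at
        n=3 the rank-test fallback caps power near the normality-gate rate."""
        rng = np.random.default_rng(7)
        hits5 = sum(two_group_test(rng.normal(0, 1, 5), rng.normal(5, 1, 5))[0] < 0.05
                    for _ in range(200))
        assert hits5 / 200 > 0.95
        hits3 = sum(two_group_test(rng.normal(0, 1, 3), rng.normal(5, 1, 3))[0] < 0.05
                    for _ in range(200))
        assert hits3 / 200 > 0.85

    def test_constant_equal_groups_p_one(self):
        meta = make_meta([1.0], replicates=2)
        scores = pd.Series(2.5, index=meta.sample_ids)
        out = group_test_by_time(scores, meta)
        assert out["p_value"].iloc[0] == 1.0
        assert not out["significant"].iloc[0]


class TestScoreCellTypes:
    def test_pure_sample_maximizes_own_type(self):
        sig, markers = random_signature(n_genes=200, n_cell_types=4, seed=5)
        collection = GeneSetCollection(
            sets={ct: ("", genes) for ct, genes in markers.items()})
        props = pd.DataFrame(np.eye(4), index=[f"pure_{c}" for c in sig.cell_types],
                             columns=sig.cell_types)
        bulk = generate_mixtures(sig, props, noise_log2_sd=0.0)
        scores = score_cell_types(bulk, collection)
        for i, ct in enumerate(sig.cell_types):
            assert scores.values.loc[f"pure_{ct}"].idxmax() == ct

    def test_identical_marker_sets_identical_columns(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.lognormal(2, 1, (60, 4)),
                              index=[f"g{i}" for i in range(60)],
                              columns=list("abcd"))
        expr = ExpressionMatrix(values=values, scale="linear")
        members = ["g3", "g9", "g15"]
        collection = GeneSetCollection(sets={"t1": ("", members),
                                             "t2": ("", list(members))})
        scores = score_cell_types(expr, collection)
        assert scores.values["t1"].equals(scores.values["t2"])

    def test_score_monotone_in_mixing_weight(self):
        sig, markers = random_signature(n_genes=150, n_cell_types=3, seed=9)
        ct = sig.cell_types[0]
        collection = GeneSetCollection(sets={ct: ("", markers[ct])})
        weights = np.linspace(0.0, 1.0, 6)
        rows = [[w, (1 - w) / 2, (1 - w) / 2] for w in weights]
        props = pd.DataFrame(rows, index=[f"s{i}" for i in range(6)],
                             columns=sig.cell_types)
        bulk = generate_mixtures(sig, props, noise_log2_sd=0.0)
        s = score_cell_types(bulk, collection).values[ct]
        assert np.all(np.diff(s.to_numpy()) > 0)


class TestDeconvolve:
    def test_noiseless_exact_recovery(self):
        sig, _ = random_signature(n_genes=200, n_cell_types=3, seed=1)
        props = pd.DataFrame([[0.2, 0.3, 0.5]], index=["s1"],
                             columns=sig.cell_types)
        bulk = generate_mixtures(sig, props, noise_log2_sd=0.0)
        est = deconvolve(bulk, sig)
        assert np.allclose(est.values.to_numpy(), props.to_numpy(), atol=1e-6)
        assert est.residuals["s1"] < 1e-6

    def test_one_hot_recovery(self):
        sig, _ = random_signature(n_genes=100, n_cell_types=4, seed=2)
        props = pd.DataFrame(np.eye(4), index=[f"s{i}" for i in range(4)],
                             columns=sig.cell_types)
        bulk = generate_mixtures(sig, props, noise_log2_sd=0.0)
        est = deconvolve(bulk, sig)
        assert np.allclose(est.values.to_numpy(), np.eye(4), atol=1e-6)

    def test_noisy_recovery_mae(self):
        sig, _ = random_signature(n_genes=200, n_cell_types=5, seed=3)
        rng = np.random.default_rng(4)
        props = pd.DataFrame(rng.dirichlet(np.ones(5), size=50),
                             index=[f"s{i}" for i in range(50)],
                             columns=sig.cell_types)
        bulk = generate_mixtures(sig, props, noise_log2_sd=0.1, seed=5)
        est = deconvolve(bulk, sig)
        mae = np.abs(est.values.to_numpy() - props.to_numpy()).mean()
        assert mae < 0.05
        assert np.allclose(est.values.sum(axis=1), 1.0, atol=1e-9)

    def test_rank_deficient_signature_rejected(self):
        col = np.abs(np.random.default_rng(0).normal(10, 2, 50))
        sig = SignatureMatrix(values=pd.DataFrame(
            {"A": col, "B": 2 * col}, index=[f"g{i}" for i in range(50)]))
        bulk = ExpressionMatrix(values=pd.DataFrame(
            {"s1": col}, index=[f"g{i}" for i in range(50)]), scale="linear")
        with pytest.raises(ValueError, match="rank-deficient"):
            deconvolve(bulk, sig)

    def test_insufficient_shared_genes_rejected(self):
        sig, _ = random_signature(n_genes=50, n_cell_types=3, seed=1,
                                  n_markers_per_type=5)
        bulk = ExpressionMatrix(values=pd.DataFrame(
            {"s1": [1.0, 2.0]}, index=["x1", "x2"]), scale="linear")
        with pytest.raises(ValueError, match="shared genes"):
            deconvolve(bulk, sig)


def _scores_frame(arr, samples, types):
    return CellTypeScores(values=pd.DataFrame(arr, index=samples, columns=types),
                          mode="marker_ssgsea")


class TestGeneCellCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(10)
        n = 12
        base = rng.normal(size=n)
        samples = [f"s{i}" for i in range(n)]
        expr = ExpressionMatrix(values=pd.DataFrame(
            {s: [np.exp(base[i]), rng.normal()] for i, s in enumerate(samples)},
            index=["g_track", "g_other"]), scale="log2")
        scores = _scores_frame(np.column_stack([base, rng.normal(size=n)]),
                               samples, ["ctA", "ctB"])
        cor = gene_cell_correlation(expr, ["g_track", "g_other"], scores)
        assert cor.rho.loc["g_track", "ctA"] == pytest.approx(1.0, abs=1e-12)
        assert cor.p.loc["g_track", "ctA"] < 1e-6

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(11)
        n, g, c = 15, 6, 3
        samples = [f"s{i}" for i in range(n)]
        E = rng.normal(size=(g, n))
        C = rng.normal(size=(n, c))
        expr = ExpressionMatrix(values=pd.DataFrame(
            E, index=[f"g{i}" for i in range(g)], columns=samples), scale="log2")
        scores = _scores_frame(C, samples, [f"ct{j}" for j in range(c)])
        cor = gene_cell_correlation(expr, [f"g{i}" for i in range(g)], scores)
        for i in range(g):
            for j in range(c):
                re, rc = stats.rankdata(E[i]), stats.rankdata(C[:, j])
                expected = np.corrcoef(re, rc)[0, 1]
                assert abs(cor.rho.iloc[i, j] - expected) < 1e-12
                assert abs(cor.p.iloc[i, j]
                           - stats.spearmanr(E[i], C[:, j]).pvalue) < 1e-9

    def test_constant_vectors_recorded_missing(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(12)
        expr = ExpressionMatrix(values=pd.DataFrame(
            {s: [1.0, rng.normal()] for s in samples},
            index=["g_const", "g_var"]), scale="log2")
        scores = _scores_frame(rng.normal(size=(8, 2)), samples, ["a", "b"])
        cor = gene_cell_correlation(expr, ["g_const", "g_var"], scores)
        assert cor.rho.loc["g_const"].isna().all()
        assert np.isnan(cor.clusters["g_const"])

    def test_genes_tracking_same_cell_type_share_cluster(self):
        rng = np.random.default_rng(13)
        n = 20
        samples = [f"s{i}" for i in range(n)]
        a, b = rng.normal(size=n), rng.normal(size=n)
        expr = ExpressionMatrix(values=pd.DataFrame(
            [a + rng.normal(0, 0.05, n), a + rng.normal(0, 0.05, n),
             b + rng.normal(0, 0.05, n), b + rng.normal(0, 0.05, n)],
            index=["gA1", "gA2", "gB1", "gB2"], columns=samples), scale="log2")
        scores = _scores_frame(np.column_stack([a, b]), samples, ["ctA", "ctB"])
        cor = gene_cell_correlation(expr, ["gA1", "gA2", "gB1", "gB2"], scores,
                                    n_clusters=2)
        assert cor.clusters["gA1"] == cor.clusters["gA2"]
        assert cor.clusters["gB1"] == cor.clusters["gB2"]
        assert cor.clusters["gA1"] != cor.clusters["gB1"]

    def test_null_rho_calibration(self):
        """Independent gene/score pairs exceed the alpha=0.05 critical value
        about 5% of the time."""
        rng = np.random.default_rng(14)
        n, reps = 12, 300
        hits = 0
        for _ in range(reps):
            rho = np.corrcoef(stats.rankdata(rng.normal(size=n)),
                              stats.rankdata(rng.normal(size=n)))[0, 1]
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            hits += 2 * stats.t.sf(abs(t), df=n - 2) < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_exact_permutation_p_small_n(self):
        rng = np.random.default_rng(15)
        n = 5
        samples = [f"s{i}" for i in range(n)]
        expr = ExpressionMatrix(values=pd.DataFrame(
            rng.normal(size=(2, n)), index=["g0", "g1"], columns=samples),
            scale="log2")
        scores = _scores_frame(rng.normal(size=(n, 1)), samples, ["ct"])
        cor = gene_cell_correlation(expr, ["g0", "g1"], scores, p_method="exact")
        assert ((cor.p > 0) & (cor.p <= 1)).all().all()
        # a perfectly tracking gene attains the minimal two-sided exact p: 2/5!
        expr2 = ExpressionMatrix(values=pd.DataFrame(
            [scores.values["ct"].to_numpy(), rng.normal(size=n)],
            index=["g0", "g1"], columns=samples), scale="log2")
        cor2 = gene_cell_correlation(expr2, ["g0", "g1"], scores, p_method="exact")
        assert cor2.p.loc["g0", "ct"] == pytest.approx(2 / 120, abs=1e-12)

    def test_too_few_shared_samples_rejected(self):
        samples = [f"s{i}" for i in range(4)]
        expr = ExpressionMatrix(values=pd.DataFrame(
            np.random.default_rng(0).normal(size=(2, 4)),
            index=["g0", "g1"], columns=samples), scale="log2")
        scores = _scores_frame(np.random.default_rng(1).normal(size=(4, 2)),
                               samples, ["a", "b"])
        with pytest.raises(ValueError, match="5 shared"):
            gene_cell_correlation(expr, ["g0"], scores)
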
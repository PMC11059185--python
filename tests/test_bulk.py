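"""Tests for bulk count filtering, MGP estimation and GSR enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import spearmanr

import oracles
from cistrat import bulk


def toy_counts(n_genes=50, n_samples=10, seed=0):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(50, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return counts


def _filter_fixpoint_oracle(counts, dominant_frac=0.006,
                            dominant_sample_frac=0.5, low_count=5,
                            low_sample_frac=0.8):
    """Gene-by-gene reapplication of both count rules until stable."""
    current = counts.copy()
    while True:
        survivors = []
        for g in current.index:
            shares = current.loc[g] / current.sum(axis=0)
            dominant = (shares > dominant_frac).mean() > dominant_sample_frac
            low = (current.loc[g] < low_count).mean() >= low_sample_frac
            if not dominant and not low:
                survivors.append(g)
        if len(survivors) == len(current):
            return current
        current = current.loc[survivors]


class TestFilterGenes:
    def test_dominant_gene_removed(self):
        counts = toy_counts(n_genes=400)
        # give g0 ~1% of reads in 6 of 10 samples (> 0.6% in > half)
        total = counts.sum(axis=0)
        counts.loc["g0"] = 0
        counts.loc["g0", counts.columns[:6]] = (total[:6] * 0.0101).astype(int)
        filtered, report = bulk.filter_genes(counts)
        assert "g0" not in filtered.index
        assert report.loc["g0", "rule"] == "dominant"

    def test_low_expression_boundary_is_strict(self):
        counts = toy_counts(n_genes=400)
        counts.loc["g1"] = 100
        counts.loc["g1", counts.columns[:8]] = 4   # <5 in 80% -> removed
        counts.loc["g2"] = 100
        counts.loc["g2", counts.columns[:8]] = 5   # ==5 not below -> kept
        filtered, report = bulk.filter_genes(counts)
        assert "g1" not in filtered.index
        assert report.loc["g1", "rule"] == "low_expression"
        assert "g2" in filtered.index

    def test_annotation_rule_removes_mito_and_scaffolds(self):
        counts = toy_counts(n_genes=400)
        chroms = ["1", "MT", "GL000194.1", "X"] + ["2"] * 396
        anno = pd.DataFrame({"chromosome": chroms}, index=counts.index)
        filtered, report = bulk.filter_genes(counts, gene_annotation=anno)
        assert "g1" not in filtered.index and "g2" not in filtered.index
        assert {"g0", "g3"}.issubset(filtered.index)
        assert report.loc["g1", "rule"] == "annotation"
        assert report.loc["g2", "rule"] == "annotation"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(2, 0.02, size=(500, 20)),
            index=[f"g{i}" for i in range(500)],
            columns=[f"s{j}" for j in range(20)],
        )
        filtered, _ = bulk.filter_genes(counts)
        expected = _filter_fixpoint_oracle(counts)
        assert list(filtered.index) == list(expected.index)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.negative_binomial(2, 0.05, size=(300, 12)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(12)],
        )
        once, _ = bulk.filter_genes(counts)
        twice, _ = bulk.filter_genes(once)
        assert list(once.index) == list(twice.index)

    def test_all_removed_is_error(self):
        counts = pd.DataFrame(
            np.ones((3, 10), dtype=int),
            index=["a", "b", "c"], columns=[f"s{j}" for j in range(10)],
        )
        with pytest.raises(ValueError, match="all genes"):
            bulk.filter_genes(counts)


class TestSexNoise:
    def test_zero_leak_gives_zero_threshold(self):
        counts = toy_counts(n_genes=10)
        counts.loc["XIST"] = [100] * 5 + [0] * 5
        counts.loc["KDM5D"] = [0] * 5 + [80] * 5
        counts.loc["RPS4Y1"] = [0] * 5 + [90] * 5
        sex = pd.Series(["F"] * 5 + ["M"] * 5, index=counts.columns)
        thr, flags = bulk.sex_noise_threshold(counts, sex)
        assert thr == 0.0
        assert not flags[[f"g{i}" for i in range(10)]].any()

    def test_threshold_tracks_planted_leak_quantile(self):
        rng = np.random.default_rng(3)
        n = 400
        cols = [f"s{j}" for j in range(n)]
        counts = pd.DataFrame(100, index=["XIST", "KDM5D", "RPS4Y1", "other"],
                              columns=cols, dtype=float)
        sex = pd.Series(["F"] * (n // 2) + ["M"] * (n // 2), index=cols)
        lam = 6.0
        leak = rng.poisson(lam, n // 2)
        counts.loc["XIST", sex == "M"] = leak  # female gene leaking in males
        counts.loc["KDM5D", sex == "F"] = 0
        counts.loc["RPS4Y1", sex == "F"] = 0
        thr, _ = bulk.sex_noise_threshold(counts, sex)
        q95 = np.quantile(rng.poisson(lam, 200_000), 0.95)
        se = 3  # Poisson quantile Monte-Carlo slack at n=200
        assert abs(thr - q95) <= se

    def test_missing_sex_genes_warns_and_skips(self):
        counts = toy_counts()
        sex = pd.Series(["F"] * 5 + ["M"] * 5, index=counts.columns)
        with pytest.warns(UserWarning, match="absent"):
            thr, flags = bulk.sex_noise_threshold(counts, sex)
        assert thr == 0.0 and not flags.any()


class TestMGP:
    def test_monotone_mixture_ranks_and_sign_flip(self):
        # all markers of type T scale as 1x, 2x, 3x across samples
        base = np.array([5.0, 3.0, 7.0])
        expr = pd.DataFrame(
            {f"s{k}": base * (k + 1) + 0.01 * np.arange(3) for k in range(3)},
            index=["m1", "m2", "m3"],
        )
        res = bulk.mgp_estimate(expr, {"T": ["m1", "m2", "m3"]})
        scores = res.scores["T"]
        assert list(scores.sort_values().index) == ["s0", "s1", "s2"]
        flipped = bulk.mgp_estimate(-expr, {"T": ["m1", "m2", "m3"]})
        assert list(flipped.scores["T"].sort_values().index) == ["s2", "s1", "s0"]

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(5, 2, size=(3, 4)),
                            index=["m1", "m2", "m3"],
                            columns=[f"s{k}" for k in range(4)])
        res = bulk.mgp_estimate(expr, {"T": ["m1", "m2", "m3"]})
        z = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).to_numpy()
        expected = oracles.first_pc_eigh(z)
        got = res.scores["T"].to_numpy()
        if np.corrcoef(got, expected)[0, 1] < 0:
            expected = -expected
        assert got == pytest.approx(expected, abs=1e-8)

    def test_marker_and_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(5, 2, size=(6, 8)),
                            index=[f"m{i}" for i in range(6)],
                            columns=[f"s{k}" for k in range(8)])
        markers = {"T": [f"m{i}" for i in range(6)]}
        a = bulk.mgp_estimate(expr, markers).scores["T"]
        b = bulk.mgp_estimate(
            expr.iloc[::-1, ::-1], {"T": markers["T"][::-1]}
        ).scores["T"]
        assert a.sort_index().to_numpy() == pytest.approx(
            b.sort_index().to_numpy(), abs=1e-8
        )

    def test_too_few_markers_skipped(self):
        expr = toy_counts(20, 6).astype(float)
        with pytest.warns(UserWarning, match="skipped"):
            res = bulk.mgp_estimate(
                expr, {"ok": ["g0", "g1", "g2", "g3"], "tiny": ["g4", "absent"]}
            )
        assert res.skipped == ["tiny"]
        assert list(res.scores.columns) == ["ok"]

    def test_recovers_planted_proportions(self, bulk_mixture):
        counts, meta, markers, proportions = bulk_mixture
        lc = bulk.logcpm(counts)
        res = bulk.mgp_estimate(lc, markers)
        for t in res.scores.columns:
            rho = spearmanr(res.scores[t], proportions[t]).statistic
            assert rho > 0.8, f"{t}: rho={rho:.2f}"


class TestGroupAnalysis:
    def test_planted_driver_detected(self, bulk_mixture):
        counts, meta, markers, _ = bulk_mixture
        lc = bulk.logcpm(counts)
        res = bulk.mgp_estimate(lc, markers)
        out = bulk.mgp_group_analysis(
            res, meta.set_index("subject_id"), group_col="bulk_group",
            reference="control",
        )
        eff = out["effects"].set_index("cell_type")
        assert eff.loc["GabaVIPReln", "estimate"] < 0
        assert eff.loc["GabaVIPReln", "p_value"] < 0.05
        assert out["driver"] == "GabaVIPReln"

    def test_driver_candidate_table_is_order_invariant(self, bulk_mixture):
        counts, meta, markers, _ = bulk_mixture
        lc = bulk.logcpm(counts)
        res = bulk.mgp_estimate(lc, markers)
        md = meta.set_index("subject_id")
        out1 = bulk.mgp_group_analysis(res, md, group_col="bulk_group")
        shuffled = bulk.MGPResult(
            scores=res.scores[list(res.scores.columns)[::-1]],
            variance_explained=res.variance_explained,
            markers_used=res.markers_used,
        )
        out2 = bulk.mgp_group_analysis(shuffled, md, group_col="bulk_group")
        assert out1["driver"] == out2["driver"]

    def test_type_i_error_controlled_under_null(self):
        rng = np.random.default_rng(10)
        n = 30
        n_sims = 60
        false_pos = 0
        total = 0
        for sim in range(n_sims):
            md = pd.DataFrame({
                "group": ["a"] * (n // 2) + ["b"] * (n // 2),
                "age": rng.normal(80, 5, n),
                "sex": rng.choice(["M", "F"], n),
                "pmi": rng.lognormal(3, 0.4, n),
                "cohort": rng.choice(["NOR", "ESP"], n),
            }, index=[f"s{i}" for i in range(n)])
            scores = pd.DataFrame(rng.normal(size=(n, 4)),
                                  index=md.index,
                                  columns=list("WXYZ"))
            out = bulk.mgp_group_analysis(
                scores, md, group_col="group", reference="a", stepwise=False
            )
            false_pos += int((out["effects"]["p_value"] < 0.05).sum())
            total += len(out["effects"])
        rate = false_pos / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 4 * se

    def test_missing_covariate_rejected(self, bulk_mixture):
        counts, meta, markers, _ = bulk_mixture
        lc = bulk.logcpm(counts)
        res = bulk.mgp_estimate(lc, markers)
        with pytest.raises(ValueError, match="missing covariates"):
            bulk.mgp_group_analysis(
                res, meta.set_index("subject_id"), group_col="bulk_group",
                covariates=("age", "nonexistent"),
            )


class TestGSR:
    def test_flat_scores_give_p_near_one(self):
        genes = [f"g{i}" for i in range(100)]
        scores = pd.Series(0.5, index=genes)
        res = bulk.gsr_enrichment(
            scores, {"S": genes[:30]}, n_resample=200, seed=0
        )
        assert res.loc["S", "p_value"] == pytest.approx(1.0)

    def test_enrichment_p_matches_enumeration_oracle(self):
        # universe of 50 genes, 5 with score 1, rest 0; set of 20.
        # Null mean-score tail is hypergeometric in the number of hits.
        genes = [f"g{i}" for i in range(50)]
        pvals = pd.Series([10 ** -1.0] * 5 + [1.0] * 45, index=genes)
        hits_in_set = 3
        members = genes[:hits_in_set] + genes[20:20 + (20 - hits_in_set)]
        res = bulk.gsr_enrichment(
            pvals, {"S": members}, n_resample=20_000, seed=1
        )
        # observed mean = 3/20 * 1; null P(mean >= obs) = P(X >= 3),
        # X ~ Hypergeom(M=50, n=5, N=20)
        exact = oracles.hypergeom_upper_tail(3, 50, 5, 20)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert res.loc["S", "p_value"] == pytest.approx(exact, abs=3 * se + 1e-4)

    def test_size_bounds_applied(self):
        genes = [f"g{i}" for i in range(600)]
        scores = pd.Series(np.linspace(0.01, 1, 600), index=genes)
        sets = {"tiny": genes[:10], "ok": genes[:25], "huge": genes}
        res = bulk.gsr_enrichment(scores, sets, n_resample=100, seed=0)
        assert list(res.index) == ["ok"]

    def test_p_uniform_under_permuted_scores(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        ps = []
        for _ in range(200):
            scores = pd.Series(rng.uniform(0, 1, 200), index=genes)
            members = list(rng.choice(genes, 25, replace=False))
            res = bulk.gsr_enrichment(
                scores, {"S": members}, n_resample=199,
                seed=int(rng.integers(2**31)),
            )
            ps.append(res.loc["S", "p_value"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_sum_scores_flag_shifted_genes(self, bulk_mixture):
        counts, meta, markers, _ = bulk_mixture
        lc = bulk.logcpm(counts)
        scores = bulk.rank_sum_gene_scores(
            lc, meta.set_index("subject_id")["bulk_group"], "CI-PD", "control"
        )
        gaba = [g for g in markers["GabaVIPReln"] if g in scores.index]
        background = [g for g in scores.index if g.startswith("BG")]
        assert scores[gaba].median() < scores[background].median()
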
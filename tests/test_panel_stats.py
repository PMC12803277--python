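"""Aggregation, correlation, z-score shift, secretome and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duplexium.io_formats import CellByGeneMatrix
from duplexium.panel_stats import (
    UndefinedCorrelationError,
    adjusted_rand_index,
    aggregate_counts,
    cluster_label_concordance,
    compare_overlap_sensitivity,
    correlate_aggregates,
    per_gene_cross_chemistry_rho,
    per_sample_correlation_matrix,
    secretome_diversity,
    wilcoxon_signed_rank,
    zscore_across_genes,
)


def _matrix(dense, samples=None, name="V1", genes=None):
    n, g = np.asarray(dense).shape
    cells = [f"c{i:03d}" for i in range(n)]
    feats = [f"{genes[j] if genes else f'G{j:03d}'}-{name}" for j in range(g)]
    metrics = None
    if samples is not None:
        metrics = pd.DataFrame(
            {"cell_area": 50.0, "nucleus_area": 10.0, "sample_id": samples},
            index=pd.Index(cells, name="cell_id"),
        )
    return CellByGeneMatrix(cells, feats, np.asarray(dense), metrics=metrics, name=name)


class TestAggregate:
    def test_all_zero(self):
        agg = aggregate_counts(_matrix(np.zeros((4, 3), dtype=int)))
        assert (agg["total"] == 0).all()

    def test_single_cell_single_gene(self):
        agg = aggregate_counts(_matrix([[7]]))
        assert agg["total"].iloc[0] == 7

    def test_equals_independent_tally(self, small_experiment):
        from duplexium.assignment import compute_cell_metrics, filter_transcripts
        from duplexium.merge_qc import build_matrix, parse_feature

        exp = small_experiment
        kept1, _ = filter_transcripts(exp.transcripts_run1)
        kept2, _ = filter_transcripts(exp.transcripts_run2)
        m = build_matrix(
            {"V1": kept1, "Prime": kept2}, exp.panels, compute_cell_metrics(exp.cells)
        )
        agg = aggregate_counts(m.view("Prime"))
        tally = kept2["gene"].value_counts()
        for feat, total in agg["total"].items():
            assert total == tally.get(parse_feature(feat)[0], 0)
        # per-sample columns sum to the slide total
        sample_cols = [c for c in agg.columns if c.startswith("sample:")]
        np.testing.assert_array_equal(
            agg[sample_cols].sum(axis=1).to_numpy(), agg["total"].to_numpy()
        )


class TestCorrelate:
    def test_self_correlation_is_one(self):
        a = pd.Series([5, 9, 2, 14], index=list("abcd"))
        assert correlate_aggregates(a, a) == pytest.approx(1.0)
        assert correlate_aggregates(a, a, method="spearman") == pytest.approx(1.0)

    def test_reverse_ranked_spearman(self):
        a = pd.Series([1, 5, 9, 20], index=list("abcd"))
        b = pd.Series([20, 9, 5, 1], index=list("abcd"))
        assert correlate_aggregates(a, b, method="spearman") == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.poisson(20, 30), index=[f"g{i}" for i in range(30)])
        b = pd.Series(rng.poisson(20, 30), index=[f"g{i}" for i in range(30)])
        assert correlate_aggregates(a, b) == pytest.approx(correlate_aggregates(b, a))

    def test_too_few_or_constant_raises(self):
        a = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(UndefinedCorrelationError):
            correlate_aggregates(a, a)
        c = pd.Series([3, 3, 3], index=list("abc"))
        v = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(UndefinedCorrelationError):
            correlate_aggregates(c, v)

    def test_solo_vs_dual_high_correlation_without_attenuation(self):
        """Same underlying rates ⇒ aggregate correlation r ≥ 0.95 in every
        one of 20 simulated slide pairs."""
        from duplexium.simulate import SimConfig, simulate_solo_dual_prime_totals

        cfg = SimConfig(
            n_cells=200, n_samples=2, n_genes_v1=60, n_genes_prime=300,
            n_overlap=30, prime_overlap_attenuation=1.0,
        )
        for seed in range(20):
            solo, dual = simulate_solo_dual_prime_totals(cfg, 3000 + seed)
            r = correlate_aggregates(solo, dual, transform="log1p")
            assert r >= 0.95


class TestPerSample:
    def _aggs(self, seed=0, n_samples=17):
        rng = np.random.default_rng(seed)
        samples = np.repeat([f"S{i:02d}" for i in range(n_samples)], 10)
        dense = rng.poisson(5.0, size=(len(samples), 40))
        m = _matrix(dense, samples=samples)
        return aggregate_counts(m)

    def test_identical_runs_all_ones(self):
        agg = self._aggs()
        r = per_sample_correlation_matrix(agg, agg)
        assert len(r) == 17
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_only_perturbed_sample_drops(self):
        agg_a = self._aggs(seed=1)
        agg_b = agg_a.copy()
        perm = np.random.default_rng(2).permutation(len(agg_b))
        agg_b["sample:S03"] = agg_b["sample:S03"].to_numpy()[perm]
        r = per_sample_correlation_matrix(agg_a, agg_b)
        assert r["S03"] < 0.7
        others = r.drop("S03")
        assert (others > 0.999).all()


class TestZScores:
    def test_two_gene_hand_value(self):
        """Totals (0, 10) on the raw scale: z = ∓0.707 under the sample-sd
        (ddof = 1) convention."""
        z = zscore_across_genes(pd.Series([0, 10], index=["a", "b"]), transform="raw")
        np.testing.assert_allclose(
            z.z.to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        totals = pd.Series(rng.poisson(50, 200), index=[f"g{i}" for i in range(200)])
        z = zscore_across_genes(totals)
        assert z.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance_raw(self):
        totals = pd.Series([3.0, 9.0, 27.0, 81.0], index=list("abcd"))
        z1 = zscore_across_genes(totals, transform="raw")
        z2 = zscore_across_genes(5.0 * totals + 11.0, transform="raw")
        np.testing.assert_allclose(z1.z.to_numpy(), z2.z.to_numpy(), atol=1e-12)

    def test_constant_totals_error(self):
        with pytest.raises(UndefinedCorrelationError):
            zscore_across_genes(pd.Series([4, 4, 4], index=list("abc")))


class TestWilcoxon:
    def test_matches_scipy_approximation(self):
        """The in-package signed-rank statistic and normal-approximation
        p-value agree with scipy's implementation (ties included)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = np.round(rng.normal(0.2, 1.0, size=60), 1)  # rounding → ties
            d = d[d != 0]
            w, p = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(
                d, correction=True, mode="approx", zero_method="wilcox"
            )
            # scipy reports min(W+, W-); ours is W+
            n = len(d)
            assert min(w, n * (n + 1) / 2 - w) == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_and_symmetric(self):
        assert wilcoxon_signed_rank(np.array([])) == (0.0, 1.0)
        w, p = wilcoxon_signed_rank(np.array([-1.0, 1.0, -2.0, 2.0]))
        assert p == pytest.approx(1.0, abs=0.1)


class TestOverlapSensitivity:
    def _ztables(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        totals = pd.Series(rng.poisson(100, n), index=genes).astype(float)
        z = zscore_across_genes(totals, run="solo")
        return z

    def test_identical_tables_give_zero_medians(self):
        z = self._ztables()
        res = compare_overlap_sensitivity(z, z, overlap_genes=z.z.index[:20], seed=1)
        assert res.overlap_median_dz == 0.0
        assert res.random_median_dz == 0.0
        assert res.overlap_p == pytest.approx(1.0)

    def test_empty_overlap_errors(self):
        z = self._ztables()
        with pytest.raises(ValueError):
            compare_overlap_sensitivity(z, z, overlap_genes=[], seed=1)

    def test_n_random_exceeding_pool_errors(self):
        z = self._ztables(n=30)
        with pytest.raises(ValueError, match="n_random"):
            compare_overlap_sensitivity(
                z, z, overlap_genes=z.z.index[:10], n_random=25, seed=1
            )

    def test_random_subset_is_seeded_and_disjoint(self):
        z = self._ztables()
        overlap = z.z.index[:20]
        a = compare_overlap_sensitivity(z, z, overlap, seed=7)
        b = compare_overlap_sensitivity(z, z, overlap, seed=7)
        c = compare_overlap_sensitivity(z, z, overlap, seed=8)
        assert a.random_genes == b.random_genes
        assert a.random_genes != c.random_genes
        assert not set(a.random_genes) & set(overlap)

    def test_detects_synthetic_attenuation(self):
        """Attenuation 0.8 on overlap genes only: positive overlap median
        shift, null-consistent random subset."""
        from duplexium.simulate import SimConfig, simulate_solo_dual_prime_totals

        cfg = SimConfig(
            n_cells=250, n_samples=2, n_genes_v1=96, n_genes_prime=1000,
            n_overlap=48, prime_overlap_attenuation=0.8,
        )
        overlap = [f"OLG{i:04d}" for i in range(48)]
        hits = 0
        for seed in range(20):
            solo, dual = simulate_solo_dual_prime_totals(cfg, 4000 + seed)
            zs = zscore_across_genes(solo, run="solo")
            zd = zscore_across_genes(dual, run="dual")
            res = compare_overlap_sensitivity(zs, zd, overlap, seed=seed)
            hits += res.overlap_shifted and res.random_subset_null_consistent
        assert hits >= 19


class TestCrossChemistryRho:
    def _views(self, v1_col, pr_col, gene="OLG1"):
        v1 = CellByGeneMatrix(
            [f"c{i}" for i in range(len(v1_col))], [f"{gene}-V1"],
            np.asarray(v1_col).reshape(-1, 1), name="V1",
        )
        pr = CellByGeneMatrix(
            [f"c{i}" for i in range(len(pr_col))], [f"{gene}-Prime"],
            np.asarray(pr_col).reshape(-1, 1), name="Prime",
        )
        return v1, pr

    def test_identical_columns_rho_one(self):
        col = [0, 1, 3, 2, 8, 5]
        v1, pr = self._views(col, col)
        rho = per_gene_cross_chemistry_rho(v1, pr, ["OLG1"])
        assert rho.loc["OLG1", "rho"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        v1, pr = self._views([1, 1, 1, 1], [0, 2, 1, 4])
        rho = per_gene_cross_chemistry_rho(v1, pr, ["OLG1"])
        assert rho.loc["OLG1", "undefined"]
        assert np.isnan(rho.loc["OLG1", "rho"])

    def test_roster_mismatch_errors(self):
        v1, _ = self._views([1, 2, 3], [1, 2, 3])
        _, pr = self._views([1, 2, 3, 4], [1, 2, 3, 4])
        from duplexium.merge_qc import IntegrityError

        with pytest.raises(IntegrityError):
            per_gene_cross_chemistry_rho(v1, pr, ["OLG1"])

    def test_independent_columns_near_zero(self):
        """Independent counts, 1,000 cells: |rho| < 0.1 in ≥95% of 100 seeds."""
        rng = np.random.default_rng(5)
        ok = 0
        for _ in range(100):
            x = rng.poisson(3.0, 1000)
            y = rng.poisson(3.0, 1000)
            ok += abs(stats.spearmanr(x, y).statistic) < 0.1
        assert ok >= 95

    def test_shared_latent_rho_attenuated_and_monotone(self):
        """Configured latent correlation 0.5: observed count-level rho is
        positive but attenuated below 0.5, and grows with Prime depth."""
        from duplexium.merge_qc import build_matrix
        from duplexium.simulate import (
            SimConfig, draw_count_matrices, make_panels, _gene_base_expression,
        )

        mean_rhos = []
        for mean_prime in (20.0, 200.0):
            # huge gamma shape ⇒ size factors ≈ 1, isolating the latent channel
            cfg = SimConfig(
                n_cells=1500, n_samples=2, n_genes_v1=10, n_genes_prime=20,
                n_overlap=10, mean_counts_v1=200.0, mean_counts_prime=mean_prime,
                latent_corr=0.5, gamma_shape=1e6, seed=6,
            )
            rng = np.random.default_rng(6)
            panels = make_panels(cfg.n_genes_v1, cfg.n_genes_prime, cfg.n_overlap)
            base = _gene_base_expression(panels, rng)
            c_v1, c_pr = draw_count_matrices(cfg, panels, base, rng)
            rhos = [
                stats.spearmanr(c_v1[:, g], c_pr[:, g]).statistic
                for g in range(cfg.n_overlap)
            ]
            mean_rhos.append(np.mean(rhos))
        low_depth, high_depth = mean_rhos
        assert 0 < low_depth < high_depth < 0.5


class TestSecretome:
    def test_counting_with_min_count(self):
        m = _matrix([[2, 0, 1]], genes=["A", "B", "C"])
        div = secretome_diversity(m, ["A", "B", "C"])
        assert div.iloc[0] == 2
        assert secretome_diversity(m, ["A", "B", "C"], min_count=3).iloc[0] == 0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            secretome_diversity(_matrix([[1]]), [])

    def test_bounded_by_genes_and_set(self, small_experiment):
        from duplexium.assignment import compute_cell_metrics, filter_transcripts
        from duplexium.merge_qc import build_matrix
        from duplexium.simulate import default_secreted_sets

        exp = small_experiment
        kept2, _ = filter_transcripts(exp.transcripts_run2)
        m = build_matrix(
            {"V1": exp.transcripts_run1.iloc[:0], "Prime": kept2},
            exp.panels, compute_cell_metrics(exp.cells),
        ).view("Prime")
        secreted = default_secreted_sets(exp.panels, n_v1=10, n_prime=60)["Prime"]
        div = secretome_diversity(m, secreted)
        assert (div <= np.minimum(m.n_genes, len(secreted))).all()

    def test_broader_panel_dominates(self):
        """At equal per-gene rates, a 60-gene secreted set yields
        stochastically more per-cell secreted diversity than a 10-gene set."""
        rng = np.random.default_rng(7)
        counts = rng.poisson(0.5, size=(500, 60))
        m_prime = _matrix(counts, name="Prime")
        m_v1 = _matrix(counts[:, :10], name="V1")
        div_pr = secretome_diversity(m_prime, [f"G{j:03d}" for j in range(60)])
        div_v1 = secretome_diversity(m_v1, [f"G{j:03d}" for j in range(10)])
        # stochastic dominance of the survival functions
        for q in range(0, 15):
            assert (div_pr > q).mean() >= (div_v1 > q).mean()
        assert div_pr.mean() > div_v1.mean()


class TestConcordance:
    def test_identical_labelings(self):
        labels = pd.Series(["a", "a", "b", "c"], index=[f"c{i}" for i in range(4)])
        table, ari = cluster_label_concordance(labels, labels)
        assert ari == pytest.approx(1.0)
        off_diag = table.to_numpy().sum() - np.diag(table.to_numpy()).sum()
        assert off_diag == 0

    def test_filtered_cells_tracked(self):
        a = pd.Series(["x", "x", "y"], index=["c1", "c2", "c3"])
        b = pd.Series(["x", "y"], index=["c1", "c2"])
        table, _ = cluster_label_concordance(a, b)
        assert table.loc["y", "filtered"] == 1

    def test_merged_clusters_single_confluence(self):
        a = pd.Series(["k1", "k1", "k2", "k2", "k3"], index=[f"c{i}" for i in range(5)])
        b = a.replace({"k2": "k1"})
        table, ari = cluster_label_concordance(a, b)
        assert table.loc["k1", "k1"] == 2 and table.loc["k2", "k1"] == 2
        assert 0 < ari < 1

    def test_empty_intersection_errors(self):
        a = pd.Series(["x"], index=["c1"])
        b = pd.Series(["x"], index=["c2"])
        with pytest.raises(ValueError):
            cluster_label_concordance(a, b)

    def test_matches_sklearn_ari(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.integers(0, 6, 500)
            b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 6, 500))
            table = pd.crosstab(a, b).to_numpy()
            assert adjusted_rand_index(table) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_random_labels_near_zero(self):
        """Uniform-random labels over k = 5, n = 10,000: |ARI| < 0.02 in all
        of 50 seeds."""
        base = np.repeat(np.arange(5), 2000)
        idx = [f"c{i}" for i in range(10_000)]
        a = pd.Series(base, index=idx)
        for seed in range(50):
            rng = np.random.default_rng(900 + seed)
            b = pd.Series(rng.integers(0, 5, 10_000), index=idx)
            _, ari = cluster_label_concordance(a, b)
            assert abs(ari) < 0.02
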
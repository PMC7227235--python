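"""Identity-score metrics, gene matching, z-scores and the scoring driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idscore import (
    ClusterExpressionMatrix,
    ClusterMarkerTable,
    METHODS,
    LOGFC_METHODS,
    compute_reference_logfc,
    compute_z_scores,
    generate_experiment,
    generate_reference,
    make_truth,
    match_genes,
    score_all_genes_correlation,
    score_experiment,
    score_logfc_correlation,
    score_logfc_dot_product,
    subset_reference,
)

from conftest import make_reference


def marker_table(rows):
    return ClusterMarkerTable(
        table=pd.DataFrame(rows, columns=["gene", "cluster", "logfc"])
    )


class TestMatchGenes:
    def test_intersection_in_reference_order(self):
        m = match_genes(["CD3E", "NKG7"], ["NKG7", "CD3E", "GZMB"])
        assert m.matched_genes == ["NKG7", "CD3E"]
        assert m.n_input_only == 0
        assert m.n_reference_only == 1

    def test_species_conventions_meet_after_uppercasing(self):
        # loaders uppercase, so mouse Cd3e and human CD3E intersect
        assert match_genes(["CD3E"], ["CD3E", "GZMB"]).n_matched == 1

    def test_disjoint_lists_are_a_hard_error(self):
        with pytest.raises(ValueError, match="no shared genes"):
            match_genes(["A", "B"], ["C", "D"])

    def test_low_match_fraction_warns(self):
        with pytest.warns(UserWarning, match="matched"):
            m = match_genes(["A", "B", "C", "D", "E"], ["A", "Z1", "Z2"])
        assert m.matched_genes == ["A"]


class TestDotProduct:
    def make_ref_logfc(self, values, genes, samples):
        ref = make_reference(values, genes, samples)
        return compute_reference_logfc(ref)

    def test_hand_arithmetic(self):
        # [+1, -2] . [+2, +1] = 0; logfc panel built to have those columns
        panel = np.array([[2.0, -2.0], [1.0, -1.0]])
        ref_logfc = self.make_ref_logfc(
            panel + 5.0, ["G1", "G2"], ["s1", "s2"]
        )  # centering restores +/-2, +/-1
        vec = pd.Series([1.0, -2.0], index=["G1", "G2"])
        scores = score_logfc_dot_product(vec, ref_logfc)
        assert scores["s1"] == pytest.approx(0.0)
        assert scores["s2"] == pytest.approx(0.0)

    def test_self_alignment_is_the_maximum_of_a_rank_one_panel(self):
        """A cluster equal to one column v scores sum(v^2) there, and every
        other column (a sign-flipped permutation of v with imperfect
        alignment) scores strictly less — checked by brute force."""
        rng = np.random.default_rng(11)
        v = rng.normal(size=12)
        cols = [v]
        for _ in range(6):
            perm = rng.permutation(12)
            flip = rng.choice([-1.0, 1.0], size=12)
            cols.append(v[perm] * flip)
        panel = np.column_stack(cols)
        panel -= panel.mean(axis=1, keepdims=True)  # center rows like a logFC panel
        genes = [f"G{i}" for i in range(12)]
        samples = [f"s{i}" for i in range(7)]
        ref_logfc = self.make_ref_logfc(panel + 3.0, genes, samples)
        x = ref_logfc.values["s0"]
        scores = score_logfc_dot_product(pd.Series(x, index=genes), ref_logfc)
        brute = {s: float(x @ ref_logfc.values[s]) for s in samples}
        assert scores["s0"] == pytest.approx(float(x @ x))
        assert scores.idxmax() == "s0"
        for s in samples:
            assert scores[s] == pytest.approx(brute[s])

    def test_anti_correlated_column_scores_negative(self):
        v = np.array([1.0, -2.0, 3.0])
        panel = np.column_stack([v, -v])
        ref_logfc = self.make_ref_logfc(panel, ["G1", "G2", "G3"], ["s1", "s2"])
        scores = score_logfc_dot_product(
            pd.Series(v, index=["G1", "G2", "G3"]), ref_logfc
        )
        assert scores["s2"] == pytest.approx(-float(v @ v))
        assert scores["s2"] <= 0

    def test_linearity_in_the_cluster_vector(self):
        rng = np.random.default_rng(2)
        ref_logfc = self.make_ref_logfc(
            rng.normal(size=(20, 6)),
            [f"G{i}" for i in range(20)],
            [f"s{i}" for i in range(6)],
        )
        genes = ref_logfc.genes
        u = pd.Series(rng.normal(size=20), index=genes)
        v = pd.Series(rng.normal(size=20), index=genes)
        a, b = 2.5, -1.25
        lhs = score_logfc_dot_product(a * u + b * v, ref_logfc)
        rhs = a * score_logfc_dot_product(u, ref_logfc) + b * score_logfc_dot_product(
            v, ref_logfc
        )
        assert np.allclose(lhs, rhs)

    def test_unmatched_marker_genes_are_dropped_not_zero_filled(self):
        ref_logfc = self.make_ref_logfc(
            np.array([[1.0, 3.0], [2.0, 0.0]]), ["G1", "G2"], ["s1", "s2"]
        )
        with_extra = pd.Series([1.0, 1.0, 99.0], index=["G1", "G2", "NOTINREF"])
        without = pd.Series([1.0, 1.0], index=["G1", "G2"])
        assert np.allclose(
            score_logfc_dot_product(with_extra, ref_logfc),
            score_logfc_dot_product(without, ref_logfc),
        )


class TestCorrelationScores:
    def test_self_correlation_is_one(self, random_reference):
        ref_logfc = compute_reference_logfc(random_reference)
        vec = ref_logfc.values["s03"]
        for flavor in ("spearman", "pearson"):
            scores = score_logfc_correlation(
                pd.Series(vec, index=ref_logfc.genes), ref_logfc, flavor
            )
            assert scores["s03"] == pytest.approx(1.0)

    def test_monotone_transform_separates_spearman_from_pearson(self):
        # x = (1..5), y = x^3: perfect rank agreement, imperfect linear fit
        ref = make_reference(
            np.column_stack([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]]).astype(float),
            [f"G{i}" for i in range(5)],
            ["s1", "s2"],
        )
        ref_logfc = compute_reference_logfc(ref)
        cubed = pd.Series(
            np.array([1.0, 8.0, 27.0, 64.0, 125.0]), index=ref.genes
        )
        sp = score_logfc_correlation(cubed, ref_logfc, "spearman")
        pe = score_logfc_correlation(cubed, ref_logfc, "pearson")
        assert sp["s1"] == pytest.approx(1.0)
        assert pe["s1"] < 1.0
        assert sp["s2"] == pytest.approx(-1.0)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(8)
        panel = rng.normal(size=(30, 5))
        ref = make_reference(
            panel, [f"G{i}" for i in range(30)], [f"s{i}" for i in range(5)]
        )
        ref_logfc = compute_reference_logfc(ref)
        vec = pd.Series(rng.normal(size=30), index=ref.genes)
        sp = score_logfc_correlation(vec, ref_logfc, "spearman")
        pe = score_logfc_correlation(vec, ref_logfc, "pearson")
        for j, s in enumerate(ref.samples):
            col = ref_logfc.values[s].to_numpy()
            assert sp[s] == pytest.approx(stats.spearmanr(vec, col).statistic)
            assert pe[s] == pytest.approx(stats.pearsonr(vec, col).statistic)

    def test_spearman_handles_ties_with_average_ranks(self):
        # hand-computed: x=[1,1,2,3], y=[10,20,20,30]
        # avg ranks x=[1.5,1.5,3,4], y=[1,2.5,2.5,4]; Pearson of ranks ~ 0.8
        ref = make_reference(
            np.column_stack([[10.0, 20.0, 20.0, 30.0], [1.0, 2.0, 3.0, 4.0]]),
            ["G1", "G2", "G3", "G4"],
            ["s1", "s2"],
        )
        vec = pd.Series([1.0, 1.0, 2.0, 3.0], index=ref.genes)
        scores = score_all_genes_correlation(vec, ref, "spearman")
        expected = stats.spearmanr(
            [1, 1, 2, 3], [10, 20, 20, 30]
        ).statistic
        assert scores["s1"] == pytest.approx(expected)

    def test_fewer_than_three_matched_genes_rejected(self):
        ref = make_reference(
            np.ones((3, 2)) + np.arange(6).reshape(3, 2),
            ["G1", "G2", "G3"],
            ["s1", "s2"],
        )
        vec = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(ValueError, match="at least 3"):
            score_all_genes_correlation(vec, ref, "pearson")

    def test_zero_variance_side_scores_zero_with_warning(self):
        ref = make_reference(
            np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
            ["G1", "G2", "G3"],
            ["s1", "s2"],
        )
        vec = pd.Series([1.0, 4.0, 9.0], index=ref.genes)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = score_all_genes_correlation(vec, ref, "pearson")
        assert scores["s2"] == 0.0
        assert abs(scores["s1"]) <= 1.0

    def test_all_genes_spearman_invariant_to_monotone_reference_transform(
        self, random_reference
    ):
        vec = pd.Series(
            np.random.default_rng(1).normal(size=random_reference.n_genes),
            index=random_reference.genes,
        )
        base = score_all_genes_correlation(vec, random_reference, "spearman")
        transformed = make_reference(
            np.exp(random_reference.values.to_numpy() / 2.0),
            random_reference.genes,
            random_reference.samples,
            list(random_reference.metadata["cell_type"]),
        )
        after = score_all_genes_correlation(vec, transformed, "spearman")
        assert np.allclose(base, after)


class TestZScores:
    def test_known_values_under_population_sd(self):
        z = compute_z_scores(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        # population sd of [1,2,3] is sqrt(2/3); (1-2)/sqrt(2/3) = -sqrt(1.5)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        z = compute_z_scores(rng.normal(10, 3, size=50))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_scores_give_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = compute_z_scores(np.full(5, 3.3))
        assert (z == 0).all()


@pytest.fixture(scope="module")
def small_panel():
    ref = generate_reference(n_genes=800, n_samples=24, n_cell_types=6, seed=9)
    truth = make_truth(ref, n_clusters=3, noise_sd=0.05, seed=9)
    markers, avg = generate_experiment(ref, truth)
    return ref, truth, markers, avg


class TestScoreExperiment:
    def test_one_score_per_cluster_sample_pair(self, small_panel):
        ref, truth, markers, avg = small_panel
        for method in METHODS:
            experiment = markers if method in LOGFC_METHODS else avg
            table = score_experiment(experiment, ref, method)
            assert len(table) == len(truth.cluster_sources) * ref.n_samples
            for _, group in table.groupby("cluster"):
                assert sorted(group["rank"]) == list(range(1, ref.n_samples + 1))
                assert abs(group["z_score"].mean()) < 1e-9
                assert group["z_score"].std(ddof=0) == pytest.approx(1.0)

    def test_correlation_scores_bounded(self, small_panel):
        ref, _, markers, avg = small_panel
        for method in ("logfc_spearman", "all_genes_pearson"):
            experiment = markers if method in LOGFC_METHODS else avg
            table = score_experiment(experiment, ref, method)
            assert table["score"].between(-1, 1).all()

    def test_incompatible_method_input_pairs_rejected(self, small_panel):
        _, _, markers, avg = small_panel
        ref = small_panel[0]
        with pytest.raises(TypeError, match="marker table"):
            score_experiment(avg, ref, "logfc_dot_product")
        with pytest.raises(TypeError, match="average-expression"):
            score_experiment(markers, ref, "all_genes_spearman")

    def test_rank_one_is_generating_sample_for_all_methods(self, small_panel):
        ref, truth, markers, avg = small_panel
        for method in METHODS:
            experiment = markers if method in LOGFC_METHODS else avg
            table = score_experiment(experiment, ref, method)
            best = table[table["rank"] == 1].set_index("cluster")["sample_id"]
            for cluster, source in truth.cluster_sources.items():
                assert best[cluster] == source, method

    def test_all_genes_scores_invariant_to_subsetting(self, small_panel):
        ref, _, _, avg = small_panel
        keep = ref.cell_types[:3]
        sub = subset_reference(ref, keep)
        full = score_experiment(avg, ref, "all_genes_spearman")
        subset = score_experiment(avg, ref, "all_genes_spearman", keep_cell_types=keep)
        merged = full.merge(
            subset, on=["cluster", "sample_id"], suffixes=("_full", "_sub")
        )
        assert len(merged) == len(subset)
        assert np.allclose(merged["score_full"], merged["score_sub"])

    def test_logfc_scores_change_after_subsetting(self, small_panel):
        ref, _, markers, _ = small_panel
        keep = ref.cell_types[:3]
        full = score_experiment(markers, ref, "logfc_dot_product")
        subset = score_experiment(
            markers, ref, "logfc_dot_product", keep_cell_types=keep
        )
        merged = full.merge(
            subset, on=["cluster", "sample_id"], suffixes=("_full", "_sub")
        )
        assert not np.allclose(merged["score_full"], merged["score_sub"])

    def test_variance_filter_reduces_genes_used(self, small_panel):
        ref, _, _, avg = small_panel
        full = score_experiment(avg, ref, "all_genes_pearson")
        filtered = score_experiment(avg, ref, "all_genes_pearson", keep_top_percent=10)
        assert filtered["n_genes_used"].iloc[0] < full["n_genes_used"].iloc[0]
        assert filtered["n_genes_used"].iloc[0] == int(np.ceil(0.1 * ref.n_genes))

    def test_rank_ties_broken_by_ascending_sample_id(self):
        ref = make_reference(
            np.array([[1.0, 1.0, 2.0], [2.0, 2.0, 1.0], [3.0, 3.0, 5.0]]),
            ["G1", "G2", "G3"],
            ["sB", "sA", "sC"],
        )
        markers = marker_table(
            [["G1", "c1", 1.0], ["G2", "c1", -1.0], ["G3", "c1", 0.5]]
        )
        table = score_experiment(markers, ref, "logfc_dot_product")
        # columns sB and sA are identical -> tied scores; sA must rank first
        scores = table.set_index("sample_id")
        assert scores.loc["sA", "score"] == scores.loc["sB", "score"]
        assert scores.loc["sA", "rank"] < scores.loc["sB", "rank"]
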
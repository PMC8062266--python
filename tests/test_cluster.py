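import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from cellclock.cluster import (
    MethylationMatrix,
    bootstrap_stability,
    composition_test,
    cut,
    filter_probes,
    fisher_exact_2x2,
    median_group_value,
    pearson_distance,
    top_variable,
    ward_cluster,
)
from _oracles import fisher_bruteforce, pearson_distance_formula


def toy_matrix(values, probe_ann=None, sample_ann=None):
    values = pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(len(values))],
        columns=[f"cg{j:03d}" for j in range(len(values[0]))],
    )
    if probe_ann is None:
        probe_ann = pd.DataFrame(
            {"chrom": "1", "snp_overlap": False, "on_450k": True, "on_850k": True},
            index=values.columns,
        )
    if sample_ann is None:
        sample_ann = pd.DataFrame(
            {"age_years": 30.0, "location": "supratentorial", "diagnosis": "PA"},
            index=values.index,
        )
    return MethylationMatrix(values, probe_ann, sample_ann)


class TestMethylationMatrix:
    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            toy_matrix([[0.5, 1.2], [0.3, 0.4]])

    def test_annotation_dimension_mismatch_rejected(self):
        values = pd.DataFrame([[0.1, 0.2]], index=["S0"], columns=["cg0", "cg1"])
        probe_ann = pd.DataFrame({"chrom": ["1"]}, index=["cg0"])
        sample_ann = pd.DataFrame({"age_years": [5.0]}, index=["S0"])
        with pytest.raises(ValueError, match="probe_annotations"):
            MethylationMatrix(values, probe_ann, sample_ann)

    def test_stratum_reads_only_requested_location(self):
        m = toy_matrix(
            np.random.default_rng(0).uniform(0, 1, (6, 4)),
            sample_ann=pd.DataFrame(
                {
                    "age_years": 30.0,
                    "location": ["supratentorial"] * 3 + ["infratentorial"] * 3,
                    "diagnosis": "PA",
                },
                index=[f"S{i}" for i in range(6)],
            ),
        )
        sup = m.stratum("supratentorial")
        assert set(sup.sample_annotations["location"]) == {"supratentorial"}
        assert list(sup.values.index) == ["S0", "S1", "S2"]
        with pytest.raises(ValueError, match="no samples"):
            m.stratum("spinal")


class TestFilterProbes:
    def test_disjoint_flag_counting(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (3, 10))
        probe_ann = pd.DataFrame(
            {
                # probes 0-2 SNP-flagged, 3-4 on chrX, 5 single-platform
                "chrom": ["1", "2", "3", "X", "X", "4", "5", "6", "7", "8"],
                "snp_overlap": [True] * 3 + [False] * 7,
                "on_450k": [True] * 10,
                "on_850k": [True] * 5 + [False] + [True] * 4,
            },
            index=[f"cg{j:03d}" for j in range(10)],
        )
        m = toy_matrix(values, probe_ann=probe_ann)
        out = filter_probes(m)
        assert out.n_probes == 4
        assert list(out.values.columns) == ["cg006", "cg007", "cg008", "cg009"]

    def test_no_flags_is_identity(self):
        m = toy_matrix(np.random.default_rng(2).uniform(0, 1, (3, 5)))
        out = filter_probes(m)
        assert list(out.values.columns) == list(m.values.columns)

    def test_missing_annotation_column_rejected(self):
        m = toy_matrix(np.random.default_rng(3).uniform(0, 1, (3, 5)))
        broken = MethylationMatrix(
            m.values, m.probe_annotations.drop(columns=["snp_overlap"]), m.sample_annotations
        )
        with pytest.raises(ValueError, match="snp_overlap"):
            filter_probes(broken)


class TestTopVariable:
    def test_full_fraction_is_identity(self):
        m = toy_matrix(np.random.default_rng(4).uniform(0, 1, (5, 8)))
        assert list(top_variable(m, 1.0).values.columns) == list(m.values.columns)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        m = toy_matrix(rng.uniform(0, 1, (6, 200)))
        out = top_variable(m, 0.01)
        assert out.n_probes == 2
        sd = m.values.std(ddof=1)
        want = set(sd.sort_values(ascending=False).index[:2])
        assert set(out.values.columns) == want

    def test_missing_value_probe_excluded(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0.4, 0.6, (4, 5))
        values[:, 0] = [0.0, 1.0, 0.0, 1.0]  # highest SD but will get a NaN
        values[0, 0] = np.nan
        m = toy_matrix(values)
        out = top_variable(m, 0.25)  # 1 of 4 rankable probes
        assert "cg000" not in out.values.columns

    def test_bad_fraction_rejected(self):
        m = toy_matrix(np.random.default_rng(7).uniform(0, 1, (3, 4)))
        with pytest.raises(ValueError):
            top_variable(m, 0.0)


class TestPearsonDistance:
    def test_duplicate_sample_at_zero(self):
        x = np.vstack([np.linspace(0.1, 0.9, 10)] * 2)
        d = pearson_distance(toy_matrix(x))
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_at_two(self):
        base = np.linspace(0.1, 0.9, 10)
        d = pearson_distance(toy_matrix(np.vstack([base, 1.0 - base])))
        assert d.iloc[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, (5, 20))
        d = pearson_distance(toy_matrix(x))
        np.testing.assert_allclose(d.to_numpy(), pearson_distance_formula(x), atol=1e-12)

    def test_zero_variance_sample_named(self):
        x = np.random.default_rng(9).uniform(0, 1, (3, 6))
        x[1, :] = 0.5
        with pytest.raises(ValueError, match="S1"):
            pearson_distance(toy_matrix(x))


# Frozen oracle: R hclust(method = "ward.D") on d = 1 - cor(t(x)) for the
# fixed 8 x 5 matrix below (heights to 1e-12; merges and the k=2 cut agree).
R_ORACLE_X = np.array(
    [
        [0.914806, 0.656992, 0.978226, 0.082438, 0.388108],
        [0.937075, 0.705065, 0.117487, 0.514212, 0.685170],
        [0.286140, 0.457742, 0.474997, 0.390203, 0.003948],
        [0.830448, 0.719112, 0.560333, 0.905738, 0.832916],
        [0.641746, 0.934672, 0.904031, 0.446970, 0.007334],
        [0.519096, 0.255429, 0.138710, 0.836004, 0.207659],
        [0.736588, 0.462293, 0.988892, 0.737596, 0.906601],
        [0.134667, 0.940015, 0.946668, 0.811055, 0.611779],
    ]
)
R_ORACLE_HEIGHTS = [
    0.086261407195,
    0.247950564228,
    0.620276982092,
    0.692027770526,
    1.010589435560,
    1.493792611759,
    3.451533429824,
]
R_ORACLE_CUT2 = [0, 1, 0, 1, 0, 1, 0, 0]


class TestWardCluster:
    def test_two_samples_single_merge(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        Z = ward_cluster(d)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.7)

    def test_three_point_lance_williams_by_hand(self):
        """d(0,1)=1, d(0,2)=d(1,2)=10: first merge (0,1) at height 1; the
        updated distance is ((1+1)*10 + (1+1)*10 - 1*1)/3 = 13."""
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        Z = ward_cluster(d)
        assert (Z[0, 0], Z[0, 1]) == (0, 1)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(13.0)

    def test_matches_r_hclust_ward_d(self):
        d = 1.0 - np.corrcoef(R_ORACLE_X)
        np.fill_diagonal(d, 0.0)
        Z = ward_cluster(d)
        np.testing.assert_allclose(Z[:, 2], R_ORACLE_HEIGHTS, atol=1e-9)
        assert cut(Z, 2).tolist() == R_ORACLE_CUT2

    def test_heights_nondecreasing_on_random_input(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x = rng.uniform(0, 1, (12, 9))
            d = 1.0 - np.corrcoef(x)
            np.fill_diagonal(d, 0.0)
            Z = ward_cluster(d)
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(d)


class TestCut:
    @pytest.fixture()
    def tree(self):
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        return ward_cluster(d)

    def test_k_equals_n_gives_singletons(self, tree):
        assert cut(tree, 3).tolist() == [0, 1, 2]

    def test_k_one_single_cluster(self, tree):
        assert cut(tree, 1).tolist() == [0, 0, 0]

    def test_k_two_splits_odd_point_out(self, tree):
        assert cut(tree, 2).tolist() == [0, 0, 1]

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut(tree, 4)


class TestBootstrapStability:
    def test_strong_planted_clusters_fully_stable(self, strong_methylome):
        matrix, truth = strong_methylome
        bp, skipped = bootstrap_stability(filter_probes(matrix), k=2, B=100, seed=1)
        assert skipped == 0
        assert (bp == 1.0).all()

    def test_pure_noise_clusters_unstable(self):
        from cellclock.methylome_sim import null_matrix

        m = null_matrix(30, 400, seed=11)
        bp, _ = bootstrap_stability(m, k=2, B=50, seed=12, fraction=0.05)
        assert bp.mean() < 0.9

    def test_same_seed_identical(self, strong_methylome):
        matrix, _ = strong_methylome
        m = filter_probes(matrix)
        a, _ = bootstrap_stability(m, k=2, B=20, seed=5)
        b, _ = bootstrap_stability(m, k=2, B=20, seed=5)
        assert a.equals(b)


class TestCompositionTest:
    def test_adult_enriched_cluster_table(self):
        """17/20 adults in one cluster vs 4/34 in the other is far beyond
        chance under fixed margins."""
        assignments = pd.Series([0] * 20 + [1] * 34)
        adult = pd.Series(["adult"] * 17 + ["ped"] * 3 + ["adult"] * 4 + ["ped"] * 30)
        table, p = composition_test(assignments, adult)
        assert table.to_numpy().sum() == 54
        assert p < 0.001
        assert p == pytest.approx(scipy_fisher(table.to_numpy())[1], rel=1e-9)

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T), abs=1e-12)

    def test_matches_exhaustive_enumeration_small_margins(self):
        """Every 2×2 table with all margins ≤ 12 matches the exact-rational
        brute-force enumeration to 1e-12."""
        for r1 in range(0, 13):
            for c1 in range(0, 13):
                for a in range(0, min(r1, c1) + 1):
                    for d in range(0, 13 - max(r1 - a, c1 - a)):
                        b, c = r1 - a, c1 - a
                        if b + d > 12 or c + d > 12:
                            continue
                        table = [[a, b], [c, d]]
                        got = fisher_exact_2x2(np.array(table))
                        assert got == pytest.approx(fisher_bruteforce(table), abs=1e-12)

    def test_more_than_two_groups_rejected(self):
        assignments = pd.Series([0, 0, 1, 1, 2, 2])
        group = pd.Series(["a", "b"] * 3)
        with pytest.raises(ValueError, match="pairwise"):
            composition_test(assignments, group)


class TestMedianGroupValue:
    def test_singleton_and_even_cluster_medians(self):
        assignments = pd.Series([0, 1, 1], index=["a", "b", "c"])
        values = pd.Series([3.0, 2.0, 4.0], index=["a", "b", "c"])
        med = median_group_value(assignments, values)
        assert med[0] == 3.0
        assert med[1] == 3.0  # mean of central pair

    def test_missing_value_rejected(self):
        assignments = pd.Series([0, 1], index=["a", "b"])
        values = pd.Series([3.0, np.nan], index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            median_group_value(assignments, values)
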
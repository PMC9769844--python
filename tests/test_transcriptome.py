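"""Size factors, rlog-like transform, DE testing, MDS, centroid
dissimilarity, and the dissimilarity-fitness regression."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy.stats import ortho_group

import oriscope as osc
from oriscope.simulate import ExpressionDesign, PopulationDesign, simulate_counts
from oriscope.transcriptome import (
    MdsEmbedding,
    NBWaldDE,
    centroid_dissimilarity,
    classical_mds,
    de_test,
    deg_overlap,
    fitness_regression,
    rlog_like,
    size_factors,
    validate_meta,
)


def make_counts(array, samples=None):
    array = np.asarray(array)
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return pd.DataFrame(array, index=[f"g{i}" for i in range(array.shape[0])],
                        columns=samples)


def make_meta(populations, lineage="WT", ancestor=None, fitness=None):
    ancestor = ancestor or populations[0]
    rows = []
    counter = {}
    for p in populations:
        counter[p] = counter.get(p, 0) + 1
        rows.append({
            "sample_id": f"{p}_r{counter[p]}",
            "population": p,
            "replicate": counter[p],
            "lineage": lineage,
            "relative_fitness": (fitness or {}).get(p, 1.0),
            "is_ancestor": p == ancestor,
        })
    return pd.DataFrame(rows).set_index("sample_id")


class TestSizeFactors:
    def test_exact_doubling_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        counts = make_counts(np.column_stack([base, base * 2]))
        s = size_factors(counts)
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0)

    def test_identical_samples_get_equal_factors(self):
        base = np.arange(1, 41)
        counts = make_counts(np.column_stack([base] * 4))
        assert size_factors(counts).nunique() == 1

    def test_planted_library_scalars_recovered(self):
        pops = (PopulationDesign("anc", 1.0, 6, "WT", True),)
        design = ExpressionDesign(populations=pops, n_genes=1500,
                                  shifted_fraction=0.0, effect_scale=0.0,
                                  dispersion=0.05, seed=21)
        counts, meta = simulate_counts(design)
        s = size_factors(counts)
        truth = meta["true_size_factor"]
        ratio = (s / s.iloc[0]) / (truth / truth.iloc[0])
        assert np.max(np.abs(ratio - 1.0)) < 0.05

    def test_requires_an_all_positive_gene(self):
        counts = make_counts([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            size_factors(counts)


class TestRlogLike:
    def test_worked_values(self):
        counts = make_counts([[0], [3]])
        s = pd.Series([1.0], index=counts.columns)
        y = rlog_like(counts, s)
        assert y.iloc[0, 0] == 0.0
        assert y.iloc[1, 0] == pytest.approx(2.0)  # log2(3 + 1)

    def test_monotone_in_counts(self):
        counts = make_counts([[1], [5], [500]])
        y = rlog_like(counts, pd.Series([1.0], index=counts.columns))
        assert y.iloc[0, 0] < y.iloc[1, 0] < y.iloc[2, 0]


class TestDeTest:
    def test_identical_groups_yield_no_degs(self):
        base = np.arange(10, 110)
        meta = make_meta(["A", "A", "B", "B"])
        counts = make_counts(np.column_stack([base] * 4), samples=list(meta.index))
        res = de_test(counts, meta, "A", "B")
        assert (res.log2_fold_change == 0).all()
        assert not res.is_deg.any()

    def test_null_false_positive_rate_is_calibrated(self):
        pops = (PopulationDesign("A", 1.0, 3, "WT", True),
                PopulationDesign("B", 1.0, 3, "WT", False))
        design = ExpressionDesign(populations=pops, n_genes=2000,
                                  shifted_fraction=0.0, effect_scale=0.0,
                                  seed=11)
        counts, meta = simulate_counts(design)
        res = de_test(counts, meta, "A", "B")
        fpr = (res.p_value < 0.05).mean()
        assert 0.02 <= fpr <= 0.08

    def test_planted_fourfold_genes_are_detected(self):
        rng = np.random.default_rng(7)
        n_genes, n_planted, disp = 2000, 100, 0.01
        base = np.full(n_genes, 500.0)
        fold = np.ones(n_genes)
        fold[:n_planted] = 4.0

        def nb(mean):
            lam = rng.gamma(1 / disp, mean * disp)
            return rng.poisson(lam)

        a = np.column_stack([nb(base) for _ in range(3)])
        b = np.column_stack([nb(base * fold) for _ in range(3)])
        meta = make_meta(["A"] * 3 + ["B"] * 3)
        counts = make_counts(np.column_stack([a, b]), samples=list(meta.index))
        res = de_test(counts, meta, "A", "B")
        power = res.is_deg.iloc[:n_planted].mean()
        assert power >= 0.8
        assert res.is_deg.iloc[n_planted:].mean() < 0.01

    def test_q_values_are_bh_monotone(self):
        pops = (PopulationDesign("A", 1.0, 2, "WT", True),
                PopulationDesign("B", 1.0, 2, "WT", False))
        design = ExpressionDesign(populations=pops, n_genes=500,
                                  shifted_fraction=0.0, effect_scale=0.0, seed=3)
        counts, meta = simulate_counts(design)
        res = de_test(counts, meta, "A", "B").sort_values("p_value")
        assert np.all(np.diff(res.q_value.to_numpy()) >= -1e-12)

    def test_all_zero_genes_are_excluded_and_reported(self):
        base = np.arange(10, 50)
        arr = np.column_stack([base] * 4)
        arr[5, :] = 0
        meta = make_meta(["A", "A", "B", "B"])
        counts = make_counts(arr, samples=list(meta.index))
        est = NBWaldDE().fit(counts, meta, "A", "B")
        assert list(est.excluded_genes_) == ["g5"]
        assert "g5" not in est.results_.index

    def test_single_replicate_group_rejected(self):
        meta = make_meta(["A", "B", "B"])
        counts = make_counts(np.ones((10, 3), dtype=int), samples=list(meta.index))
        with pytest.raises(ValueError):
            de_test(counts, meta, "A", "B")


class TestDegOverlap:
    def test_worked_example(self):
        report = deg_overlap({
            "p1": ({"a", "b", "c"}, set()),
            "p2": ({"b", "c", "d"}, set()),
            "p3": ({"c"}, set()),
        })
        assert report.common_up == {"c"}
        assert report.common_up_pct == pytest.approx(25.0)  # 1 of 4

    def test_disjoint_sets_share_nothing(self):
        report = deg_overlap({"p1": ({"a"}, {"x"}), "p2": ({"b"}, {"y"})})
        assert report.common_up_pct == 0.0
        assert report.common_down_pct == 0.0

    def test_exclusive_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            p: set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for p in ["p1", "p2", "p3", "p4"]
        }
        report = deg_overlap({p: (s, set()) for p, s in sets.items()})
        union = set().union(*sets.values())
        assert sum(report.up_exclusive.values()) == len(union)
        # oracle: enumerate every non-empty membership pattern explicitly
        for r in range(1, 5):
            for members in combinations(sorted(sets), r):
                exact = set(universe)
                for p in sets:
                    exact &= sets[p] if p in members else (union - sets[p])
                key = tuple(p for p in sets if p in members)
                assert report.up_exclusive.get(key, 0) == len(exact)


class TestClassicalMDS:
    def test_recovers_distances_of_random_3d_configuration(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(14, 3))
        emb = classical_mds(pd.DataFrame(points), m=3)
        got = np.linalg.norm(
            emb.coordinates.to_numpy()[:, None] - emb.coordinates.to_numpy()[None],
            axis=-1,
        )
        want = np.linalg.norm(points[:, None] - points[None], axis=-1)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_two_points_split_symmetrically(self):
        points = np.array([[0.0], [6.0]])
        emb = osc.ClassicalMDS(n_components=1).fit(points)
        np.testing.assert_allclose(np.abs(emb.embedding_[:, 0]), 3.0, atol=1e-10)

    def test_equilateral_triangle_preserved(self):
        # three unit-distance points embedded in the plane
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        emb = classical_mds(pd.DataFrame(pts), m=2)
        coords = emb.coordinates.to_numpy()
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0,
                                                                          abs=1e-10)

    def test_embedded_distances_never_exceed_inputs(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(12, 30))
        emb = classical_mds(pd.DataFrame(points), m=3)
        got = np.linalg.norm(
            emb.coordinates.to_numpy()[:, None] - emb.coordinates.to_numpy()[None],
            axis=-1,
        )
        want = np.linalg.norm(points[:, None] - points[None], axis=-1)
        assert np.all(got <= want + 1e-8)

    def test_degenerate_configuration_truncates_with_warning(self):
        points = np.column_stack([np.arange(6.0)])  # collinear
        with pytest.warns(UserWarning):
            emb = classical_mds(pd.DataFrame(points), m=3)
        assert emb.truncated
        assert emb.n_dims == 1


def embedding_from(points, samples):
    return MdsEmbedding(
        pd.DataFrame(points, index=samples,
                     columns=[f"mds{i+1}" for i in range(points.shape[1])]),
        eigenvalues=np.ones(points.shape[1]),
    )


class TestCentroidDissimilarity:
    def test_distance_between_tight_clusters(self):
        p, q = np.array([1.0, 2.0, 2.0]), np.array([1.0, 0.0, 0.0])
        points = np.vstack([q, q, p, p])
        samples = ["anc_r1", "anc_r2", "evo_r1", "evo_r2"]
        meta = make_meta(["anc", "anc", "evo", "evo"])
        out = centroid_dissimilarity(embedding_from(points, samples), meta)
        assert out.loc["evo", "dissimilarity"] == pytest.approx(np.linalg.norm(p - q))
        assert out.loc["anc", "dissimilarity"] == 0.0

    def test_rigid_motion_leaves_dissimilarity_unchanged(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(8, 3))
        samples = [f"{p}_r{r}" for p in ["anc", "e1", "e2", "e3"] for r in (1, 2)]
        meta = make_meta(["anc", "anc", "e1", "e1", "e2", "e2", "e3", "e3"])
        base = centroid_dissimilarity(embedding_from(points, samples), meta)
        rot = ortho_group.rvs(3, random_state=4)
        moved = points @ rot.T + np.array([5.0, -2.0, 1.0])
        out = centroid_dissimilarity(embedding_from(moved, samples), meta)
        np.testing.assert_allclose(out["dissimilarity"], base["dissimilarity"],
                                   atol=1e-9)

    def test_lineages_pair_with_their_own_ancestor(self):
        rows = []
        for pop, lin, anc in [("wt_anc", "WT", True), ("wt_evo", "WT", False),
                              ("o3_anc", "O3", True), ("o3_evo", "O3", False)]:
            rows.append({"sample_id": f"{pop}_r1", "population": pop,
                         "replicate": 1, "lineage": lin,
                         "relative_fitness": 1.0, "is_ancestor": anc})
        meta = pd.DataFrame(rows).set_index("sample_id")
        points = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0], [14.0, 0, 0]])
        out = centroid_dissimilarity(
            embedding_from(points, list(meta.index)), meta
        )
        assert out.loc["wt_evo", "dissimilarity"] == pytest.approx(1.0)
        assert out.loc["o3_evo", "dissimilarity"] == pytest.approx(4.0)

    def test_missing_ancestor_rejected(self):
        meta = make_meta(["a", "b"])
        meta["is_ancestor"] = False
        points = np.zeros((2, 3))
        with pytest.raises(ValueError):
            validate_meta(meta)


class TestFitnessRegression:
    @staticmethod
    def points_frame(x, y):
        return pd.DataFrame({
            "relative_fitness": x,
            "dissimilarity": y,
            "is_ancestor": [False] * len(x),
            "lineage": "WT",
        }, index=[f"p{i}" for i in range(len(x))])

    def test_collinear_points_give_unit_r_squared(self):
        x = np.array([1.0, 1.1, 1.2, 1.3])
        res = fitness_regression(self.points_frame(x, 2 * x - 1))
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(1.0, 1.5, 12)
        y = 3 * x + rng.normal(0, 0.2, 12)
        res = fitness_regression(self.points_frame(x, y))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert 0.0 <= res.r_squared <= 1.0

    def test_ancestor_exclusion_flag(self):
        df = self.points_frame(np.array([1.0, 1.2, 1.3, 1.4]),
                               np.array([0.0, 2.0, 3.0, 4.0]))
        df.iloc[0, df.columns.get_loc("is_ancestor")] = True
        with_anc = fitness_regression(df, include_ancestors=True)
        without = fitness_regression(df, include_ancestors=False)
        assert with_anc.n == 4 and without.n == 3

    def test_zero_variance_predictor_rejected(self):
        df = self.points_frame(np.ones(4), np.arange(4.0))
        with pytest.raises(ValueError):
            fitness_regression(df)


class TestEndToEndDissimilarity:
    def test_planted_fitness_signal_recovered_in_regression(self):
        # populations spanning the observed fitness range, 2 replicates each
        r2 = []
        for seed in range(20):
            counts, meta = simulate_counts(osc.default_expression_design(seed=seed))
            emb = classical_mds(rlog_like(counts).T, m=3)
            points = centroid_dissimilarity(emb, meta)
            r2.append(fitness_regression(points).r_squared)
        assert np.median(r2) >= 0.8
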
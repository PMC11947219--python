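"""Tests of neighbourhood aggregation, FMI stability selection and the CN
summary statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antoni.neighbourhoods import (
    aggregate_features,
    build_spatial_graph,
    cn_enrichment,
    cn_proximity,
    correlate_with_covariate,
    derive_neighbourhoods,
    fowlkes_mallows,
    select_k,
)


def fmi_oracle(a, b):
    """Brute-force pair counting over all item pairs."""
    a, b = np.asarray(a), np.asarray(b)
    tp = fp = fn = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        tp += sa and sb
        fp += sa and not sb
        fn += (not sa) and sb
    if tp == 0:
        return 0.0
    return tp / np.sqrt((tp + fp) * (tp + fn))


class TestSpatialGraph:
    def test_edges_respect_trim_and_no_self_loops(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 500, (200, 2))
        edges = build_spatial_graph(xy, trim_um=30)
        assert (edges[:, 0] != edges[:, 1]).all()
        d = np.hypot(*(xy[edges[:, 0]] - xy[edges[:, 1]]).T)
        assert (d <= 30).all()

    def test_degenerate_inputs(self):
        assert len(build_spatial_graph(np.empty((0, 2)))) == 0
        assert len(build_spatial_graph(np.array([[0.0, 0.0]]))) == 0
        e = build_spatial_graph(np.array([[0.0, 0.0], [5.0, 0.0]]), trim_um=30)
        assert len(e) == 1


class TestAggregateFeatures:
    def test_depth_zero_is_identity(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        F, flags = aggregate_features(X, np.array([[0, 1]]), L=0)
        assert np.array_equal(F, X) and flags.shape == (4, 0)

    def test_path_graph_hand_enumeration(self):
        # path 0-1-2; middle cell's shell-1 mean = mean of cells 0 and 2
        X = np.array([[1.0, 0.0], [0.0, 1.0], [3.0, 5.0]])
        edges = np.array([[0, 1], [1, 2]])
        F, flags = aggregate_features(X, edges, L=2)
        assert np.allclose(F[1, 2:4], [(1 + 3) / 2, (0 + 5) / 2])
        # end cell 0: shell 1 = {1}, shell 2 = {2}
        assert np.allclose(F[0, 2:4], X[1]) and np.allclose(F[0, 4:6], X[2])
        # the middle cell has no node at hop distance 2: flagged, zero-padded
        assert flags[1, 1] and np.allclose(F[1, 4:6], 0.0)
        assert not flags[[0, 2]].any()

    def test_disconnected_singleton_zero_padded_and_flagged(self):
        X = np.ones((3, 2))
        edges = np.array([[0, 1]])  # cell 2 isolated
        F, flags = aggregate_features(X, edges, L=2)
        assert np.allclose(F[2, 2:], 0.0)
        assert flags[2].all()


class TestFowlkesMallows:
    def test_identical_labelings_score_one(self):
        assert fowlkes_mallows([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_six_item_example_matches_pair_counting_oracle(self):
        a, b = [1, 1, 2, 2, 3, 3], [1, 1, 1, 2, 2, 3]
        assert fowlkes_mallows(a, b) == pytest.approx(fmi_oracle(a, b))

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 20)
        b = rng.integers(0, 4, 20)
        assert fowlkes_mallows(a, b) == pytest.approx(fowlkes_mallows(2 - a, b + 7))

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            fowlkes_mallows([1], [1])
        with pytest.raises(ValueError):
            fowlkes_mallows([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.integers(2, 8).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 3), min_size=n, max_size=n),
            st.lists(st.integers(0, 3), min_size=n, max_size=n),
        )
    ))
    def test_matches_oracle_on_random_labelings(self, ab):
        a, b = ab
        assert fowlkes_mallows(a, b) == pytest.approx(fmi_oracle(a, b))


class TestSelectK:
    def _domains(self, seed, n=600):
        # three well-separated components with unequal weights and an
        # asymmetric layout: a perfectly symmetric mixture is degenerate
        # for within-K stability (every repeat merges the same two blobs
        # at K=2, tying the planted K at stability 1 and losing the tie
        # to parsimony)
        rng = np.random.default_rng(seed)
        centres = np.array([[0, 0], [5.0, 0.5], [1.0, 6.0]])
        lab = rng.choice(3, n, p=[0.45, 0.35, 0.2])
        X = centres[lab] + rng.normal(0, 0.5, (n, 2))
        return X, lab

    def test_three_planted_gaussians_select_k3(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for rep in range(3):
            X, lab = self._domains(rep)
            curve, model, labels = select_k(X, range(2, 6), repeats=5, seed=rep)
            if curve.selected_k == 3 and adjusted_rand_score(lab, labels) >= 0.95:
                hits += 1
        assert hits >= 2

    def test_duplicating_points_keeps_selected_k(self):
        X, _ = self._domains(1, n=300)
        c1, _, _ = select_k(X, range(2, 5), repeats=4, seed=0)
        c2, _, _ = select_k(np.vstack([X, X]), range(2, 5), repeats=4, seed=0)
        assert c1.selected_k == c2.selected_k

    def test_single_repeat_rejected(self):
        X, _ = self._domains(0, n=100)
        with pytest.raises(ValueError, match="repeats"):
            select_k(X, range(2, 4), repeats=1, seed=0)

    def test_k_range_bounds_enforced(self):
        X, _ = self._domains(0, n=50)
        with pytest.raises(ValueError, match="k_range"):
            select_k(X, range(2, 30), repeats=2, seed=0)

    def test_deterministic_given_seed(self):
        X, _ = self._domains(2, n=200)
        c1, _, l1 = select_k(X, range(2, 5), repeats=3, seed=9)
        c2, _, l2 = select_k(X, range(2, 5), repeats=3, seed=9)
        assert c1.stability == c2.stability and np.array_equal(l1, l2)

    def test_between_mode_runs_and_selects_within_range(self):
        X, _ = self._domains(3, n=300)
        curve, _, _ = select_k(X, range(2, 6), repeats=3, seed=0, mode="between")
        assert curve.selected_k in range(2, 6) and curve.mode == "between"


class TestCNSummaries:
    def test_single_cn_enrichment_all_ones(self):
        e = cn_enrichment(["c"] * 10, ["A"] * 6 + ["B"] * 4)
        assert np.allclose(e.to_numpy(), 1.0)

    def test_hand_contingency_table(self):
        cn = ["1"] * 4 + ["2"] * 6
        pop = ["A", "A", "A", "B", "A", "B", "B", "B", "B", "B"]
        e = cn_enrichment(cn, pop)
        # overall: A 4/10, B 6/10; CN1: A 3/4 -> 0.75/0.4
        assert e.loc["1", "A"] == pytest.approx((3 / 4) / (4 / 10))
        assert e.loc["2", "B"] == pytest.approx((5 / 6) / (6 / 10))

    def test_absent_type_is_zero(self):
        e = cn_enrichment(["1", "1", "2", "2"], ["A", "A", "B", "B"])
        assert e.loc["1", "B"] == 0.0

    def test_weighted_row_average_is_one(self):
        rng = np.random.default_rng(0)
        cn = rng.integers(0, 3, 200)
        pop = rng.choice(list("ABCD"), 200)
        e = cn_enrichment(cn, pop)
        overall = pd.Series(pop).value_counts(normalize=True).reindex(e.columns)
        assert np.allclose((e * overall).sum(axis=1), 1.0)

    def test_proximity_null_scores_near_zero(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, (400, 2))
        edges = build_spatial_graph(xy, 40)
        labels = rng.integers(0, 3, 400).astype(str)
        z = cn_proximity(labels, edges, n_perm=100, seed=0)
        assert (np.abs(z.to_numpy()) < 3).mean() >= 0.99

    def test_segregated_cns_positive_diagonal(self):
        rng = np.random.default_rng(2)
        xy = np.vstack([rng.uniform([0, 0], [200, 500], (200, 2)),
                        rng.uniform([300, 0], [500, 500], (200, 2))])
        edges = build_spatial_graph(xy, 60)
        labels = np.array(["L"] * 200 + ["R"] * 200)
        z = cn_proximity(labels, edges, n_perm=100, seed=0)
        assert z.loc["L", "L"] > 3 and z.loc["R", "R"] > 3
        assert z.loc["L", "R"] < 0 and z.loc["R", "L"] < 0

    def test_single_cn_proximity_zero_matrix(self):
        z = cn_proximity(np.array(["c"] * 5), np.array([[0, 1], [1, 2]]), n_perm=10, seed=0)
        assert z.shape == (1, 1) and z.iloc[0, 0] == 0.0


class TestCovariateCorrelation:
    def test_exact_line_gives_r_one(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        res = correlate_with_covariate(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0) and res["p"] < 1e-6
        assert res["slope"] == pytest.approx(2.0) and res["intercept"] == pytest.approx(1.0)

    def test_pearson_matches_covariance_formula_oracle(self):
        idx = list("abcdef")
        x = pd.Series([1.2, 2.8, 3.1, 4.9, 5.3, 6.0], index=idx)
        y = pd.Series([0.9, 2.2, 3.8, 4.1, 5.9, 6.3], index=idx)
        res = correlate_with_covariate(x, y)
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res["method"] == "pearson" and res["r"] == pytest.approx(float(r_oracle))

    def test_heavy_tailed_covariate_takes_spearman_branch(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(20)]
        x = pd.Series(rng.normal(size=20), index=idx)
        y = pd.Series(np.exp(rng.standard_cauchy(20).__abs__()), index=idx)
        res = correlate_with_covariate(x, y)
        assert res["method"] == "spearman"

    def test_contract_errors(self):
        x = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(ValueError, match="4 cases"):
            correlate_with_covariate(x, x)
        x5 = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.raises(ValueError, match="variance"):
            correlate_with_covariate(x5, pd.Series([1.0, 2, 3, 4, 5], index=list("abcde")))


class TestDeriveNeighbourhoods:
    def test_planted_spatial_domains_recovered(self, small_study):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        rows = []
        # two ROIs, each split into 2 composition domains (left/right)
        for roi in ("r1", "r2"):
            xy = rng.uniform(0, [1000, 1000], (800, 2))
            left = xy[:, 0] < 500
            m1 = np.where(left, 0.9, 0.1) + rng.normal(0, 0.05, 800)
            m2 = np.where(left, 0.1, 0.9) + rng.normal(0, 0.05, 800)
            for k in range(800):
                rows.append({"cell_id": k, "roi_id": roi, "case_id": "c1",
                             "region": "AntoniA",
                             "population": "L" if left[k] else "R",
                             "x_um": xy[k, 0], "y_um": xy[k, 1],
                             "M1_norm": np.clip(m1[k], 0, 1),
                             "M2_norm": np.clip(m2[k], 0, 1)})
        cells = pd.DataFrame(rows)
        model = derive_neighbourhoods(cells, ["M1", "M2"], k_range=range(2, 5),
                                      hop_depth=1, repeats=4, n_perm=20, seed=0)
        assert model.stability.selected_k == 2
        truth = (cells["population"] == "L").astype(int)
        assert adjusted_rand_score(truth, pd.Series(model.labels).astype("category").cat.codes) >= 0.8
        assert np.allclose(model.abundance_roi.sum(axis=1), 1.0)
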
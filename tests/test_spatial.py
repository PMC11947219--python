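"""Tests of the cross-PCF, its edge correction, permutation significance
and the adjacency cell network statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antoni._geometry import annulus_rectangle_area, circle_rectangle_area
from antoni.spatial import (
    acn,
    acn_significance_roi,
    cross_pcf,
    interaction_network,
    pcf_heatmap,
    pcf_significance,
    pcf_significance_all_pairs,
)

from conftest import cocluster_roi, csr_roi


def _df(xy, labels, roi="r"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"roi_id": roi, "population": list(labels),
                         "x_um": xy[:, 0], "y_um": xy[:, 1]})


class TestGeometry:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.floats(-2, 5), st.floats(-2, 4), st.floats(0.1, 4),
    )
    def test_circle_rectangle_area_matches_grid_integration(self, cx, cy, r):
        W, H = 3.0, 2.0
        exact = float(circle_rectangle_area(cx, cy, r, W, H))
        xs = np.linspace(0, W, 601)[:-1] + W / 1200
        ys = np.linspace(0, H, 401)[:-1] + H / 800
        gx, gy = np.meshgrid(xs, ys)
        numeric = ((gx - cx) ** 2 + (gy - cy) ** 2 <= r * r).mean() * W * H
        assert abs(exact - numeric) < 0.02

    def test_interior_annulus_is_full_ring(self):
        a = annulus_rectangle_area(np.array([500.0]), np.array([500.0]), 19, 20, 1000, 1000)
        assert np.isclose(a[0], np.pi * (400 - 361))

    def test_corner_annulus_is_quarter_ring(self):
        a = annulus_rectangle_area(np.array([0.0]), np.array([0.0]), 19, 20, 1000, 1000)
        assert np.isclose(a[0], np.pi * (400 - 361) / 4)


class TestCrossPCF:
    def test_lone_a_with_no_b_in_range_gives_zero_curve(self):
        df = _df([[500, 500], [900, 900]], ["A", "B"])
        res = cross_pcf(df, "A", "B", 1000, 1000)
        assert np.allclose(res.g, 0.0) and res.gr20 == 0.0 and not res.empty

    def test_missing_type_flags_empty_not_nan(self):
        df = _df([[10, 10]], ["A"])
        res = cross_pcf(df, "A", "B", 100, 100)
        assert res.empty and np.isfinite(res.g).all()

    def test_ten_point_configuration_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 100, (10, 2))
        labels = ["A"] * 5 + ["B"] * 5
        df = _df(xy, labels)
        for ec in (False, True):
            res = cross_pcf(df, "A", "B", 100, 100, edge_correction=ec)
            g = np.zeros(20)
            rho_b = 5 / 1e4
            for i in range(10):
                if labels[i] != "A":
                    continue
                for j in range(10):
                    if j == i or labels[j] != "B":
                        continue
                    d = np.hypot(*(xy[i] - xy[j]))
                    k = int(d // 1.0)
                    if k >= 20:
                        continue
                    if ec:
                        area = annulus_rectangle_area(
                            np.array([xy[i, 0]]), np.array([xy[i, 1]]), k, k + 1, 100, 100
                        )[0]
                    else:
                        area = np.pi * ((k + 1) ** 2 - k**2)
                    g[k] += 1 / area
            g /= 5 * rho_b
            assert np.allclose(res.g, g)

    def test_symmetry_without_edge_correction(self):
        df = csr_roi(5)
        ab = cross_pcf(df, "A", "B", 1000, 1000, edge_correction=False)
        ba = cross_pcf(df, "B", "A", 1000, 1000, edge_correction=False)
        assert np.allclose(ab.g, ba.g)

    def test_csr_mean_gr20_near_one(self):
        vals = [cross_pcf(csr_roi(s), "A", "B", 1000, 1000).gr20 for s in range(60)]
        assert 0.75 < np.mean(vals) < 1.25

    def test_self_pair_excludes_the_cell_itself(self):
        df = _df([[50, 50], [55, 50]], ["A", "A"])
        res = cross_pcf(df, "A", "A", 100, 100, edge_correction=False)
        # exactly the two ordered (i, j) pairs at distance 5
        assert res.g[5] > 0 and res.g[[0, 1, 2, 3, 4]].sum() == 0

    def test_gr20_increases_with_cocluster_strength(self):
        means = []
        for strength in (0.5, 1.0, 2.0):
            vals = [cross_pcf(cocluster_roi(s, strength), "A", "B", 1000, 1000).gr20
                    for s in range(10)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestPCFSignificance:
    def test_planted_cocluster_detected_as_enriched(self):
        hits = 0
        for s in range(10):
            res = pcf_significance(cocluster_roi(s), "A", "B", 1000, 1000,
                                   n_perm=199, seed=s)
            hits += res.p_value < 0.05 and res.direction == "enriched"
        assert hits >= 9

    def test_null_rejection_rate_is_valid(self):
        # the tie-inclusive permutation p is conservative for a sparse,
        # heavily discrete gr20: rate must not exceed alpha (validity)
        rej = 0
        n = 60
        for s in range(n):
            res = pcf_significance(csr_roi(s), "A", "B", 1000, 1000, n_perm=99, seed=s)
            rej += res.p_value < 0.05
        assert rej / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)

    def test_seeded_pvalues_reproduce_bit_exactly(self):
        df = cocluster_roi(1)
        r1 = pcf_significance(df, "A", "B", 1000, 1000, n_perm=99, seed=5)
        r2 = pcf_significance(df, "A", "B", 1000, 1000, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.envelope_lo, r2.envelope_lo)

    def test_gr20_of_one_gives_large_p(self):
        # with zero pairs anywhere near 20 um every permutation ties obs
        df = _df([[10, 10], [12, 10], [900, 900], [902, 900]], ["A", "B", "A", "B"])
        res = pcf_significance(df, "A", "B", 1000, 1000, n_perm=99, seed=0)
        assert res.p_value > 0.5

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            pcf_significance(csr_roi(0), "A", "B", 1000, 1000, n_perm=20, seed=0)

    def test_envelope_brackets_null_curve(self):
        res = pcf_significance(csr_roi(2), "A", "B", 1000, 1000, n_perm=199, seed=2)
        assert (res.envelope_lo <= res.envelope_hi).all()


class TestACN:
    def test_no_b_cells_flagged_zero(self):
        df = _df([[10, 10]], ["A"])
        res = acn(df, "A", "B", 10)
        assert res.flagged and res.n_a_touching_b == 0 and res.prop_b_touched_by_a == 0.0

    def test_five_cell_toy_matches_hand_enumeration(self, toy_cells):
        # distances: 1-3 ~ 5.4 (contact), 2-5 ~ 8.2 (contact); 4 isolated
        res = acn(toy_cells, "A", "B", contact_radius=10)
        assert res.n_a_touching_b == 2  # cells 1 and 2 each touch a B
        assert np.isclose(res.prop_b_touched_by_a, 2 / 3)  # B cells 3 and 5

    def test_self_pair_never_self_contact(self):
        df = _df([[10, 10], [13, 14]], ["A", "A"])
        res = acn(df, "A", "A", contact_radius=10)
        assert res.n_a_touching_b == 2 and res.prop_b_touched_by_a == 1.0

    def test_contact_relation_symmetric(self):
        df = csr_roi(9)
        ab = acn(df, "A", "B", 10)
        ba = acn(df, "B", "A", 10)
        # identical unordered contact pairs: counts agree when viewed from
        # either side
        assert ab.n_a_touching_b == int(round(ba.prop_b_touched_by_a * ba.n_b))

    def test_invalid_radius_rejected(self, toy_cells):
        with pytest.raises(ValueError):
            acn(toy_cells, "A", "B", 0)


class TestACNSignificance:
    def test_null_rejection_rate_is_valid_and_bh_bounded(self):
        rej_raw, rej_bh, n = 0, 0, 40
        for s in range(n):
            out = acn_significance_roi(csr_roi(s), [("A", "B"), ("B", "A")],
                                       contact_radius=10, n_perm=99, seed=s)
            rej_raw += (out["p_value"] < 0.05).sum()
            rej_bh += (out["q_value"] < 0.05).sum()
        assert rej_raw / (2 * n) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (2 * n))
        assert rej_bh <= rej_raw

    def test_planted_cocluster_yields_network_edge(self):
        frames_acn, frames_pcf = [], []
        for s in range(4):
            df = cocluster_roi(s)
            frames_acn.append(acn_significance_roi(df, [("A", "B")], 10, n_perm=199, seed=s))
            frames_pcf.append(
                pcf_significance_all_pairs(df, [("A", "B")], 1000, 1000, n_perm=99, seed=s))
        acn_all = pd.concat(frames_acn, ignore_index=True)
        pcf_all = pd.concat(frames_pcf, ignore_index=True)
        ab = pd.DataFrame({"A": [0.25], "B": [0.25], "C": [0.5]})
        g, edges = interaction_network(acn_all, pcf_all, ab)
        assert len(edges) == 1 and edges.loc[0, "type_a"] == "A"
        assert g.edges[("A", "B")]["weight"] == pytest.approx(pcf_all["gr20"].mean())

    def test_single_significant_pair_edge_weight(self):
        acn_df = pd.DataFrame({
            "roi_id": ["r1"], "type_a": ["A"], "type_b": ["B"], "contact_radius": [10.0],
            "n_a": [10], "n_b": [10], "n_a_touching_b": [8],
            "prop_b_touched_by_a": [0.8], "flagged": [False],
            "p_value": [0.001], "q_value": [0.002],
        })
        pcf_df = pd.DataFrame({"roi_id": ["r1"], "type_a": ["A"], "type_b": ["B"],
                               "gr20": [2.5], "q_value": [0.002]})
        ab = pd.DataFrame({"A": [0.4], "B": [0.6]})
        g, edges = interaction_network(acn_df, pcf_df, ab)
        assert len(edges) == 1 and edges.loc[0, "weight_gr20"] == 2.5
        assert g.nodes["A"]["abundance"] == 0.4


class TestHeatmap:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["roi_id", "type_a", "type_b", "gr20", "q_value"])

    def test_single_significant_pair(self):
        res = self._frame([["r1", "A", "B", 2.2, 0.01]])
        mat, mask = pcf_heatmap(res)
        assert mat.loc["A", "B"] == 2.2 and not mask.loc["A", "B"]

    def test_all_nonsignificant_fully_masked(self):
        res = self._frame([["r1", "A", "B", 2.2, 0.2], ["r1", "B", "A", 1.1, 0.9]])
        mat, mask = pcf_heatmap(res)
        assert mask.to_numpy().all() and mat.isna().to_numpy().all()

    def test_mean_across_rois(self):
        res = self._frame([["r1", "A", "B", 1.5, 0.01], ["r2", "A", "B", 2.0, 0.01],
                           ["r3", "A", "B", 2.5, 0.01]])
        mat, _ = pcf_heatmap(res)
        assert mat.loc["A", "B"] == pytest.approx(2.0)
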
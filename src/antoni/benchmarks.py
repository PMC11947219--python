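"""Calibration and planted-structure benchmark suites.

Self-contained simulation studies that exercise the pipeline under known
truth: CSR calibration of the cross-PCF and its permutation test,
detection of planted co-clusters, recovery of planted cellular
neighbourhoods, planted ligand--receptor pairs, quantification
round-trips and the type-I error of the case-level comparison.  Used by
the validation test-suite and by the results-reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .group_stats import compare_two_groups
from .ligand_receptor import LRPair, filter_and_rank, lr_permutation_test
from .neighbourhoods import aggregate_features, build_spatial_graph, select_k
from .quantify import extract_cells
from .spatial import cross_pcf, pcf_significance
from .synthetic import (
    CoClusterSpec,
    PlantedPair,
    PopulationSpec,
    TissueSpec,
    generate_channel_stack,
    generate_expression_counts,
    generate_roi,
    lognormalize_counts,
)


def _csr_roi(seed, lam=100.0):
    pops = [
        PopulationSpec("A", "Other", lam, {"M": 1.0}),
        PopulationSpec("B", "Other", lam, {"M": 1.0}),
    ]
    return generate_roi(TissueSpec(populations=pops, seed=int(seed) % (2**31 - 1),
                                   roi_id=f"csr{seed}"))


def csr_gr20_calibration(n_rois: int = 200, lam: float = 100.0, seed: int = 0) -> float:
    """Mean gr20 of the edge-corrected cross-PCF over CSR ROIs.

    Two independent homogeneous Poisson populations at intensity ``lam``
    per mm^2 on a 1 mm^2 window; an unbiased estimator has mean 1.
    """
    rng = substream(seed, "csr_gr20")
    vals = []
    for _ in range(n_rois):
        df = _csr_roi(rng.integers(2**31 - 1))
        vals.append(cross_pcf(df, "A", "B", 1000.0, 1000.0).gr20)
    return float(np.mean(vals))


def pcf_type_one_rate(
    n_rois: int = 500, lam: float = 100.0, n_perm: int = 199,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Empirical rejection rate of the gr20 permutation test under CSR."""
    rng = substream(seed, "pcf_typeI")
    rej = 0
    for _ in range(n_rois):
        s = int(rng.integers(2**31 - 1))
        df = _csr_roi(s)
        res = pcf_significance(df, "A", "B", 1000.0, 1000.0, n_perm=n_perm, seed=s)
        rej += res.p_value < alpha
    return rej / n_rois


def cocluster_detection_rate(
    n_seeds: int = 100, strength: float = 2.0, n_perm: int = 199, seed: int = 0,
) -> float:
    """Fraction of seeds where a planted co-clustered pair is called
    significantly enriched (p < 0.05, gr20 > 1)."""
    rng = substream(seed, "cocluster")
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        pops = [
            PopulationSpec("A", "Other", 100, {"M": 1.0}),
            PopulationSpec("B", "Other", 100, {"M": 1.0}),
            PopulationSpec("C", "Other", 200, {"M": 1.0}),
        ]
        spec = TissueSpec(populations=pops,
                          planted_pairs=(CoClusterSpec("A", "B", strength=strength),),
                          seed=s, roi_id=f"cc{s}")
        res = pcf_significance(generate_roi(spec), "A", "B", 1000.0, 1000.0,
                               n_perm=n_perm, seed=s)
        hits += (res.p_value < 0.05) and res.direction == "enriched"
    return hits / n_seeds


def planted_cn_recovery(n_repeats: int = 10, seed: int = 0):
    """Recovery of three planted spatial neighbourhood domains.

    Each repeat builds one ROI with three vertical composition bands,
    aggregates hop-1 neighbourhood features on the trimmed Delaunay graph
    and runs FMI stability selection over K = 2..6 (10 GMM repeats).

    Returns ``(rate_k3, mean_ari)``: the fraction of repeats selecting
    K* = 3 and the mean adjusted Rand index of the final labels against
    the planted domains (over repeats that selected K* = 3).
    """
    from sklearn.metrics import adjusted_rand_score

    rng = substream(seed, "planted_cn")
    k3 = 0
    aris = []
    profiles = np.array([
        [1.0, 0.0, 0.0, 0.2, 0.1, 0.0],
        [0.0, 1.0, 0.0, 0.1, 0.2, 0.0],
        [0.0, 0.0, 1.0, 0.0, 0.1, 0.2],
    ])
    for _ in range(n_repeats):
        r = np.random.default_rng(int(rng.integers(2**31 - 1)))
        n = 1200
        xy = r.uniform(0, [1000, 1000], (n, 2))
        dom = np.minimum((xy[:, 0] // 334).astype(int), 2)
        X = profiles[dom] + r.normal(0, 0.15, (n, 6))
        edges = build_spatial_graph(xy, trim_um=40)
        feats, _ = aggregate_features(X, edges, L=1)
        curve, _, labels = select_k(feats, range(2, 7), repeats=10,
                                    seed=int(r.integers(2**31 - 1)))
        if curve.selected_k == 3:
            k3 += 1
            aris.append(adjusted_rand_score(dom, labels))
    return k3 / n_repeats, (float(np.mean(aris)) if aris else 0.0)


def lr_planted_rate(n_seeds: int = 20, fold: float = 8.0, n_perm: int = 199,
                    seed: int = 0) -> float:
    """Fraction of seeds where a planted fold-``fold`` ligand--receptor
    pair is permutation-significant AND ranks first after filtering."""
    rng = substream(seed, "lr_planted")
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        counts = generate_expression_counts(
            ["sender", "receiver", "bystander"],
            [PlantedPair("LIG", "REC", "sender", "receiver", fold)],
            n_cells_per_pop=200, seed=s)
        expr = lognormalize_counts(counts)
        labels = expr.pop("population").to_numpy()
        genes = list(expr.columns)
        pairs = [LRPair("planted", ("LIG",), ("REC",))] + [
            LRPair(f"bg{i}", (genes[2 + i],), (genes[10 + i],)) for i in range(8)]
        res = lr_permutation_test(expr, labels, pairs, [("sender", "receiver")],
                                  n_perm=n_perm, seed=s)
        ranked = filter_and_rank(res)
        ok = (len(ranked) > 0 and ranked.iloc[0]["pair_id"] == "planted"
              and float(res.loc[res.pair_id == "planted", "p_value"].iloc[0]) < 0.05)
        hits += ok
    return hits / n_seeds


def roundtrip_max_error(seed: int = 0, n_cells: int = 12) -> float:
    """Max |recovered - planted| marker mean over a disc-rendering
    round trip (disjoint cells; exact recovery expected)."""
    rng = substream(seed, "roundtrip")
    grid = np.array([(20 + 40 * (k % 5), 20 + 40 * (k // 5)) for k in range(n_cells)],
                    dtype=float)
    cells = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "x_um": grid[:, 0], "y_um": grid[:, 1],
        "M1": rng.uniform(0.1, 10, n_cells),
        "M2": rng.uniform(0.1, 10, n_cells),
    })
    stack, mask = generate_channel_stack(cells, ["M1", "M2"], 240, 240)
    tab = extract_cells(mask, stack, ["M1", "M2"], expansion_px=1)
    err = max(
        np.abs(tab["M1"].to_numpy() - cells["M1"].to_numpy()).max(),
        np.abs(tab["M2"].to_numpy() - cells["M2"].to_numpy()).max(),
    )
    return float(err)


def two_group_type_one_rate(n_sims: int = 1000, n_a: int = 13, n_b: int = 10,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of the gated two-group comparison under a shared
    normal null at the study's case counts."""
    rng = substream(seed, "two_group")
    rej = 0
    for _ in range(n_sims):
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0, 1, n_b)
        rej += compare_two_groups(a, b).p_value < alpha
    return rej / n_sims
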
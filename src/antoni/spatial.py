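"""Direct cell--cell interaction statistics for one or more ROIs.

Two complementary statistics, computed per ROI for ordered population
pairs (A, B):

* the cross-pair correlation function g_AB(r) out to 20 um with exact
  rectangular edge correction, summarised by ``gr20`` (the value of the
  final 1-um bin, [19, 20) um), and
* adjacency cell network (ACN) contact statistics: the number of A cells
  in contact with a B cell and the proportion of B cells touched by an A
  cell, with contact defined as centroid distance <= ``contact_radius``
  (default 10 um, about one cell diameter).

Significance for both comes from a label-permutation null: cell positions
stay fixed, population labels are shuffled over all cells of the ROI.
The PCF test is two-sided around the CSR value g = 1; the ACN test is
two-sided around the permutation-null mean.  Benjamini--Hochberg FDR is
applied across pairs within each ROI, and pairs significant in a majority
of a region class's ROIs form that class's interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from ._geometry import annulus_rectangle_area
from ._rng import substream


@dataclass
class PCFResult:
    type_a: str
    type_b: str
    roi_id: str
    bin_edges: np.ndarray
    g: np.ndarray
    gr20: float
    n_a: int
    n_b: int
    empty: bool = False
    p_value: float | None = None
    direction: str | None = None
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None


@dataclass
class ACNResult:
    type_a: str
    type_b: str
    roi_id: str
    contact_radius: float
    n_a: int
    n_b: int
    n_a_touching_b: int
    prop_b_touched_by_a: float
    flagged: bool = False
    p_value: float | None = None
    q_value: float | None = None


# ---------------------------------------------------------------------------
# cross-PCF engine


class _PairEngine:
    """Precomputed pair geometry of one ROI for fast label permutation.

    Stores every ordered pair (i, j), i != j, with centroid distance
    < r_max, its distance bin, and 1 / (rho-free annulus area of cell i's
    bin), so that a g-curve for any label assignment is a masked bincount.
    """

    def __init__(self, xy, width, height, r_max=20.0, dr=1.0, edge_correction=True):
        self.xy = np.asarray(xy, dtype=float)
        self.width, self.height = float(width), float(height)
        self.r_max, self.dr = float(r_max), float(dr)
        self.n_bins = int(round(r_max / dr))
        self.bin_edges = np.arange(0.0, self.n_bins + 1) * dr
        n = len(self.xy)
        areas = np.empty((n, self.n_bins))
        for k in range(self.n_bins):
            if edge_correction:
                areas[:, k] = annulus_rectangle_area(
                    self.xy[:, 0], self.xy[:, 1], k * dr, (k + 1) * dr, width, height
                )
            else:
                areas[:, k] = np.pi * (((k + 1) * dr) ** 2 - (k * dr) ** 2)
        if n >= 2:
            tree = cKDTree(self.xy)
            pairs = tree.query_pairs(r_max - 1e-12, output_type="ndarray")
            if len(pairs):
                d = np.hypot(*(self.xy[pairs[:, 0]] - self.xy[pairs[:, 1]]).T)
                I = np.concatenate([pairs[:, 0], pairs[:, 1]])
                J = np.concatenate([pairs[:, 1], pairs[:, 0]])
                b = np.minimum((np.concatenate([d, d]) / dr).astype(int), self.n_bins - 1)
            else:
                I = J = b = np.empty(0, dtype=int)
        else:
            I = J = b = np.empty(0, dtype=int)
        self.I, self.J, self.bins = I, J, b
        a = areas[I, b] if len(I) else np.empty(0)
        with np.errstate(divide="ignore"):
            self.inv_area = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)

    def curve(self, is_a: np.ndarray, is_b: np.ndarray) -> np.ndarray:
        """g_AB per bin for boolean A/B membership vectors."""
        n_a, n_b = int(is_a.sum()), int(is_b.sum())
        if n_a == 0 or n_b == 0:
            return np.zeros(self.n_bins)
        rho_b = n_b / (self.width * self.height)
        m = is_a[self.I] & is_b[self.J]
        g = np.bincount(self.bins[m], weights=self.inv_area[m], minlength=self.n_bins)
        return g / (n_a * rho_b)


def cross_pcf(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    width: float,
    height: float,
    r_max: float = 20.0,
    dr: float = 1.0,
    edge_correction: bool = True,
    label_col: str = "population",
) -> PCFResult:
    """Cross-pair correlation function g_AB(r) of one ROI.

    g_AB(r_k) = (1/n_A) sum_{i in A} c_i(r_k) / (rho_B a_i(r_k)), where
    c_i counts B cells at distance in [r_k, r_k + dr) of A-cell i (a cell
    never counts itself when A = B), rho_B is the B intensity and a_i the
    window-clipped annulus area around i.  ``gr20`` is the final bin.
    """
    roi = str(cells["roi_id"].iloc[0]) if len(cells) else ""
    labels = cells[label_col].to_numpy()
    eng = _PairEngine(cells[["x_um", "y_um"]].to_numpy(), width, height, r_max, dr, edge_correction)
    is_a, is_b = labels == type_a, labels == type_b
    n_a, n_b = int(is_a.sum()), int(is_b.sum())
    if n_a == 0 or n_b == 0:
        return PCFResult(type_a, type_b, roi, eng.bin_edges, np.zeros(eng.n_bins),
                         0.0, n_a, n_b, empty=True)
    g = eng.curve(is_a, is_b)
    return PCFResult(type_a, type_b, roi, eng.bin_edges, g, float(g[-1]), n_a, n_b)


def pcf_significance(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    width: float,
    height: float,
    n_perm: int = 1000,
    seed: int = 0,
    r_max: float = 20.0,
    dr: float = 1.0,
    alpha: float = 0.05,
    edge_correction: bool = True,
    label_col: str = "population",
) -> PCFResult:
    """Label-permutation significance of gr20 for one pair in one ROI.

    Positions stay fixed; the multiset of population labels is shuffled
    over all cells ``n_perm`` times.  Two-sided
    p = (1 + #{|g*_20 - 1| >= |g_20 - 1|}) / (n_perm + 1); direction from
    the sign of g_20 - 1 when significant, else ``"ns"``.  Also returns
    the per-bin 2.5/97.5% permutation envelope.
    """
    import warnings

    if n_perm < 99:
        warnings.warn("n_perm < 99 gives very coarse p-value resolution", stacklevel=2)
    res = cross_pcf(cells, type_a, type_b, width, height, r_max, dr, edge_correction, label_col)
    if res.empty:
        return res
    labels = cells[label_col].to_numpy()
    eng = _PairEngine(cells[["x_um", "y_um"]].to_numpy(), width, height, r_max, dr, edge_correction)
    rng = substream(seed, "pcf_perm", res.roi_id, type_a, type_b)
    curves = np.empty((n_perm, eng.n_bins))
    for p in range(n_perm):
        perm = rng.permutation(labels)
        curves[p] = eng.curve(perm == type_a, perm == type_b)
    perm_gr = curves[:, -1]
    p_val = (1 + np.sum(np.abs(perm_gr - 1.0) >= np.abs(res.gr20 - 1.0) - 1e-12)) / (n_perm + 1)
    res.p_value = float(p_val)
    res.envelope_lo = np.quantile(curves, 0.025, axis=0)
    res.envelope_hi = np.quantile(curves, 0.975, axis=0)
    if p_val < alpha:
        res.direction = "enriched" if res.gr20 > 1 else "depleted"
    else:
        res.direction = "ns"
    return res


def pcf_heatmap(results: pd.DataFrame, alpha: float = 0.05, q_col: str = "q_value"):
    """Pair x pair matrix of mean significant gr20 across ROIs.

    ``results`` is a tidy frame (one row per pair per ROI) holding
    ``type_a``, ``type_b``, ``gr20`` and a multiplicity-controlled
    ``q_value``.  Each matrix entry is the mean gr20 over ROIs where the
    pair was significant; the companion mask is True where a pair was
    never significant (or never measured).
    """
    types_a = sorted(results["type_a"].unique())
    types_b = sorted(results["type_b"].unique())
    mat = pd.DataFrame(np.nan, index=types_a, columns=types_b)
    mask = pd.DataFrame(True, index=types_a, columns=types_b)
    sig = results[results[q_col] < alpha]
    for (a, b), grp in sig.groupby(["type_a", "type_b"]):
        mat.loc[a, b] = grp["gr20"].mean()
        mask.loc[a, b] = False
    return mat, mask


# ---------------------------------------------------------------------------
# adjacency cell networks


def acn(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    contact_radius: float = 10.0,
    label_col: str = "population",
) -> ACNResult:
    """Contact statistics for one ordered pair in one ROI.

    Contact = centroid distance <= ``contact_radius``; a cell is never its
    own contact.  With no B cells present the proportion is defined as 0
    and the result flagged.
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be > 0")
    roi = str(cells["roi_id"].iloc[0]) if len(cells) else ""
    labels = cells[label_col].to_numpy()
    is_a, is_b = labels == type_a, labels == type_b
    n_a, n_b = int(is_a.sum()), int(is_b.sum())
    if n_a == 0 or n_b == 0:
        return ACNResult(type_a, type_b, roi, contact_radius, n_a, n_b, 0, 0.0, flagged=True)
    xy = cells[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(contact_radius, output_type="ndarray")
    if len(pairs):
        I = np.concatenate([pairs[:, 0], pairs[:, 1]])
        J = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        I = J = np.empty(0, dtype=int)
    touching_a = np.zeros(len(cells), bool)
    touching_a[I[(is_a[I]) & (is_b[J])]] = True  # A cells with a B contact
    touched_b = np.zeros(len(cells), bool)
    touched_b[J[(is_a[I]) & (is_b[J])]] = True  # B cells with an A contact
    return ACNResult(
        type_a, type_b, roi, contact_radius, n_a, n_b,
        int(np.sum(touching_a & is_a)), float(np.sum(touched_b & is_b) / n_b),
    )


def acn_significance_roi(
    cells: pd.DataFrame,
    pairs,
    contact_radius: float = 10.0,
    n_perm: int = 1000,
    seed: int = 0,
    label_col: str = "population",
) -> pd.DataFrame:
    """Permutation p-values and BH q-values for ACN pairs of one ROI.

    The null shuffles labels over all cells (positions fixed) and
    recomputes the proportion of B touched by A; the two-sided p compares
    the observed deviation from the permutation mean.  BH is applied
    across the tested pairs within the ROI.
    """
    roi = str(cells["roi_id"].iloc[0]) if len(cells) else ""
    labels = cells[label_col].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(xy) if len(cells) >= 2 else None
    pr = tree.query_pairs(contact_radius, output_type="ndarray") if tree is not None else np.empty((0, 2), int)
    if len(pr):
        I = np.concatenate([pr[:, 0], pr[:, 1]])
        J = np.concatenate([pr[:, 1], pr[:, 0]])
    else:
        I = J = np.empty(0, dtype=int)
    rng = substream(seed, "acn_perm", roi)
    perms = [rng.permutation(labels) for _ in range(n_perm)]

    rows = []
    for (a, b) in pairs:
        obs = acn(cells, a, b, contact_radius, label_col)
        row = {
            "roi_id": roi, "type_a": a, "type_b": b,
            "contact_radius": contact_radius,
            "n_a": obs.n_a, "n_b": obs.n_b,
            "n_a_touching_b": obs.n_a_touching_b,
            "prop_b_touched_by_a": obs.prop_b_touched_by_a,
            "flagged": obs.flagged,
        }
        if obs.flagged:
            row["p_value"] = np.nan
        else:
            stat = np.empty(n_perm)
            for k, perm in enumerate(perms):
                ia, ib = perm == a, perm == b
                touched = np.zeros(len(cells), bool)
                if len(I):
                    touched[J[ia[I] & ib[J]]] = True
                stat[k] = np.sum(touched & ib) / ib.sum()
            centre = stat.mean()
            p = (1 + np.sum(np.abs(stat - centre) >= np.abs(obs.prop_b_touched_by_a - centre) - 1e-12)) / (
                n_perm + 1
            )
            row["p_value"] = float(p)
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out


def interaction_network(
    acn_results: pd.DataFrame,
    pcf_results: pd.DataFrame,
    abundance: pd.DataFrame,
    alpha: float = 0.05,
    consensus_frac: float = 0.5,
):
    """Region-class interaction network from per-ROI ACN significance.

    An (A, B) edge exists when the pair is BH-significant in more than
    ``consensus_frac`` of the ROIs where it was measurable; edge weight is
    the pair's mean gr20 over those ROIs and node size the population's
    mean abundance.  Returns ``(networkx.Graph, edge_list_frame)``.
    """
    import networkx as nx

    g = nx.Graph()
    mean_ab = abundance.mean(axis=0) if len(abundance) else pd.Series(dtype=float)
    edges = []
    measurable = acn_results[~acn_results["flagged"].astype(bool)]
    for (a, b), grp in measurable.groupby(["type_a", "type_b"]):
        frac_sig = float((grp["q_value"] < alpha).mean())
        if frac_sig <= consensus_frac:
            continue
        sub = pcf_results[(pcf_results["type_a"] == a) & (pcf_results["type_b"] == b)]
        weight = float(sub["gr20"].mean()) if len(sub) else np.nan
        edges.append({"type_a": a, "type_b": b, "frac_significant_rois": frac_sig,
                      "weight_gr20": weight})
    for e in edges:
        for t in (e["type_a"], e["type_b"]):
            if t not in g:
                g.add_node(t, abundance=float(mean_ab.get(t, np.nan)))
        g.add_edge(e["type_a"], e["type_b"], weight=e["weight_gr20"],
                   frac_significant_rois=e["frac_significant_rois"])
    return g, pd.DataFrame(edges, columns=["type_a", "type_b", "frac_significant_rois", "weight_gr20"])


def pcf_significance_all_pairs(
    cells: pd.DataFrame,
    pairs,
    width: float,
    height: float,
    n_perm: int = 1000,
    seed: int = 0,
    r_max: float = 20.0,
    dr: float = 1.0,
    alpha: float = 0.05,
    label_col: str = "population",
) -> pd.DataFrame:
    """gr20 + permutation significance for many pairs of one ROI, with BH
    across pairs; returns a tidy frame (one row per pair)."""
    rows = []
    for (a, b) in pairs:
        r = pcf_significance(cells, a, b, width, height, n_perm, seed, r_max, dr, alpha,
                             label_col=label_col)
        rows.append({
            "roi_id": r.roi_id, "type_a": a, "type_b": b, "gr20": r.gr20,
            "n_a": r.n_a, "n_b": r.n_b, "empty": r.empty,
            "p_value": r.p_value if r.p_value is not None else np.nan,
        })
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["direction"] = "ns"
    sig = (out["q_value"] < alpha).fillna(False)
    out.loc[sig & (out["gr20"] > 1), "direction"] = "enriched"
    out.loc[sig & (out["gr20"] < 1), "direction"] = "depleted"
    return out
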
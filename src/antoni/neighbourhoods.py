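"""Cellular neighbourhoods (CNs) by neighbourhood aggregation + GMM.

Cells of each ROI are joined by a Delaunay triangulation trimmed at a
maximum edge length (default 30 um); each cell's feature vector is its
own normalised marker profile concatenated with the mean profile of each
hop shell up to depth L.  Pooled features are clustered with Gaussian
mixture models; the number of clusters K is selected by running the GMM
R times (default 10) per K and picking the K with the highest
Fowlkes--Mallows (FMI) stability, ties to the smaller K.  Downstream
summaries: CN x cell-type enrichment, CN abundance per ROI/case, and a
CN x CN proximity z-score matrix (sender rows, receiver columns) from
label shuffles on the fixed spatial graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import pearsonr, shapiro, spearmanr
from sklearn.metrics import fowlkes_mallows_score
from sklearn.mixture import GaussianMixture

from ._rng import substream


# ---------------------------------------------------------------------------
# spatial graph


def build_spatial_graph(xy: np.ndarray, trim_um: float = 30.0) -> np.ndarray:
    """Delaunay edges of one ROI trimmed at ``trim_um``.

    Returns an (n_edges, 2) int array of undirected edges (i < j), with a
    pairwise-distance fallback for degenerate inputs (< 3 cells or
    collinear points).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 2:
        return np.empty((0, 2), dtype=int)

    def _fallback():
        tree = cKDTree(xy)
        pr = tree.query_pairs(trim_um, output_type="ndarray")
        return pr if len(pr) else np.empty((0, 2), dtype=int)

    if n < 4:
        return _fallback()
    try:
        tri = Delaunay(xy)
    except Exception:
        return _fallback()
    edges = set()
    for simplex in tri.simplices:
        for k in range(3):
            a, b = int(simplex[k]), int(simplex[(k + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges), dtype=int)
    d = np.hypot(*(xy[edges[:, 0]] - xy[edges[:, 1]]).T)
    return edges[d <= trim_um]


def aggregate_features(X: np.ndarray, edges: np.ndarray, L: int = 3):
    """Hop-shell aggregated features.

    Each cell's output is ``[own features, shell-1 mean, ..., shell-L
    mean]`` where shell s holds the cells at graph distance exactly s.
    Empty shells contribute zeros and are flagged.

    Returns ``(features, empty_shell_flags)`` with shapes
    (n, d * (L + 1)) and (n, L).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if L < 0:
        raise ValueError("L must be >= 0")
    out = [X]
    flags = np.zeros((n, L), dtype=bool)
    if L == 0:
        return X.copy(), flags
    if len(edges):
        A = sp.csr_matrix(
            (np.ones(2 * len(edges)), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                       np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(n, n), dtype=bool,
        )
    else:
        A = sp.csr_matrix((n, n), dtype=bool)
    reached = sp.identity(n, dtype=bool, format="csr")
    frontier = sp.identity(n, dtype=bool, format="csr")
    for s in range(1, L + 1):
        nxt = (frontier @ A).astype(bool)
        shell = nxt > reached  # in nxt and not yet reached
        shell = shell.tocsr()
        counts = np.asarray(shell.sum(axis=1)).ravel()
        means = shell.astype(float) @ X
        nonzero = counts > 0
        means[nonzero] /= counts[nonzero, None]
        means[~nonzero] = 0.0
        flags[:, s - 1] = ~nonzero
        out.append(means)
        reached = (reached + shell).astype(bool)
        frontier = shell
    return np.hstack(out), flags


# ---------------------------------------------------------------------------
# stability selection


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Fowlkes--Mallows index TP / sqrt((TP+FP)(TP+FN)) over item pairs."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    if len(labels_a) < 2:
        raise ValueError("need at least 2 items")
    return float(fowlkes_mallows_score(labels_a, labels_b))


@dataclass
class StabilityCurve:
    k_values: list
    stability: list
    repeats: int
    selected_k: int
    mode: str = "within"


def select_k(
    X: np.ndarray,
    k_range,
    repeats: int = 10,
    seed: int = 0,
    mode: str = "within",
    reg_covar: float = 1e-6,
):
    """FMI-stability selection of the GMM cluster number.

    For each K, ``repeats`` seeded full-covariance GMMs are fitted.
    ``mode="within"`` scores K by the mean pairwise FMI among its own
    repeats; ``mode="between"`` by the mean FMI between K's labelings and
    those of K-1 and K+1 (the CellCharter-style variant).  K* is the
    argmax, ties to the smallest K; the returned model is the best
    log-likelihood fit at K*.

    Returns ``(StabilityCurve, fitted_model, labels)``.
    """
    X = np.asarray(X, dtype=float)
    k_range = sorted(int(k) for k in k_range)
    if repeats < 2:
        raise ValueError("stability needs repeats >= 2")
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    if min(k_range) < 2 or max(k_range) > max(2, len(X) // 10):
        raise ValueError("k_range must lie within [2, n/10]")
    rng = substream(seed, "select_k")
    fit_seeds = rng.integers(0, 2**31 - 1, size=(len(k_range), repeats))
    models: dict = {}
    labelings: dict = {}
    for ki, K in enumerate(k_range):
        ms, ls = [], []
        for r in range(repeats):
            gm = GaussianMixture(
                n_components=K, covariance_type="full", reg_covar=reg_covar,
                random_state=int(fit_seeds[ki, r]), n_init=1,
            ).fit(X)
            ms.append(gm)
            ls.append(gm.predict(X))
        models[K], labelings[K] = ms, ls

    stability = []
    for K in k_range:
        ls = labelings[K]
        if mode == "within":
            vals = [
                fowlkes_mallows(ls[i], ls[j])
                for i in range(repeats)
                for j in range(i + 1, repeats)
            ]
        else:
            vals = []
            for other in (K - 1, K + 1):
                if other in labelings:
                    vals += [
                        fowlkes_mallows(a, b) for a in ls for b in labelings[other]
                    ]
            if not vals:  # isolated K: fall back to within-K pairs
                vals = [
                    fowlkes_mallows(ls[i], ls[j])
                    for i in range(repeats)
                    for j in range(i + 1, repeats)
                ]
        stability.append(float(np.mean(vals)))
    best = int(np.argmax(stability))  # argmax returns the first (smallest K) tie
    k_star = k_range[best]
    ll = [m.score(X) for m in models[k_star]]
    final = models[k_star][int(np.argmax(ll))]
    curve = StabilityCurve(list(k_range), stability, repeats, k_star, mode)
    return curve, final, final.predict(X)


# ---------------------------------------------------------------------------
# CN summaries


def cn_enrichment(cn_labels, population_labels) -> pd.DataFrame:
    """CN x cell-type enrichment: within-CN fraction / overall fraction."""
    cn_labels = pd.Series(np.asarray(cn_labels), name="cn")
    pops = pd.Series(np.asarray(population_labels), name="population")
    tab = pd.crosstab(cn_labels, pops)
    frac = tab.div(tab.sum(axis=1), axis=0)
    overall = tab.sum(axis=0) / tab.values.sum()
    return frac.div(overall, axis=1).fillna(0.0)


def cn_abundance(cells: pd.DataFrame, cn_col: str = "cn", level: str = "roi") -> pd.DataFrame:
    """Relative CN abundance per ROI or case (rows sum to 1)."""
    counts = cells.groupby(["case_id", "roi_id", cn_col], observed=True).size().unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    if level == "roi":
        return frac
    return frac.groupby(level="case_id", observed=True).mean()


def cn_proximity(
    cn_labels: np.ndarray,
    edges: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    roi_ids=None,
) -> pd.DataFrame:
    """CN x CN proximity enrichment on a fixed spatial graph.

    observed(i, j) = fraction of directed edges leaving CN-i cells that
    end in CN-j cells; the null shuffles CN labels over nodes (within
    each ROI when ``roi_ids`` is given, matching pooling of several ROIs'
    graphs); score = (observed - null mean) / null sd.  Rows are senders,
    columns receivers.  A single CN yields a 1x1 zero matrix.
    """
    cn_labels = np.asarray(cn_labels)
    cats = np.unique(cn_labels)
    k = len(cats)
    if k == 1:
        return pd.DataFrame([[0.0]], index=cats, columns=cats)
    if len(edges) == 0:
        return pd.DataFrame(np.zeros((k, k)), index=cats, columns=cats)
    code = {c: i for i, c in enumerate(cats)}
    lab = np.array([code[c] for c in cn_labels])
    I = np.concatenate([edges[:, 0], edges[:, 1]])
    J = np.concatenate([edges[:, 1], edges[:, 0]])

    def observed(lv):
        m = np.zeros((k, k))
        np.add.at(m, (lv[I], lv[J]), 1.0)
        rows = m.sum(axis=1, keepdims=True)
        return np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)

    obs = observed(lab)
    rng = substream(seed, "cn_proximity")
    roi_ids = np.asarray(roi_ids) if roi_ids is not None else np.zeros(len(lab), dtype=int)
    groups = [np.nonzero(roi_ids == r)[0] for r in np.unique(roi_ids)]
    null = np.empty((n_perm, k, k))
    for p in range(n_perm):
        lv = lab.copy()
        for g in groups:
            lv[g] = lab[g][rng.permutation(len(g))]
        null[p] = observed(lv)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z = np.divide(obs - mu, sd, out=np.zeros_like(obs), where=sd > 0)
    return pd.DataFrame(z, index=cats, columns=cats)


def correlate_with_covariate(values: pd.Series, covariate: pd.Series, alpha: float = 0.05):
    """Shapiro--Wilk-gated Pearson/Spearman correlation across cases.

    Both variables normal at ``alpha`` -> Pearson, otherwise Spearman.
    Also returns the least-squares line (slope, intercept).

    Returns a dict with r, p, method, shapiro p-values, slope, intercept
    and n.
    """
    common = values.index.intersection(covariate.index)
    x = values.loc[common].to_numpy(dtype=float)
    y = covariate.loc[common].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 cases with covariate values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance variable")
    sw_x, sw_y = shapiro(x).pvalue, shapiro(y).pvalue
    if sw_x > alpha and sw_y > alpha:
        r, p = pearsonr(x, y)
        method = "pearson"
    else:
        r, p = spearmanr(x, y)
        method = "spearman"
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "r": float(r), "p": float(p), "method": method,
        "shapiro_p_x": float(sw_x), "shapiro_p_y": float(sw_y),
        "slope": float(slope), "intercept": float(intercept), "n": int(len(x)),
    }


# ---------------------------------------------------------------------------
# driver


@dataclass
class CNModel:
    """A fitted cellular-neighbourhood model for one region class (or the
    combined data)."""

    region: str
    hop_depth: int
    stability: StabilityCurve
    labels: np.ndarray
    enrichment: pd.DataFrame
    abundance_roi: pd.DataFrame
    abundance_case: pd.DataFrame
    proximity: pd.DataFrame


def derive_neighbourhoods(
    cells: pd.DataFrame,
    markers,
    k_range=range(2, 9),
    hop_depth: int = 3,
    trim_um: float = 30.0,
    repeats: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    region: str = "combined",
    norm_suffix: str = "_norm",
    stability_mode: str = "within",
) -> CNModel:
    """End-to-end CN derivation on the given cells (one region class or
    the combined table -- the caller decides, and the result records which)."""
    norm_cols = [m + norm_suffix for m in markers]
    feats, all_edges, offsets, roi_of_cell = [], [], 0, []
    for roi, grp in cells.groupby("roi_id", observed=True, sort=True):
        xy = grp[["x_um", "y_um"]].to_numpy()
        edges = build_spatial_graph(xy, trim_um)
        f, _ = aggregate_features(grp[norm_cols].to_numpy(), edges, hop_depth)
        feats.append(f)
        if len(edges):
            all_edges.append(edges + offsets)
        roi_of_cell += [roi] * len(grp)
        offsets += len(grp)
    order = cells.sort_values("roi_id", kind="stable").index  # groupby(sort=True) order
    X = np.vstack(feats)
    edges = np.vstack(all_edges) if all_edges else np.empty((0, 2), dtype=int)
    curve, model, labels = select_k(X, k_range, repeats, seed=seed, mode=stability_mode)
    sorted_cells = cells.loc[order].copy()
    sorted_cells["cn"] = [f"CN{l + 1}" for l in labels]
    enr = cn_enrichment(sorted_cells["cn"], sorted_cells["population"])
    prox = cn_proximity(sorted_cells["cn"].to_numpy(), edges, n_perm=n_perm, seed=seed,
                        roi_ids=np.asarray(roi_of_cell))
    out_labels = sorted_cells["cn"].reindex(cells.index)
    return CNModel(
        region=region,
        hop_depth=hop_depth,
        stability=curve,
        labels=out_labels.to_numpy(),
        enrichment=enr,
        abundance_roi=cn_abundance(sorted_cells, level="roi"),
        abundance_case=cn_abundance(sorted_cells, level="case"),
        proximity=prox,
    )
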
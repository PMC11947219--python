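"""Marker normalisation and cell phenotyping.

The phenotyping scheme mirrors common multiplexed-imaging practice:
per-marker 99.9th-percentile normalisation, a batch-balanced kNN graph
across cases, Leiden community detection, assignment of coarse clusters
to four parent groups by canonical markers, per-group reclustering at a
finer resolution, and rule-based annotation of the resulting
sub-populations.  Marker rules live in YAML config, not code, because
fine population labels are an expert-annotation product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._rng import substream


# ---------------------------------------------------------------------------
# normalisation


def percentile_divisors(cells: pd.DataFrame, markers, q: float = 99.9) -> dict:
    """Per-marker q-th percentile across all cells (linear interpolation)."""
    if not 50 < q <= 100:
        raise ValueError("q must be in (50, 100]")
    out = {}
    for m in markers:
        out[m] = float(np.percentile(cells[m].to_numpy(dtype=float), q, method="linear"))
    return out


def normalize_percentile(
    cells: pd.DataFrame,
    markers,
    q: float = 99.9,
    divisors: dict | None = None,
    suffix: str = "_norm",
):
    """Scale each marker by its q-th percentile and clip to [0, 1].

    Already-computed ``divisors`` may be passed for reuse (e.g. to apply a
    fitted normalisation to new data); this also makes the operation
    idempotent on normalised columns.  An all-zero marker has an undefined
    divisor: its normalised values are set to 0 and it is flagged.

    Returns ``(cells_with_norm_columns, divisors, flagged_markers)``.
    """
    markers = list(markers)
    if divisors is None:
        divisors = percentile_divisors(cells, markers, q)
    out = cells.copy()
    flagged = []
    for m in markers:
        d = divisors[m]
        if d <= 0:
            out[m + suffix] = 0.0
            flagged.append(m)
        else:
            out[m + suffix] = np.clip(cells[m].to_numpy(dtype=float) / d, 0.0, 1.0)
    return out, divisors, flagged


# ---------------------------------------------------------------------------
# batch-balanced kNN graph


def build_bbknn_graph(
    X: np.ndarray, batches, k_per_batch: int = 3, symmetrize: bool = True
) -> sp.csr_matrix:
    """Batch-balanced kNN graph: per-cell k nearest neighbours *within each
    batch*, unioned over batches.

    Edge weights decay with Euclidean distance as 1 / (1 + d).  A batch
    holding fewer than ``k_per_batch`` other cells contributes all of
    them.  Returns a symmetric CSR adjacency (max of the two directions)
    by default; ``symmetrize=False`` keeps the directed union, in which
    every cell has at most ``k_per_batch * n_batches`` out-neighbours.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k_per_batch < 1:
        raise ValueError("k_per_batch must be >= 1")
    batches = np.asarray(batches)
    rows, cols, vals = [], [], []
    for b in np.unique(batches):
        idx = np.nonzero(batches == b)[0]
        k = min(k_per_batch + 1, len(idx))  # +1 slot absorbs self-hits
        nn = NearestNeighbors(n_neighbors=k).fit(X[idx])
        dist, nbr = nn.kneighbors(X)
        j = idx[nbr]  # (n, k) global neighbour ids, sorted by distance
        nonself = j != np.arange(n)[:, None]
        keep = nonself & (np.cumsum(nonself, axis=1) <= k_per_batch)
        r = np.broadcast_to(np.arange(n)[:, None], j.shape)[keep]
        rows.append(r)
        cols.append(j[keep])
        vals.append(1.0 / (1.0 + dist[keep]))
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    A.sum_duplicates()
    if symmetrize:
        A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def _graph_from_adjacency(A: sp.csr_matrix):
    import igraph as ig

    coo = sp.triu(A, k=1).tocoo()
    g = ig.Graph(
        n=A.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    g.es["weight"] = coo.data.tolist()
    return g


def cluster_cells(A: sp.csr_matrix, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a weighted adjacency.

    RBConfiguration (modularity with a resolution parameter) objective;
    deterministic for a given seed.
    """
    import leidenalg

    if A.shape[0] == 0:
        raise ValueError("empty graph")
    g = _graph_from_adjacency(A)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed) & 0x7FFFFFFF,
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# hierarchical reclustering and annotation


@dataclass
class PopulationRule:
    """Annotation rule: mean normalised marker thresholds for one population."""

    name: str
    parent_group: str
    positive: dict = field(default_factory=dict)  # marker -> min mean
    negative: dict = field(default_factory=dict)  # marker -> max mean

    def matches(self, profile: pd.Series) -> bool:
        ok = all(profile.get(m, 0.0) >= t for m, t in self.positive.items())
        ok &= all(profile.get(m, 0.0) <= t for m, t in self.negative.items())
        return ok


def rules_from_config(cfg: list) -> list:
    """Build :class:`PopulationRule` objects from YAML-style dicts."""
    return [
        PopulationRule(
            name=r["name"],
            parent_group=r["parent_group"],
            positive=dict(r.get("positive", {})),
            negative=dict(r.get("negative", {})),
        )
        for r in cfg
    ]


def assign_parent_groups(
    cells: pd.DataFrame,
    coarse_labels: np.ndarray,
    group_markers: dict,
    norm_suffix: str = "_norm",
    min_score: float = 0.1,
) -> pd.Series:
    """Map each coarse cluster to a parent group by canonical-marker means.

    ``group_markers`` maps group name -> list of canonical markers.  A
    cluster goes to the group with the highest mean canonical score, or to
    ``"Other"`` when every score is below ``min_score``.
    """
    out = pd.Series(index=cells.index, dtype=object)
    for lab in np.unique(coarse_labels):
        sel = coarse_labels == lab
        scores = {
            g: float(np.mean([cells.loc[sel, m + norm_suffix].mean() for m in ms]))
            for g, ms in group_markers.items()
        }
        best = max(scores, key=lambda g: scores[g])
        out[sel] = best if scores[best] >= min_score else "Other"
    return out


def recluster_hierarchical(
    cells: pd.DataFrame,
    markers,
    coarse_labels: np.ndarray,
    group_markers: dict,
    population_rules: list,
    fine_resolution: float = 1.5,
    k_per_batch: int = 3,
    batch_key: str = "case_id",
    norm_suffix: str = "_norm",
    seed: int = 0,
):
    """Two-level phenotyping: parent groups, per-group fine Leiden,
    rule-based sub-population annotation.

    Cells matching no rule within their group are labelled ``"Other"``.
    Returns ``(population, parent_group)`` Series aligned to ``cells``.
    """
    norm_cols = [m + norm_suffix for m in markers]
    groups = assign_parent_groups(cells, coarse_labels, group_markers, norm_suffix)
    population = pd.Series("Other", index=cells.index, dtype=object)
    rules = list(population_rules)
    for gname in groups.unique():
        sel = np.nonzero((groups == gname).to_numpy())[0]
        if gname == "Other" or len(sel) == 0:
            continue
        sub = cells.iloc[sel]
        if len(sel) <= k_per_batch + 1:
            fine = np.zeros(len(sel), dtype=int)  # too few cells: one population
        else:
            A = build_bbknn_graph(
                sub[norm_cols].to_numpy(), sub[batch_key].to_numpy(), k_per_batch
            )
            fine = cluster_cells(A, fine_resolution, seed=substream(seed, "fine", gname).integers(2**31))
        grules = [r for r in rules if r.parent_group == gname]
        for fl in np.unique(fine):
            fsel = sel[fine == fl]
            profile = cells.iloc[fsel][norm_cols].mean()
            profile.index = [c[: -len(norm_suffix)] for c in profile.index]
            name = "Other"
            for r in grules:
                if r.matches(profile):
                    name = r.name
                    break
            population.iloc[fsel] = name
    return population, groups


# ---------------------------------------------------------------------------
# abundance


def abundance_table(
    cells: pd.DataFrame,
    level: str = "roi",
    label_col: str = "population",
    exclude_regions=("Mixed",),
) -> pd.DataFrame:
    """Relative abundance of populations per ROI or per case.

    ROIs whose region annotation is in ``exclude_regions`` are dropped
    first.  ``level="case"`` averages each case's ROI rows (case-averaged
    abundance), so each row still sums to 1.
    """
    if level not in ("roi", "case"):
        raise ValueError("level must be 'roi' or 'case'")
    df = cells[~cells["region"].isin(set(exclude_regions))]
    if df.empty:
        return pd.DataFrame()
    counts = df.groupby(["case_id", "roi_id", label_col], observed=True).size().unstack(fill_value=0)
    rows = counts.sum(axis=1)
    frac = counts.div(rows, axis=0)
    frac = frac[rows > 0]
    if level == "roi":
        return frac
    return frac.groupby(level="case_id", observed=True).mean()
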
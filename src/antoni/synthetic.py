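"""Synthetic multiplexed-imaging tissue generator.

Generates multi-ROI single-cell datasets with the spatial and statistical
structure of schwannoma tissue as seen by imaging mass cytometry (IMC):
1000x1000 um regions of interest at 1 um^2 per pixel, cell populations in
four parent groups (Schwann, myeloid, lymphoid, vascular), hypercellular
"Antoni A"-like ROIs with Thomas-clustered Schwann cells, perivascular
niches and TAM--T cell aggregates, and hypocellular "Antoni B"-like ROIs
with interspersed T cell / PD-L1+ Schwann mixing.  Also produces rendered
channel stacks with matched nuclear label masks, perturbed masks for
segmentation QC, and negative-binomial expression counts with planted
ligand--receptor pairs.

Placement models
----------------
``csr``
    Homogeneous Poisson process: N ~ Poisson(density * area), uniform
    positions.
``thomas``
    Thomas cluster process: Poisson parents, Gaussian-displaced offspring.
``perivascular``
    Uniform along a vessel polyline with a uniform radial offset within
    the vessel's halo.
Co-clustered pairs share Thomas parents (type-specific offspring), which
guarantees a positive cross-pair correlation at short range.

All randomness flows from ``TissueSpec.seed`` via named substreams
(placement / intensity / counts / mask), so identical specs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

PARENT_GROUPS = ("Schwann", "Myeloid", "Lymphoid", "Vascular", "Other")
REGION_CLASSES = ("AntoniA", "AntoniB", "Mixed")

#: Marker panel used by the default populations (a compact subset of a
#: 40-channel IMC panel covering the four parent groups).
DEFAULT_MARKERS = (
    "S100B", "SOX10", "PDL1",
    "Iba1", "HLADR", "CD68", "CD163",
    "CD3", "CD4", "CD8a", "CD45RA", "CD20",
    "CD31", "SMA",
    "Ki67", "CD44",
)

_MAX_CELLS_PER_ROI = 200_000
_BACKGROUND_SCALE = 0.02  # exponential background added to every marker


@dataclass(frozen=True)
class VesselSpec:
    """A vessel as a polyline with a perivascular halo.

    polyline : (n, 2) array of control points in um, inside the ROI.
    halo_radius_um : radius within which perivascular populations sit.
    """

    polyline: np.ndarray
    halo_radius_um: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "polyline", np.asarray(self.polyline, dtype=float))
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2 or len(self.polyline) < 2:
            raise ValueError("polyline must be an (n>=2, 2) array of points")
        if self.halo_radius_um <= 0:
            raise ValueError("halo_radius_um must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population: density, marker profile and placement model."""

    name: str
    parent_group: str
    density: float  # cells / mm^2
    marker_profile: dict = field(default_factory=dict)
    dispersion: float = 0.15  # sd of log-normal intensity noise
    placement: str = "csr"  # csr | thomas | perivascular
    thomas_parents_per_mm2: float = 10.0
    thomas_sd_um: float = 25.0

    def __post_init__(self):
        if self.density < 0:
            raise ValueError(f"density must be >= 0 (population {self.name!r})")
        if any(v < 0 for v in self.marker_profile.values()):
            raise ValueError(f"marker_profile must be non-negative ({self.name!r})")
        if self.parent_group not in PARENT_GROUPS:
            raise ValueError(f"unknown parent_group {self.parent_group!r}")
        if self.placement not in ("csr", "thomas", "perivascular"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class CoClusterSpec:
    """A planted co-clustered pair: both types share Thomas parents.

    ``strength`` scales the tightness of the shared clusters; the offspring
    displacement sd is ``base_sd_um / sqrt(strength)`` so the short-range
    cross-pair correlation increases monotonically with strength.
    """

    type_a: str
    type_b: str
    strength: float = 1.0
    parents_per_mm2: float = 10.0
    base_sd_um: float = 25.0

    @property
    def sd_um(self) -> float:
        return self.base_sd_um / np.sqrt(self.strength)


@dataclass(frozen=True)
class TissueSpec:
    """Full specification of one synthetic ROI."""

    populations: tuple
    roi_width_um: float = 1000.0
    roi_height_um: float = 1000.0
    region_class: str = "AntoniA"
    vessels: tuple = ()
    planted_pairs: tuple = ()
    batch_factors: dict = field(default_factory=dict)  # marker -> multiplicative case effect
    roi_id: str = "ROI1"
    case_id: str = "case1"
    seed: int = 0

    def __post_init__(self):
        if self.roi_width_um <= 0 or self.roi_height_um <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "vessels", tuple(self.vessels))
        object.__setattr__(self, "planted_pairs", tuple(self.planted_pairs))

    @property
    def area_mm2(self) -> float:
        return self.roi_width_um * self.roi_height_um / 1e6

    def markers(self) -> list:
        seen: dict = {}
        for p in self.populations:
            for m in p.marker_profile:
                seen.setdefault(m, None)
        return list(seen)


# ---------------------------------------------------------------------------
# point placement


def _csr_points(rng, n, w, h):
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _thomas_points(rng, density, parents_per_mm2, sd_um, w, h, parents=None):
    """Thomas process offspring inside the window; outside offspring are
    redrawn around their parent (bounded retries)."""
    area = w * h / 1e6
    if parents is None:
        n_par = rng.poisson(parents_per_mm2 * area)
        parents = _csr_points(rng, n_par, w, h)
    if len(parents) == 0:
        return np.empty((0, 2)), parents
    mu = density * area / len(parents)
    counts = rng.poisson(mu, len(parents))
    pts = []
    for p, c in zip(parents, counts):
        if c == 0:
            continue
        got = np.empty((0, 2))
        for _ in range(200):
            need = c - len(got)
            if need <= 0:
                break
            cand = p + rng.normal(0, sd_um, (need, 2))
            ok = (
                (cand[:, 0] >= 0) & (cand[:, 0] < w)
                & (cand[:, 1] >= 0) & (cand[:, 1] < h)
            )
            got = np.vstack([got, cand[ok]])
        else:
            raise RuntimeError(
                "rejection sampling failed: offspring cannot be placed inside the window"
            )
        pts.append(got[:c])
    return (np.vstack(pts) if pts else np.empty((0, 2))), parents


def _polyline_arclengths(polyline):
    seg = np.diff(polyline, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    return lengths, np.concatenate([[0.0], np.cumsum(lengths)])


def _perivascular_points(rng, n, vessels, w, h):
    if not vessels:
        raise ValueError("perivascular population requires at least one vessel")
    # choose vessels proportional to their arc length
    lengths = []
    for v in vessels:
        seg, _ = _polyline_arclengths(v.polyline)
        lengths.append(seg.sum())
    lengths = np.asarray(lengths)
    probs = lengths / lengths.sum()
    pts = np.empty((0, 2))
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 1000:
            raise RuntimeError("rejection sampling failed for perivascular placement")
        need = n - len(pts)
        vi = rng.choice(len(vessels), size=need, p=probs)
        cand = np.empty((need, 2))
        for k, i in enumerate(vi):
            v = vessels[i]
            seg, cum = _polyline_arclengths(v.polyline)
            s = rng.uniform(0, cum[-1])
            j = np.searchsorted(cum[1:], s, side="right")
            t = (s - cum[j]) / seg[j] if seg[j] > 0 else 0.0
            base = v.polyline[j] + t * (v.polyline[j + 1] - v.polyline[j])
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, v.halo_radius_um)
            cand[k] = base + rad * np.array([np.cos(ang), np.sin(ang)])
        ok = (cand[:, 0] >= 0) & (cand[:, 0] < w) & (cand[:, 1] >= 0) & (cand[:, 1] < h)
        pts = np.vstack([pts, cand[ok]])
    return pts[:n]


# ---------------------------------------------------------------------------
# ROI generation


def generate_roi(spec: TissueSpec) -> pd.DataFrame:
    """Generate the cell table of one ROI from a :class:`TissueSpec`.

    Returns a DataFrame with one row per cell: ``cell_id``, ``roi_id``,
    ``case_id``, ``region``, ``population``, ``parent_group``, ``x_um``,
    ``y_um`` and one raw-intensity column per marker.  Fully determined by
    ``spec.seed``.
    """
    w, h = spec.roi_width_um, spec.roi_height_um
    markers = spec.markers() or list(DEFAULT_MARKERS)
    pop_by_name = {p.name: p for p in spec.populations}
    expected = sum(p.density for p in spec.populations) * spec.area_mm2
    if expected > _MAX_CELLS_PER_ROI:
        raise ValueError(
            f"expected cell count {expected:.0f} exceeds the {_MAX_CELLS_PER_ROI} "
            "per-ROI limit; reduce densities"
        )

    cocluster_names = set()
    placed: list = []  # (population, points)
    for k, pair in enumerate(spec.planted_pairs):
        for t in (pair.type_a, pair.type_b):
            if t not in pop_by_name:
                raise ValueError(f"planted pair references unknown population {t!r}")
        cocluster_names.update([pair.type_a, pair.type_b])
        rng = substream(spec.seed, "placement", spec.roi_id, "pair", k)
        n_par = rng.poisson(pair.parents_per_mm2 * spec.area_mm2)
        parents = _csr_points(rng, n_par, w, h)
        for t in (pair.type_a, pair.type_b):
            pop = pop_by_name[t]
            pts, _ = _thomas_points(
                rng, pop.density, pair.parents_per_mm2, pair.sd_um, w, h, parents=parents
            )
            placed.append((pop, pts))

    for pop in spec.populations:
        if pop.name in cocluster_names:
            continue
        rng = substream(spec.seed, "placement", spec.roi_id, pop.name)
        if pop.placement == "csr":
            n = rng.poisson(pop.density * spec.area_mm2)
            pts = _csr_points(rng, n, w, h)
        elif pop.placement == "thomas":
            pts, _ = _thomas_points(
                rng, pop.density, pop.thomas_parents_per_mm2, pop.thomas_sd_um, w, h
            )
        else:  # perivascular
            n = rng.poisson(pop.density * spec.area_mm2)
            pts = _perivascular_points(rng, n, spec.vessels, w, h)
        placed.append((pop, pts))

    rows_pop, rows_group, xy = [], [], []
    for pop, pts in placed:
        rows_pop += [pop.name] * len(pts)
        rows_group += [pop.parent_group] * len(pts)
        xy.append(pts)
    xy = np.vstack(xy) if xy else np.empty((0, 2))
    n_cells = len(xy)

    irng = substream(spec.seed, "intensity", spec.roi_id)
    intens = np.zeros((n_cells, len(markers)))
    for j, m in enumerate(markers):
        base = np.array([pop_by_name[p].marker_profile.get(m, 0.0) for p in rows_pop])
        disp = np.array([pop_by_name[p].dispersion for p in rows_pop])
        noise = np.exp(irng.normal(0.0, 1.0, n_cells) * disp)
        bg = irng.exponential(_BACKGROUND_SCALE, n_cells)
        intens[:, j] = (base * noise + bg) * spec.batch_factors.get(m, 1.0)

    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "roi_id": spec.roi_id,
            "case_id": spec.case_id,
            "region": spec.region_class,
            "population": pd.Series(rows_pop, dtype=object),
            "parent_group": pd.Series(rows_group, dtype=object),
            "x_um": xy[:, 0] if n_cells else pd.Series(dtype=float),
            "y_um": xy[:, 1] if n_cells else pd.Series(dtype=float),
        }
    )
    for j, m in enumerate(markers):
        df[m] = intens[:, j] if n_cells else pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# image rendering


def generate_channel_stack(
    cells: pd.DataFrame,
    markers,
    width_px: int,
    height_px: int,
    nucleus_radius_px: float = 2.0,
    signal_radius_px: float | None = None,
):
    """Render a cell table into a per-marker image stack and a nuclear mask.

    Each cell paints its marker values uniformly over a disc of radius
    ``signal_radius_px`` (default ``nucleus_radius_px + 1.5``, which covers
    the 8-connected one-pixel expansion of the nucleus disc); overlapping
    signal discs are summed.  The mask contains the nucleus disc of each
    cell labelled by ``cell_id``; pixels claimed by several nuclei go to
    the nearest cell centre (ties to the lower label).

    Returns ``(stack, mask)`` with ``stack`` of shape (n_markers, H, W)
    float32 and ``mask`` uint16.
    """
    markers = list(markers)
    if signal_radius_px is None:
        signal_radius_px = nucleus_radius_px + 1.5
    H, W = int(height_px), int(width_px)
    stack = np.zeros((len(markers), H, W), dtype=np.float32)
    mask = np.zeros((H, W), dtype=np.uint16)
    if len(cells) == 0:
        return stack, mask
    if (cells["x_um"].min() < 0 or cells["y_um"].min() < 0
            or cells["x_um"].max() >= W or cells["y_um"].max() >= H):
        raise ValueError("cell coordinates fall outside the image bounds")
    if cells["cell_id"].max() > np.iinfo(np.uint16).max:
        raise ValueError("cell_id exceeds uint16 label range")

    best = np.full((H, W), np.inf)
    vals = cells[markers].to_numpy(dtype=np.float32)
    r_out = float(signal_radius_px)
    for idx, row in enumerate(cells.itertuples(index=False)):
        cx, cy, lab = row.x_um, row.y_um, int(row.cell_id)
        j0, j1 = max(0, int(cx - r_out - 1)), min(W, int(cx + r_out + 2))
        i0, i1 = max(0, int(cy - r_out - 1)), min(H, int(cy + r_out + 2))
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        d2 = (jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2
        sig = d2 <= r_out**2
        for c in range(len(markers)):
            stack[c, i0:i1, j0:j1][sig] += vals[idx, c]
        nuc = d2 <= nucleus_radius_px**2
        sub_best = best[i0:i1, j0:j1]
        sub_mask = mask[i0:i1, j0:j1]
        take = nuc & (
            (d2 < sub_best)
            | (np.isclose(d2, sub_best) & (sub_mask == 0))
        )
        sub_best[take] = d2[take]
        sub_mask[take] = lab
    return stack, mask


def generate_mask_pair(mask: np.ndarray, perturbation: int, seed: int = 0, ops=("shift", "erode", "dilate")):
    """Return a perturbed copy of a label mask plus a per-object report.

    Each object is independently shifted, eroded or dilated by up to
    ``perturbation`` pixels (labels preserved); objects erased by erosion
    are flagged in the report.  ``perturbation = 0`` returns an identical
    mask.
    """
    from scipy import ndimage

    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask)
    report = {"ops": {}, "vanished": []}
    if perturbation == 0:
        return mask.copy(), report
    rng = substream(seed, "mask_perturb")
    struct = np.ones((3, 3), bool)
    for lab in labels:
        obj = mask == lab
        op = str(rng.choice(list(ops)))
        k = int(rng.integers(1, perturbation + 1))
        if op == "shift":
            dx = int(rng.integers(-perturbation, perturbation + 1))
            dy = int(rng.integers(-perturbation, perturbation + 1))
            new = np.roll(np.roll(obj, dy, axis=0), dx, axis=1)
            report["ops"][int(lab)] = ("shift", dx, dy)
        elif op == "erode":
            new = ndimage.binary_erosion(obj, struct, iterations=k)
            report["ops"][int(lab)] = ("erode", k)
        else:
            new = ndimage.binary_dilation(obj, struct, iterations=k)
            report["ops"][int(lab)] = ("dilate", k)
        if not new.any():
            report["vanished"].append(int(lab))
            continue
        out[new] = lab
    return out, report


# ---------------------------------------------------------------------------
# expression counts


@dataclass(frozen=True)
class PlantedPair:
    """A ligand--receptor pair planted into the synthetic transcriptomes."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    fold: float = 8.0

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")


def generate_expression_counts(
    populations,
    lr_pairs,
    n_cells_per_pop: int,
    n_background_genes: int = 20,
    nb_dispersion: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix with planted ligand--receptor pairs.

    Baseline gene means are shared across populations (exchangeable null);
    each planted pair's ligand mean is multiplied by ``fold`` in its sender
    population and the receptor mean by ``fold`` in its receiver.

    Returns a DataFrame with a ``population`` column followed by one count
    column per gene.
    """
    populations = list(populations)
    pairs = list(lr_pairs)
    for pr in pairs:
        if pr.sender not in populations or pr.receiver not in populations:
            raise ValueError(f"planted pair references unknown population: {pr}")
    genes: list = []
    for pr in pairs:
        for g in (pr.ligand, pr.receptor):
            if g not in genes:
                genes.append(g)
    genes += [f"BG{i:03d}" for i in range(n_background_genes)]

    if n_cells_per_pop < 0:
        raise ValueError("n_cells_per_pop must be >= 0")
    rng = substream(seed, "counts")
    base_mean = np.exp(rng.uniform(np.log(0.5), np.log(5.0), len(genes)))
    rows, labels = [], []
    theta = nb_dispersion
    for pop in populations:
        mu = base_mean.copy()
        for pr in pairs:
            if pop == pr.sender:
                mu[genes.index(pr.ligand)] *= pr.fold
            if pop == pr.receiver:
                mu[genes.index(pr.receptor)] *= pr.fold
        p = theta / (theta + mu)
        counts = rng.negative_binomial(theta, p[None, :].repeat(n_cells_per_pop, 0))
        rows.append(counts)
        labels += [pop] * n_cells_per_pop
    mat = np.vstack(rows) if rows else np.empty((0, len(genes)), dtype=int)
    df = pd.DataFrame(mat, columns=genes)
    df.insert(0, "population", pd.Series(labels, dtype=object))
    return df


def lognormalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalise to the median depth and log1p-transform.

    Accepts the frame returned by :func:`generate_expression_counts`
    (``population`` column preserved untouched).
    """
    out = counts.copy()
    gene_cols = [c for c in counts.columns if c != "population"]
    mat = counts[gene_cols].to_numpy(dtype=float)
    depth = mat.sum(axis=1)
    target = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.divide(target, depth, out=np.zeros_like(depth), where=depth > 0)
    out[gene_cols] = np.log1p(mat * scale[:, None])
    return out


# ---------------------------------------------------------------------------
# default study conditions


def default_vessels(seed: int = 0, n: int = 3, width: float = 1000.0, height: float = 1000.0):
    """Random gently-curved vessel polylines spanning the ROI."""
    rng = substream(seed, "vessels")
    vessels = []
    for _ in range(n):
        x = np.linspace(50, width - 50, 6)
        y0 = rng.uniform(0.15 * height, 0.85 * height)
        y = y0 + np.cumsum(rng.normal(0, 60, 6))
        y = np.clip(y, 10, height - 10)
        pts = np.column_stack([x, y])
        if rng.random() < 0.5:
            pts = pts[:, ::-1]
        vessels.append(VesselSpec(pts, halo_radius_um=30.0))
    return vessels


def default_populations(region_class: str = "AntoniA"):
    """Population panel emulating the four parent groups of schwannoma.

    Antoni A: dense, organised -- Thomas-clustered Schwann cells,
    TAM--T cell aggregates (planted co-clusters) and perivascular mural
    cells.  Antoni B: sparse -- mostly CSR with PD-L1+ Schwann cells
    co-mixing with T cells.  Returns ``(populations, planted_pairs)``.
    """
    dense = region_class == "AntoniA"
    s = 1.0 if dense else 0.35
    P = PopulationSpec
    pops = [
        P("Schwann_core", "Schwann", (1400 if dense else 300),
          {"S100B": 4.0, "SOX10": 3.0, "CD44": 0.8},
          placement="thomas", thomas_parents_per_mm2=25, thomas_sd_um=60),
        P("Schwann_PDL1", "Schwann", 150 * s,
          {"S100B": 3.5, "SOX10": 2.5, "PDL1": 2.5, "CD44": 1.0},
          placement="csr"),
        P("TAM_classical", "Myeloid", 350 * s,
          {"Iba1": 3.0, "HLADR": 2.5, "CD68": 2.5}),
        P("TAM_alternative", "Myeloid", 250 * s,
          {"Iba1": 3.0, "CD163": 3.0, "CD44": 1.2}),
        P("T_CD4", "Lymphoid", 120 * s, {"CD3": 3.0, "CD4": 2.5}),
        P("T_CD8", "Lymphoid", 120 * s, {"CD3": 3.0, "CD8a": 2.5}),
        P("T_TEMRA", "Lymphoid", 60 * s, {"CD3": 3.0, "CD8a": 2.5, "CD45RA": 2.5}),
        P("B_cell", "Lymphoid", 40 * s, {"CD20": 3.0}),
        P("Endothelial", "Vascular", 120 * s, {"CD31": 3.0}, placement="perivascular"),
        P("Pericyte", "Vascular", 100 * s, {"SMA": 3.5}, placement="perivascular"),
        P("Proliferating", "Other", 50 * s, {"Ki67": 3.0}),
    ]
    if dense:
        # TAM-rich aggregates sequester T cells away from Schwann-cell areas
        pairs = (
            CoClusterSpec("TAM_classical", "T_CD8", strength=2.0, parents_per_mm2=12),
            CoClusterSpec("TAM_alternative", "T_CD4", strength=2.0, parents_per_mm2=12),
        )
    else:
        # loose mixing of T cells with PD-L1+ Schwann cells
        pairs = (CoClusterSpec("Schwann_PDL1", "T_CD8", strength=1.2, parents_per_mm2=8),)
    return pops, pairs


def batch_factors_for_case(case_id: str, markers, seed: int, log_sd: float = 0.15) -> dict:
    """Multiplicative log-normal per-(case, marker) intensity shifts."""
    rng = substream(seed, "batch", case_id)
    return {m: float(np.exp(rng.normal(0.0, log_sd))) for m in markers}


def simulate_study(
    n_cases: int = 6,
    rois_per_case: int = 3,
    seed: int = 0,
    region_cycle=("AntoniA", "AntoniA", "AntoniB"),
    batch_log_sd: float = 0.15,
):
    """Generate a multi-case, multi-ROI study.

    Returns ``(cells, clinical)``: the concatenated cell table and a
    per-case clinical frame (severity in mild/moderate/severe, treatment in
    naive/bevacizumab, a log-normal volumetric growth rate in %/year).
    """
    crng = substream(seed, "clinical")
    frames = []
    clin = []
    severities = ["mild", "moderate", "severe"]
    for ci in range(n_cases):
        case = f"case{ci + 1:02d}"
        bf = batch_factors_for_case(case, DEFAULT_MARKERS, seed, batch_log_sd)
        severity = severities[ci % 3]
        treatment = "bevacizumab" if ci >= n_cases - max(1, n_cases // 4) else "naive"
        growth = float(np.exp(crng.normal(np.log(30.0), 0.5)))
        clin.append(
            {"case_id": case, "severity": severity, "treatment": treatment,
             "growth_rate": round(growth, 2)}
        )
        for ri in range(rois_per_case):
            region = region_cycle[ri % len(region_cycle)]
            pops, pairs = default_populations(region)
            roi = f"{case}_roi{ri + 1}"
            spec = TissueSpec(
                populations=pops,
                region_class=region,
                vessels=tuple(default_vessels(seed=seed * 1000 + ci * 10 + ri)),
                planted_pairs=pairs,
                batch_factors=bf,
                roi_id=roi,
                case_id=case,
                seed=(seed * 100_003 + ci * 101 + ri) % (2**31 - 1),
            )
            frames.append(generate_roi(spec))
    cells = pd.concat(frames, ignore_index=True)
    return cells, pd.DataFrame(clin)
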
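"""Pipeline orchestration: config, stages, manifests.

Each stage reads the previous stage's CSV artefacts from ``outdir``,
writes its own versioned outputs plus a ``manifest_<stage>.json``
recording parameters, seed and SHA-256 checksums of everything written.
Stage order: simulate -> quantify -> phenotype -> spatial ->
neighbourhoods -> lr -> stats -> report.  Region handling: mixed-region
ROIs are excluded from A-vs-B contrasts; cellular neighbourhoods are
derived per region class by default (``combined`` optionally), never
mixed silently -- every CN output is tagged with the region it came from.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import (
    group_stats,
    ligand_receptor as lr_mod,
    neighbourhoods as nb_mod,
    phenotype as ph_mod,
    quantify as qt_mod,
    spatial as sp_mod,
    synthetic as syn_mod,
)
log = logging.getLogger("antoni.pipeline")

STAGES = ("simulate", "quantify", "phenotype", "spatial", "neighbourhoods", "lr", "stats", "report")


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cases: int = 6
    rois_per_case: int = 3
    n_image_rois: int = 1
    batch_log_sd: float = 0.15
    n_cells_per_pop: int = 200
    n_background_genes: int = 20
    planted_lr: list = [
        {"ligand": "LIGA", "receptor": "RECA", "sender": "T_CD8",
         "receiver": "TAM_classical", "fold": 8.0},
    ]


class PhenotypeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    percentile: float = 99.9
    k_per_batch: int = 3
    coarse_resolution: float = 1.0
    fine_resolution: float = 1.5
    rules_file: Optional[str] = None  # default: bundled population_rules.yaml


class SpatialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_max: float = 20.0
    dr: float = 1.0
    contact_radius: float = 10.0
    n_perm: int = 199
    alpha: float = 0.05
    min_cells: int = 20
    max_pairs: int = 40
    consensus_frac: float = 0.5


class NeighbourhoodConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_min: int = 2
    k_max: int = 8
    hop_depth: int = 3
    trim_um: float = 30.0
    repeats: int = 10
    n_perm: int = 100
    stability_mode: Literal["within", "between"] = "within"


class LRConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 1000
    min_frac: float = 0.05
    top_n: int = 20
    alpha: float = 0.05
    frac_mode: Literal["and", "or"] = "and"


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    match_counts: Optional[dict] = None  # {n_total, n_aligned, n_matched}


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    region: Literal["A", "B", "combined"] = "combined"
    simulate: SimulateConfig = SimulateConfig()
    phenotype: PhenotypeConfig = PhenotypeConfig()
    spatial: SpatialConfig = SpatialConfig()
    neighbourhoods: NeighbourhoodConfig = NeighbourhoodConfig()
    lr: LRConfig = LRConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


# ---------------------------------------------------------------------------
# helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, files: list):
    manifest = {
        "stage": stage,
        "parameters": params,
        "outputs": {str(f.relative_to(outdir)): _sha256(f) for f in files},
    }
    p = outdir / f"manifest_{stage}.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return p


def _require(outdir: Path, fname: str, producer: str) -> Path:
    p = outdir / fname
    if not p.exists():
        raise FileNotFoundError(
            f"missing artefact {fname!r}; run the {producer!r} stage first"
        )
    return p


def _markers(cells: pd.DataFrame) -> list:
    meta = {"cell_id", "roi_id", "case_id", "region", "population", "parent_group",
            "population_pred", "parent_group_pred", "population_model",
            "x_um", "y_um", "area_px", "severity", "treatment", "cn", "cn_region_scope"}
    return [c for c in cells.columns if c not in meta and not c.endswith("_norm")]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path):
    import tifffile

    c = cfg.simulate
    cells, clinical = syn_mod.simulate_study(
        n_cases=c.n_cases, rois_per_case=c.rois_per_case, seed=cfg.seed,
        batch_log_sd=c.batch_log_sd,
    )
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    f = outdir / "cells_truth.csv"
    cells.to_csv(f, index=False)
    files.append(f)
    f = outdir / "clinical.csv"
    clinical.to_csv(f, index=False)
    files.append(f)

    pops = sorted(cells["population"].unique())
    pairs = [syn_mod.PlantedPair(**p) for p in c.planted_lr]
    counts = syn_mod.generate_expression_counts(
        pops, pairs, n_cells_per_pop=c.n_cells_per_pop,
        n_background_genes=c.n_background_genes, seed=cfg.seed,
    )
    f = outdir / "expression_counts.csv"
    counts.to_csv(f, index=False)
    files.append(f)
    lr_db = pd.DataFrame(
        [{"pair_id": f"{p.ligand}_{p.receptor}", "ligand": p.ligand, "receptor": p.receptor,
          "ligand_complex": "", "receptor_complex": ""} for p in pairs]
        + [{"pair_id": f"BG{i:03d}_BG{i + 1:03d}", "ligand": f"BG{i:03d}",
            "receptor": f"BG{i + 1:03d}", "ligand_complex": "", "receptor_complex": ""}
           for i in range(0, min(10, c.n_background_genes - 1))]
    )
    f = outdir / "lr_pairs.csv"
    lr_db.to_csv(f, index=False)
    files.append(f)

    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    markers = _markers(cells)
    for roi in sorted(cells["roi_id"].unique())[: c.n_image_rois]:
        sub = cells[cells["roi_id"] == roi].reset_index(drop=True)
        stack, mask = syn_mod.generate_channel_stack(sub, markers, 1000, 1000)
        tifffile.imwrite(img_dir / f"{roi}_stack.tiff", stack)
        tifffile.imwrite(img_dir / f"{roi}_mask.tiff", mask)
        manual, _ = syn_mod.generate_mask_pair(mask, perturbation=1, seed=cfg.seed)
        tifffile.imwrite(img_dir / f"{roi}_manual_mask.tiff", manual)
        files += [img_dir / f"{roi}_stack.tiff", img_dir / f"{roi}_mask.tiff",
                  img_dir / f"{roi}_manual_mask.tiff"]
    _write_manifest(outdir, "simulate", c.model_dump() | {"seed": cfg.seed}, files)


def stage_quantify(cfg: PipelineConfig, outdir: Path):
    import tifffile

    cells_f = _require(outdir, "cells_truth.csv", "simulate")
    cells = pd.read_csv(cells_f)
    markers = _markers(cells)
    img_dir = outdir / "images"
    masks = sorted(img_dir.glob("*_mask.tiff")) if img_dir.exists() else []
    masks = [m for m in masks if not m.name.endswith("_manual_mask.tiff")]
    if not masks:
        raise FileNotFoundError("missing artefact 'images/*_mask.tiff'; run the 'simulate' stage first")
    tables, qc = [], {}
    files = []
    for mf in masks:
        roi = mf.name[: -len("_mask.tiff")]
        manual_f = img_dir / f"{roi}_manual_mask.tiff"
        try:
            mask = tifffile.imread(mf)
            stack = tifffile.imread(img_dir / f"{roi}_stack.tiff")
            manual = tifffile.imread(manual_f) if manual_f.exists() else None
        except Exception as exc:  # corrupted input: localise failure to this stage
            raise RuntimeError(f"quantify: failed to read TIFF for ROI {roi!r} ({mf}): {exc}") from exc
        tab = qt_mod.extract_cells(mask, stack, markers, expansion_px=1, roi_id=roi)
        tables.append(tab)
        if manual is not None:
            _, summary = qt_mod.jaccard_qc(mask, manual, seed=cfg.seed)
            qc[roi] = summary
    f = outdir / "cell_table_measured.csv"
    pd.concat(tables, ignore_index=True).to_csv(f, index=False)
    files.append(f)
    f = outdir / "jaccard_qc.json"
    f.write_text(json.dumps(qc, indent=2, sort_keys=True))
    files.append(f)
    _write_manifest(outdir, "quantify", {"expansion_px": 1, "seed": cfg.seed}, files)


def _load_rules(cfg: PhenotypeConfig):
    if cfg.rules_file:
        path = Path(cfg.rules_file)
    else:
        path = Path(__file__).parent / "data" / "population_rules.yaml"
    raw = yaml.safe_load(path.read_text())
    return raw["group_markers"], ph_mod.rules_from_config(raw["population_rules"])


def stage_phenotype(cfg: PipelineConfig, outdir: Path):
    cells = pd.read_csv(_require(outdir, "cells_truth.csv", "simulate"))
    markers = _markers(cells)
    c = cfg.phenotype
    cells, divisors, flagged = ph_mod.normalize_percentile(cells, markers, q=c.percentile)
    norm_cols = [m + "_norm" for m in markers]
    A = ph_mod.build_bbknn_graph(cells[norm_cols].to_numpy(), cells["case_id"].to_numpy(),
                                 c.k_per_batch)
    coarse = ph_mod.cluster_cells(A, c.coarse_resolution, seed=cfg.seed)
    group_markers, rules = _load_rules(c)
    population, groups = ph_mod.recluster_hierarchical(
        cells, markers, coarse, group_markers, rules,
        fine_resolution=c.fine_resolution, k_per_batch=c.k_per_batch, seed=cfg.seed,
    )
    cells["population_pred"] = population
    cells["parent_group_pred"] = groups
    files = []
    f = outdir / "cell_table_phenotyped.csv"
    cells.to_csv(f, index=False)
    files.append(f)
    f = outdir / "divisors.json"
    f.write_text(json.dumps({"divisors": divisors, "flagged": flagged, "q": c.percentile},
                            indent=2, sort_keys=True))
    files.append(f)
    for level in ("roi", "case"):
        ab = ph_mod.abundance_table(cells, level=level, label_col="population_pred")
        f = outdir / f"abundance_{level}.csv"
        ab.to_csv(f)
        files.append(f)
    _write_manifest(outdir, "phenotype", c.model_dump() | {"seed": cfg.seed}, files)


def _region_filter(cells: pd.DataFrame, region: str) -> pd.DataFrame:
    if region == "A":
        return cells[cells["region"] == "AntoniA"]
    if region == "B":
        return cells[cells["region"] == "AntoniB"]
    return cells[cells["region"] != "Mixed"]


def stage_spatial(cfg: PipelineConfig, outdir: Path):
    import networkx as nx

    cells = pd.read_csv(_require(outdir, "cell_table_phenotyped.csv", "phenotype"))
    c = cfg.spatial
    label_col = "population_pred"
    files = []
    pcf_all, acn_all = [], []
    for region in ("AntoniA", "AntoniB"):
        sub = cells[cells["region"] == region]
        for roi, grp in sub.groupby("roi_id", observed=True):
            grp = grp.reset_index(drop=True)
            counts = grp[label_col].value_counts()
            pops = sorted(counts[counts >= c.min_cells].index)
            pairs = [(a, b) for a in pops for b in pops if a != b]
            # keep the most populous pairs when capped
            pairs.sort(key=lambda ab: -min(counts[ab[0]], counts[ab[1]]))
            pairs = sorted(pairs[: c.max_pairs])
            if not pairs:
                continue
            pcf = sp_mod.pcf_significance_all_pairs(
                grp, pairs, 1000.0, 1000.0, n_perm=c.n_perm, seed=cfg.seed,
                r_max=c.r_max, dr=c.dr, alpha=c.alpha, label_col=label_col,
            )
            pcf["region"] = region
            pcf_all.append(pcf)
            acn_df = sp_mod.acn_significance_roi(
                grp, pairs, contact_radius=c.contact_radius, n_perm=c.n_perm,
                seed=cfg.seed, label_col=label_col,
            )
            acn_df["region"] = region
            acn_all.append(acn_df)
    pcf_all = pd.concat(pcf_all, ignore_index=True) if pcf_all else pd.DataFrame()
    acn_all = pd.concat(acn_all, ignore_index=True) if acn_all else pd.DataFrame()
    f = outdir / "pcf_results.csv"
    pcf_all.to_csv(f, index=False)
    files.append(f)
    f = outdir / "acn_results.csv"
    acn_all.to_csv(f, index=False)
    files.append(f)
    for region in ("AntoniA", "AntoniB"):
        pr = pcf_all[pcf_all["region"] == region] if len(pcf_all) else pd.DataFrame()
        ar = acn_all[acn_all["region"] == region] if len(acn_all) else pd.DataFrame()
        if len(pr):
            mat, mask = sp_mod.pcf_heatmap(pr, alpha=c.alpha)
            f = outdir / f"pcf_heatmap_{region}.csv"
            mat.to_csv(f)
            files.append(f)
        if len(pr) and len(ar):
            ab = ph_mod.abundance_table(cells[cells["region"] == region], level="roi",
                                        label_col=label_col, exclude_regions=())
            g, edges = sp_mod.interaction_network(ar, pr, ab, alpha=c.alpha,
                                                  consensus_frac=c.consensus_frac)
            f = outdir / f"network_{region}.graphml"
            nx.write_graphml(g, f)
            files.append(f)
            f = outdir / f"network_edges_{region}.csv"
            edges.to_csv(f, index=False)
            files.append(f)
    _write_manifest(outdir, "spatial", c.model_dump() | {"seed": cfg.seed}, files)


def stage_neighbourhoods(cfg: PipelineConfig, outdir: Path):
    cells = pd.read_csv(_require(outdir, "cell_table_phenotyped.csv", "phenotype"))
    clinical = pd.read_csv(_require(outdir, "clinical.csv", "simulate"))
    c = cfg.neighbourhoods
    markers = _markers(cells)
    cells = cells.rename(columns={"population_pred": "population_model"})
    cells["population"] = cells["population_model"]
    files = []
    if cfg.region == "combined":
        runs = [("combined", cells[cells["region"] != "Mixed"])]
    else:
        region = "AntoniA" if cfg.region == "A" else "AntoniB"
        runs = [(region, cells[cells["region"] == region])]
    label_frames = []
    for name, sub in runs:
        sub = sub.reset_index(drop=True)
        n = len(sub)
        k_max = min(c.k_max, max(2, n // 10))
        model = nb_mod.derive_neighbourhoods(
            sub, markers, k_range=range(c.k_min, k_max + 1), hop_depth=c.hop_depth,
            trim_um=c.trim_um, repeats=c.repeats, n_perm=c.n_perm, seed=cfg.seed,
            region=name, stability_mode=c.stability_mode,
        )
        sub = sub.copy()
        sub["cn"] = model.labels
        sub["cn_region_scope"] = name
        label_frames.append(sub[["cell_id", "roi_id", "case_id", "region", "cn",
                                 "cn_region_scope"]])
        f = outdir / f"cn_stability_{name}.csv"
        pd.DataFrame({"k": model.stability.k_values,
                      "stability": model.stability.stability}).to_csv(f, index=False)
        files.append(f)
        f = outdir / f"cn_stability_{name}.json"
        f.write_text(json.dumps({"selected_k": model.stability.selected_k,
                                 "repeats": model.stability.repeats,
                                 "mode": model.stability.mode}, indent=2))
        files.append(f)
        for label, frame in (("enrichment", model.enrichment),
                             ("abundance_roi", model.abundance_roi),
                             ("abundance_case", model.abundance_case),
                             ("proximity", model.proximity)):
            f = outdir / f"cn_{label}_{name}.csv"
            frame.to_csv(f)
            files.append(f)
        cov = clinical.set_index("case_id")["growth_rate"]
        corr_rows = []
        for cn in model.abundance_case.columns:
            vals = model.abundance_case[cn]
            try:
                res = nb_mod.correlate_with_covariate(vals, cov)
            except ValueError:
                continue
            corr_rows.append({"cn": cn, "scope": name} | res)
        f = outdir / f"cn_growth_correlation_{name}.csv"
        pd.DataFrame(corr_rows).to_csv(f, index=False)
        files.append(f)
    f = outdir / "cn_labels.csv"
    pd.concat(label_frames, ignore_index=True).to_csv(f, index=False)
    files.append(f)
    _write_manifest(outdir, "neighbourhoods",
                    c.model_dump() | {"seed": cfg.seed, "region": cfg.region}, files)


def stage_lr(cfg: PipelineConfig, outdir: Path):
    counts = pd.read_csv(_require(outdir, "expression_counts.csv", "simulate"))
    lr_db = pd.read_csv(_require(outdir, "lr_pairs.csv", "simulate"))
    c = cfg.lr
    expr = syn_mod.lognormalize_counts(counts)
    labels = expr.pop("population").to_numpy()
    pairs = lr_mod.load_lr_database(lr_db)
    planted = cfg.simulate.planted_lr
    combos = sorted({(p["sender"], p["receiver"]) for p in planted})
    lymph = sorted({p["sender"] for p in planted})
    res = lr_mod.lr_permutation_test(expr, labels, pairs, combos,
                                     n_perm=c.n_perm, seed=cfg.seed)
    ranked = lr_mod.filter_and_rank(res, min_frac=c.min_frac, top_n=c.top_n,
                                    alpha=c.alpha, frac_mode=c.frac_mode)
    ranked = lr_mod.annotate_direction(ranked, lymph)
    files = []
    f = outdir / "lr_all_scores.csv"
    res.to_csv(f, index=False)
    files.append(f)
    f = outdir / "lr_results.csv"
    ranked.to_csv(f, index=False)
    files.append(f)
    _write_manifest(outdir, "lr", c.model_dump() | {"seed": cfg.seed}, files)


def stage_stats(cfg: PipelineConfig, outdir: Path):
    cells = pd.read_csv(_require(outdir, "cell_table_phenotyped.csv", "phenotype"))
    clinical = pd.read_csv(_require(outdir, "clinical.csv", "simulate"))
    c = cfg.stats
    label_col = "population_pred"
    rows, audit = [], []
    ab_a = ph_mod.abundance_table(cells[cells["region"] == "AntoniA"], level="case",
                                  label_col=label_col, exclude_regions=())
    ab_b = ph_mod.abundance_table(cells[cells["region"] == "AntoniB"], level="case",
                                  label_col=label_col, exclude_regions=())
    for pop in sorted(set(ab_a.columns) & set(ab_b.columns)):
        a, b = ab_a[pop].dropna(), ab_b[pop].dropna()
        if len(a) < 3 or len(b) < 3:
            continue
        r = group_stats.compare_two_groups(a, b, "AntoniA", "AntoniB")
        rows.append({"comparison": f"abundance:{pop}:AntoniA_vs_AntoniB", "test": r.test,
                     "statistic": r.statistic, "p_value": r.p_value})
        audit.append({"comparison": rows[-1]["comparison"], "normality_p": r.normality_p,
                      "normal": r.normal, "notes": r.notes})
    ab_all = ph_mod.abundance_table(cells, level="case", label_col=label_col)
    sev = clinical.set_index("case_id")["severity"]
    for pop in sorted(ab_all.columns):
        by = {g: ab_all.loc[sev[sev == g].index.intersection(ab_all.index), pop].to_numpy()
              for g in ("mild", "moderate", "severe")}
        if any(len(v) < 3 for v in by.values()):
            continue
        r = group_stats.compare_three_groups(by)
        rows.append({"comparison": f"abundance:{pop}:severity", "test": r.test,
                     "statistic": r.statistic, "p_value": r.p_value})
        audit.append({"comparison": rows[-1]["comparison"], "normality_p": r.normality_p,
                      "normal": r.normal, "notes": r.notes})
    try:
        r = group_stats.tam_ratio_comparison(
            cells.rename(columns={label_col: "population"}), region=None)
        rows.append({"comparison": "tam_ratio:classical_vs_alternative", "test": r.test,
                     "statistic": r.statistic, "p_value": r.p_value})
        audit.append({"comparison": rows[-1]["comparison"], "normality_p": r.normality_p,
                      "normal": r.normal, "notes": r.notes})
    except ValueError as exc:
        audit.append({"comparison": "tam_ratio", "skipped": str(exc)})
    files = []
    f = outdir / "comparisons.csv"
    pd.DataFrame(rows).to_csv(f, index=False)
    files.append(f)
    f = outdir / "stats_audit.json"
    f.write_text(json.dumps(audit, indent=2, sort_keys=True, default=float))
    files.append(f)
    if c.match_counts:
        acc = group_stats.match_accounting(**c.match_counts)
        f = outdir / "match_accounting.json"
        f.write_text(json.dumps(acc, indent=2, sort_keys=True))
        files.append(f)
    _write_manifest(outdir, "stats", c.model_dump() | {"seed": cfg.seed}, files)


def stage_report(cfg: PipelineConfig, outdir: Path):
    summary = {}
    for name in ("jaccard_qc.json", "divisors.json", "match_accounting.json"):
        p = outdir / name
        if p.exists():
            summary[name.removesuffix(".json")] = json.loads(p.read_text())
    for pat, key in (("cn_stability_*.json", "cn_selected_k"),):
        summary[key] = {
            p.stem: json.loads(p.read_text()) for p in sorted(outdir.glob(pat))
        }
    for csv_name in ("comparisons.csv", "lr_results.csv"):
        p = outdir / csv_name
        if p.exists():
            summary[csv_name.removesuffix(".csv") + "_rows"] = int(
                len(pd.read_csv(p)) if p.stat().st_size > 1 else 0
            )
    f = outdir / "report_summary.json"
    f.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    _write_manifest(outdir, "report", {"seed": cfg.seed}, [f])


_STAGE_FN = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "phenotype": stage_phenotype,
    "spatial": stage_spatial,
    "neighbourhoods": stage_neighbourhoods,
    "lr": stage_lr,
    "stats": stage_stats,
    "report": stage_report,
}


def run(stage: str, cfg: PipelineConfig, outdir) -> None:
    """Run one pipeline stage (or ``"all"``) writing artefacts to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for s in stages:
        if s not in _STAGE_FN:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES + ('all',)}")
        log.info("stage %s starting (seed=%d, outdir=%s)", s, cfg.seed, outdir)
        _STAGE_FN[s](cfg, outdir)
        log.info("stage %s done", s)
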
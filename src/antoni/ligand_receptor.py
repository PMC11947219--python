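"""Receptor--ligand interaction scoring between cell populations.

CellPhoneDB/Squidpy-style analysis: the interaction score of a
ligand--receptor pair between a sender and a receiver population is the
mean of the ligand's mean expression in the sender and the receptor's
mean expression in the receiver; multi-subunit complexes contribute their
per-cell subunit-wise minimum.  One-sided significance comes from
shuffling population labels across cells; results are filtered so that at
least 5% of sender cells express the ligand and 5% of receiver cells the
receptor (AND rule by default, OR available), BH-adjusted within each
(sender, receiver) combination, and ranked keeping the top 20 scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import substream


@dataclass
class LRPair:
    pair_id: str
    ligand: tuple  # subunit genes
    receptor: tuple
    annotation: str = ""


def load_lr_database(df: pd.DataFrame) -> list:
    """Build LR pairs from a CellPhoneDB-like table.

    Expected columns: ``pair_id``, ``ligand``, ``receptor`` and optional
    ``ligand_complex`` / ``receptor_complex`` holding ':'-joined subunit
    lists (taking precedence over the single-gene columns).
    """
    pairs = []
    for row in df.itertuples(index=False):
        lig = getattr(row, "ligand_complex", "") or ""
        rec = getattr(row, "receptor_complex", "") or ""
        lig = tuple(str(lig).split(":")) if lig and not pd.isna(lig) else (str(row.ligand),)
        rec = tuple(str(rec).split(":")) if rec and not pd.isna(rec) else (str(row.receptor),)
        pairs.append(LRPair(str(row.pair_id), lig, rec, str(getattr(row, "annotation", ""))))
    return pairs


def resolve_pairs(pairs, genes) -> tuple:
    """Split pairs into (resolvable, dropped) against available genes."""
    genes = set(genes)
    ok, dropped = [], []
    for p in pairs:
        if set(p.ligand) <= genes and set(p.receptor) <= genes:
            ok.append(p)
        else:
            dropped.append(p.pair_id)
    return ok, dropped


def _complex_expression(expr: pd.DataFrame, subunits: tuple) -> np.ndarray:
    """Per-cell complex expression = subunit-wise minimum."""
    return expr[list(subunits)].to_numpy(dtype=float).min(axis=1)


def interaction_score(
    expr: pd.DataFrame,
    labels,
    pair: LRPair,
    sender: str,
    receiver: str,
):
    """Mean-of-means interaction score plus expressed fractions.

    score = (mean ligand expression in sender + mean receptor expression
    in receiver) / 2; the expressed fraction is the share of cells with
    complex expression > 0.
    """
    labels = np.asarray(labels)
    in_s, in_r = labels == sender, labels == receiver
    if not in_s.any() or not in_r.any():
        raise ValueError("sender and receiver populations must be non-empty")
    lig = _complex_expression(expr, pair.ligand)
    rec = _complex_expression(expr, pair.receptor)
    score = 0.5 * (lig[in_s].mean() + rec[in_r].mean())
    return {
        "score": float(score),
        "frac_ligand_sender": float((lig[in_s] > 0).mean()),
        "frac_receptor_receiver": float((rec[in_r] > 0).mean()),
    }


def lr_permutation_test(
    expr: pd.DataFrame,
    labels,
    pairs,
    combos,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided permutation p-values for every (pair, sender, receiver).

    ``combos`` is an iterable of (sender, receiver) population pairs.
    Labels are shuffled across all cells; p = (1 + #{score* >= score}) /
    (n_perm + 1).  Pairs with genes absent from ``expr`` are skipped and
    recorded in the frame's ``attrs['dropped_pairs']``.
    """
    labels = np.asarray(labels)
    pairs, dropped = resolve_pairs(pairs, expr.columns)
    combos = list(combos)
    # per-cell complex expression is label-independent: precompute
    lig_mat = np.column_stack([_complex_expression(expr, p.ligand) for p in pairs]) \
        if pairs else np.empty((len(expr), 0))
    rec_mat = np.column_stack([_complex_expression(expr, p.receptor) for p in pairs]) \
        if pairs else np.empty((len(expr), 0))

    def group_means(lv):
        pops = sorted(set(s for s, _ in combos) | set(r for _, r in combos))
        mask = np.stack([(lv == p) for p in pops]).astype(float)
        sizes = mask.sum(axis=1, keepdims=True)
        M = np.divide(mask, sizes, out=np.zeros_like(mask), where=sizes > 0)
        return pops, M @ lig_mat, M @ rec_mat  # (pops x pairs)

    pops, lig_obs, rec_obs = group_means(labels)
    pidx = {p: i for i, p in enumerate(pops)}
    obs = {}
    for (s, r) in combos:
        obs[(s, r)] = 0.5 * (lig_obs[pidx[s]] + rec_obs[pidx[r]])

    rng = substream(seed, "lr_perm")
    exceed = {c: np.zeros(len(pairs)) for c in combos}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, lig_p, rec_p = group_means(perm)
        for (s, r) in combos:
            stat = 0.5 * (lig_p[pidx[s]] + rec_p[pidx[r]])
            exceed[(s, r)] += stat >= obs[(s, r)] - 1e-12

    rows = []
    for (s, r) in combos:
        in_s, in_r = labels == s, labels == r
        for k, p in enumerate(pairs):
            rows.append({
                "pair_id": p.pair_id,
                "sender": s,
                "receiver": r,
                "score": float(obs[(s, r)][k]),
                "p_value": float((1 + exceed[(s, r)][k]) / (n_perm + 1)),
                "frac_ligand_sender": float((lig_mat[in_s, k] > 0).mean()) if in_s.any() else 0.0,
                "frac_receptor_receiver": float((rec_mat[in_r, k] > 0).mean()) if in_r.any() else 0.0,
            })
    out = pd.DataFrame(rows, columns=[
        "pair_id", "sender", "receiver", "score", "p_value",
        "frac_ligand_sender", "frac_receptor_receiver",
    ])
    out.attrs["dropped_pairs"] = dropped
    return out


def filter_and_rank(
    results: pd.DataFrame,
    min_frac: float = 0.05,
    top_n: int = 20,
    alpha: float = 0.05,
    frac_mode: str = "and",
    bh_family: str = "per_combo",
) -> pd.DataFrame:
    """Apply the 5% expression filter, BH FDR and top-N ranking.

    ``frac_mode="and"`` (default) requires the ligand expressed in >= 5%
    of sender cells AND the receptor in >= 5% of receiver cells;
    ``"or"`` accepts either.  BH is applied within each (sender, receiver)
    combination by default (``bh_family="global"`` adjusts over
    everything); only q < alpha survives, and the ``top_n`` largest scores
    per combination are kept.
    """
    if results.empty:
        out = results.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    if frac_mode == "and":
        keep = (results["frac_ligand_sender"] >= min_frac) & (
            results["frac_receptor_receiver"] >= min_frac
        )
    elif frac_mode == "or":
        keep = (results["frac_ligand_sender"] >= min_frac) | (
            results["frac_receptor_receiver"] >= min_frac
        )
    else:
        raise ValueError("frac_mode must be 'and' or 'or'")
    out = results[keep].copy()
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        return out
    if bh_family == "per_combo":
        out["q_value"] = np.nan
        for _, idx in out.groupby(["sender", "receiver"]).groups.items():
            out.loc[idx, "q_value"] = multipletests(out.loc[idx, "p_value"], method="fdr_bh")[1]
    elif bh_family == "global":
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        raise ValueError("bh_family must be 'per_combo' or 'global'")
    out = out[out["q_value"] < alpha]
    out = (
        out.sort_values(["sender", "receiver", "score"], ascending=[True, True, False])
        .groupby(["sender", "receiver"], group_keys=False)
        .head(top_n)
        .reset_index(drop=True)
    )
    return out


def annotate_direction(results: pd.DataFrame, lymphocyte_populations) -> pd.DataFrame:
    """Add the lymphocyte-orientation ``direction`` column.

    ``"sender"`` when the lymphocyte population expresses the ligand (it
    is the sender of the interaction), ``"receiver"`` when it expresses
    the receptor; interactions not involving a lymphocyte get ``"na"``.
    """
    lymph = set(lymphocyte_populations)
    out = results.copy()
    out["direction"] = np.where(
        out["sender"].isin(lymph), "sender",
        np.where(out["receiver"].isin(lymph), "receiver", "na"),
    )
    return out
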
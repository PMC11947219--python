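"""Case-level comparison statistics with normality gating.

Comparisons are made on case averages (one value per case, never per
ROI, to avoid pseudo-replication).  The test is gated by Shapiro--Wilk
normality at alpha = 0.05: two normal groups get an unpaired t-test
(Welch variant when the variance ratio exceeds 4), otherwise a two-sided
Mann--Whitney U; three groups get one-way ANOVA with Tukey's HSD when all
normal, otherwise Kruskal--Wallis with Dunnett's T3 pairwise comparisons
(implemented as pairwise Welch statistics with a Sidak-type adjustment,
which equals the studentized-maximum-modulus criterion under
independence).  Every result records the gate evidence so the chosen
test is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComparisonResult:
    groups: list
    n_per_group: list
    test: str
    statistic: float
    p_value: float
    normality_p: dict
    normal: bool
    pairwise: pd.DataFrame | None = None
    notes: list = field(default_factory=list)


def _shapiro_gate(groups_values, alpha=0.05):
    """Shapiro--Wilk p per group; constant groups force the nonparametric
    branch (normality undefined)."""
    pvals, normal, notes = {}, True, []
    for name, v in groups_values.items():
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            pvals[name] = np.nan
            normal = False
            notes.append(f"group {name!r} is constant; normality undefined")
        else:
            p = float(stats.shapiro(v).pvalue)
            pvals[name] = p
            normal &= p > alpha
    return pvals, normal, notes


def compare_two_groups(
    values_a,
    values_b,
    name_a: str = "A",
    name_b: str = "B",
    paired: bool = False,
    alpha: float = 0.05,
    welch_variance_ratio: float = 4.0,
) -> ComparisonResult:
    """Normality-gated two-group comparison of case averages.

    Both groups normal: two-tailed unpaired t-test, switching to the
    Welch variant when the larger/smaller variance ratio exceeds
    ``welch_variance_ratio``; otherwise two-tailed Mann--Whitney U.
    Paired mode uses the paired t-test / Wilcoxon signed-rank instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 cases per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal-length groups")
    pvals, normal, notes = _shapiro_gate({name_a: a, name_b: b}, alpha)
    if normal:
        if paired:
            st = stats.ttest_rel(a, b)
            test = "paired t"
        else:
            va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
            ratio = max(va, vb) / min(va, vb) if min(va, vb) > 0 else np.inf
            welch = ratio > welch_variance_ratio
            st = stats.ttest_ind(a, b, equal_var=not welch)
            test = "Welch t" if welch else "t"
    else:
        if paired:
            st = stats.wilcoxon(a, b)
            test = "Wilcoxon"
        else:
            st = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
    return ComparisonResult(
        groups=[name_a, name_b],
        n_per_group=[len(a), len(b)],
        test=test,
        statistic=float(st.statistic),
        p_value=float(st.pvalue),
        normality_p=pvals,
        normal=normal,
        notes=notes,
    )


def _dunnett_t3(groups_values: dict) -> pd.DataFrame:
    """Dunnett's T3 pairwise comparisons for unequal variances.

    Pairwise Welch statistics with Welch--Satterthwaite df, adjusted with
    the Sidak-type bound 1 - (1 - p)^m (the studentized-maximum-modulus
    criterion under independence).
    """
    names = list(groups_values)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups_values[names[i]], dtype=float)
            b = np.asarray(groups_values[names[j]], dtype=float)
            sa, sb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
            se = np.sqrt(sa + sb)
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            df = (sa + sb) ** 2 / (
                sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
            ) if se > 0 else len(a) + len(b) - 2
            p = 2 * stats.t.sf(abs(t), df)
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": float(t), "p_raw": float(p),
                "p_adjusted": float(min(1.0, 1.0 - (1.0 - p) ** m)),
            })
    return pd.DataFrame(rows)


def compare_three_groups(values_by_group: dict, alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated three-group comparison.

    All groups normal: one-way ANOVA with Tukey's HSD pairwise p-values;
    otherwise Kruskal--Wallis with Dunnett's T3 pairwise comparisons.
    """
    if len(values_by_group) != 3:
        raise ValueError("exactly three groups required")
    for name, v in values_by_group.items():
        if len(v) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 cases")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    pvals, normal, notes = _shapiro_gate(arrays, alpha)
    names = list(arrays)
    if normal:
        st = stats.f_oneway(*arrays.values())
        test = "ANOVA + Tukey"
        tk = stats.tukey_hsd(*arrays.values())
        rows = []
        for i in range(3):
            for j in range(i + 1, 3):
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "statistic": float(tk.statistic[i, j]),
                    "p_adjusted": float(tk.pvalue[i, j]),
                })
        pairwise = pd.DataFrame(rows)
    else:
        st = stats.kruskal(*arrays.values())
        test = "Kruskal-Wallis + Dunnett T3"
        pairwise = _dunnett_t3(arrays)
    return ComparisonResult(
        groups=names,
        n_per_group=[len(v) for v in arrays.values()],
        test=test,
        statistic=float(st.statistic),
        p_value=float(st.pvalue),
        normality_p=pvals,
        normal=normal,
        pairwise=pairwise,
        notes=notes,
    )


def tam_ratio_comparison(
    cells: pd.DataFrame,
    classical: str = "TAM_classical",
    alternative: str = "TAM_alternative",
    region: str | None = None,
    paired: bool = False,
) -> ComparisonResult:
    """Compare case-averaged abundances of the two TAM phenotypes.

    Restricts to ``region`` when given (cases lacking that region are
    dropped), computes each case's mean relative abundance of the
    classical and alternative TAM populations over its ROIs, and runs the
    gated two-group comparison.
    """
    from .phenotype import abundance_table

    df = cells if region is None else cells[cells["region"] == region]
    ab = abundance_table(df, level="case", exclude_regions=())
    for pop in (classical, alternative):
        if pop not in ab.columns:
            raise ValueError(f"population {pop!r} absent from abundance table")
    a = ab[classical].to_numpy(dtype=float)
    b = ab[alternative].to_numpy(dtype=float)
    return compare_two_groups(a, b, classical, alternative, paired=paired)


def match_accounting(
    n_total: int,
    n_aligned: int,
    n_matched: int,
    score_threshold: float = 0.3,
) -> dict:
    """Data accounting for cross-modal cell matching.

    Reports the aligned share of the total (2 dp) and the matched share
    of the aligned cells (1 dp), as percentages, plus the match-score
    threshold applied.
    """
    if not 0 <= n_matched <= n_aligned <= n_total:
        raise ValueError("require 0 <= n_matched <= n_aligned <= n_total")
    return {
        "n_total": int(n_total),
        "n_aligned": int(n_aligned),
        "n_matched": int(n_matched),
        "aligned_pct": round(100.0 * n_aligned / n_total, 2),
        "matched_pct": round(100.0 * n_matched / n_aligned, 1) if n_aligned else 0.0,
        "score_threshold": score_threshold,
    }
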
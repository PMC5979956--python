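"""Group statistics: one-way ANOVA with Scheffé post hoc, demographics
tests, and metric-clinical correlations.

Each tract x metric combination is tested independently at alpha = 0.05
with no multiplicity correction across tracts or metrics.  Clinical
correlations use Spearman rank correlation (the disability score is
ordinal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "oneway_anova_scheffe",
    "chi_square_independence",
    "mann_whitney_z",
    "correlate_clinical",
    "compare_cohort",
    "format_report",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    F: float
    p_overall: float
    pairwise: dict[tuple[str, str], float]
    group_means: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)
    metric: str = ""
    tract: str = ""

    def significant(self, pair: tuple[str, str] | None = None) -> bool:
        if pair is None:
            return self.p_overall < ALPHA
        key = pair if pair in self.pairwise else (pair[1], pair[0])
        return self.pairwise[key] < ALPHA


def oneway_anova_scheffe(groups: dict[str, np.ndarray]) -> ComparisonResult:
    """Classical one-way ANOVA with Scheffé's all-pairs post hoc test.

    The Scheffé p for a pair is the survival probability of
    ``F_pair / (k - 1)`` under F(k-1, N-k), where ``F_pair`` is the
    two-group contrast statistic on the pooled within-group variance.
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2 or any(d.size < 2 for d in data):
        raise ValueError("need >=2 groups with >=2 observations each")
    k = len(data)
    n_tot = sum(d.size for d in data)
    grand = np.concatenate(data)
    ms_within = sum(((d - d.mean()) ** 2).sum() for d in data) / (n_tot - k)
    if ms_within == 0:
        means = [d.mean() for d in data]
        if np.ptp(means) > 0:
            warnings.warn("zero within-group variance with unequal means",
                          stacklevel=2)
            f_stat, p = np.inf, 0.0
        else:
            warnings.warn("all observations identical; ANOVA undefined",
                          stacklevel=2)
            f_stat, p = np.nan, np.nan
    else:
        f_stat, p = sps.f_oneway(*data)
        f_stat, p = float(f_stat), float(p)
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(k), 2):
        a, b = data[i], data[j]
        if ms_within == 0:
            pairwise[(names[i], names[j])] = (
                0.0 if a.mean() != b.mean() else np.nan
            )
            continue
        f_pair = (a.mean() - b.mean()) ** 2 / (
            ms_within * (1.0 / a.size + 1.0 / b.size)
        )
        pairwise[(names[i], names[j])] = float(
            sps.f.sf(f_pair / (k - 1), k - 1, n_tot - k)
        )
    means = {
        n: (float(d.mean()), float(d.std(ddof=1)), int(d.size))
        for n, d in zip(names, data)
    }
    return ComparisonResult(F=f_stat, p_overall=p, pairwise=pairwise,
                            group_means=means)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (statistic, p).  Zero row or column margins are an error.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def mann_whitney_z(a, b) -> tuple[float, float, float]:
    """Mann-Whitney U with the tie-corrected normal approximation.

    Returns ``(U, z, p)`` where ``U`` counts pairs in which an ``a``
    observation beats a ``b`` observation (midrank ties) and
    ``z = (U - n1 n2 / 2) / sqrt(var)`` with the tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var == 0:
        warnings.warn("all values tied across both samples", stacklevel=2)
        return float(u), 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(z), float(p)


def correlate_clinical(
    table: pd.DataFrame,
    metric_cols: list[str] | None = None,
    clinical_cols: tuple[str, ...] = ("mjoa", "n_levels"),
) -> pd.DataFrame:
    """Spearman correlations between tract metrics and clinical scores.

    ``table`` is the long cohort table; patients' per-side metric values
    are correlated with their clinical variables.  Constant columns give
    NaN.  Returns rows (metric, tract, clinical, rho, p, n).
    """
    pat = table[table["group"] != "control"]
    if pat.empty:
        raise ValueError("no patient records to correlate")
    rows = []
    for (tract, metric), sub in pat.groupby(["tract", "metric"]):
        if metric_cols and metric not in metric_cols:
            continue
        for clin in clinical_cols:
            x = sub["value"].to_numpy()
            y = sub[clin].to_numpy(dtype=float)
            if x.size < 3:
                raise ValueError("need >=3 complete records")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = sps.spearmanr(x, y)
            rows.append(
                {"metric": metric, "tract": tract, "clinical": clin,
                 "rho": float(rho), "p": float(p), "n": int(x.size)}
            )
    return pd.DataFrame(rows)


GROUP_ORDER = ("affected", "unaffected", "control")


def compare_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """ANOVA + Scheffé for every tract x metric of a cohort table.

    Groups are the per-side labels (affected / unaffected / control).
    Returns one row per tract x metric with group means +- SD, the
    overall F and p, pairwise Scheffé p values and significance flags.
    """
    present = [g for g in GROUP_ORDER if g in set(table["group"])]
    if len(present) < 2:
        raise ValueError("need >=2 groups for the cohort comparison")
    rows = []
    for (tract, metric), sub in table.groupby(["tract", "metric"]):
        groups = {
            g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in present
        }
        res = oneway_anova_scheffe(groups)
        row = {"tract": tract, "metric": metric, "F": res.F,
               "p_overall": res.p_overall}
        for g in present:
            m, sd, n = res.group_means[g]
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = sd
            row[f"n_{g}"] = n
        for (ga, gb), p in res.pairwise.items():
            row[f"p_{ga}_vs_{gb}"] = p
            row[f"sig_{ga}_vs_{gb}"] = bool(p < ALPHA)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(results: pd.DataFrame) -> str:
    """Plain-text summary table of the cohort comparison."""
    lines = ["Tract metrics by cord side group (mean ± SD; * p < 0.05)", ""]
    for _, r in results.iterrows():
        lines.append(f"{r['tract']} / {r['metric']}:")
        for g in GROUP_ORDER:
            if f"mean_{g}" in r:
                lines.append(
                    f"  {g:10s} {r[f'mean_{g}']:.4f} ± {r[f'sd_{g}']:.4f}"
                    f" (n={int(r[f'n_{g}'])})"
                )
        lines.append(f"  ANOVA F = {r['F']:.3f}, p = {r['p_overall']:.4f}")
        for col in results.columns:
            if col.startswith("p_") and col != "p_overall":
                star = "*" if r[f"sig_{col[2:]}"] else ""
                lines.append(f"  Scheffé {col[2:]:25s} p = {r[col]:.4f} {star}")
        lines.append("")
    return "\n".join(lines)
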
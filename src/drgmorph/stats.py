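"""Group-comparison statistics for morphometric endpoints.

The analysis strategy is: screen each endpoint's distribution for
normality (Kolmogorov–Smirnov, D'Agostino–Pearson omnibus and
Shapiro–Wilk; any p < 0.05 routes to the non-parametric branch),
compare treatment groups with the tie-corrected Kruskal–Wallis test,
follow up with Dunn's multiple-comparison test on pooled ranks, measure
the association between minimum and maximum branching with Pearson's r,
and test the association between neurite presence and soma-size class
with a 2×2 χ² test.  Significance is declared at α = 0.05 and reported
in tiers: p < 0.001 '***', 0.001–0.01 '**', 0.01–0.05 '*', else 'ns'.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Omnibus + pairwise results for one endpoint across k groups."""

    variable: str
    group_sizes: dict[str, int]
    statistic: float     # Kruskal–Wallis H
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj, tier


def significance_tier(p: float) -> str:
    """Map a p-value to the reporting tier used throughout the outputs."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normality_suite(x) -> tuple[float, float, float]:
    """(Kolmogorov–Smirnov, D'Agostino–Pearson, Shapiro–Wilk) p-values.

    The KS test is the classical one-sample test against a normal with
    sample-estimated mean and SD (no Lilliefors correction), which makes
    it conservative; the omnibus and Shapiro–Wilk tests carry the power.
    Downstream rule: any p < 0.05 routes to the non-parametric branch.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InvalidParameterError(
            "normality_suite needs n >= 8 (D'Agostino-Pearson omnibus minimum)")
    if np.ptp(x) == 0:
        raise InvalidParameterError("constant sample: normality tests undefined")
    ks_p = float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    dp_p = float(sps.normaltest(x).pvalue)
    sw_p = float(sps.shapiro(x).pvalue)
    return ks_p, dp_p, sw_p


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its χ²(k−1) p-value.

    Degenerate all-tied data (every observation identical) yields
    H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise InvalidParameterError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InvalidParameterError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise InvalidParameterError("Kruskal-Wallis needs a total n of at least 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: dict[str, np.ndarray] | list,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's multiple-comparison test on pooled ranks with tie correction.

    For groups a, b the statistic is

        z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T) (1/n_a + 1/n_b)),

    where R̄ are mean pooled ranks, N the total sample size and
    T = Σ(t³ − t) / (12 (N − 1)) the tie correction.  Two-sided normal
    p-values are family-wise adjusted over all k(k−1)/2 pairs
    (``bonferroni`` | ``holm`` | ``none``).  All-tied pooled data gives
    z = 0, p = 1 for every pair.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = [str(i) for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidParameterError("Dunn's test needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise InvalidParameterError("empty group")
    if adjust not in ("bonferroni", "holm", "none"):
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for a in arrays:
        mean_ranks.append(ranks[offset:offset + a.size].mean())
        sizes.append(a.size)
        offset += a.size

    _uniq, tie_counts = np.unique(pooled, return_counts=True)
    if n_total > 1:
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    else:
        tie_term = 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for ia, ib in combinations(range(len(arrays)), 2):
        if var_base <= 0:  # every pooled value tied
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(var_base * (1.0 / sizes[ia] + 1.0 / sizes[ib]))
            z = (mean_ranks[ia] - mean_ranks[ib]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[ia], "group_b": labels[ib],
                     "n_a": sizes[ia], "n_b": sizes[ib],
                     "z": float(z), "p_raw": float(p)})
    table = pd.DataFrame(rows)

    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(1.0, table["p_raw"] * len(table))
    elif adjust == "holm":
        table["p_adj"] = multipletests(table["p_raw"], method="holm")[1]
    else:
        table["p_adj"] = table["p_raw"]
    table["tier"] = table["p_adj"].map(significance_tier)
    return table


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("pearson_corr needs paired vectors of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def chi2_association(table) -> tuple[float, float]:
    """Pearson χ² (1 df, no continuity correction) on a 2×2 contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise InvalidParameterError("chi2_association expects a 2x2 table")
    if np.any(table < 0):
        raise InvalidParameterError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidParameterError("zero margin: association undefined")
    chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_groups(records: pd.DataFrame, variable: str, by: str = "group",
                   adjust: str = "bonferroni") -> GroupComparison:
    """Kruskal–Wallis omnibus + Dunn post hoc on one endpoint of a metrics table."""
    if variable not in records.columns:
        raise InvalidParameterError(f"no column {variable!r} in records")
    grouped = {str(label): sub[variable].dropna().to_numpy()
               for label, sub in records.groupby(by, sort=False)}
    h, p = kruskal_wallis(list(grouped.values()))
    pairwise = dunn_posthoc(grouped, adjust=adjust)
    return GroupComparison(
        variable=variable,
        group_sizes={k: int(v.size) for k, v in grouped.items()},
        statistic=h, p_value=p, pairwise=pairwise)
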
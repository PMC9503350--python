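"""Stratified phenotype summaries, group tests and obesity-response classes.

Adult offspring of high-fat-diet dams split into two weight-response
phenotypes: maternally induced obesity (MIO) and obesity-resistant (MIOR).
The published criterion is verbal ("adulthood body weight fell in the normal
range"); here it is operationalized as a z-threshold above the normal-diet
offspring mean (default 2 SD), with an explicit fixed cutoff as the
alternative. Group summaries report mean +/- SEM per cell with Welch t
(two groups), one-way ANOVA (more), or Wilcoxon rank-sum on request; raw
p-values are reported without multiplicity correction across phenotype
variables, mirroring the summary-table convention of small-cohort studies.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .microbiome import AbundanceTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class StratificationRule:
    """How adult HFD offspring are split into MIO vs MIOR."""

    method: str = "z_threshold"
    z: float = 2.0
    fixed_cutoff: float | None = None  # g

    def __post_init__(self) -> None:
        if self.method not in ("z_threshold", "fixed_cutoff"):
            raise ValueError("method must be 'z_threshold' or 'fixed_cutoff'")
        if self.method == "z_threshold" and self.z <= 0:
            raise ValueError("z must be positive")
        if self.method == "fixed_cutoff" and (
            self.fixed_cutoff is None or self.fixed_cutoff <= 0
        ):
            raise ValueError("fixed_cutoff must be a positive weight (g)")


def stratify_mio(
    hfd_weights,
    nd_weights=None,
    rule: StratificationRule = StratificationRule(),
) -> np.ndarray:
    """Label each adult HFD weight 'MIO' (obese) or 'MIOR' (resistant).

    z_threshold: MIO iff weight > mean(ND) + z * SD(ND); fixed_cutoff: MIO
    iff weight > cutoff. Order-invariant in both inputs.
    """
    hfd = np.asarray(hfd_weights, dtype=float)
    if rule.method == "fixed_cutoff":
        cutoff = float(rule.fixed_cutoff)
    else:
        if nd_weights is None:
            raise ValueError("z_threshold stratification needs ND reference weights")
        nd = np.asarray(nd_weights, dtype=float)
        if nd.size < 2:
            raise ValueError("need >= 2 ND weights for the z-threshold method")
        sd = float(nd.std(ddof=1))
        if sd == 0:
            raise ValueError(
                "ND weights have zero spread; use method='fixed_cutoff' instead"
            )
        cutoff = float(nd.mean()) + rule.z * sd
    return np.where(hfd > cutoff, "MIO", "MIOR")


def summarize(
    data: pd.DataFrame,
    variables: list[str],
    group_keys: list[str],
    compare: str | None = None,
    nonnormal: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-cell mean +/- SEM summary with group comparisons.

    Cells are combinations of `group_keys`. If `compare` names one of the
    keys, each variable is tested across its groups within every combination
    of the remaining keys: Welch t-test for two groups, one-way ANOVA for
    more; variables listed in `nonnormal` use Wilcoxon rank-sum /
    Kruskal-Wallis instead. Empty cells are omitted with a warning.
    """
    for col in group_keys + variables:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    rows: list[dict] = []
    strata = [k for k in group_keys if k != compare]

    for cell, sub in data.groupby(group_keys, sort=True, observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        for var in variables:
            values = sub[var].dropna().to_numpy(dtype=float)
            if values.size == 0:
                logger.warning("empty cell %s for %s; omitted", cell, var)
                continue
            sd = values.std(ddof=1) if values.size > 1 else 0.0
            rows.append(
                dict(zip(group_keys, cell))
                | {
                    "variable": var,
                    "mean": values.mean(),
                    "sem": sd / np.sqrt(values.size),
                    "n": values.size,
                }
            )
    summary = pd.DataFrame(rows)
    if summary.empty or compare is None:
        if not summary.empty:
            summary[["test", "statistic", "p"]] = [None, np.nan, np.nan]
        return summary

    tests: dict[tuple, tuple[str, float, float]] = {}
    iterator = (
        data.groupby(strata, sort=True, observed=True) if strata else [((), data)]
    )
    for stratum, sub in iterator:
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        for var in variables:
            groups = [
                g[var].dropna().to_numpy(dtype=float)
                for _, g in sub.groupby(compare, sort=True, observed=True)
            ]
            groups = [g for g in groups if g.size >= 2]
            if len(groups) < 2:
                continue
            if var in nonnormal:
                if len(groups) == 2:
                    stat, p = stats.ranksums(*groups)
                    name = "wilcoxon_rank_sum"
                else:
                    stat, p = stats.kruskal(*groups)
                    name = "kruskal_wallis"
            elif len(groups) == 2:
                stat, p = stats.ttest_ind(*groups, equal_var=False)
                name = "welch_t"
            else:
                stat, p = stats.f_oneway(*groups)
                name = "anova"
            tests[stratum + (var,)] = (name, float(stat), float(p))

    def lookup(row):
        key = tuple(row[k] for k in strata) + (row["variable"],)
        return tests.get(key, (None, np.nan, np.nan))

    summary[["test", "statistic", "p"]] = summary.apply(
        lookup, axis=1, result_type="expand"
    )
    return summary


def fold_change(
    table: AbundanceTable | pd.DataFrame,
    samples_a,
    samples_b,
    feature: str,
) -> float:
    """Ratio of group-mean relative abundances, mean(A) / mean(B).

    Returns NaN (logged) when the denominator group mean is zero.
    """
    data = table.data if isinstance(table, AbundanceTable) else table
    if feature not in data.columns:
        raise ValueError(f"feature {feature!r} not in table")
    a = data.loc[list(samples_a), feature].to_numpy(dtype=float)
    b = data.loc[list(samples_b), feature].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_b = b.mean()
    if mean_b <= 0:
        logger.warning("fold change undefined for %s: zero group-B mean", feature)
        return float("nan")
    return float(a.mean() / mean_b)
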
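"""Associations between imaging parameters and microbial relative abundances.

16S-derived taxa tables (phylum/order/family/genus) and predicted KEGG
pathway tables are consumed as samples x features matrices, total-sum-scaling
(TSS) normalized. Each feature is related to each imaging parameter by
Spearman rank correlation; p-values come from the exact permutation
distribution for small samples (n <= 9) and the t approximation otherwise,
and are Benjamini-Hochberg adjusted within one family per
(site, level, imaging parameter) — the per-level correction a published
association table implies when the same raw p maps to different adjusted
values at family vs genus level.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Default output column order of association tables.
ASSOCIATION_COLUMNS = [
    "site",
    "level",
    "parameter",
    "feature",
    "rho",
    "p",
    "q",
    "mean_abund",
    "n",
]


@dataclasses.dataclass
class AbundanceTable:
    """Relative abundances of one (site, level): samples x features."""

    site: str
    level: str
    data: pd.DataFrame
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("abundances must be non-negative")
        if self.normalized:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-6)].tolist()
                raise ValueError(f"rows do not sum to 1 for samples {bad[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> pd.Index:
        return self.data.columns

    def to_frame(self) -> pd.DataFrame:
        return self.data.reset_index()

    def to_tsv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, sep="\t", index=False, float_format="%.8f")

    @classmethod
    def from_tsv(
        cls, path: str | Path, site: str, level: str, normalized: bool = True
    ) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        df.index.name = "animal_id"
        return cls(site=site, level=level, data=df, normalized=normalized)


def tss_normalize(
    counts: pd.DataFrame | AbundanceTable, site: str = "", level: str = ""
) -> AbundanceTable:
    """Total sum scaling: divide each sample row by its total.

    Idempotent on already-normalized tables; fails loudly on all-zero samples.
    """
    if isinstance(counts, AbundanceTable):
        site = site or counts.site
        level = level or counts.level
        df = counts.data
    else:
        df = counts
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {df.index[zero].tolist()}")
    return AbundanceTable(
        site=site, level=level, data=df.div(sums, axis=0), normalized=True
    )


def prevalence_filter(
    table: AbundanceTable,
    min_prevalence: float = 0.2,
    min_mean_abund: float = 1e-4,
) -> AbundanceTable:
    """Drop features detected in < min_prevalence of samples or with mean
    relative abundance < min_mean_abund. Values are kept as-is (fractions of
    the original composition), so the result is flagged non-normalized."""
    for thr in (min_prevalence, min_mean_abund):
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must be in [0, 1]")
    detected = (table.data > 0).mean(axis=0)
    mean_ab = table.data.mean(axis=0)
    keep = (detected >= min_prevalence) & (mean_ab >= min_mean_abund)
    removed = table.features[~keep].tolist()
    if removed:
        logger.info(
            "prevalence filter removed %d/%d features from %s/%s: %s",
            len(removed),
            table.data.shape[1],
            table.site,
            table.level,
            ", ".join(removed),
        )
    return AbundanceTable(
        site=table.site,
        level=table.level,
        data=table.data.loc[:, keep],
        normalized=False,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite (no NaN/inf)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@lru_cache(maxsize=4)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n (<= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    perms = _permutation_matrix(x.size)
    rhos = (ry[perms] @ rx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_assoc(
    table: AbundanceTable,
    imaging: pd.DataFrame,
    parameters: list[str] | None = None,
    min_n: int = 4,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Spearman associations of every feature with every imaging parameter.

    `imaging` is indexed by sample/animal id with one column per parameter.
    Pairs are matched by id; incomplete pairs are dropped per test. Features
    with fewer than `min_n` complete pairs are skipped (logged). BH-FDR is
    applied within each (site, level, parameter) family; rows are sorted by
    parameter then q then p. `mean_abund` is the mean relative abundance of
    the feature, in percent, over the samples used.
    """
    if parameters is None:
        parameters = list(imaging.columns)
    shared = table.sample_ids.intersection(imaging.index)
    rows: list[dict] = []
    for param in parameters:
        x_all = imaging.loc[shared, param].to_numpy(dtype=float)
        for feature in table.features:
            y_all = table.data.loc[shared, feature].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(ok.sum())
            if n < min_n:
                logger.info(
                    "skipping %s x %s: only %d complete pairs (< %d)",
                    param,
                    feature,
                    n,
                    min_n,
                )
                continue
            x, y = x_all[ok], y_all[ok]
            if np.all(x == x[0]) or np.all(y == y[0]):
                logger.info("skipping %s x %s: constant input", param, feature)
                continue
            rho, p = stats.spearmanr(x, y)
            if n <= exact_max_n:
                p = _spearman_exact_p(x, y, rho)
            rows.append(
                {
                    "site": table.site,
                    "level": table.level,
                    "parameter": param,
                    "feature": feature,
                    "rho": float(rho),
                    "p": float(p),
                    "mean_abund": float(y.mean() * 100.0),
                    "n": n,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    result["q"] = np.nan
    for param, idx in result.groupby("parameter").groups.items():
        result.loc[idx, "q"] = bh_fdr(result.loc[idx, "p"].to_numpy())
    result = result.sort_values(
        ["parameter", "q", "p", "feature"], kind="stable"
    ).reset_index(drop=True)
    return result[ASSOCIATION_COLUMNS]
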
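"""Count normalization and the strongly-male-biased classification cascade.

Normalization is the median-of-ratios estimator: each sample's size factor
is the median, over genes with all-positive counts, of that sample's count
divided by the gene's geometric mean across samples; normalized counts are
raw counts divided column-wise by the size factors.

The cascade identifying strongly male-biased genes:

1. two log2 male:female fold-change estimators on group means of normalized
   counts, differing only in pseudocount (c1 = 1, light; c2 = 8, shrunken);
   a gene is a *candidate* when either exceeds the threshold L (default 2);
2. candidates are filtered to genes whose summed normalized count over the
   male-group samples exceeds T (default 1000);
3. the top fraction q (default 20%, ceiling rounding) of the survivors,
   ranked by max of the two estimators (ties broken by gene id), are called
   *strongly male-biased*.

Male groups default to prospective plus definitive males (PM, EM, MM, LM);
female groups to definitive females (EF, MF, LF); undifferentiated larvae
(UD) sit in neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierParams",
    "size_factors",
    "normalize_counts",
    "group_summary",
    "log2_mf",
    "classify_male_biased",
    "embryo_classify",
]

MALE_GROUPS = ("PM", "EM", "MM", "LM")
FEMALE_GROUPS = ("EF", "MF", "LF")


@dataclass
class ClassifierParams:
    """Cascade thresholds; defaults mirror the published analysis."""

    L: float = 2.0  # logFC threshold, strict >
    c1: float = 1.0  # pseudocount, light estimator
    c2: float = 8.0  # prior count, shrunken estimator
    T: float = 1000.0  # male total normalized-count filter, strict >
    q: float = 0.20  # top fraction called strong
    male_groups: tuple[str, ...] = MALE_GROUPS
    female_groups: tuple[str, ...] = FEMALE_GROUPS

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("pseudocounts must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not (0 < self.q <= 1):
            raise ValueError("q must be in (0, 1]")
        if not self.male_groups or not self.female_groups:
            raise ValueError("male and female group sets must be non-empty")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    sf_j = median over genes i (with count > 0 in every sample) of
    k_ij / geomean_i(k_i.).  Raises when no gene is positive in all samples.
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "undefined (add a pseudocount or subset genes)"
        )
    logs = np.log(arr[all_pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts.div(sf.loc[counts.columns], axis=1)


def _group_columns(sheet: pd.Series, group: str) -> pd.Index:
    return sheet.index[sheet == group]


def _mean_over_groups(
    norm: pd.DataFrame, sheet: pd.Series, groups: tuple[str, ...]
) -> pd.Series:
    cols = sheet.index[sheet.isin(groups)]
    if len(cols) == 0:
        raise ValueError(f"no samples in groups {groups}")
    return norm[cols].mean(axis=1)


def group_summary(
    norm: pd.DataFrame,
    sheet: pd.Series,
    low_threshold: float = 5.0,
    pooled: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-gene median normalized count within each group.

    Columns: median_<group> and low_<group> (strict median < low_threshold)
    for every group present in the sheet, plus median_/low_ columns for any
    requested pooled group (e.g. all male stages pooled).  Medians use the
    midpoint convention for even sample counts.
    """
    out = pd.DataFrame(index=norm.index)
    for group in pd.unique(sheet):
        cols = _group_columns(sheet, group)
        if len(cols) == 0:
            raise ValueError(f"empty group {group!r}")
        med = norm[cols].median(axis=1)
        out[f"median_{group}"] = med
        out[f"low_{group}"] = med < low_threshold
    if pooled:
        for name, groups in pooled.items():
            cols = sheet.index[sheet.isin(groups)]
            if len(cols) == 0:
                raise ValueError(f"pooled group {name!r} matches no samples")
            med = norm[cols].median(axis=1)
            out[f"median_{name}"] = med
            out[f"low_{name}"] = med < low_threshold
    return out


def log2_mf(
    norm: pd.DataFrame,
    sheet: pd.Series,
    c1: float = 1.0,
    male_groups: tuple[str, ...] = MALE_GROUPS,
    female_groups: tuple[str, ...] = FEMALE_GROUPS,
) -> pd.Series:
    """Per-gene log2((male mean + c1) / (female mean + c1)) of normalized
    counts, male/female means taken over the corresponding group samples."""
    m = _mean_over_groups(norm, sheet, male_groups)
    f = _mean_over_groups(norm, sheet, female_groups)
    ratio = np.log2((m + c1) / (f + c1))
    ratio.name = "log2_mf"
    return ratio


def classify_male_biased(
    norm: pd.DataFrame, sheet: pd.Series, params: ClassifierParams | None = None
) -> pd.DataFrame:
    """Run the strongly-male-biased cascade on normalized counts.

    Returns a DataFrame indexed by gene id with columns logfc_a, logfc_b,
    candidate, male_total, passes_filter, rank_score and strong.  The strong
    set has exactly ceil(q * #passing-candidates) members.
    """
    p = params if params is not None else ClassifierParams()
    m = _mean_over_groups(norm, sheet, p.male_groups)
    f = _mean_over_groups(norm, sheet, p.female_groups)
    logfc_a = np.log2((m + p.c1) / (f + p.c1))
    logfc_b = np.log2((m + p.c2) / (f + p.c2))
    candidate = (logfc_a > p.L) | (logfc_b > p.L)
    male_cols = sheet.index[sheet.isin(p.male_groups)]
    male_total = norm[male_cols].sum(axis=1)
    passes = candidate & (male_total > p.T)
    rank_score = np.maximum(logfc_a, logfc_b)

    res = pd.DataFrame(
        {
            "logfc_a": logfc_a,
            "logfc_b": logfc_b,
            "candidate": candidate,
            "male_total": male_total,
            "passes_filter": passes,
            "rank_score": rank_score,
            "strong": False,
        },
        index=norm.index,
    )
    n_pass = int(passes.sum())
    if n_pass > 0:
        k = math.ceil(p.q * n_pass)
        pool = res.loc[passes]
        # descending score; exact ties break to the smaller gene id
        order = np.lexsort((pool.index.to_numpy(), -pool["rank_score"].to_numpy()))
        pool = pool.iloc[order]
        res.loc[pool.index[:k], "strong"] = True
    return res


def embryo_classify(
    counts: pd.DataFrame,
    sheet: pd.Series,
    expressed_threshold: float = 1.0,
    high_threshold: float = 50.0,
) -> pd.DataFrame:
    """Pre- vs post-rearrangement embryo expression flags.

    Per gene: mean count in the pre_pgr and post_pgr sample groups;
    expressed_* when the mean is >= expressed_threshold (default 1),
    high_* when strictly > high_threshold (default 50).
    """
    pre_cols = _group_columns(sheet, "pre_pgr")
    post_cols = _group_columns(sheet, "post_pgr")
    if len(pre_cols) == 0 or len(post_cols) == 0:
        raise ValueError("both pre_pgr and post_pgr groups must be present")
    mean_pre = counts[pre_cols].mean(axis=1)
    mean_post = counts[post_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_pre": mean_pre,
            "mean_post": mean_post,
            "expressed_pre": mean_pre >= expressed_threshold,
            "expressed_post": mean_post >= expressed_threshold,
            "high_pre": mean_pre > high_threshold,
            "high_post": mean_post > high_threshold,
        },
        index=counts.index,
    )
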
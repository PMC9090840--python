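"""Contingency and distributional statistics for the compartment analysis.

The headline statistic is the sample odds ratio of strong male bias between
the germline-restricted and somatic gene sets, with a two-sided Fisher exact
p-value computed in log space (so astronomically small p-values keep a
finite log10).  The two-sided rule is the usual "probabilities at most that
of the observed table" convention, with the same 1 + 1e-7 relative tie
tolerance R uses.

The published repeated-measures mixed model comparing stage-expression
profiles between genomes is replaced by a distribution-free permutation test
on the same response (per-gene stage proportions), Benjamini–Hochberg
adjusted across stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import gaussian_kde
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OddsRatioResult",
    "DistSummary",
    "fisher_or",
    "stage_proportions",
    "genome_stage_comparison",
    "mf_distribution",
    "STAGE_POOLS",
]

# stage pools for the proportion analysis: each male stage separately,
# all female stages pooled
STAGE_POOLS: dict[str, tuple[str, ...]] = {
    "PM": ("PM",),
    "EM": ("EM",),
    "MM": ("MM",),
    "LM": ("LM",),
    "Fem": ("EF", "MF", "LF"),
}

_TIE_TOL = np.log(1 + 1e-7)


@dataclass(frozen=True)
class OddsRatioResult:
    """Sample odds ratio (a/b)/(c/d) and two-sided Fisher exact p."""

    table: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    log10_p: float


@dataclass(frozen=True)
class DistSummary:
    """KDE summary of a set of per-gene log2 M:F values."""

    n: int
    grid: np.ndarray
    density: np.ndarray
    mode: float
    bandwidth: float


_LOGFACT = gammaln(np.arange(2049, dtype=float))  # log((i-1)!) at index i


def _logfact(n: int) -> np.ndarray:
    """log k! for k = 0..n, cached and grown on demand."""
    global _LOGFACT
    if n + 1 >= _LOGFACT.size:
        _LOGFACT = gammaln(np.arange(2 * (n + 2), dtype=float))
    return _LOGFACT


def _log_binom(n, k, lf):
    return lf[n + 1] - lf[np.asarray(k) + 1] - lf[n - np.asarray(k) + 1]


def _lse(x: np.ndarray) -> float:
    """log(sum(exp(x))) with max-shift; inlined for per-table speed."""
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def fisher_or(a: int, b: int, c: int, d: int, method: str = "prob") -> OddsRatioResult:
    """Fisher exact test and sample odds ratio for the 2x2 table
    [[a, b], [c, d]].

    method 'prob' (default): two-sided p sums hypergeometric probabilities,
    with margins fixed, of every table at most as probable as the observed
    one.  method 'doubled': twice the smaller one-sided tail, capped at 1.
    The odds ratio is the sample (a*d)/(b*c), reported as inf when b*c = 0
    and a*d > 0, and nan for the doubly degenerate 0/0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    n = r1 + r2

    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    lf = _logfact(n)
    logpmf = (
        _log_binom(r1, ks, lf)
        + _log_binom(r2, c1 - ks, lf)
        - _log_binom(n, c1, lf)
    )
    log_obs = logpmf[a - lo]
    if method == "prob":
        sel = logpmf <= log_obs + _TIE_TOL
    elif method == "doubled":
        lower = logsumexp(logpmf[ks <= a])
        upper = logsumexp(logpmf[ks >= a])
        log_p = min(np.log(2) + min(lower, upper), 0.0)
        return OddsRatioResult(
            (a, b, c, d), odds, float(np.exp(log_p)), float(log_p / np.log(10))
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    # normalize in log space so rounding in the pmf cancels; keeping the
    # sums in log space preserves a finite log10_p for astronomically
    # small p-values
    log_p = min(_lse(logpmf[sel]) - _lse(logpmf), 0.0)
    return OddsRatioResult(
        (a, b, c, d), odds, float(np.exp(log_p)), float(log_p / np.log(10))
    )


def stage_proportions(
    norm: pd.DataFrame,
    sheet: pd.Series,
    genes: pd.Index | None = None,
    pools: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-gene proportion of summed normalized counts in each stage pool.

    For gene g and pool P, p_g(P) = sum of normalized counts of g over P's
    samples divided by the sum over all pools.  Genes with a zero grand
    total are dropped; their count is returned alongside the table.
    """
    if pools is None:
        pools = STAGE_POOLS
    sub = norm if genes is None else norm.loc[norm.index.intersection(genes)]
    if sub.shape[0] == 0:
        raise ValueError("gene subset is empty")
    sums = {}
    for name, groups in pools.items():
        cols = sheet.index[sheet.isin(groups)]
        if len(cols) == 0:
            raise ValueError(f"stage pool {name!r} matches no samples")
        sums[name] = sub[cols].sum(axis=1)
    pooled = pd.DataFrame(sums)
    total = pooled.sum(axis=1)
    nonzero = total > 0
    n_dropped = int((~nonzero).sum())
    props = pooled.loc[nonzero].div(total.loc[nonzero], axis=0)
    return props, n_dropped


def genome_stage_comparison(
    props: pd.DataFrame,
    compartments: pd.Series,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> dict:
    """Permutation comparison of mean stage proportions between compartments.

    Per stage, the statistic is |mean proportion over GSR genes - mean over
    somatic genes|; the null is built from n_perm seeded shuffles of the
    compartment labels across genes; p = (1 + #{perm >= obs}) / (n_perm + 1),
    Benjamini-Hochberg adjusted across the stages.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    warnings: list[str] = []
    if n_perm < 100:
        warnings.append(f"n_perm={n_perm} is below 100; p-values are coarse")
    comp = compartments.loc[props.index]
    is_gsr = (comp == "GSR").to_numpy()
    n_gsr = int(is_gsr.sum())
    n_tot = len(comp)
    if n_gsr == 0 or n_gsr == n_tot:
        raise ValueError("both compartments must be represented")
    X = props.to_numpy(dtype=float)
    col_sum = X.sum(axis=0)

    def stat(mask: np.ndarray) -> np.ndarray:
        g = X[mask].sum(axis=0) / mask.sum()
        s = (col_sum - X[mask].sum(axis=0)) / (n_tot - mask.sum())
        return np.abs(g - s)

    obs = stat(is_gsr)
    count = np.zeros_like(obs)
    mask = is_gsr.copy()
    for _ in range(n_perm):
        rng.shuffle(mask)
        count += stat(mask) >= obs
    p_raw = (1 + count) / (n_perm + 1)
    _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    stages = list(props.columns)
    return {
        "stages": stages,
        "observed": dict(zip(stages, obs.tolist())),
        "p_raw": dict(zip(stages, p_raw.tolist())),
        "p_adjusted": dict(zip(stages, p_adj.tolist())),
        "significant": dict(zip(stages, (p_adj < alpha).tolist())),
        "n_perm": n_perm,
        "alpha": alpha,
        "warnings": warnings,
    }


def _silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * n ** (-1 / 5)


def mf_distribution(values: pd.Series | np.ndarray, n_grid: int = 512) -> DistSummary:
    """Gaussian-KDE summary (Silverman bandwidth) of log2 M:F values.

    The mode is the argmax of the density on an n_grid-point grid spanning
    the observed data range.  Degenerate input (all values equal) returns
    that value as the mode with zero bandwidth.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite values")
    bw = _silverman_bandwidth(vals)
    if bw == 0.0:  # all values identical
        v = float(vals[0])
        grid = np.full(n_grid, v)
        dens = np.zeros(n_grid)
        dens[0] = 1.0
        return DistSummary(vals.size, grid, dens, v, 0.0)
    grid = np.linspace(vals.min(), vals.max(), n_grid)
    kde = gaussian_kde(vals, bw_method=bw / np.std(vals, ddof=1))
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    return DistSummary(vals.size, grid, density, mode, bw)
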
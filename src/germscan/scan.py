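"""Differential-coverage scan for germline-restricted regions.

Given per-base depth for a germline sample (sperm) and a somatic sample
(blood), the scan

1. standardizes the two libraries by the genome-wide ratio of mean depths
   over *valid* bases (the adjustment factor, AFR);
2. tiles each sequence into intervals holding an equal number of valid bases
   (equal information per interval);
3. scores each interval E = log2((d1 + psi) / (AFR * (d2 + psi))), where d1,
   d2 are mean sperm/blood depth over the interval's valid bases and psi is a
   small pseudodepth that keeps E finite when blood depth is zero;
4. segments each sequence's interval-score series by recursive binary
   segmentation with a permutation acceptance test;
5. calls segments with mean score strictly above a threshold tau (default 2,
   i.e. >4-fold standardized enrichment) as germline-enriched, and labels
   whole sequences germline / somatic / mixed.

A base is *valid* when its depth is >= dmin in at least one sample and
<= dmax in both (dmax guards collapsed repeats; None disables the cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import DepthTrack, SeqDict

__all__ = [
    "ScanParams",
    "ScanInterval",
    "Segment",
    "compute_afr",
    "valid_mask",
    "make_intervals",
    "enrichment_score",
    "segment",
    "call_enriched",
    "classify_sequences",
]


@dataclass
class ScanParams:
    """Tuning parameters for the coverage scan.

    V: valid bases per interval. dmin/dmax: per-base validity bounds.
    psi: pseudodepth added to both interval means (default 1/V).
    tau: enrichment threshold, strict >. alpha / min_width / n_perm: binary
    segmentation acceptance level, minimum segment width in intervals, and
    permutation count. seed feeds the segmentation permutation stream.
    """

    V: int = 1000
    dmin: int = 1
    dmax: int | None = None
    psi: float | None = None
    tau: float = 2.0
    alpha: float = 0.01
    min_width: int = 2
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V < 10:
            raise ValueError("V must be >= 10")
        if self.dmin < 0:
            raise ValueError("dmin must be >= 0")
        if self.dmax is not None and self.dmax < self.dmin:
            raise ValueError("dmax must be >= dmin")
        if self.psi is not None and self.psi <= 0:
            raise ValueError("psi must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @property
    def pseudodepth(self) -> float:
        return self.psi if self.psi is not None else 1.0 / self.V


@dataclass(frozen=True)
class ScanInterval:
    seq: str
    start: int
    end: int
    n_valid: int
    d1: float
    d2: float
    score: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("interval start must be < end")
        if self.n_valid > self.end - self.start:
            raise ValueError("n_valid exceeds interval width")
        if not np.isfinite(self.score):
            raise ValueError("interval score must be finite")


@dataclass(frozen=True)
class Segment:
    seq: str
    start: int
    end: int
    n_intervals: int
    score: float
    enriched: bool


def valid_mask(sperm: np.ndarray, blood: np.ndarray, params: ScanParams) -> np.ndarray:
    """Boolean mask of valid bases for one sequence."""
    m = (sperm >= params.dmin) | (blood >= params.dmin)
    if params.dmax is not None:
        m &= (sperm <= params.dmax) & (blood <= params.dmax)
    return m


def compute_afr(sperm: DepthTrack, blood: DepthTrack, params: ScanParams) -> float:
    """Genome-wide adjustment factor: mean sperm depth / mean blood depth
    over valid bases."""
    if sperm.seqdict != blood.seqdict:
        raise ValueError("tracks are on different SeqDicts")
    s_sum = b_sum = 0.0
    n = 0
    for name in sperm.seqdict:
        m = valid_mask(sperm[name], blood[name], params)
        s_sum += float(sperm[name][m].sum())
        b_sum += float(blood[name][m].sum())
        n += int(m.sum())
    if n == 0:
        raise ValueError("no valid bases genome-wide; cannot standardize")
    if b_sum == 0:
        raise ValueError("zero valid blood coverage genome-wide; cannot standardize")
    return (s_sum / n) / (b_sum / n)


def enrichment_score(
    d1: float | np.ndarray, d2: float | np.ndarray, afr: float, psi: float
) -> float | np.ndarray:
    """E = log2((d1 + psi) / (AFR * (d2 + psi))); finite for all inputs
    including d2 = 0 since psi > 0."""
    return np.log2((np.asarray(d1, dtype=float) + psi) / (afr * (np.asarray(d2, dtype=float) + psi)))


def make_intervals(
    sperm: DepthTrack, blood: DepthTrack, params: ScanParams, afr: float | None = None
) -> list[ScanInterval]:
    """Tile each sequence into intervals of V valid bases.

    A linear pass accumulates valid bases; an interval closes at its V-th
    valid base.  A trailing partial interval is kept when it holds >= V/2
    valid bases, merged into the previous interval otherwise (or kept alone
    when it is the only one).  d1/d2 are means over valid bases only.
    Sequences with zero valid bases yield no intervals.
    """
    if afr is None:
        afr = compute_afr(sperm, blood, params)
    psi = params.pseudodepth
    V = params.V
    out: list[ScanInterval] = []
    for name in sperm.seqdict:
        s, b = sperm[name], blood[name]
        idx = np.flatnonzero(valid_mask(s, b, params))
        n = idx.size
        if n == 0:
            continue
        n_full = n // V
        rem = n - n_full * V
        if n_full == 0:
            bounds = [n]  # single partial interval, kept alone
        elif rem >= V / 2:
            bounds = [V * (k + 1) for k in range(n_full)] + [n]
        else:
            bounds = [V * (k + 1) for k in range(n_full - 1)] + [n]  # merge trailing
        offsets = np.concatenate(([0], np.asarray(bounds[:-1], dtype=np.int64)))
        s_sums = np.add.reduceat(s[idx].astype(np.float64), offsets)
        b_sums = np.add.reduceat(b[idx].astype(np.float64), offsets)
        prev_end = int(idx[0])  # first interval starts at first valid base
        for k, bound in enumerate(bounds):
            lo = 0 if k == 0 else bounds[k - 1]
            nv = bound - lo
            start = prev_end
            end = int(idx[bound - 1]) + 1
            d1 = float(s_sums[k]) / nv
            d2 = float(b_sums[k]) / nv
            out.append(
                ScanInterval(
                    seq=name,
                    start=start,
                    end=end,
                    n_valid=nv,
                    d1=d1,
                    d2=d2,
                    score=float(enrichment_score(d1, d2, afr, psi)),
                )
            )
            prev_end = end
    return out


# ---------------------------------------------------------------------------
# binary segmentation


def _split_t_stats(x: np.ndarray, min_width: int) -> np.ndarray:
    """|two-sample t| for every split k (left = x[:k]) with
    min_width <= k <= n - min_width; -inf outside that range.

    Zero pooled variance with unequal means gives +inf (a perfect step);
    with equal means, 0.
    """
    n = x.size
    t = np.full(n + 1, -np.inf)
    if n < 2 * min_width:
        return t
    ks = np.arange(min_width, n - min_width + 1)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    tot, tot2 = cs[-1], css[-1]
    nl = ks.astype(float)
    nr = n - nl
    ml = cs[ks - 1] / nl
    mr = (tot - cs[ks - 1]) / nr
    ssl = css[ks - 1] - nl * ml * ml
    ssr = (tot2 - css[ks - 1]) - nr * mr * mr
    sp2 = np.maximum(ssl + ssr, 0.0) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / nl + 1.0 / nr))
    diff = np.abs(ml - mr)
    with np.errstate(divide="ignore", invalid="ignore"):
        tk = diff / se
    tk[(se == 0) & (diff > 0)] = np.inf
    tk[(se == 0) & (diff == 0)] = 0.0
    t[ks] = tk
    return t


def _best_split(x: np.ndarray, min_width: int) -> tuple[int, float]:
    t = _split_t_stats(x, min_width)
    k = int(np.argmax(t))
    return k, float(t[k])


def _max_t_rows(mat: np.ndarray, min_width: int) -> np.ndarray:
    """Row-wise max split t over a matrix of series (vectorized permutations)."""
    n_rows, n = mat.shape
    if n < 2 * min_width:
        return np.zeros(n_rows)
    ks = np.arange(min_width, n - min_width + 1)
    cs = np.cumsum(mat, axis=1)
    css = np.cumsum(mat * mat, axis=1)
    tot = cs[:, -1:]
    tot2 = css[:, -1:]
    nl = ks.astype(float)
    nr = n - nl
    csk = cs[:, ks - 1]
    cssk = css[:, ks - 1]
    ml = csk / nl
    mr = (tot - csk) / nr
    ssl = cssk - nl * ml * ml
    ssr = (tot2 - cssk) - nr * mr * mr
    sp2 = np.maximum(ssl + ssr, 0.0) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / nl + 1.0 / nr))
    diff = np.abs(ml - mr)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff > 0)] = np.inf
    t[(se == 0) & (diff == 0)] = 0.0
    return t.max(axis=1)


def _perm_pvalue(
    x: np.ndarray, t_obs: float, min_width: int, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p for the best-split statistic: shuffle the series,
    recompute the best split each time; p = (1 + #{perm >= obs}) / (n_perm + 1)."""
    n = x.size
    count = 0
    block = max(1, int(5_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        mat = np.broadcast_to(x, (b, n)).copy()
        mat = rng.permuted(mat, axis=1)
        count += int(np.sum(_max_t_rows(mat, min_width) >= t_obs))
        done += b
    return (1 + count) / (n_perm + 1)


def _binseg(
    x: np.ndarray, params: ScanParams, rng: np.random.Generator, lo: int, cuts: list[int]
) -> None:
    n = x.size
    if n < 2 * params.min_width:
        return
    if np.all(x == x[0]):
        return
    k, t_obs = _best_split(x, params.min_width)
    if not np.isfinite(t_obs) and t_obs < 0:
        return
    p = _perm_pvalue(x, t_obs, params.min_width, params.n_perm, rng)
    if p >= params.alpha:
        return
    cuts.append(lo + k)
    _binseg(x[:k], params, rng, lo, cuts)
    _binseg(x[k:], params, rng, lo + k, cuts)


def segment(
    intervals: Sequence[ScanInterval], params: ScanParams, rng: np.random.Generator | None = None
) -> list[Segment]:
    """Recursive binary segmentation of each sequence's interval-score series.

    At each step the split maximizing the two-sample t statistic is accepted
    when its permutation p-value is below alpha and both sides hold at least
    min_width intervals.  Segment score = mean member score; segments tile
    exactly the union of each sequence's intervals, in order.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    out: list[Segment] = []
    by_seq: dict[str, list[ScanInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq, []).append(iv)
    for name, ivs in by_seq.items():
        x = np.array([iv.score for iv in ivs], dtype=float)
        cuts: list[int] = []
        _binseg(x, params, rng, 0, cuts)
        bounds = [0] + sorted(cuts) + [len(ivs)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            score = float(x[a:b].mean())
            out.append(
                Segment(
                    seq=name,
                    start=ivs[a].start,
                    end=ivs[b - 1].end,
                    n_intervals=b - a,
                    score=score,
                    enriched=score > params.tau,
                )
            )
    return out


def call_enriched(segments: Sequence[Segment], tau: float) -> tuple[list[Segment], int]:
    """Segments with mean score strictly above tau, plus their total span."""
    enriched = [
        Segment(s.seq, s.start, s.end, s.n_intervals, s.score, True)
        for s in segments
        if s.score > tau
    ]
    span = sum(s.end - s.start for s in enriched)
    return enriched, span


def classify_sequences(
    segments: Sequence[Segment],
    seqdict: SeqDict,
    tau: float,
    germline_min_frac: float = 0.5,
    mixed_max_frac: float = 0.2,
) -> dict[str, str]:
    """Label each sequence germline / somatic / mixed.

    germline: >= germline_min_frac of the sequence's interval-covered bases
    lie in enriched segments AND no single non-enriched segment covers
    >= mixed_max_frac of them.  somatic: zero enriched bases (including
    sequences with no intervals at all).  mixed: anything else — a violation
    of whole-sequence elimination.
    """
    cover: dict[str, int] = {name: 0 for name in seqdict}
    enr: dict[str, int] = {name: 0 for name in seqdict}
    max_non: dict[str, int] = {name: 0 for name in seqdict}
    for s in segments:
        width = s.end - s.start
        cover[s.seq] += width
        if s.score > tau:
            enr[s.seq] += width
        else:
            max_non[s.seq] = max(max_non[s.seq], width)
    labels: dict[str, str] = {}
    for name in seqdict:
        if enr[name] == 0:
            labels[name] = "somatic"
        elif (
            enr[name] / cover[name] >= germline_min_frac
            and max_non[name] / cover[name] < mixed_max_frac
        ):
            labels[name] = "germline"
        else:
            labels[name] = "mixed"
    return labels
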
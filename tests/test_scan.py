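"""Coverage-scan unit and property tests.

Segmentation is checked against an exhaustive-search oracle that tries every
split point with the same acceptance rule; interval construction is checked
against hand-traced examples of the valid-base accumulation rule.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germscan._rng import substream
from germscan.formats import DepthTrack, SeqDict
from germscan.scan import (
    ScanParams,
    Segment,
    call_enriched,
    classify_sequences,
    compute_afr,
    enrichment_score,
    make_intervals,
    segment,
)
from germscan.scan import _best_split, _perm_pvalue  # white-box oracle hooks


def _tracks(sperm: dict[str, list[int]], blood: dict[str, list[int]]) -> tuple:
    sd = SeqDict({k: len(v) for k, v in sperm.items()})
    return (
        DepthTrack("sperm", sd, {k: np.array(v, dtype=np.int64) for k, v in sperm.items()}),
        DepthTrack("blood", sd, {k: np.array(v, dtype=np.int64) for k, v in blood.items()}),
    )


class TestAfr:
    def test_identical_tracks_give_one(self):
        s, b = _tracks({"c": [5] * 100}, {"c": [5] * 100})
        assert compute_afr(s, b, ScanParams(V=10)) == pytest.approx(1.0)

    def test_doubled_sperm_gives_two(self):
        s, b = _tracks({"c": [10] * 50}, {"c": [5] * 50})
        assert compute_afr(s, b, ScanParams(V=10)) == pytest.approx(2.0)

    def test_all_zero_blood_errors(self):
        s, b = _tracks({"c": [10] * 50}, {"c": [0] * 50})
        with pytest.raises(ValueError, match="blood"):
            compute_afr(s, b, ScanParams(V=10))


class TestEnrichmentScore:
    def test_symmetry_zero(self):
        assert enrichment_score(30, 30, 1.0, 1e-3) == pytest.approx(0.0)

    def test_fourfold_is_two(self):
        # 40 vs 10 with vanishing pseudodepth -> log2(4) = 2 exactly
        assert enrichment_score(40, 10, 1.0, 1e-12) == pytest.approx(2.0, abs=1e-9)

    def test_zero_blood_finite(self):
        e = enrichment_score(40, 0, 1.0, 0.001)
        assert e == pytest.approx(np.log2(40.001 / 0.001), abs=1e-9)
        assert e == pytest.approx(15.29, abs=0.01)

    def test_track_swap_negates_score(self):
        # E(d1,d2 | AFR) = -E(d2,d1 | 1/AFR) exactly as psi -> 0
        rng = np.random.default_rng(5)
        d1, d2 = rng.uniform(1, 100, 50), rng.uniform(1, 100, 50)
        afr = d1.mean() / d2.mean()
        e_fwd = enrichment_score(d1, d2, afr, 1e-12)
        e_rev = enrichment_score(d2, d1, 1 / afr, 1e-12)
        np.testing.assert_allclose(e_fwd, -e_rev, atol=1e-6)


class TestMakeIntervals:
    def test_uniform_exact_tiling(self):
        s, b = _tracks({"c": [10] * 10}, {"c": [10] * 10})
        ivs = make_intervals(s, b, ScanParams(V=10, dmin=1), afr=1.0)
        # length 10 is a single interval at V=10; use V via params override
        assert [(iv.start, iv.end) for iv in ivs] == [(0, 10)]

    def test_trailing_short_merged(self):
        # 12 valid bases, V=10: trailing 2 < V/2 merges into the previous
        s, b = _tracks({"c": [10] * 12}, {"c": [10] * 12})
        ivs = make_intervals(s, b, ScanParams(V=10), afr=1.0)
        assert [(iv.start, iv.end, iv.n_valid) for iv in ivs] == [(0, 12, 12)]

    def test_trailing_half_kept(self):
        # 15 valid bases, V=10: trailing 5 >= V/2 stays its own interval
        s, b = _tracks({"c": [10] * 15}, {"c": [10] * 15})
        ivs = make_intervals(s, b, ScanParams(V=10), afr=1.0)
        assert [(iv.start, iv.end, iv.n_valid) for iv in ivs] == [
            (0, 10, 10),
            (10, 15, 5),
        ]

    def test_invalid_bases_stretch_interval(self):
        # hand trace: V=10, bases 8..9 invalid (0 depth both samples)
        depths = [7] * 8 + [0, 0] + [7] * 12
        s, b = _tracks({"c": depths}, {"c": depths})
        ivs = make_intervals(s, b, ScanParams(V=10), afr=1.0)
        assert (ivs[0].start, ivs[0].end, ivs[0].n_valid) == (0, 12, 10)
        assert (ivs[1].start, ivs[1].end, ivs[1].n_valid) == (12, 22, 10)

    def test_zero_valid_sequence_yields_nothing(self):
        s, b = _tracks({"c": [0] * 30}, {"c": [0] * 30})
        assert make_intervals(s, b, ScanParams(V=10), afr=1.0) == []

    def test_means_over_valid_bases_only(self):
        sperm = [20] * 8 + [0, 0] + [20] * 2
        blood = [5] * 8 + [0, 0] + [5] * 2
        s, b = _tracks({"c": sperm}, {"c": blood})
        (iv,) = make_intervals(s, b, ScanParams(V=10), afr=1.0)
        assert iv.d1 == pytest.approx(20.0)
        assert iv.d2 == pytest.approx(5.0)

    @settings(max_examples=30, deadline=None)
    @given(
        depths=st.lists(st.integers(0, 40), min_size=30, max_size=200),
        v=st.sampled_from([10, 15]),
    )
    def test_tiling_invariants(self, depths, v):
        """Intervals are disjoint, ordered, and their valid-base counts sum
        to the sequence's total valid bases."""
        s, b = _tracks({"c": depths}, {"c": depths})
        params = ScanParams(V=v)
        ivs = make_intervals(s, b, params, afr=1.0)
        n_valid_total = int(np.sum(np.array(depths) >= 1))
        assert sum(iv.n_valid for iv in ivs) == n_valid_total
        for a, c in zip(ivs, ivs[1:]):
            assert a.end == c.start  # tile without gaps inside covered span
        if ivs:
            assert all(
                iv.n_valid >= min(v // 2, n_valid_total) or len(ivs) == 1 for iv in ivs
            )


def _oracle_binseg(x, params, rng):
    """Exhaustive-split oracle: same statistic and acceptance rule, but the
    split search enumerates every candidate explicitly."""
    cuts = []

    def rec(lo, hi):
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * params.min_width or np.all(seg == seg[0]):
            return
        best_t, best_k = -np.inf, None
        for k in range(params.min_width, n - params.min_width + 1):
            left, right = seg[:k], seg[k:]
            ml, mr = left.mean(), right.mean()
            ss = ((left - ml) ** 2).sum() + ((right - mr) ** 2).sum()
            sp2 = ss / (n - 2)
            se = np.sqrt(sp2 * (1 / k + 1 / (n - k)))
            if se == 0:
                t = np.inf if ml != mr else 0.0
            else:
                t = abs(ml - mr) / se
            if t > best_t:
                best_t, best_k = t, k
        p = _perm_pvalue(seg, best_t, params.min_width, params.n_perm, rng)
        if p < params.alpha:
            cuts.append(lo + best_k)
            rec(lo, lo + best_k)
            rec(lo + best_k, hi)

    rec(0, len(x))
    return sorted(cuts)


class TestSegmentation:
    def _segment_scores(self, series, params, seed=0):
        sd = SeqDict({"c": len(series) * params.V})
        ivs = []
        from germscan.scan import ScanInterval

        for i, e in enumerate(series):
            ivs.append(
                ScanInterval("c", i * params.V, (i + 1) * params.V, params.V, 1.0, 1.0, e)
            )
        return segment(ivs, params, rng=substream(seed, "segmentation"))

    def test_constant_series_one_segment(self):
        params = ScanParams(V=10, n_perm=200)
        segs = self._segment_scores([1.5] * 30, params)
        assert len(segs) == 1
        assert segs[0].score == pytest.approx(1.5)

    def test_noiseless_step_recovers_boundary(self):
        params = ScanParams(V=10, n_perm=500)
        series = [0.0] * 20 + [3.0] * 20
        segs = self._segment_scores(series, params)
        assert [(s.n_intervals, s.score) for s in segs] == [(20, 0.0), (20, 3.0)]
        assert segs[0].end == segs[1].start == 200

    def test_short_series_never_split(self):
        params = ScanParams(V=10, min_width=2, n_perm=200)
        segs = self._segment_scores([0.0, 5.0, 0.0], params)
        assert len(segs) == 1

    def test_matches_exhaustive_oracle(self):
        """Binary segmentation cut set equals the exhaustive-split oracle on
        noisy series of up to 50 intervals."""
        params = ScanParams(V=10, n_perm=300)
        gen = np.random.default_rng(42)
        for trial in range(6):
            n1, n2 = gen.integers(5, 25), gen.integers(5, 25)
            x = np.concatenate(
                [gen.normal(0, 0.3, n1), gen.normal(3, 0.3, n2)]
            )
            segs = self._segment_scores(list(x), params, seed=trial)
            bounds = np.cumsum([s.n_intervals for s in segs])[:-1].tolist()
            oracle = _oracle_binseg(x, params, substream(trial, "segmentation"))
            assert bounds == oracle

    def test_deterministic_for_fixed_seed(self):
        params = ScanParams(V=10, n_perm=300)
        x = list(np.random.default_rng(3).normal(0, 1, 40))
        a = self._segment_scores(x, params, seed=9)
        b = self._segment_scores(x, params, seed=9)
        assert a == b


class TestCallEnriched:
    def _seg(self, score):
        return Segment("c", 0, 100, 1, score, score > 2)

    def test_strict_threshold(self):
        segs = [self._seg(1.9), self._seg(2.0), self._seg(2.5)]
        enriched, span = call_enriched(segs, 2.0)
        assert [s.score for s in enriched] == [2.5]
        assert span == 100

    def test_minus_infinity_keeps_all(self):
        segs = [self._seg(-3.0), self._seg(0.0)]
        enriched, _ = call_enriched(segs, -np.inf)
        assert len(enriched) == 2

    def test_empty_input(self):
        assert call_enriched([], 2.0) == ([], 0)

    @settings(max_examples=30, deadline=None)
    @given(
        scores=st.lists(st.floats(-5, 5, allow_nan=False), max_size=20),
        taus=st.tuples(st.floats(-4, 4), st.floats(-4, 4)),
    )
    def test_span_monotone_in_tau(self, scores, taus):
        segs = [Segment("c", i * 10, (i + 1) * 10, 1, sc, False) for i, sc in enumerate(scores)]
        lo, hi = min(taus), max(taus)
        _, span_lo = call_enriched(segs, lo)
        _, span_hi = call_enriched(segs, hi)
        assert span_hi <= span_lo


class TestClassifySequences:
    def _mk(self, spans):
        # spans: list of (start, end, score)
        return [Segment("c", s, e, 1, sc, sc > 2) for s, e, sc in spans]

    def test_all_enriched_is_germline(self):
        sd = SeqDict({"c": 1000})
        labels = classify_sequences(self._mk([(0, 500, 5.0), (500, 1000, 4.0)]), sd, 2.0)
        assert labels["c"] == "germline"

    def test_none_enriched_is_somatic(self):
        sd = SeqDict({"c": 1000})
        labels = classify_sequences(self._mk([(0, 1000, 0.2)]), sd, 2.0)
        assert labels["c"] == "somatic"

    def test_no_intervals_is_somatic(self):
        sd = SeqDict({"c": 1000})
        assert classify_sequences([], sd, 2.0)["c"] == "somatic"

    def test_60_40_split_is_mixed(self):
        sd = SeqDict({"c": 1000})
        labels = classify_sequences(
            self._mk([(0, 600, 5.0), (600, 1000, 0.0)]), sd, 2.0
        )
        assert labels["c"] == "mixed"

    def test_small_cold_segment_tolerated(self):
        sd = SeqDict({"c": 1000})
        labels = classify_sequences(
            self._mk([(0, 900, 5.0), (900, 1000, 1.0)]), sd, 2.0
        )
        assert labels["c"] == "germline"
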
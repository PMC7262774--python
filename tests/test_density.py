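"""Sliding-window density statistic: oracles, suppression, classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icrscan import (
    AMBIGUOUS,
    ROBUST,
    ScanParams,
    Site,
    call_peaks,
    classify_peak,
    collapse_sites,
    window_counts,
)

W = 850


def sites_at(starts, chrom="chr", length=6):
    return [Site(chrom, s, s + length) for s in sorted(starts)]


def brute_window_counts(starts, window, hi=None):
    """All-anchor evaluation via numpy searchsorted (independent oracle)."""
    starts = np.sort(np.asarray(starts))
    hi = (hi or starts.max()) + 1
    anchors = np.arange(0, hi)
    counts = np.searchsorted(starts, anchors + window, side="left") - np.searchsorted(
        starts, anchors, side="left"
    )
    counts[counts <= 1] = 0  # isolated occurrences are background noise
    return counts


def brute_call_peaks(starts, params):
    """Definition-level peak caller: explicit chaining + anchor sweep."""
    starts = sorted(starts)
    clusters, cur = [], [starts[0]]
    for s in starts[1:]:
        if s - cur[-1] <= params.chain_gap:
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    out = []
    for c in clusters:
        if len(c) < params.min_cluster_count:
            continue
        mwc = max(
            sum(1 for s in c if x <= s < x + params.window_length)
            for x in range(c[0] - params.window_length, c[-1] + 1)
        )
        out.append((c[0], len(c), mwc, ROBUST if mwc >= params.robust_threshold else AMBIGUOUS))
    return out


def expand(runs, hi):
    dense = np.zeros(hi, dtype=int)
    for s, e, v in runs:
        dense[s : min(e, hi)] = v
    return dense


class TestCollapseSites:
    def test_overlapping_merged(self):
        merged = collapse_sites([Site("c", 10, 18), Site("c", 12, 20)])
        assert merged == [Site("c", 10, 20)]

    def test_disjoint_unchanged(self):
        sites = [Site("c", 0, 6), Site("c", 10, 16)]
        assert collapse_sites(sites) == sites

    def test_idempotent(self):
        sites = [Site("c", 0, 8), Site("c", 4, 12), Site("c", 30, 36)]
        once = collapse_sites(sites)
        assert collapse_sites(once) == once

    def test_disabled_is_identity(self):
        sites = [Site("c", 10, 18), Site("c", 12, 20)]
        assert collapse_sites(sites, enabled=False) == sites

    def test_per_chromosome(self):
        merged = collapse_sites([Site("a", 0, 10), Site("b", 5, 15)])
        assert len(merged) == 2


class TestWindowCounts:
    @pytest.mark.parametrize(
        "starts,expected_max",
        [([100, 500], 2), ([100, 2000], 0), ([0, 400, 800], 3)],
    )
    def test_examples_against_brute_force(self, starts, expected_max):
        runs = window_counts(sites_at(starts), ScanParams())
        hi = max(starts) + 2
        dense = expand(runs, hi)
        assert np.array_equal(dense, brute_window_counts(starts, W, hi=hi - 1))
        assert dense.max() == expected_max

    def test_isolated_pair_suppressed(self):
        assert window_counts(sites_at([100, 2000]), ScanParams()) == []

    def test_three_in_window_max_at_zero(self):
        runs = window_counts(sites_at([0, 400, 800]), ScanParams())
        assert expand(runs, 1)[0] == 3

    @given(
        st.lists(st.integers(0, 6000), min_size=1, max_size=40, unique=True),
        st.integers(50, 1200),
    )
    def test_property_matches_brute_force(self, starts, window):
        params = ScanParams(window_length=window)
        runs = window_counts(sites_at(starts, length=1), params)
        hi = max(starts) + 2
        assert np.array_equal(expand(runs, hi), brute_window_counts(starts, window, hi=hi - 1))

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="multiple chromosomes"):
            window_counts([Site("a", 0, 6), Site("b", 0, 6)], ScanParams())


class TestCallPeaks:
    def test_pair_plus_isolated(self):
        peaks = call_peaks(sites_at([100, 500, 2000]), ScanParams())
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.n_sites, p.max_window_count, p.peak_class) == (
            100, 2, 2, AMBIGUOUS,
        )

    def test_three_within_window_robust(self):
        (p,) = call_peaks(sites_at([0, 400, 800]), ScanParams())
        assert (p.n_sites, p.max_window_count, p.peak_class) == (3, 3, ROBUST)

    def test_chained_but_never_three_per_window(self):
        (p,) = call_peaks(sites_at([0, 800, 1600]), ScanParams())
        assert (p.n_sites, p.max_window_count, p.peak_class) == (3, 2, AMBIGUOUS)

    def test_span_is_first_start_to_last_end(self):
        (p,) = call_peaks(sites_at([0, 800, 1600], length=9), ScanParams())
        assert (p.start, p.end) == (0, 1609)

    def test_suppression_of_spread_sites(self):
        assert call_peaks(sites_at([0, 850, 1700, 2550]), ScanParams(chain_gap=849)) == []

    @given(st.lists(st.integers(0, 8000), min_size=1, max_size=60, unique=True))
    def test_property_matches_brute_force(self, starts):
        params = ScanParams()
        got = [
            (p.start, p.n_sites, p.max_window_count, p.peak_class)
            for p in call_peaks(sites_at(starts, length=1), params)
        ]
        assert got == brute_call_peaks(starts, params)

    @given(
        st.lists(st.integers(0, 8000), min_size=2, max_size=40, unique=True),
        st.integers(0, 8000),
    )
    def test_adding_a_site_is_monotone(self, starts, extra):
        params = ScanParams()
        before = call_peaks(sites_at(starts, length=1), params)
        after = call_peaks(sites_at(set(starts) | {extra}, length=1), params)
        # no peak vanishes: every old peak lies inside some new peak,
        # and robust peaks are never demoted
        for old in before:
            containing = [
                p for p in after if p.start <= old.start and old.end <= p.end
            ]
            assert containing
            if old.peak_class == ROBUST:
                assert containing[0].peak_class == ROBUST
        # window counts never decrease anywhere
        hi = max(starts + [extra]) + 2
        assert np.all(
            expand(window_counts(sites_at(set(starts) | {extra}, length=1), params), hi)
            >= expand(window_counts(sites_at(starts, length=1), params), hi)
        )

    def test_peaks_never_share_sites(self):
        peaks = call_peaks(sites_at([0, 100, 2000, 2100, 5000]), ScanParams())
        spans = [(p.chrom, p.start, p.end) for p in peaks]
        assert spans == sorted(spans)
        for (_, _, e1), (_, s2, _) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestClassifyAndParams:
    @pytest.mark.parametrize("mwc,expected", [(2, AMBIGUOUS), (3, ROBUST), (7, ROBUST)])
    def test_default_threshold(self, mwc, expected):
        assert classify_peak(mwc, ScanParams()) == expected

    @pytest.mark.parametrize("threshold", [3, 4, 6])
    def test_boundary_below_threshold(self, threshold):
        params = ScanParams(robust_threshold=threshold)
        assert classify_peak(threshold - 1, params) == AMBIGUOUS
        assert classify_peak(threshold, params) == ROBUST

    def test_defaults_match_method(self):
        p = ScanParams()
        assert (p.window_length, p.min_cluster_count, p.robust_threshold) == (850, 2, 3)
        assert p.chain_gap == 850

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_length": 0},
            {"min_cluster_count": 1},
            {"min_cluster_count": 4, "robust_threshold": 3},
            {"chain_gap": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScanParams(**kwargs)
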
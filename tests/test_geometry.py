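"""Circular-chromosome headful geometry against brute-force per-base oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ltmob import (
    AttBSite,
    CircularInterval,
    GenomicLocus,
    PHAGE_80ALPHA,
    PHAGE_P22,
    ProphageModel,
    directed_distance,
    format_headful_range,
    headful_index,
    headful_windows,
    locus_compatibility_table,
    locus_headful_range,
    lt_reach_span,
    polylysogen_coverage,
    reach_interval,
)
from ltmob.geometry import GeometryError

from _oracles import (
    per_base_coverage,
    per_base_headful,
    per_base_locus_range,
    walk_distance,
)

positions = st.integers(min_value=0, max_value=9999)
directions = st.sampled_from([+1, -1])


class TestDirectedDistance:
    @pytest.mark.parametrize(
        "a, b, direction, expected",
        [(100, 100, +1, 0), (100, 100, -1, 0), (100, 50, +1, 950), (100, 50, -1, 50)],
    )
    def test_examples(self, a, b, direction, expected):
        assert directed_distance(a, b, direction, 1000) == expected

    @pytest.mark.parametrize("direction", [+1, -1])
    def test_matches_base_by_base_walk(self, direction):
        L = 97
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b = int(rng.integers(L)), int(rng.integers(L))
            assert directed_distance(a, b, direction, L) == walk_distance(a, b, direction, L)

    @given(a=positions, b=positions, d=directions)
    def test_complementarity(self, a, b, d):
        L = 10_000
        total = directed_distance(a, b, d, L) + directed_distance(b, a, d, L)
        assert total in (0, L)

    def test_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            directed_distance(1000, 5, +1, 1000)


class TestHeadfulIndex:
    def test_locus_at_attb_is_hf1(self):
        site = AttBSite("sa7", 5000, +1)
        assert headful_index(site, 5000, PHAGE_80ALPHA, 3_000_000) == 1

    def test_marker_35kb_downstream_is_hf1(self):
        # cadmium cassette 35 kb downstream of the attB, 45 kb headful
        site = AttBSite("sa7", 100_000, +1)
        assert headful_index(site, 135_000, PHAGE_80ALPHA, 3_000_000) == 1

    def test_100kb_is_hf3(self):
        site = AttBSite("s", 0, +1)
        assert headful_index(site, 100_000, PHAGE_80ALPHA, 3_000_000) == 3

    def test_out_of_reach(self):
        site = AttBSite("s", 0, +1)
        assert headful_index(site, 320_000, PHAGE_80ALPHA, 3_000_000) is None

    @given(dist=st.integers(min_value=0, max_value=90_000))
    def test_monotone_and_increments_at_multiples_of_h(self, dist):
        L, H = 3_000_000, 45_000
        site = AttBSite("s", 0, +1)
        idx = headful_index(site, dist, PHAGE_80ALPHA, L)
        assert idx == dist // H + 1
        nxt = headful_index(site, dist + 1, PHAGE_80ALPHA, L)
        assert nxt >= idx
        if (dist + 1) % H != 0:
            assert nxt == idx


class TestHeadfulWindows:
    def test_single_window(self):
        model = ProphageModel("p", 5000, 1)
        site = AttBSite("s", 100, +1)
        (window,) = headful_windows(site, model, 100_000)
        assert (window.start, window.length) == (100, 5000)

    def test_80alpha_reach_is_315kb(self):
        site = AttBSite("s", 0, +1)
        windows = headful_windows(site, PHAGE_80ALPHA, 3_000_000)
        assert len(windows) == 7
        assert sum(w.length for w in windows) == 315_000

    @pytest.mark.parametrize("direction", [+1, -1])
    def test_windows_tile_reach_per_base(self, direction):
        L = 50_000
        model = ProphageModel("p", 7000, 4)
        site = AttBSite("s", 41_213, direction)
        windows = headful_windows(site, model, L)
        marks = np.zeros(L, dtype=int)
        for k, win in enumerate(windows, start=1):
            for s, e in win.segments():
                marks[s:e] += 1
        oracle = per_base_headful(site.position, direction, 7000, 4, L)
        assert np.array_equal(marks > 0, oracle > 0)  # same footprint
        assert marks.max() == 1  # no overlap
        # per-base window identity matches the headful index
        for k, win in enumerate(windows, start=1):
            for s, e in win.segments():
                assert np.all(oracle[s:e] == k)

    def test_truncation_beyond_full_circle_warns(self):
        site = AttBSite("s", 10, +1)
        with pytest.warns(UserWarning, match="truncat"):
            windows = headful_windows(site, ProphageModel("p", 6000, 9), 20_000)
        assert sum(w.length for w in windows) == 20_000


class TestReach:
    def test_spans(self):
        assert lt_reach_span(PHAGE_80ALPHA) == 315_000
        assert lt_reach_span(PHAGE_P22) == 516_000

    def test_degenerate_model_rejected(self):
        with pytest.raises(GeometryError):
            ProphageModel("bad", 45_000, 0)

    def test_direction_flip_mirrors_reach(self):
        L = 400_000
        model = ProphageModel("p", 10_000, 3)
        fwd = reach_interval(AttBSite("s", 150_000, +1), model, L)
        rev = reach_interval(AttBSite("s", 150_000, -1), model, L)
        # mirrored about the site: walk k forward in one equals k backward in the other
        fwd_set = {p for s, e in fwd.segments() for p in range(s, e)}
        mirrored = {(2 * 150_000 - p) % L for p in fwd_set}
        rev_set = {p for s, e in rev.segments() for p in range(s, e)}
        assert mirrored == rev_set


class TestCoverage:
    def test_single_site_fraction(self):
        sites = [AttBSite("s1", 0, +1)]
        summary = polylysogen_coverage(1_000_000, sites, {"s1": PHAGE_80ALPHA})
        assert summary.covered_bp == 315_000
        assert summary.fraction == pytest.approx(0.315)

    def test_two_sites_overlapping_by_one_headful(self):
        model = ProphageModel("p", 10_000, 3)  # reach 30 kb
        L = 200_000
        sites = [AttBSite("a", 0, +1), AttBSite("b", 20_000, +1)]
        summary = polylysogen_coverage(L, sites, {"a": model, "b": model})
        assert summary.covered_bp == 2 * 30_000 - 10_000
        oracle = per_base_coverage(sites, {"a": model, "b": model}, L)
        assert summary.covered_bp == int(oracle.sum())

    def test_saturation(self):
        model = ProphageModel("p", 10_000, 3)
        sites = [AttBSite("a", 0, +1), AttBSite("b", 25_000, +1)]
        summary = polylysogen_coverage(50_000, sites, {"a": model, "b": model})
        assert summary.fraction == 1.0

    def test_duplicate_site_rejected(self):
        sites = [AttBSite("a", 0, +1), AttBSite("a", 100, -1)]
        with pytest.raises(GeometryError, match="duplicate"):
            polylysogen_coverage(10_000, sites, {"a": ProphageModel("p", 100, 1)})

    def test_monotone_in_sites(self):
        L = 120_000
        model = ProphageModel("p", 9_000, 3)
        rng = np.random.default_rng(11)
        sites = [
            AttBSite(f"s{i}", int(rng.integers(L)), int(rng.choice([1, -1])))
            for i in range(6)
        ]
        models = {s.site_id: model for s in sites}
        prev = 0
        for k in range(1, len(sites) + 1):
            cov = polylysogen_coverage(L, sites[:k], models).covered_bp
            assert cov >= prev
            prev = cov

    def test_disjoint_reaches_additive(self):
        model = ProphageModel("p", 5_000, 2)  # reach 10 kb
        sites = [AttBSite("a", 0, +1), AttBSite("b", 50_000, +1)]
        summary = polylysogen_coverage(100_000, sites, {"a": model, "b": model})
        assert summary.covered_bp == 20_000


class TestCompatibility:
    def test_locus_inside_one_window(self):
        model = ProphageModel("p", 10_000, 7)
        L = 200_000
        site = AttBSite("s", 0, +1)
        locus = GenomicLocus("v", CircularInterval(21_000, 2_000, L))  # inside HF3
        assert locus_headful_range(site, locus, model, L) == (3, 3)
        assert format_headful_range((3, 3)) == "HF 3"

    def test_locus_straddling_boundary(self):
        model = ProphageModel("p", 10_000, 7)
        L = 200_000
        site = AttBSite("s", 0, +1)
        locus = GenomicLocus("v", CircularInterval(48_000, 4_000, L))  # HF5 into HF6
        assert locus_headful_range(site, locus, model, L) == (5, 6)
        assert format_headful_range((5, 6)) == "HF 5-6"

    def test_out_of_reach_renders_dash(self):
        model = ProphageModel("p", 10_000, 2)
        L = 200_000
        site = AttBSite("s", 0, +1)
        locus = GenomicLocus("v", CircularInterval(100_000, 500, L))
        assert locus_headful_range(site, locus, model, L) is None
        assert format_headful_range(None) == "—"

    def test_random_table_matches_per_base_oracle(self):
        rng = np.random.default_rng(23)
        L = 80_000
        model = ProphageModel("p", 9_000, 5)
        sites = [
            AttBSite(f"s{i}", int(rng.integers(L)), int(rng.choice([1, -1])))
            for i in range(4)
        ]
        loci = [
            GenomicLocus(f"l{i}", CircularInterval(int(rng.integers(L)), int(rng.integers(200, 15_000)), L))
            for i in range(10)
        ]
        models = {s.site_id: model for s in sites}
        table = locus_compatibility_table(loci, sites, models, L)
        for locus in loci:
            for site in sites:
                assert table[locus.locus_id][site.site_id] == per_base_locus_range(
                    site, locus, model, L
                ), (locus.locus_id, site.site_id)


class TestCircularInterval:
    def test_wrapped_membership(self):
        iv = CircularInterval(950, 100, 1000)
        assert iv.contains(999) and iv.contains(0) and iv.contains(49)
        assert not iv.contains(50) and not iv.contains(949)
        assert iv.segments() == [(950, 1000), (0, 50)]

    def test_contains_interval(self):
        outer = CircularInterval(900, 300, 1000)
        assert outer.contains_interval(CircularInterval(950, 200, 1000))
        assert not outer.contains_interval(CircularInterval(950, 300, 1000))

    @given(
        start=st.integers(min_value=0, max_value=999),
        length=st.integers(min_value=1, max_value=1000),
        p=st.integers(min_value=0, max_value=999),
    )
    def test_membership_matches_enumeration(self, start, length, p):
        iv = CircularInterval(start, length, 1000)
        member = any(s <= p < e for s, e in iv.segments())
        assert iv.contains(p) == member
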
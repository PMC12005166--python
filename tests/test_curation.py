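"""Region curation against brute-force interval oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demodfe import curation as cu


def brute_force_complement(functional, length, min_distance):
    """Per-base oracle: bases farther than min_distance from any functional bp."""
    base = np.ones(length, dtype=bool)
    for s, e in functional:
        base[max(0, s - min_distance) : e + min_distance] = False
    out, start = [], None
    for i, ok in enumerate(base):
        if ok and start is None:
            start = i
        if not ok and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return np.asarray(out).reshape(-1, 2)


def uniform_map(chrom, length, rate):
    return pd.DataFrame([(chrom, 0, length, rate)],
                        columns=["chrom", "start", "end", "rate"])


class TestIntervalOps:
    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 20)), max_size=8),
           st.lists(st.tuples(st.integers(0, 180), st.integers(1, 20)), max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_subtract_matches_boolean_oracle(self, a, b):
        length = 200
        iv_a = np.array([(s, s + w) for s, w in a]).reshape(-1, 2)
        iv_b = np.array([(s, s + w) for s, w in b]).reshape(-1, 2)
        got = cu.subtract_intervals(iv_a, iv_b)
        mask = np.zeros(length + 50, dtype=bool)
        for s, e in iv_a:
            mask[s:e] = True
        for s, e in iv_b:
            mask[s:e] = False
        expect = np.flatnonzero(mask)
        got_bases = np.concatenate([np.arange(s, e) for s, e in got]) if got.size else np.array([])
        assert np.array_equal(np.sort(got_bases), expect)

    def test_normalize_merges_and_warns_on_overlap(self):
        with pytest.warns(UserWarning):
            out = cu.normalize_intervals(np.array([[0, 10], [5, 20], [30, 40]]), warn=True)
        assert np.array_equal(out, [[0, 20], [30, 40]])


class TestRegionMeanRate:
    def test_uniform_map_returns_rate_exactly(self):
        m = uniform_map("chr1", 1000, 1.7e-8)
        rate, cov = cu.region_mean_rate(100, 900, m, "chr1")
        assert rate == pytest.approx(1.7e-8) and cov == 1.0

    def test_length_weighted_mean(self):
        m = pd.DataFrame([("chr1", 0, 500, 1e-8), ("chr1", 500, 1000, 2e-8)],
                         columns=["chrom", "start", "end", "rate"])
        rate, cov = cu.region_mean_rate(0, 1000, m, "chr1")
        assert rate == pytest.approx(1.5e-8)

    def test_equal_halves_give_two_e_minus_eight(self):
        m = pd.DataFrame([("chr1", 0, 100, 1e-8), ("chr1", 100, 200, 3e-8)],
                         columns=["chrom", "start", "end", "rate"])
        rate, _ = cu.region_mean_rate(0, 200, m, "chr1")
        assert rate == pytest.approx(2e-8)

    def test_zero_coverage_signals_no_rate(self):
        m = uniform_map("chr1", 100, 1e-8)
        assert cu.region_mean_rate(500, 600, m, "chr1") is None


class TestSelectNonfunctional:
    def _masks(self, inacc=(), cons=()):
        return {"chr1": cu.MaskSet(np.array(inacc).reshape(-1, 2),
                                   np.array(cons).reshape(-1, 2))}

    def test_single_gene_hand_interval_arithmetic(self):
        ann = {"chr1": np.array([[40_000, 45_000]])}
        regions = cu.select_nonfunctional(
            ann, self._masks(), uniform_map("chr1", 100_000, 1e-8),
            uniform_map("chr1", 100_000, 1e-8), {"chr1": 100_000},
            min_distance=10_000, min_length=15_000)
        assert [(r.start, r.end) for r in regions] == [(0, 30_000), (55_000, 100_000)]

    def test_fully_masked_region_removed(self):
        ann = {"chr1": np.array([[40_000, 45_000]])}
        regions = cu.select_nonfunctional(
            ann, self._masks(inacc=[(0, 30_000)]), uniform_map("chr1", 100_000, 1e-8),
            uniform_map("chr1", 100_000, 1e-8), {"chr1": 100_000})
        assert [(r.start, r.end) for r in regions] == [(55_000, 100_000)]

    def test_no_annotation_gives_whole_chromosome(self):
        regions = cu.select_nonfunctional(
            {}, self._masks(), uniform_map("chr1", 100_000, 1e-8),
            uniform_map("chr1", 100_000, 1e-8), {"chr1": 100_000})
        assert [(r.start, r.end) for r in regions] == [(0, 100_000)]

    def test_masked_bases_deducted_not_split(self):
        regions = cu.select_nonfunctional(
            {}, self._masks(inacc=[(10_000, 12_000)], cons=[(50_000, 50_500)]),
            uniform_map("chr1", 100_000, 1e-8), uniform_map("chr1", 100_000, 1e-8),
            {"chr1": 100_000})
        assert len(regions) == 1
        assert regions[0].accessible_bp == 100_000 - 2_500

    @given(st.lists(st.tuples(st.integers(0, 90_000), st.integers(100, 5_000)),
                    max_size=5),
           st.sampled_from([5_000, 10_000, 20_000]),
           st.sampled_from([10_000, 15_000, 30_000]))
    @settings(max_examples=25, deadline=None)
    def test_boundaries_match_brute_force_oracle(self, genes, min_dist, min_len):
        length = 100_000
        ann = {"chr1": np.array([(s, s + w) for s, w in genes]).reshape(-1, 2)}
        regions = cu.select_nonfunctional(
            ann, self._masks(), uniform_map("chr1", length, 1e-8),
            uniform_map("chr1", length, 1e-8), {"chr1": length},
            min_distance=min_dist, min_length=min_len)
        merged = cu.normalize_intervals(ann["chr1"]) if ann["chr1"].size else ann["chr1"]
        oracle = brute_force_complement(merged, length, min_dist)
        oracle = oracle[(oracle[:, 1] - oracle[:, 0]) >= min_len] if oracle.size else oracle
        assert [(r.start, r.end) for r in regions] == [tuple(x) for x in oracle]

    def test_monotone_in_thresholds(self):
        ann = {"chr1": np.array([[20_000, 25_000], [60_000, 61_000]])}
        counts = []
        for min_dist in (5_000, 10_000, 20_000):
            regions = cu.select_nonfunctional(
                ann, self._masks(), uniform_map("chr1", 100_000, 1e-8),
                uniform_map("chr1", 100_000, 1e-8), {"chr1": 100_000},
                min_distance=min_dist, min_length=10_000)
            counts.append(len(regions))
        assert counts == sorted(counts, reverse=True)

    def test_empty_rate_map_errors(self):
        with pytest.raises(ValueError):
            cu.select_nonfunctional(
                {}, self._masks(), pd.DataFrame(columns=["chrom", "start", "end", "rate"]),
                uniform_map("chr1", 100_000, 1e-8), {"chr1": 100_000})


class TestSelectExonic:
    def test_exons_without_rate_coverage_dropped(self):
        ann = {"chr1": np.array([[0, 100], [200, 300], [400, 500], [600, 700],
                                 [90_000, 90_100]])}
        mu = uniform_map("chr1", 1_000, 1e-8)  # covers only the first four
        rec = uniform_map("chr1", 1_000, 1e-8)
        regions = cu.select_exonic(ann, mu, rec)
        assert len(regions) == 4

    def test_length_weighted_exon_rate(self):
        ann = {"chr1": np.array([[0, 200]])}
        mu = pd.DataFrame([("chr1", 0, 100, 1e-8), ("chr1", 100, 200, 3e-8)],
                          columns=["chrom", "start", "end", "rate"])
        regions = cu.select_exonic(ann, mu, uniform_map("chr1", 200, 1e-8))
        assert regions[0].mean_mu == pytest.approx(2e-8)

    def test_empty_annotation(self):
        assert cu.select_exonic({}, uniform_map("chr1", 100, 1e-8),
                                uniform_map("chr1", 100, 1e-8)) == []


class TestRoundTrip:
    def test_regions_tsv_roundtrip(self, tmp_path):
        regions = [cu.CuratedRegion("chr1", 0, 20_000, "nonfunctional", 1e-8, 2e-8, 18_000)]
        path = tmp_path / "regions.tsv"
        cu.write_regions(regions, path)
        back = cu.read_regions(path)
        assert back[0].start == 0 and back[0].end == 20_000
        assert back[0].mean_mu == pytest.approx(1e-8)

    def test_curation_is_idempotent(self):
        """Feeding curated output back as 'annotation-free' geometry is a fixed point."""
        regions = cu.select_nonfunctional(
            {"chr1": np.array([[40_000, 45_000]])},
            {"chr1": cu.MaskSet(np.zeros((0, 2)), np.zeros((0, 2)))},
            uniform_map("chr1", 100_000, 1e-8), uniform_map("chr1", 100_000, 1e-8),
            {"chr1": 100_000})
        # re-curating each returned span with no annotation returns it unchanged
        for r in regions:
            again = cu.select_nonfunctional(
                {}, {"chr1": cu.MaskSet(np.zeros((0, 2)), np.zeros((0, 2)))},
                uniform_map("chr1", r.end - r.start, 1e-8),
                uniform_map("chr1", r.end - r.start, 1e-8),
                {"chr1": r.end - r.start})
            assert [(x.start, x.end) for x in again] == [(0, r.end - r.start)]
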
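"""Tag I/O, the Poisson window scan, and table-style summaries."""

import numpy as np
import pytest
from scipy import stats

from h2azdyn.genome_model import ChromSizes
from h2azdyn.peakcall import (Peak, PeakCallParams, TagSet, call_peaks, read_peaks,
                              read_tags, round_half_up, summarize_library,
                              summarize_peaks, write_peaks)


def uniform_tagset(seed: int, n: int, length: int, sample_id: str = "null") -> TagSet:
    rng = np.random.default_rng(seed)
    return TagSet(sample_id=sample_id,
                  positions={"chr1": rng.integers(0, length, size=n, dtype=np.int64)},
                  strands={"chr1": rng.random(n) < 0.5})


class TestReadTags:
    def test_five_prime_convention_and_counts(self, tmp_path):
        p = tmp_path / "tags.bed"
        p.write_text("chr1\t500\t536\tr1\t0\t+\n"
                     "chr1\t100\t136\tr2\t0\t-\n"
                     "chr1\t300\t336\tr3\t0\t+\n")
        tags = read_tags(p, "s1", ChromSizes({"chr1": 1000}))
        assert tags.library_size == 3
        # minus-strand record [100,136) has its 5' end at 135; input is
        # unsorted, positions come back sorted
        assert tags.positions["chr1"].tolist() == [135, 300, 500]
        assert tags.strands["chr1"].tolist() == [True, False, False]

    def test_unknown_chromosome_is_listed(self, tmp_path):
        p = tmp_path / "tags.bed"
        p.write_text("chrZ\t10\t46\tr\t0\t+\n")
        with pytest.raises(ValueError, match="chrZ"):
            read_tags(p, "s1", ChromSizes({"chr1": 1000}))


class TestCallPeaks:
    def test_empty_tagset_rejected(self):
        empty = TagSet("s", {}, {})
        with pytest.raises(ValueError, match="empty"):
            call_peaks(empty, ChromSizes({"chr1": 1000}))

    def test_null_rate_within_ten_times_nominal(self):
        """Uniform tags: significant-window fraction stays near nominal."""
        length, n = 5_000_000, 500_000
        tags = uniform_tagset(seed=11, n=n, length=length)
        sizes = ChromSizes({"chr1": length})
        params = PeakCallParams()
        width, step = 2 * params.bandwidth, params.bandwidth // 2
        mu = n / length * width
        k_min = int(stats.poisson.isf(params.p_threshold, mu)) + 1
        starts = np.arange(0, length - width + 1, step)
        pos = tags.positions["chr1"]
        counts = np.searchsorted(pos, starts + width) - np.searchsorted(pos, starts)
        frac = float((counts >= k_min).mean())
        assert frac <= 10 * params.p_threshold
        # and the caller itself reports at most that many merged regions
        peaks = call_peaks(tags, sizes, params)
        assert len(peaks) <= (counts >= k_min).sum()

    def test_single_planted_block_yields_one_overlapping_peak(self):
        """A 10x-enriched 600 bp block over flat background -> one peak."""
        length = 1_000_000
        rng = np.random.default_rng(3)
        bg = rng.integers(0, length, size=50_000, dtype=np.int64)  # 0.05/bp
        block = rng.integers(400_000, 400_600, size=300, dtype=np.int64)  # +0.5/bp
        pos = np.concatenate([bg, block])
        tags = TagSet("planted", {"chr1": pos},
                      {"chr1": rng.random(len(pos)) < 0.5})
        peaks = call_peaks(tags, ChromSizes({"chr1": length}))
        overlapping = [p for p in peaks if p.start < 400_600 and p.end > 400_000]
        assert len(overlapping) == 1
        p = overlapping[0]
        assert 400_000 <= p.summit < 400_600
        assert p.score >= 4  # at least -log10(1e-4)

    def test_stricter_threshold_never_increases_peak_count(self, default_world):
        tags = default_world["samples"]["iPSC"]["tags"]
        sizes = default_world["sizes"]
        counts = [len(call_peaks(tags, sizes, PeakCallParams(p_threshold=p_thr)))
                  for p_thr in (1e-2, 1e-4, 1e-6, 1e-8)]
        assert counts == sorted(counts, reverse=True)

    def test_peak_invariants_hold_on_synthetic_sample(self, default_world):
        world = default_world
        tags = world["samples"]["MEF"]["tags"]
        peaks = call_peaks(tags, world["sizes"])
        assert peaks == sorted(peaks, key=lambda p: (p.chrom, p.start))
        for p in peaks:
            assert p.start <= p.summit < p.end
            assert p.score >= 4
            assert p.tag_count > 0


class TestSummaries:
    @pytest.mark.parametrize("n_peaks, total, expected_mean", [
        (23_818, 32_163_617, 1_350),
        (13_744, 17_951_826, 1_306),
        (14_768, 12_532_924, 849),
    ])
    def test_mean_peak_length_rounding(self, n_peaks, total, expected_mean):
        """Mean length = total/count rounded half-up, at published precision."""
        assert int(round_half_up(total / n_peaks)) == expected_mean

    def test_summarize_peaks_small_case(self):
        peaks = [Peak("chr1", 0, 100, 50, 10, 5.0),
                 Peak("chr1", 500, 700, 600, 20, 6.0)]
        s = summarize_peaks(peaks)
        assert (s.n_peaks, s.total_length, s.mean_length, s.median_length) == \
            (2, 300, 150, 150.0)

    def test_summarize_peaks_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_peaks([])

    def test_library_summary_published_row(self):
        s = summarize_library(12_807_843, 49, 12_458_074, 11_216_366)
        assert s.output_bases == 627_584_307
        assert s.mapped_pct == 97.27
        assert s.unique_pct == 87.57

    def test_library_summary_identity_case(self):
        s = summarize_library(100, 36, 100, 100)
        assert s.mapped_pct == s.unique_pct == 100.00

    def test_library_summary_ordering_enforced(self):
        with pytest.raises(ValueError):
            summarize_library(100, 36, 50, 80)  # unique > mapped

    @pytest.mark.parametrize("seed", range(10))
    def test_summaries_agree_with_direct_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(50, 5000, size=int(rng.integers(1, 40)))
        peaks = []
        pos = 0
        for i, L in enumerate(lengths):
            peaks.append(Peak("chr1", pos, pos + int(L), pos, 1, 5.0))
            pos += int(L) + 100
        s = summarize_peaks(peaks)
        assert s.total_length == int(lengths.sum())
        assert s.mean_length == int(round_half_up(lengths.sum() / len(lengths)))
        assert s.median_length == float(np.median(lengths))


class TestPeakIO:
    def test_round_trip_preserves_peaks(self, tmp_path):
        peaks = [Peak("chr1", 100, 700, 350, 42, 7.1234),
                 Peak("chr1", 900, 1200, 1000, 17, 4.5),
                 Peak("chr2", 0, 300, 299, 8, 12.0)]
        path = tmp_path / "peaks.bed"
        write_peaks(peaks, path)
        back = read_peaks(path)
        assert [(p.chrom, p.start, p.end, p.summit, p.tag_count) for p in back] == \
            [(p.chrom, p.start, p.end, p.summit, p.tag_count) for p in peaks]
        for a, b in zip(peaks, back):
            assert abs(a.score - b.score) < 1e-4

    def test_summit_outside_interval_rejected_on_read(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tpeak_1\t5.0\t.\t150\t10\n")  # summit 250
        with pytest.raises(ValueError, match="summit"):
            read_peaks(path)

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\tnope\tpeak_1\t5.0\t.\t10\t10\n")
        with pytest.raises(ValueError, match="malformed"):
            read_peaks(path)
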
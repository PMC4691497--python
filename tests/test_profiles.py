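"""Composite profiles, coverage pileup, and expression stratification."""

import numpy as np
import pytest

from h2azdyn.genome_model import ChromSizes, GeneModel
from h2azdyn.peakcall import TagSet
from h2azdyn.profiles import (composite_profile, coverage_vector,
                              stratified_profiles, stratify_by_expression)

from oracles import coverage_by_per_base_count


def tagset_from(positions, strands, sample_id="s"):
    pos = np.array(positions, dtype=np.int64)
    return TagSet(sample_id, {"chr1": pos},
                  {"chr1": np.array(strands, dtype=bool)})


class TestCoverageVector:
    def test_single_plus_tag_covers_extension_bases(self):
        tags = tagset_from([1000], [False])
        cov = coverage_vector(tags, "chr1", 900, 1300, extension=150)
        expected = 1e6 / 1
        assert np.all(cov[100:250] == expected)
        assert cov[99] == 0 and cov[250] == 0

    def test_minus_tag_extends_leftwards(self):
        tags = tagset_from([1000], [True])
        cov = coverage_vector(tags, "chr1", 700, 1100, extension=150)
        # covers (1000-150, 1000] = [851, 1001)
        assert cov[150] == 0          # position 850
        assert cov[151] > 0           # position 851
        assert cov[300] > 0           # position 1000
        assert cov[301] == 0          # position 1001

    def test_duplicate_tags_double_coverage(self):
        one = tagset_from([1000], [False])
        two = tagset_from([1000, 1000], [False, False])
        cov1 = coverage_vector(one, "chr1", 900, 1300)
        cov2 = coverage_vector(two, "chr1", 900, 1300)
        # RPM rescales by library size, so doubled tags at doubled library
        # size leave the curve unchanged
        assert np.allclose(cov1, cov2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        pos = rng.integers(0, 5000, size=n)
        strands = rng.random(n) < 0.5
        tags = tagset_from(pos, strands)
        cov = coverage_vector(tags, "chr1", 500, 4500, extension=150)
        oracle = np.array(coverage_by_per_base_count(pos, strands, 500, 4500, 150))
        assert np.allclose(cov, oracle * 1e6 / n)

    def test_inverted_interval_rejected(self):
        tags = tagset_from([10], [False])
        with pytest.raises(ValueError):
            coverage_vector(tags, "chr1", 500, 400)


class TestCompositeProfile:
    def _genes(self, n, sizes, strand_cycle=("+", "-")):
        genes = []
        spacing = sizes["chr1"] // n
        for i in range(n):
            lo = i * spacing + 6000
            hi = lo + 8000
            strand = strand_cycle[i % len(strand_cycle)]
            tss, tes = (lo, hi) if strand == "+" else (hi, lo)
            genes.append(GeneModel(f"g{i}", "chr1", strand, tss, tes,
                                   exons=((lo, hi),)))
        return genes

    def test_uniform_tags_give_flat_curve(self):
        sizes = ChromSizes({"chr1": 600_000})
        genes = self._genes(20, sizes)
        rng = np.random.default_rng(42)
        n = 400_000  # deep uniform coverage
        tags = tagset_from(rng.integers(0, 600_000, size=n), rng.random(n) < 0.5)
        curve = composite_profile(tags, genes, sizes, "TSS")
        assert curve.values.max() / curve.values.min() < 1.2

    def test_gene_with_no_tags_gives_zero_curve(self):
        sizes = ChromSizes({"chr1": 100_000})
        genes = self._genes(1, sizes)
        tags = TagSet("s", {"chr1": np.array([95_000], dtype=np.int64)},
                      {"chr1": np.array([False])})
        curve = composite_profile(tags, genes, sizes, "TSS")
        assert np.all(curve.values == 0)

    def test_minus_strand_gene_mirrors_plus_strand(self):
        """A reflected minus-strand gene with reflected tags gives the same curve."""
        L = 100_000
        sizes = ChromSizes({"chr1": L})
        plus = GeneModel("gp", "chr1", "+", 40_000, 48_000, exons=((40_000, 48_000),))
        minus = GeneModel("gm", "chr1", "-", L - 40_000, L - 48_000,
                          exons=((L - 48_000, L - 40_000),))
        rng = np.random.default_rng(9)
        pos = rng.integers(35_000, 46_000, size=5000).astype(np.int64)
        strands = rng.random(5000) < 0.5
        # reflect a tag's covered fragment: 5' of the mirror fragment
        refl_pos = (L - 1 - pos).astype(np.int64)
        tags_p = tagset_from(pos, strands)
        tags_m = tagset_from(refl_pos, ~strands)
        curve_p = composite_profile(tags_p, [plus], sizes, "TSS")
        curve_m = composite_profile(tags_m, [minus], sizes, "TSS")
        assert np.allclose(curve_p.values, curve_m.values)

    def test_cohort_union_is_mean_of_cohort_curves(self):
        sizes = ChromSizes({"chr1": 600_000})
        genes = self._genes(20, sizes)
        rng = np.random.default_rng(5)
        n = 100_000
        tags = tagset_from(rng.integers(0, 600_000, size=n), rng.random(n) < 0.5)
        c_all = composite_profile(tags, genes, sizes, "TSS")
        c_a = composite_profile(tags, genes[:10], sizes, "TSS")
        c_b = composite_profile(tags, genes[10:], sizes, "TSS")
        assert np.allclose(c_all.values, (c_a.values + c_b.values) / 2)

    def test_flank_must_divide_by_window(self, default_world):
        world = default_world
        with pytest.raises(ValueError, match="divisible"):
            composite_profile(world["samples"]["MEF"]["tags"], world["genes"],
                              world["sizes"], "TSS", flank=5000, window=300)

    def test_forty_window_variant_supported(self, default_world):
        """250 bp windows give 40 windows over the 10 kb span."""
        world = default_world
        curve = composite_profile(world["samples"]["MEF"]["tags"], world["genes"],
                                  world["sizes"], "TSS", window=250)
        assert len(curve.values) == 40

    def test_edge_genes_are_excluded_not_padded(self):
        sizes = ChromSizes({"chr1": 100_000})
        inner = GeneModel("gi", "chr1", "+", 40_000, 48_000)
        edge = GeneModel("ge", "chr1", "+", 3_000, 9_000)  # flank crosses 0
        rng = np.random.default_rng(1)
        tags = tagset_from(rng.integers(0, 100_000, size=1000), np.zeros(1000, bool))
        curve = composite_profile(tags, [inner, edge], sizes, "TSS")
        assert curve.n_genes == 1
        with pytest.raises(ValueError):
            composite_profile(tags, [edge], sizes, "TSS")


class TestStratification:
    def test_equal_split_of_eight_genes(self):
        expr = {f"g{i}": float(i) for i in range(8)}
        labels = stratify_by_expression(expr)
        assert sorted(labels.values()).count("high") == 2
        assert labels["g7"] == "high" and labels["g6"] == "high"
        assert labels["g0"] == "lowest" and labels["g1"] == "lowest"

    def test_remainder_goes_to_highest_class(self):
        expr = {f"g{i}": float(i) for i in range(9)}
        labels = stratify_by_expression(expr)
        from collections import Counter
        counts = Counter(labels.values())
        assert counts == {"high": 3, "middle": 2, "low": 2, "lowest": 2}

    def test_ties_break_deterministically_by_gene_id(self):
        expr = {g: 1.0 for g in ("b", "d", "a", "c")}
        labels = stratify_by_expression(expr)
        assert labels == {"a": "high", "b": "middle", "c": "low", "d": "lowest"}

    def test_fewer_genes_than_classes_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_expression({"a": 1.0, "b": 2.0})

    def test_class_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        expr = {f"g{i}": float(v) for i, v in enumerate(rng.random(23))}
        from collections import Counter
        counts = Counter(stratify_by_expression(expr).values())
        assert max(counts.values()) - min(counts.values()) <= 1


class TestStratifiedProfiles:
    def test_amplitude_proportional_classes_order_strictly(self, default_world):
        world = default_world
        strat = stratified_profiles(world["samples"]["MEF"]["tags"], world["genes"],
                                    world["sizes"], world["expression"])
        maxima = {k: v.values.max() for k, v in strat.items()}
        assert maxima["high"] > maxima["middle"] > maxima["low"] > maxima["lowest"]

    def test_equal_amplitudes_give_equal_curves_within_noise(self):
        from h2azdyn import SampleSignalParams, SimulationConfig, simulate_all
        cfg = SimulationConfig(
            class_amplitudes={"high": 2.0, "middle": 2.0, "low": 2.0, "lowest": 2.0},
            samples={"flat": SampleSignalParams(intensity=1.0, occupied_fraction=1.0)},
            seed=13)
        world = simulate_all(cfg)
        strat = stratified_profiles(world["samples"]["flat"]["tags"], world["genes"],
                                    world["sizes"], world["expression"])
        maxima = sorted(v.values.max() for v in strat.values())
        assert maxima[-1] / maxima[0] < 1.25
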
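"""Seeded synthetic ChIP-seq data with planted ground truth.

The generator emulates the signal structure a histone-variant occupancy
analysis assumes, so every downstream module can be exercised end to end
without any external data:

* uniform Poisson background tags over the whole genome;
* gene-anchored enrichment as a two-Gaussian mixture of fragment centers
  flanking the TSS, with a depleted zone over the TSS itself (the
  nucleosome-free-region dip of the classic bimodal TSS profile);
* signal amplitude scaling with the gene's expression class, so composite
  profiles stratify monotonically by expression;
* per-sample global intensity and occupied-gene fraction, so the three
  reprogramming-stage samples differ both in profile height (intermediate
  stage highest, endpoint lowest) and in which genes carry signal at all.

Every draw is deterministic given (seed, sample_id); the planted truth
records which genes carry signal, where, and at what expected fold over
background, so recovery tests have an exact reference.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .genome_model import ChromSizes, GeneModel
from .peakcall import TagSet
from .profiles import stratify_by_expression

DEFAULT_SAMPLE_IDS = ("MEF", "Day7", "iPSC")


@dataclass(frozen=True)
class SampleSignalParams:
    """Per-sample knobs: global signal intensity and occupied-gene fraction."""

    intensity: float = 1.0
    occupied_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if not 0 <= self.occupied_fraction <= 1:
            raise ValueError("occupied_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Defaults define the simulated study conditions.

    Genes are long (12-16 kb) relative to the 5 kb profile flank so TSS
    signal never leaks into the TES composite; the two fragment-center
    modes sit 300 bp either side of the TSS (flanking-nucleosome spacing)
    with an excluded dip zone over the TSS itself. Sample intensities
    order the intermediate stage highest and the endpoint lowest;
    occupied fractions shrink across the course, echoing a genome-wide
    contraction of the occupied-gene set.
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 80
    read_length: int = 49
    extension: int = 150
    background_rate: float = 200.0    # tags per kb, per sample
    base_signal_tags: float = 1000.0  # expected signal tags for amplitude 1
    peak_offsets: tuple[int, int] = (-300, 300)  # fragment-center modes vs TSS
    peak_sd: float = 80.0
    dip_width: int = 150              # centers within +-dip_width/2 of TSS resampled
    class_amplitudes: dict = field(default_factory=lambda: {
        "high": 4.0, "middle": 3.0, "low": 2.0, "lowest": 1.5})
    samples: dict = field(default_factory=lambda: {
        "MEF": SampleSignalParams(intensity=1.0, occupied_fraction=0.80),
        "Day7": SampleSignalParams(intensity=1.5, occupied_fraction=0.65),
        "iPSC": SampleSignalParams(intensity=0.75, occupied_fraction=0.55)})
    library_size: int | None = None   # optional cap on expected tags per sample
    seed: int = 7

    def __post_init__(self) -> None:
        amps = list(self.class_amplitudes.values())
        if any(a < 0 for a in amps):
            raise ValueError("class amplitudes must be non-negative")
        if self.background_rate < 0 or self.base_signal_tags < 0:
            raise ValueError("rates must be non-negative")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """One independent, reproducible stream per (seed, sample)."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Annotation and expression
# ---------------------------------------------------------------------------

#: margin on each side of a gene: promoter (2 kb) + profile flank (5 kb)
_GENE_MARGIN = 7000
_GENE_LEN_RANGE = (12_000, 16_000)


def generate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], ChromSizes]:
    """Non-overlapping genes with alternating strands and minimal exon/CDS
    structure so every one of the seven partition classes is populated.

    Deterministic for a fixed config seed. Every tenth gene is left
    non-coding (no CDS) to exercise the non-coding labeling rule.
    """
    rng = np.random.default_rng([config.seed, 0])
    sizes = ChromSizes({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})

    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    max_len = _GENE_LEN_RANGE[1]
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(sizes):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = config.chrom_length // n
        need = max_len + 2 * _GENE_MARGIN
        if slot < need:
            raise ValueError(
                f"{n} genes do not fit on a {config.chrom_length} bp chromosome; "
                f"need at least {n * need} bp")
        for si in range(n):
            length = int(rng.integers(*_GENE_LEN_RANGE))
            jitter = int(rng.integers(0, slot - length - 2 * _GENE_MARGIN + 1))
            lo = si * slot + _GENE_MARGIN + jitter
            hi = lo + length
            strand = "+" if gi % 2 == 0 else "-"
            # three exons with a 500 bp terminal UTR on each end of the CDS span
            exons = ((lo, lo + 1000),
                     (lo + length // 2, lo + length // 2 + 1500),
                     (hi - 1000, hi))
            cds = None if gi % 10 == 9 else (lo + 500, hi - 500)
            tss, tes = (lo, hi) if strand == "+" else (hi, lo)
            genes.append(GeneModel(gene_id=f"gene_{gi + 1:04d}", chrom=chrom,
                                   strand=strand, tss=tss, tes=tes,
                                   exons=exons, cds=cds))
            gi += 1
    return genes, sizes


def generate_expression(genes: list[GeneModel], seed: int) -> dict[str, float]:
    """Log-normal per-gene expression values, deterministic per seed."""
    rng = np.random.default_rng([seed, 1])
    values = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
    return {g.gene_id: float(v) for g, v in zip(genes, values)}


# ---------------------------------------------------------------------------
# Tag generation with planted truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedGene:
    gene_id: str
    occupied: bool
    signal_intervals: list[tuple[str, int, int]]  # (chrom, start, end) per mode
    expected_signal_tags: float
    expected_fold: float  # expected best-window fold over background


@dataclass
class PlantedTruth:
    sample_id: str
    genes: dict[str, PlantedGene]
    background_tags: int
    signal_tags: int

    @property
    def occupied_set(self) -> set[str]:
        return {g for g, pg in self.genes.items() if pg.occupied}

    def genes_at_fold(self, min_fold: float) -> set[str]:
        return {g for g, pg in self.genes.items()
                if pg.occupied and pg.expected_fold >= min_fold}

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"sample_id": self.sample_id,
                       "background_tags": self.background_tags,
                       "signal_tags": self.signal_tags,
                       "genes": {g: asdict(pg) for g, pg in self.genes.items()}},
                      fh, indent=1)


def _expected_fold(n_signal: float, config: SimulationConfig, window: int = 600) -> float:
    """Expected fold over background of the best window on one signal mode."""
    capture = norm.cdf(window / 2, scale=config.peak_sd) - norm.cdf(-window / 2, scale=config.peak_sd)
    mode_tags = (n_signal / 2) * capture
    bg_tags = config.background_rate / 1000 * window
    return 1.0 + mode_tags / bg_tags


def generate_tags(genes: list[GeneModel], expression: Mapping[str, float],
                  config: SimulationConfig, sample_id: str,
                  sizes: ChromSizes | None = None) -> tuple[TagSet, PlantedTruth]:
    """Background + planted TSS-flanking signal for one sample.

    Background tag counts are Poisson at ``background_rate`` per kb,
    positions uniform. Each occupied gene draws Poisson-many fragment
    centers from a two-Gaussian mixture at ``tss + peak_offsets`` (signs
    flipped for minus-strand genes), with centers inside the TSS dip zone
    resampled; the read falls on either fragment end with equal
    probability, which sets its strand and 5' position, so extension-based
    pileup is centered on the fragment.
    """
    if sample_id not in config.samples:
        raise KeyError(f"sample {sample_id!r} not in config.samples")
    sp: SampleSignalParams = config.samples[sample_id]
    if sizes is None:
        sizes = ChromSizes({f"chr{i + 1}": config.chrom_length
                            for i in range(config.n_chroms)})
    rng = _sample_rng(config.seed, sample_id)

    class_of = stratify_by_expression({g.gene_id: expression[g.gene_id] for g in genes}) \
        if genes else {}

    # budget check before any drawing
    exp_bg = config.background_rate / 1000 * sizes.total
    mean_amp = float(np.mean(list(config.class_amplitudes.values()))) if genes else 0.0
    exp_sig = (config.base_signal_tags * mean_amp * sp.intensity
               * sp.occupied_fraction * len(genes))
    if config.library_size is not None and exp_bg + exp_sig > config.library_size:
        raise ValueError(
            f"expected tag count {exp_bg + exp_sig:.0f} exceeds the library budget "
            f"{config.library_size}")

    pos_chunks: dict[str, list[np.ndarray]] = {c: [] for c in sizes}
    strand_chunks: dict[str, list[np.ndarray]] = {c: [] for c in sizes}

    # uniform background
    n_bg_total = 0
    for chrom, length in sizes.items():
        n_bg = int(rng.poisson(config.background_rate / 1000 * length))
        pos_chunks[chrom].append(rng.integers(0, length, size=n_bg, dtype=np.int64))
        strand_chunks[chrom].append(rng.random(n_bg) < 0.5)
        n_bg_total += n_bg

    # gene-anchored signal
    occupied_mask = rng.random(len(genes)) < sp.occupied_fraction
    half_ext = config.extension // 2
    dip_half = config.dip_width / 2
    truth_genes: dict[str, PlantedGene] = {}
    n_sig_total = 0
    for gene, occ in zip(genes, occupied_mask):
        amp = config.class_amplitudes[class_of[gene.gene_id]]
        n_expected = config.base_signal_tags * amp * sp.intensity
        sign = 1 if gene.strand == "+" else -1
        modes = [gene.tss + sign * off for off in config.peak_offsets]
        intervals = [(gene.chrom,
                      int(m - 3 * config.peak_sd), int(m + 3 * config.peak_sd))
                     for m in sorted(modes)]
        if not occ:
            truth_genes[gene.gene_id] = PlantedGene(gene.gene_id, False, intervals, 0.0, 1.0)
            continue
        n = int(rng.poisson(n_expected))
        centers = np.asarray(rng.choice(modes, size=n)) + rng.normal(0, config.peak_sd, size=n)
        # resample centers landing in the TSS-dip exclusion zone
        for _ in range(20):
            bad = np.abs(centers - gene.tss) < dip_half
            if not bad.any():
                break
            k = int(bad.sum())
            centers[bad] = (np.asarray(rng.choice(modes, size=k))
                            + rng.normal(0, config.peak_sd, size=k))
        minus = rng.random(n) < 0.5
        five_prime = np.where(minus, np.round(centers) + half_ext - 1,
                              np.round(centers) - half_ext).astype(np.int64)
        np.clip(five_prime, 0, sizes[gene.chrom] - 1, out=five_prime)
        pos_chunks[gene.chrom].append(five_prime)
        strand_chunks[gene.chrom].append(minus)
        n_sig_total += n
        truth_genes[gene.gene_id] = PlantedGene(
            gene.gene_id, True, intervals, n_expected,
            _expected_fold(n_expected, config))

    tags = TagSet(
        sample_id=sample_id,
        positions={c: np.concatenate(pos_chunks[c]) if pos_chunks[c]
                   else np.empty(0, dtype=np.int64) for c in sizes},
        strands={c: np.concatenate(strand_chunks[c]) if strand_chunks[c]
                 else np.empty(0, dtype=bool) for c in sizes},
        read_length=config.read_length,
    )
    truth = PlantedTruth(sample_id=sample_id, genes=truth_genes,
                         background_tags=n_bg_total, signal_tags=n_sig_total)
    return tags, truth


def simulate_all(config: SimulationConfig) -> dict:
    """Generate annotation, expression, and all per-sample tag sets + truth."""
    genes, sizes = generate_annotation(config)
    expression = generate_expression(genes, config.seed)
    samples = {}
    for sample_id in config.samples:
        tags, truth = generate_tags(genes, expression, config, sample_id, sizes)
        samples[sample_id] = {"tags": tags, "truth": truth}
    return {"genes": genes, "sizes": sizes, "expression": expression,
            "samples": samples}


# ---------------------------------------------------------------------------
# On-disk output
# ---------------------------------------------------------------------------

def write_annotation_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.body
            exons = g.exons if g.exons else ((lo, hi),)
            sizes_col = ",".join(str(e - s) for s, e in exons)
            starts_col = ",".join(str(s - lo) for s, _ in exons)
            cs, ce = g.cds if g.cds else (lo, lo)
            fh.write(f"{g.chrom}\t{lo}\t{hi}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{cs}\t{ce}\t0\t{len(exons)}\t{sizes_col}\t{starts_col}\n")


def write_expression(expression: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in sorted(expression):
            fh.write(f"{g}\t{expression[g]:.6g}\n")
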
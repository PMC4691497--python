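"""Occupied-gene sets and their three-sample Venn decomposition.

A gene counts as occupied when at least one peak overlaps (by >= 1 base,
configurable) the union of its promoter (2 kb upstream of the TSS by
default) and its gene body (TSS to TES, introns included). Comparing the
occupied sets of three samples yields the seven-region Venn counts that
summarize how occupancy is gained and lost across conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_model import GeneModel
from .peakcall import Peak


def _occupancy_interval(gene: GeneModel, promoter_bp: int) -> tuple[int, int]:
    """Promoter + gene body as one interval (they are always contiguous)."""
    lo, hi = gene.body
    ps, pe = gene.promoter(promoter_bp)
    return (min(lo, ps), max(hi, pe))


def occupied_genes(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                   promoter_bp: int = 2000, min_overlap: int = 1) -> set[str]:
    """Gene ids with >= ``min_overlap`` bases of peak overlap in promoter or body."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    # sort peaks per chromosome for a binary-search sweep
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts[chrom] = np.array([s for s, _ in ivals], dtype=np.int64)
        ends[chrom] = np.array([e for _, e in ivals], dtype=np.int64)

    occupied: set[str] = set()
    for gene in genes:
        if gene.chrom not in starts:
            continue
        g_lo, g_hi = _occupancy_interval(gene, promoter_bp)
        s, e = starts[gene.chrom], ends[gene.chrom]
        # candidate peaks cannot start at/after g_hi; check overlap length
        hi_idx = int(np.searchsorted(s, g_hi))
        overlap = np.minimum(e[:hi_idx], g_hi) - np.maximum(s[:hi_idx], g_lo)
        if hi_idx and int(overlap.max()) >= min_overlap:
            occupied.add(gene.gene_id)
    return occupied


@dataclass(frozen=True)
class VennCounts:
    """Seven-region decomposition of three occupied-gene sets."""

    sample_ids: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_size(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab_only + self.ac_only + self.bc_only + self.abc)

    def per_sample_totals(self) -> dict[str, int]:
        a, b, c = self.sample_ids
        return {
            a: self.only_a + self.ab_only + self.ac_only + self.abc,
            b: self.only_b + self.ab_only + self.bc_only + self.abc,
            c: self.only_c + self.ac_only + self.bc_only + self.abc,
        }

    def to_dict(self) -> dict[str, int]:
        a, b, c = self.sample_ids
        return {
            f"{a}_only": self.only_a,
            f"{b}_only": self.only_b,
            f"{c}_only": self.only_c,
            f"{a}_{b}_only": self.ab_only,
            f"{a}_{c}_only": self.ac_only,
            f"{b}_{c}_only": self.bc_only,
            f"{a}_{b}_{c}": self.abc,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def venn_counts(sets: Mapping[str, set[str]]) -> VennCounts:
    """Exact seven-region decomposition of exactly three gene sets."""
    if len(sets) != 3:
        raise ValueError(f"need exactly 3 samples, got {len(sets)}")
    (ida, a), (idb, b), (idc, c) = sets.items()
    return VennCounts(
        sample_ids=(ida, idb, idc),
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )


def sample_gene_lists(occupancy: Mapping[str, set[str]], out_dir: str | Path) -> dict[str, Path]:
    """Write one sorted gene-id list per sample; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for sample_id, genes in occupancy.items():
        path = out_dir / f"{sample_id}_occupied_genes.tsv"
        with open(path, "w") as fh:
            for g in sorted(genes):
                fh.write(f"{g}\n")
        written[sample_id] = path
    return written


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
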
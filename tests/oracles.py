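"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-base loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from h2azdyn.genome_model import ChromSizes, GeneModel

PRIORITY = ("promoter", "utr5", "cds", "utr3", "downstream", "intron")


def brute_force_label(genes: list[GeneModel], sizes: ChromSizes,
                      chrom: str, pos: int,
                      promoter_bp: int = 2000, downstream_bp: int = 2000) -> str:
    """Label one base by evaluating every gene's candidate regions directly."""
    candidates: set[str] = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        if g.strand == "+":
            prom = (g.tss - promoter_bp, g.tss)
            down = (g.tes, g.tes + downstream_bp)
        else:
            prom = (g.tss, g.tss + promoter_bp)
            down = (g.tes - downstream_bp, g.tes)
        if prom[0] <= pos < prom[1]:
            candidates.add("promoter")
        if down[0] <= pos < down[1]:
            candidates.add("downstream")
        exons = g.exons if g.exons else ((lo, hi),)
        in_exon = any(s <= pos < e for s, e in exons)
        if lo <= pos < hi:
            if not in_exon:
                candidates.add("intron")
            elif g.cds is None:
                candidates.add("cds")
            else:
                cs, ce = g.cds
                if cs <= pos < ce:
                    candidates.add("cds")
                else:
                    before_cds = pos < cs
                    five_prime_side = before_cds if g.strand == "+" else not before_cds
                    candidates.add("utr5" if five_prime_side else "utr3")
    for cls in PRIORITY:
        if cls in candidates:
            return cls
    return "intergenic"


def hypergeom_upper_tail_enumeration(n_universe: int, big_k: int, n_query: int,
                                     k: int) -> float:
    """P(|query ∩ term| >= k) by exhaustive enumeration of all query subsets."""
    universe = list(range(n_universe))
    term = set(range(big_k))
    hits = sum(1 for subset in combinations(universe, n_query)
               if len(term.intersection(subset)) >= k)
    return hits / comb(n_universe, n_query)


def venn_by_enumeration(a: set, b: set, c: set) -> dict[str, int]:
    """Seven-region counts by checking membership of every union element."""
    counts = {"a": 0, "b": 0, "c": 0, "ab": 0, "ac": 0, "bc": 0, "abc": 0}
    for x in a | b | c:
        key = "".join(n for n, s in (("a", a), ("b", b), ("c", c)) if x in s)
        counts[key] += 1
    return counts


def occupied_by_all_pairs(peaks, genes, promoter_bp: int = 2000) -> set[str]:
    """Occupied genes via a quadratic all-pairs overlap check."""
    occupied = set()
    for g in genes:
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        if g.strand == "+":
            lo = min(lo, g.tss - promoter_bp)
        else:
            hi = max(hi, g.tss + promoter_bp)
        for p in peaks:
            if p.chrom == g.chrom and p.start < hi and p.end > lo:
                occupied.add(g.gene_id)
                break
    return occupied


def coverage_by_per_base_count(positions, strands, start: int, end: int,
                               extension: int) -> list[int]:
    """Per-base extended-fragment depth via an O(n*L) double loop."""
    cov = [0] * (end - start)
    for p, minus in zip(positions, strands):
        if minus:
            fs, fe = p - extension + 1, p + 1
        else:
            fs, fe = p, p + extension
        for x in range(max(fs, start), min(fe, end)):
            cov[x - start] += 1
    return cov
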
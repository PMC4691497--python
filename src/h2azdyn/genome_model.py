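"""Gene models, chromosome sizes, and the seven-class genome partition.

All coordinates are 0-based, half-open. For a plus-strand gene the TSS is
the interval start and the TES the interval end; for a minus-strand gene
the roles are swapped, so ``tss > tes`` and the gene body is always
``[min(tss, tes), max(tss, tes))``.

Every base of every chromosome is assigned exactly one of seven feature
classes: ``promoter`` (2 kb upstream of the TSS by default), ``utr5``,
``cds``, ``intron``, ``utr3``, ``downstream`` (2 kb past the TES), and
``intergenic`` (everything else). Overlapping candidate labels from
different genes are resolved by a fixed, configurable priority order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

FEATURE_CLASSES = (
    "promoter",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "downstream",
    "intergenic",
)

#: Default priority when candidate labels from different genes overlap.
#: Earlier entries win; anything unlabeled falls to ``intergenic``.
DEFAULT_PRIORITY = ("promoter", "utr5", "cds", "utr3", "downstream", "intron")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand-aware TSS/TES anchors plus exon/CDS structure."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[int, int] | None = None
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise AnnotationError(f"{self.gene_id}: zero-length gene (tss == tes == {self.tss})")
        if self.strand == "+" and not self.tss < self.tes:
            raise AnnotationError(f"{self.gene_id}: plus-strand gene requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise AnnotationError(f"{self.gene_id}: minus-strand gene requires tss > tes")
        lo, hi = self.body
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise AnnotationError(f"{self.gene_id}: exon [{s},{e}) outside gene body [{lo},{hi})")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not e0 <= s1:
                raise AnnotationError(f"{self.gene_id}: exons unsorted or overlapping")

    @property
    def body(self) -> tuple[int, int]:
        """Gene body ``[min(tss,tes), max(tss,tes))``, introns included."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter(self, promoter_bp: int = 2000) -> tuple[int, int]:
        """Strand-aware promoter window immediately upstream of the TSS."""
        if self.strand == "+":
            return (self.tss - promoter_bp, self.tss)
        return (self.tss, self.tss + promoter_bp)

    def downstream(self, downstream_bp: int = 2000) -> tuple[int, int]:
        """Strand-aware window immediately past the TES."""
        if self.strand == "+":
            return (self.tes, self.tes + downstream_bp)
        return (self.tes - downstream_bp, self.tes)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bases."""

    def __init__(self, mapping: dict[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(mapping)
        for name, length in self.items():
            if int(length) <= 0:
                raise AnnotationError(f"chromosome {name}: non-positive length {length}")
            self[name] = int(length)

    @property
    def total(self) -> int:
        return sum(self.values())

    @classmethod
    def read(cls, path: str | Path) -> "ChromSizes":
        """Read a two-column (name, length) TSV."""
        sizes = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise AnnotationError(f"{path}:{i}: expected two tab-separated columns")
                sizes[parts[0]] = int(parts[1])
        return cls(sizes)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class RegionPartition:
    """Disjoint labeled intervals covering every base of the genome.

    ``intervals[chrom]`` is a sorted list of ``(start, end, feature_class)``
    half-open triples whose union is ``[0, chrom_length)``; ``base_counts``
    totals the bases in each of the seven classes genome-wide.
    """

    intervals: dict[str, list[tuple[int, int, str]]]
    base_counts: dict[str, int]
    sizes: ChromSizes
    # per-chrom numpy views for O(log n) point lookup
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _labels: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, ivals in self.intervals.items():
            self._starts[chrom] = np.array([s for s, _, _ in ivals], dtype=np.int64)
            self._labels[chrom] = [c for _, _, c in ivals]

    def class_at(self, chrom: str, pos: int) -> str:
        """Feature class of the base at ``pos``."""
        if chrom not in self.intervals:
            raise KeyError(f"chromosome {chrom} not in partition")
        if not 0 <= pos < self.sizes[chrom]:
            raise ValueError(f"position {pos} outside chromosome {chrom} [0,{self.sizes[chrom]})")
        idx = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return self._labels[chrom][idx]

    def base_fractions(self) -> dict[str, float]:
        total = self.sizes.total
        return {c: self.base_counts.get(c, 0) / total for c in FEATURE_CLASSES}

    def write_bed(self, path: str | Path) -> None:
        """Write the partition as BED with the feature class in the name column."""
        with open(path, "w") as fh:
            for chrom in self.intervals:
                for s, e, c in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")

    def write_base_counts(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_class\tbases\n")
            for c in FEATURE_CLASSES:
                fh.write(f"{c}\t{self.base_counts.get(c, 0)}\n")


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

def _bed12_to_gene(fields: Sequence[str], lineno: int, path: str) -> GeneModel:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
    except (IndexError, ValueError) as exc:
        raise AnnotationError(f"{path}:{lineno}: malformed BED line ({exc})") from None
    if strand not in ("+", "-"):
        raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
    exons: tuple[tuple[int, int], ...] = ()
    cds = None
    if len(fields) >= 12:
        thick_start, thick_end = int(fields[6]), int(fields[7])
        n_blocks = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(block_sizes) != n_blocks or len(block_starts) != n_blocks:
            raise AnnotationError(f"{path}:{lineno}: block count mismatch")
        exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(block_starts, block_sizes))
        if thick_end > thick_start:
            cds = (thick_start, thick_end)
    else:
        exons = ((start, end),)
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id=name, chrom=chrom, strand=strand, tss=tss, tes=tes,
                     exons=exons, cds=cds)


def _parse_gtf_attrs(attr_field: str, lineno: int, path: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    if "gene_id" not in attrs:
        raise AnnotationError(f"{path}:{lineno}: GTF attributes lack gene_id")
    return attrs


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene annotations from a GTF or BED12 file.

    One :class:`GeneModel` per ``gene_id``. GTF coordinates (1-based closed)
    are converted to the internal 0-based half-open convention on read.
    When a gene has several transcripts in a GTF, the union of its exon
    intervals is merged into one model (logged).

    Parameters
    ----------
    path:
        Annotation file.
    format:
        ``"GTF"`` or ``"BED12"``; inferred from the file extension when None.
    """
    path = Path(path)
    if format is None:
        format = "GTF" if path.suffix.lower() in (".gtf", ".gff") else "BED12"
    format = format.upper()
    if format not in ("GTF", "BED12"):
        raise ValueError(f"unknown annotation format {format!r}")

    if format == "BED12":
        genes = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) >= 6 and fields[5] not in ("+", "-"):
                    logger.warning("%s:%d: record %s rejected (strand %r)", path, i,
                                   fields[3] if len(fields) > 3 else "?", fields[5])
                    continue
                genes.append(_bed12_to_gene(fields, i, str(path)))
        return genes

    # GTF: collect exon and CDS records per gene_id
    per_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{i}: GTF line has {len(fields)} fields, expected 9")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_field = fields[:9]
            if feature not in ("exon", "CDS", "gene", "transcript"):
                continue
            if strand not in ("+", "-"):
                logger.warning("%s:%d: record rejected (strand %r)", path, i, strand)
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # GTF 1-based closed -> half-open
            except ValueError:
                raise AnnotationError(f"{path}:{i}: non-integer coordinates") from None
            attrs = _parse_gtf_attrs(attr_field, i, str(path))
            gid = attrs["gene_id"]
            if gid not in per_gene:
                per_gene[gid] = {"chrom": chrom, "strand": strand, "exons": [],
                                 "cds": [], "symbol": attrs.get("gene_name")}
                order.append(gid)
            rec = per_gene[gid]
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise AnnotationError(f"{path}:{i}: gene {gid} spans chromosomes or strands")
            if feature == "exon":
                rec["exons"].append((start, end))
            elif feature == "CDS":
                rec["cds"].append((start, end))

    genes = []
    for gid in order:
        rec = per_gene[gid]
        exons = _merge_intervals(rec["exons"])
        if not exons:
            logger.warning("gene %s has no exon records; skipped", gid)
            continue
        lo, hi = exons[0][0], exons[-1][1]
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        tss, tes = (lo, hi) if rec["strand"] == "+" else (hi, lo)
        genes.append(GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                               tss=tss, tes=tes, exons=tuple(exons), cds=cds,
                               symbol=rec["symbol"]))
    return genes


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# Partition construction
# ---------------------------------------------------------------------------

def _gene_candidate_intervals(gene: GeneModel, promoter_bp: int, downstream_bp: int
                              ) -> dict[str, list[tuple[int, int]]]:
    """Candidate (unclipped) intervals per class for one gene.

    UTR/CDS labels come from the exon and CDS structure: exonic bases inside
    the CDS are ``cds``, exonic bases 5' of it are ``utr5`` and 3' of it
    ``utr3`` (strand-aware). A gene with no annotated CDS contributes all
    its exonic bases to the ``cds`` bucket so the seven classes stay fixed.
    Intron is the gene body minus exons.
    """
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in FEATURE_CLASSES if c != "intergenic"}
    out["promoter"].append(gene.promoter(promoter_bp))
    out["downstream"].append(gene.downstream(downstream_bp))

    lo, hi = gene.body
    exons = list(gene.exons) if gene.exons else [(lo, hi)]
    if gene.cds is None:
        out["cds"].extend(exons)
    else:
        cs, ce = gene.cds
        for s, e in exons:
            left = (s, min(e, cs))
            mid = (max(s, cs), min(e, ce))
            right = (max(s, ce), e)
            left_class, right_class = ("utr5", "utr3") if gene.strand == "+" else ("utr3", "utr5")
            if left[0] < left[1]:
                out[left_class].append(left)
            if mid[0] < mid[1]:
                out["cds"].append(mid)
            if right[0] < right[1]:
                out[right_class].append(right)

    # introns: gene body minus exons
    prev = lo
    for s, e in sorted(exons):
        if prev < s:
            out["intron"].append((prev, s))
        prev = max(prev, e)
    if prev < hi:
        out["intron"].append((prev, hi))
    return out


def build_partition(genes: Sequence[GeneModel], sizes: ChromSizes,
                    promoter_bp: int = 2000, downstream_bp: int = 2000,
                    priority: Sequence[str] = DEFAULT_PRIORITY) -> RegionPartition:
    """Label every genomic base with one of the seven feature classes.

    Overlaps are resolved by ``priority`` (earlier wins); bases claimed by
    no gene are intergenic. Promoter/downstream windows are clipped at the
    chromosome ends (logged).

    The implementation paints a per-base class-code array per chromosome,
    writing classes from lowest to highest priority so that later (higher
    priority) paints overwrite earlier ones, then extracts maximal runs.
    """
    if promoter_bp <= 0 or downstream_bp <= 0:
        raise ValueError("promoter_bp and downstream_bp must be positive")
    if sorted(priority) != sorted(c for c in FEATURE_CLASSES if c != "intergenic"):
        raise ValueError("priority must be a permutation of the six gene-derived classes")

    for g in genes:
        if g.chrom not in sizes:
            raise AnnotationError(f"gene {g.gene_id}: chromosome {g.chrom} absent from sizes")

    code_of = {c: np.uint8(i + 1) for i, c in enumerate(priority)}
    intergenic_code = np.uint8(0)
    class_of_code = {int(v): k for k, v in code_of.items()}
    class_of_code[0] = "intergenic"

    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in sizes}
    for g in genes:
        by_chrom[g.chrom].append(g)

    intervals: dict[str, list[tuple[int, int, str]]] = {}
    base_counts = {c: 0 for c in FEATURE_CLASSES}
    paint_order = list(reversed(priority))  # lowest priority first

    for chrom, length in sizes.items():
        arr = np.full(length, intergenic_code, dtype=np.uint8)
        cands = [(_gene_candidate_intervals(g, promoter_bp, downstream_bp), g) for g in by_chrom[chrom]]
        for cls in paint_order:
            code = code_of[cls]
            for cand, g in cands:
                for s, e in cand[cls]:
                    cs, ce = max(0, s), min(length, e)
                    if (cs, ce) != (s, e) and cls in ("promoter", "downstream"):
                        logger.info("gene %s: %s window [%d,%d) clipped to [%d,%d)",
                                    g.gene_id, cls, s, e, cs, ce)
                    if cs < ce:
                        arr[cs:ce] = code
        # extract maximal runs
        runs: list[tuple[int, int, str]] = []
        if length > 0:
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [length]))
            for s, e in zip(starts, ends):
                cls = class_of_code[int(arr[s])]
                runs.append((int(s), int(e), cls))
                base_counts[cls] += int(e - s)
        intervals[chrom] = runs

    return RegionPartition(intervals=intervals, base_counts=base_counts, sizes=sizes)
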
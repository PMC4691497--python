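"""Tag I/O, Poisson sliding-window peak calling, and library/peak summaries.

The caller scans fixed-width windows (2x the bandwidth, stepping by half a
bandwidth) against a single genome-wide Poisson background rate
``lambda_bg = library_size / genome_length``, keeps windows whose upper-tail
Poisson probability falls below the threshold, merges nearby significant
windows, and places the summit at the maximum of the extended-fragment
pileup inside each merged region. This is a deliberately transparent scan:
no fragment-shift model estimation and no local dynamic background, so a
``mfold`` parameter is accepted for interface compatibility but unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_model import ChromSizes

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TagSet:
    """Aligned tag 5' positions per chromosome, with strands.

    ``positions[chrom]`` is a sorted int64 array of 5' positions;
    ``strands[chrom]`` is a boolean array aligned with it (True = minus
    strand). ``library_size`` is the total tag count.
    """

    sample_id: str
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]
    read_length: int = 49

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = np.asarray(pos, dtype=np.int64)[order]
            self.strands[chrom] = np.asarray(self.strands[chrom], dtype=bool)[order]

    @property
    def library_size(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tag 5' ends in ``[start, end)``."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def read_tags(path: str | Path, sample_id: str, sizes: ChromSizes | None = None,
              read_length: int = 49) -> TagSet:
    """Read a BED-like tag file (chrom, start, end, name, score, strand).

    The tag 5' position is the interval start for plus-strand records and
    ``end - 1`` for minus-strand records. Positions are sorted per
    chromosome on read. When ``sizes`` is given, records on unknown
    chromosomes raise an error listing the offenders.
    """
    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_strand: dict[str, list[bool]] = {}
    unknown: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{i}: expected >=6 BED columns, got {len(f)}")
            chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{i}: unknown strand {strand!r}")
            if sizes is not None and chrom not in sizes:
                unknown.add(chrom)
                continue
            five_prime = start if strand == "+" else end - 1
            per_chrom_pos.setdefault(chrom, []).append(five_prime)
            per_chrom_strand.setdefault(chrom, []).append(strand == "-")
    if unknown:
        raise ValueError(f"{path}: records on chromosomes absent from sizes: {sorted(unknown)}")
    return TagSet(
        sample_id=sample_id,
        positions={c: np.array(v, dtype=np.int64) for c, v in per_chrom_pos.items()},
        strands={c: np.array(v, dtype=bool) for c, v in per_chrom_strand.items()},
        read_length=read_length,
    )


def write_tags(tags: TagSet, path: str | Path) -> None:
    """Write tags as 6-column BED (unit intervals at the 5' position)."""
    with open(path, "w") as fh:
        for chrom in sorted(tags.positions):
            pos = tags.positions[chrom]
            neg = tags.strands[chrom]
            for p, is_minus in zip(pos, neg):
                if is_minus:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t0\t-\n")
                else:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t0\t+\n")


@dataclass(frozen=True)
class PeakCallParams:
    """Parameters of the Poisson window scan.

    ``mfold`` is accepted for interface compatibility with model-building
    callers but is not used by the scan (logged once per run).
    """

    p_threshold: float = 1e-4
    bandwidth: int = 300
    mfold: float = 32.0
    extension: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.bandwidth <= 0 or self.extension <= 0:
            raise ValueError("bandwidth and extension must be positive")


@dataclass(frozen=True)
class Peak:
    """A called enriched interval."""

    chrom: str
    start: int
    end: int
    summit: int
    tag_count: int
    score: float  # -log10 of the best window p-value

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak [{self.start},{self.end}): start must precede end")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside peak [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def pileup(positions: np.ndarray, strands: np.ndarray, start: int, end: int,
           extension: int) -> np.ndarray:
    """Extended-fragment depth over ``[start, end)`` (unnormalized counts).

    Each tag is extended ``extension`` bases in its strand direction: a
    plus tag at p covers ``[p, p+extension)``, a minus tag at p covers
    ``(p-extension, p]`` i.e. ``[p-extension+1, p+1)``.
    """
    if end <= start:
        raise ValueError(f"inverted interval [{start},{end})")
    n = end - start
    diff = np.zeros(n + 1, dtype=np.int64)
    # fragments overlapping the region
    lo = np.searchsorted(positions, start - extension)
    hi = np.searchsorted(positions, end + extension)
    pos = positions[lo:hi]
    neg = strands[lo:hi]
    frag_start = np.where(neg, pos - extension + 1, pos)
    frag_end = frag_start + extension
    s = np.clip(frag_start - start, 0, n)
    e = np.clip(frag_end - start, 0, n)
    keep = e > s
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1])


def call_peaks(tags: TagSet, sizes: ChromSizes,
               params: PeakCallParams = PeakCallParams()) -> list[Peak]:
    """Call enriched intervals against a genome-wide Poisson background.

    Returns peaks sorted by (chrom, start). An empty result is not an
    error; an empty tag set is.
    """
    if tags.library_size == 0:
        raise ValueError("empty TagSet: cannot estimate background rate")
    genome_length = sizes.total
    if genome_length <= 0:
        raise ValueError("genome length must be positive")

    lam_bg = tags.library_size / genome_length
    width = 2 * params.bandwidth
    step = max(1, params.bandwidth // 2)
    mu = lam_bg * width
    logger.info("call_peaks[%s]: lambda_bg=%.3e/bp, window=%dbp, step=%dbp, mu=%.2f "
                "(mfold=%g accepted but unused)", tags.sample_id, lam_bg, width, step,
                params.mfold)

    # minimum count k* with P(X >= k*) < threshold; windows below never qualify
    k_min = int(stats.poisson.isf(params.p_threshold, mu)) + 1

    peaks: list[Peak] = []
    for chrom in sorted(sizes):
        length = sizes[chrom]
        pos = tags.positions.get(chrom, np.empty(0, dtype=np.int64))
        strand = tags.strands.get(chrom, np.empty(0, dtype=bool))
        if length < width:
            continue
        starts = np.arange(0, length - width + 1, step, dtype=np.int64)
        counts = np.searchsorted(pos, starts + width) - np.searchsorted(pos, starts)
        sig = counts >= k_min
        if not sig.any():
            continue
        sig_idx = np.flatnonzero(sig)
        sig_starts = starts[sig_idx]
        sig_counts = counts[sig_idx]
        pvals = stats.poisson.sf(sig_counts - 1, mu)

        # merge significant windows whose gap <= bandwidth
        merged: list[tuple[int, int, float]] = []  # (start, end, best_p)
        cur_s, cur_e, cur_p = int(sig_starts[0]), int(sig_starts[0]) + width, float(pvals[0])
        for ws, p in zip(sig_starts[1:], pvals[1:]):
            ws = int(ws)
            if ws - cur_e <= params.bandwidth:
                cur_e = ws + width
                cur_p = min(cur_p, float(p))
            else:
                merged.append((cur_s, cur_e, cur_p))
                cur_s, cur_e, cur_p = ws, ws + width, float(p)
        merged.append((cur_s, cur_e, cur_p))

        for s, e, best_p in merged:
            depth = pileup(pos, strand, s, e, params.extension)
            summit = s + int(np.argmax(depth))
            k = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            score = float(-np.log10(best_p)) if best_p > 0 else 324.0
            peaks.append(Peak(chrom=chrom, start=s, end=e, summit=summit,
                              tag_count=k, score=score))
    return peaks


# ---------------------------------------------------------------------------
# Summaries (table-style arithmetic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSummary:
    n_peaks: int
    total_length: int
    mean_length: int  # rounded half-up to integer
    median_length: float


def summarize_peaks(peaks: Sequence[Peak]) -> PeakSummary:
    """Peak-count and length summary (mean rounded half-up to an integer)."""
    if not peaks:
        raise ValueError("cannot summarize an empty peak list")
    lengths = np.array([p.length for p in peaks], dtype=np.int64)
    total = int(lengths.sum())
    return PeakSummary(
        n_peaks=len(peaks),
        total_length=total,
        mean_length=int(round_half_up(total / len(peaks))),
        median_length=float(np.median(lengths)),
    )


@dataclass(frozen=True)
class LibrarySummary:
    total_reads: int
    read_length: int
    output_bases: int
    mapped_reads: int
    unique_mapped_reads: int
    mapped_pct: float
    unique_pct: float


def summarize_library(total_reads: int, read_length: int, mapped_reads: int,
                      unique_mapped_reads: int) -> LibrarySummary:
    """Sequencing-library summary: output bases and mapping percentages.

    ``output_bases`` is the exact product reads x read length; percentages
    are 100 x count / total_reads, rounded half-up to two decimals.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= unique_mapped_reads <= mapped_reads <= total_reads:
        raise ValueError("require 0 <= unique_mapped <= mapped <= total reads")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return LibrarySummary(
        total_reads=total_reads,
        read_length=read_length,
        output_bases=total_reads * read_length,
        mapped_reads=mapped_reads,
        unique_mapped_reads=unique_mapped_reads,
        mapped_pct=round_half_up(100 * mapped_reads / total_reads, 2),
        unique_pct=round_half_up(100 * unique_mapped_reads / total_reads, 2),
    )


# ---------------------------------------------------------------------------
# Peak I/O (BED6+ with summit offset and tag count)
# ---------------------------------------------------------------------------

def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2: chrom start end name score strand summit_offset tag_count.

    The score column carries -log10(p) with 4 decimals.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:.4f}\t.\t"
                     f"{p.summit - p.start}\t{p.tag_count}\n")


def read_peaks(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{i}: expected 8 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                score = float(f[4])
                summit_off, tag_count = int(f[6]), int(f[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed peak row ({exc})") from None
            peaks.append(Peak(chrom=chrom, start=start, end=end,
                              summit=start + summit_off, tag_count=tag_count, score=score))
    return peaks
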
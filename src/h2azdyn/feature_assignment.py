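"""Assign peaks to feature classes; peak distributions and relative enrichment.

Each peak is assigned to exactly one class — the class of the partition
interval containing its summit — so class fractions sum to one. The
relative enrichment of a class is

    (peaks in class / total peaks) / (bases in class / total genome bases),

the ratio of the class's share of peaks to its share of the genome; 1
means no preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_model import FEATURE_CLASSES, RegionPartition
from .peakcall import Peak


@dataclass(frozen=True)
class DistributionTable:
    """Per-class peak counts and fractions; classes with zero peaks included."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total_peaks: int


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-class peak fraction, base fraction, and their ratio.

    Classes with zero genomic bases (and hence zero peaks under a complete
    partition) are omitted rather than reported as a division by zero.
    """

    peak_fractions: dict[str, float]
    base_fractions: dict[str, float]
    relative_enrichment: dict[str, float]


def assign_peak(peak: Peak, partition: RegionPartition) -> str:
    """Feature class of the partition interval containing the peak summit."""
    return partition.class_at(peak.chrom, peak.summit)


def peak_distribution(peaks: Sequence[Peak], partition: RegionPartition) -> DistributionTable:
    if not peaks:
        raise ValueError("cannot compute a distribution over zero peaks")
    counts = {c: 0 for c in FEATURE_CLASSES}
    for p in peaks:
        counts[assign_peak(p, partition)] += 1
    n = len(peaks)
    return DistributionTable(counts=counts,
                             fractions={c: counts[c] / n for c in FEATURE_CLASSES},
                             total_peaks=n)


def relative_enrichment(dist: DistributionTable, partition: RegionPartition) -> EnrichmentTable:
    base_fr = partition.base_fractions()
    peak_fr, re = {}, {}
    out_base = {}
    for c in FEATURE_CLASSES:
        if base_fr[c] == 0:
            if dist.counts.get(c, 0) > 0:
                raise ValueError(f"peaks assigned to class {c!r} which has zero bases")
            continue  # omit zero-base classes
        peak_fr[c] = dist.fractions[c]
        out_base[c] = base_fr[c]
        re[c] = dist.fractions[c] / base_fr[c]
    return EnrichmentTable(peak_fractions=peak_fr, base_fractions=out_base,
                           relative_enrichment=re)


def enrichment_frame(dist: DistributionTable, table: EnrichmentTable) -> pd.DataFrame:
    """One row per class: count, peak_fraction, base_fraction, relative_enrichment."""
    rows = []
    for c in FEATURE_CLASSES:
        if c not in table.base_fractions:
            continue
        rows.append({
            "feature_class": c,
            "peak_count": dist.counts[c],
            "peak_fraction": table.peak_fractions[c],
            "base_fraction": table.base_fractions[c],
            "relative_enrichment": table.relative_enrichment[c],
        })
    return pd.DataFrame(rows)


def write_enrichment(dist: DistributionTable, table: EnrichmentTable,
                     path: str | Path) -> None:
    enrichment_frame(dist, table).to_csv(path, sep="\t", index=False)
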
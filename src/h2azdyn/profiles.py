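"""Composite (metagene) coverage profiles around TSS/TES and expression strata.

A composite profile averages reads-per-million coverage in fixed-width
windows across a cohort of genes aligned at a common anchor (TSS or TES)
and oriented 5'->3' by strand. Expression stratification splits genes into
near-equal rank classes by decreasing expression (``high``, ``middle``,
``low``, ``lowest`` for the default four).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ChromSizes, GeneModel
from .peakcall import TagSet, pileup

logger = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = ("high", "middle", "low", "lowest")


@dataclass(frozen=True)
class ProfileCurve:
    """Windowed mean RPM coverage around an anchor across a gene cohort."""

    anchor: str  # "TSS" or "TES"
    flank: int
    window: int
    values: np.ndarray  # length 2*flank/window, ordered 5'->3'
    n_genes: int

    @property
    def offsets(self) -> np.ndarray:
        """Window midpoint offsets relative to the anchor (5'->3')."""
        n = len(self.values)
        return np.arange(n) * self.window - self.flank + self.window / 2

    def anchor_window_value(self) -> float:
        """Mean of the two windows straddling the anchor."""
        n = len(self.values)
        return float((self.values[n // 2 - 1] + self.values[n // 2]) / 2)


def coverage_vector(tags: TagSet, chrom: str, start: int, end: int,
                    extension: int = 150) -> np.ndarray:
    """Per-base RPM coverage of extended fragments over ``[start, end)``."""
    if end <= start:
        raise ValueError(f"inverted interval [{start},{end})")
    pos = tags.positions.get(chrom, np.empty(0, dtype=np.int64))
    strand = tags.strands.get(chrom, np.empty(0, dtype=bool))
    depth = pileup(pos, strand, start, end, extension)
    return depth * (1e6 / tags.library_size)


def _gene_anchor(gene: GeneModel, anchor: str) -> int:
    anchor = anchor.upper()
    if anchor == "TSS":
        return gene.tss
    if anchor == "TES":
        return gene.tes
    raise ValueError(f"anchor must be 'TSS' or 'TES', got {anchor!r}")


def composite_profile(tags: TagSet, genes: Sequence[GeneModel], sizes: ChromSizes,
                      anchor: str = "TSS", flank: int = 5000, window: int = 200,
                      extension: int = 150) -> ProfileCurve:
    """Mean windowed RPM coverage around the anchor over a gene cohort.

    Minus-strand genes are reversed so every per-gene vector runs 5'->3'.
    Genes whose anchor +- flank region crosses a chromosome boundary are
    excluded (counted and logged). Raises if no gene remains.
    """
    if not genes:
        raise ValueError("empty gene cohort")
    if flank % window != 0:
        raise ValueError(f"flank ({flank}) must be divisible by window ({window})")
    n_windows = 2 * flank // window
    acc = np.zeros(n_windows)
    n_used = 0
    n_excluded = 0
    for gene in genes:
        a = _gene_anchor(gene, anchor)
        lo, hi = a - flank, a + flank
        if lo < 0 or hi > sizes[gene.chrom]:
            n_excluded += 1
            continue
        cov = coverage_vector(tags, gene.chrom, lo, hi, extension)
        if gene.strand == "-":
            cov = cov[::-1]
        acc += cov.reshape(n_windows, window).mean(axis=1)
        n_used += 1
    if n_excluded:
        logger.info("composite_profile[%s,%s]: %d genes excluded at chromosome edges",
                    tags.sample_id, anchor, n_excluded)
    if n_used == 0:
        raise ValueError("no gene region fits within its chromosome at the given flank")
    return ProfileCurve(anchor=anchor.upper(), flank=flank, window=window,
                        values=acc / n_used, n_genes=n_used)


# ---------------------------------------------------------------------------
# Expression stratification
# ---------------------------------------------------------------------------

def stratify_by_expression(expression: Mapping[str, float], n_classes: int = 4,
                           class_names: Sequence[str] | None = None) -> dict[str, str]:
    """Split genes into near-equal classes of decreasing expression.

    Genes are ranked by decreasing expression value (ties broken by
    gene_id, lexicographic, so the split is deterministic) and cut into
    ``n_classes`` contiguous rank blocks; when the count does not divide
    evenly, earlier (higher-expression) classes take the remainder.

    Returns a mapping gene_id -> class label.
    """
    if len(expression) < n_classes:
        raise ValueError(f"need at least {n_classes} genes, got {len(expression)}")
    if class_names is None:
        class_names = (DEFAULT_CLASS_NAMES if n_classes == 4
                       else tuple(f"class_{i + 1}" for i in range(n_classes)))
    if len(class_names) != n_classes:
        raise ValueError("class_names length must equal n_classes")
    ranked = sorted(expression, key=lambda g: (-expression[g], g))
    n = len(ranked)
    base, rem = divmod(n, n_classes)
    labels: dict[str, str] = {}
    idx = 0
    for ci, name in enumerate(class_names):
        size = base + (1 if ci < rem else 0)
        for g in ranked[idx:idx + size]:
            labels[g] = name
        idx += size
    return labels


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column (gene_id, expression) TSV with a header."""
    df = pd.read_csv(path, sep="\t")
    gene_col, value_col = df.columns[0], df.columns[1]
    values = dict(zip(df[gene_col].astype(str), df[value_col].astype(float)))
    if any(v < 0 for v in values.values()):
        raise ValueError(f"{path}: expression values must be non-negative")
    return values


def stratified_profiles(tags: TagSet, genes: Sequence[GeneModel], sizes: ChromSizes,
                        expression: Mapping[str, float], anchor: str = "TSS",
                        flank: int = 5000, window: int = 200, extension: int = 150,
                        n_classes: int = 4) -> dict[str, ProfileCurve]:
    """One composite profile per expression class."""
    labels = stratify_by_expression(
        {g.gene_id: expression[g.gene_id] for g in genes if g.gene_id in expression},
        n_classes=n_classes)
    cohorts: dict[str, list[GeneModel]] = {}
    for g in genes:
        lab = labels.get(g.gene_id)
        if lab is not None:
            cohorts.setdefault(lab, []).append(g)
    out = {}
    for lab, cohort in cohorts.items():
        if not cohort:
            raise ValueError(f"expression class {lab!r} has no genes")
        out[lab] = composite_profile(tags, cohort, sizes, anchor=anchor, flank=flank,
                                     window=window, extension=extension)
    return out


def profile_frame(curves: Mapping[str, ProfileCurve]) -> pd.DataFrame:
    """Matrix of window-midpoint offsets vs mean RPM, one column per curve."""
    first = next(iter(curves.values()))
    df = pd.DataFrame({"offset": first.offsets})
    for name, curve in curves.items():
        df[name] = curve.values
    return df


def write_profiles(curves: Mapping[str, ProfileCurve], path: str | Path) -> None:
    profile_frame(curves).to_csv(path, sep="\t", index=False)


def plot_profiles(curves: Mapping[str, ProfileCurve], path: str | Path,
                  title: str = "") -> None:
    """Write a simple line plot of one or more composite curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve.offsets, curve.values, label=name)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean coverage (RPM)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
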
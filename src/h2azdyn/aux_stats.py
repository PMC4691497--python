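"""Gene-set over-representation, rank-percentile reporting, and qPCR folds.

Over-representation uses the plain hypergeometric upper tail with
Benjamini-Hochberg adjustment across the reported terms — a transparent
generic test, not a replica of any annotation web service's modified
score. Rank percentiles normalize a term's position in each sample's
sorted term table to a 0-100 scale so term prominence can be compared
across samples with different table sizes. ChIP-qPCR enrichment over the
IgG control is the standard 2^(Ct_IgG - Ct_ChIP) fold.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ora(query_genes: set[str], term_map: Mapping[str, set[str]],
        universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene sets.

    For each term with gene set of size K in a universe of size N, and a
    query of size n overlapping the term in k genes, the p-value is the
    hypergeometric upper tail P(X >= k). BH adjustment runs across all
    reported terms. Returns a DataFrame sorted by ascending p (ties by
    term_id) with columns term_id, K, k, p, q, neg_log10_p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query_genes:
        raise ValueError("empty query gene list")
    if not query_genes <= universe:
        extra = sorted(query_genes - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    n_universe = len(universe)
    n_query = len(query_genes)
    rows = []
    for term_id, term_genes in term_map.items():
        if not term_genes <= universe:
            extra = sorted(term_genes - universe)[:5]
            raise ValueError(f"term {term_id!r} has genes outside the universe, e.g. {extra}")
        big_k = len(term_genes)
        k = len(term_genes & query_genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append({"term_id": term_id, "K": big_k, "k": k, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["neg_log10_p"] = -np.log10(df["p"])
    return df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def term_rank_percentile(term_tables: Mapping[str, pd.DataFrame],
                         term_id: str) -> dict[str, float | None]:
    """Percentile rank of a term within each sample's sorted term table.

    percentile = 100 * rank / n_terms with rank the 1-based position by
    ascending p (ties broken by term_id). A sample whose table lacks the
    term maps to None, never to 0.
    """
    out: dict[str, float | None] = {}
    for sample, table in term_tables.items():
        ordered = table.sort_values(["p", "term_id"], kind="stable")["term_id"].tolist()
        if term_id not in ordered:
            out[sample] = None
            continue
        rank = ordered.index(term_id) + 1
        out[sample] = 100.0 * rank / len(ordered)
    return out


def qpcr_fold(ct_chip: float, ct_igg: float) -> float:
    """ChIP-qPCR fold enrichment over the IgG control: 2^(Ct_IgG - Ct_ChIP)."""
    if not (math.isfinite(ct_chip) and math.isfinite(ct_igg)):
        raise ValueError("Ct values must be finite")
    if ct_chip <= 0 or ct_igg <= 0:
        raise ValueError("Ct values must be positive")
    return 2.0 ** (ct_igg - ct_chip)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, genes... per line."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs term, description, >=1 gene")
            term_map[fields[0]] = set(fields[2:])
    return term_map


def write_term_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
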
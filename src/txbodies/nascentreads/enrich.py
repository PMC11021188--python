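"""Chromosome-level gene-set enrichment: ratio, hypergeometric tail, BH."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["chrom_enrichment"]


def chrom_enrichment(
    gene_set: set[str], universe: dict[str, str]
) -> pd.DataFrame:
    """Per-chromosome enrichment of ``gene_set`` against the gene universe.

    ratio = (k/n)/(K/N) with N genes total, K on the chromosome, n in the
    set and k of those on the chromosome; p is the upper-tail hypergeometric
    P(X ≥ k); adjusted across chromosomes with Benjamini–Hochberg.
    """
    unknown = gene_set - set(universe)
    if unknown:
        raise ValueError(f"gene_set contains genes outside the universe: {sorted(unknown)[:5]}")
    n_total = len(universe)
    n_set = len(gene_set)
    if n_set == 0:
        raise ValueError("gene_set is empty")
    chroms = sorted(set(universe.values()))
    rows = []
    for chrom in chroms:
        K = sum(1 for c in universe.values() if c == chrom)
        k = sum(1 for g in gene_set if universe[g] == chrom)
        ratio = (k / n_set) / (K / n_total)
        p = float(stats.hypergeom.sf(k - 1, n_total, K, n_set))
        rows.append({"chrom": chrom, "N": n_total, "K": K, "n": n_set, "k": k,
                     "ratio": ratio, "p_value": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
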
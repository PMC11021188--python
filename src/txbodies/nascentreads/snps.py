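"""Natural-SNP calling on pileup columns and multi-sample consensus.

Thresholds mirror the upstream caller's printed settings: min coverage 20,
min variant-supporting reads 5, min mean variant base quality 15, min
variant frequency 0.25, significance ≤ 0.01. The significance model is a
one-sided exact binomial test of the variant-read count against a 1%
per-base error null (a documented, pluggable approximation of the original
tool's test).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .pileup import PileupColumn

__all__ = ["SnpCallParams", "SNPRecord", "binomial_significance", "call_snps",
           "consensus_snps", "snps_to_frame"]


@dataclass(frozen=True)
class SnpCallParams:
    min_coverage: int = 20
    min_reads2: int = 5
    min_avg_qual: float = 15.0
    min_var_freq: float = 0.25
    max_p: float = 0.01
    error_rate: float = 0.01  # per-base null for the significance test


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    frequency: float
    supporting_reads: int
    p_value: float


def binomial_significance(variant_reads: int, coverage: int, error_rate: float = 0.01) -> float:
    """P(X ≥ variant_reads) for X ~ Binomial(coverage, error_rate)."""
    if coverage == 0:
        return 1.0
    return float(
        stats.binomtest(variant_reads, coverage, error_rate, alternative="greater").pvalue
    )


def call_snps(
    columns: list[PileupColumn], params: SnpCallParams = SnpCallParams()
) -> list[SNPRecord]:
    """A column is a SNP iff all five thresholds pass simultaneously."""
    out = []
    for c in columns:
        if c.variant_base is None:
            continue
        if c.coverage < params.min_coverage:
            continue
        if c.variant_reads < params.min_reads2:
            continue
        if c.mean_variant_quality < params.min_avg_qual:
            continue
        if c.variant_frequency < params.min_var_freq:
            continue
        p = binomial_significance(c.variant_reads, c.coverage, params.error_rate)
        if p > params.max_p:
            continue
        out.append(
            SNPRecord(
                chrom=c.chrom,
                pos=c.pos,
                ref=c.ref_base,
                alt=c.variant_base,
                frequency=c.variant_frequency,
                supporting_reads=c.variant_reads,
                p_value=p,
            )
        )
    return out


def consensus_snps(per_sample_snps: list[list[SNPRecord]]) -> set[tuple[str, int, str]]:
    """Union of per-sample SNP calls, keyed by (chrom, pos, alt)."""
    if not per_sample_snps:
        raise ValueError("at least one sample required")
    out: set[tuple[str, int, str]] = set()
    for sample in per_sample_snps:
        out.update((s.chrom, s.pos, s.alt) for s in sample)
    return out


def snps_to_frame(snps: list[SNPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "frequency": s.frequency,
                "supporting_reads": s.supporting_reads,
                "p_value": s.p_value,
            }
            for s in snps
        ],
        columns=["chrom", "pos", "ref", "alt", "frequency", "supporting_reads", "p_value"],
    )
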
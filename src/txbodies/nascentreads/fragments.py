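"""Strand-aware conversion classification of read pairs with SNP masking.

Transcript sense is inferred from the mate flags of the reverse-stranded
library: read 2 maps in the transcript's orientation. Candidate conversions
are genomic T→C mismatches for plus-sense fragments and A→G for minus-sense
fragments, recomputed directly against the reference (MD tags are only a
cross-check elsewhere). Positions in the SNP consensus and bases below the
quality cutoff never count; positions covered by both mates count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pysam

__all__ = ["FragmentClassification", "pair_fragments", "classify_fragment",
           "classify_fragments", "classifications_to_frame"]


@dataclass
class FragmentClassification:
    fragment_id: str
    chrom: str
    strand: str  # inferred transcript strand
    conversions: list[tuple[int, str, str, int]] = field(default_factory=list)
    n_conversions: int = 0
    labeled: bool = False
    orphan: bool = False


def pair_fragments(
    alignments: list[pysam.AlignedSegment],
) -> dict[str, list[pysam.AlignedSegment]]:
    """Group primary alignments into fragments by query name."""
    pairs: dict[str, list[pysam.AlignedSegment]] = {}
    for a in alignments:
        if a.is_secondary or a.is_supplementary or a.is_unmapped or a.is_duplicate:
            continue
        pairs.setdefault(a.query_name, []).append(a)
    return pairs


def _transcript_strand(reads: list[pysam.AlignedSegment]) -> str:
    """RF library: read 2's mapping orientation is the transcript sense."""
    for a in reads:
        if a.is_read2:
            return "-" if a.is_reverse else "+"
    # orphan read 1: its orientation is anti-sense to the transcript
    a = reads[0]
    return "+" if a.is_reverse else "-"


def classify_fragment(
    reads: list[pysam.AlignedSegment],
    reference: dict[str, str],
    snps: set[tuple[str, int]],
    min_base_quality: int = 20,
) -> FragmentClassification:
    """Classify one fragment (1 or 2 mates) as labeled or unlabeled."""
    strand = _transcript_strand(reads)
    chrom = reads[0].reference_name
    want_ref, want_alt = ("T", "C") if strand == "+" else ("A", "G")
    ref_seq = reference[chrom]
    seen: dict[int, tuple[int, str, str, int]] = {}
    for a in reads:
        seq = a.query_sequence
        quals = a.query_qualities
        if seq is None:
            continue
        for qpos, rpos in a.get_aligned_pairs(matches_only=True):
            if (chrom, rpos) in snps:
                continue
            q = quals[qpos] if quals is not None else 0
            if q < min_base_quality:
                continue
            if ref_seq[rpos].upper() == want_ref and seq[qpos].upper() == want_alt:
                if rpos not in seen:
                    seen[rpos] = (rpos, want_ref, want_alt, q)
    conversions = [seen[p] for p in sorted(seen)]
    return FragmentClassification(
        fragment_id=reads[0].query_name,
        chrom=chrom,
        strand=strand,
        conversions=conversions,
        n_conversions=len(conversions),
        labeled=len(conversions) >= 1,
        orphan=len(reads) < 2,
    )


def classify_fragments(
    alignments: list[pysam.AlignedSegment],
    reference: dict[str, str],
    snps: set[tuple[str, int]],
    min_base_quality: int = 20,
) -> list[FragmentClassification]:
    pairs = pair_fragments(alignments)
    return [
        classify_fragment(reads, reference, snps, min_base_quality)
        for _, reads in sorted(pairs.items())
    ]


def classifications_to_frame(frags: list[FragmentClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "chrom": f.chrom,
                "strand": f.strand,
                "n_conversions": f.n_conversions,
                "labeled": f.labeled,
                "orphan": f.orphan,
                "conversion_positions": ",".join(str(c[0]) for c in f.conversions),
            }
            for f in frags
        ],
        columns=[
            "fragment_id", "chrom", "strand", "n_conversions", "labeled",
            "orphan", "conversion_positions",
        ],
    )
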
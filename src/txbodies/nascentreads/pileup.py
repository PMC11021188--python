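"""Pileup construction from primary alignments against a reference."""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

__all__ = ["PileupColumn", "load_alignments", "load_reference", "build_pileup"]

_BASES = "ACGT"


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in _BASES})
    variant_base: str | None = None
    variant_reads: int = 0
    coverage: int = 0
    mean_variant_quality: float = 0.0
    variant_frequency: float = 0.0


def load_reference(path: str) -> dict[str, str]:
    """Read a FASTA into a chrom → sequence dict (small references only)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_alignments(path: str) -> list[pysam.AlignedSegment]:
    """Primary, mapped, non-duplicate alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return [
            a
            for a in fh
            if not a.is_unmapped
            and not a.is_secondary
            and not a.is_supplementary
            and not a.is_duplicate
        ]


def build_pileup(
    alignments: list[pysam.AlignedSegment],
    reference: dict[str, str],
) -> list[PileupColumn]:
    """One column per covered reference position, sorted by (chrom, pos).

    Soft-clipped bases never contribute (they have no reference position);
    deleted reference positions are skipped. The variant base of a column is
    its most frequent non-reference base; ties resolve alphabetically.
    """
    acc: dict[tuple[str, int], dict] = {}
    for a in alignments:
        chrom = a.reference_name
        seq = a.query_sequence
        quals = a.query_qualities
        if seq is None:
            continue
        for qpos, rpos in a.get_aligned_pairs(matches_only=True):
            base = seq[qpos].upper()
            if base not in _BASES:
                continue
            key = (chrom, rpos)
            col = acc.setdefault(
                key, {"counts": {b: 0 for b in _BASES}, "quals": {b: [] for b in _BASES}}
            )
            col["counts"][base] += 1
            col["quals"][base].append(quals[qpos] if quals is not None else 0)

    columns: list[PileupColumn] = []
    for (chrom, pos) in sorted(acc):
        entry = acc[(chrom, pos)]
        ref_base = reference[chrom][pos].upper()
        counts = entry["counts"]
        coverage = sum(counts.values())
        non_ref = [(b, n) for b, n in counts.items() if b != ref_base and n > 0]
        if non_ref:
            non_ref.sort(key=lambda x: (-x[1], x[0]))
            vb, vn = non_ref[0]
            quals = entry["quals"][vb]
            mean_q = sum(quals) / len(quals) if quals else 0.0
        else:
            vb, vn, mean_q = None, 0, 0.0
        columns.append(
            PileupColumn(
                chrom=chrom,
                pos=pos,
                ref_base=ref_base,
                base_counts=counts,
                variant_base=vb,
                variant_reads=vn,
                coverage=coverage,
                mean_variant_quality=mean_q,
                variant_frequency=vn / coverage if coverage else 0.0,
            )
        )
    return columns
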
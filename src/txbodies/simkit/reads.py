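"""Synthetic aligned read sets with planted conversions, SNPs and errors.

Emits plain-text SAM (minimal valid header, MD tags, mate flags, no
secondary/supplementary records) plus the reference FASTA and a complete
ground truth. Library layout is reverse-stranded paired-end: read 2 carries
the transcript-sense sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..genemodels import Gene
from .truth import FragmentTruth, GroundTruth, SnpTruth

__all__ = [
    "gen_reference",
    "gen_read_set",
    "write_sam",
    "write_fasta",
    "md_tag",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def gen_reference(genes: list[Gene], seed: int, pad: int = 50) -> dict[str, str]:
    """Random reference sequences long enough to hold every gene plus padding."""
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.span[1] + pad)
    return {
        chrom: "".join(rng.choice(list(_BASES), size=n))
        for chrom, n in sorted(lengths.items())
    }


def md_tag(read_seq: str, ref_seq: str) -> str:
    """MD tag for an all-match CIGAR alignment of equal-length sequences."""
    parts: list[str] = []
    run = 0
    for r, q in zip(ref_seq, read_seq):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


@dataclass
class SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based leftmost
    mapq: int
    cigar: str
    mate_pos: int
    tlen: int
    seq: str  # reference-forward orientation, as stored in SAM
    qual: str
    md: str

    def to_line(self) -> str:
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                self.chrom,
                str(self.pos + 1),
                str(self.mapq),
                self.cigar,
                "=",
                str(self.mate_pos + 1),
                str(self.tlen),
                self.seq,
                self.qual,
                f"MD:Z:{self.md}",
                "NM:i:" + str(sum(1 for c in self.md if c in _BASES)),
            ]
        )


def gen_read_set(
    genes: list[Gene],
    p_label: float,
    p_conv: float,
    snps: list[tuple[str, int]],
    err: float,
    n_fragments: int,
    seed: int,
    reference: dict[str, str] | None = None,
    read_len: int = 60,
    frag_len_range: tuple[int, int] = (100, 180),
    base_quality: int = 37,
) -> tuple[list[SamRecord], dict[str, str], GroundTruth]:
    """Simulate aligned paired-end fragments over exons of ``genes``.

    A fragment is labeled with probability ``p_label``; labeled fragments
    convert each eligible transcript-sense uridine (genomic T on + genes,
    A on − genes, SNP positions excluded) with probability ``p_conv``.
    SNP alleles (transitions of the reference base) are planted in every
    overlapping fragment regardless of label; sequencing errors hit each
    read base independently with probability ``err``.
    """
    for p, name in ((p_label, "p_label"), (p_conv, "p_conv"), (err, "err")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    for g in genes:
        if g.exonic_length == 0:
            raise ValueError(f"gene {g.gene_id} has zero exonic length")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = gen_reference(genes, seed=seed)

    snp_map: dict[tuple[str, int], tuple[str, str]] = {}
    truth = GroundTruth(seed=seed)
    for chrom, pos in sorted(set(snps)):
        ref_base = reference[chrom][pos]
        alt = _TRANSITION[ref_base]
        snp_map[(chrom, pos)] = (ref_base, alt)
        truth.snps.append(SnpTruth(chrom=chrom, pos=pos, ref=ref_base, alt=alt))

    fl_lo, fl_hi = frag_len_range
    usable = []
    for g in genes:
        exons = [(s, e) for s, e in g.exons if e - s >= read_len]
        if exons:
            usable.append((g, exons, [e - s for s, e in exons]))
    if not usable:
        raise ValueError(f"no exon is at least read_len={read_len} nt long")

    records: list[SamRecord] = []
    qual_str = chr(33 + base_quality) * read_len
    sense_base = {"+": "T", "-": "A"}

    for i in range(n_fragments):
        g, exons, weights = usable[rng.integers(len(usable))]
        w = np.asarray(weights, dtype=float)
        ei = rng.choice(len(exons), p=w / w.sum())
        s, e = exons[ei]
        max_fl = min(fl_hi, e - s)
        frag_len = int(rng.integers(max(fl_lo, read_len), max_fl + 1)) if max_fl > max(
            fl_lo, read_len
        ) else max(read_len, min(fl_lo, max_fl))
        start = int(s + rng.integers(0, e - s - frag_len + 1))
        end = start + frag_len
        ref = reference[g.chrom]

        mods: dict[int, str] = {}
        for pos in range(start, end):
            hit = snp_map.get((g.chrom, pos))
            if hit is not None:
                mods[pos] = hit[1]

        labeled = bool(rng.random() < p_label)
        conv_positions: list[int] = []
        if labeled:
            target = sense_base[g.strand]
            for pos in range(start, end):
                if (g.chrom, pos) in snp_map or ref[pos] != target:
                    continue
                if rng.random() < p_conv:
                    mods[pos] = _TRANSITION[target]
                    conv_positions.append(pos)

        frag_seq = list(ref[start:end])
        for pos, base in mods.items():
            frag_seq[pos - start] = base

        spans = {"left": (start, start + read_len), "right": (end - read_len, end)}
        if g.strand == "+":
            layout = {"r2": ("left", False), "r1": ("right", True)}
        else:
            layout = {"r2": ("right", True), "r1": ("left", False)}

        qname = f"frag{i:06d}"
        read_mismatches: dict[str, list] = {}
        rec_pair: dict[str, SamRecord] = {}
        for rname, (side, is_rev) in layout.items():
            rs, re_ = spans[side]
            seq = frag_seq[rs - start : re_ - start].copy()
            for j in range(len(seq)):
                if rng.random() < err:
                    choices = [b for b in _BASES if b != seq[j]]
                    seq[j] = choices[rng.integers(3)]
            seq_s = "".join(seq)
            ref_s = ref[rs:re_]
            read_mismatches[rname] = [
                [rs + j, seq_s[j]] for j in range(read_len) if seq_s[j] != ref_s[j]
            ]
            flag = 0x1 | 0x2
            flag |= 0x40 if rname == "r1" else 0x80
            if is_rev:
                flag |= 0x10
            else:
                flag |= 0x20
            mate_side = "right" if side == "left" else "left"
            tlen = frag_len if side == "left" else -frag_len
            rec_pair[rname] = SamRecord(
                qname=qname,
                flag=flag,
                chrom=g.chrom,
                pos=rs,
                mapq=60,
                cigar=f"{read_len}M",
                mate_pos=spans[mate_side][0],
                tlen=tlen,
                seq=seq_s,
                qual=qual_str,
                md=md_tag(seq_s, ref_s),
            )
        records.extend([rec_pair["r1"], rec_pair["r2"]])
        truth.fragments.append(
            FragmentTruth(
                fragment_id=qname,
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                start=start,
                end=end,
                labeled=labeled,
                conversion_positions=conv_positions,
                read_mismatches=read_mismatches,
            )
        )

    records.sort(key=lambda r: (r.chrom, r.pos, r.qname, r.flag))
    return records, reference, truth


def write_sam(records: list[SamRecord], reference: dict[str, str], path: str | Path) -> None:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in sorted(reference):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(reference[chrom])}")
    lines.extend(r.to_line() for r in records)
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    out = []
    for chrom in sorted(reference):
        out.append(f">{chrom}")
        seq = reference[chrom]
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(out) + "\n")
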
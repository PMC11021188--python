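"""Minimal gene models (exon unions) with GTF read/write.

Coordinates are 0-based half-open internally; the GTF boundary converts to
and from the format's 1-based inclusive convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Gene", "merge_intervals", "read_gtf", "write_gtf"]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted union."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = merge_intervals([(int(s), int(e)) for s, e in self.exons])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gtf(path: str | Path) -> list[Gene]:
    """Parse exon records of a GTF into Gene objects (grouped by gene_id)."""
    genes: dict[str, Gene] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        attrs = dict(_ATTR_RE.findall(f[8]))
        gid = attrs.get("gene_id")
        if gid is None:
            raise ValueError(f"exon record without gene_id: {line}")
        start, end = int(f[3]) - 1, int(f[4])
        g = genes.get(gid)
        if g is None:
            genes[gid] = Gene(gene_id=gid, chrom=f[0], strand=f[6], exons=[(start, end)])
        else:
            if g.chrom != f[0] or g.strand != f[6]:
                raise ValueError(f"inconsistent chrom/strand for gene {gid}")
            g.exons = merge_intervals(g.exons + [(start, end)])
    return list(genes.values())


def write_gtf(genes: list[Gene], path: str | Path) -> None:
    lines = []
    for g in genes:
        for s, e in g.exons:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            lines.append(
                "\t".join(
                    [g.chrom, "sim", "exon", str(s + 1), str(e), ".", g.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
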
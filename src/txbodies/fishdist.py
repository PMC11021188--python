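"""DNA-FISH downstream analysis and Oligopaint probe validation.

Assigns localized spots to nuclei, keeps per-channel allele spots (the 20
brightest gene spots and the 2 brightest locus spots per nucleus), computes
3D distances from each gene spot to the nearest selected locus spot, and
reports the fraction colocalized within a radius (default 0.5 μm, strict
inequality). Probe oligos are validated against the library's structural
rules: six ordered segments, assembled length 130–137 nt, density 10 ± 1
probes per kilobase, ≥400 probes over ≥40 kb of gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .spotfit import SpotRecord, top_k_brightest

__all__ = [
    "DistanceRecord",
    "ProbeOligo",
    "SEGMENT_ORDER",
    "assign_spots_to_nuclei",
    "select_allele_spots",
    "distances_to_locus",
    "colocalized_fraction",
    "assemble_and_validate_probes",
]

SEGMENT_ORDER = (
    "forward_priming",
    "rt_priming",
    "gene_readout",
    "genomic_target",
    "group_readout",
    "reverse_priming",
)

_IUPAC = set("ACGTURYSWKMBDHVN")

LENGTH_WINDOW = (130, 137)
DENSITY_WINDOW = (9.0, 11.0)
MIN_PROBES = 400
MIN_GENE_LENGTH = 40_000


@dataclass
class DistanceRecord:
    nucleus: int
    gene_group: str | None
    spot_um: tuple[float, float, float]
    nearest_locus_um: tuple[float, float, float]
    distance_um: float


@dataclass
class ProbeOligo:
    gene_id: str
    group: str
    segments: dict[str, str]
    sequence: str = ""
    flags: list[str] = field(default_factory=list)


def assign_spots_to_nuclei(
    spots: list[SpotRecord], nuclei_labels: np.ndarray
) -> tuple[list[SpotRecord], int]:
    """Label each spot with the nucleus containing its rounded center voxel.

    Spots whose center voxel falls outside every nucleus (or outside the
    image) are dropped; the drop count is returned alongside the kept spots.
    """
    kept: list[SpotRecord] = []
    dropped = 0
    shape = np.asarray(nuclei_labels.shape)
    for s in spots:
        vox = np.round(s.center_vox).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            dropped += 1
            continue
        label = int(nuclei_labels[tuple(vox)])
        if label == 0:
            dropped += 1
            continue
        s.nucleus = label
        kept.append(s)
    return kept, dropped


def select_allele_spots(
    spots: list[SpotRecord],
    k_gene: int = 20,
    k_locus: int = 2,
    locus_channel: str = "mir430",
) -> tuple[dict[tuple[int, str], list[SpotRecord]], dict[tuple[int, str], bool]]:
    """Keep the brightest spots per nucleus per channel.

    The locus channel keeps ``k_locus`` spots (diploid alleles), every other
    channel ``k_gene``. Returns the selection and a per-(nucleus, channel)
    shortfall flag for groups with fewer spots than requested.
    """
    groups: dict[tuple[int, str], list[SpotRecord]] = {}
    for s in spots:
        if s.nucleus is None:
            raise ValueError("spots must be assigned to nuclei first")
        groups.setdefault((s.nucleus, s.channel or ""), []).append(s)
    selected: dict[tuple[int, str], list[SpotRecord]] = {}
    shortfall: dict[tuple[int, str], bool] = {}
    for key, grp in sorted(groups.items()):
        k = k_locus if key[1] == locus_channel else k_gene
        selected[key], shortfall[key] = top_k_brightest(grp, k)
    return selected, shortfall


def distances_to_locus(
    gene_spots: list[SpotRecord],
    locus_spots: list[SpotRecord],
    gene_group: str | None = None,
) -> list[DistanceRecord]:
    """Euclidean μm distance from each gene spot to its nearest locus spot.

    Both lists must belong to one nucleus; an empty side means the nucleus
    is skipped upstream (callers log it), so here it is an error.
    """
    if not gene_spots or not locus_spots:
        raise ValueError("both gene and locus spot sets must be non-empty")
    locus_centers = np.asarray([s.center_um for s in locus_spots], dtype=float)
    out = []
    for s in gene_spots:
        c = np.asarray(s.center_um, dtype=float)
        d = np.linalg.norm(locus_centers - c, axis=1)
        j = int(np.argmin(d))
        out.append(
            DistanceRecord(
                nucleus=s.nucleus if s.nucleus is not None else -1,
                gene_group=gene_group,
                spot_um=tuple(float(v) for v in c),
                nearest_locus_um=tuple(float(v) for v in locus_centers[j]),
                distance_um=float(d[j]),
            )
        )
    return out


def colocalized_fraction(
    records: list[DistanceRecord], radius_um: float = 0.5
) -> tuple[float, int, int]:
    """Fraction of distance records strictly below the radius.

    Returns (fraction, n_colocalized, n_total); pooled over all records.
    """
    if not records:
        raise ValueError("no distance records")
    n_coloc = sum(1 for r in records if r.distance_um < radius_um)
    return n_coloc / len(records), n_coloc, len(records)


def _validate_segment(seq: str) -> bool:
    return bool(seq) and all(c in _IUPAC for c in seq.upper())


def assemble_and_validate_probes(
    segments: pd.DataFrame, gene_lengths: dict[str, int]
) -> tuple[list[ProbeOligo], pd.DataFrame]:
    """Assemble six-segment oligos 5′→3′ and QC them against the library rules.

    ``segments`` needs columns ``gene_id``, ``group`` and the six segment
    names in :data:`SEGMENT_ORDER`. Per-probe flag: assembled length outside
    [130, 137] nt. Per-gene flags: probe density outside 10 ± 1 per kb,
    fewer than 400 probes, gene shorter than 40 kb.
    """
    missing = [c for c in ("gene_id", "group", *SEGMENT_ORDER) if c not in segments]
    if missing:
        raise ValueError(f"segments table missing columns: {missing}")
    probes: list[ProbeOligo] = []
    for _, row in segments.iterrows():
        segs = {name: str(row[name]).upper() for name in SEGMENT_ORDER}
        for name, seq in segs.items():
            if not _validate_segment(seq):
                raise ValueError(
                    f"probe for {row['gene_id']}: segment {name!r} is not a "
                    f"valid IUPAC nucleotide string: {seq!r}"
                )
        seq = "".join(segs[name] for name in SEGMENT_ORDER)
        flags = []
        if not LENGTH_WINDOW[0] <= len(seq) <= LENGTH_WINDOW[1]:
            flags.append("length_out_of_range")
        probes.append(
            ProbeOligo(
                gene_id=str(row["gene_id"]),
                group=str(row["group"]),
                segments=segs,
                sequence=seq,
                flags=flags,
            )
        )

    qc_rows = []
    by_gene: dict[str, list[ProbeOligo]] = {}
    for p in probes:
        by_gene.setdefault(p.gene_id, []).append(p)
    for gene_id, plist in sorted(by_gene.items()):
        length = gene_lengths.get(gene_id)
        if length is None:
            raise ValueError(f"no gene length supplied for {gene_id}")
        n = len(plist)
        density = n / (length / 1000.0)
        flags = []
        if not DENSITY_WINDOW[0] <= density <= DENSITY_WINDOW[1]:
            flags.append("density_out_of_range")
        if n < MIN_PROBES:
            flags.append("too_few_probes")
        if length < MIN_GENE_LENGTH:
            flags.append("gene_too_short")
        n_bad_length = sum(1 for p in plist if p.flags)
        qc_rows.append(
            {
                "gene_id": gene_id,
                "group": plist[0].group,
                "n_probes": n,
                "gene_length_bp": length,
                "density_per_kb": density,
                "n_length_flagged": n_bad_length,
                "flags": ";".join(flags),
                "pass": not flags and n_bad_length == 0,
            }
        )
    return probes, pd.DataFrame(qc_rows)
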
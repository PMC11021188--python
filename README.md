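# txbodies

A toolkit for the quantitative analysis of nuclear transcription bodies and
conversion-based nascent-transcript sequencing, with a first-class synthetic
data generator so every pipeline stage is testable against known ground
truth.

## What it does

| Module | Purpose |
| --- | --- |
| `txbodies.simkit` | Synthetic inputs with machine-readable ground truth: ellipsoidal nuclei in 3D label images, diffraction-limited Gaussian spots with Poisson(+Gaussian) noise, multi-channel body scenes with analytic enrichment expectations, timelapses with body appearance / fusion / envelope-breakdown events, and RF-stranded paired-end SAM read sets carrying planted T→C conversions, SNPs and sequencing errors. |
| `txbodies.spotfit` | Sub-voxel 3D spot localization: difference-of-Gaussians band-pass, 26-connected local-maxima detection, and an iterative fixed-σ Gaussian-mask centroid fit yielding coordinates (voxels and μm) and intensities; `top_k_brightest` selection. |
| `txbodies.bodies` | Transcription-body detection inside segmented nuclei, reporter-overlap identity classification (mir430 vs ectopic), initiation/elongation state pairing, per-nucleus tracking with cell-cycle alignment (t = 0 at first body appearance, envelope-breakdown exclusion, fusion-preserving counts), and per-timepoint summaries. |
| `txbodies.enrichquant` | Per-nucleus enrichment statistics for the two large bodies — percentage area, percentage intensity, intensity enrichment (observed/expected) — with no-primary background correction, plus the eGFP/RFP sensor ratio. |
| `txbodies.fishdist` | DNA-FISH downstream analysis: nucleus assignment, per-channel allele selection (20 brightest gene spots, 2 brightest locus spots), nearest-locus 3D distances in μm, colocalized fraction (strict < 0.5 μm), and Oligopaint six-segment probe assembly/QC (length 130–137 nt, 10 ± 1 probes/kb, ≥400 probes, ≥40 kb). |
| `txbodies.nascentreads` | Pileup construction, SNP calling with the five printed thresholds (coverage ≥ 20, variant reads ≥ 5, mean quality ≥ 15, frequency ≥ 0.25, p ≤ 0.01), multi-sample SNP consensus, strand-aware T→C fragment classification with SNP masking, fragment-level gene counting (reverse-stranded, min-overlap 10, ambiguous dropped), non-expressed flagging (< 10 reads total), and chromosome-level hypergeometric enrichment with BH correction. |

Conventions: axis order (z, y, x) everywhere, 0-based voxel indices,
physical coordinate = index × spacing (μm, voxel centers); genomic
coordinates 0-based half-open internally, 1-based only at SAM/GTF
boundaries.

## CLI

```bash
# synthetic data (TIFF + JSON sidecars, SAM/FASTA/GTF, truth JSON)
simulate scene     --seed 1 --outdir out/scene
simulate timelapse --seed 1 --outdir out/tl
simulate reads     --seed 1 --outdir out/reads

# analysis
detect-spots out/scene/ser2p.tif --threshold 20 \
    --nuclei out/scene/nuclei_labels.tif --out spots.tsv
classify-bodies --ser5p t0_ser5p.tif --ser2p t0_ser2p.tif --movie t0_movie.tif \
    --nuclei nuclei_labels.tif --threshold 30 --out bodies.tsv
quantify-enrichment measurements.tsv --controls controls.tsv --out enrich.tsv
fish-distances spots.tsv --nuclei nuclei_labels.tif --radius 0.5 --out dist.tsv
validate-probes segments.tsv --gene-lengths lengths.tsv --out qc.tsv
call-nascent snps     reads.sam --reference ref.fa --out snps.tsv
call-nascent classify reads.sam --reference ref.fa --snps snps.tsv --out frags.tsv
call-nascent count    reads.sam --gtf genes.gtf --out counts.tsv
call-nascent enrich   gene_set.tsv --universe universe.tsv --out chrom.tsv
```

YAML configs (`--config`) override the simulators' defaults; intensity
thresholds for body detection are deliberately required options with no
default.

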
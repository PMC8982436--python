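# embryoquant

Single-cell quantification of spatial gene expression for smFISH-style
experiments, with a ground-truthed synthetic embryo generator so the whole
pipeline can be exercised, calibrated and benchmarked without microscope
data.

The package is aimed at the analysis done in single-molecule FISH studies of
the early *Drosophila* blastoderm — a gene such as *rhomboid* transcribed in
a lateral stripe nested inside a broader miRNA expression domain, compared
between a wild-type and a miRNA-knockout genotype — but every stage is
generic: it applies to any planar epithelium, any stripe gene, and any
two-condition comparison of per-cell molecule counts.

## What it computes

**Synthetic embryos** (`embryoquant.synth`). A 2-D strip of cells (jittered
hexagonal Voronoi lattice), per-gene dorsoventral expression domains with
the stripe gene nested inside the miRNA domain, and per-allele bursty
transcription under the two-state *telegraph model*: each allele switches
OFF↔ON at rates k_on/k_off, produces mRNA at k_tx while ON, and transcripts
decay at k_deg. The stationary per-cell moments are

    E[M]   = n_alleles · p_on · k_tx / k_deg,      p_on = k_on/(k_on+k_off)
    Var[M] = E[M] · (1 + k_tx·k_off / ((k_on+k_off)(k_on+k_off+k_deg)))

and the sampler is exact (the conditional count given the promoter path is
Poisson in the decay-weighted ON exposure). A knockout genotype degrades
mRNA `ko_deg_factor`-fold slower, raising counts proportionally. Active
alleles appear as transcription sites (TS); embryos are rendered into
four-channel images (exon, intron, membrane, nuclei) with Gaussian-PSF
spots and camera noise, alongside exact ground-truth tables.

**Imaging quantification** (`embryoquant.quant`). Marker-controlled
watershed segmentation from membrane + nuclei channels, Laplacian-of-
Gaussian spot detection with a robust (MAD-based) threshold and sub-pixel
localization, transcription-site calling from intron-channel spots inside
nuclei (with colocalized exon spots excluded from the mature-mRNA count),
and spot-to-cell assignment with strict count conservation.

**Single-cell statistics** (`embryoquant.stats`). The low-expression filter
(cells with fewer than 10 mRNAs dropped), TS-class subgrouping (0 / 1 / 2+
active alleles), the immediate-neighbor graph, and per-cluster dispersion:
Fano factor FF = variance/mean (1 for Poisson) and CV = sd/mean. Genotype
comparison is a two-sided Mann-Whitney rank test (exact enumeration for
small tie-free samples), with medians and the Hodges-Lehmann shift as the
effect summary. Protein staining is measured as
`adjusted = integrated density − area × background mean`
over 15 random areas per embryo (5 per anterior/central/posterior region),
reported on a log10 scale.

**Seed-site scanning** (`embryoquant.sites`). Canonical miRNA target sites
on 3'UTRs — 8mer, 7mer-m8, 7mer-A1, defined from miRNA nt 1–8 — with
strongest-type precedence, brute-force-verified matching, and FASTA → TSV
batch scanning.

## Worked example

Two replicate count experiments (3 simulated embryos per genotype each,
knockout degrading mRNA 1.5× slower):

```bash
python examples/04_genotype_comparison.py
```

```
experiment 0: median count WT 92 vs KO 130 (p = 1.04e-13); median cluster FF WT 5.63 vs KO 3.71 (p = 0.044)
experiment 1: median count WT 94 vs KO 129 (p = 8.00e-14); median cluster FF WT 4.49 vs KO 5.67 (p = 0.190)
```

The knockout's slower decay lifts the per-cell median by roughly the
degradation factor (92 → 130), and the rank test on hundreds of cells is
decisive in both replicates; the neighbor-cluster Fano factor differs only
marginally and inconsistently — the count shift, not the dispersion, is the
robust signal. The other examples (`examples/01…06`) cover simulation,
image quantification, dispersion maps, the protein time course, and the
site scanner, each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
embryoquant simulate --out sim/ --genotype KO --seed 1
embryoquant quantify --image sim/embryo.tiff --labels sim/labels.tiff --psf-sigma 1.2 --out quant/
embryoquant scan-sites --utrs utrs.fa --mirnas mirs.fa --out hits.tsv
```

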
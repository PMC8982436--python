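# Methods

## The model system

The package emulates and analyzes a stage-5 fly blastoderm imaged by
single-molecule FISH: a lateral stripe of cells transcribing a target gene
(*rho*-like), nested inside a broader miRNA expression domain, in two
genotypes (WT and a miRNA knockout). The analysis unit is the single
segmented cell; the quantities of interest are per-cell mature-mRNA counts,
the number of active transcription sites (TSs), local (neighbor-cluster)
count dispersion, and background-adjusted protein fluorescence.

## Tissue geometry

The tissue is a 2-D strip — the imaged blastoderm surface is a cell
monolayer, so a planar model captures the geometry that matters for
segmentation and neighbor statistics. Cell centers sit on a hexagonal
lattice (rows offset by half a pitch, vertical pitch = `cell_pitch_px`·√3/2)
jittered by a uniform displacement of up to `jitter`·pitch per axis, and
each pixel joins its nearest center. Distance in x is measured periodically,
which makes all cells congruent at zero jitter (the exact-equal-area
degenerate case used by tests); the raster itself is not wrapped, and
border cells are flagged. `area_px` is the exact geometric area of the
clipped Voronoi region, not the pixel count, so area invariants hold to
floating-point precision.

## Transcription: exact telegraph sampling

Each allele is an independent two-state promoter: OFF→ON at `k_on`, ON→OFF
at `k_off`, transcription at `k_tx` while ON, first-order decay at `k_deg`.
The per-cell TS classes (0/1/2+) map directly onto allele ON states, which
is why this model and not a finer kinetic scheme is used. Replication is
modeled as `n_alleles = 4` with independent alleles (off by default; real
images show very few 3–4-TS cells).

The sampler simulates the promoter path event-by-event with exponential
dwell times (initial state from the stationary Bernoulli), then draws the
mRNA count at `t_end` from its exact conditional law: births form a Cox
process along the path and each transcript survives independently with
probability exp(−k_deg·(t_end−s)), so the count given the path is Poisson
with mean k_tx·∫_ON exp(−k_deg (t_end − s)) ds. This is an exact sampler of
the process (no time discretization) at a cost proportional to the number
of promoter switches rather than the number of molecules, which keeps
hundred-replicate calibration runs cheap. With `t_end = 60` min and
`k_deg ≥ 0.2`/min the transient from the empty initial condition is below
e⁻¹² and the closed-form stationary moments

    mean  = n_alleles · p_on · k_tx/k_deg
    var   = mean · (1 + k_tx k_off/((k_on+k_off)(k_on+k_off+k_deg)))

serve as the oracle for the simulation tests.

Each cell draws from an RNG stream keyed by (seed, genotype, cell label),
so a cell's realization is independent of lattice size and iteration order,
and identical configuration + seed reproduces ground truth bit-for-bit.

Cells outside the gene's domain transcribe at a basal leak rate
(`leak_frac` = 2% of k_tx) and never display a TS: the leak emulates the
sporadic low counts seen outside the stripe (and exercises the <10-count
filter), while TSs outside the stripe are not part of the emulated biology.
A TS is likewise only "visible" when its allele is ON and the effective
transcription rate is positive.

## Kinetic defaults (illustrative)

No kinetic rates are available for the real system; defaults are chosen to
give a realistic regime, not to reproduce any measured value: `k_on = 1.0`,
`k_off = 0.5`/min (ON fraction 2/3, switching faster than decay),
`k_tx = 20`/min, `k_deg_wt = 0.3`/min → WT stationary mean ≈ 89 mRNA/cell,
of the order seen for strong developmental genes; `ko_deg_factor = 1.5`
slows decay in the knockout, lifting the mean ≈1.5-fold — the direction and
rough size of the published genotype contrast. Stationary FF ≈ 4.7, i.e.
clearly super-Poissonian bursty transcription.

## Protein

Protein is deterministic: zero before a genotype-specific onset
(`protein_onset_ko < protein_onset_wt`; the knockout accumulates protein
earlier), then linear birth–death fed by the genotype's closed-form mean
mRNA, p(t) = (k_translate·m̄/k_pdeg)(1 − e^{−k_pdeg(t−onset)}). The t→∞
limit k_translate·m̄/k_pdeg is the oracle for the 1% steady-state test.
Stochastic protein noise is deliberately omitted — the measured quantity is
a 15-area fluorescence average per embryo, which the camera-noise model
already perturbs.

## Rendering and the camera model

Mature mRNAs are Gaussian spots (σ = `psf_sigma_px`, peak `spot_amp`) at
uniform positions inside their cell (exon channel only). Each active TS
adds one spot inside the nucleus disk to both intron and exon channels —
nascent transcripts carry intron and exon sequence; mature mRNA has lost
the intron — with amplitude proportional to its nascent load. This is the
physical basis of intron-probe TS detection, and the reason the exon-channel
ground-truth spot count per cell equals true mRNA + active TSs. Membrane is
the rasterized boundary network, nuclei are filled disks, and every channel
receives N(background_mean, noise_sd²) read noise before uint16 rounding.
Default spot SNR (peak/noise) is 120/15 = 8.

Two placement details exist for the benefit of well-posed ground truth:
TSs sit ≥2 px inside the nucleus rim (so rounding cannot push a detection
outside the mask), and when `min_spot_sep_px` is set, positions are
rejection-sampled image-wide (best-candidate fallback after 1000 tries) and
kept 2 px off cell boundaries so sub-pixel localization error cannot flip a
spot's cell. That switch defines the "well-separated" regime in which
noise-free recovery is exact; it is off by default.

## Spot detection

Scale-normalized LoG filtering at the PSF scale, sign-flipped so spots are
maxima. The discrete LoG kernel leaks a small DC response proportional to
the image mean, so the response is median-centered before thresholding.
Threshold = `threshold_factor` × (1.4826·MAD of the response), floored at
2% of the peak response — the MAD term adapts to camera noise, the floor
covers the (near-)noiseless regime where MAD reflects only quantization
ripple. The default factor 6 keeps pure-noise images detection-free in
≥99% of cases while leaving SNR-8 spots with a ~4× margin. Positions are
refined by a 3×3 response centroid; detections within ~one PSF radius are
deduplicated (quantized plateaus can split one spot into two maxima);
intensity is the background-subtracted sum over a 3σ window. Raising the
threshold factor can only remove detections (monotonicity).

## TS calling and assignment

An intron-channel spot inside the nuclei mask is a TS. Each TS is greedily
matched (closest pair first) to at most one exon-channel spot within
`coloc_radius_px` (default 2·psf_sigma, the same radius used to score
detection); matched exon spots are excluded from the mature-mRNA count,
unmatched intron spots still count as TSs. Exon-channel brightness is
deliberately *not* a TS criterion — intron-primary logic is simpler and
testable. Per-cell TS counts are capped at 4 (two alleles, four after
replication) with excess logged. Spots are assigned to the cell whose label
sits under their rounded position; label 0 leaves them unassigned. Count
conservation — mRNA-counted + TS-flagged + unassigned = all exon spots —
is asserted on every path.

## Segmentation

Marker-controlled watershed: seeds are local maxima of the
Gaussian-smoothed nuclei channel above an Otsu threshold, flooding runs on
the smoothed membrane channel, ties resolved deterministically by marker
order. A precomputed label image bypasses segmentation (ground-truth mode);
benchmarks that isolate counting from segmentation error use that mode.

## Neighbor clusters and dispersion

Two cells are neighbors iff their labels touch across a pixel edge
(4-connectivity); a Delaunay graph with >2×-median-length edges pruned is
the fallback when only centroids exist (both definitions agree on regular
lattice interiors). For each focal cell the cluster is the focal cell plus
its neighbors; the focal cell's membership is exposed as a flag
(`include_focal`, default true — larger, more stable clusters; the
alternative reduction is one call away). Border cells are excluded as focal
cells but allowed as neighbors. Sample variance uses denominator n−1
(clusters have ~7 members; the bias matters). FF = var/mean, CV = sd/mean;
clusters with <3 members or zero mean are missing, never zero — 0/0 is not
evidence of low variability — and missing values are excluded from
comparisons. Both per-cluster and pooled-per-embryo FF reductions are
provided.

## Genotype comparison

Mann-Whitney U, two-sided (the defensible nonparametric default for count
data when no test is otherwise specified): exact enumeration when both
samples have n ≤ 8 without ties, else the normal approximation with tie and
continuity corrections. The far tail of the normal approximation deviates
from exact enumeration by design of the approximation; agreement within 10%
is only expected (and only asserted) at moderate p. Effect size is reported
as both medians plus the Hodges-Lehmann shift. Cells are the unit of
analysis; `embryo_id` is carried in every table so users can aggregate per
embryo, but mixed-effects modeling is out of scope.

## Protein measurement

15 square measurement areas per embryo — 5 per anterior/central/posterior
third of the stripe's long axis — sampled uniformly, pairwise disjoint,
fully inside the tissue mask; the ROI edge defaults to a quarter of the
cell pitch so the grid always fits. Background is the mean over 5 boxes
outside the stripe (the per-picture background measurements). Each area is
adjusted as integrated density − area × background mean; negative values
(background overestimate) are kept and flagged, never clamped. The log10
transform is applied only at presentation, with non-positive values
propagating as missing there and dropped from nothing else.

## Seed sites

Canonical site types only: 8mer (reverse complement of miRNA nt 2–8
followed by A), 7mer-m8 (reverse complement of nt 2–8), 7mer-A1 (reverse
complement of nt 2–7 followed by A). The A opposite nt 1 is a target
requirement, not a pairing. Positions are 0-based at the site's first UTR
nucleotide (1-based via flag, since published tables are not always
explicit); `7_m8`/`7_A1` aliases are available. Overlaps resolve
strongest-first (8mer > 7mer-m8 > 7mer-A1) and 7mers inside a reported 8mer
window are suppressed, so each physical site appears once. DNA and RNA
alphabets are both accepted (canonicalized to RNA); N never matches. A
naive brute-force scanner written independently in the test suite is the
equivalence oracle.

## What the generator does and does not emulate

Emulated: nested expression domains with a miRNA-only ventral band, allele-
resolved bursty transcription with super-Poissonian dispersion, leaky
transcription outside the stripe, genotype contrast via degradation rate,
earlier protein onset in the knockout, diffraction-limited spots with
Poisson-free Gaussian camera noise, and segmentable membrane/nuclei
channels. Not emulated: 3-D PSFs and optical sectioning, deconvolution
artifacts, chromatic aberration, autofluorescence gradients, segmentation
errors from real membrane stains, cell movement/gastrulation, and any
direct miRNA-binding kinetics — the knockout acts only through the decay
rate. Passing tests therefore demonstrate the correctness and calibration
of the *analysis*, not biological conclusions about any real system.

## Problem sizes and numerical choices

Simulation tests use ≥500 cells for moment oracles (Monte-Carlo error ~3
SE), one 16×8-cell embryo (~960×416 px) for imaging recovery, and 8×5-cell
embryos for the 120 replicate power/type-I calibration runs — sizes at
which every check is stable across seeds while the whole suite runs in
well under a minute per module. Degenerate inputs are defined, not
accidental: empty images yield empty tables, a single cell yields an
edgeless graph, all-zero rates yield zero counts, and zero-mean clusters
are missing values. All randomness flows from explicit seeds through keyed
SeedSequence streams; reruns are bit-identical.

## Known limitations

Very high spot densities (expected spacing < 2σ) make counting unreliable;
the renderer logs a warning in that regime but the detector does not
attempt mixture splitting. Nascent-load estimation from TS intensity is out
of scope (TS count, not load, is the measured quantity). The Delaunay
fallback graph can differ from label adjacency at jittered tissue borders.
The scanner implements canonical site types only — no 6mers, 3'
supplementary pairing, or context scoring.
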
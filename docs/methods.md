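# Methods

`spatialfuse` implements a serial-section, multi-platform tissue mapping
workflow: spatial transcriptomics on a barcoded chip, mass spectrometry
imaging (MSI), and sequential immunofluorescence (seqIF) are acquired on
adjacent sections of one FFPE block, registered into the chip's micron
coordinate frame, and summarized per "Leiden voxel" — a bin50 square of
chip spots carrying a Leiden cluster label and a globally unique 16-bit
index. This note records the model, the defaults and their rationale,
the numerical choices, and what the synthetic phantom does and does not
establish.

## Coordinate model

The reference frame is the transcriptomics chip in microns, origin at
the top-left, x rightward, y downward. Spot indices are 0-based and
physical position is `index * pitch`; all rasters use half-open pixel
intervals `[i*p, (i+1)*p)`. Every other modality carries one 2x3 affine
transform mapping its native coordinates into the reference frame; the
linear part must be invertible. Label and index rasters are always
resampled by inverse-mapped nearest-neighbour lookup, which can never
invent a label value; linear interpolation is reserved for intensity
rasters.

Voxel membership uses the same half-open convention, so an MSI pixel
center or a cell centroid belongs to at most one voxel. Voxel indices
are assigned consecutively from 1 in row-major bin order; 0 is
background. More than 65535 voxels is a hard capacity error because the
index image is 16-bit by design (a tissue section at bin50 typically
produces 15,000–25,000 voxels, comfortably inside the range).

## Read processing

Read 1 is a 25-base spot barcode (CID) followed by a 6-base molecular
identifier (MID); read 2 identifies the transcript. Rules, in order:

* CID: exact layout match, else a *unique* Hamming-distance-1 neighbour
  (one-mismatch correction). Zero or multiple neighbours reject the
  read — ambiguity must not cause spatial misassignment.
* MID: rejected if it contains N or more than 2 bases with Phred
  quality strictly below 10.
* Transcript: hits with MAPQ ≤ 10 are discarded; non-host hits are
  tallied per taxonomic class; unmatched reads are kept as
  "unassigned" so the per-read partition is complete.
* Molecule counting: per (spot, gene), the MID count is the number of
  connected components of the graph on distinct MIDs with edges at
  Hamming distance ≤ 1. Components are the plainest reading of
  "collapse allowing one mismatch"; count-aware directional collapse is
  a known alternative and deliberately not the default.

Alignment itself is out of scope: read 2 carries an exact 40-base tag
resolved by dictionary lookup against a toy reference. The reference
still exercises the aligner-facing contracts (MAPQ filtering via
multi-mapping tags emitted at MAPQ 0, and a small fixed taxonomy whose
dominant classes are Actinomycetia and Gammaproteobacteria for the
microbial partition). Multi-mapping tags are drawn from genes expressed
uniformly across compartments so the MAPQ filter never silently removes
a planted marker.

## Bin-level analysis

Spots are summed into square bins of `bin_size` spots per side
(`bin index = floor(spot_index / bin_size)`); counts are conserved
exactly. At the 0.5 um chip pitch, bin50 = 25 um and bin20 = 10 um.
QC removes bins with fewer than 3 detected genes or mitochondrial
percentage strictly above 20%, and genes detected in fewer than 3 bins;
the two filters are iterated to a fixed point so the operation is
idempotent. "Minimum genes by counts = 3" is read as min-cells-style
gene filtering; this is the one genuinely ambiguous QC rule and it is
exposed as module constants.

Sections are merged with a batch label, scaled to the median per-bin
total (the normalization target is a parameter), and log1p-transformed.
A latent-space batch-correction hook exists but defaults to a no-op;
the phantom has no batch effect, and batch integration internals are
out of scope. Clustering is PCA → kNN graph (15 neighbours) → Leiden at
resolution 1.0 with a mandatory seed.

Markers are selected per cluster with a two-sided Wilcoxon rank-sum
test (cluster vs rest), implemented as the normal-approximation
statistic without tie or continuity correction; a gene is reported iff
p < 0.01 and log2 fold change > 1 *in every section of the batch*.
P-values are raw by design; a Benjamini–Hochberg column is emitted for
transparency. Fold change is computed on normalized data as
`log2((mean expm1 in + 1e-9) / (mean expm1 rest + 1e-9))`; the
pseudo-count only guards empty groups.

A note on cluster granularity: at fixed resolution, Leiden's
characteristic community size grows with the graph, so a homogeneous
region several times larger than the other compartments tends to split
into subclusters. Recovery of planted compartments as single clusters
is therefore assessed on balanced-area geometry; on imbalanced tissue
the per-compartment marker signal, not the cluster count, is the stable
readout.

## MSI

Spectra are centroided per pixel on a 20 um grid. "Peak width" is the
*total* ppm window: a peak at offset `|dm|/m * 1e6 <= width/2` is
included (15 ppm for metabolites, 10 ppm for glycans and peptides by
default). Window aggregation is a sum, so ion images are linear in the
spectra and per-voxel aggregation conserves intensity. Adduct
annotation derives the neutral mass from each observed m/z under
[M−H]⁻, [M]⁻, [M+Cl]⁻ (negative) or [M+H]⁺, [M+Na]⁺, [M+K]⁺ (positive)
using exact proton/electron/Cl/Na/K masses, and matches a neutral
monoisotopic mass table within a ppm tolerance. Peak picking is a
curated input; a local-maximum helper over the mean spectrum is
provided as a convenience only. Sequential same-section datasets
(metabolite → glycan → peptide) share one pixel grid and are treated as
identity-co-registered.

## seqIF

Tissue segmentation thresholds each rule channel (Otsu by default),
assigns tissue pixels to the compartment with the strongest rule
response, then strips each compartment within `erosion_um` (default
50 um) of the *other* compartments; the union of stripped pixels is the
interface. The distance-transform formulation is identical to disk
erosion at a shared boundary — a straight boundary at 1 um/px yields an
exactly 100 px band — but ignores image borders and tissue holes, so a
lone compartment produces no interface.

Cell segmentation replaces the proprietary pretrained segmenter with a
deterministic classical pipeline (Gaussian smooth, Otsu, distance-
transform watershed, area filter, label expansion for the cell body);
the workflow contribution exercised here is the downstream phenotyping
and aggregation, not segmenter weights. The per-cell, per-marker
feature is the mean of the pixels at or above the cell's 80th intensity
percentile in that channel (the "top 20%" rule), which is
scale-equivariant; cells under 5 pixels fall back to the plain mean and
are flagged. Features are k-means clustered (k = number of markers by
default, seeded) and clusters are named by their dominant marker via a
configurable map. Autofluorescence subtraction is modelled as optional
background-image subtraction clipped at zero.

## Registration and aggregation

Transforms are fitted to ≥ 3 non-collinear landmark pairs by linear
least squares; the RMS residual is reported and collinear landmarks
raise a degenerate-fit error. Landmarks come from the phantom truth or
a user CSV — interactive fine alignment is out of scope. Per voxel, the
table records the Leiden cluster, bin50 gene expression joined by bin
coordinates (inherently aligned), the mean (parameterized:
mean/median/sum) of ion-image pixels whose warped centers fall inside
the voxel — a voxel covered by no MSI pixel is missing, never zero —
and phenotyped cell counts by warped centroid. Per-cluster summaries
report n, mean, variance and quartiles with missing values excluded.

## 3D stack

Analyzed sections are 5 um thick with centers 10 um apart by default
("three sections spaced ten microns apart"); the source describes both
this and an every-third-section (15 um) layout, so spacing is a
configuration field, not a constant. Stack depth is thickness-inclusive
(top of first section to bottom of last) and can be overridden — the
reference crop depth of 19.6 um is a stated value, not derivable from
the section geometry, so it is passed explicitly where needed. XY is
resampled to the isotropic voxel size (0.23 um, the seqIF pixel pitch)
preserving aspect ratio; the slice count is `floor(depth / voxel)`
(19.6 / 0.23 → 85), and each output slice copies the nearest section in
Z (linear Z interpolation is available for intensity volumes only).
Cross-section proximity uses Euclidean distance with ΔZ taken from
section Z centers, so cells two analyzed sections apart at the same XY
are 20 um apart.

## Phantom

The phantom is a columnar 3D block: a 2D compartment geometry (tumor
disk in stroma by default) extruded through the section stack, with an
interface band within 50 um of the tumor–stroma boundary. Cells of
20 um diameter are placed in 3D, so one cell intersects 4–5 consecutive
5 um sections. Defaults and the reasons for them:

* 60-gene panel, 12 tumor and 12 stroma markers planted at 4x
  (log2FC 2) over a shared baseline, symmetric so library-size
  normalization does not compress the planted effect; depth targets
  ~500 UMIs per analysis bin, matching the published per-bin capture
  scale (median ~8,000–10,000 MIDs per bin200 ⇒ ~500 per bin50, with
  hundreds of detected gene types per bin50).
* Tumor disk radius 240 um in a 600 um field, i.e. roughly equal
  tumor/stroma areas, mirroring the broad comparable compartments of
  the tissue this workflow targets.
* Mitochondrial read fraction 1% (reported "< 2%"), microbial fraction
  0.5%, barcode substitution rate 1%, MID low-quality (Q8) base rate 5%
  against the Q30 baseline — the two-point quality distribution exists
  to exercise the Q<10 filter.
* MSI pixels 20 um, seqIF pixels 0.23 um, chip spots 0.5 um; tests and
  the recovery analyses use coarser spot pitches and smaller fields
  (e.g. 200x200 spots at 4 um binned 10x10, ~400 bins/section over
  three sections) to keep problem sizes proportionate while preserving
  per-bin depth.
* Ground-truth misalignments default to a few degrees of rotation and
  ~10 um translations per modality.

Everything is deterministic given the configuration seed.

What the phantom does *not* emulate: optics and point-spread functions,
isotopic envelopes and mass-accuracy drift, FFPE chemistry artifacts,
segmentation-hostile nuclear morphology, spatial expression gradients
within a compartment, and batch effects between sections. Passing
recovery tests therefore demonstrates that the pipeline's bookkeeping,
statistics and geometry are correct under known truth — not that the
thresholds are optimal for real tissue.

## Known limitations

* Tag-based assignment cannot model splice-aware or partial alignments;
  the MAPQ contract is exercised only at its boundary (0 vs 255).
* Leiden cluster count at fixed resolution depends on dataset size (see
  above); cross-section cluster identity relies on merged clustering
  rather than label matching.
* K-means phenotyping assumes roughly spherical marker-feature groups;
  a kNN-graph Leiden alternative is the natural extension.
* The 16-bit voxel index caps a section at 65,535 voxels; larger fields
  need coarser bins or tiling.
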
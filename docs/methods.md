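# Methods

This note documents the models, parameter choices and numerical decisions
behind `presynquant`, and what the synthetic-data tests do and do not
establish.

## Scope and coordinate conventions

The package quantifies presynaptic protein organization from fluorescence
microscopy and post-processes mass-spectrometry site tables. All imaging
operations work on 2D planes with a physical pixel size in nm (default
20 nm/px, the STED acquisition setting). Pixel indices are 0-based
`(row, col)`; the physical coordinate of pixel `(i, j)` is its centre
`((j + 0.5)·px, (i + 0.5)·px)`. This convention is applied consistently in
rendering (synthetic puncta are sampled at pixel centres) and in measurement
(centroids are converted back with the same rule), so sub-pixel ground truth
is exact. Distances are always reported in nm.

## Axon segmentation

Chain: local-contrast normalization → Gaussian blur (σ = 280 nm) → Triangle
binarization → morphological closing (1.41 µm, interpreted as
structuring-element *diameter*, disk radius = half) → filamentous gating →
skeletonization. Physical sigmas are converted to real-valued pixel sigmas
without rounding.

*Local-contrast normalization* standardizes each block (default 127 px)
toward the global SD with the gain clamped to `[1/max_slope, max_slope]`
(default slope 3); flat blocks pass through unchanged and the output is
rescaled to the input range, so a constant image maps to itself.

*Triangle threshold*: on a 256-bin histogram spanning the observed range, a
chord is drawn in (bin, count) coordinates from the histogram peak to the
farthest occupied bin; the threshold is the bin of maximum perpendicular
distance to that chord (ties toward the lower bin). The 256-bin rule
normalizes any bit depth to the behaviour of 8-bit auto-thresholds; it is a
package convention, configurable in principle through `histogram_256`.

*Filamentous gating* realizes "ridge detection" as the Sato
Hessian-eigenvalue tubeness filter at a scale defaulting to 200 nm (about
the axon half-width). Because the original macro's use of the ridge step is
not specified beyond its position in the chain, the gate is applied to the
binarized mask: a connected component survives only if its mean tubeness
reaches half the mask-wide mean. This removes blob-like false positives
without eroding the axon; an alternative pre-binarization multiplicative
mode is available (`ridge_order="before_binarization"`).

*Skeleton accuracy.* Skeletonization of a tube retracts and rounds the end
caps, so the skeleton can overshoot the true centreline's endpoints along
the tube axis by up to the tube half-width. Accuracy is therefore assessed
as the directed distance from interior skeleton pixels to the true path:
median ≤ 1 px and worst case ≤ 2.5 px (50 nm) on noise-free scenes, with
exactly two endpoints and no branch points. A symmetric Hausdorff bound of
1 px is not attainable for realistic tube widths and is not claimed.

## Cluster (puncta) segmentation

Chain: rolling-ball background subtraction (default radius 500 nm — well
above the punctum size, well below axon-scale background) → Gaussian blur
(σ = 140 nm) → grayscale opening (default 60 nm, i.e. a 3-px disk at
20 nm/px; the published chain names the opening but not its size) →
Intermodes binarization → watershed splitting → axon-overlap gating.

*Intermodes threshold*: the 256-bin histogram is smoothed with a 3-bin
running mean (replicate edge padding) until exactly two local maxima
survive; the threshold is the mode midpoint. Histograms that reach fewer
than two maxima, or fail within 10,000 passes, are not bimodalizable. In
the composite `segment_clusters` this condition falls back to the Triangle
threshold with a warning rather than raising: sparse-puncta images have a
monotone intensity tail that is frequently not bimodalizable, and the
composite contract is that degenerate inputs yield empty or best-effort
cluster sets, not errors.

*Watershed splitting* seeds basins from maxima of the interior Euclidean
distance transform after h-maxima suppression with h = 1 px. Without the
suppression, the discrete EDT of a single convex blob carries several
spurious 1-px-deep maxima and the watershed over-splits; with it, only
genuine two-blob saddles deeper than 1 px split. Long plateau ridges can
still produce more than one seed per blob; labels always cover the mask and
refine its connected components.

*Centroids* are intensity-weighted (computed on the subtracted, blurred
image), which is required for sub-pixel nearest-neighbor analysis;
binary centroids would quantize at the pixel scale. Gating is ≥ 1 shared
pixel between cluster and axon mask (`"overlap"`), with a
centre-on-skeleton alternative. All clusters are retained in output tables
with an `in_axon` flag; only gated clusters feed downstream statistics.

*Rolling-ball caveat.* The background estimate interacts with any feature
narrower than the ball: a second subtraction pass changes an isolated
Gaussian spot by ~2% at ball radius/σ ≈ 12 and < 1% only at ratios ≳ 35.
The default radius (500 nm against σ = 80 nm spots) favours background
tracking over strict idempotence; the idempotence property is verified in
the scale-separated regime.

## Nearest-neighbor analysis and synapse membership

NN distances are Euclidean between intensity-weighted centroids, per image;
pooling across images is an explicit separate step. Self-pairing is
excluded only when source and target are the same set. Histograms use
right-open bins (default 50 nm; the modal-bin tie breaks toward the smaller
bin). A cluster is "within a synapse" when its centre lies within 1.4 µm
(≈ one presynaptic diameter) of the nearest reference centre — the boundary
is read inclusively (≤).

## pHluorin release quantification

Per bouton, F0 and Fmax are the mean of the maximum-projected stack within
the ROI (the within-ROI statistic is not stated in the source protocol;
mean is the default, max available via config) and the release metric is
(Fmax − F0)/Fmax. Boutons with Fmax ≤ 0 are dropped with a warning;
negative metrics (photobleaching) are retained and flagged, never clamped.
F_NH4Cl is recorded and an optional pool-normalized metric
(Fmax − F0)/(F_NH4Cl − F0) is exposed as a clearly-labelled extension; it
does not enter the headline metric.

Group comparison uses the tie-corrected Kruskal–Wallis H with mid-ranks and
a χ²(k−1) p-value; when all pooled values are identical H is defined as 0
and p as 1. The χ² approximation tracks an exact permutation p to within
~0.02 at group sizes ≥ 12 (verified against a 4,000-permutation reference);
at very small n the permutation test should be preferred. Pairwise
follow-up is Dunn's z-test on mean ranks with Holm adjustment — the source
reports pairwise significance without naming a post-hoc procedure, so this
is a package choice.

## Gel densitometry

Lane profiles are row sums of a rectangular selection. Band area is the sum
of the profile above a straight-line chord joining the profile values at
two endpoint rows (defaults: first and last row of the selection),
emulating the "close off the area under the curve" step; negative
excursions are clipped. Ratios are (co-IP/IP) normalized to the
non-stimulated control pair, which reads exactly 1 by construction.

## Filopodia density

The cell border is found by Triangle binarization, closing, largest
component with filled holes, then a morphological opening (default 5 px)
that shaves off thin protrusions so the traced border runs through the
bright filopodium bases rather than around them; the border itself is
traced on the smoothed binary body so it does not track pixel-level
threshold noise. Circumference is the polygonal arc length of the sub-pixel
contour × pixel size (within 5% of the analytic value for discs and
squares).

The outline signal samples, at each contour point, the *maximum* intensity
within ±4 px along the local normal. Strict line sampling is unusable in
principle here: a threshold-derived contour is an iso-intensity line, so
intensity along it is nearly constant and peak visibility would depend on
±1–2 px of border placement. The band makes the signal insensitive to that
placement. Peaks are counted on the circular signal (rotated so its global
minimum is the origin, hence a peak spanning the chain start counts once)
with minimum separation 300 nm and prominence defaulting to
max(2 × robust noise SD of the raw signal, 25% of the signal swing); the
noise SD comes from successive differences so genuine peaks do not inflate
it, and the range floor rejects correlated baseline wobble. The referenced
macro's exact settings are unpublished; all of these are configurable and
logged.

## Phosphoproteomics post-processing

Site intensities are divided by the protein abundance of the same replicate
(missing stays missing; measured intensity with zero/missing abundance is
an error). The high-confidence filter keeps sites present in ≥ 3 of 4
replicates with localization probability **strictly** above 0.75 — a site
at exactly 0.75 is dropped — evaluated per protein variant
(membrane-tagged vs cytosolic), with the union across variants reported and
flagged `unique_to_<variant>` / `both`. Presence is evaluated on
(non-missing) normalized intensities; normalization preserves missingness,
so this equals evaluation before normalization.

Interaction-partner enrichment between phospho- and non-phospho-column
eluates requires ≥ 2 valid log2 intensities per group, computes per-protein
log2FC as the difference of group means on the log2 scale, and reports
proteins with |log2FC| ≥ 2 in either direction. The published threshold
statement ("≤ 0.05 and ≥ 2") is internally inconsistent — most plausibly a
typo for a symmetric ±2 rule or a conflation with the min-valid filter —
so the symmetric rule is implemented and both directions are always
reported; the two direction sets are disjoint by construction.

The PKA consensus scan reports S/T acceptors whose N-terminal flank matches
a configurable pattern set, default `{[RK][RK]x[ST], [RK]xx[ST]}` — the
canonical basophilic PKA arrangements, which recover the canonical R-R-x-S
site and the K-R-x-S context of the S351 peptide (LKRASVDVDLLA). Positions
are 1-based protein coordinates; a position matched by several patterns is
reported once.

Conservation of a site across a pre-computed multiple alignment maps the
1-based ungapped reference position to its alignment column and counts
strict residue identity; gaps are non-conserved. Residues in the same
physicochemical class (e.g. S/T) are tallied separately as conservative
substitutions and never counted as conserved, matching the narrative
distinction between conservation and conservative substitution.

## Synthetic data: the stated world

`generate_axon_scene` renders a gently curved axon (heading random walk,
curvature radius ≥ ~80 px so the 1.41 µm closing cannot fill a bend and the
path cannot self-intersect within one PSF; the path is monotone in x) with
Gaussian cross-section of FWHM 400 nm — a realistic distal axon shaft — at
20 nm/px in a 672² field. Channel-A puncta (σ = 80 nm, an effective
STED-like PSF; peak 300 counts over a 10-count background) sit on the path
with ≥ 600 nm spacing; channel-B puncta are displaced by `nn_offset_nm`
(default 100 nm, the co-clustering distance the analysis must resolve) in a
uniformly random direction. The axon ridge is rendered into a separate
marker plane (the role the vesicle marker plays in the experiment, where
axons are segmented from a marker channel distinct from the proteins under
study) with peak 60 counts. Noise is Poisson on signal + background
followed by additive Gaussian read noise (SD 2); both are switchable to
zero for exact tests. The spacing default matters: after the 140 nm
analysis blur, puncta closer than ~500 nm merge above threshold and must be
recovered by watershed, so 600 nm keeps detection and splitting regimes
separable in the acceptance checks.

`generate_phluorin_pair` lays uniform-disc boutons (F0 = 100 counts) on a
dark quenched background and sets `Fmax = F0/(1 − r)` per bouton so the
release metric equals r exactly without noise; r defaults to
Uniform(0.1, 0.6), spanning the range the assay reports. The dark
background is deliberate: any uniform background inside the ROI would bias
the ratio metric, which is a property of the metric, not of the code.

`generate_phosphosite_table` emits MaxQuant-style tables (log-normal
intensities, per-replicate presence drawn uniformly over 0–4 replicates,
localization probabilities from a high/low Beta mixture populating both
sides of the 0.75 cut). The truth flag is computed from the generating
state, independently of the filter implementation.

`generate_cell_scene` fills a 10 µm-radius cell uniformly (as a
farnesylated membrane marker appears in projection) and adds
`n_filopodia` tight stems (σ = 150 nm, a realistic filopodium width) just
outside the body border with ≥ 0.35 rad angular separation.

What the generators do **not** emulate: realistic optics (no vectorial or
depth-dependent PSF, no STED depletion), axon varicosities or branching,
bouton morphology and vesicle-pool structure, chromatic shift between
channels, detector fixed-pattern noise, or MS-specific artefacts
(missing-not-at-random intensities, peptide-level interference). A green
test therefore establishes that the measurement chain recovers known
geometry/algebra under controlled noise — not that it is robust to every
property of real specimens.

## Determinism and provenance

A seed fully determines every generator output (bit-identical reruns). The
pipeline embeds a SHA-256 hash of the run configuration in every output
table and in `provenance.json`; reruns with the same seed and configuration
are byte-identical.
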
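# Methods

## Imaging model and segmentation chain

The pipeline assumes three aligned 2-D channels per field — phase contrast,
DNA stain (Hoechst 33342) and reporter fluorescence (mNeonGreen) — at
0.103 μm/px. All thresholds are relative to image statistics (mean, s.d.)
so that the chain is invariant to additive offsets in phase contrast and to
multiplicative gain in the DNA channel.

**Flat-field.** Static illumination structure is removed by subtracting the
per-pixel median over all images of one acquisition session, separately per
channel. Negative values are preserved; downstream statistics are
mean-relative, so no zero clipping is needed. Cells whose compartment means
end up at or below zero after correction have the means floored at machine
epsilon before ratio division and are flagged.

**Cells.** Phase-contrast images pass through a cascade of Gaussian unsharp
filters, `I ← (I − w·G_σ(I)) / (1 − w)` with weight w = 0.4 and σ taken
from the radius ladder [1, 6, 11, 16, 21, 26, 31] px in order. The stated
ladder convention ("1 to 35 in 5 px steps") is arithmetically inconsistent
(1 + 5k never reaches 35); we keep the start and step and expose the ladder
in configuration. Cells are dark connected components (8-connectivity,
holes filled) below mean − 1 s.d. of the processed image, restricted to
2000–7000 px², with their darkest processed pixel at least 2 s.d. under the
mean, and not touching the image border (a partial cytoplasm would bias the
partition ratios). Area, depth and threshold all use the processed image's
statistics — a single statistics source for the whole filter set. Whether
the depth filter should use raw or processed intensities is not fixed by
any convention we know of; we use processed.

**DNA objects.** The DNA channel is blurred (σ = 1 px) and background-
subtracted with a 15 px rolling ball (`skimage.restoration.rolling_ball`).
Local maxima with topographic prominence above 1.5× the image s.d. —
computed as morphological h-maxima, the dynamics-based equivalent of a
maxima finder with noise tolerance — seed objects; each object is the
connected region above 0.4× its seed's peak value, and pixels claimed by
several seeds go to the nearest seed. Object counts are invariant to
multiplying the channel by any positive constant (the prominence cut and
the growth threshold are both relative); the rolling ball itself has an
absolute intensity scale, but it only shapes the background estimate.

**K/N assignment.** Trypanosomes carry exactly one or two kinetoplasts (K)
and one or two nuclei (N), and the kinetoplast divides first, so a cell
with 2, 3 or 4 DNA objects is read as 1K1N, 2K1N or 2K2N, with the largest
object (two largest for 4) taken as nucleus. Other counts exclude the cell
from partition analysis. Area ties at the deciding rank break by higher
integrated intensity, then lower label — deterministic by construction.

**Nucleus geometry and nucleolus.** The nucleus radius r is the average of
the full major and minor axes of the moments-fitted ellipse (for the
default phantom nuclei of 28 × 22 px axes, r ≈ 25 px). The nucleolus
appears as a Hoechst-dark disc inside the nucleus: its centre is the
darkest pixel of the preprocessed DNA channel at least r/8 (Euclidean
distance transform) from the nucleus edge — evaluated on the preprocessed
rather than raw channel for noise robustness — and its mask is the disc of
radius r/4 about that centre, clipped to the nucleus. Ties break by
proximity to the nucleus centroid, then scan order. Nuclei too small to
contain any candidate pixel exclude their cell with a logged reason.

## Partition quantification

Compartments partition the cell mask exactly: cytoplasm = cell − nuclei,
nucleoplasm = nuclei − nucleolus discs, nucleolus = discs. Sums over the
three compartments add up to the whole-cell sum by construction. For 2K2N
cells, pixels are pooled across both nuclei and discs before means are
taken. Ratios use compartment means, not sums.

One definitional point was genuinely open: whether the "nuclear" mean in
the nucleus/cytoplasm ratio includes the nucleolus. The r/4 disc is a
quarter of the nucleus area, so for nucleolus-enriched reporters the two
conventions differ by tens of percent. We default to the nucleoplasmic
mean, under which each ratio recovers its compartment concentration ratio
exactly on uniform phantoms (the ground-truth contract of the generator),
report the pooled nuclear mean alongside in every `CellMeasurement`, and
expose `nuclear_includes_nucleolus` to switch the convention. Note the
pooled convention makes the nuclear cutoff more sensitive to purely
nucleolar proteins; with the default convention such proteins rely on
their (invariably elevated) nucleoplasmic signal to cross the nuclear
cutoff first.

Expression filtering retains cells whose mean whole-cell reporter signal
exceeds the untagged parental mean by k s.d. (default k = 3); parental
statistics are mandatory inputs. Lines aggregate as unweighted means of
per-cell ratios; lines with fewer than 20 cells are flagged low-confidence.
Classification applies two cutoffs: nuclear iff ratio_nc ≥ t_nc; nuclear
lines split into nucleolar (ratio_nn ≥ t_nn) or nucleoplasmic; non-nuclear
lines are cytoplasmic. The cutoffs default to 2.0/2.0 — chosen to split
clearly bimodal phantom populations, since no canonical values exist — and
every output records the thresholds used.

## Sequence analyses

Residue classes follow the standard groupings: charged RHKDE = basic KRH ∪
acidic DE (disjoint, so the charged fraction is exactly the sum of the
other two), hydrophobic AILMFWYV, polar STNQ. Histidine counts as basic
throughout; on the mNeonGreen reporter this convention reproduces the
expected 32 basic residues, which K+R alone does not. Molecular mass uses
average residue masses plus one water (Biopython).

pI is the root of the Henderson–Hasselbalch net charge (termini plus
D, E, C, Y, H, K, R side chains), found by bisection on pH ∈ [−2, 16] to an
interval of 1e-6 — well inside the 0.01-pH reporting precision, and tight
enough that the residual charge at the root is < 1e-3 even for strongly
basic sequences where the charge curve is steep. The default pKa set is the
Bjellqvist/ExPASy table, which places the mNeonGreen reporter at pI 7.22
(the EMBOSS table, also shipped, gives 7.76); a ±0.3 tolerance on reporter
pI absorbs this pKa-set variation. The expressed reporter construct carries
one extra neutral linker residue relative to the 236-residue fluorophore,
which shifts the charge fractions by under 0.1 percentage points; tests use
a ±0.3 percentage-point tolerance accordingly.

KRXR scanning reports all, possibly overlapping, matches of K-R-X-R
(1-based inclusive coordinates) and flags a hit N-/C-proximal when the
whole motif lies within the first/last 15 residues — short sequences can
carry both flags. IDR segmentation takes maximal runs of disorder score
strictly above 0.5 from externally supplied per-residue scores; disorder
prediction itself is out of scope. The Das–Pappu diagram of states uses the
standard five-region boundaries on (f⁺, f⁻): FCR < 0.25 weak polyampholyte,
0.25 ≤ FCR ≤ 0.35 boundary, FCR > 0.35 with |NCPR| ≤ 0.35 strong
polyampholyte, and a polyelectrolyte when only one charge fraction exceeds
0.35. Composition matrices are per-protein residue fractions over the
20-letter alphabet; the optional N-terminal trim (default 30 when used)
discounts organellar targeting presequences before counting. 2-D embedding
of these matrices is delegated to standard tools (PCA/t-SNE); only the
feature extraction is provided here.

## Statistics

Two-group comparisons default to the Wilcoxon rank-sum (Mann–Whitney) test,
since the compared protein sets are independent; the Wilcoxon signed-rank
test is available behind `paired=True` for genuinely paired designs. Exact
small-sample nulls are used when both n ≤ 25 and the data permit, otherwise
the normal approximation with tie correction. Enrichment uses the Pearson
chi-squared test on 2×2 tables without continuity correction (Yates behind
a flag); both margins must be positive. No multiple-testing correction is
applied by default; Benjamini–Hochberg is available (`bh_adjust`).

## Synthetic phantoms: what they emulate, and what they do not

The generator renders fields of bent-capsule cells (a curved constant-width
rod, width 30 px, length set from a target area drawn inside 2000–7000 px²
with a 3% interior margin so rasterisation cannot push a cell across the
area filter), one cell per tile of a grid with random heading, bend and
jitter — guaranteeing separation and border clearance. Cell-cycle
configurations 1K1N/2K1N/2K2N are drawn with probabilities (0.7, 0.2, 0.1),
roughly the proportions of an asynchronous procyclic culture, and exercise
every K/N assignment branch. Phase contrast renders cells as interiors at
(1 − d)·background with a thin halo at (1 + d)·background (d = 0.35): deep
enough that the mean − 1 s.d. threshold finds them even in noise-free
renders. Hoechst nuclei are parabolic domes (brightest centrally) rather
than flat plateaus — flat-topped nuclei with an off-centre dark disc
develop genuinely split intensity ridges that any prominence-based maxima
finder fragments, which real dome-shaped nuclei do not. The nucleolar dip
is deepest at its centre and its centre sits on the integer pixel grid,
consistent with the label-image ground-truth contract and with the
pixel-valued output of the darkest-point detector. Reporter signal is
piecewise-constant per compartment; shot noise (Poisson) and Gaussian read
noise (σ = 2 by default) are applied per channel from independently spawned
seeds, so each channel is reproducible in isolation.

Ground truth records every mask as a label image plus the analytic
partition ratios (c_nucleoplasm/c_cyto, c_nucleolus/c_nucleoplasm).
Phantom defaults for camera statistics (background 200, DNA levels
150/180, read noise 2) are free parameters — no acquisition metadata
constrains them — and are chosen to give realistic single-cell SNR.

What passing phantom tests does **not** show: robustness to uneven
illumination beyond the median model, overlapping or touching cells,
out-of-focus fields, photobleaching, autofluorescence, partial nucleolar
dimming, or nuclei whose Hoechst texture deviates from a smooth dome. The
phantoms verify the algorithmic contract of each stage against exact
truth, not performance on real micrographs.

## Problem sizes and numerical choices

Acceptance runs use six 9-cell fields (54 cells, ≥ 50) for imaging
recovery, 1000 random sequences for the scanner oracle, 1000 random tables
for the chi-squared oracle, 20 sequences × a 0.001-pH grid for the pI
oracle, and 1000/300 replicates for rank-test type-I error and power at
n = 50 per group — sizes at which every stochastic check is stable across
seeds while the whole script completes in well under a minute of compute.
All randomness descends from a single seed via `numpy.random.SeedSequence`
spawning. Degenerate inputs are defined, not left to chance: constant
images segment to nothing; sub-4-pixel nuclei refuse ellipse fitting;
empty cytoplasm or nucleoplasm excludes the cell with a reason; zero-cell
lines produce no summary.
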
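# Methods

This note documents the measurement procedures, the synthetic scenes
they are validated against, and the numerical choices made where the
design was open. Units are µm throughout; rasters default to 1 µm/px.

## Synthetic scenes

The generator (`gastruloid_quant.scenes`) is the package's validation
substrate: every geometry the pipeline quantifies can be rendered with a
known answer. Nuclei are anti-aliased filled discs (default radius
5 µm) placed by dart throwing with a minimum centre separation of
1.6 × nucleus radius, a cheap stand-in for non-overlapping epithelial
packing; the placement budget is 10 attempts per requested nucleus, and
an infeasible request fails naming the achievable maximum. Per channel,
each nucleus carries a binary class label assigned by a spatial rule
(uniform, central disc, annulus, edge band, random mixture with an exact
positive count, or suppression within a distance of the nearest
secretor cell); rendering composites class intensities over a uniform
background and adds optional Gaussian pixel noise clipped at zero. One
`numpy.random.default_rng(seed)` stream drives each scene, so identical
spec + seed is bit-identical.

Default colony geometry matches the emulated experiments: 250 µm analysis radius (500 µm
disc patterns) and a live-imaging packing of 683–785 nuclei per colony,
encoded as the default density 3700 nuclei/mm². Z-stacks model a
monolayer whose apical (ZO-1) surface is a base height plus optional
sinusoidal undulation; ZO-1 is a Gaussian band in z centred on that
surface (σ_z = 1 µm), other channels are offset by per-position signed
distances (positive = basal = deeper z), and optional gap patches
silence ZO-1 locally. Time-lapses share one nucleus placement across
frames; the reporter-positive disc follows a per-frame radius schedule
(the default 101 frames × 30 min span the 50 h course), and a separate
N:C variant renders a cytoplasmic level everywhere with nuclei at a
scheduled nuclear level.

What the scenes do **not** emulate: nuclear texture and shape
variation, signaling physics (no reaction–diffusion), illumination
vignetting beyond a stated additive ramp, photobleaching, drift, or 3D
nucleus shapes. Passing tests therefore certify the estimators against
the stated geometries and noise model, not against the full variability
of real micrographs.

## Colony detection and exclusion

Fields are assembled from tiles by linear feather blending over the
declared overlap (weights sum to one, so reassembling tiles cut from
one render is exact). Background is a grey-opening with a flat window
(default bounds: at least 4 nucleus radii so nuclei survive, at most
one colony diameter so field-scale gradients are tracked), smoothed and
subtracted with clipping at zero.

Colonies are detected on the DAPI channel smoothed with σ = nucleus
radius, thresholded by Otsu; foreground pixel positions are closed into
solid footprints by an **alpha shape** — the union of Delaunay
triangles with circumradius ≤ α, implemented in
`gastruloid_quant.geometry` — with α = expected radius / 5, scaling the
closure to colony size. Note the closure can bridge between objects
whose edge gap is below ~2α, so scenes and chips should keep colonies
at least that far apart. Candidate footprints within [0.25, 4]× the
expected disc area become regions; exclusion then rejects area outside
[0.5, 1.5]× the expected disc area (merged pairs, partial colonies) or
circularity 4πA/P² < 0.8, each with an explicit reason. These
thresholds are config defaults for an exclusion practice that is
standard in micropattern work but has no canonical cut-offs.

## Nuclear segmentation

Seeds are local maxima of a scale-normalized inverted
Laplacian-of-Gaussian response (σ = nucleus radius/√2) above an Otsu
cut on the response. Minimum seed separation (1.5 × nucleus radius) is
enforced **Euclidean**, by greedy suppression in response order — a
square suppression footprint culls diagonal neighbours at distances up
to √2 times the nominal separation and cost ~18% recall at study
packing. Watershed floods the inverted lightly-smoothed DAPI
(σ = nucleus radius/4; heavier smoothing blurs the foreground boundary
outward and inflates label areas) from the seeds, restricted to an Otsu
foreground mask. The cell table records centroid, radial distance from
the colony centre, area, and per-channel **median** intensities.
Counting accuracy at study packing is ≤3% over seeds; residual misses
are pairs at the minimum separation whose LoG peaks merge.

## Positivity calling

Per-cell marker medians are divided by the DAPI median (cells with
non-positive DAPI are dropped and logged). A two-component Gaussian
mixture is fitted by EM with multi-start: the standard k-means
initialization plus moment-matched initializations from hard splits at
several candidate positive fractions, best likelihood kept — the
smeared single-basin optimum otherwise captures the fit whenever
positives are rare. The cut-off between the two populations is the
crossing of the weighted component densities; Otsu's threshold on the
empirical histogram is the fallback when the fitted density is not
bimodal. Otsu alone was measured to split the majority class once the
positive fraction drops (estimated fraction 0.28 for a true 0.05 at 4σ
class separation), which is why the mixture boundary, not the Otsu cut,
is primary. A fit whose density has a single mode is flagged
(`converged=False`): the sample is effectively unimodal and the
threshold untrustworthy. Calls are strict (`value > threshold`); ties
are negative.

## Radial statistics

Profiles bin mean ± sd ± n against distance from the colony centre
(cell mode: per-cell medians at centroid radii; pixel mode: every pixel,
optionally masked to foreground), bins contiguous with width
2–50 µm (default 10). Empty bins stay null. The ring width of
edge-restricted signaling is analysis radius − r½, where r½ is the
innermost upward crossing of (min+max)/2, linearly interpolated; a
profile already above half-max at the centre yields the full radius,
one that never rises yields 0 with a "no ring" flag. The same half-max
rule gives the secretor inhibition range on profiles binned by distance
to the nearest secretor centroid (KD-tree). Centre-vs-edge contrasts
use a 100 µm central disc and a 50 µm edge band by default.

## Germ-layer domains

Within the analysis disc, each marker channel is split into three
intensity classes by multi-Otsu (background / marker-negative nuclei /
marker-positive nuclei). A guard at the per-nucleus scale — mean
intensity per connected nuclear component must be bimodal under the
mixture criterion above — prevents calling a domain for a marker with
no positive population (raw pixel histograms always carry an
anti-aliased rim mode and cannot be used for this test). The first
marker's positive pixels, solidified by an alpha shape (α = 20 µm,
footprints under 50 µm² discarded, largest component kept), form the
central domain; the second marker's form the middle ring; the rest of
the disc is the outer domain. The three labels partition the disc
exactly. Domain identity is asserted, not assumed: if the central
domain is not innermost by mean radius the map is flagged.

Known limitation — rim shortfall: with nuclei rendered as discs, the
footprint of the positive nuclei ends about half the inter-nuclear
spacing inside the generating radius (~5 µm at study packing), so
absolute domain areas are biased low by a few percent. Cohort-level
percent changes, the quantities reported, are ratios in which this bias
cancels; the area-convergence tests therefore use densely filled
regions, and per-pixel accuracy is certified at ≥95% on fine-packed
scenes and ≥90% at study packing.

## Apicobasal polarity

Per lateral position, profiles along z are background-subtracted (10th
percentile, clipped at zero) and additionally floored at 50% of the
profile peak — without the relative floor, residual noise spread over
the whole z range dominates the centroid variance at moderate SNR. The
apical height is the intensity-weighted mean z of the ZO-1 profile
(centroids are sub-plane accurate, unlike argmax); positions whose
integrated ZO-1 falls below a noise floor (default 20% of the median)
are masked invalid, filled by nearest-neighbour, and the surface is
smoothed laterally with σ = 2 µm. Channel depths are computed the same
way and the signed distance (channel − surface, positive basal)
summarized by median and quartiles (reported for ≥100 valid positions).
Surface recovery RMS error is ≤ z_step/2 for undulation amplitudes up
to 3 µm at SNR ≥ 5. Group inference on the per-condition tables is
delegated to the statistics layer.

## Live dynamics

The reporter-domain radius is read per max-projected frame from an Otsu
foreground mask: the pixel-mode radial profile of the mask occupancy is
scanned from the outside for the half-max crossing (outermost, because
the reporter domain is centre-filled), interpolated, and offset by half
a bin; frames without foreground report 0 with a flag. Per-frame error
is ≤5 µm against scheduled radii. N:C traces segment nuclei from the
H2B channel with the operators above; the nuclear mean is taken over a
1 px-eroded mask, the cytoplasmic mean over a 2 px ring that starts one
pixel outside the nucleus (the guard pixel skips the anti-aliased rim,
which otherwise inflates the cytoplasmic estimate ~5% at N:C = 3) and
excludes all other nuclei. Cells link frame-to-frame by nearest
centroid with a 10 µm/frame cap; lost tracks truncate and are logged.
The stimulation frame (T = 0) is a config input.

## Derived assays and statistics

TEER per unit area is (sample − control) × membrane area, Ω·cm², with
a warning flag when the sample reads below the no-cell control. qPCR
fold changes use efficiency-2 ΔΔCt arithmetic with Ct-first
aggregation: technical replicate Ct values are averaged per sample,
ΔCt subtracts the reference gene, ΔΔCt subtracts the baseline
(condition, timepoint) mean per gene, fold = 2^(−ΔΔCt) with replicate
spread propagated on the log2 scale. Group comparisons are pure
delegation: Mann-Whitney for two groups; Kruskal-Wallis followed by
pairwise Mann-Whitney with Holm correction for more (no suitable
implementation of Dunn's rank-based post-hoc exists among the project's
dependencies, and implementing one would cross the no-bespoke-statistics
boundary; Holm-corrected rank-sum tests are the standard conservative
substitute).

## Interfaces

The library functions and the numbered `analysis/` drivers are the
package's interface; the drivers double as command-line entry points
for each pipeline stage (simulation, detection, rings, domains,
transwell/secretors, polarity, dynamics, assays), and `pipeline.run_pipeline`
executes a configured end-to-end run with a JSON manifest. Rasters are
read and written as TIFF/OME-TIFF via `tifffile`; tables as CSV; scene
parameters and reports as JSON.

## Problem sizes

The validation suite and the reproduction script run colonies at the
study geometry (250 µm radius, ~700–730 nuclei) with 5 seeds for the
ring and transwell recoveries and cohorts of 10 colonies per condition
for the domain contrasts; these sizes hold the sampling error of each
recovered quantity well inside its stated tolerance while keeping a
full run in the minutes range on one CPU.
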
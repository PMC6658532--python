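# Methods

This note records the models, conventions and numerical choices behind
`junctiontrack`, and what the synthetic-data generators do and do not
emulate.

## Coordinates, rasters and units

Localization coordinates are continuous nanometres with the origin at the
lower-left corner of the region of interest (ROI) and y increasing upward.
Rasters use half-open 10-nm bins `[k·p, (k+1)·p)` — a point exactly on a
pixel boundary lands in the higher-index pixel — with row index following y
and column index following x. MSD values are reported in μm², diffusion
coefficients in μm²/s, times in seconds (50-ms camera frames by default).

Rendering follows the averaged-shifted-histogram convention: the raster is
the mean of `shifts²` histograms whose bin origins are offset on a
sub-pixel lattice (default `shifts = 2`). Shifted bins are clipped at the
ROI boundary rather than wrapped, so rendering conserves the localization
count exactly. Binary maps are obtained with a `count > 0` threshold
(configurable).

## Drift correction and registration

Per-frame drift is the mean displacement of fiducial-marker tracks from the
first frame, with linear interpolation across fiducial blink gaps; frames
covered by no fiducial must not exceed 10% of the acquisition. Two-channel
registration is a least-squares rigid transform from matched fiducial
positions — translation-only by default, with an optional Kabsch rotation —
because nothing in two-camera-path PALM data requires scaling.

## Diffusion estimation

For 2D Brownian motion ⟨r²⟩ = 4Dτ. Two biases affect camera-based
single-step estimates:

* **Localization error.** Each position carries an independent Gaussian
  error σ per axis, so ⟨r²_observed⟩ = ⟨r²_step⟩ + 4σ²_axis. The term is
  measured from stationary ("fixed-cell") emitter trajectories as the
  single-interval MSD: `MSD₁,fixed = 2σ²_2D = 4σ²_axis`.
* **Motion blur.** Continuous illumination averages the emitter position
  over the frame; for free diffusion this contracts the apparent
  single-step MSD by a factor 2/3, corrected by multiplying by 1.5.

Hence the single-step estimator
`D₁ = 1.5·(MSD₁ − MSD₁,fixed)/(4·0.05 s)` and the slope estimator
`D₂ = (MSD₂ − MSD₁)/(4·0.05 s)`, in which both corrections cancel. Negative
estimates are reported and flagged, never clamped, because truncation would
bias ensemble averages.

MSD curves average squared displacements over **all (overlapping) index
pairs** at each lag by default, matching common practice; the overlapping
sample is serially correlated, and the per-lag SEM ignores that correlation
(a deliberate, documented simplification). A non-overlapping alternative
uses strictly disjoint localization pairs (stride = lag + 1). `compute_msd`
raises if the requested maximum lag exceeds every track.

The confinement radius uses the closed form for uniformly distributed
positions in a disc of radius R: E|X − Y|² = R², so
`r_c = √(plateau − MSD₁,fixed)`. The plateau is the mean MSD over the
400–500 ms lag window by default (the window is a package choice; no
numerical definition of "plateau" is standard). Two caveats, both verified
in simulation: the relation presumes instantaneous sampling (motion blur
shrinks a confined plateau by up to ~10% at 50-ms frames), and the plateau
must have equilibrated — positions decorrelate at rate ≈ (1.84/R)²·D, so
slow confined motion has not plateaued by 500 ms.

## Tracking

Detections in consecutive frames are paired by minimum total squared
displacement (Hungarian algorithm) among candidates within 480 nm; a
missing frame terminates the track, and tracks shorter than 3 localizations
are dropped. Optimal assignment was chosen over greedy nearest-neighbor as
the defensible reference formulation; at the sparse densities typical of
sptPALM (~0.1 molecules/μm²) linking agrees with simulation ground truth
>99%.

## Junction analysis and the engagement estimator

STIM1-marked junction masks: density filter (≥5 neighbors within 100 nm,
single pass on the unfiltered table), 10-nm rasterization, 50-nm (5-pixel)
Euclidean-disc dilation to fill intra-cluster gaps. Track classification:
*on junction* if the first localization is inside the mask, *off junction*
if every localization is outside; tracks starting outside but entering
later satisfy neither rule and are kept as an explicit *excluded* class
rather than silently dropped. Excursion analysis uses tracks of 6–25 steps;
`d_max` is the largest displacement from the first localization, and
comparisons between conditions use seeded 1,500-track subsamples, pooled
across cells.

The engagement fraction treats junctional wildtype ORAI1 as a two-state
mixture: free channels diffusing like the STIM-blind LSLD mutant measured
at junctions, and bound channels diffusing like STIM1. Because the mean
first-step r² is linear in the state occupancies,
`f = (D_LSLD − D_WT)/(D_LSLD − D_STIM1)` is an unbiased ensemble estimate;
simulation recovery is within ±0.07 at ≥1,500 tracks for planted fractions
0.25–0.84. Out-of-range fractions are flagged, not clamped. The bound-state
reference may be averaged across conditions when the condition-wise values
agree within error. An r² > 0.1 μm² outlier cut is supported as a
display convention: it is available but not applied to the mean entering
D by default, since the estimator's definition states no trimming.

## Colocalization

NCG is evaluated on binary pixel maps of identical geometry and is
undefined (an error, not zero) when either channel is empty. The median
distance dilates the reference territory stepwise by 3 pixels (30 nm) until
≥50% of target pixels are covered; step k uses a Euclidean disc of radius
3k around the original territory, evaluated on one exact distance
transform. (Iterating a 3-pixel lattice dilation k times under-reaches the
Euclidean distance diagonally and was rejected.) The reported distance is
quantized to the 30-nm step grid without interpolation.

On a planted field whose inside/outside density ratio is e and whose
territory occupies a fraction a of the ROI, the expected NCG is
`e/(e·a + 1 − a)`, which approaches e only for small territories — the
package's enrichment-recovery tests compare against this expectation.

## Cluster segmentation

The Voronoi tessellation is clipped to the ROI exactly by mirroring the
point set across the four ROI edges before tessellating, so polygon areas
sum to the ROI area to float precision. Exact duplicate coordinates are
deterministically jittered by <0.01 nm (keyed to record index); fully
collinear inputs are rejected.

The area threshold comes from a Monte-Carlo complete-spatial-randomness
null: 100 CSR fields matched in count and ROI, log-spaced 50-bin area
histograms, threshold at the first crossing of the observed histogram below
the CSR mean, scanning upward from the peak of the observed small-area
excess. Two robustness measures matter in practice:

* clustering also *stretches* background cells, producing a large-area
  excess; the crossing search is therefore restricted to areas below the
  median CSR polygon area;
* "clustering detected" requires the cumulative small-area excess to
  exceed 3 standard deviations of the CSR iteration spread — a raw
  histogram comparison flips by chance on CSR input.

Candidate selection for segmentation uses the **first-rank
neighbor-averaged** polygon area (mean over each cell and its Voronoi
neighbors) against the same threshold. Raw per-cell areas admit isolated
background cells that rasterize to ≥10 pixels and masquerade as clusters;
neighbor averaging suppresses them while retaining cluster cores and most
of their fringe. The 10-nm density map assigns each pixel the first-rank
density (1/area) of the polygon containing its center when that polygon is
a candidate, is smoothed with a 1-pixel Gaussian, seeded from local maxima
at least 15 pixels apart within each connected candidate region, and
watershed-partitioned; segments under 10 pixels are discarded. On the
simulated benchmark (17 clusters of 200 nm, 32 localizations each, 70-nm
uncertainty, 0.7% background pixels in 4 × 4 μm) the mean recovered count
over 10 seeds is ≈17; 400-nm/100-localization fields over-segment
(detected ≥ planted), reproducing the known behavior of
Voronoi-tessellation segmentation on large composite clusters. Note that
with 70-nm uncertainty on 100-nm-radius discs the fringe localization
density genuinely overlaps the background, so no area threshold separates
both populations at the 90% level; the count, not per-localization recall,
is the validated quantity.

Particle analysis labels 8-connected components of a binary rendering with
the same 10-pixel minimum and statistics, serving as the independent
cross-check; on well-separated planted fields the two methods agree within
±2 clusters. Percent changes between two field summaries are
`(a − b)/a × 100`, rounded half-up to integer percent.

## Synthetic data

The two-state simulator draws track lengths uniformly (default 7–26
localizations, i.e. 6–25 steps), assigns molecules free (default
0.084 μm²/s) or bound (default 0.0394 μm²/s) states with probability
`p_bound` (optionally Markov-switching at rates k_bind/k_release), confines
bound molecules to reflecting discs, propagates Brownian substeps (default
10 per 50-ms frame), and reports the substep mean per frame (continuous-
illumination blur; `report_blur=False` reports the instantaneous frame-end
position) plus independent per-axis Gaussian error (default 46 nm). The
radial-mirror reflection at disc boundaries slightly biases the stationary
distribution when steps are comparable to the disc radius; fine substeps
make the bias negligible, which is why closed-form confinement checks run
with ≥20 substeps.

The cluster-field generator places centers uniformly in the ROI inset by
the disc radius (so discs fit), draws localizations uniformly in each disc
plus isotropic 70-nm Gaussian uncertainty, and adds background as an exact
count of distinct pixels — `round(0.007 × n_pixels)` — with one
localization per chosen pixel center and no extra jitter. The
dual-channel generator plants an exact inside/outside density ratio.

What the generators do **not** emulate: fluorophore photophysics (blinking,
photon-budget-dependent localization precision), detection failures in
dense regions, camera noise, 3D motion, or inter-molecular interactions.
Passing tests therefore validate the estimators under their own model
assumptions — unbiasedness, corrections, parameter recovery — not
robustness to the full complexity of cellular PALM data.

## Problem sizes and determinism

All generators and the Monte-Carlo threshold take explicit seeds and are
bit-reproducible. Test and acceptance runs use scaled problem sizes chosen
for tight statistical bounds at modest cost: 4,000–25,000 simulated tracks
for diffusion properties, 8,000 tracks per condition for engagement
recovery, 20,000 emitters for the calibration simulation, and 10 replicate
fields × 100 Monte-Carlo iterations for the cluster benchmark.
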
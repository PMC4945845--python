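# Methods

This note documents the models, measurement operators, numerical choices
and known limitations of `qctlung`, in the spirit of a software methods
section.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement problem

Pulmonary congestion raises the attenuation of lung parenchyma on CT.
Because extravascular lung water (EVLW) accumulates heterogeneously, its
first-order signature is not a large mean shift but a heavier right-hand
tail of the lung attenuation histogram: skewness and excess kurtosis fall,
the full width at half maximum (FWHM) grows, and the fraction of voxels
above −500 HU (the congestion index) rises.  Airway wall engorgement, if
present, would show up in per-generation lumen/wall morphometry.  The
package computes both families of indices from a 3-D HU volume and runs
the group-level statistics of a two-arm (control vs. heart failure),
pre/post-bronchodilator study design.

## Density indices

- Moments are computed on the raw voxel values of the analysis mask, not
  on binned counts.  Skewness is the biased sample estimator
  g1 = m3/m2^1.5; kurtosis is reported as excess (g2 = m4/m2² − 3) with
  the raw variant (g2 + 3) carried alongside, since published tables do
  not always state which convention they use.
- The analysis mask is lung ∧ ¬lumen ∧ (−1000 ≤ HU ≤ 0), boundary values
  inclusive: "outside the range" excludes strictly-outside voxels only.
  Airway *wall* voxels are not excluded — only the lumen — because walls
  are tissue and their fate inside the lung field is ambiguous; the choice
  is isolated in `apply_analysis_exclusions`.
- FWHM: histogram with fixed 1 HU bins (fine enough that interpolation
  error is below a bin), mode chosen with ties broken toward lower HU, and
  the two half-maximum crossings found searching outward with linear
  interpolation between bin centers.  Density is taken as zero outside the
  binned range, so a flat-topped histogram of width W reports W and a
  single occupied bin reports one bin width.  FWHM is the one index that
  needs a large voxel count: with ~10⁴ voxels the mode bin is selected by
  an upward noise fluctuation and the width biases low by several HU, so
  cohort-level simulations at reduced voxel counts treat FWHM as noisy.
- Congestion index uses a strict `>` at −500 HU.
- Air/tissue partition: f_air = (55 − HU)/1055 clamped to [0, 1];
  f_tis = 1 − f_air identically, so conservation is exact per voxel and
  V_air + V_tis equals the masked volume to rounding error.
- Percent change of the mean HU uses a magnitude convention,
  100·(|post| − |pre|)/|pre|, so a leftward shift toward −1000 HU (fluid
  clearing) is a positive change — matching the sign convention of
  published pre/post tables; a `signed` variant is available.  All other
  indices use 100·(post − pre)/|pre|.

## Lung segmentation

Thresholding at −320 HU (midway between parenchyma and soft tissue),
removal of border-connected components (ambient air), retention of the two
largest interior components, a one-voxel 26-neighborhood closing and hole
filling.  Component labeling itself uses face (6-) connectivity: a
one-voxel-thick airway wall can be crossed diagonally under
26-connectivity, which would merge the airway lumen with the lung fields.
Bright intra-parenchymal voxels (vessels, edema) are absorbed by the
closing/fill step.  Left/right separation and lobe segmentation are out of
scope.

## Airway pipeline

**Lumen segmentation** is threshold-relaxation region growing: the
connected component of the seed below −950 HU, relaxed in 25 HU steps to
−400 HU.  A step that multiplies the accepted volume by more than the leak
ratio (2×) — or that reaches the grid border — is interpreted as the region
bursting through a wall and is rolled back; growth stops at the last safe
threshold.  This is a deliberately simple, auditable stand-in for
multiseed fuzzy-connectivity airway segmenters; it is exact on phantoms
and contains single-voxel wall perforations (verified by a punched-wall
fixture).

**Tree extraction**: 3-D topology-preserving thinning
(`skimage.morphology.skeletonize`), a 26-neighborhood voxel graph, cycles
broken by a minimum-spanning tree (keeping the shortest edges), and
condensation into a segment multigraph whose nodes are endpoints and
bifurcation clusters.  Leaf spurs shorter than 3 mm are pruned and
pass-through nodes re-merged.  Thinning recedes from blunt tube ends by
several lumen radii, which would consume the proximal trachea; when a
tracheal hint voxel is supplied, a path from the hint through the lumen
mask is grafted onto the skeleton and the root centerline additionally
extended through the mask.  Generations count bifurcations from the root
(trachea = 1; an offset is configurable); all children of a branch point,
including trifurcations, get generation parent + 1.

**Cross-sectional measurement**: at up to 40 cross-sections perpendicular
to the smoothed centerline, 24 rays are cast with radial sampling at a
quarter voxel.  The wall appears as an attenuation bump between the dark
lumen and parenchyma; the inner edge is the half-maximum crossing between
lumen level and bump peak, the outer edge the half-maximum crossing back
down to the beyond-bump level (the full-width-half-maximum principle,
which degrades gracefully near the resolution limit).  Luminal area is the
radial integral (π/n)Σrᵢ² — exact for circles, unlike the inscribed
polygon, which biases ~1% low at 24 rays.  Per cross-section the wall is
the median over rays, robust to rays that run into a neighbouring branch;
an outer edge further than 5 mm beyond the inner edge is rejected as a
distant structure (e.g. the mediastinum–lung boundary seen from inside
the trachea).  Cross-sections within half a local diameter of either
branch end (the bifurcations) are discarded; segment values are medians
over the survivors.  Quality flags: `ok`; `wall_unreliable` when the area
is valid but the wall estimate sits at the resolution floor (below 1.25
voxels — a sub-voxel wall blurs to a ~1.1 voxel bump, so thinner walls are
indistinguishable) or no outer contrast exists; `unreliable` when fewer
than 3 cross-sections survive.  Per-generation summaries average segment
means within each generation (segment-mean-then-generation-mean),
including `wall_unreliable` areas but not their walls, and analysis stops
at generation 6.

**Normalizations**: area/TLC (mm²/L) and wall/area (mm/mm²).  Because
figure captions and methods text of published studies disagree on whether
walls are normalized to area or radius, a wall/equivalent-radius ratio is
emitted alongside.

## The phantom

A soft-tissue body ellipsoid (+30 HU) containing two lung ellipsoids and a
dichotomous airway tree rendered as nested capsules (lumen −1000 HU, wall
+30 HU), with a 2 mm peribronchial soft-tissue sheath guaranteeing the
lumen is always enclosed, and the lungs clipped 2 mm inside the body
surface so lung air never touches ambient air.  Voxels are assigned by
center-point membership (no antialiasing): truth masks are exact at the
cost of a ≤1 voxel bias in rendered radii.

Parenchymal attenuation is a mixture: with probability `evlw_weight` a
voxel is drawn from the bright EVLW component Normal(−700, 150) HU;
otherwise HU = −1000·f + 30·(1 − f) + Normal(0, 40) with f the lung air
fraction (default 0.9).  The EVLW component location/width and the 40 HU
parenchymal noise were fixed analytically so that (a) a 5%-weight
"control" and 25%-weight "HF" phantom land near published cohort values of
skewness, kurtosis, FWHM and congestion index, and (b) the EVLW tail
overlaps the parenchymal peak — a far-off narrow component (e.g. centered
at −300 HU) provably cannot move the histogram's half-max crossings, which
would make fluid clearance leave the FWHM unchanged, contradicting the
observed post-bronchodilator narrowing.  Within the congested range the
mixture reproduces the clinical ordering: rising EVLW weight monotonically
raises the congestion index and mean HU while lowering skewness and
kurtosis; against the symmetric zero-weight baseline any tail raises
skewness from zero (both behaviours are tested).

An optional `vascular_weight` adds a second, *uncleared* tail component
(small vessels and interstitium, which congestion indices also measure).
It defaults to 0 — the plain two-component mixture — but is enabled in the
cohort defaults (4%), because a near-clean control lung whose only tail is
clearable EVLW would show *falling* skewness after clearance (the mixture
skew vanishes as the tail weight goes to zero), whereas real control
histograms retain an intrinsic right tail and show rising skewness.

The simulated bronchodilator resamples a chosen fraction of EVLW voxels
from the clean parenchymal model and thins airway walls by a fraction with
the lumen untouched; freed wall voxels inside the lung territory become
parenchyma, outside they revert to body tissue.

Tree geometry: trachea along the slice axis (root radius 8 mm, wall
2.5 mm, length 28 mm), planar dichotomous branching at ±32° with the
branching plane alternating per generation, radius decay 0.71 per
generation (halving the area), wall decay 0.9 (−10%), length decay 0.78.
These defaults keep six generations inside a 128×120×120 mm grid with the
distal lumen ~3 voxels wide at 1 mm spacing — resolvable but near the
acknowledged 2-pixel measurement limit.

## Cohort simulation

Subject parameters (EVLW weight, TLC, clearance fraction, wall thinning,
spirometry % predicted, per-generation areas) are drawn from group
mean/SD distributions; generation areas and spirometry are coupled through
a Gaussian copula whose latent correlation matrix carries configurable
(generation, variable, ρ) targets plus within-block correlations, with a
positive-semi-definiteness check (an error on infeasible targets).  Linear
(Gaussian) marginals make the target Pearson correlations exact in
expectation.  The clearance fraction is correlated with baseline EVLW
weight (ρ = 0.5 by default): subjects with more fluid clear more, which is
what produces the negative baseline-versus-percent-change correlations for
skewness/kurtosis/FWHM/congestion and the positive one for mean HU.
Cohort realism is limited to first two moments plus these correlation
targets; no subject-level distributions beyond that are modeled.

Cohort-scale Monte-Carlo checks (type-I error over 1000 replicates, copula
correlation recovery over 200, paired-t power) sample the parenchymal HU
mixture directly instead of rasterizing volumes — the identical generative
model, minus rendering — at 10⁴–10⁵ voxels per scan; full-volume paths are
exercised end-to-end on small grids by the pipeline and determinism tests.

## Statistics

Welch (unequal-variance) t throughout for group contrasts — published
methods rarely state pooled vs. Welch, and Welch is the safer default
(configurable in spirit: the pooled form is a one-line change via scipy).
Raw-sample and summary-form (mean, SD, n) code paths agree to 10⁻¹² and the
summary form reproduces significance calls from printed tables.  Paired t
on post − pre differences, with the zero-variance-difference cases handled
explicitly (identical pairs → t = 0, p = 1; constant shift → degenerate
p → 0).  Bonferroni adjustment min(1, p·m) with m = 6 generation-level
tests by default.  Two-sided tests at α = 0.05.  Subjects lacking a post
scan contribute to baseline tables only and are listed in an exclusions
table.  Percent-change summaries are mean ± SD of per-subject percent
changes, not the percent change of group means.

## Determinism and sizes

Every stochastic component takes an explicit seed (`numpy.random.default_rng`);
equal seeds give bit-identical volumes, and `run_cohort` outputs are
byte-identical across reruns of the same manifest and configuration.  The
default phantom grid is 128×120×120 at 1 mm (≈1.8 M voxels, ~250 k
parenchymal voxels); tests that sweep many phantoms use a 96×88×88 grid
with proportionally shortened branches, chosen so the suite exercises the
full pipeline at cohort scale while remaining quick to run.

## Known limitations

- Center-point rendering biases rendered radii by up to one voxel;
  measured luminal areas inherit a few-percent bias at 1 mm spacing that
  shrinks with voxel size (verified on digital cylinders at 1.0/0.5/0.25 mm).
- The mediastinal trachea has no parenchymal contrast, so its wall
  thickness is flagged rather than measured; generation-6 walls overlap
  between sibling branches and are near the resolution floor.
- The phantom has no lobar anatomy, vasculature, cardiac structures,
  breathing motion, reconstruction-kernel effects or gravitational EVLW
  gradients; passing tests demonstrate correctness of the measurement
  operators under the stated generative model, not performance on real
  scanner data.
- FWHM magnitudes respond only weakly to the EVLW mixture (a few HU),
  versus tens of HU in real congested lungs whose parenchymal peak itself
  broadens; the direction of the effect is reproduced, the magnitude is
  not.
- DICOM support is read-only and minimal (rescale slope/intercept,
  consistent slice spacing); NIfTI is the native format.
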
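# Methods

This note documents the models, numerical choices and limitations of
dentamorph, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## The measurement problem

Hippocampal dentation — the ridged undulation of the inferior CA1 /
subiculum surface — has bump heights of a few tenths of a millimetre,
below the voxel size of clinical T1 imaging (~1 mm isotropic after
resampling).  A segmentation at native resolution therefore cannot carry
the feature, but the *grayscale* image does: partial-volume intensities
encode the surface position at sub-voxel precision, and a surface that
is driven to the image's edges can recover it.  dentamorph separates the
problem into (a) recovering a fine surface from a coarse probability map
plus the image, and (b) reducing that surface to two interpretable
numbers, bump amplitude `A` and bump frequency `f`.

## Fine-scale surface refinement

The coarse probability map is cropped to the region of interest
(threshold 0.1, margin 2 mm), then cubic-spline upsampled by an integer
factor `H` (default 5; 1 mm → 0.2 mm).  Upsampling uses align-corners
node placement — coarse voxel centres remain exact sample points — with
linear-extrapolation padding so that linear intensity trends are
reproduced exactly up to the boundary.  The companion image is upsampled
identically.

The surface is the zero level set of a signed field φ (negative inside),
initialized as the signed distance to the high-confidence region
`{M > η}` (largest connected component; ties broken by mean
probability).  The normal speed combines three forces:

* **Edge**: the Laplacian-of-Gaussian response of the upsampled image
  (`log_sigma_mm` = 0.5 mm at the fine grid), rescaled to [−1, 1] per
  volume so that the weights α and β are comparable across images.  The
  LoG is negative just inside a bright object's edge and positive just
  outside, so the surface is attracted to the zero crossing from both
  sides.  The image is assumed brighter inside the structure.
* **Regional**: `−α·M` along the inward normal — outward pressure
  wherever the probability map is high (α = 1).
* **Curvature**: `β·ν` with ν the divergence of the outward unit normal
  (sum of principal curvatures, +2/R for a ball); β = 0.2.  Pure
  curvature flow shrinks a ball as `R² = R0² − 4βt`, which is the oracle
  used to validate the discretization (within 10 %).

Numerics: Godunov upwinding for the advective terms, central differences
for curvature (clipped to ±1/voxel), CFL time step
`dt = dt_cfl / (max|F|/h + 6β/h²)`.  φ is maintained distance-like by
Sussman reinitialization; because the signed-distance structure is only
repaired at reinitialization, the reinit interval is chosen so the front
cannot cross more than half the narrow band between repairs.  Evolution
stops when the relative volume change over a 10-iteration window falls
below 2·10⁻⁴ (default), or optionally when the discrete surface energy
`E = −α∫inside M + β·Area` stops decreasing (`stop_on_energy_increase`)
— the appropriate rule for the pure regional+curvature flow, which on a
*binary* map has no stable discrete equilibrium (the one-sided force
lets the front creep sub-voxel-per-tens-of-iterations past the support
edge; the edge force, when present, supplies the restoring term and
makes the default rule sufficient).

Defaults η = 0.5, α = 1.0, β = 0.2, LoG σ = 0.5 mm were fixed so that
the end-to-end synthetic benchmark (below) holds Dice ≥ 0.95 on every
amplitude/frequency combination; β trades bump preservation against
noise robustness, and larger values visibly flatten the dentations.

## Dentation quantification

The refined mask interior is represented by `n_points` uniform samples
(rejection sampling against the bounding box; a deterministic
voxel-centre mode exists and agrees with sampling to within 2 % on the
fitted parameters).  PCA of the point cloud gives the long
anterior–posterior axis `e1` (the hippocampus is longest front-to-back)
and the sheet normal `e3`, oriented toward the anatomical inferior side
taken from the volume's axis labels or an explicit hint.  Points are
projected onto the (e1, e3) plane; heights are measured along the
superior-pointing axis so the inferior boundary is a per-bin *minimum*.
The silhouette is a binned lower envelope (bin width 0.2 mm = one fine
voxel by default, bins with < 5 points dropped, 10 % of the long-axis
range trimmed per end to exclude the curved head and tail of a real
hippocampus; a 5th-percentile robust envelope is available for noisy
masks).

The silhouette is fit with `y = A sin(wx + φ) + b` by minimizing the
mean squared residual with simulated annealing: variance-normalized
cost, T₀ = 1, geometric cooling 0.95 to T_min = 10⁻⁴, 50 single-
parameter Gaussian proposals per temperature (step ∝ √T; frequency
proposed in log-space), 4 restarts, best-ever solution polished by
Nelder–Mead and kept only if it improves the cost within the bounds
(A ∈ [0, 2] mm, f ∈ [0.02, 0.5] bumps/mm, b within the data range
± 2 mm — generous brackets around physiological dentation).  A
silhouette with variance < 10⁻¹⁰ short-circuits to A = 0 ("flat").
Reported measures: `f = w/2π`, bump height `H = 2A`, width `L = 1/f`.

## Synthetic validation

`shapesim` generates a dentated cuboid (default 40 × 20 × 10 mm — long
enough for ≥ 4 periods at the lowest frequency of interest) whose
inferior face is displaced by `A·sin(2πFx + φ)`; the superior face stays
flat, ridges run parallel to the left–right axis, as on the real
structure.  Voxelization marks a voxel foreground iff its centre lies
inside the continuous shape (0.2 mm default grid, 2-voxel margin).
Degradation to a "native" acquisition box-averages to 1 mm, blurs with a
0.5 mm Gaussian, and adds clipped Gaussian noise (sd 0.05 on
probabilities); the companion image uses means 120/40, a 0.3 mm PSF and
noise sd 5 — contrasts and noise chosen to resemble a T1 hippocampus
against surrounding tissue.

The recovery study runs the 16 combinations A ∈ {0.1, 0.2, 0.3, 0.4} mm
× F ∈ {0.1, 0.125, 0.2, 0.25} bumps/mm with phase randomized per
replicate, in three modes:

* **analytic** — noise-free silhouettes; isolates the optimizer
  (recovery to 10⁻³).
* **direct** — rejection sampling from the *continuous* shape, then the
  full shape-analysis chain.  This is the quantitative validation of
  the dentation measurement; the study uses 300 000 points and 0.1 mm
  bins (finer than the per-subject defaults) because the binned
  minimum carries a one-sided noise term of order
  (cross-section height)/(points per bin) and an envelope erosion bias
  of order `A(wΔ)²/16` for bin width Δ, both of which must sit well
  below the millimetre-fraction effects being measured.
* **full** — voxelize, degrade, refine, extract, fit.  Frequency
  survives the whole pipeline (< 1 % error for bumps of at least one
  voxel); amplitude does not survive quantitatively: a 0.2 mm grid
  cannot express a 0.1 mm amplitude (2A = one voxel), and
  re-voxelization alone perturbs fitted amplitude by ±0.01–0.03 mm.
  The full mode therefore validates surface recovery (Dice, slice-wise
  Hausdorff against the unrefined native segmentation) and the
  *qualitative* amplitude behaviour — underestimation, worst at the
  shallowest bumps — rather than amplitude decimals.

What passing these tests does **not** show: anatomically realistic
hippocampus geometry (curved medial axis, non-parallel ridges, per-slice
width variation), scanner artefacts beyond stationary Gaussian noise,
or segmentation-model failure modes; the cuboid phantom isolates the
measurement chain, not the biology.

## Group comparison

Per-subject records (side, group, A, f) are compared with pairwise
two-sided Welch t-tests, sides kept separate, significance tiers at raw
p < 0.05 / 0.005 / 0.001 without multiple-testing correction (the tiers
mirror the three-star convention; the choice is recorded in the output
metadata).  Box-plot summary statistics (median, quartiles, 1.5-IQR
whiskers) are exported per group.  Calibration is checked against the
closed-form two-sample power at n = 90 per group.

## Degenerate inputs and tie-breaks

Empty super-threshold set at cropping or initialization → explicit
errors naming the remedy; several equal-size largest components → the
one with the highest mean probability; near-isotropic point clouds →
warning (principal axes ill-determined); coplanar clouds → error; flat
silhouettes → A = 0 result, not an error; surface collapse during
evolution → error suggesting a smaller β.

## Known limitations

* Amplitudes below half the fine voxel size are unmeasurable from
  binary masks; measure at the level-set stage's resolution or refine
  deeper if shallower dentation matters.
* The pipeline assumes the structure is brighter than its surroundings;
  invert the image otherwise.
* PCA requires the dentated sheet to be the thinnest principal
  direction; pathological shapes (near-isotropic, strongly curved) are
  flagged but not handled specially.
* The sinusoid model is single-frequency; mixed or non-stationary
  dentation patterns are summarized, not decomposed.
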
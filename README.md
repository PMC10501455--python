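# dentamorph

Fine-scale morphometry of hippocampal **dentation** — the small, bumpy
ridges on the inferior surface of CA1/subiculum that vary from smooth to
strongly dentated across individuals.  Clinical-resolution (~1 mm) MRI
segmentations smooth these bumps away; this toolkit refines a coarse
segmentation probability map to a sub-voxel surface, extracts the
inferior silhouette of the shape, and quantifies the dentation pattern
with two numbers: bump amplitude and bump frequency.  It is written for
neuroimaging researchers who already have a hippocampus probability map
(from any segmentation model) and want reproducible dentation measures,
plus a fully synthetic validation path that needs no image data at all.

## Method

1. **Fine-scale refinement** (`finescale`).  The probability map
   `M : Ω → [0,1]` is cropped to the hippocampal region of interest and
   cubic-spline upsampled by a factor `H` (default 5: 1 mm → 0.2 mm).
   The high-confidence region `C = {x : M(x) > η}` initializes a closed
   surface ζ, evolved as the zero level set of a signed field φ under

       ∂ζ/∂t = [ LoG(I) − α·M + β·ν ] · V

   with `V` the inward unit normal, `ν` the mean curvature (sum of
   principal curvatures), `LoG(I)` the Laplacian-of-Gaussian edge
   response of the grayscale image (rescaled to [−1, 1]), and the
   corresponding energy  E(ζ) = −α ∫inside M dx + β ∫ζ dA.
   The regional term grows the surface where `M` is high, the edge term
   locks it onto intensity edges at sub-voxel precision, the curvature
   term regularizes.

2. **Silhouette extraction** (`dentation`).  The refined mask is
   represented as a uniform interior point cloud (rejection sampling).
   PCA gives the long (anterior–posterior) axis `e1` and the sheet
   normal `e3`; points are projected onto the (e1, e3) plane and the
   inferior boundary is read off as a binned lower envelope `y(x)`.

3. **Sinusoidal fit** (`sinfit`).  The silhouette is modelled as
   `y = A·sin(wx + φ) + b` by minimizing the mean squared residual
   `J(A, w, φ, b)` with simulated annealing (worse moves accepted iff
   `exp(−ΔD/T) > u`, geometric cooling) plus a Nelder–Mead polish.
   Reported measures: frequency `f = w/2π` (bumps/mm), bump height
   `H = 2A`, bump width `L = 1/f`.

4. **Validation & statistics** (`shapesim`, `evalmetrics`, `study`).
   Synthetic dentated cuboids with known `(A, F)` are generated,
   optionally degraded into coarse noisy probability maps, and pushed
   through the pipeline to measure recovery error; segmentations are
   scored with Dice/Jaccard/precision/recall and HD / HD95; group
   differences in `A` and `f` are tested with pairwise Welch t-tests
   (tiers at p < 0.05 / 0.005 / 0.001).

## Worked example (fully synthetic)

```python
import dentamorph as dm

spec  = dm.SimShapeSpec(amplitude_mm=0.3, frequency_bpm=0.2, phase_rad=0.7)
truth = dm.simulate_dentated_cuboid(spec)                      # 0.2 mm mask
image = dm.companion_intensity_image(truth, fg_mean=120, bg_mean=40,
                                     noise_sd=5.0, seed=1)
prob  = dm.degrade_to_probability_map(truth, coarse_spacing_mm=1.0,
                                      blur_sigma_mm=0.5, noise_sd=0.05, seed=2)
image_native = dm.box_downsample(image, 1.0)                   # ~1 mm "scan"

cfg     = dm.RunConfig(seed=7)
refined = dm.fine_scale_segment(image_native, prob, cfg)       # back to 0.2 mm
sil     = dm.silhouette_from_mask(refined, n_points=cfg.n_points,
                                  seed=cfg.seed, bin_width_mm=cfg.bin_width_mm,
                                  trim_fraction=cfg.trim_fraction)
fit     = dm.fit_sinusoid_sa(sil, dm.FitBounds(), dm.SASchedule(seed=cfg.seed))
print(f"amplitude A = {fit.A_mm:.3f} mm   (true 0.300)")
print(f"frequency f = {fit.f_bpm:.3f} bumps/mm  (true 0.200)")
print(f"bump height H = 2A = {fit.H_mm:.3f} mm")
print(f"bump width  L = 1/f = {fit.L_mm:.2f} mm")
```

prints

```
amplitude A = 0.176 mm   (true 0.300)
frequency f = 0.201 bumps/mm  (true 0.200)
bump height H = 2A = 0.352 mm
bump width  L = 1/f = 4.99 mm
```

Frequency comes back essentially exact.  The amplitude is
underestimated: after degradation to 1 mm and re-voxelization at
0.2 mm, a 0.3 mm bump spans only 1.5 fine voxels, and the surviving
discretization plus blur eats part of the bump height — the same
shallow-bump underestimation the validation study quantifies.  Running
the shape-analysis chain alone (no degradation; `mode="direct"` of the
recovery study) recovers both parameters to well under 1 %.

The same steps are available from the shell:
`dentamorph simulate | degrade | refine | extract | fit | evaluate |
study | compare` (see `dentamorph --help`).

## Defaults

| parameter | default | meaning |
|---|---|---|
| `upsample_factor` | 5 | native → fine upsampling factor H |
| `eta` | 0.5 | high-confidence threshold η on the upsampled map |
| `alpha` | 1.0 | regional (probability) force weight α |
| `beta` | 0.2 | mean-curvature force weight β |
| `log_sigma_mm` | 0.5 | LoG edge-detector scale at the fine grid (mm) |
| `sa_t0` | 1.0 | initial annealing temperature (variance-normalized cost) |
| `sa_cooling` | 0.95 | geometric cooling factor |
| `sa_iters_per_temp` | 50 | proposals per temperature |
| `sa_t_min` | 0.0001 | final temperature |
| `sa_restarts` | 4 | independent annealing restarts |
| `n_points` | 20000 | interior points sampled per hippocampus |
| `bin_width_mm` | 0.2 | silhouette bin width (mm) |
| `trim_fraction` | 0.1 | long-axis fraction trimmed per end |
| `seed` | 0 | master seed |

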
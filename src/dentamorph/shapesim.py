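"""Synthetic dentated shapes.

Generates the simulation phantoms used to validate the dentation
morphometry: a cuboid body whose *inferior* face is displaced by a
sinusoid ``z = A * sin(2*pi*F*x + phase)`` along the height axis, with
``x`` the position along the length (anterior-posterior) axis.  The
superior face stays flat; the dentation ridges run parallel to the
left-right axis, as they do on the real hippocampus.

The same module degrades a fine mask into a coarse, blurred, noisy
probability map that stands in for a segmentation network's output, and
builds a companion grayscale image whose Laplacian-of-Gaussian supplies
the edge force of the surface refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .volume import (BinaryMask, ProbabilityMap, ScalarVolume, box_downsample)

log = logging.getLogger("dentamorph")

#: background margin around the shape, in voxels
MARGIN_VOXELS = 2


@dataclass
class SimShapeSpec:
    """Parameters of a simulated dentated cuboid.

    amplitude_mm : dentation amplitude A (half the bump height), >= 0.
    frequency_bpm : dentation frequency F in bumps per mm, > 0.
    length_mm, width_mm, height_mm : cuboid body dimensions.
    phase_rad : phase of the sinusoidal displacement.
    voxel_mm : fine-grid spacing for voxelization (default 0.2 mm).
    """

    amplitude_mm: float
    frequency_bpm: float
    length_mm: float = 40.0
    width_mm: float = 20.0
    height_mm: float = 10.0
    phase_rad: float = 0.0
    voxel_mm: float = 0.2

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ParameterError("amplitude_mm must be non-negative")
        if not self.frequency_bpm > 0:
            raise ParameterError("frequency_bpm must be positive")
        for name in ("length_mm", "width_mm", "height_mm", "voxel_mm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.length_mm * self.frequency_bpm < 3:
            raise ParameterError(
                f"length_mm * frequency_bpm = "
                f"{self.length_mm * self.frequency_bpm:.3g} < 3: fewer than "
                f"3 full bump periods fit on the shape")
        if not 2 * self.amplitude_mm < self.height_mm:
            raise ParameterError(
                "2 * amplitude_mm must be smaller than height_mm")
        if self.amplitude_mm > 0 and self.voxel_mm > self.amplitude_mm:
            log.warning(
                "voxel_mm=%.3g exceeds amplitude_mm=%.3g: bumps are "
                "sub-voxel and will be poorly represented in the mask",
                self.voxel_mm, self.amplitude_mm)

    # -- continuous geometry -----------------------------------------
    def inferior_height(self, x) -> np.ndarray:
        """Height of the inferior face at length-axis position x (mm)."""
        return self.amplitude_mm * np.sin(
            2 * np.pi * self.frequency_bpm * np.asarray(x, dtype=float)
            + self.phase_rad)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Continuous indicator: True where (x, y, z) lies inside the shape."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        s = self.inferior_height(p[:, 0])
        return ((p[:, 0] >= 0) & (p[:, 0] < self.length_mm)
                & (p[:, 1] >= 0) & (p[:, 1] < self.width_mm)
                & (p[:, 2] > s) & (p[:, 2] < self.height_mm))

    @property
    def analytic_volume_mm3(self) -> float:
        """Exact volume: the sinusoidal displacement integrates to zero over
        whole periods, and to a small closed-form remainder otherwise."""
        A, F, phi = self.amplitude_mm, self.frequency_bpm, self.phase_rad
        w = 2 * np.pi * F
        # integral of A*sin(w x + phi) dx over [0, L]
        disp = A / w * (np.cos(phi) - np.cos(w * self.length_mm + phi))
        return self.width_mm * (self.length_mm * self.height_mm - disp)


def simulate_dentated_cuboid(spec: SimShapeSpec) -> BinaryMask:
    """Voxelize the dentated cuboid on a fine isotropic grid.

    A voxel is foreground iff its centre lies inside the continuous shape.
    World coordinates of the returned mask coincide with the shape's own
    coordinates (length axis = anterior-posterior, bump axis =
    superior-inferior, inferior face toward smaller height coordinate).
    A two-voxel background margin surrounds the shape.
    """
    h = spec.voxel_mm
    m = MARGIN_VOXELS * h
    lo = np.array([-m, -m, -spec.amplitude_mm - m])
    hi = np.array([spec.length_mm + m, spec.width_mm + m, spec.height_mm + m])
    n = np.ceil((hi - lo) / h - 1e-9).astype(int)
    centers = [lo[k] + (np.arange(n[k]) + 0.5) * h for k in range(3)]
    X = centers[0][:, None, None]
    Y = centers[1][None, :, None]
    Z = centers[2][None, None, :]
    s = spec.inferior_height(X)
    fg = ((X >= 0) & (X < spec.length_mm)
          & (Y >= 0) & (Y < spec.width_mm)
          & (Z > s) & (Z < spec.height_mm))
    origin = lo + 0.5 * h
    return BinaryMask(data=fg.astype(np.uint8), spacing_mm=h,
                      origin_mm=origin, axes=("A", "R", "S"))


def sample_shape_points(spec: SimShapeSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` uniform interior points from the *continuous* shape by
    rejection sampling against its bounding box.

    Used by the validation study's direct-silhouette mode, where the
    shape-analysis chain is exercised without voxelization error.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 0.0, -spec.amplitude_mm])
    hi = np.array([spec.length_mm, spec.width_mm, spec.height_mm])
    out = []
    remaining = n
    while remaining > 0:
        batch = int(remaining * 1.5) + 256
        cand = rng.uniform(lo, hi, size=(batch, 3))
        keep = cand[spec.contains(cand)]
        out.append(keep[:remaining])
        remaining -= len(out[-1])
    return np.vstack(out)


def degrade_to_probability_map(mask: BinaryMask, coarse_spacing_mm: float,
                               blur_sigma_mm: float, noise_sd: float,
                               seed: int) -> ProbabilityMap:
    """Degrade a fine binary mask into a coarse probability map.

    Models a segmentation network's output at native scanner resolution:
    box-averaging to the coarse grid (partial volume), Gaussian blur of
    ``blur_sigma_mm``, optional clipped Gaussian noise, then clipping to
    [0, 1].  The 0.5 level set of the result stays within about one coarse
    voxel of the true surface.
    """
    if coarse_spacing_mm < mask.spacing_mm - 1e-12:
        raise ParameterError(
            f"coarse spacing {coarse_spacing_mm} mm must not be finer than "
            f"the mask spacing {mask.spacing_mm} mm")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    fine = ScalarVolume(data=mask.data.astype(float),
                        spacing_mm=mask.spacing_mm,
                        origin_mm=mask.origin_mm, axes=mask.axes)
    coarse = box_downsample(fine, coarse_spacing_mm)
    data = coarse.data
    if blur_sigma_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma_mm / coarse_spacing_mm,
                                       mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.clip(rng.normal(0.0, noise_sd, size=data.shape),
                        -3 * noise_sd, 3 * noise_sd)
        data = data + noise
    data = np.clip(data, 0.0, 1.0)
    return ProbabilityMap(data=data, spacing_mm=coarse.spacing_mm,
                          origin_mm=coarse.origin_mm, axes=mask.axes)


def companion_intensity_image(mask: BinaryMask, fg_mean: float = 120.0,
                              bg_mean: float = 40.0, noise_sd: float = 0.0,
                              seed: int = 0,
                              psf_sigma_mm: float = 0.3) -> ScalarVolume:
    """Build a grayscale image consistent with a mask.

    Piecewise-constant foreground/background means, blurred by a small
    Gaussian point-spread function so edges are smooth (the intensity
    gradient is maximal at the true surface), plus optional Gaussian
    noise added after blurring.
    """
    if fg_mean == bg_mean:
        raise ParameterError("fg_mean must differ from bg_mean")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    data = bg_mean + (fg_mean - bg_mean) * mask.data.astype(float)
    if psf_sigma_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=psf_sigma_mm / mask.spacing_mm,
                                       mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ScalarVolume(data=data, spacing_mm=mask.spacing_mm,
                        origin_mm=mask.origin_mm, axes=mask.axes)
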
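"""Sub-voxel surface refinement of a coarse probability map.

The pipeline is ``crop -> upsample -> threshold -> evolve``: the coarse
probability map is cropped to the region of interest, cubic-spline
upsampled by an integer factor H (native ~1 mm to fine 0.2 mm at H=5),
thresholded at a high-confidence level eta to initialize a closed
surface, and the surface is then evolved as the zero level set of a
signed field phi under the normal speed

    s = LoG(image) - alpha * M + beta * kappa

applied along the *inward* unit normal: the Laplacian-of-Gaussian edge
force pulls the surface to intensity edges (it is negative just inside a
bright object's edge and positive just outside, so both sides drift
toward the zero crossing), the regional force ``-alpha*M`` pushes the
surface outward wherever the probability map is high, and the
mean-curvature term ``beta*kappa`` regularizes.

Conventions (stated because the sphere-shrinkage oracle depends on
them): phi is negative inside; kappa is the divergence of the outward
unit normal, i.e. the sum of the two principal curvatures (+2/R for a
ball of radius R), so pure curvature flow shrinks a ball as
R^2(t) = R0^2 - 4*beta*t.  The grayscale image is assumed brighter
inside the structure than outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DentamorphError, ParameterError, StageError
from .config import RunConfig
from .volume import (BinaryMask, ProbabilityMap, ScalarVolume, require_same_grid,
                     spline_upsample)

log = logging.getLogger("dentamorph")


@dataclass
class EvolveParams:
    """Numerical parameters of the level-set evolution."""

    alpha: float = 1.0
    beta: float = 0.2
    log_sigma_mm: float = 0.5
    dt_cfl: float = 0.9
    max_iters: int = 200
    converge_tol: float = 2e-4
    converge_window: int = 10
    band_halfwidth_mm: float = 1.0
    reinit_every: int = 20
    use_edge_force: bool = True
    stop_on_energy_increase: bool = False
    track_energy: bool = False

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")
        if not self.log_sigma_mm > 0:
            raise ParameterError("log_sigma_mm must be positive")
        if not 0 < self.dt_cfl <= 1:
            raise ParameterError("dt_cfl must lie in (0, 1]")
        if self.max_iters < 1 or self.converge_window < 1:
            raise ParameterError("max_iters and converge_window must be >= 1")
        if not self.converge_tol > 0:
            raise ParameterError("converge_tol must be positive")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "EvolveParams":
        return cls(alpha=cfg.alpha, beta=cfg.beta, log_sigma_mm=cfg.log_sigma_mm)


@dataclass
class LevelSetState:
    """Implicit surface state: phi < 0 inside, zero level = surface."""

    phi: np.ndarray
    spacing_mm: float
    band_halfwidth_mm: float
    iteration: int = 0
    last_volume_mm3: float = 0.0
    volumes_mm3: list = field(default_factory=list)
    energies: list = field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def upsample_probability(M: ProbabilityMap, H: int) -> ProbabilityMap:
    """Cubic-spline upsample a probability map by an integer factor H.

    Output spacing is ``spacing / H``; coarse voxel centres are kept as
    exact sample points (align-corners placement, ``(n-1)*H + 1`` nodes
    per axis), values are clipped to [0, 1] and the origin is unchanged,
    so world coordinates are preserved.
    """
    if H < 1:
        raise ParameterError(f"upsampling factor H must be >= 1, got {H}")
    data = np.clip(spline_upsample(M.data, int(H)), 0.0, 1.0)
    return ProbabilityMap(data=data, spacing_mm=M.spacing_mm / int(H),
                          origin_mm=M.origin_mm, axes=M.axes)


def upsample_intensity(vol: ScalarVolume, H: int) -> ScalarVolume:
    """Same node placement as :func:`upsample_probability`, without clipping."""
    if H < 1:
        raise ParameterError(f"upsampling factor H must be >= 1, got {H}")
    data = spline_upsample(vol.data, int(H))
    return ScalarVolume(data=data, spacing_mm=vol.spacing_mm / int(H),
                        origin_mm=vol.origin_mm, axes=vol.axes)


def roi_slices(M: ProbabilityMap, threshold: float, margin_mm: float):
    """Axis-aligned bounding box of {M > threshold} padded by margin_mm,
    clipped to the grid; returned as a tuple of slices."""
    above = np.argwhere(M.data > threshold)
    if above.size == 0:
        raise ParameterError(
            f"no foreground at threshold {threshold} (max value "
            f"{float(M.data.max()):.4g})")
    pad = int(np.ceil(margin_mm / M.spacing_mm))
    lo = np.maximum(above.min(axis=0) - pad, 0)
    hi = np.minimum(above.max(axis=0) + 1 + pad, M.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def crop_roi(M: ProbabilityMap, threshold: float, margin_mm: float) -> ProbabilityMap:
    """Crop a probability map to its super-threshold bounding box plus a
    margin; the origin is updated so world coordinates are preserved."""
    sl = roi_slices(M, threshold, margin_mm)
    lo = np.array([s.start for s in sl], dtype=float)
    return ProbabilityMap(data=M.data[sl].copy(), spacing_mm=M.spacing_mm,
                          origin_mm=M.origin_mm + lo * M.spacing_mm,
                          axes=M.axes)


def crop_like(vol: ScalarVolume, sl) -> ScalarVolume:
    """Apply a precomputed ROI slice tuple to another volume on the same grid."""
    lo = np.array([s.start for s in sl], dtype=float)
    return ScalarVolume(data=vol.data[sl].copy(), spacing_mm=vol.spacing_mm,
                        origin_mm=vol.origin_mm + lo * vol.spacing_mm,
                        axes=vol.axes)


def init_high_confidence(Mup: ProbabilityMap, eta: float) -> BinaryMask:
    """High-confidence region C = {M > eta}, reduced to its largest
    connected component (ties broken by highest mean probability)."""
    if not 0 <= eta <= 1:
        raise ParameterError("eta must lie in [0, 1]")
    fg = Mup.data > eta
    if not fg.any():
        raise ParameterError(
            f"no voxel exceeds eta={eta} (max probability "
            f"{float(Mup.data.max()):.4g}); lower eta")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if len(best) > 1:
            means = ndimage.mean(Mup.data, labels, index=best)
            keep = int(best[np.argmax(means)])
        else:
            keep = int(best[0])
        log.info("init_high_confidence: kept largest of %d components "
                 "(%d voxels), discarded %d voxels", n, int(sizes.max()),
                 int(fg.sum() - sizes[keep - 1]))
        fg = labels == keep
    return BinaryMask(data=fg.astype(np.uint8), spacing_mm=Mup.spacing_mm,
                      origin_mm=Mup.origin_mm, axes=Mup.axes)


# ---------------------------------------------------------------------------
# level-set evolution
# ---------------------------------------------------------------------------

def _signed_distance(fg: np.ndarray, h: float) -> np.ndarray:
    inside = ndimage.distance_transform_edt(fg, sampling=h)
    outside = ndimage.distance_transform_edt(~fg, sampling=h)
    return (outside - inside).astype(np.float32)


def _one_sided(phi: np.ndarray, h: float, axis: int):
    """Backward and forward differences with replicated edges."""
    dm = np.zeros_like(phi)
    dp = np.zeros_like(phi)
    sl = [slice(None)] * phi.ndim
    sl_lo, sl_hi = list(sl), list(sl)
    sl_lo[axis] = slice(1, None)
    sl_hi[axis] = slice(None, -1)
    diff = (phi[tuple(sl_lo)] - phi[tuple(sl_hi)]) / h
    dm[tuple(sl_lo)] = diff
    dp[tuple(sl_hi)] = diff
    return dm, dp


def _godunov_norms(phi: np.ndarray, h: float):
    """(grad_minus, grad_plus): upwind gradient norms for speeds of either
    sign in phi_t = a * |grad phi| (grad_minus is correct where a > 0)."""
    gm2 = np.zeros_like(phi)
    gp2 = np.zeros_like(phi)
    for axis in range(3):
        dm, dp = _one_sided(phi, h, axis)
        gm2 += np.minimum(dm, 0) ** 2 + np.maximum(dp, 0) ** 2
        gp2 += np.maximum(dm, 0) ** 2 + np.minimum(dp, 0) ** 2
    return np.sqrt(gm2), np.sqrt(gp2)


def _curvature_times_grad(phi: np.ndarray, h: float, kappa_max: float):
    """kappa * |grad phi| with central differences; kappa clipped to
    +-kappa_max to keep far-from-interface noise bounded.  Also returns
    the central-difference gradient norm."""
    gx, gy, gz = np.gradient(phi, h)
    gxx = np.gradient(gx, h, axis=0)
    gyy = np.gradient(gy, h, axis=1)
    gzz = np.gradient(gz, h, axis=2)
    gxy = np.gradient(gx, h, axis=1)
    gxz = np.gradient(gx, h, axis=2)
    gyz = np.gradient(gy, h, axis=2)
    g2 = gx * gx + gy * gy + gz * gz
    denom = g2 * np.sqrt(g2) + 1e-12
    kappa = ((gyy + gzz) * gx * gx + (gxx + gzz) * gy * gy
             + (gxx + gyy) * gz * gz
             - 2 * (gx * gy * gxy + gx * gz * gxz + gy * gz * gyz)) / denom
    np.clip(kappa, -kappa_max, kappa_max, out=kappa)
    gnorm = np.sqrt(g2)
    return kappa * gnorm, gnorm


def _sussman_reinit(phi: np.ndarray, h: float, steps: int = 10) -> np.ndarray:
    """A few iterations of the distance-reinitialization PDE
    phi_tau = S(phi0) (1 - |grad phi|), preserving the zero crossing to
    first order."""
    S = phi / np.sqrt(phi * phi + h * h)
    dtau = 0.3 * h
    for _ in range(steps):
        gm, gp = _godunov_norms(phi, h)
        # for S > 0 the information flows outward: use gp; for S < 0 use gm
        G = np.where(S > 0, gp, gm)
        phi = phi - dtau * S * (G - 1.0)
    return phi


def interface_area_mm2(phi: np.ndarray, h: float) -> float:
    """Surface area of the zero level set, via a smoothed delta function."""
    eps = 1.5 * h
    delta = np.where(np.abs(phi) < eps,
                     (1 + np.cos(np.pi * phi / eps)) / (2 * eps), 0.0)
    gx, gy, gz = np.gradient(phi, h)
    gnorm = np.sqrt(gx * gx + gy * gy + gz * gz)
    return float(np.sum(delta * gnorm) * h ** 3)


def discrete_energy(phi: np.ndarray, M: np.ndarray, alpha: float, beta: float,
                    h: float) -> float:
    """Discrete value of the surface energy
    E = -alpha * integral_{inside} M dx + beta * Area(surface)."""
    inside = phi < 0
    region = -alpha * float(M[inside].sum()) * h ** 3
    return region + beta * interface_area_mm2(phi, h)


def evolve_surface(Mup: ProbabilityMap, image_up: ScalarVolume,
                   init: BinaryMask, params: EvolveParams,
                   return_state: bool = False):
    """Evolve the zero level set of phi under
    ``phi_t = (LoG - alpha*M + beta*kappa) |grad phi|``.

    Stops when the relative volume change over ``converge_window``
    iterations falls below ``converge_tol``, or at ``max_iters``.
    Deterministic: identical inputs give identical outputs.
    """
    require_same_grid(Mup, image_up, "probability map and image")
    require_same_grid(Mup, init, "probability map and init mask")
    fg0 = init.data.astype(bool)
    if not fg0.any():
        raise ParameterError("init mask is empty")
    h = float(Mup.spacing_mm)
    phi = _signed_distance(fg0, h)

    M = Mup.data.astype(np.float32)
    if params.use_edge_force:
        Lg = ndimage.gaussian_laplace(image_up.data.astype(np.float32),
                                      sigma=params.log_sigma_mm / h)
        amax = float(np.abs(Lg).max())
        if amax > 0:
            Lg = Lg / amax  # rescale edge response to [-1, 1] per volume
    else:
        Lg = np.zeros_like(M)
    F_adv = (Lg - params.alpha * M).astype(np.float32)

    kappa_max = 1.0 / h
    fmax = float(np.abs(F_adv).max())
    dt = params.dt_cfl / (fmax / h + 6.0 * params.beta / h ** 2 + 1e-12)
    band = params.band_halfwidth_mm
    # the signed-distance structure is only repaired at reinitialization,
    # so reinitialize before the front can cross half the band
    move_per_iter = dt * (fmax + params.beta * kappa_max)
    reinit_every = max(1, min(params.reinit_every,
                              int((band / 2) / max(move_per_iter, 1e-12))))
    sussman_steps = min(30, int(np.ceil(reinit_every * move_per_iter
                                        / (0.3 * h))) + 4)

    state = LevelSetState(phi=phi, spacing_mm=h, band_halfwidth_mm=band)
    pos = np.where(F_adv > 0)
    volumes = state.volumes_mm3
    track_energy = params.track_energy or params.stop_on_energy_increase
    best_energy = np.inf
    best_phi = None
    if track_energy:
        best_energy = discrete_energy(phi, M, params.alpha, params.beta, h)
        best_phi = phi.copy()
        state.energies.append(best_energy)
    for it in range(1, params.max_iters + 1):
        phi = state.phi
        gm, gp = _godunov_norms(phi, h)
        grad_upwind = gp.copy()
        grad_upwind[pos] = gm[pos]
        update = F_adv * grad_upwind
        if params.beta > 0:
            kg, _ = _curvature_times_grad(phi, h, kappa_max)
            update += params.beta * kg
        # restrict the update to a band around the interface; the far field
        # is refreshed by reinitialization
        in_band = np.abs(phi) < band
        phi = phi + dt * np.where(in_band, update, 0.0)
        if it % reinit_every == 0:
            phi = _sussman_reinit(phi, h, steps=sussman_steps)
        np.clip(phi, -(band + 4 * h), band + 4 * h, out=phi)
        state.phi = phi
        state.iteration = it

        vol = float(np.count_nonzero(phi < 0)) * h ** 3
        volumes.append(vol)
        state.last_volume_mm3 = vol
        if vol == 0.0:
            raise DentamorphError(
                f"surface collapsed to empty at iteration {it}; "
                f"try a smaller beta (current beta={params.beta})")
        w = params.converge_window
        if track_energy and it % w == 0:
            energy = discrete_energy(phi, M, params.alpha, params.beta, h)
            state.energies.append(energy)
            if params.stop_on_energy_increase:
                # pure-descent stopping on the surface energy: an increase
                # means the front overstepped the variational minimum
                if energy >= best_energy - 1e-12:
                    state.phi = best_phi
                    state.converged = True
                    break
                best_energy = energy
                best_phi = phi.copy()
        if len(volumes) > w:
            rel = abs(volumes[-1] - volumes[-1 - w]) / max(volumes[-1 - w], 1e-12)
            if rel < params.converge_tol:
                state.converged = True
                break
    else:
        log.info("evolve_surface reached max_iters=%d without meeting the "
                 "volume-change tolerance", params.max_iters)

    out = BinaryMask(data=(state.phi < 0).astype(np.uint8),
                     spacing_mm=h, origin_mm=Mup.origin_mm, axes=Mup.axes)
    if return_state:
        return out, state
    return out


# ---------------------------------------------------------------------------
# composed fine-scale segmentation
# ---------------------------------------------------------------------------

def fine_scale_segment(image: ScalarVolume, M: ProbabilityMap, cfg: RunConfig,
                       roi_threshold: float = 0.1, margin_mm: float = 2.0,
                       params: EvolveParams | None = None) -> BinaryMask:
    """Full refinement: crop ROI, upsample probability map and image by
    cfg.upsample_factor, threshold at cfg.eta, evolve the surface.

    The output mask is on the fine grid with world coordinates preserved.
    Errors from individual stages are re-raised labelled with the stage.
    """
    require_same_grid(image, M, "image and probability map")
    if params is None:
        params = EvolveParams.from_config(cfg)
    try:
        sl = roi_slices(M, roi_threshold, margin_mm)
        M_roi = crop_roi(M, roi_threshold, margin_mm)
        img_roi = crop_like(image, sl)
    except DentamorphError as e:
        raise StageError("crop_roi", e) from e
    try:
        Mup = upsample_probability(M_roi, cfg.upsample_factor)
        img_up = upsample_intensity(img_roi, cfg.upsample_factor)
    except DentamorphError as e:
        raise StageError("upsample", e) from e
    try:
        init = init_high_confidence(Mup, cfg.eta)
    except DentamorphError as e:
        raise StageError("init_high_confidence", e) from e
    try:
        return evolve_surface(Mup, img_up, init, params)
    except DentamorphError as e:
        raise StageError("evolve_surface", e) from e
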
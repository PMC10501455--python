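"""From a fine-scale mask to the 2D inferior silhouette.

The dentations sit on the inferior surface of the hippocampus as ridges
roughly parallel to the left-right axis.  Viewed from the side, the
inferior boundary of the shape is a function y(x) along the long
(anterior-posterior) axis with a sinusoidal appearance.  This module
builds that function: the mask interior is represented as a uniform
point cloud (rejection sampling), a PCA frame identifies the long axis
(first eigenvector) and the sheet normal (third eigenvector), points are
projected onto the plane spanned by the first and third eigenvectors,
and the inferior boundary is read off as a binned lower envelope.

Height convention: the third principal axis is stored pointing toward
the anatomical *inferior* side (``e3 . inferior_hint > 0``); silhouette
heights are measured along the opposite (superior-pointing) direction,
so the most inferior point of a bin is the bin's *minimum* height and a
flat inferior face gives a constant silhouette.  Amplitude and frequency
of a fitted sinusoid are unaffected by this sign choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateShapeError, ParameterError
from .volume import BinaryMask

log = logging.getLogger("dentamorph")


@dataclass
class PointCloud3D:
    """Uniformly sampled interior points of a shape, in world mm."""

    points: np.ndarray
    source_mask_id: str = ""
    seed: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("points must be an N x 3 array")
        if len(self.points) < 1:
            raise ParameterError("point cloud is empty")


@dataclass
class PCAFrame:
    """Principal-axis frame of a point cloud.

    e1 is the long (anterior-posterior) axis, e3 the sheet normal
    oriented toward the inferior side, e2 = e3 x e1 (right-handed).
    """

    mean_mm: np.ndarray
    eigvecs: np.ndarray  # rows e1, e2, e3
    eigvals: np.ndarray  # descending

    @property
    def e1(self) -> np.ndarray:
        return self.eigvecs[0]

    @property
    def e2(self) -> np.ndarray:
        return self.eigvecs[1]

    @property
    def e3(self) -> np.ndarray:
        return self.eigvecs[2]


@dataclass
class Silhouette2D:
    """Binned inferior boundary: height y (superior-positive, mm) at
    sorted positions x along the long axis."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    bin_width_mm: float
    n_raw_points: int
    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if self.x_mm.shape != self.y_mm.shape or self.x_mm.ndim != 1:
            raise ParameterError("x_mm and y_mm must be matching 1D arrays")
        if len(self.x_mm) < 10:
            raise ParameterError(
                f"silhouette has {len(self.x_mm)} samples; at least 10 required")
        if not np.all(np.diff(self.x_mm) > 0):
            raise ParameterError("x_mm must be strictly increasing")
        if not (np.all(np.isfinite(self.x_mm)) and np.all(np.isfinite(self.y_mm))):
            raise ParameterError("silhouette contains non-finite values")


# ---------------------------------------------------------------------------
# point cloud extraction
# ---------------------------------------------------------------------------

def sample_point_cloud(mask: BinaryMask, n: int, seed: int,
                       source_mask_id: str = "") -> PointCloud3D:
    """Draw n points uniformly from the mask foreground by rejection
    sampling against its bounding box.  Deterministic given the seed."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    fg = mask.data.astype(bool)
    idx = np.argwhere(fg)
    if idx.size == 0:
        raise ParameterError("mask has no foreground voxels")
    h = mask.spacing_mm
    lo_i, hi_i = idx.min(axis=0), idx.max(axis=0)
    # voxel i spans [origin + (i - 1/2) h, origin + (i + 1/2) h)
    lo = mask.origin_mm + (lo_i - 0.5) * h
    hi = mask.origin_mm + (hi_i + 0.5) * h
    bbox_vol = float(np.prod(hi - lo))
    fg_vol = float(fg.sum()) * h ** 3
    if fg_vol / bbox_vol < 1e-6:
        raise ParameterError(
            "foreground occupies < 1e-6 of its bounding box; rejection "
            "sampling would be impractical - use voxel_center_cloud instead")
    rng = np.random.default_rng(seed)
    accept_rate = max(fg_vol / bbox_vol, 1e-3)
    out = []
    remaining = n
    while remaining > 0:
        batch = int(remaining / accept_rate * 1.2) + 256
        cand = rng.uniform(lo, hi, size=(batch, 3))
        iv = np.rint((cand - mask.origin_mm) / h).astype(int)
        ok = np.all((iv >= 0) & (iv < np.array(mask.shape)), axis=1)
        ok[ok] = fg[tuple(iv[ok].T)]
        keep = cand[ok]
        out.append(keep[:remaining])
        remaining -= len(out[-1])
    return PointCloud3D(points=np.vstack(out), source_mask_id=source_mask_id,
                        seed=seed)


def voxel_center_cloud(mask: BinaryMask, source_mask_id: str = "") -> PointCloud3D:
    """Deterministic alternative to sampling: all foreground voxel centres."""
    idx = np.argwhere(mask.data.astype(bool))
    if idx.size == 0:
        raise ParameterError("mask has no foreground voxels")
    pts = mask.origin_mm + idx * mask.spacing_mm
    return PointCloud3D(points=pts, source_mask_id=source_mask_id, seed=-1)


# ---------------------------------------------------------------------------
# PCA frame and projection
# ---------------------------------------------------------------------------

def pca_frame(cloud: PointCloud3D, inferior_hint,
              anterior_hint=None) -> PCAFrame:
    """Principal axes of the point cloud with anatomically fixed signs.

    e3 (smallest variance) is flipped so ``e3 . inferior_hint > 0``;
    e1 is flipped toward ``anterior_hint`` when given (otherwise a
    deterministic sign rule is applied); e2 = e3 x e1.
    """
    pts = cloud.points
    if len(pts) < 4:
        raise DegenerateShapeError("need at least 4 points for a PCA frame")
    inferior_hint = np.asarray(inferior_hint, dtype=float)
    if not np.linalg.norm(inferior_hint) > 0:
        raise ParameterError("inferior_hint must be a non-zero vector")
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    if vals[0] <= 0 or vals[2] / vals[0] < 1e-10:
        raise DegenerateShapeError(
            f"point cloud is (near-)coplanar: eigenvalues {vals}")
    if (vals[0] - vals[2]) / vals[0] < 0.05:
        log.warning("pca_frame: near-isotropic eigenvalue spread %s; "
                    "principal directions are poorly determined", vals)
    e1, e3 = vecs[:, 0], vecs[:, 2]
    if e3 @ inferior_hint < 0:
        e3 = -e3
    if anterior_hint is not None:
        anterior_hint = np.asarray(anterior_hint, dtype=float)
        if e1 @ anterior_hint < 0:
            e1 = -e1
    elif e1[np.argmax(np.abs(e1))] < 0:
        e1 = -e1
    e2 = np.cross(e3, e1)
    return PCAFrame(mean_mm=mean, eigvecs=np.vstack([e1, e2, e3]),
                    eigvals=vals)


def project_to_plane(cloud: PointCloud3D, frame: PCAFrame) -> np.ndarray:
    """Project points onto the (e1, e3) plane: each point x maps to
    ``((x - mean) . e1, (x - mean) . e3)``; the e2 component is dropped."""
    centered = cloud.points - frame.mean_mm
    return np.column_stack([centered @ frame.e1, centered @ frame.e3])


# ---------------------------------------------------------------------------
# silhouette extraction
# ---------------------------------------------------------------------------

def inferior_silhouette(points2d: np.ndarray, bin_width_mm: float,
                        trim_fraction: float, min_per_bin: int = 5,
                        stat: str = "min") -> Silhouette2D:
    """Binned lower envelope of the projected points.

    The e1 axis is partitioned into bins of ``bin_width_mm`` after
    removing the first and last ``trim_fraction`` of the x-range (the
    curved head and tail of a real hippocampus).  Per bin the most
    inferior point is kept - the minimum of the superior-pointing height
    ``-v`` (see the module docstring for the sign convention).  Bins with
    fewer than ``min_per_bin`` points are dropped.  ``stat='p5'``
    substitutes the 5th percentile for the minimum, a robust variant for
    noisy masks.
    """
    if not bin_width_mm > 0:
        raise ParameterError("bin_width_mm must be positive")
    if not 0 <= trim_fraction < 0.5:
        raise ParameterError("trim_fraction must lie in [0, 0.5)")
    if stat not in ("min", "p5"):
        raise ParameterError("stat must be 'min' or 'p5'")
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points2d must be an N x 2 array")
    u = pts[:, 0]
    height = -pts[:, 1]  # superior-positive height
    lo, hi = u.min(), u.max()
    span = hi - lo
    a = lo + trim_fraction * span
    b = hi - trim_fraction * span
    n_bins = int(np.floor((b - a) / bin_width_mm))
    if n_bins < 10:
        raise ParameterError(
            f"only {n_bins} bins of width {bin_width_mm} mm fit in the "
            f"trimmed range [{a:.3g}, {b:.3g}] mm ({len(pts)} points); "
            f"reduce bin_width_mm or trim_fraction")
    sel = (u >= a) & (u < a + n_bins * bin_width_mm)
    ui, hi_ = u[sel], height[sel]
    which = np.floor((ui - a) / bin_width_mm).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    if stat == "min":
        env = np.full(n_bins, np.inf)
        np.minimum.at(env, which, hi_)
    else:
        env = np.full(n_bins, np.inf)
        order = np.argsort(which, kind="stable")
        wsort, hsort = which[order], hi_[order]
        starts = np.searchsorted(wsort, np.arange(n_bins))
        ends = np.searchsorted(wsort, np.arange(n_bins) + 1)
        for k in range(n_bins):
            if ends[k] > starts[k]:
                env[k] = np.percentile(hsort[starts[k]:ends[k]], 5)
    keep = counts >= min_per_bin
    if keep.sum() < 10:
        raise ParameterError(
            f"only {int(keep.sum())} bins of width {bin_width_mm} mm hold "
            f">= {min_per_bin} points ({len(pts)} points total)")
    centers = a + (np.arange(n_bins) + 0.5) * bin_width_mm
    return Silhouette2D(x_mm=centers[keep], y_mm=env[keep],
                        bin_width_mm=bin_width_mm,
                        n_raw_points=int(len(pts)), counts=counts[keep])


def silhouette_from_mask(mask: BinaryMask, n_points: int, seed: int,
                         bin_width_mm: float, trim_fraction: float,
                         inferior_hint=None, deterministic: bool = False,
                         stat: str = "min") -> Silhouette2D:
    """Convenience composition mask -> cloud -> PCA -> projection ->
    silhouette.  ``inferior_hint`` defaults to the mask's own anatomical
    inferior direction; ``deterministic=True`` uses all voxel centres
    instead of rejection sampling."""
    if inferior_hint is None:
        inferior_hint = mask.direction_vector("inferior")
    anterior_hint = None
    try:
        anterior_hint = mask.direction_vector("anterior")
    except Exception:
        pass
    if deterministic:
        cloud = voxel_center_cloud(mask)
    else:
        cloud = sample_point_cloud(mask, n_points, seed)
    frame = pca_frame(cloud, inferior_hint, anterior_hint)
    pts2d = project_to_plane(cloud, frame)
    return inferior_silhouette(pts2d, bin_width_mm, trim_fraction, stat=stat)
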
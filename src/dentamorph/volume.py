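"""Volume containers and NIfTI I/O.

The toolkit works on 3D scalar grids with *isotropic* spacing.  World
coordinates are defined as ``world_mm = origin_mm + index * spacing_mm``
per grid axis (0-based indices, axis-aligned grids); every geometric
operation downstream works in world millimetres, never in raw indices,
because the pipeline changes spacing (native ~1 mm to fine 0.2 mm).

Anatomical orientation is carried as a tuple of axis codes in the
nibabel convention: each grid axis is labelled with the anatomical
direction of *increasing* index, one of ``R/L`` (left-right), ``A/P``
(anterior-posterior), ``S/I`` (superior-inferior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError, ParameterError

log = logging.getLogger("dentamorph")

# axis code -> (RAS axis, sign of increasing index)
_CODE_TO_RAS = {
    "R": (0, +1), "L": (0, -1),
    "A": (1, +1), "P": (1, -1),
    "S": (2, +1), "I": (2, -1),
}

# anatomical direction name -> (RAS axis, sign)
_DIRECTION_TO_RAS = {
    "right": (0, +1), "left": (0, -1),
    "anterior": (1, +1), "posterior": (1, -1),
    "superior": (2, +1), "inferior": (2, -1),
}

# slice-plane name -> RAS axis the plane is perpendicular to
_PLANE_TO_RAS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class ScalarVolume:
    """A 3D scalar grid with isotropic spacing and anatomical axis labels."""

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {self.data.ndim}D")
        self.spacing_mm = float(self.spacing_mm)
        if not self.spacing_mm > 0:
            raise ParameterError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume data must be finite everywhere")
        self.axes = tuple(self.axes)
        ras = sorted(_CODE_TO_RAS[c][0] for c in self.axes)
        if ras != [0, 1, 2]:
            raise ParameterError(
                f"axes {self.axes} must name three distinct anatomical directions")
        self._check_values()

    def _check_values(self):  # overridden by subclasses
        pass

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_from_index(self, idx) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def index_from_world(self, world) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin_mm) / self.spacing_mm

    def direction_vector(self, name: str) -> np.ndarray:
        """Unit vector (in grid/world axes) pointing toward an anatomical
        direction, e.g. ``direction_vector("inferior")``."""
        try:
            ras_axis, want_sign = _DIRECTION_TO_RAS[name.lower()]
        except KeyError:
            raise ParameterError(f"unknown anatomical direction {name!r}") from None
        v = np.zeros(3)
        for grid_axis, code in enumerate(self.axes):
            axis, sign = _CODE_TO_RAS[code]
            if axis == ras_axis:
                v[grid_axis] = sign * want_sign
                return v
        raise ParameterError(f"axes {self.axes} do not cover direction {name!r}")

    def plane_axis(self, plane: str) -> int:
        """Grid axis perpendicular to a named slice plane ('sagittal', ...)."""
        try:
            ras_axis = _PLANE_TO_RAS[plane.lower()]
        except KeyError:
            raise ParameterError(f"unknown slice plane {plane!r}") from None
        for grid_axis, code in enumerate(self.axes):
            if _CODE_TO_RAS[code][0] == ras_axis:
                return grid_axis
        raise ParameterError(f"axes {self.axes} do not cover plane {plane!r}")


@dataclass
class ProbabilityMap(ScalarVolume):
    """A ScalarVolume with values in [0, 1]."""

    def _check_values(self):
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ParameterError(
                f"probability map values must lie in [0, 1], got [{lo}, {hi}]")
        # tolerate tiny numerical excursions from interpolation
        if lo < 0 or hi > 1:
            self.data = np.clip(self.data, 0.0, 1.0)


@dataclass
class BinaryMask(ScalarVolume):
    """A ScalarVolume with values in {0, 1}."""

    def _check_values(self):
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError(
                f"binary mask values must be exactly 0 or 1, got {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


def grids_match(a: ScalarVolume, b: ScalarVolume, atol: float = 1e-6) -> bool:
    return (a.shape == b.shape
            and abs(a.spacing_mm - b.spacing_mm) <= atol
            and np.allclose(a.origin_mm, b.origin_mm, atol=atol))


def require_same_grid(a: ScalarVolume, b: ScalarVolume, what: str = "volumes"):
    if not grids_match(a, b):
        raise GeometryError(
            f"{what} must share one grid: shapes {a.shape}/{b.shape}, "
            f"spacings {a.spacing_mm}/{b.spacing_mm}, "
            f"origins {a.origin_mm}/{b.origin_mm}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_KIND_TO_CLASS = {"intensity": ScalarVolume, "probability": ProbabilityMap,
                  "mask": BinaryMask}


def read_volume(path, kind: str = "intensity", axes=None) -> ScalarVolume:
    """Read a 3D NIfTI-1 volume.

    Anisotropic inputs are resampled to isotropic spacing equal to the
    smallest header spacing (cubic interpolation for intensities and
    probabilities, nearest-neighbour for masks); the resampling is logged.

    Parameters
    ----------
    path : file path to a ``.nii`` / ``.nii.gz`` file.
    kind : 'intensity', 'probability' or 'mask'; selects the returned class
        and the resampling interpolation order.
    axes : optional explicit axis-code triple overriding the header
        orientation (needed for synthetic volumes without anatomical
        headers).
    """
    path = Path(path)
    if kind not in _KIND_TO_CLASS:
        raise ParameterError(f"kind must be one of {sorted(_KIND_TO_CLASS)}")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several types
        raise FormatError(f"cannot read {path} as NIfTI: {e}") from e
    if len(img.shape) != 3:
        raise FormatError(
            f"{path} is {len(img.shape)}D; only 3D scalar volumes are supported")
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if axes is None:
        try:
            axes = nib.aff2axcodes(img.affine)
        except Exception as e:
            raise FormatError(
                f"cannot determine orientation of {path}; pass axes explicitly "
                f"(e.g. axes=('R','A','S')): {e}") from e
        if any(a not in _CODE_TO_RAS for a in axes):
            raise FormatError(
                f"unreadable orientation {axes} in {path}; pass axes explicitly")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    rot = img.affine[:3, :3]
    if not np.allclose(np.abs(rot), np.diag(np.abs(np.diag(rot))), atol=1e-3 * zooms.max()):
        log.warning("%s has an oblique affine; treating the grid as axis-aligned", path)

    spacing = float(zooms.min())
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        order = 0 if kind == "mask" else 3
        factors = zooms / spacing
        data = ndimage.zoom(data, factors, order=order, mode="nearest",
                            grid_mode=False)
        log.info("resampled %s from spacing %s to isotropic %.6g mm (order %d)",
                 path, tuple(zooms), spacing, order)
    if kind == "probability":
        data = np.clip(data, 0.0, 1.0)
    if kind == "mask":
        data = (data > 0.5).astype(np.uint8)
    return _KIND_TO_CLASS[kind](data=data, spacing_mm=spacing,
                                origin_mm=origin, axes=tuple(axes))


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume as NIfTI-1, preserving spacing, origin and axis codes.

    Masks are stored as uint8 and round-trip bit-identically; real-valued
    volumes are stored as float64 and round-trip to well below 1e-6.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for grid_axis, code in enumerate(vol.axes):
        ras_axis, sign = _CODE_TO_RAS[code]
        affine[ras_axis, grid_axis] = sign * vol.spacing_mm
    affine[:3, 3] = vol.origin_mm
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vol.spacing_mm,) * 3)
    try:
        nib.save(img, str(path))
    except Exception as e:
        raise IOError(f"cannot write {path}: {e}") from e


# ---------------------------------------------------------------------------
# Resampling helpers shared by several modules
# ---------------------------------------------------------------------------

def _pad_linear(data: np.ndarray, pad: int) -> np.ndarray:
    """Pad by linear extrapolation along every axis.

    Cubic-spline interpolation reproduces smooth trends near the grid
    boundary only if the implicit extension continues the trend; mirror or
    nearest extensions would bend a linear ramp at the edge.
    """
    out = data.astype(float)
    for ax in range(out.ndim):
        first = np.take(out, [0], axis=ax)
        second = np.take(out, [1], axis=ax)
        last = np.take(out, [-1], axis=ax)
        penult = np.take(out, [-2], axis=ax)
        lo = [first + (first - second) * (k + 1) for k in range(pad)][::-1]
        hi = [last + (last - penult) * (k + 1) for k in range(pad)]
        out = np.concatenate(lo + [out] + hi, axis=ax)
    return out


def spline_upsample(data: np.ndarray, factor: int) -> np.ndarray:
    """Cubic-spline upsampling with align-corners node placement.

    The fine grid places ``factor`` nodes per coarse cell and keeps the
    coarse nodes as exact sample points: output length ``(n-1)*factor + 1``
    per axis.  Linear trends are reproduced exactly everywhere (linear
    extrapolation padding keeps the spline straight at the edges).
    """
    if factor < 1:
        raise ParameterError(f"upsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return data.astype(float).copy()
    pad = 8
    padded = _pad_linear(data, pad)
    coords = [np.linspace(0, n - 1, (n - 1) * factor + 1) + pad
              for n in data.shape]
    grids = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(padded, np.array(grids), order=3,
                                   mode="nearest")


def box_downsample(vol: ScalarVolume, coarse_spacing_mm: float) -> ScalarVolume:
    """Box-average a volume onto a coarser grid (partial-volume model).

    Each coarse sample is the mean of the fine volume over a cube of the
    coarse spacing centred on the coarse voxel centre; coarse voxel centres
    are laid out to cover the same physical extent.
    """
    if coarse_spacing_mm < vol.spacing_mm - 1e-12:
        raise ParameterError(
            f"coarse spacing {coarse_spacing_mm} mm is finer than the input "
            f"spacing {vol.spacing_mm} mm")
    if abs(coarse_spacing_mm - vol.spacing_mm) < 1e-12:
        return replace(vol, data=vol.data.astype(float).copy())
    ratio = coarse_spacing_mm / vol.spacing_mm
    size = max(int(round(ratio)), 1)
    smoothed = ndimage.uniform_filter(vol.data.astype(float), size=size,
                                      mode="nearest")
    n_coarse = [max(int(np.floor(n * vol.spacing_mm / coarse_spacing_mm)), 1)
                for n in vol.shape]
    # centre the coarse grid on the fine grid's physical extent
    coords = []
    origin = np.empty(3)
    for ax, (n_f, n_c) in enumerate(zip(vol.shape, n_coarse)):
        extent = n_f * vol.spacing_mm
        pad_mm = (extent - n_c * coarse_spacing_mm) / 2
        centers = pad_mm + (np.arange(n_c) + 0.5) * coarse_spacing_mm
        # world position of the fine voxel centre i is origin + i*spacing;
        # fine extent starts half a voxel before the first centre
        start_mm = vol.origin_mm[ax] - vol.spacing_mm / 2
        origin[ax] = start_mm + centers[0]
        coords.append((start_mm + centers - vol.origin_mm[ax]) / vol.spacing_mm)
    grids = np.meshgrid(*coords, indexing="ij")
    data = ndimage.map_coordinates(smoothed, np.array(grids), order=1,
                                   mode="nearest")
    return ScalarVolume(data=data, spacing_mm=coarse_spacing_mm,
                        origin_mm=origin, axes=vol.axes)
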
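"""qHCR voxel quantitation.

Relative quantitation rests on HCR signal scaling approximately linearly
with target abundance: when one target is detected redundantly in two
spectrally distinct channels, a scatter plot of normalized subcellular
voxel intensities should form a tight line through the origin.  Accuracy
is read off the fit (linearity, zero intercept), precision off the
orthogonal scatter around the line.

The line is fitted by total least squares (orthogonal regression), since
both channels carry comparable noise under redundant detection; ordinary
least squares is available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely

_REL_TOL = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Subcellular voxel intensities with the pixel-space bookkeeping
    needed to map voxels back onto the image."""

    values: np.ndarray                 # (n_vr, n_vc), nonnegative
    voxel_size_um: tuple[float, float]
    pixel_size_um: float
    origin_pixel: tuple[int, int]      # pixel coords of voxel (0, 0)
    pixels_per_voxel: tuple[int, int]
    image_shape: tuple[int, int]
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"voxel values must be 2D, got shape {v.shape}")
        if any(p < 1 for p in self.pixels_per_voxel):
            raise ValueError(f"pixels_per_voxel must be >= 1, got {self.pixels_per_voxel}")
        object.__setattr__(self, "values", v)

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def footprint(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Pixel-space boolean mask of the (optionally masked) voxels."""
        pr, pc = self.pixels_per_voxel
        sel = np.ones(self.values.shape, bool) if mask is None else np.asarray(mask, bool)
        pix = np.zeros(self.image_shape, bool)
        block = np.kron(sel, np.ones((pr, pc), bool))
        r0, c0 = self.origin_pixel
        pix[r0:r0 + block.shape[0], c0:c0 + block.shape[1]] = block
        return pix


@dataclass(frozen=True)
class ScatterResult:
    """Accuracy/precision readout of a two-channel voxel comparison."""

    slope: float
    intercept: float
    pearson_r: float
    orth_rms: float
    n_voxels: int
    mask_fraction: float
    method: str = "tls"

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "pearson_r": self.pearson_r, "orth_rms": self.orth_rms,
                "n_voxels": self.n_voxels, "mask_fraction": self.mask_fraction,
                "method": self.method}


def snap_voxel_size(pixel_size: float, requested: float) -> float:
    """Largest pixel-commensurate voxel size <= the requested size.

    A 2 µm voxel request on 0.16 µm pixels is not an integer block; this
    convention realizes 1.92 µm (12x12 pixels).  At least one pixel.
    """
    n = max(1, int(math.floor(requested / pixel_size + _REL_TOL)))
    return n * pixel_size


def bin_voxels(image: np.ndarray, pixel_size: float,
               voxel_size: float | tuple[float, float],
               aggregator: str = "mean",
               origin_pixel: tuple[int, int] = (0, 0)) -> VoxelGrid:
    """Aggregate non-overlapping pixel blocks into subcellular voxels.

    ``voxel_size`` must be an integer multiple of ``pixel_size`` in each
    dimension (to within 1e-6 relative); trailing partial blocks are
    discarded.  Use :func:`snap_voxel_size` to round a non-commensurate
    request down first.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"image must be 2D, got shape {image.shape}")
    if aggregator not in ("mean", "sum"):
        raise ValueError(f"aggregator must be 'mean' or 'sum', got {aggregator!r}")
    vsz = (voxel_size, voxel_size) if np.isscalar(voxel_size) else tuple(voxel_size)
    ppv = []
    for v in vsz:
        ratio = v / pixel_size
        n = round(ratio)
        if n < 1 or abs(ratio - n) > _REL_TOL * ratio:
            raise ValueError(
                f"voxel size {v} µm is not an integer multiple of pixel size "
                f"{pixel_size} µm ({ratio:.6g} pixels/voxel); "
                "use snap_voxel_size() to choose a commensurate size")
        ppv.append(int(n))
    pr, pc = ppv
    r0, c0 = origin_pixel
    sub = image[r0:, c0:]
    n_vr, n_vc = sub.shape[0] // pr, sub.shape[1] // pc
    if n_vr < 1 or n_vc < 1:
        raise ValueError(
            f"image of shape {image.shape} holds no complete {pr}x{pc}-pixel voxel")
    blocks = sub[:n_vr * pr, :n_vc * pc].reshape(n_vr, pr, n_vc, pc)
    values = blocks.mean(axis=(1, 3)) if aggregator == "mean" else blocks.sum(axis=(1, 3))
    return VoxelGrid(values=values,
                     voxel_size_um=(pr * pixel_size, pc * pixel_size),
                     pixel_size_um=pixel_size, origin_pixel=(r0, c0),
                     pixels_per_voxel=(pr, pc), image_shape=image.shape)


def normalize_voxels(grid: VoxelGrid, background_level: float = 0.0,
                     dark_offset: float = 0.0,
                     percentile: float = 0.995) -> VoxelGrid:
    """Map voxel intensities onto [0, 1].

    Subtracts the instrument dark offset and the background level, clips at
    zero, then divides by the given upper quantile of the remaining values
    (0.995 by default, to resist single-voxel outliers); values above 1 are
    clipped.
    """
    if grid.normalized:
        raise ValueError("grid is already normalized")
    if not 0.0 < percentile <= 1.0:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    v = np.clip(grid.values - dark_offset - background_level, 0.0, None)
    scale = float(np.quantile(v, percentile))
    if scale <= 0.0:
        raise ValueError(
            "normalization scale is zero: no voxel intensity remains above "
            "dark offset + background")
    with np.errstate(over="ignore"):  # subnormal scales clip to 1 anyway
        scaled = np.clip(v / scale, 0.0, 1.0)
    return replace(grid, values=scaled, normalized=True)


def expressing_mask(grids: Sequence[VoxelGrid] | VoxelGrid,
                    background_mean: float | Sequence[float],
                    background_sd: float | Sequence[float],
                    k: float = 2.0) -> np.ndarray:
    """Voxels whose raw intensity exceeds background mean + k·SD in at
    least one channel.

    Keeps empty extracellular voxels from dominating the correlation.
    Background statistics are scalars shared across channels or one value
    per channel.
    """
    if isinstance(grids, VoxelGrid):
        grids = [grids]
    shapes = {g.values.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"voxel grids have differing shapes: {sorted(shapes)}")
    n = len(grids)
    means = np.broadcast_to(np.asarray(background_mean, float), (n,))
    sds = np.broadcast_to(np.asarray(background_sd, float), (n,))
    mask = np.zeros(grids[0].values.shape, bool)
    for g, m, s in zip(grids, means, sds):
        mask |= g.values > m + k * s
    return mask


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Orthogonal-regression line through a point cloud.

    Returns (slope, intercept, orth_rms).  The line direction is the
    leading eigenvector of the 2x2 covariance; the perpendicular RMS is the
    square root of the trailing eigenvalue (population normalisation).
    """
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    cov = np.array([[dx @ dx, dx @ dy], [dx @ dy, dy @ dy]]) / x.size
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, 1]
    if v[0] == 0.0:
        raise ValueError("orthogonal fit is vertical; slope undefined")
    slope = v[1] / v[0]
    return slope, ym - slope * xm, float(np.sqrt(max(evals[0], 0.0)))


def fit_scatter(ch1: VoxelGrid, ch2: VoxelGrid,
                mask: np.ndarray | None = None,
                method: str = "tls") -> ScatterResult:
    """Fit the two-channel voxel scatter and summarise accuracy/precision.

    Requires both grids normalized and of equal shape, and at least two
    masked voxels with nonzero variance in each channel.  ``method`` is
    ``'tls'`` (orthogonal regression, default) or ``'ols'``.
    """
    if not (ch1.normalized and ch2.normalized):
        raise ValueError("fit_scatter expects normalized voxel grids")
    if ch1.values.shape != ch2.values.shape:
        raise ValueError(
            f"grid shapes differ: {ch1.values.shape} vs {ch2.values.shape}")
    if method not in ("tls", "ols"):
        raise ValueError(f"method must be 'tls' or 'ols', got {method!r}")
    sel = np.ones(ch1.values.shape, bool) if mask is None else np.asarray(mask, bool)
    if sel.shape != ch1.values.shape:
        raise ValueError("mask shape does not match the voxel grids")
    x = ch1.values[sel].ravel()
    y = ch2.values[sel].ravel()
    if x.size < 2:
        raise ValueError(f"need >= 2 masked voxels, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in a channel; correlation undefined")
    if method == "tls":
        slope, intercept, orth_rms = _tls_line(x, y)
    else:
        slope = float(np.cov(x, y, ddof=0)[0, 1] / np.var(x))
        intercept = float(y.mean() - slope * x.mean())
        d = np.abs(slope * x - y + intercept) / math.hypot(slope, 1.0)
        orth_rms = float(np.sqrt(np.mean(d**2)))
    r = float(np.corrcoef(x, y)[0, 1])
    return ScatterResult(slope=float(slope), intercept=float(intercept),
                         pearson_r=r, orth_rms=float(orth_rms),
                         n_voxels=int(x.size),
                         mask_fraction=float(x.size / ch1.values.size),
                         method=method)


def _region_voxel_mask(region: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Voxels whose pixel footprint intersects the pixel-space region."""
    region = np.asarray(region, bool)
    if region.shape != grid.image_shape:
        raise ValueError(
            f"region shape {region.shape} != image shape {grid.image_shape}")
    pr, pc = grid.pixels_per_voxel
    r0, c0 = grid.origin_pixel
    n_vr, n_vc = grid.values.shape
    sub = region[r0:r0 + n_vr * pr, c0:c0 + n_vc * pc]
    return sub.reshape(n_vr, pr, n_vc, pc).any(axis=(1, 3))


def read_out(region: np.ndarray, ch1: VoxelGrid,
             ch2: VoxelGrid) -> np.ndarray:
    """Anatomical space -> expression space.

    Returns the (n, 2) array of normalized intensity pairs for every voxel
    whose pixel footprint intersects the region; empty region gives an
    empty array.
    """
    if ch1.values.shape != ch2.values.shape:
        raise ValueError("channel grids have differing shapes")
    sel = _region_voxel_mask(region, ch1)
    return np.column_stack([ch1.values[sel], ch2.values[sel]])


def read_in(gate: Sequence[tuple[float, float]], ch1: VoxelGrid,
            ch2: VoxelGrid, mask: np.ndarray | None = None) -> np.ndarray:
    """Expression space -> anatomical space.

    ``gate`` is a simple polygon in the normalized (x1, x2) plane; the
    returned pixel mask marks the footprint of every (masked) voxel whose
    intensity pair lies inside or on the gate boundary.  Self-intersecting
    polygons are rejected.
    """
    if ch1.values.shape != ch2.values.shape:
        raise ValueError("channel grids have differing shapes")
    poly = shapely.Polygon(gate)
    if not poly.is_valid:
        raise ValueError("gate polygon is not simple (self-intersecting)")
    sel = np.ones(ch1.values.shape, bool) if mask is None else np.asarray(mask, bool)
    pts = shapely.points(ch1.values[sel].ravel(), ch2.values[sel].ravel())
    inside = shapely.covers(poly, pts)
    voxel_mask = np.zeros(ch1.values.shape, bool)
    voxel_mask[sel] = inside
    return ch1.footprint(voxel_mask)


__all__ = [
    "VoxelGrid", "ScatterResult", "snap_voxel_size", "bin_voxels",
    "normalize_voxels", "expressing_mask", "fit_scatter", "read_out",
    "read_in",
]
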
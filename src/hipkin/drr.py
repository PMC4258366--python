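"""Digitally reconstructed radiograph (DRR) rendering by ray casting.

A DRR pixel is the line integral of the (trilinearly interpolated) bone
density along the ray from the X-ray point source to that pixel center, in
density*mm units.  Working in the log domain rather than with exponential
attenuation keeps pixel values linear in density; the correlation metric
used for registration is invariant to monotone intensity maps, so nothing
downstream depends on that choice.

Rays are clipped to the volume's interpolation support before sampling and
pixels whose rays miss the projected volume bounding box are skipped, so
rendering cost scales with the bone's footprint on the panel rather than
with the full panel.  Coarse passes decimate the pixel grid (``downsample``)
instead of the volume, which keeps the projection geometry exact across
resolutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConstantImageError, NonProjectablePointError, ParameterError
from .geometry import Pose, ProjectionGeometry, project
from .volume_io import DensityVolume


@dataclass
class DRRImage:
    """Rendered projection: ``pixels[row, col]`` with row along v, col along u."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    geometry: ProjectionGeometry
    pose: Pose
    downsample: int = 1
    step: float | None = None


def default_step(v: DensityVolume) -> float:
    """Half the smallest voxel spacing — Nyquist-safe for trilinear fields."""
    return float(v.spacing.min()) / 2.0


def _pixel_roi(
    v: DensityVolume, p: Pose, g: ProjectionGeometry, downsample: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Decimated pixel index ranges covering the projected volume box.

    Returns (u_indices, v_indices) on the fine pixel grid, or None when the
    volume projects nowhere onto the panel.
    """
    nv, nu = g.grid_shape
    us_full = np.arange(0, nu, downsample)
    vs_full = np.arange(0, nv, downsample)
    lo, hi = v.bounds()
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
         for z in (lo[2], hi[2])]
    )
    try:
        uv = project(g, p.apply(corners))
    except NonProjectablePointError:
        return us_full, vs_full  # conservative: render the whole panel
    du, dv = g.pixel_spacing
    u0 = int(np.floor(uv[:, 0].min() / du)) - downsample
    u1 = int(np.ceil(uv[:, 0].max() / du)) + downsample
    v0 = int(np.floor(uv[:, 1].min() / dv)) - downsample
    v1 = int(np.ceil(uv[:, 1].max() / dv)) + downsample
    us = us_full[(us_full >= u0) & (us_full <= u1)]
    vs = vs_full[(vs_full >= v0) & (vs_full <= v1)]
    if us.size == 0 or vs.size == 0:
        return None
    return us, vs


def render(
    v: DensityVolume,
    p: Pose,
    g: ProjectionGeometry,
    step: float | None = None,
    downsample: int = 1,
) -> DRRImage:
    """Render a DRR of volume ``v`` posed by ``p`` under geometry ``g``.

    ``step`` is the ray sampling interval in mm (default: half the smallest
    voxel spacing); ``downsample`` renders every n-th pixel in each panel
    direction.  Voxels outside the grid contribute zero; a volume that does
    not project onto the panel yields an all-zero image.
    """
    if step is None:
        step = default_step(v)
    if step <= 0:
        raise ParameterError("ray sampling step must be positive")
    if downsample < 1 or int(downsample) != downsample:
        raise ParameterError("downsample must be a positive integer")
    downsample = int(downsample)

    nv, nu = g.grid_shape
    out_shape = (len(range(0, nv, downsample)), len(range(0, nu, downsample)))
    out = np.zeros(out_shape, dtype=float)
    spacing = (g.pixel_spacing[0] * downsample, g.pixel_spacing[1] * downsample)

    roi = _pixel_roi(v, p, g, downsample)
    if roi is None or not np.any(v.data):
        return DRRImage(out, spacing, g, p, downsample, step)
    us, vs = roi

    uu, vv = np.meshgrid(us, vs)  # (nrow, ncol) fine-grid indices
    pix_world = g.pixel_center(uu.ravel(), vv.ravel())

    # Ray geometry in model coordinates (rigid, so mm distances survive).
    src_m = p.apply_inverse(g.source)[0]
    pix_m = p.apply_inverse(pix_world)
    dirs = pix_m - src_m
    lengths = np.linalg.norm(dirs, axis=1)
    dirs = dirs / lengths[:, None]

    # Slab intersection with the interpolation-support box.
    lo, hi = v.bounds()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - src_m) / dirs
        t_hi = (hi - src_m) / dirs
    t_near = np.nanmax(np.where(np.isfinite(t_lo), np.minimum(t_lo, t_hi),
                                -np.inf), axis=1)
    t_far = np.nanmin(np.where(np.isfinite(t_hi), np.maximum(t_lo, t_hi),
                               np.inf), axis=1)
    # Axis-parallel rays starting outside the slab never enter it.
    parallel_miss = np.any(
        (dirs == 0) & ((src_m < lo) | (src_m > hi)), axis=1
    )
    t_near = np.maximum(t_near, 0.0)
    hit = (t_far > t_near) & ~parallel_miss
    if not np.any(hit):
        return DRRImage(out, spacing, g, p, downsample, step)

    ray_idx = np.nonzero(hit)[0]
    t0 = t_near[hit]
    span = t_far[hit] - t0
    counts = np.maximum(np.ceil(span / step).astype(int), 1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = offsets[-1]
    sample_ray = np.repeat(np.arange(len(ray_idx)), counts)
    # distance along each ray at every sample, in one flat float32 pass
    s = np.arange(total, dtype=np.float32)
    s -= offsets[sample_ray].astype(np.float32)
    s += 0.5
    s *= np.float32(step)
    s += t0[sample_ray].astype(np.float32)
    pts = np.repeat(dirs[ray_idx].astype(np.float32), counts, axis=0)
    pts *= s[:, None]
    pts += src_m.astype(np.float32)
    pts -= v.origin.astype(np.float32)
    pts /= v.spacing.astype(np.float32)
    data = v.data if v.data.dtype in (np.float32, np.float64) else \
        np.asarray(v.data, dtype=float)
    vals = ndimage.map_coordinates(
        data, pts.T, order=1, mode="constant", cval=0.0, prefilter=False,
    )
    integrals = np.bincount(sample_ray, weights=vals,
                            minlength=len(ray_idx)) * step

    flat = np.zeros(uu.size)
    flat[ray_idx] = integrals
    # Scatter the ROI block into the decimated panel image.
    row0 = int(vs[0]) // downsample
    col0 = int(us[0]) // downsample
    block = flat.reshape(uu.shape)
    out[row0:row0 + block.shape[0], col0:col0 + block.shape[1]] = block
    return DRRImage(out, spacing, g, p, downsample, step)


def binarize(img, method="otsu") -> np.ndarray:
    """Threshold a DRR or radiograph into a boolean silhouette mask.

    ``method`` is either the string "otsu" or a fixed numeric threshold.
    Automatic thresholding of a constant image is undefined and raises
    :class:`ConstantImageError`.
    """
    pixels = img.pixels if isinstance(img, DRRImage) else np.asarray(img)
    if isinstance(method, str):
        if method != "otsu":
            raise ParameterError(f"unknown binarization method: {method!r}")
        if np.ptp(pixels) == 0:
            raise ConstantImageError("cannot auto-threshold a constant image")
        level = threshold_otsu(pixels)
    else:
        level = float(method)
    return pixels > level


# ---------------------------------------------------------------------------
# 16-bit image I/O with a linear-scaling sidecar
# ---------------------------------------------------------------------------


def save_image16(path, pixels: np.ndarray) -> None:
    """Write a float image as 16-bit TIFF/PNG plus a JSON scaling sidecar.

    Values are min-max scaled to the uint16 range; the sidecar records
    (scale, offset) so ``value = raw * scale + offset`` recovers the data.
    """
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    pixels = np.asarray(pixels, dtype=float)
    offset = float(pixels.min())
    span = float(pixels.max() - pixels.min())
    scale = span / 65535.0 if span > 0 else 1.0
    raw = np.round((pixels - offset) / scale).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), raw)
    elif path.suffix.lower() == ".png":
        iio.imwrite(str(path), raw)
    else:
        raise ParameterError(f"unsupported image format: {path.suffix}")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"scale": scale, "offset": offset}, fh)


def load_image16(path) -> np.ndarray:
    """Read a 16-bit image written by :func:`save_image16`."""
    import imageio.v3 as iio

    path = Path(path)
    raw = np.asarray(iio.imread(str(path)), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return raw * meta["scale"] + meta["offset"]
    return raw
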
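"""Image ingestion and the shared correction cascade.

All downstream quantification (FRET index maps, nuclear morphometry, gel
densitometry) consumes images through the primitives in this module:
background subtraction, illumination-gradient correction, inter-channel
registration and 3x3 smoothing, applied in that order where a cascade is
required.

Conventions
-----------
2D images are indexed (row=y, col=x), origin top-left, 0-based; stacks are
(z, y, x).  All physical quantities are in micrometres.  Every correction
emits a JSON provenance record through the ``nucleomech`` logger so a run
can be audited.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball

logger = logging.getLogger("nucleomech")


def _log(op: str, **params) -> None:
    """Append one provenance record (JSON line) to the package logger."""
    logger.info(json.dumps({"op": op, **params}, default=float))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Image2D:
    """A single-channel 2D intensity image with isotropic in-plane scale.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities.
    pixel_size : float
        Micrometres per pixel (isotropic in-plane).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D requires a 2D array, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class VoxelGrid:
    """A 3D intensity grid with physical voxel dimensions (z, y, x)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("VoxelGrid intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("VoxelGrid intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class BackgroundSpec:
    """How to estimate the background of an image.

    ``mode`` selects the estimator:

    * ``"region"`` -- mean intensity of a user-supplied cell-free rectangle
      ``(x0, y0, width, height)`` in 0-based pixel units (the default used
      for fluorescence channels).
    * ``"constant"`` -- a fixed non-negative value.
    * ``"rolling-ball"`` -- morphological rolling-ball background with the
      given radius in pixels (offered for gel images).
    """

    mode: Literal["region", "constant", "rolling-ball"] = "constant"
    region: tuple[int, int, int, int] | None = None
    value: float | None = None
    radius: float | None = None

    def resolve(self, img: Image2D) -> tuple[np.ndarray | float, dict]:
        """Resolve this spec against an image to a scalar or a smooth field."""
        if self.mode == "constant":
            if self.value is None or self.value < 0:
                raise ValueError("constant background requires a non-negative value")
            return float(self.value), {"mode": "constant", "value": float(self.value)}
        if self.mode == "region":
            if self.region is None:
                raise ValueError("region background requires a rectangle")
            x0, y0, w, h = self.region
            H, W = img.shape
            if w <= 0 or h <= 0:
                raise ValueError("background region is empty")
            if x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
                raise ValueError("background region lies outside the image")
            patch = img.pixels[y0 : y0 + h, x0 : x0 + w]
            bg = float(patch.mean())
            return bg, {"mode": "region", "region": list(self.region), "value": bg}
        if self.mode == "rolling-ball":
            if self.radius is None or self.radius <= 0:
                raise ValueError("rolling-ball background requires a positive radius")
            field_ = rolling_ball(img.pixels, radius=self.radius)
            return field_, {"mode": "rolling-ball", "radius": float(self.radius)}
        raise ValueError(f"unknown background mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Stack ingestion
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    dz: float | None = None,
    dxy: float | None = None,
) -> VoxelGrid:
    """Read a multi-page grayscale TIFF z-stack into a :class:`VoxelGrid`.

    Voxel size is taken from explicit ``dz``/``dxy`` arguments when given,
    otherwise from TIFF/ImageJ metadata (resolution tags for the in-plane
    scale, ImageJ ``spacing`` for the z-step).  Volumes are meaningless
    without a voxel size, so an unresolvable scale is a hard error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        if dxy is None:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and unit is not None:
                num, den = xres.value
                if num > 0 and unit.value == 3:  # centimetre
                    dxy = 1e4 * den / num
        if dz is None and tf.imagej_metadata:
            dz = tf.imagej_metadata.get("spacing")

    if data.ndim == 2:
        warnings.warn(f"{path.name}: single-page TIFF, treating as z-extent 1 stack")
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected single-channel grayscale pages, got shape {data.shape}")
    if data.shape[-1] in (3, 4) and data.dtype == np.uint8 and data.shape[-1] < min(data.shape[:-1]):
        raise ValueError(f"{path.name}: expected single-channel, got RGB(A) data")

    if dz is None or dxy is None or dz <= 0 or dxy <= 0:
        raise ValueError(
            f"{path.name}: voxel size unresolved (dz={dz}, dxy={dxy}); "
            "supply dz/dxy explicitly or embed them in the TIFF metadata"
        )
    grid = VoxelGrid(np.maximum(data.astype(np.float64), 0.0), (float(dz), float(dxy), float(dxy)))
    _log("read_stack", path=str(path), shape=list(grid.shape), voxel_size=list(grid.voxel_size))
    return grid


def write_image(path: str | Path, img: Image2D | np.ndarray) -> None:
    """Write an image as 32-bit float TIFF."""
    arr = img.pixels if isinstance(img, Image2D) else np.asarray(img)
    tifffile.imwrite(str(path), arr.astype(np.float32))


# ---------------------------------------------------------------------------
# Correction cascade
# ---------------------------------------------------------------------------


def subtract_background(img: Image2D, bg: BackgroundSpec) -> Image2D:
    """Subtract an estimated background, clipping at zero.

    The resolved background (scalar or rolling-ball field) is recorded in
    the provenance log; output intensities are ``max(input - background, 0)``.
    """
    background, record = bg.resolve(img)
    out = np.maximum(img.pixels - background, 0.0)
    _log("subtract_background", **record)
    return Image2D(out, img.pixel_size)


def _quadratic_design(shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    # centre and scale coordinates for conditioning
    xs = (xx - (W - 1) / 2) / max(W, 1)
    ys = (yy - (H - 1) / 2) / max(H, 1)
    cols = [np.ones(H * W), xs.ravel(), ys.ravel(),
            (xs * xs).ravel(), (xs * ys).ravel(), (ys * ys).ravel()]
    return np.column_stack(cols)


def correct_illumination(img: Image2D, reference: Image2D | None = None) -> Image2D:
    """Divide out a fitted quadratic illumination surface.

    A low-order (quadratic in x, y) intensity surface is fitted by
    intensity-squared-weighted least squares and divided out; the result
    is rescaled to preserve the global mean.  The quadratic weighting
    makes the fit track the specimen rather than empty background:
    illumination is only observable where there is signal.  A flat image
    passes through unchanged.  No flat-field reference image is assumed.

    When ``reference`` is given the surface is fitted on the reference and
    applied to ``img`` -- channels acquired under the same excitation
    share one illumination field, and dividing them by a common surface
    leaves their pixel-wise ratios exactly intact.
    """
    H, W = img.shape
    if H < 16 or W < 16:
        raise ValueError("image too small to fit an illumination surface (need >= 16x16)")
    ref = (reference or img).pixels.ravel()
    w = ref * ref
    if w.sum() <= 0:
        warnings.warn("image carries no intensity; illumination left unchanged")
        return Image2D(img.pixels.copy(), img.pixel_size)
    A = _quadratic_design(img.shape)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], ref * sw, rcond=None)
    surface = (A @ coef).reshape(img.shape)
    if not np.all(np.isfinite(surface)):
        raise ValueError("degenerate illumination fit (non-finite surface)")
    if surface.mean() <= 0 or np.any(surface <= 0):
        # an (almost) empty channel has no illumination signal to correct
        warnings.warn("illumination surface not strictly positive; image left unchanged")
        return Image2D(img.pixels.copy(), img.pixel_size)
    # illumination varies smoothly and mildly; bound the gain so corner
    # extrapolation of the quadratic cannot blow up empty-background noise
    gain = np.clip(surface / surface.mean(), 0.25, 4.0)
    out = img.pixels / gain
    # renormalize so the global mean is preserved
    if out.mean() > 0:
        out *= img.pixels.mean() / out.mean()
    _log("correct_illumination", coef=[float(c) for c in coef])
    return Image2D(np.maximum(out, 0.0), img.pixel_size)


def register_channels(
    reference: Image2D,
    moving: Image2D,
) -> tuple[tuple[float, float], Image2D]:
    """Estimate and apply the inter-channel pixel shift.

    The integer displacement comes from masked cross-correlation (exact
    for non-periodic content); subpixel refinement solves the linearized
    brightness-constancy equations (optical-flow style) on lightly
    smoothed copies, reaching well under 0.1 px on structured scenes.
    ``moving`` is then resampled onto the reference grid by bilinear
    interpolation; pixels shifted in from outside the field are marked
    invalid (NaN) rather than extrapolated.

    Returns
    -------
    shift : (dy, dx)
        Estimated displacement of the moving image, in pixels.
    shifted : Image2D-like
        The moving image aligned to the reference (may contain NaN borders).
    """
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must have the same shape")
    if reference.pixels.std() == 0 or moving.pixels.std() == 0:
        warnings.warn("featureless image: registration confidence too low, assuming zero shift")
        return (0.0, 0.0), Image2D(moving.pixels.copy(), moving.pixel_size)

    ref_px = reference.pixels
    mov_px = moving.pixels
    # integer lag from masked cross-correlation (exact for non-periodic
    # content), then parabolic refinement on the local NCC surface
    shift = phase_cross_correlation(
        ref_px, mov_px,
        reference_mask=np.isfinite(ref_px), moving_mask=np.isfinite(mov_px),
    )[0]
    iy, ix = int(round(float(shift[0]))), int(round(float(shift[1])))

    def _ncc(dy: int, dx: int) -> float:
        H, W = ref_px.shape
        ys = slice(max(0, dy), min(H, H + dy))
        xs = slice(max(0, dx), min(W, W + dx))
        ys_m = slice(max(0, -dy), min(H, H - dy))
        xs_m = slice(max(0, -dx), min(W, W - dx))
        a = ref_px[ys, xs].ravel()
        b = mov_px[ys_m, xs_m].ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 16 or a.std() == 0 or b.std() == 0:
            return -1.0
        return float(np.corrcoef(a, b)[0, 1])

    c0 = _ncc(iy, ix)

    # subpixel refinement: iterated linearized least squares (optical-flow
    # style) -- solve grad(ref) . d = (shifted_mov - ref) on the overlap
    # estimation runs on lightly smoothed copies: registration is a
    # low-frequency problem and raw noise would bias the gradient solve
    mov_clean0 = ndimage.gaussian_filter(np.where(np.isfinite(mov_px), mov_px, 0.0), 2.0)
    ref_clean = ndimage.gaussian_filter(np.where(np.isfinite(ref_px), ref_px, 0.0), 2.0)
    gy, gx = np.gradient(ref_clean)
    corr_y, corr_x = float(iy), float(ix)
    for _ in range(4):
        sh_mov = ndimage.shift(mov_clean0, (corr_y, corr_x), order=3,
                               mode="constant", cval=np.nan)
        valid = np.isfinite(sh_mov) & np.isfinite(ref_px)
        valid[:2, :] = valid[-2:, :] = False
        valid[:, :2] = valid[:, -2:] = False
        if valid.sum() < 64:
            break
        r = (sh_mov - ref_clean)[valid]
        G = np.column_stack([gy[valid], gx[valid]])
        try:
            d, *_ = np.linalg.lstsq(G, r, rcond=None)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(d)) or np.hypot(*d) > 2.0:
            break
        corr_y += float(d[0])
        corr_x += float(d[1])
        if np.hypot(*d) < 1e-3:
            break
    if c0 < 0.2:
        warnings.warn("registration correlation peak below confidence floor; assuming zero shift")
        return (0.0, 0.0), Image2D(moving.pixels.copy(), moving.pixel_size)
    mov_clean = np.where(np.isfinite(mov_px), mov_px, 0.0)
    shifted = ndimage.shift(mov_clean, (corr_y, corr_x), order=1, mode="constant", cval=np.nan)
    shifted[~np.isfinite(ndimage.shift(np.where(np.isfinite(mov_px), 1.0, np.nan),
                                       (corr_y, corr_x), order=1,
                                       mode="constant", cval=np.nan))] = np.nan
    _log("register_channels", shift=[-corr_y, -corr_x], peak_ncc=float(c0))
    out = Image2D.__new__(Image2D)  # allow NaN border markers without triggering validation
    out.pixels = shifted
    out.pixel_size = moving.pixel_size
    return (-corr_y, -corr_x), out


def smooth3(img: Image2D) -> Image2D:
    """Three-point smoothing: one pass of a 3x3 uniform mean filter.

    Edge handling replicates the border pixel, so a constant image is a
    fixed point and the global mean is preserved to well under 0.5%.
    """
    # direct convolution: NaN pixels (invalid registration borders) spread
    # only to their 3x3 neighbourhood instead of poisoning running sums
    kernel = np.full((3, 3), 1.0 / 9.0)
    out = ndimage.convolve(img.pixels, kernel, mode="nearest")
    res = Image2D.__new__(Image2D)
    res.pixels = out
    res.pixel_size = img.pixel_size
    return res
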
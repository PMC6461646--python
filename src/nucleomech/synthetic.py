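"""Synthetic ground-truth data for every pipeline stage.

Generates nuclei z-stacks, three-cube FRET scenes, FRAP traces and gel
images with known ground truth, so segmentation, calibration,
normalization and densitometry can be validated by parameter recovery
without any external data.  Every generator is a pure function of its
parameters and seed: the same call yields byte-identical output.

What is emulated (and what is not): nuclei are randomly oriented
ellipsoids with lognormally distributed volumes, blurred by an anisotropic
Gaussian point-spread function (twice as wide axially as laterally) and
corrupted by Poisson-Gaussian noise -- real nuclei are irregular and real
PSFs have diffraction structure, so recovery here bounds algorithmic, not
optical, error.  FRET scenes compose the FRET channel as
``x*D + y*A + se*A`` inside perinuclear rings, with per-excitation
illumination gradients and an inter-channel pixel shift.  FRAP traces
follow a single-exponential recovery with acquisition photobleaching
applied equally to bleached and reference ROIs.  Gels place Gaussian
bands by a fixed log-linear mobility law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import Image2D, VoxelGrid
from .frap import FrapSeries
from .fret import FretAcquisition

# ---------------------------------------------------------------------------
# Ground-truth record
# ---------------------------------------------------------------------------


@dataclass
class SceneGroundTruth:
    """True parameters of one generated scene, emitted beside the data."""

    kind: str
    seed: int
    params: dict
    objects: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "seed": self.seed, "params": self.params,
                 "objects": self.objects},
                fh, indent=2, default=float,
            )


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal (mu, sigma) for a given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


# ---------------------------------------------------------------------------
# Nuclei stacks
# ---------------------------------------------------------------------------


def _sample_ellipsoid(rng, volume: float, aspect_range: tuple[float, float]):
    """Semi-axes (um) of a random ellipsoid with the given volume."""
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    f = rng.uniform(aspect_range[0], aspect_range[1], size=3)
    f /= f.prod() ** (1.0 / 3.0)  # geometric mean 1 -> volume preserved
    return r * f


def _paint_ellipsoid(canvas, center, axes, rot, voxel_size, amplitude):
    """Rasterize one ellipsoid (physical um coordinates) into the canvas."""
    vs = np.asarray(voxel_size)
    rmax = float(axes.max())
    lo = np.maximum(np.floor((center - rmax) / vs).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + rmax) / vs).astype(int) + 2, canvas.shape)
    if np.any(lo >= hi):
        return 0
    grids = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, vs)], indexing="ij"
    )
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = rel @ rot  # rotate into the ellipsoid frame
    inside = np.sum((local / axes) ** 2, axis=-1) <= 1.0
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, inside * amplitude, out=sub)
    return int(inside.sum())


def _place_nuclei(
    rng, volumes, aspect_range, field_um, touching_fraction, max_attempts=2000,
    best_effort=False,
):
    """Place ellipsoids without overlap (bounding-sphere test), fully interior.

    A controlled fraction of nuclei is instead placed touching an existing
    one.  Returns the placed subset (all, unless ``best_effort``).
    """
    placed = []  # (center, axes, rot, volume)
    n_touch = int(round(touching_fraction * len(volumes) / 2))
    for i, vol in enumerate(volumes):
        axes = _sample_ellipsoid(rng, vol, aspect_range)
        rot = _random_rotation(rng)
        rmax = float(axes.max())
        margin = rmax + 0.3
        if np.any(2 * margin >= field_um):
            if best_effort:
                break
            raise ValueError(
                f"nucleus of volume {vol:.0f} um^3 cannot fit the field "
                f"{tuple(field_um)} um; use a larger field"
            )
        # the first n_touch nuclei after the first are placed touching a
        # previously placed partner; the rest must not overlap anything
        touching = bool(placed) and i <= n_touch and touching_fraction > 0
        ok = False
        for _ in range(max_attempts):
            if touching:
                base_idx = int(rng.integers(len(placed)))
                base = placed[base_idx]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                c = base[0] + direction * 0.85 * (base[1].max() + rmax)
                others = [p for j, p in enumerate(placed) if j != base_idx]
            else:
                c = np.array([rng.uniform(margin, f - margin) for f in field_um])
                others = placed
            if np.any(c < margin) or np.any(c > field_um - margin):
                continue
            if all(np.linalg.norm(c - p[0]) >= 0.95 * (p[1].max() + rmax) + 0.2
                   for p in others):
                placed.append((c, axes, rot, vol))
                ok = True
                break
        if not ok:
            if best_effort:
                break
            raise ValueError(
                f"could not place nucleus {i + 1}/{len(volumes)} after "
                f"{max_attempts} attempts; use a larger field"
            )
    return placed


def _image_noise(canvas, blur_sigma, voxel_size, background, snr, amplitude,
                 rng, shape):
    """PSF blur plus Poisson-Gaussian noise; ``snr <= 0`` means noiseless.

    The Gaussian PSF is twice as wide axially as laterally; the Poisson
    photon scale is set so the shot-noise SD at full foreground amplitude
    is amplitude/snr, with Gaussian read noise at half that."""
    if blur_sigma > 0:
        sigma_vox = (2 * blur_sigma / voxel_size[0],
                     blur_sigma / voxel_size[1], blur_sigma / voxel_size[2])
        canvas = ndimage.gaussian_filter(canvas, sigma_vox)
    img = canvas + background
    if snr <= 0:
        return img
    lam = snr**2 / amplitude  # photons per intensity unit
    return rng.poisson(img * lam) / lam + rng.normal(
        0.0, amplitude / (2 * snr), size=shape)


def make_nuclei_scene(
    n: int,
    volume_mean: float = 207.0,
    volume_sd: float = 58.0,
    aspect_range: tuple[float, float] = (1.0, 1.4),
    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1),
    shape: tuple[int, int, int] = (80, 256, 256),
    blur_sigma: float = 0.2,
    snr: float = 20.0,
    touching_fraction: float = 0.0,
    seed: int = 0,
    amplitude: float = 1000.0,
    background: float = 50.0,
) -> tuple[VoxelGrid, SceneGroundTruth]:
    """One synthetic DAPI z-stack of ``n`` ellipsoidal nuclei.

    Volumes are lognormal, moment-matched to ``(volume_mean, volume_sd)``
    um^3 (positivity with only two stated moments).  Nuclei are placed
    without overlap except for a controlled ``touching_fraction``; the
    stack is blurred by an anisotropic Gaussian PSF (sigma ``blur_sigma``
    um laterally, twice that axially) and corrupted by Poisson-Gaussian
    noise at the stated SNR (foreground amplitude over noise SD).
    Placement failure after bounded attempts is an error suggesting a
    larger field.
    """
    if volume_mean <= 0 or volume_sd >= volume_mean:
        raise ValueError("need volume_mean > 0 and volume_sd < volume_mean")
    rng = _rng(seed)
    mu, sig = _lognormal_params(volume_mean, volume_sd)
    volumes = rng.lognormal(mu, sig, size=n)
    field_um = np.array(shape) * np.asarray(voxel_size)
    placed = _place_nuclei(rng, volumes, aspect_range, field_um, touching_fraction)

    canvas = np.zeros(shape, dtype=np.float64)
    objects = []
    for c, axes, rot, vol in placed:
        _paint_ellipsoid(canvas, c, axes, rot, voxel_size, amplitude)
        objects.append({"volume_um3": float(vol), "center_um": [float(v) for v in c],
                        "semi_axes_um": [float(a) for a in axes]})

    noisy = _image_noise(canvas, blur_sigma, voxel_size, background, snr,
                         amplitude, rng, shape)
    gt = SceneGroundTruth(
        kind="nuclei", seed=seed,
        params={"n": n, "volume_mean": volume_mean, "volume_sd": volume_sd,
                "aspect_range": list(aspect_range), "voxel_size": list(voxel_size),
                "shape": list(shape), "blur_sigma": blur_sigma, "snr": snr,
                "touching_fraction": touching_fraction, "amplitude": amplitude,
                "background": background},
        objects=objects,
    )
    return VoxelGrid(np.clip(noisy, 0, None), voxel_size), gt


def make_nuclei_fields(
    n_total: int,
    volume_mean: float,
    volume_sd: float,
    seed: int = 0,
    **scene_kw,
) -> list[tuple[VoxelGrid, SceneGroundTruth]]:
    """Enough fields of the standard size to hold ``n_total`` nuclei.

    Large nuclei pack sparsely at the standard field size, so a population
    is imaged across several fields, as in a real confocal session.
    Volumes for the whole population are drawn up front from one lognormal
    stream, then packed field by field (best effort per field).
    """
    rng = _rng(seed)
    mu, sig = _lognormal_params(volume_mean, volume_sd)
    volumes = list(rng.lognormal(mu, sig, size=n_total))
    aspect_range = scene_kw.pop("aspect_range", (1.0, 1.4))
    voxel_size = scene_kw.pop("voxel_size", (0.25, 0.1, 0.1))
    shape = scene_kw.pop("shape", (80, 256, 256))
    touching = scene_kw.pop("touching_fraction", 0.0)
    field_um = np.array(shape) * np.asarray(voxel_size)

    fields = []
    remaining = volumes
    field_idx = 0
    while remaining:
        sub_rng = _rng(int(np.random.SeedSequence([seed, field_idx]).generate_state(1)[0] % 2**31))
        placed = _place_nuclei(sub_rng, remaining, aspect_range, field_um,
                               touching, best_effort=True)
        if not placed:
            raise ValueError(
                f"nucleus of volume {remaining[0]:.0f} um^3 cannot fit a "
                f"{tuple(field_um)} um field"
            )
        k = len(placed)
        canvas = np.zeros(shape, dtype=np.float64)
        objects = []
        amplitude = scene_kw.get("amplitude", 1000.0)
        background = scene_kw.get("background", 50.0)
        blur_sigma = scene_kw.get("blur_sigma", 0.2)
        snr = scene_kw.get("snr", 20.0)
        for c, axes, rot, vol in placed:
            _paint_ellipsoid(canvas, c, axes, rot, voxel_size, amplitude)
            objects.append({"volume_um3": float(vol),
                            "center_um": [float(v) for v in c],
                            "semi_axes_um": [float(a) for a in axes]})
        noisy = _image_noise(canvas, blur_sigma, voxel_size, background, snr,
                             amplitude, sub_rng, shape)
        gt = SceneGroundTruth(
            kind="nuclei", seed=seed,
            params={"n": k, "volume_mean": volume_mean, "volume_sd": volume_sd,
                    "field_index": field_idx, "voxel_size": list(voxel_size),
                    "shape": list(shape), "blur_sigma": blur_sigma, "snr": snr},
            objects=objects,
        )
        fields.append((VoxelGrid(np.clip(noisy, 0, None), voxel_size), gt))
        remaining = remaining[k:]
        field_idx += 1
        if field_idx > 10 * n_total:
            raise RuntimeError("field packing did not converge")
    return fields


# ---------------------------------------------------------------------------
# FRET scenes
# ---------------------------------------------------------------------------


def _ring_scene(rng, n_cells, shape, pixel_size):
    """Perinuclear ring masks: label map plus per-cell amplitudes."""
    H, W = shape
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:H, 0:W]
    centers = []
    lab = 0
    for _ in range(n_cells * 200):
        if lab >= n_cells:
            break
        r_in = rng.uniform(8, 12)
        r_out = r_in + rng.uniform(3, 5)
        c = rng.uniform(r_out + 3, [H - r_out - 3, W - r_out - 3])
        if any(np.hypot(*(c - p[:2])) < r_out + p[2] + 2 for p in centers):
            continue
        d = np.hypot(yy - c[0], xx - c[1])
        lab += 1
        labels[(d >= r_in) & (d <= r_out)] = lab
        centers.append(np.array([c[0], c[1], r_out]))
    if lab < n_cells:
        raise ValueError("could not place all cells; reduce n_cells or enlarge the field")
    return labels


def _blob_field(rng, shape, amp, n_blobs=60):
    """Dense field of overlapping Gaussian blobs with a wide intensity
    range, emulating a field of transfected calibration cells."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    field = np.zeros(shape)
    cy = rng.uniform(0, H, n_blobs)
    cx = rng.uniform(0, W, n_blobs)
    sig = rng.uniform(6, 14, n_blobs)
    a = rng.uniform(0.15, 1.0, n_blobs)
    for i in range(n_blobs):
        field += a[i] * np.exp(-((yy - cy[i]) ** 2 + (xx - cx[i]) ** 2) / (2 * sig[i] ** 2))
    return field * (amp / field.max())


def make_fret_scene(
    n_cells: int = 16,
    true_se_fraction: float = 0.15,
    x: float = 0.25,
    y: float = 0.10,
    gradient_amplitude: float = 0.0,
    shift_px: tuple[float, float] = (0.0, 0.0),
    snr: float = 20.0,
    shape: tuple[int, int] = (320, 320),
    pixel_size: float = 0.16,
    seed: int = 0,
    background: float = 100.0,
) -> tuple[dict, SceneGroundTruth]:
    """A three-cube FRET scene plus matching calibration acquisitions.

    Donor and acceptor fluorophores co-localize in perinuclear rings (a
    nuclear-envelope tension-sensor geometry).  The FRET channel is
    composed as ``x*D + y*A + se*A``; ``true_se_fraction = 0`` reproduces
    a headless-control scene with no energy transfer.  Donor-excited
    channels (donor, FRET) share one illumination gradient; the
    acceptor-excited channel carries the opposite gradient, and the
    acceptor acquisition is additionally shifted by ``shift_px`` --
    gradient and shift are applied after composition, then background and
    Gaussian noise (amplitude / snr) are added.

    Returns a dict with keys ``sensor``, ``donor_only``, ``acceptor_only``
    (each a :class:`FretAcquisition`), ``masks`` (ring label map), and the
    ground-truth record.
    """
    if not (0 <= true_se_fraction < 1):
        raise ValueError("true_se_fraction must lie in [0, 1)")
    rng = _rng(seed)
    H, W = shape
    ramp = (np.arange(W) / max(W - 1, 1) - 0.5) * 2  # -1..1 across the field
    g_donor = 1.0 + gradient_amplitude / 2 * ramp[None, :]
    g_acceptor = 1.0 - gradient_amplitude / 2 * ramp[None, :]

    def _compose(D, A, se):
        """Channels from true donor/acceptor fields: compose, then apply
        gradients, shift, background and noise."""
        F = x * D + y * A + se * A
        D_img = g_donor * D
        F_img = g_donor * F
        A_img = g_acceptor * A
        if any(shift_px):
            A_img = ndimage.shift(A_img, shift_px, order=1, mode="constant", cval=0.0)
        out = {}
        for name, img in (("donor", D_img), ("fret", F_img), ("acceptor", A_img)):
            # shot-noise-like scaling: each channel's noise follows its own
            # signal scale (a dim channel is also a quiet channel)
            noise_sd = max(np.max(img), background) / snr if snr else 0.0
            noisy = img + background + (rng.normal(0, noise_sd, shape) if noise_sd else 0)
            out[name] = Image2D(np.clip(noisy, 0, None), pixel_size)
        return FretAcquisition(**out)

    # sensor: donor and acceptor co-localized in perinuclear rings with a
    # narrow expression spread -- the scene isolates the optical effects
    # under test (leakage, cross-excitation, gradient, shift, noise);
    # expression heterogeneity of real transfections is not modelled here
    masks = _ring_scene(rng, n_cells, shape, pixel_size)
    damp = 800.0 * rng.uniform(0.97, 1.03, size=n_cells)
    aamp = 700.0 * rng.uniform(0.97, 1.03, size=n_cells)
    D_rings = np.zeros(shape)
    A_rings = np.zeros(shape)
    for lab in range(1, n_cells + 1):
        m = masks == lab
        D_rings[m] = damp[lab - 1]
        A_rings[m] = aamp[lab - 1]
    sensor = _compose(D_rings, A_rings, true_se_fraction)

    # calibration samples: dense fields of single-fluorophore cells with a
    # wide intensity range, which is what conditions the slope fit well
    donor_only = _compose(_blob_field(rng, shape, 800.0), np.zeros(shape), 0.0)
    acceptor_only = _compose(np.zeros(shape), _blob_field(rng, shape, 700.0), 0.0)

    gt = SceneGroundTruth(
        kind="fret", seed=seed,
        params={"n_cells": n_cells, "true_se_fraction": true_se_fraction, "x": x,
                "y": y, "gradient_amplitude": gradient_amplitude,
                "shift_px": list(shift_px), "snr": snr, "shape": list(shape),
                "pixel_size": pixel_size, "background": background},
        objects=[{"cell": i + 1, "donor_amp": float(damp[i]),
                  "acceptor_amp": float(aamp[i])} for i in range(n_cells)],
    )
    return {"sensor": sensor, "donor_only": donor_only,
            "acceptor_only": acceptor_only, "masks": masks}, gt


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def default_frap_schedule(n_prebleach: int = 3, bleach_gap: float = 20.0) -> np.ndarray:
    """Reference acquisition schedule: pre-bleach frames at 0.78 s, a
    ~20 s bleach gap, then 10 frames at 0.78 s and 30 frames at 2 s."""
    pre = np.arange(n_prebleach) * 0.78
    t0 = pre[-1] + bleach_gap
    fast = t0 + np.arange(10) * 0.78
    slow = fast[-1] + 2.0 * np.arange(1, 31)
    return np.concatenate([pre, fast, slow])


def make_frap_traces(
    m: float = 0.8,
    tau_s: float = 10.0,
    bleach_depth: float = 0.8,
    acq_decay_per_frame: float = 0.0,
    noise_sd: float = 0.0,
    schedule: np.ndarray | None = None,
    n_prebleach: int = 3,
    bleach_gap: float = 20.0,
    seed: int = 0,
    base: float = 1000.0,
    reference_base: float = 900.0,
    bg: float = 100.0,
) -> tuple[FrapSeries, SceneGroundTruth]:
    """Synthetic three-ROI FRAP traces with known recovery parameters.

    ROI1 follows ``base * decay(t) * [1 - bleach_depth * (1 - m * (1 -
    exp(-t'/tau)))]`` after the bleach (t' from the first post-bleach
    frame), ROI2 is an unbleached reference with the same per-frame
    acquisition decay, ROI3 is flat background.  ``noise_sd`` is Gaussian
    noise as a fraction of ``base`` added to every ROI sample.
    """
    if not (0 <= m <= 1):
        raise ValueError("mobile fraction m must lie in [0, 1]")
    if not (0 < bleach_depth < 1):
        raise ValueError("bleach_depth must lie in (0, 1)")
    rng = _rng(seed)
    times = default_frap_schedule(n_prebleach, bleach_gap) if schedule is None \
        else np.asarray(schedule, dtype=float)
    n = times.size
    frame_idx = np.arange(n)
    decay = (1.0 - acq_decay_per_frame) ** frame_idx

    rel = np.ones(n)
    post = slice(n_prebleach, None)
    tprime = times[post] - times[n_prebleach]
    with np.errstate(over="ignore"):
        recovery = m * (1.0 - np.exp(-tprime / tau_s)) if tau_s > 0 else np.full(tprime.shape, m)
    rel[post] = 1.0 - bleach_depth * (1.0 - recovery)

    sd = noise_sd * base
    roi1 = base * decay * rel + bg + rng.normal(0, sd, n)
    roi2 = reference_base * decay + bg + rng.normal(0, sd, n)
    roi3 = bg + rng.normal(0, sd, n)
    series = FrapSeries(times=times, roi1=roi1, roi2=roi2, roi3=roi3,
                        n_prebleach=n_prebleach, bleach_gap=bleach_gap)
    gt = SceneGroundTruth(
        kind="frap", seed=seed,
        params={"m": m, "tau_s": tau_s, "half_time_s": tau_s * np.log(2),
                "bleach_depth": bleach_depth,
                "acq_decay_per_frame": acq_decay_per_frame, "noise_sd": noise_sd,
                "n_prebleach": n_prebleach, "bleach_gap": bleach_gap,
                "base": base, "reference_base": reference_base, "bg": bg},
    )
    return series, gt


def make_frap_movie(
    series: FrapSeries,
    shape: tuple[int, int] = (64, 96),
    seed: int = 0,
) -> tuple[list[Image2D], dict[str, tuple[int, int, int, int]]]:
    """Render a FRAP series as an image time series with three ROIs.

    A convenience for exercising ROI extraction: each frame paints the
    bleached spot, the reference nucleus and pure background at the
    trace values.  Returns frames plus the ROI rectangles.
    """
    rois = {"roi1": (8, 8, 12, 12), "roi2": (40, 8, 12, 12), "roi3": (8, 40, 12, 12)}
    frames = []
    for i in range(series.times.size):
        img = np.full(shape, series.roi3[i])
        for name, src in (("roi1", series.roi1), ("roi2", series.roi2)):
            x0, y0, w, h = rois[name]
            img[y0:y0 + h, x0:x0 + w] = src[i]
        frames.append(Image2D(np.clip(img, 0, None), 0.16))
    return frames, rois


# ---------------------------------------------------------------------------
# Gels
# ---------------------------------------------------------------------------


def make_gel(
    lanes: list[list[tuple[float, float]]],
    ladder_sizes: tuple[float, ...] = (10000, 3000, 1000, 500, 100),
    spread_px: float = 6.0,
    snr: float = 30.0,
    seed: int = 0,
    lane_width: int = 40,
    gap_px: int = 24,
    height: int = 512,
    background: float = 50.0,
    total_intensity: float = 2000.0,
) -> tuple[Image2D, dict, SceneGroundTruth]:
    """A synthetic gel image: one ladder lane plus sample lanes.

    Each sample lane is a list of ``(size_bp, weight)`` with weights
    summing to 1.  Band centres follow a fixed log-linear mobility law
    anchored at the ladder extremes; bands are Gaussian in the migration
    direction with ``spread_px`` SD.  Returns the image, the lane layout
    (``ladder`` and ``lanes`` rectangles as (x0, y0, w, h)), and ground
    truth.  Fragment sizes outside the mobility-law domain are an error.
    """
    rng = _rng(seed)
    ladder_sizes = tuple(sorted(ladder_sizes, reverse=True))
    smax, smin = ladder_sizes[0], ladder_sizes[-1]
    top, bottom = 40.0, height - 40.0
    scale = (bottom - top) / (np.log10(smax) - np.log10(smin))

    def pos(size: float) -> float:
        if not (smin <= size <= smax):
            raise ValueError(
                f"fragment size {size} bp outside mobility-law domain [{smin}, {smax}]"
            )
        return top + scale * (np.log10(smax) - np.log10(size))

    for lane in lanes:
        if abs(sum(w for _, w in lane) - 1.0) > 1e-9:
            raise ValueError("lane mixture weights must sum to 1")

    n_lanes = 1 + len(lanes)
    width = gap_px + n_lanes * (lane_width + gap_px)
    img = np.zeros((height, width))
    rows = np.arange(height, dtype=float)

    def _paint(x0: int, bands: list[tuple[float, float]]):
        profile = np.zeros(height)
        for size, weight in bands:
            mu = pos(size)
            profile += (weight * total_intensity / (spread_px * np.sqrt(2 * np.pi))
                        * np.exp(-0.5 * ((rows - mu) / spread_px) ** 2))
        img[:, x0:x0 + lane_width] += profile[:, None]

    layout = {}
    x0 = gap_px
    ladder_bands = [(s, 1.0 / len(ladder_sizes)) for s in ladder_sizes]
    _paint(x0, ladder_bands)
    layout["ladder"] = (x0, 0, lane_width, height)
    lane_rects = []
    for lane in lanes:
        x0 += lane_width + gap_px
        _paint(x0, lane)
        lane_rects.append((x0, 0, lane_width, height))
    layout["lanes"] = lane_rects

    peak = total_intensity / (spread_px * np.sqrt(2 * np.pi))
    noisy = img + background
    if snr > 0:
        noisy = noisy + rng.normal(0, peak / snr, img.shape)
    gt = SceneGroundTruth(
        kind="gel", seed=seed,
        params={"ladder_sizes": list(ladder_sizes), "spread_px": spread_px,
                "snr": snr, "mobility_top_px": top, "mobility_scale_px_per_log10": scale,
                "lane_width": lane_width, "gap_px": gap_px, "height": height},
        objects=[{"lane": i + 1,
                  "mixture": [{"size_bp": s, "weight": w, "position_px": pos(s)}
                              for s, w in lane]}
                 for i, lane in enumerate(lanes)],
    )
    return Image2D(np.clip(noisy, 0, None), 1.0), layout, gt
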
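"""Nuclear segmentation and shape statistics.

Segments DAPI-stained nuclei in 2D images and anisotropic confocal
z-stacks, splits touching nuclei by seeded watershed on the physical
(Euclidean) distance transform, and computes the morphometric readouts:

* circularity ``4*pi*area / perimeter**2`` (1 for a disc), with the
  perimeter estimated by the 4-direction Crofton formula -- pixel-edge
  counting would bias circularity low by roughly a quarter for discs, and
  the estimator used is recorded in output metadata;
* nuclear volume in um^3 as (voxel count) x (voxel volume).

Objects touching the xy image border, and objects whose watershed split is
ambiguous, are flagged and excluded from population statistics rather than
deleted, mirroring the practice of discarding nuclei that cannot be
segmented confidently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton
from skimage.segmentation import watershed

from .core_io import Image2D, VoxelGrid, _log

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SegmentationParams:
    """Parameters of nucleus segmentation.

    Parameters
    ----------
    threshold_mode : "auto" or float
        "auto" uses Otsu's threshold on the smoothed image; a float fixes
        the threshold manually.
    seed_point_diameter : float
        Minimum physical separation (um) between watershed seed points;
        roughly the diameter of the smallest nucleus to be resolved.
    min_volume : float
        Objects below this size are discarded (um^3 in 3D; read as um^2
        in 2D).
    surface_smoothing : float
        Gaussian pre-smoothing sigma in um, sub-nuclear by construction.
    """

    threshold_mode: str | float = "auto"
    seed_point_diameter: float = 6.0
    min_volume: float = 20.0
    surface_smoothing: float = 0.2

    def __post_init__(self) -> None:
        if self.seed_point_diameter <= 0:
            raise ValueError("seed_point_diameter must be positive")
        if self.min_volume < 0:
            raise ValueError("min_volume must be non-negative")


@dataclass
class LabelMap:
    """Integer label image/stack; 0 is background.

    ``scale`` is the physical pixel/voxel size inherited from the source
    (a float for 2D, an (dz, dy, dx) tuple for 3D).  ``meta`` carries
    segmentation diagnostics (seed counts per pre-split component) used by
    :func:`filter_objects`.
    """

    labels: np.ndarray
    scale: float | tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class NucleusMeasurement:
    """Per-nucleus morphometry record.

    Volume is in um^3 (3D only); area (um^2), perimeter (um) and
    circularity are 2D only.  ``flags`` is a subset of
    ``{"border_touching", "unresolved_merge"}``; flagged objects are kept
    in the label map but excluded from population statistics.
    """

    label: int
    volume: float | None = None
    area: float | None = None
    perimeter: float | None = None
    circularity: float | None = None
    centroid: tuple[float, ...] = ()
    flags: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# 2D segmentation and circularity
# ---------------------------------------------------------------------------


def segment_nuclei_2d(img: Image2D, params: SegmentationParams | None = None) -> LabelMap:
    """Threshold-and-label segmentation of a 2D DAPI image.

    The image is Gaussian-smoothed (sigma = ``surface_smoothing`` um),
    thresholded (Otsu by default), holes are filled and connected
    components above the minimum area are labelled.
    """
    params = params or SegmentationParams()
    sigma_px = params.surface_smoothing / img.pixel_size
    smoothed = ndimage.gaussian_filter(img.pixels, sigma_px)
    if params.threshold_mode == "auto":
        if smoothed.max() == smoothed.min():
            warnings.warn("no foreground found: image is uniform")
            return LabelMap(np.zeros(img.shape, dtype=np.int32), img.pixel_size)
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold_mode)
    mask = smoothed > thr
    if not mask.any():
        warnings.warn("no foreground pixels above threshold")
        return LabelMap(np.zeros(img.shape, dtype=np.int32), img.pixel_size)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if params.min_volume > 0:
        min_px = params.min_volume / img.pixel_size**2
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_px)
        keep = keep[keep > 0]
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    return LabelMap(labels.astype(np.int32), img.pixel_size)


def circularity(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Circularity ``4*pi*area / perimeter**2`` of a single-object mask.

    Area is (pixel count) * pixel_size^2; the perimeter is the 4-direction
    Crofton estimate.  The value is returned without clipping, so slight
    overshoots above 1 for near-perfect discs are visible rather than
    hidden.
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < 9:
        raise ValueError("component smaller than 9 px: perimeter estimate unreliable")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one connected component, got {n_comp}")
    area = n_px * pixel_size**2
    perim = perimeter_crofton(mask, directions=4) * pixel_size
    return float(4.0 * np.pi * area / perim**2)


# ---------------------------------------------------------------------------
# 3D segmentation
# ---------------------------------------------------------------------------


def _edt_seeds(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    seed_point_diameter: float,
) -> tuple[np.ndarray, dict[int, dict]]:
    """Find watershed seeds on the physical distance transform.

    Candidate nucleus centres are local maxima of the Euclidean distance
    transform (computed with physical voxel sampling) clustered by a ridge
    test: two maxima joined by a high-distance path belong to one nucleus
    (elongated nuclei have a ridge of equal-distance maxima along their
    long axis).  Candidates closer than ``seed_point_diameter`` are then
    greedily suppressed, keeping the deeper candidate; ties break by
    lexicographic voxel order so the output is deterministic.

    Returns the seed marker array and, per connected component, the
    candidate and accepted seed counts (a discrepancy marks a potential
    unresolved merge).
    """
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    cc, n_cc = ndimage.label(mask)
    vs = np.asarray(voxel_size)

    # local maxima of the EDT, deep enough to be a nucleus core
    min_depth = max(2.0 * min(voxel_size), 0.15 * seed_point_diameter)
    peaks = peak_local_max(
        edt, min_distance=2, threshold_abs=min_depth, labels=cc, exclude_border=False
    )
    # deterministic order: decreasing depth, then lexicographic position
    depth = edt[tuple(peaks.T)] if peaks.size else np.empty(0)
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], -depth)) if peaks.size else []
    peaks = peaks[order]
    depth = depth[order] if peaks.size else depth

    markers = np.zeros(mask.shape, dtype=np.int32)
    comp_info: dict[int, dict] = {c: {"candidates": 0, "seeds": 0} for c in range(1, n_cc + 1)}
    next_id = 1
    by_comp: dict[int, list[tuple[np.ndarray, float]]] = {}
    for p, d in zip(peaks, depth):
        by_comp.setdefault(int(cc[tuple(p)]), []).append((p, float(d)))

    def _ridge_joined(a: np.ndarray, da: float, b: np.ndarray, db: float) -> bool:
        # sample the EDT along the straight segment: an elongated nucleus
        # has a ridge of near-equal depth between its maxima (ratio ~1),
        # while even a strongly overlapping sphere pair has a saddle
        # (ratio sqrt(1 - (d/2r)^2) < 0.95 for d > 0.6 r)
        n_samp = 9
        ts = np.linspace(0.0, 1.0, n_samp)
        pts = a[None, :] * (1 - ts[:, None]) + b[None, :] * ts[:, None]
        vals = ndimage.map_coordinates(edt, pts.T, order=1, mode="nearest")
        return float(vals.min()) >= 0.9 * min(da, db)

    for comp, plist in by_comp.items():
        # cluster ridge-connected maxima into candidates
        reps: list[tuple[np.ndarray, float]] = []
        for p, d in plist:
            for rp, rd in reps:
                if _ridge_joined(p, d, rp, rd):
                    break
            else:
                reps.append((p, d))
        comp_info[comp]["candidates"] = len(reps)
        # greedy physical-distance suppression -> accepted seeds
        accepted: list[np.ndarray] = []
        for p, d in reps:
            pos = p * vs
            if all(np.linalg.norm(pos - a * vs) >= seed_point_diameter for a in accepted):
                accepted.append(p)
                markers[tuple(p)] = next_id
                next_id += 1
        comp_info[comp]["seeds"] = len(accepted)
        if not accepted and plist:  # component with only shallow maxima: keep deepest
            p = plist[0][0]
            markers[tuple(p)] = next_id
            next_id += 1
            comp_info[comp]["seeds"] = 1
    return markers, comp_info


def segment_nuclei_3d(stack: VoxelGrid, params: SegmentationParams | None = None) -> LabelMap:
    """Segment nuclei in an anisotropic confocal z-stack.

    The stack is Gaussian-smoothed with a physically isotropic sigma of
    ``surface_smoothing`` um, thresholded globally (Otsu on the smoothed
    stack by default, emulating an auto-generated average threshold), and
    touching nuclei are split by seeded watershed on the physical-distance
    transform with seeds separated by at least ``seed_point_diameter`` um.
    Objects below ``min_volume`` um^3 are removed.  All distances are
    physical, so voxel anisotropy does not skew the split.
    """
    params = params or SegmentationParams()
    dz, dy, dx = stack.voxel_size
    sigma_vox = tuple(params.surface_smoothing / s for s in stack.voxel_size)
    smoothed = ndimage.gaussian_filter(stack.voxels, sigma_vox)
    if params.threshold_mode == "auto":
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold_mode)
    mask = smoothed > thr
    if not mask.any():
        warnings.warn("no foreground voxels above threshold")
        return LabelMap(np.zeros(stack.shape, dtype=np.int32), stack.voxel_size)
    mask = ndimage.binary_fill_holes(mask)

    markers, comp_info = _edt_seeds(mask, stack.voxel_size, params.seed_point_diameter)
    edt = ndimage.distance_transform_edt(mask, sampling=stack.voxel_size)
    labels = watershed(-edt, markers, mask=mask)

    # drop small objects (below min_volume um^3)
    voxvol = stack.voxel_volume
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts * voxvol >= params.min_volume)
    keep = keep[keep > 0]
    relabel = np.zeros(counts.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1)
    labels = relabel[labels]

    # map final labels to their pre-split component diagnostics
    cc, _ = ndimage.label(mask)
    label_comp: dict[int, dict] = {}
    for lab in range(1, int(labels.max()) + 1):
        where = np.argwhere(labels == lab)
        if where.size:
            comp = int(cc[tuple(where[0])])
            label_comp[lab] = comp_info.get(comp, {"candidates": 1, "seeds": 1})
    _log(
        "segment_nuclei_3d",
        threshold=float(thr),
        n_objects=int(labels.max()),
        seed_point_diameter=params.seed_point_diameter,
        surface_smoothing=params.surface_smoothing,
        perimeter_estimator="crofton-4",
    )
    return LabelMap(labels.astype(np.int32), stack.voxel_size, meta={"per_label": label_comp})


def filter_objects(labels: LabelMap) -> dict[int, frozenset[str]]:
    """Flag objects whose measurement would be unreliable.

    ``border_touching``: the object touches the xy image border (z-clipped
    objects are pervasive in confocal stacks and only trigger a warning).
    ``unresolved_merge``: the object's pre-split component had more
    candidate nucleus cores than accepted seeds at the configured seed
    diameter, so it may still contain a merged pair.  Flagged objects stay
    in the map but are excluded from statistics.
    """
    arr = labels.labels
    flags: dict[int, set[str]] = {lab: set() for lab in range(1, int(arr.max()) + 1)}
    if arr.ndim == 3:
        border = np.zeros(arr.shape, dtype=bool)
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        z_border = np.unique(arr[[0, -1], :, :])
    else:
        border = np.zeros(arr.shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        z_border = np.empty(0)
    for lab in np.unique(arr[border]):
        if lab > 0:
            flags[int(lab)].add("border_touching")
    z_clipped = [int(l) for l in z_border if l > 0]
    if z_clipped:
        warnings.warn(f"objects truncated at z-borders: {sorted(set(z_clipped))}")
    for lab, info in labels.meta.get("per_label", {}).items():
        if info["candidates"] != info["seeds"]:
            flags[int(lab)].add("unresolved_merge")
    return {lab: frozenset(fl) for lab, fl in flags.items()}


# ---------------------------------------------------------------------------
# Measurement and statistics
# ---------------------------------------------------------------------------


def measure_volumes(
    labels: LabelMap,
    voxel_size: tuple[float, float, float] | None = None,
    flags: dict[int, frozenset[str]] | None = None,
) -> list[NucleusMeasurement]:
    """Volume and centroid of every labelled 3D object.

    Volume is voxel count times the physical voxel volume; centroids are
    in physical (z, y, x) um coordinates.  Flags from
    :func:`filter_objects` are attached when provided.
    """
    arr = labels.labels
    if arr.ndim != 3:
        raise ValueError("measure_volumes requires a 3D label map")
    vs = tuple(voxel_size) if voxel_size is not None else tuple(labels.scale)
    voxvol = float(np.prod(vs))
    n = int(arr.max())
    if n == 0:
        return []
    counts = np.bincount(arr.ravel(), minlength=n + 1)
    centroids = ndimage.center_of_mass(np.ones_like(arr), arr, range(1, n + 1))
    flags = flags or {}
    out = []
    for lab in range(1, n + 1):
        if counts[lab] == 0:
            continue
        c = tuple(float(ci * si) for ci, si in zip(centroids[lab - 1], vs))
        out.append(
            NucleusMeasurement(
                label=lab,
                volume=float(counts[lab] * voxvol),
                centroid=c,
                flags=flags.get(lab, frozenset()),
            )
        )
    return out


def measure_shapes_2d(
    labels: LabelMap,
    flags: dict[int, frozenset[str]] | None = None,
) -> list[NucleusMeasurement]:
    """Area, perimeter and circularity of every labelled 2D object."""
    arr = labels.labels
    if arr.ndim != 2:
        raise ValueError("measure_shapes_2d requires a 2D label map")
    ps = float(labels.scale)
    flags = flags or {}
    out = []
    for lab in range(1, int(arr.max()) + 1):
        mask = arr == lab
        n_px = int(mask.sum())
        if n_px == 0:
            continue
        area = n_px * ps**2
        perim = perimeter_crofton(mask, directions=4) * ps
        cy, cx = ndimage.center_of_mass(mask)
        out.append(
            NucleusMeasurement(
                label=lab,
                area=area,
                perimeter=perim,
                circularity=float(4 * np.pi * area / perim**2) if n_px >= 9 else None,
                centroid=(cy * ps, cx * ps),
                flags=flags.get(lab, frozenset()),
            )
        )
    return out


def nuclear_stats(
    measurements: list[NucleusMeasurement],
    other: list[NucleusMeasurement] | None = None,
    attr: str = "volume",
) -> dict:
    """Population summary (n, mean, SD, median) of one morphometric value.

    Flagged objects are excluded.  When a second group is given, the two
    are compared by a two-tailed unpaired t-test and the summary carries
    the t statistic and p value.
    """

    def _values(ms: list[NucleusMeasurement]) -> np.ndarray:
        vals = [getattr(m, attr) for m in ms if not m.flags and getattr(m, attr) is not None]
        return np.asarray(vals, dtype=float)

    a = _values(measurements)
    if a.size < 2:
        raise ValueError("need at least 2 unflagged objects for population statistics")
    summary = {
        "n": int(a.size),
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)),
        "median": float(np.median(a)),
    }
    if other is not None:
        b = _values(other)
        if b.size < 2:
            raise ValueError("comparison group needs at least 2 unflagged objects")
        t, p = stats.ttest_ind(a, b)
        summary["comparison"] = {
            "n_other": int(b.size),
            "mean_other": float(b.mean()),
            "sd_other": float(b.std(ddof=1)),
            "t": float(t),
            "p": float(p),
        }
    return summary


def measure_nuclei_stack(
    stack: VoxelGrid,
    params: SegmentationParams | None = None,
) -> list[NucleusMeasurement]:
    """Segment, quality-filter and measure one z-stack in a single call."""
    labels = segment_nuclei_3d(stack, params)
    flags = filter_objects(labels)
    return measure_volumes(labels, flags=flags)


def measurements_to_csv(measurements: list[NucleusMeasurement], path) -> None:
    """Write measurements as the standard CSV layout."""
    import pandas as pd

    rows = []
    for m in measurements:
        c = list(m.centroid) + [np.nan] * (3 - len(m.centroid))
        rows.append(
            {
                "label": m.label,
                "volume_um3": m.volume,
                "area_um2": m.area,
                "perimeter_um": m.perimeter,
                "circularity": m.circularity,
                "cx": c[-1],
                "cy": c[-2],
                "cz": c[0] if len(m.centroid) == 3 else np.nan,
                "flags": ";".join(sorted(m.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
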
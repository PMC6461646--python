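"""DNase I digestion gel densitometry.

Partial DNase I digestion of nuclei probes chromatin accessibility: at a
matched enzyme dose, more accessible chromatin is cut into smaller DNA
fragments, visible as a downward shift of the lane smear on an agarose
gel.  This module turns a gel image into quantitative fragment-size
distributions:

* lane intensity profiles normalized as ``I = (I_n - I_b) / I_total``
  where ``I_n`` is the intensity at gel position n, ``I_b`` the
  background, and ``I_total`` the sum of ``I_n - I_b`` over the lane, so
  every non-empty lane integrates to exactly 1;
* a ladder-based monotone migration -> fragment-size calibration
  (piecewise-linear in log10 size; no extrapolation beyond the ladder);
* re-binning of lane mass onto a log-size axis, and accessibility
  summaries comparing two lanes (median size, mass fraction below a
  cutoff).

The mobility model is an empirical log-linear interpolation, not a
physical migration model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core_io import Image2D, _log

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LaneProfile:
    """Intensity-vs-migration profile of one gel lane.

    ``positions`` are migration distances in px from the well (strictly
    increasing); ``normalized`` sums to 1 whenever the lane carries
    signal.  Negative background-subtracted values are clipped to zero
    before normalization and the clipped mass is reported.
    """

    positions: np.ndarray
    raw: np.ndarray
    background: np.ndarray | float
    normalized: np.ndarray
    I_total: float
    clipped_mass: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class SizeCalibration:
    """Monotone migration-position -> fragment-size map from a ladder.

    Valid only within the ladder span; queries outside return NaN and are
    flagged by callers.  Internally linear in (position, log10 size).
    """

    ladder_positions: np.ndarray
    ladder_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.ladder_positions = np.asarray(self.ladder_positions, dtype=float)
        self.ladder_sizes = np.asarray(self.ladder_sizes, dtype=float)
        if self.ladder_positions.size != self.ladder_sizes.size:
            raise ValueError("ladder positions and sizes must pair up")
        if self.ladder_positions.size < 2:
            raise ValueError("need at least two ladder bands")
        if np.any(np.diff(self.ladder_positions) <= 0):
            raise ValueError("ladder band positions must strictly increase")
        if np.any(np.diff(self.ladder_sizes) >= 0):
            raise ValueError("fragment size must strictly decrease with migration distance")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ladder_positions[0]), float(self.ladder_positions[-1])

    def position_to_size(self, positions: np.ndarray | float) -> np.ndarray:
        """Map migration positions to fragment sizes (bp); NaN outside the span."""
        pos = np.atleast_1d(np.asarray(positions, dtype=float))
        logsize = np.interp(pos, self.ladder_positions, np.log10(self.ladder_sizes))
        out = 10.0**logsize
        out[(pos < self.ladder_positions[0]) | (pos > self.ladder_positions[-1])] = np.nan
        return out if np.ndim(positions) else out  # always an array


@dataclass
class SizeDistribution:
    """Fragment-size mass distribution on a log10-size grid.

    ``mass`` is the normalized lane mass falling in each bin (sums to the
    in-span fraction of the lane); ``density`` is mass per unit log10
    size (Jacobian-corrected), for plotting.
    """

    bin_edges_bp: np.ndarray
    mass: np.ndarray
    out_of_span_mass: float = 0.0

    @property
    def bin_centers_bp(self) -> np.ndarray:
        e = np.log10(self.bin_edges_bp)
        return 10.0 ** ((e[:-1] + e[1:]) / 2)

    @property
    def density(self) -> np.ndarray:
        widths = np.diff(np.log10(self.bin_edges_bp))
        return self.mass / widths


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_lane_profile(
    gel: Image2D,
    lane: tuple[int, int, int, int],
    background: str | float = "flank",
    flank_px: int = 5,
    axis: str = "vertical",
    rolling_radius: float = 50.0,
) -> LaneProfile:
    """Extract and normalize the intensity profile of one lane.

    ``lane`` is an ``(x0, y0, width, height)`` rectangle; the migration
    axis is vertical by default (wells at top).  The raw profile is the
    per-row mean across the lane width.  Background is, per the default,
    the mean of the two flanking inter-lane strips of ``flank_px``
    columns ("flank"); alternatives are a fixed scalar or per-row
    rolling-ball ("rolling-ball").  Normalization follows
    ``I = (I_n - I_b) / I_total`` with negative values clipped to zero
    before summation.
    """
    px = gel.pixels if axis == "vertical" else gel.pixels.T
    H, W = px.shape
    x0, y0, w, h = lane
    if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
        raise ValueError(f"lane rectangle {lane} outside gel image {W}x{H}")
    strip = px[y0 : y0 + h, x0 : x0 + w]
    raw = strip.mean(axis=1)
    positions = np.arange(y0, y0 + h, dtype=float)

    bg: np.ndarray | float
    if background == "flank":
        flanks = []
        if x0 - flank_px >= 0:
            flanks.append(px[y0 : y0 + h, x0 - flank_px : x0])
        if x0 + w + flank_px <= W:
            flanks.append(px[y0 : y0 + h, x0 + w : x0 + w + flank_px])
        if not flanks:
            raise ValueError("no room for flanking background strips beside the lane")
        bg = float(np.mean([f.mean() for f in flanks]))
    elif background == "rolling-ball":
        from skimage.restoration import rolling_ball

        bg = rolling_ball(raw[:, None], radius=rolling_radius)[:, 0]
    else:
        bg = float(background)
        if bg < 0:
            raise ValueError("constant background must be non-negative")

    net = raw - bg
    clipped = float(-net[net < 0].sum())
    net = np.clip(net, 0.0, None)
    I_total = float(net.sum())
    if I_total <= 0:
        raise ValueError("empty lane: total background-subtracted intensity is not positive")
    _log("extract_lane_profile", lane=list(lane), background=background,
         I_total=I_total, clipped_mass=clipped / I_total if I_total else 0.0)
    return LaneProfile(positions=positions, raw=raw, background=bg,
                       normalized=net / I_total, I_total=I_total,
                       clipped_mass=clipped / I_total)


def detect_bands(profile: LaneProfile, smooth_px: float = 2.0,
                 prominence_frac: float = 0.05) -> np.ndarray:
    """Band positions as local maxima of the smoothed normalized profile.

    Peaks need a prominence of at least ``prominence_frac`` of the profile
    maximum; ties and plateaus resolve to the smallest position
    (deterministic).  Returns positions in px, ascending.
    """
    y = ndimage.gaussian_filter1d(profile.normalized, smooth_px)
    peaks, _ = signal.find_peaks(y, prominence=prominence_frac * y.max())
    return profile.positions[peaks]


def calibrate_sizes(ladder: LaneProfile, sizes: list[float], **detect_kw) -> SizeCalibration:
    """Fit the migration -> size map from a ladder lane.

    Detected band count must match the supplied size list; sizes are
    assigned largest-first (largest fragment migrates least).
    """
    sizes = np.sort(np.asarray(sizes, dtype=float))[::-1]
    bands = detect_bands(ladder, **detect_kw)
    if bands.size != sizes.size:
        raise ValueError(
            f"detected {bands.size} ladder bands but {sizes.size} sizes were given"
        )
    return SizeCalibration(ladder_positions=bands, ladder_sizes=sizes)


def size_distribution(
    profile: LaneProfile,
    cal: SizeCalibration,
    n_bins: int = 60,
) -> SizeDistribution:
    """Re-bin normalized lane mass onto a log10 fragment-size axis.

    Each profile position carries a discrete mass; the position -> size
    map assigns it to a log-size bin, so total in-span mass is conserved
    exactly and the reported per-bin ``density`` (mass / Delta log10 size)
    absorbs the Jacobian of the nonlinear migration map.  More than 20% of
    mass outside the calibration span triggers a warning.
    """
    sizes = cal.position_to_size(profile.positions)
    in_span = np.isfinite(sizes)
    out_mass = float(profile.normalized[~in_span].sum())
    if out_mass > 0.2:
        warnings.warn(
            f"{out_mass:.0%} of lane mass lies outside the ladder span; "
            "distribution covers the remainder only"
        )
    lo, hi = np.log10(cal.ladder_sizes[-1]), np.log10(cal.ladder_sizes[0])
    edges = np.logspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, sizes[in_span], side="right") - 1, 0, n_bins - 1)
    mass = np.bincount(idx, weights=profile.normalized[in_span], minlength=n_bins)
    return SizeDistribution(bin_edges_bp=edges, mass=mass, out_of_span_mass=out_mass)


def accessibility_summary(
    dist_a: SizeDistribution,
    dist_b: SizeDistribution,
    size_threshold_bp: float = 500.0,
) -> dict:
    """Compare two fragment-size distributions as accessibility readouts.

    At a matched DNase dose, more digestion (smaller fragments) means more
    accessible chromatin, so the accessibility score is the mass fraction
    below ``size_threshold_bp``.  Reports per-lane median fragment size,
    the score, and A - B differences.
    """
    if (dist_a.bin_edges_bp.shape != dist_b.bin_edges_bp.shape
            or not np.allclose(dist_a.bin_edges_bp, dist_b.bin_edges_bp)):
        raise ValueError("distributions must share one size grid")

    def _median(d: SizeDistribution) -> float:
        total = d.mass.sum()
        if total <= 0:
            return np.nan
        cum = np.cumsum(d.mass) / total
        i = int(np.searchsorted(cum, 0.5))
        return float(d.bin_centers_bp[min(i, d.mass.size - 1)])

    def _score(d: SizeDistribution) -> float:
        total = d.mass.sum()
        if total <= 0:
            return np.nan
        centers = d.bin_centers_bp
        return float(d.mass[centers < size_threshold_bp].sum() / total)

    med_a, med_b = _median(dist_a), _median(dist_b)
    sc_a, sc_b = _score(dist_a), _score(dist_b)
    return {
        "median_bp_a": med_a, "median_bp_b": med_b,
        "median_bp_diff": med_a - med_b,
        "size_threshold_bp": size_threshold_bp,
        "accessibility_a": sc_a, "accessibility_b": sc_b,
        "accessibility_diff": sc_a - sc_b,
    }
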
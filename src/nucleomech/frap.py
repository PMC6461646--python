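"""FRAP double normalization and recovery statistics.

A FRAP experiment records three ROI traces: the bleached spot (ROI1), an
unbleached reference nucleus (ROI2) correcting for acquisition
photobleaching, and a background region (ROI3).  The double normalization
first computes, per frame,

    I_t = (ROI1_t - ROI3_t) / (ROI2_t - ROI3_t)

which removes background and acquisition photobleaching (any per-frame
multiplicative loss common to ROI1 and ROI2 cancels in the ratio), and
then rescales

    I = (I_t - I_4) / (I_ave - I_4)

where ``I_ave`` is the mean I_t of the pre-bleach frames (three in the
reference protocol) and ``I_4`` is the first post-bleach I_t.  By
construction I is exactly 0 at the first post-bleach frame and the
pre-bleach frames average exactly 1 -- pre-bleach frames are reported
through the same transform rather than forced to 1, so both anchors are
testable.

A single-exponential recovery model ``I(t) = m (1 - exp(-t / tau))`` over
the post-bleach frames (time zeroed at the first post-bleach frame)
provides scalar summaries: the mobile fraction ``m`` and the half-time
``tau * ln 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_io import Image2D, _log

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FrapSeries:
    """Raw three-ROI FRAP traces.

    ``times`` are seconds from the first acquisition and must be strictly
    increasing; the first ``n_prebleach`` frames precede the bleach, which
    lasts ``bleach_gap`` seconds (no frames are acquired during it).
    """

    times: np.ndarray
    roi1: np.ndarray
    roi2: np.ndarray
    roi3: np.ndarray
    n_prebleach: int = 3
    bleach_gap: float = 20.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi1 = np.asarray(self.roi1, dtype=float)
        self.roi2 = np.asarray(self.roi2, dtype=float)
        self.roi3 = np.asarray(self.roi3, dtype=float)
        n = self.times.size
        if not (self.roi1.size == self.roi2.size == self.roi3.size == n):
            raise ValueError("times and the three ROI traces must have equal length")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.n_prebleach >= n:
            raise ValueError("series has no post-bleach frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.roi2 <= self.roi3):
            raise ValueError("reference ROI2 must exceed background ROI3 at every frame")


@dataclass
class FrapCurve:
    """Double-normalized recovery curve.

    ``I`` includes the pre-bleach frames (transformed like the rest);
    ``I_ave`` and ``I_4`` are the normalization anchors on the I_t scale.
    """

    times: np.ndarray
    I: np.ndarray
    I_ave: float
    I_4: float
    n_prebleach: int = 3


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_frap(series: FrapSeries) -> FrapCurve:
    """Apply the double normalization to a raw FRAP series.

    Raises if no bleach is detectable (``I_ave <= I_4``): the rescaling
    would be degenerate or flip the curve's sense.
    """
    I_t = (series.roi1 - series.roi3) / (series.roi2 - series.roi3)
    npre = series.n_prebleach
    I_ave = float(I_t[:npre].mean())
    I_4 = float(I_t[npre])
    if I_ave <= I_4:
        raise ValueError(
            f"no detectable bleach: pre-bleach mean I_t ({I_ave:.4f}) "
            f"does not exceed first post-bleach I_t ({I_4:.4f})"
        )
    I = (I_t - I_4) / (I_ave - I_4)
    _log("normalize_frap", I_ave=I_ave, I_4=I_4, n_prebleach=npre)
    return FrapCurve(times=series.times.copy(), I=I, I_ave=I_ave, I_4=I_4, n_prebleach=npre)


def recovery_stats(curve: FrapCurve) -> dict:
    """Mobile fraction and half-time from a single-exponential fit.

    Fits ``I(t') = m (1 - exp(-t'/tau))`` over the post-bleach frames by
    least squares, with t' zeroed at the first post-bleach frame (original
    timestamps are preserved on the curve).  Mobile fractions above 1 are
    physically suspect and flagged; above 1.2 the fit is rejected.
    """
    npre = curve.n_prebleach
    t = curve.times[npre:] - curve.times[npre]
    y = curve.I[npre:]
    if t.size < 10:
        raise ValueError("need at least 10 post-bleach frames for a recovery fit")

    if np.allclose(y, 0.0, atol=1e-12):  # immobile sample: exact degenerate case
        return {"mobile_fraction": 0.0, "half_time_s": np.nan, "tau_s": np.nan,
                "rmse": 0.0, "flagged": False}

    def model(tt, m, tau):
        return m * (1.0 - np.exp(-tt / tau))

    m0 = float(np.clip(np.mean(y[-3:]), 1e-3, 1.2))
    above = np.nonzero(y >= 0.5 * m0)[0]
    tau0 = float(t[above[0]] / np.log(2)) if above.size and t[above[0]] > 0 else max(t[-1] / 5, 1e-3)
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=(m0, tau0), bounds=([0.0, 1e-6], [1.5, np.inf]), maxfev=10000
        )
    except RuntimeError as err:
        resid = y - model(t, m0, tau0)
        raise ValueError(
            f"recovery fit did not converge (initial-guess RMS residual "
            f"{float(np.sqrt(np.mean(resid**2))):.4f})"
        ) from err
    m, tau = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((y - model(t, m, tau)) ** 2)))
    if m > 1.2:
        raise ValueError(f"implausible mobile fraction {m:.3f} > 1.2 (rmse {rmse:.4f})")
    flagged = m > 1.0
    if flagged:
        warnings.warn(f"mobile fraction {m:.3f} exceeds 1; check normalization anchors")
    _log("recovery_stats", mobile_fraction=m, tau_s=tau, rmse=rmse)
    return {"mobile_fraction": m, "half_time_s": tau * np.log(2), "tau_s": tau,
            "rmse": rmse, "flagged": flagged}


def extract_rois_from_images(
    frames: list[Image2D],
    times: np.ndarray,
    rois: dict[str, tuple[int, int, int, int]],
    n_prebleach: int = 3,
    bleach_gap: float = 20.0,
) -> FrapSeries:
    """Build a :class:`FrapSeries` from an image time series and ROI rectangles.

    ``rois`` maps ``"roi1"``, ``"roi2"``, ``"roi3"`` to ``(x0, y0, width,
    height)`` rectangles (0-based pixels).  ROI1 and ROI2 must not overlap
    and all rectangles must lie inside the frames.  The acquisition
    schedule is taken from the supplied timestamps, never assumed.
    """
    times = np.asarray(times, dtype=float)
    if len(frames) != times.size:
        raise ValueError("one timestamp per frame required")
    H, W = frames[0].shape
    rects = {}
    for name in ("roi1", "roi2", "roi3"):
        if name not in rois:
            raise ValueError(f"missing ROI rectangle {name!r}")
        x0, y0, w, h = rois[name]
        if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
            raise ValueError(f"{name} rectangle {rois[name]} outside image {W}x{H}")
        rects[name] = (slice(y0, y0 + h), slice(x0, x0 + w))

    def _overlap(a, b):
        return not (a[0].stop <= b[0].start or b[0].stop <= a[0].start
                    or a[1].stop <= b[1].start or b[1].stop <= a[1].start)

    if _overlap(rects["roi1"], rects["roi2"]):
        raise ValueError("ROI1 (bleach) and ROI2 (reference) must not overlap")

    traces = {name: np.array([f.pixels[sl].mean() for f in frames])
              for name, sl in rects.items()}
    return FrapSeries(times=times, roi1=traces["roi1"], roi2=traces["roi2"],
                      roi3=traces["roi3"], n_prebleach=n_prebleach, bleach_gap=bleach_gap)


def read_frap_csv(path, n_prebleach: int = 3, bleach_gap: float = 20.0) -> FrapSeries:
    """Read a (time_s, roi1, roi2, roi3) CSV with header into a series."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    need = ["time_s", "roi1", "roi2", "roi3"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise ValueError(f"FRAP CSV missing columns {missing}; found {list(df.columns)}")
    return FrapSeries(
        times=df[cols["time_s"]].to_numpy(),
        roi1=df[cols["roi1"]].to_numpy(),
        roi2=df[cols["roi2"]].to_numpy(),
        roi3=df[cols["roi3"]].to_numpy(),
        n_prebleach=n_prebleach,
        bleach_gap=bleach_gap,
    )
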
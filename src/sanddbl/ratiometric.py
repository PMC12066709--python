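"""Ratiometric O2 imaging: Stern-Volmer calibration, concentration maps and
pixel-wise volumetric O2 production/consumption rates.

Sensor particles carry an O2-quenched indicator dye (red emission) and an
O2-insensitive reference dye (green). The ratio ``red / green`` compensates
bleaching and uneven illumination and maps to O2 concentration through the
Stern-Volmer relation

    R0 / R(C) = 1 + K_sv * C                      (simple)
    R(C) = R0 * (f / (1 + K_sv * C) + (1 - f))    (two-site)

Rates follow from the concentration difference between two imaging time
points divided by the elapsed time (hours); negative = net consumption.
Post-processing mirrors the standard workflow: outlier thresholding, a 5x5
median filter, and masking of phototrophs by chlorophyll-a autofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import generic_filter
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

__all__ = [
    "RatioStack",
    "CalibrationCurve",
    "RateMap",
    "average_frames",
    "compute_ratio",
    "fit_calibration",
    "rate_map",
    "patch_statistics",
]


@dataclass
class RatioStack:
    """Timed two-channel image series.

    ``times_h`` are strictly increasing acquisition times in hours; ``red``
    and ``green`` are (n_frames, ny, nx) stacks of non-negative intensities.
    """

    times_h: np.ndarray
    red: np.ndarray
    green: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.red.shape != self.green.shape:
            raise ValueError("red and green stacks must have the same shape")
        if self.red.shape[0] != self.times_h.size:
            raise ValueError("one red/green frame pair per time point required")
        if np.any(self.red < 0) or np.any(self.green < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.times_h.size)


@dataclass
class CalibrationCurve:
    """Fitted Stern-Volmer calibration mapping ratio <-> O2 concentration."""

    model: Literal["simple", "two-site"]
    R0: float
    K_sv: float  # (umol/L)^-1
    f: float = 1.0
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.K_sv <= 0:
            raise ValueError("R0 and K_sv must be positive")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("accessible fraction f must lie in (0, 1]")

    def ratio(self, o2_umol_L: np.ndarray | float) -> np.ndarray | float:
        """Forward model: ratio expected at O2 concentration(s)."""
        c = np.asarray(o2_umol_L, dtype=float)
        out = self.R0 * (self.f / (1.0 + self.K_sv * c) + (1.0 - self.f))
        return out if c.ndim else float(out)

    def o2(self, ratio: np.ndarray | float) -> np.ndarray | float:
        """Inverse map: O2 concentration (umol/L) from a ratio.

        Ratios outside the physically reachable range map to NaN (above R0)
        or +inf-clipped NaN (below the f<1 plateau).
        """
        r = np.asarray(ratio, dtype=float)
        q = r / self.R0
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = q - (1.0 - self.f)
            c = (self.f / denom - 1.0) / self.K_sv
        c = np.where(denom > 0, c, np.nan)
        c = np.where(c < 0, np.nan, c)
        return c if r.ndim else float(c)


@dataclass
class RateMap:
    """Pixel-wise volumetric O2 rate (umol O2 L^-1 h^-1; negative = consumption)."""

    rate: np.ndarray
    valid_mask: np.ndarray
    chl_mask: np.ndarray | None = None
    pixel_size_um: float = 1.0


def average_frames(images: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel arithmetic mean of replicate exposures at one time point."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    arrs = [np.asarray(im, dtype=float) for im in images]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all images must share the same shape")
    return np.mean(arrs, axis=0)


def compute_ratio(
    red: np.ndarray, green: np.ndarray, green_floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise red/green ratio with a validity mask.

    Pixels whose green (reference) intensity is at or below ``green_floor``
    are flagged invalid (ratio NaN) rather than propagating infinities.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("red and green images must have the same shape")
    valid = green > green_floor
    ratio = np.full(red.shape, np.nan)
    np.divide(red, green, out=ratio, where=valid)
    return ratio, valid


def fit_calibration(
    o2_umol_L: Sequence[float],
    ratios: Sequence[float],
    model: Literal["simple", "two-site"] = "simple",
) -> CalibrationCurve:
    """Least-squares Stern-Volmer fit of a calibration table.

    Requires at least three points spanning from near-zero O2 towards air
    saturation, with ratio strictly decreasing in O2 (quenching).
    """
    c = np.asarray(o2_umol_L, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.size < 3:
        raise ValueError("need at least three calibration points")
    order = np.argsort(c)
    c, r = c[order], r[order]
    if np.any(np.diff(r) >= 0):
        raise ValueError("calibration table must be strictly monotone (quenching)")

    if model == "simple":
        def fwd(cc, R0, Ksv):
            return R0 / (1.0 + Ksv * cc)
        p0 = (r.max(), 1.0 / max(c.max(), 1.0))
        popt, _ = curve_fit(fwd, c, r, p0=p0, maxfev=10000)
        curve = CalibrationCurve("simple", R0=popt[0], K_sv=popt[1])
    elif model == "two-site":
        def fwd(cc, R0, Ksv, f):
            return R0 * (f / (1.0 + Ksv * cc) + (1.0 - f))
        p0 = (r.max(), 1.0 / max(c.max(), 1.0), 0.9)
        popt, _ = curve_fit(
            fwd, c, r, p0=p0, bounds=([1e-12, 1e-12, 1e-6], [np.inf, np.inf, 1.0]),
            maxfev=20000,
        )
        curve = CalibrationCurve("two-site", R0=popt[0], K_sv=popt[1], f=popt[2])
    else:
        raise ValueError(f"unknown calibration model {model!r}")

    pred = curve.ratio(c)
    curve.fit_residual = float(np.sqrt(np.mean((pred - r) ** 2)))
    return curve


def _nanmedian_filter(arr: np.ndarray, size: int) -> np.ndarray:
    return generic_filter(arr, np.nanmedian, size=size, mode="reflect")


def rate_map(
    stack: RatioStack,
    calibration: CalibrationCurve,
    t0_index: int = 0,
    t1_index: int = -1,
    outlier_threshold: float = 500.0,
    chl_image: np.ndarray | None = None,
    chl_threshold: float | None = None,
    median_size: int = 5,
    green_floor: float = 0.0,
) -> RateMap:
    """Volumetric O2 rate map between two time points of a ratio stack.

    Per pixel: O2 at t0 and t1 from the calibrated ratio, difference divided
    by the elapsed time (hours). Rates beyond ``outlier_threshold`` in
    magnitude are invalidated before a ``median_size`` x ``median_size``
    median filter (reflective borders, NaN-aware). The chlorophyll mask marks
    phototroph pixels: autofluorescence above ``chl_threshold`` (Otsu's
    threshold when not given).
    """
    t0 = stack.times_h[t0_index]
    t1 = stack.times_h[t1_index]
    if t1 <= t0:
        raise ValueError("t1 must be after t0")

    ratio0, v0 = compute_ratio(stack.red[t0_index], stack.green[t0_index], green_floor)
    ratio1, v1 = compute_ratio(stack.red[t1_index], stack.green[t1_index], green_floor)
    c0 = calibration.o2(ratio0)
    c1 = calibration.o2(ratio1)
    rate = (c1 - c0) / (t1 - t0)

    valid = v0 & v1 & np.isfinite(rate)
    valid &= np.abs(np.where(np.isfinite(rate), rate, np.inf)) <= outlier_threshold
    rate = np.where(valid, rate, np.nan)
    if median_size and median_size > 1:
        rate = _nanmedian_filter(rate, median_size)

    chl_mask = None
    if chl_image is not None:
        chl = np.asarray(chl_image, dtype=float)
        if chl.shape != rate.shape:
            raise ValueError("chlorophyll image shape must match the stack")
        thr = threshold_otsu(chl) if chl_threshold is None else chl_threshold
        chl_mask = chl > thr

    return RateMap(
        rate=rate,
        valid_mask=valid & np.isfinite(rate),
        chl_mask=chl_mask,
        pixel_size_um=stack.pixel_size_um,
    )


def patch_statistics(rmap: RateMap) -> dict:
    """Median and quartile O2 rates for phototroph / non-phototroph pixels.

    Returns a dict with keys ``"chl_positive"``, ``"chl_negative"`` and
    ``"all"``; each holds ``{"median", "q25", "q75", "n"}`` over valid pixels,
    or ``None`` when the class has no valid pixels.
    """
    def stats(values: np.ndarray) -> dict | None:
        values = values[np.isfinite(values)]
        if values.size == 0:
            return None
        q25, med, q75 = np.percentile(values, [25, 50, 75])
        return {"median": float(med), "q25": float(q25), "q75": float(q75),
                "n": int(values.size)}

    rate = rmap.rate
    valid = rmap.valid_mask
    out = {"all": stats(rate[valid])}
    if rmap.chl_mask is not None:
        out["chl_positive"] = stats(rate[valid & rmap.chl_mask])
        out["chl_negative"] = stats(rate[valid & ~rmap.chl_mask])
    else:
        out["chl_positive"] = None
        out["chl_negative"] = stats(rate[valid])
    return out
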
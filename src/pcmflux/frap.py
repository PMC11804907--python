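"""FRAP analysis: bleach correction, tracking, recovery curves, kymographs.

A FRAP movie is reduced to a normalized recovery curve by (1) correcting
global acquisition photobleaching with a single-exponential fit to the mean
intensity outside the bleached region, (2) tracking the bleached centrosome
so the measurement ROI follows it, (3) summing a circular ROI and applying
full-scale normalization (prebleach mean -> 1, first post-bleach value ->
0), and (4) fitting one-phase association
``Y(t) = Y0 + (plateau - Y0) * (1 - exp(-K t))``, from which the half-time
``t_half = ln 2 / K`` and the mobile fraction ``(plateau - Y0)/(1 - Y0)``
follow. Kymographs (distance-along-line x time) and paired-centrosome
redistribution (decline of the unbleached partner) are computed from the
same corrected stacks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "FRAPCurve",
    "FRAPFit",
    "Kymograph",
    "bleach_correct",
    "track_object",
    "recovery_curve",
    "fit_one_phase_association",
    "make_kymograph",
    "partner_redistribution",
]


@dataclass
class FRAPCurve:
    """A normalized fluorescence recovery time series (bleach at t = 0)."""

    times_s: np.ndarray
    normalized_intensity: np.ndarray
    raw_intensity: np.ndarray
    roi_radius_px: float
    n_prebleach_frames: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class FRAPFit:
    """One-phase-association fit parameters with standard errors."""

    Y0: float
    plateau: float
    K: float
    Y0_se: float
    plateau_se: float
    K_se: float
    success: bool

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.K

    @property
    def mobile_fraction(self) -> float:
        return (self.plateau - self.Y0) / (1.0 - self.Y0)


@dataclass
class Kymograph:
    """Space-time image sampled along a line (rows: distance, cols: time)."""

    data: np.ndarray
    line_endpoints_px: tuple[tuple[float, float], tuple[float, float]]
    width_px: int
    pixel_size_nm: float
    frame_interval_s: float


def bleach_correct(
    stack: np.ndarray,
    exclude_mask: np.ndarray,
    frame_interval_s: float = 1.0,
    offset: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Correct global acquisition photobleaching by a single-exponential fit.

    The mean intensity outside ``exclude_mask`` (minus a constant camera
    ``offset``) is fit to ``A exp(-lambda t)`` by weighted least squares on
    the log, and every frame is divided by the fitted decay. A fit that
    prefers growth is clipped to lambda = 0 with a warning. Returns the
    corrected stack and the fitted rate.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] < 10:
        raise ValueError("need at least 10 frames to fit bleaching")
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    keep = ~exclude_mask
    if not keep.any():
        raise ValueError("exclude_mask covers the whole frame")
    means = stack[:, keep].mean(axis=1) - offset
    if np.any(means <= 0):
        raise ValueError("non-positive mean intensity outside the mask")
    t = np.arange(stack.shape[0]) * frame_interval_s
    # weighted log-linear fit (weights ~ intensity, the Poisson-appropriate choice)
    wgt = means
    logy = np.log(means)
    A = np.column_stack([np.ones_like(t), -t])
    W = np.sqrt(wgt)
    coef, *_ = np.linalg.lstsq(A * W[:, None], logy * W, rcond=None)
    lam = float(coef[1])
    if lam < 0:
        warnings.warn("bleach fit prefers growth; clipping lambda to 0", stacklevel=2)
        lam = 0.0
    decay = np.exp(-lam * t)
    corrected = (stack - offset) / decay[:, None, None] + offset
    return corrected, lam


def track_object(
    stack: np.ndarray,
    start_position: tuple[float, float],
    search_radius_px: float,
    smooth_sigma_px: float = 1.5,
) -> tuple[np.ndarray, list[str]]:
    """Track one bright object frame to frame by local-maximum centroiding.

    Each frame's position is the intensity centroid around the brightest
    pixel within ``search_radius_px`` of the previous position; frames where
    no convincing maximum exists (e.g. immediately after bleaching) hold the
    previous position. Returns an (n_frames, 2) array of (y, x) positions
    and a flag list.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (t, y, x) array")
    ny, nx = stack.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    pos = np.empty((stack.shape[0], 2))
    prev = np.asarray(start_position, dtype=float)
    flags: list[str] = []
    r_refine = max(2, int(round(search_radius_px / 2)))
    for f in range(stack.shape[0]):
        frame = ndimage.gaussian_filter(stack[f], smooth_sigma_px, mode="nearest")
        sel = (yy - prev[0]) ** 2 + (xx - prev[1]) ** 2 <= search_radius_px**2
        if not sel.any():
            flags.append(f"frame {f}: search region outside image; track truncated")
            pos[f:] = prev
            break
        vals = np.where(sel, frame, -np.inf)
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
        peak = frame[iy, ix]
        bg = float(np.median(frame))
        spread = float(np.median(np.abs(frame - bg))) + 1e-12
        if peak < bg + 3.0 * spread:
            pos[f] = prev  # object dark (e.g. just bleached): hold position
            continue
        wsel = (yy - iy) ** 2 + (xx - ix) ** 2 <= r_refine**2
        w = np.clip(frame - bg, 0.0, None) * wsel
        m = w.sum()
        if m > 0:
            cy = float((w * yy).sum() / m)
            cx = float((w * xx).sum() / m)
        else:
            cy, cx = float(iy), float(ix)
        pos[f] = (cy, cx)
        prev = pos[f]
    return pos, flags


def _roi_sum(frame: np.ndarray, center: tuple[float, float], radius: float) -> float:
    ny, nx = frame.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    sel = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    return float(frame[sel].sum())


def recovery_curve(
    stack: np.ndarray,
    track: np.ndarray,
    bleach_frame: int,
    roi_radius_px: float,
    frame_interval_s: float = 1.0,
) -> FRAPCurve:
    """ROI-summed, full-scale-normalized recovery curve.

    ``F(t)`` is the circular-ROI sum following the track;
    normalization maps the prebleach mean to 1 and the first post-bleach
    value to 0: ``(F - F_bleach) / (F_pre - F_bleach)``. Times are shifted
    so the bleach frame is t = 0.
    """
    stack = np.asarray(stack, dtype=float)
    if bleach_frame < 2:
        raise ValueError("need at least 2 prebleach frames")
    raw = np.array(
        [_roi_sum(stack[f], tuple(track[f]), roi_radius_px) for f in range(stack.shape[0])]
    )
    f_pre = raw[:bleach_frame].mean()
    f_bleach = raw[bleach_frame]
    if f_pre <= f_bleach:
        raise ValueError("no bleach detected: prebleach mean <= first post-bleach value")
    norm = (raw - f_bleach) / (f_pre - f_bleach)
    times = (np.arange(stack.shape[0]) - bleach_frame) * frame_interval_s
    return FRAPCurve(
        times_s=times,
        normalized_intensity=norm,
        raw_intensity=raw,
        roi_radius_px=roi_radius_px,
        n_prebleach_frames=bleach_frame,
    )


def _one_phase(t, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def fit_one_phase_association(
    curve: FRAPCurve | tuple[np.ndarray, np.ndarray],
    max_rate_per_s: float | None = None,
) -> FRAPFit:
    """Least-squares one-phase-association fit on the post-bleach points.

    K is multi-started from the observed half-rise time (and decade
    variations around it) with bounds (0, ``max_rate_per_s``]; the best
    start by residual sum of squares wins. Standard errors come from the
    fit covariance. Non-convergence across all starts is reported via
    ``success=False`` rather than silent defaults.
    """
    if isinstance(curve, FRAPCurve):
        sel = curve.times_s >= 0
        t = curve.times_s[sel]
        y = curve.normalized_intensity[sel]
    else:
        t, y = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 post-bleach points")
    dt_min = np.diff(t).min()
    k_max = max_rate_per_s if max_rate_per_s is not None else 10.0 / dt_min

    y0_init = float(y[0])
    plat_init = float(np.mean(y[-max(3, len(y) // 10) :]))
    half = y0_init + 0.5 * (plat_init - y0_init)
    above = np.nonzero(y >= half)[0] if plat_init > y0_init else []
    t_half_guess = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] - t[0]) / 4
    k_init = math.log(2.0) / max(t_half_guess, dt_min)

    best = None
    for mult in (0.1, 0.3, 1.0, 3.0, 10.0):
        k0 = min(max(k_init * mult, 1e-8), k_max)
        try:
            popt, pcov = optimize.curve_fit(
                _one_phase,
                t,
                y,
                p0=[y0_init, plat_init, k0],
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, k_max]),
                maxfev=5000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((_one_phase(t, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return FRAPFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, success=False)
    _, popt, pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return FRAPFit(
        Y0=float(popt[0]),
        plateau=float(popt[1]),
        K=float(popt[2]),
        Y0_se=float(se[0]),
        plateau_se=float(se[1]),
        K_se=float(se[2]),
        success=True,
    )


def make_kymograph(
    stack: np.ndarray,
    line_endpoints_px: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
    pixel_size_nm: float = 100.0,
    frame_interval_s: float = 1.0,
) -> Kymograph:
    """Kymograph along a line: bilinear sampling at 1-px steps, averaged across width.

    For each frame, the line is sampled at unit spacing from the first to
    the second endpoint; ``width_px`` (odd) perpendicular offsets at unit
    spacing are averaged per sample.
    """
    stack = np.asarray(stack, dtype=float)
    (y0, x0), (y1, x1) = line_endpoints_px
    length = math.hypot(y1 - y0, x1 - x0)
    if length == 0:
        raise ValueError("degenerate zero-length line")
    if width_px % 2 == 0 or width_px < 1:
        raise ValueError("width_px must be odd and >= 1")
    n_samples = int(math.floor(length)) + 1
    s = np.linspace(0.0, length, n_samples)
    uy, ux = (y1 - y0) / length, (x1 - x0) / length
    py, px = -ux, uy  # unit perpendicular
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    ys = y0 + s[:, None] * uy + offsets[None, :] * py
    xs = x0 + s[:, None] * ux + offsets[None, :] * px
    coords = np.stack([ys.ravel(), xs.ravel()])
    data = np.empty((n_samples, stack.shape[0]))
    for f in range(stack.shape[0]):
        vals = ndimage.map_coordinates(stack[f], coords, order=1, mode="nearest")
        data[:, f] = vals.reshape(n_samples, width_px).mean(axis=1)
    return Kymograph(
        data=data,
        line_endpoints_px=line_endpoints_px,
        width_px=width_px,
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
    )


def partner_redistribution(
    stack: np.ndarray,
    bleached_track: np.ndarray,
    partner_track: np.ndarray,
    roi_radius_px: float,
    bleach_frame: int,
) -> tuple[np.ndarray, float]:
    """Unbleached-partner intensity series and its fractional loss.

    The partner's ROI sum is normalized to its prebleach mean; the returned
    statistic is ``1 - mean(final 10% of frames)`` (positive = the partner
    lost fluorescence, as expected when bleached molecules from the other
    centrosome mix in). ROIs must stay disjoint throughout.
    """
    stack = np.asarray(stack, dtype=float)
    d = np.hypot(
        bleached_track[:, 0] - partner_track[:, 0],
        bleached_track[:, 1] - partner_track[:, 1],
    )
    if np.any(d < 2 * roi_radius_px):
        raise ValueError("bleached and partner ROIs overlap")
    raw = np.array(
        [_roi_sum(stack[f], tuple(partner_track[f]), roi_radius_px) for f in range(stack.shape[0])]
    )
    pre = raw[:bleach_frame].mean()
    if pre <= 0:
        raise ValueError("partner prebleach intensity must be positive")
    series = raw / pre
    n_tail = max(1, int(round(0.1 * stack.shape[0])))
    loss = 1.0 - float(series[-n_tail:].mean())
    return series, loss
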
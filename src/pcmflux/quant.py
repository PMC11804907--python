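"""Centrosome and bead quantification in calibrated fluorescence images.

Implements the measurement chain used for scaffold quantification: maximum
z-projection, uneven-illumination background correction, Crocker-Grier
centroid detection, Otsu segmentation with per-object sum intensity and
area, centrosome-to-cytoplasm fold enrichment, and LoG-based bead
measurement.

Conventions: coordinates are (y, x), 0-based, with pixel centers at
integers; physical distances are derived via the pixel size in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Detection",
    "EnrichmentRecord",
    "correct_uneven_illumination",
    "max_project",
    "detect_centrosomes",
    "otsu_threshold",
    "measure_objects",
    "fold_enrichment",
    "measure_beads",
]

# 8-connectivity structuring element for segmentation labeling
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class Detection:
    """A detected object with optional segmentation-based measurements."""

    frame: int
    y: float
    x: float
    mass: float
    sum_intensity: float | None = None
    area_px: int | None = None
    mean_intensity: float | None = None
    label: int | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class EnrichmentRecord:
    """Fold enrichment of an object's mean intensity over the cytoplasm."""

    object_id: int
    fold_enrichment: float


def max_project(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along one axis (default: the first/z)."""
    stack = np.asarray(stack)
    if stack.ndim < 2 or stack.shape[axis] < 1:
        raise ValueError("stack must contain at least one slice")
    return stack.max(axis=axis)


def correct_uneven_illumination(
    image: np.ndarray,
    smoothing_scale_px: float,
    object_diameter_px: float | None = None,
) -> np.ndarray:
    """Subtract a smooth (Gaussian low-pass) background estimate, floored at 0.

    ``smoothing_scale_px`` should be much larger than the objects of
    interest (a warning is issued when an object diameter is supplied and
    the scale does not exceed it), so spots survive subtraction while slow
    illumination gradients and offsets are removed.
    """
    image = np.asarray(image, dtype=float)
    if smoothing_scale_px <= 0:
        raise ValueError("smoothing_scale_px must be > 0")
    if object_diameter_px is not None and smoothing_scale_px <= object_diameter_px:
        warnings.warn(
            "smoothing scale <= object diameter: background estimate may eat signal",
            stacklevel=2,
        )
    background = ndimage.gaussian_filter(image, smoothing_scale_px, mode="nearest")
    return np.clip(image - background, 0.0, None)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram bin edge maximizing between-class variance.

    The histogram spans [min, max] with ``n_bins`` bins; candidate
    thresholds are interior bin edges, ties broken toward the lower
    threshold. A constant image has no separable classes and raises.
    """
    image = np.asarray(image, dtype=float).ravel()
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("constant image: no separable classes")
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    omega0 = np.cumsum(p)  # weight of class below edge k+1
    mu_cum = np.cumsum(p * (np.arange(n_bins) + 0.5))  # in bin-index units
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[best + 1])


def _local_maxima(image: np.ndarray, size: int) -> np.ndarray:
    dil = ndimage.grey_dilation(image, size=(size, size), mode="constant")
    return (image == dil) & (image > 0)


def _disk_mask(radius: int) -> np.ndarray:
    ys, xs = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return ys**2 + xs**2 <= radius**2


def detect_centrosomes(
    image: np.ndarray,
    diameter_px: int,
    min_mass: float = 0.0,
    noise_sigma_px: float = 1.0,
) -> list[Detection]:
    """Crocker-Grier centroid detection of bright features.

    The image is band-passed (Gaussian smoothing at the noise scale minus a
    boxcar mean over the feature diameter), local maxima are found by
    grayscale dilation, and each candidate is refined by iterated centroid
    computation within a circular mask of radius diameter/2 (window re-
    centered while the offset exceeds 0.5 px). Duplicates within one radius
    keep the larger integrated mass; features below ``min_mass`` are
    dropped. Positions are subpixel.
    """
    if diameter_px % 2 == 0:
        raise ValueError("diameter_px must be odd")
    if diameter_px < 3:
        raise ValueError("diameter_px must be >= 3")
    image = np.asarray(image, dtype=float)
    radius = diameter_px // 2

    smoothed = ndimage.gaussian_filter(image, noise_sigma_px, mode="nearest")
    boxcar = ndimage.uniform_filter(image, diameter_px, mode="nearest")
    bp = np.clip(smoothed - boxcar, 0.0, None)

    mask = _disk_mask(radius)
    oy, ox = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    ny, nx = image.shape

    cands = np.argwhere(_local_maxima(bp, diameter_px))
    dets: list[Detection] = []
    for cy, cx in cands:
        y, x = int(cy), int(cx)
        # keep the refinement window fully inside the image
        y = min(max(y, radius), ny - 1 - radius)
        x = min(max(x, radius), nx - 1 - radius)
        off_y = off_x = 0.0
        for _ in range(10):
            win = bp[y - radius : y + radius + 1, x - radius : x + radius + 1]
            w = win * mask
            m = w.sum()
            if m <= 0:
                break
            off_y = float((w * oy).sum() / m)
            off_x = float((w * ox).sum() / m)
            if abs(off_y) <= 0.5 and abs(off_x) <= 0.5:
                break
            y = min(max(y + int(round(off_y)), radius), ny - 1 - radius)
            x = min(max(x + int(round(off_x)), radius), nx - 1 - radius)
        win = bp[y - radius : y + radius + 1, x - radius : x + radius + 1]
        m = float((win * mask).sum())
        if m <= 0 or m < min_mass:
            continue
        dets.append(Detection(frame=0, y=y + off_y, x=x + off_x, mass=m))

    # duplicate suppression: within one radius, keep the larger mass
    dets.sort(key=lambda d: -d.mass)
    kept: list[Detection] = []
    for d in dets:
        if all(math.hypot(d.y - k.y, d.x - k.x) >= radius for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def measure_objects(
    image: np.ndarray,
    threshold: float,
    detections: list[Detection],
) -> list[Detection]:
    """Fill per-detection sum intensity and area from Otsu-style segmentation.

    The segmented region of a detection is the 8-connected component of the
    supra-threshold mask containing its (rounded) centroid; ``area_px`` is
    the component's pixel count and ``sum_intensity`` the sum of image
    values over it. Detections landing on sub-threshold pixels get area 0
    and a ``subthreshold`` flag; detections sharing one component are
    flagged ``merged``.
    """
    image = np.asarray(image, dtype=float)
    labels, _ = ndimage.label(image > threshold, structure=_STRUCT8)
    by_label: dict[int, list[Detection]] = {}
    for det in detections:
        iy = int(round(det.y))
        ix = int(round(det.x))
        iy = min(max(iy, 0), image.shape[0] - 1)
        ix = min(max(ix, 0), image.shape[1] - 1)
        lab = int(labels[iy, ix])
        if lab == 0:
            det.area_px = 0
            det.sum_intensity = 0.0
            det.label = None
            if "subthreshold" not in det.flags:
                det.flags.append("subthreshold")
            continue
        region = labels == lab
        det.label = lab
        det.area_px = int(region.sum())
        det.sum_intensity = float(image[region].sum())
        det.mean_intensity = det.sum_intensity / det.area_px
        by_label.setdefault(lab, []).append(det)
    for shared in by_label.values():
        if len(shared) > 1:
            for det in shared:
                if "merged" not in det.flags:
                    det.flags.append("merged")
    return detections


def fold_enrichment(
    image: np.ndarray,
    object_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    object_id: int = 0,
) -> EnrichmentRecord:
    """Ratio of object mean pixel intensity to cytoplasm mean pixel intensity.

    Both means are taken on the same (consistently background-corrected)
    image, making the ratio independent of object area. The cytoplasm
    region must be disjoint from the object and have positive mean.
    """
    image = np.asarray(image, dtype=float)
    object_mask = np.asarray(object_mask, dtype=bool)
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if (object_mask & cytoplasm_mask).any():
        raise ValueError("cytoplasm region overlaps the object")
    if not object_mask.any() or not cytoplasm_mask.any():
        raise ValueError("empty object or cytoplasm region")
    cyto_mean = float(image[cytoplasm_mask].mean())
    if cyto_mean <= 0:
        raise ValueError("cytoplasm mean intensity must be > 0")
    obj_mean = float(image[object_mask].mean())
    return EnrichmentRecord(object_id=object_id, fold_enrichment=obj_mean / cyto_mean)


def measure_beads(
    image: np.ndarray,
    pixel_size_nm: float,
    estimated_diameter_um: float = 2.7,
    quality_threshold: float = 1.0,
) -> list[Detection]:
    """LoG-detect beads of a known diameter and measure their mean intensity.

    Detection uses the scale-normalized Laplacian-of-Gaussian at
    sigma = diameter / (2 sqrt 2); the mean intensity is then taken within a
    disc of the estimated diameter centered on each detection.
    """
    from .flux import detect_spots_log

    d_px = estimated_diameter_um * 1000.0 / pixel_size_nm
    if d_px < 3:
        raise ValueError("estimated diameter below 3 px at this pixel size")
    spots = detect_spots_log(image, pixel_size_nm, estimated_diameter_um, quality_threshold)
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    out = []
    r = d_px / 2.0
    for s in spots:
        disc = (yy - s.y) ** 2 + (xx - s.x) ** 2 <= r**2
        det = Detection(frame=s.frame, y=s.y, x=s.x, mass=s.quality)
        det.mean_intensity = float(image[disc].mean()) if disc.any() else 0.0
        det.area_px = int(disc.sum())
        out.append(det)
    return out
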
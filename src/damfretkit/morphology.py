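"""Morphology classification of protein assemblies from confocal images.

Workflow mirrors standard Fiji-style high-content analysis: pick the
brightest plane of a small z-stack, subtract background with a rolling ball
(radius 100 px), threshold with the ImageJ "Default" variant of the
iterative isodata intermeans algorithm, and measure each 8-connected object:
mean and SD of pixel intensity, CV = SD/mean * 100, and the aspect ratio
(AR) of the best-fit ellipse.  Objects are then classified from (CV, AR)
with one of two printed threshold sets:

set1: fibrillar  CV > 55 and AR > 1.159
      punctate   CV > 55 and AR < 1.16
      diffuse    CV < 55 and AR < 1.16
set2: fibrillar  CV > 17 and AR > 1.4
      punctate   CV > 17 and AR < 1.41
      diffuse    CV < 18 and AR < 1.41

Combinations the rules leave undefined (boundary slivers, or set1's
CV < 55 with AR > 1.16) are reported as "unclassified" rather than silently
assigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.restoration import rolling_ball

__all__ = [
    "MorphObject",
    "brightest_plane",
    "rolling_ball_subtract",
    "threshold_default",
    "object_stats",
    "classify_morphology",
    "classify_objects",
    "roi_cv_timecourse",
]

THRESHOLD_SETS = {
    "set1": {"cv_hi": 55.0, "cv_lo": 55.0, "ar_hi": 1.159, "ar_lo": 1.16},
    "set2": {"cv_hi": 17.0, "cv_lo": 18.0, "ar_hi": 1.4, "ar_lo": 1.41},
}


def brightest_plane(zstack) -> np.ndarray:
    """Plane of a z-stack with the largest summed signal (ties: lowest index)."""
    stack = np.asarray(zstack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("z-stack must be a nonempty (planes, y, x) array")
    sums = stack.reshape(stack.shape[0], -1).sum(axis=1)
    return stack[int(np.argmax(sums))]


def rolling_ball_subtract(image, radius: int = 100) -> np.ndarray:
    """Rolling-ball background subtraction; output clipped at zero."""
    img = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape):
        raise ValueError("radius must be smaller than the image")
    background = rolling_ball(img, radius=radius)
    return np.clip(img - background, 0.0, None)


def _ij_default_threshold_bin(hist: np.ndarray) -> int:
    """ImageJ 'Default' iterative intermeans on a 256-bin histogram.

    The intermeans midpoint is iterated upward from the lowest populated bin
    until it falls below the moving index.  The historical ImageJ trim of the
    first and last bins (meant for erased/saturated areas) is deliberately
    omitted: background-subtracted images concentrate their background in the
    lowest bin, which must stay in the balance.
    """
    h = np.asarray(hist, dtype=float)
    nz = np.flatnonzero(h)
    if nz.size == 0 or nz[0] >= nz[-1]:
        raise ValueError("constant image has no threshold")
    lo, hi = int(nz[0]), int(nz[-1])
    idx = np.arange(len(h), dtype=float)
    moving = lo
    while True:
        below = h[: moving + 1]
        above = h[moving + 1 :]
        mean_below = (idx[: moving + 1] * below).sum() / below.sum()
        mean_above = (idx[moving + 1 :] * above).sum() / above.sum()
        result = (mean_below + mean_above) / 2.0
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return int(round(result))


def threshold_default(image) -> tuple[np.ndarray, float]:
    """Binary mask of above-threshold pixels by the ImageJ Default method.

    The image is rescaled onto a 256-bin histogram (matching the 8-bit
    dialect of the original algorithm); the returned threshold is in the
    image's own intensity units.
    """
    img = np.asarray(image, dtype=float)
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise ValueError("constant image has no threshold")
    scaled = np.clip((img - vmin) / (vmax - vmin) * 255.0, 0, 255).astype(int)
    hist = np.bincount(scaled.ravel(), minlength=256)
    tbin = _ij_default_threshold_bin(hist)
    thr = vmin + (tbin + 0.5) / 256.0 * (vmax - vmin)
    return img > thr, thr


@dataclass(frozen=True)
class MorphObject:
    label: int
    area: int
    mean: float
    sd: float
    cv: float  # percent
    ar: float  # major/minor axis, >= 1
    centroid: tuple[float, float]


def object_stats(image, mask) -> list[MorphObject]:
    """Per-object intensity and shape statistics on 8-connected components.

    AR comes from the normalized second central moments (best-fit ellipse);
    single-pixel or otherwise degenerate components report AR = 1 and SD = 0.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    labels = sk_label(m, connectivity=2)
    if labels.max() == 0:
        raise ValueError("mask contains no objects")
    objs = []
    for rp in regionprops(labels, intensity_image=img):
        pix = img[labels == rp.label]
        mean = float(pix.mean())
        sd = float(pix.std(ddof=0))
        cv = sd / mean * 100.0 if mean != 0 else 0.0
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        ar = 1.0 if minor == 0 else float(major / minor)
        objs.append(
            MorphObject(
                label=int(rp.label),
                area=int(rp.area),
                mean=mean,
                sd=sd,
                cv=cv,
                ar=max(ar, 1.0),
                centroid=tuple(float(c) for c in rp.centroid),
            )
        )
    return objs


def classify_morphology(cv: float, ar: float, threshold_set: str = "set1") -> str:
    """Assign diffuse / punctate / fibrillar from (CV, AR).

    Exactly one printed rule must match; boundary gaps, the rules' small
    overlaps, and uncovered combinations return "unclassified".
    """
    t = THRESHOLD_SETS[threshold_set]
    matches = []
    if cv > t["cv_hi"] and ar > t["ar_hi"]:
        matches.append("fibrillar")
    if cv > t["cv_hi"] and ar < t["ar_lo"]:
        matches.append("punctate")
    if cv < t["cv_lo"] and ar < t["ar_lo"]:
        matches.append("diffuse")
    return matches[0] if len(matches) == 1 else "unclassified"


def classify_objects(
    image,
    radius: int = 100,
    threshold_set: str = "set1",
    subtract_background: bool = True,
    min_area: int = 5,
    max_foreground_fraction: float = 0.3,
) -> list[tuple[MorphObject, str]]:
    """Full image-to-classes pipeline on a single (already selected) plane.

    An image without credible objects (the threshold lands inside the
    background noise, flooding more than ``max_foreground_fraction`` of the
    pixels) yields an empty list, as do components below ``min_area`` px.
    """
    img = np.asarray(image, dtype=float)
    if subtract_background:
        img = rolling_ball_subtract(img, radius=radius)
    mask, _ = threshold_default(img)
    if mask.mean() > max_foreground_fraction or not mask.any():
        return []
    return [
        (obj, classify_morphology(obj.cv, obj.ar, threshold_set))
        for obj in object_stats(img, mask)
        if obj.area >= min_area
    ]


def roi_cv_timecourse(frames, rois) -> np.ndarray:
    """CV (percent) of fluorescence per ROI per frame.

    ``frames``: (t, y, x) array; ``rois``: list of boolean masks.  Cluster
    formation inside a cell manifests as a rising CV over time.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be a (t, y, x) array")
    out = np.empty((len(rois), stack.shape[0]))
    for i, roi in enumerate(rois):
        m = np.asarray(roi, dtype=bool)
        if m.shape != stack.shape[1:]:
            raise ValueError("ROI shape does not match the image")
        if not m.any():
            raise ValueError("empty ROI")
        for t in range(stack.shape[0]):
            pix = stack[t][m]
            mean = pix.mean()
            out[i, t] = 0.0 if mean == 0 else pix.std(ddof=0) / mean * 100.0
    return out
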
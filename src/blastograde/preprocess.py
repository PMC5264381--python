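"""Brightness standardisation and ICM pose normalisation.

Every micrograph is remapped to a common intensity scale (affine gain/offset
so the within-embryo mean and sd hit fixed targets) and rotated about the
embryo centre so that the inner cell mass sits at 12 o'clock.  Pose
normalisation makes downstream texture and region statistics comparable
across images regardless of how the embryo happened to lie under the
microscope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, remove_small_objects
from skimage.transform import rotate as _sk_rotate

from .errors import DegenerateInputError, IcmNotFoundError
from .synthgen import EmbryoCircle

TARGET_MEAN = 128.0
TARGET_SD = 30.0
# minimum brightness excess (intensity units) of an ICM candidate over the
# mean of the search disk; below this the image has no detectable ICM
ICM_MIN_CONTRAST = 10.0
# ICM search disk radius as a fraction of the embryo radius: the inner
# compartment plus a small allowance for boundary jitter
ICM_SEARCH_RADIUS = 0.78


@dataclass
class StandardizedImage:
    image: np.ndarray
    applied_gain: float
    applied_offset: float
    rotation_deg: float = 0.0


def _circle_mask(shape: tuple[int, int], circle: EmbryoCircle,
                 radius_scale: float = 1.0) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(cols - circle.cx, rows - circle.cy) <= circle.r * radius_scale


def standardize_brightness(image: np.ndarray,
                           target_mean: float = TARGET_MEAN,
                           target_sd: float = TARGET_SD,
                           circle: EmbryoCircle | None = None) -> StandardizedImage:
    """Affine intensity remap so the foreground mean/sd hit the targets.

    Statistics are taken inside the embryo circle when one is known,
    globally otherwise; the output is clipped to [0, 255].
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise DegenerateInputError("empty image")
    fg = img[_circle_mask(img.shape, circle)] if circle is not None else img
    mean = float(fg.mean())
    sd = float(fg.std())
    if sd < 1e-12:
        raise DegenerateInputError("constant image: zero intensity variance")
    gain = target_sd / sd
    offset = target_mean - gain * mean
    out = np.clip(gain * img + offset, 0, 255)
    return StandardizedImage(image=out.astype(np.uint8),
                             applied_gain=gain, applied_offset=offset)


def locate_icm_angle(image: np.ndarray, circle: EmbryoCircle) -> float:
    """Polar angle (degrees, 0 = up, clockwise) of the ICM candidate.

    The ICM is taken to be the brightest *compact* mass inside the embryo:
    Otsu-threshold the inner compartment (the disk inside the
    zona/trophectoderm ring, radius 0.78 r — the ICM sits there
    anatomically), label the connected components, score each by
    area x mean intensity x compactness (4*pi*area/perimeter^2) and return
    the centroid angle of the best.  The compactness factor suppresses any
    ring slivers that leak into the search disk.
    """
    img = np.asarray(image, dtype=float)
    # speckle is zero-mean: smoothing suppresses it before thresholding while
    # the ICM's brightness excess over the blastocoel survives
    smooth = gaussian_filter(img, sigma=2.5)
    mask = _circle_mask(img.shape, circle, radius_scale=ICM_SEARCH_RADIUS)
    vals = smooth[mask]
    if vals.size == 0:
        raise IcmNotFoundError("circle lies outside the image")
    if vals.std() < 1e-12:
        raise IcmNotFoundError("uniform interior: no ICM candidate")
    thr = threshold_otsu(vals)
    bright = (smooth > thr) & mask
    # repair fragmentation holes and drop residual noise blobs so compactness
    # scores the gross shape, not the texture
    bright = closing(bright, disk(2))
    bright = remove_small_objects(bright, max_size=24)
    img = smooth
    if not bright.any():
        raise IcmNotFoundError("no region above threshold")
    labels = label(bright)
    best_score, best_prop = -np.inf, None
    for prop in regionprops(labels, intensity_image=img):
        perim = max(prop.perimeter, 1.0)
        compact = min(4 * math.pi * prop.area / perim**2, 1.0)
        score = prop.area * prop.intensity_mean * compact
        if score > best_score:
            best_score, best_prop = score, prop
    if best_prop is None or best_prop.intensity_mean - vals.mean() < ICM_MIN_CONTRAST:
        raise IcmNotFoundError("no sufficiently bright compact region")
    # centroid weighted by brightness excess over the threshold: the ICM core
    # dominates over dim speckle tails attached to the component
    comp_mask = labels == best_prop.label
    weights = np.clip(img[comp_mask] - thr, 0, None) ** 2 + 1e-9
    coords = np.argwhere(comp_mask)
    crow, ccol = (coords * weights[:, None]).sum(0) / weights.sum()
    angle = math.degrees(math.atan2(ccol - circle.cx, -(crow - circle.cy)))
    return angle % 360.0


def rotate_icm_to_top(image: np.ndarray, angle: float,
                      circle: EmbryoCircle) -> np.ndarray:
    """Rotate the image about the embryo centre so that a feature at the
    given clockwise-from-up angle moves to 12 o'clock (bilinear)."""
    if not 0.0 <= angle < 360.0:
        angle = angle % 360.0
    if angle == 0.0:
        return np.asarray(image).copy()
    img = np.asarray(image, dtype=float)
    cval = float(np.median([img[0, 0], img[0, -1], img[-1, 0], img[-1, -1]]))
    # skimage rotates counter-clockwise (in display orientation) for positive
    # angles, which carries a feature placed clockwise-from-up back to the top.
    out = _sk_rotate(img, angle, center=(circle.cx, circle.cy), order=1,
                     mode="constant", cval=cval, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def normalize_pose(image: np.ndarray, circle: EmbryoCircle,
                   target_mean: float = TARGET_MEAN,
                   target_sd: float = TARGET_SD) -> StandardizedImage:
    """Standardise brightness, then rotate the ICM to 12 o'clock.

    If no ICM candidate is detectable the rotation is skipped (angle 0);
    texture features downstream are angle-averaged, so a missing pose
    normalisation degrades gracefully.
    """
    std = standardize_brightness(image, target_mean, target_sd, circle=circle)
    try:
        angle = locate_icm_angle(std.image, circle)
    except IcmNotFoundError:
        angle = 0.0
    rotated = rotate_icm_to_top(std.image, angle, circle)
    return StandardizedImage(image=rotated, applied_gain=std.applied_gain,
                             applied_offset=std.applied_offset,
                             rotation_deg=angle)
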
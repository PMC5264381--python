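"""Seeded generator of grade-labelled synthetic blastocyst micrographs.

Renders a stylised bovine blastocyst as an 8-bit grayscale raster: a bright
zona pellucida ring, a trophectoderm band just inside it, a dark blastocoel
cavity and a compact bright inner cell mass (ICM) placed at a random polar
angle.  Image quality degrades with the IETS grade (1 excellent/good,
2 regular, 3 poor) through four knobs: speckle noise, boundary irregularity,
extra-embryonic debris and ICM fragmentation.  A panel of three simulated
examiners labels each image with adjacent-grade confusion, and the consensus
is the mode of the panel.

Angle convention for the whole package: degrees, 0 at 12 o'clock, clockwise
positive.  Pixel coordinates are (row, col), 0-based, origin top-left; a
circle stores cx = column and cy = row of its centre.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

GRADES = (1, 2, 3)

# Fraction of the embryo radius occupied by each concentric layer.  The zona
# plus trophectoderm together span the outer quarter of the radius, matching
# the default ring split used downstream by the segmentation stage.
ZONA_OUTER = 1.0
TROPH_OUTER = 0.88  # zona occupies (0.88, 1.0] x r
INNER_OUTER = 0.75  # trophectoderm occupies (0.75, 0.88] x r

# Base layer intensities (8-bit).  Chosen so that Otsu thresholding inside
# the circle separates {zona, ICM} from {trophectoderm, blastocoel} and the
# ICM remains the brightest *compact* component.
INTENSITY = {
    "background": 50.0,
    "blastocoel": 95.0,
    "trophectoderm": 150.0,
    "zona": 205.0,
    "icm": 190.0,
}

ICM_RADIAL_POS = 0.45   # ICM centre at this fraction of the embryo radius
ICM_RADIUS = 0.22       # ICM blob radius as a fraction of the embryo radius


@dataclass(frozen=True)
class GradeDegradation:
    """Per-grade image-quality knobs."""

    speckle_sd: float          # gaussian noise sd inside the embryo, intensity units
    boundary_jitter: float     # radial boundary perturbation, fraction of radius
    debris_count: int          # bright specks outside the embryo
    icm_fragmentation: float   # 0 = compact ICM, 1 = fully broken up


DEFAULT_DEGRADATION = {
    1: GradeDegradation(speckle_sd=3.0, boundary_jitter=0.012, debris_count=0,
                        icm_fragmentation=0.0),
    2: GradeDegradation(speckle_sd=8.0, boundary_jitter=0.035, debris_count=3,
                        icm_fragmentation=0.35),
    3: GradeDegradation(speckle_sd=15.0, boundary_jitter=0.07, debris_count=7,
                        icm_fragmentation=0.7),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults define the reference study conditions used throughout the test
    suite: 256 px square frames, embryo radius 70-95 px, mild class overlap
    and a 10% chance that an examiner reports an adjacent grade.
    """

    image_size: int = 256
    embryo_radius_range: tuple[int, int] = (70, 95)
    zona_thickness: float = 1.0 - TROPH_OUTER
    grade_priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    degradation: dict[int, GradeDegradation] = field(
        default_factory=lambda: dict(DEFAULT_DEGRADATION))
    examiner_confusion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.grade_priors) - 1.0) > 1e-9:
            raise ConfigurationError("grade_priors must sum to 1")
        if not 0.0 <= self.examiner_confusion < 0.5:
            raise ConfigurationError("examiner_confusion must lie in [0, 0.5)")
        r_lo, r_hi = self.embryo_radius_range
        if not 0 < r_lo <= r_hi:
            raise ConfigurationError("invalid embryo_radius_range")
        # leave room for the zona and a couple of pixels of margin
        if r_hi * (1.0 + self.zona_thickness) + 4 > self.image_size / 2:
            raise ConfigurationError(
                "image_size too small to contain embryo_radius_range")
        d = self.degradation
        if set(d) != set(GRADES):
            raise ConfigurationError("degradation must be keyed by grades 1..3")
        for attr in ("speckle_sd", "boundary_jitter", "debris_count"):
            vals = [getattr(d[g], attr) for g in GRADES]
            if not (vals[0] < vals[1] < vals[2]):
                raise ConfigurationError(
                    f"degradation.{attr} must strictly increase with grade")


@dataclass(frozen=True)
class EmbryoCircle:
    """Embryo-bounding circle; cx = column, cy = row, r in pixels."""

    cx: float
    cy: float
    r: float
    accumulator_peak: float = 1.0


@dataclass
class GroundTruth:
    true_grade: int
    icm_angle: float                       # degrees, 0 = up, clockwise
    circle: EmbryoCircle
    region_masks: dict[str, np.ndarray]    # zona / trophectoderm / icm / blastocoel


@dataclass
class LabeledImage:
    image: np.ndarray                      # uint8, (H, W)
    truth: GroundTruth
    examiner_grades: tuple[int, int, int]
    consensus: int


# ---------------------------------------------------------------------------
# geometry helpers

def _polar_grid(size: int, cx: float, cy: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance and clockwise-from-up angle (radians) to (cx, cy)."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dx = cols - cx
    dy = rows - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dx, -dy) % (2 * math.pi)
    return dist, theta


def _jittered_radius(theta: np.ndarray, r: float, jitter: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order perturbation of the embryo boundary radius."""
    if jitter <= 0:
        return np.full_like(theta, r)
    harmonics = (2, 3, 4, 5)
    amp = rng.dirichlet(np.ones(len(harmonics)))
    phase = rng.uniform(0, 2 * math.pi, size=len(harmonics))
    wobble = np.zeros_like(theta)
    for a, k, p in zip(amp, harmonics, phase):
        wobble += a * np.sin(k * theta + p)
    return r * (1.0 + jitter * wobble)


def icm_center(circle: EmbryoCircle, angle_deg: float,
               radial_pos: float = ICM_RADIAL_POS) -> tuple[float, float]:
    """(row, col) of the ICM blob centre for a given clockwise-from-up angle."""
    th = math.radians(angle_deg)
    rho = radial_pos * circle.r
    return circle.cy - rho * math.cos(th), circle.cx + rho * math.sin(th)


# ---------------------------------------------------------------------------
# examiner panel

def simulate_examiners(true_grade: int, confusion: float,
                       seed: int) -> tuple[int, int, int]:
    """Three independent examiner labels with adjacent-grade confusion.

    Each examiner reports ``true_grade`` with probability 1 - confusion,
    otherwise an adjacent grade; grade 2 splits the confusion mass equally
    between 1 and 3.
    """
    if not 0.0 <= confusion < 0.5:
        raise ConfigurationError("confusion must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    labels = []
    for _ in range(3):
        if rng.random() < confusion:
            if true_grade == 2:
                labels.append(1 if rng.random() < 0.5 else 3)
            else:
                labels.append(2)
        else:
            labels.append(true_grade)
    return tuple(labels)


def consensus_mode(grades: tuple[int, int, int]) -> int:
    """Mode of three ordinal grades; the all-distinct tie resolves to the
    median grade, 2."""
    for g in grades:
        if g not in GRADES:
            raise ConfigurationError(f"grade {g} outside {{1,2,3}}")
    counts = {g: grades.count(g) for g in set(grades)}
    best = max(counts.values())
    if best == 1:  # (1,2,3) in some order: median grade
        return 2
    return next(g for g, c in counts.items() if c == best)


# ---------------------------------------------------------------------------
# rendering

def render_embryo(config: SynthConfig, grade: int, seed: int,
                  icm_angle: float | None = None) -> LabeledImage:
    """Render one labelled synthetic blastocyst.

    Deterministic for fixed (config, grade, seed).  ``icm_angle`` overrides
    the uniformly random ICM placement, for tests that need a known pose.
    """
    if grade not in GRADES:
        raise ConfigurationError(f"grade must be in {{1,2,3}}, got {grade}")
    if seed < 0:
        raise ConfigurationError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    size = config.image_size
    deg = config.degradation[grade]

    r = float(rng.uniform(*config.embryo_radius_range))
    max_off = max(1.0, size / 2 - r * (1 + config.zona_thickness) - 4)
    cx = size / 2 + rng.uniform(-1, 1) * min(5.0, max_off)
    cy = size / 2 + rng.uniform(-1, 1) * min(5.0, max_off)
    circle = EmbryoCircle(cx=cx, cy=cy, r=r)
    angle = float(rng.uniform(0, 360)) if icm_angle is None else float(icm_angle) % 360

    dist, theta = _polar_grid(size, cx, cy)
    r_eff = _jittered_radius(theta, r, deg.boundary_jitter, rng)

    embryo = dist <= r_eff
    zona = embryo & (dist > TROPH_OUTER * r_eff)
    troph = (dist <= TROPH_OUTER * r_eff) & (dist > INNER_OUTER * r_eff)
    inner = dist <= INNER_OUTER * r_eff

    icm_row, icm_col = icm_center(circle, angle)
    icm_dist = np.hypot(np.mgrid[0:size, 0:size][1] - icm_col,
                        np.mgrid[0:size, 0:size][0] - icm_row)
    icm = (icm_dist <= ICM_RADIUS * r) & inner
    blastocoel = inner & ~icm

    img = np.full((size, size), INTENSITY["background"], dtype=float)
    img[blastocoel] = INTENSITY["blastocoel"]
    img[troph] = INTENSITY["trophectoderm"]
    img[zona] = INTENSITY["zona"]
    img[icm] = INTENSITY["icm"]
    if deg.icm_fragmentation > 0 and icm.any():
        # fragmentation renders as intensity mottling inside the blob: a
        # fine-scale random field carves dark pits over a fraction of the
        # ICM, breaking its texture while leaving the gross footprint (and
        # hence its centroid) in place
        fieldn = gaussian_filter(rng.standard_normal((size, size)), sigma=1.5)
        pits = icm & (fieldn < np.quantile(fieldn[icm],
                                           deg.icm_fragmentation * 0.6))
        img[pits] -= 0.55 * (INTENSITY["icm"] - INTENSITY["blastocoel"])
    img = gaussian_filter(img, sigma=1.5)

    # grade-dependent speckle inside the embryo, faint sensor noise elsewhere
    noise = rng.standard_normal((size, size))
    img[embryo] += deg.speckle_sd * noise[embryo]
    img[~embryo] += 1.5 * noise[~embryo]

    for _ in range(deg.debris_count):
        for _attempt in range(50):
            drow = rng.uniform(0, size)
            dcol = rng.uniform(0, size)
            if np.hypot(drow - cy, dcol - cx) > r * (1 + config.zona_thickness) + 8:
                break
        drad = rng.uniform(2.0, 5.0)
        dint = rng.uniform(60.0, 140.0)
        dd = np.hypot(np.mgrid[0:size, 0:size][0] - drow,
                      np.mgrid[0:size, 0:size][1] - dcol)
        img += dint * np.exp(-(dd / drad) ** 2)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_grade=grade, icm_angle=angle, circle=circle,
        region_masks={"zona": zona, "trophectoderm": troph,
                      "icm": icm, "blastocoel": blastocoel})
    exam_seed = int(rng.integers(0, 2**31 - 1))
    examiners = simulate_examiners(grade, config.examiner_confusion, exam_seed)
    return LabeledImage(image=image, truth=truth,
                        examiner_grades=examiners,
                        consensus=consensus_mode(examiners))


# ---------------------------------------------------------------------------
# dataset

def sample_grades(priors: tuple[float, float, float], n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw n grades from the prior over {1, 2, 3}."""
    return rng.choice(np.array(GRADES), size=n, p=np.asarray(priors))


def _item_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_dataset(config: SynthConfig, n: int, seed: int) -> list[LabeledImage]:
    """Generate n labelled images; grades drawn from the config priors and
    per-item seeds derived deterministically from the master seed."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grades = sample_grades(config.grade_priors, n, rng)
    return [render_embryo(config, int(g), _item_seed(seed, i))
            for i, g in enumerate(grades)]


def save_dataset(dataset: list[LabeledImage], out_dir: str | Path,
                 write_masks: bool = False) -> Path:
    """Write PNGs plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_path", "true_grade", "examiner1", "examiner2",
                    "examiner3", "consensus", "icm_angle_deg", "cx", "cy", "r"])
        for i, item in enumerate(dataset):
            name = f"embryo_{i:04d}.png"
            Image.fromarray(item.image).save(out / name)
            c = item.truth.circle
            w.writerow([name, item.truth.true_grade, *item.examiner_grades,
                        item.consensus, f"{item.truth.icm_angle:.2f}",
                        f"{c.cx:.2f}", f"{c.cy:.2f}", f"{c.r:.2f}"])
            if write_masks:
                for label, mask in item.truth.region_masks.items():
                    Image.fromarray((mask * 255).astype(np.uint8)).save(
                        out / f"embryo_{i:04d}_{label}.png")
    return manifest


def config_to_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["degradation"] = {g: dataclasses.asdict(config.degradation[g])
                        for g in GRADES}
    return d
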
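"""Synthetic three-modality cardiac phantoms with ground-truth labels.

Each case is a 2-D short-axis-like scene: a circular LV blood pool inside a
myocardial annulus, a crescent-shaped RV blood pool hugging the annulus, an
angular infarct sector inside the annulus, and an edema margin surrounding
the infarct within the annulus.  Three co-registered grayscale channels are
rendered from a per-modality contrast table and emulate the clinically
relevant contrasts: the bSSFP-like channel maximizes myocardium/blood-pool
contrast, the LGE-like channel is brightest in the infarct, and the T2-like
channel is brightest in the edema.  A Gaussian blur of the class-intensity
map produces the fuzzy boundaries that make pathology segmentation hard, and
Gaussian noise is added on top.

The module also provides the standard preprocessing/augmentation chain:
center cropping, non-rigid warping driven by a bilinearly upsampled 8x8x2
uniform displacement grid, and right-angle rotation chosen uniformly from
{90, 180, 270} degrees, plus deterministic train/test splitting with 5-fold
partitioning by case.

Everything is reproducible from ``(spec, case_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

from .errors import InvalidConfigError, ShapeError
from .vocab import BACKGROUND, EDEMA, INFARCT, LV, MYO, NUM_CLASSES, RV

__all__ = [
    "PhantomSpec", "PhantomCase", "generate_phantom", "center_crop",
    "random_warp", "random_rotate", "make_dataset", "DatasetSplit",
]

# per-modality mean intensity for each class, rows = (bSSFP, LGE, T2),
# columns = (background, LV, RV, myocardium, edema, infarction)
DEFAULT_CONTRAST = np.array([
    [0.15, 0.85, 0.80, 0.35, 0.38, 0.36],   # bSSFP: blood bright, myocardium dark
    [0.10, 0.75, 0.70, 0.25, 0.35, 0.90],   # LGE: infarct brightest
    [0.10, 0.60, 0.55, 0.30, 0.90, 0.45],   # T2: edema brightest
])

MODALITY_NAMES = ("bssfp", "lge", "t2")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; geometry ranges are fractions of image_size
    (radii, thickness) or degrees (angular spans)."""

    image_size: int = 288
    seed: int = 0
    lv_radius: tuple = (0.10, 0.14)
    myo_thickness: tuple = (0.05, 0.08)
    rv_radius_factor: tuple = (0.7, 0.9)      # relative to the epicardial radius
    infarct_span_deg: tuple = (50.0, 120.0)
    edema_margin_deg: tuple = (12.0, 30.0)
    center_jitter: float = 0.03
    contrast: np.ndarray = field(default_factory=lambda: DEFAULT_CONTRAST.copy())
    boundary_blur_sigma: float = 1.5
    noise_sigma: float = 0.05

    def __post_init__(self):
        if self.image_size < 64:
            raise InvalidConfigError("image_size must be >= 64")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be non-negative")
        reach = (self.lv_radius[1] + self.myo_thickness[1]) * (
            1.0 + 0.9 + self.rv_radius_factor[1]) / 2 + self.center_jitter
        if reach > 0.5:
            raise InvalidConfigError(
                "geometry ranges cannot fit inside image_size (reduce radii or jitter)")
        if np.asarray(self.contrast).shape != (3, NUM_CLASSES):
            raise InvalidConfigError("contrast table must be 3 modalities x 6 classes")


@dataclass
class PhantomCase:
    images: list                 # three (H, W) float arrays in [0, 1]
    label: np.ndarray            # (H, W) integer label map
    spec: PhantomSpec
    case_seed: int


def _case_rng(spec: PhantomSpec, case_seed: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, case_seed & 0x7FFFFFFF])


def generate_phantom(spec: PhantomSpec, case_seed: int) -> PhantomCase:
    """Draw a geometry from the spec's seeded ranges and render the case."""
    rng = _case_rng(spec, case_seed)
    size = spec.image_size
    cy = size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter) * size
    cx = size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter) * size
    r_lv = rng.uniform(*spec.lv_radius) * size
    thickness = rng.uniform(*spec.myo_thickness) * size
    r_epi = r_lv + thickness
    r_rv = rng.uniform(*spec.rv_radius_factor) * r_epi
    theta0 = rng.uniform(0.0, 360.0)
    span = rng.uniform(*spec.infarct_span_deg)
    margin = rng.uniform(*spec.edema_margin_deg)
    rv_angle = np.deg2rad(rng.uniform(150.0, 210.0))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    d_lv = np.hypot(yy - cy, xx - cx)
    ang = np.rad2deg(np.arctan2(yy - cy, xx - cx)) % 360.0

    rv_cy = cy + 0.95 * r_epi * np.sin(rv_angle) * -1
    rv_cx = cx + 0.95 * r_epi * np.cos(rv_angle)
    d_rv = np.hypot(yy - rv_cy, xx - rv_cx)

    lv = d_lv < r_lv
    ring = (d_lv >= r_lv) & (d_lv < r_epi)
    rv = (d_rv < r_rv) & (d_lv >= r_epi + 1.0)

    def in_sector(center_deg: float, half_span: float) -> np.ndarray:
        delta = (ang - center_deg + 180.0) % 360.0 - 180.0
        return np.abs(delta) <= half_span

    infarct = ring & in_sector(theta0, span / 2)
    edema = ring & in_sector(theta0, span / 2 + margin) & ~infarct

    label = np.full((size, size), BACKGROUND, dtype=np.int64)
    label[rv] = RV
    label[ring] = MYO
    label[edema] = EDEMA
    label[infarct] = INFARCT
    label[lv] = LV

    contrast = np.asarray(spec.contrast, dtype=np.float64)
    images = []
    for m in range(3):
        img = contrast[m][label]
        if spec.boundary_blur_sigma > 0:
            img = gaussian_filter(img, spec.boundary_blur_sigma)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        images.append(np.clip(img, 0.0, 1.0).astype(np.float32))
    return PhantomCase(images=images, label=label, spec=spec, case_seed=case_seed)


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Crop the central `size` x `size` region; off-by-one margins go low-side."""
    H, W = img.shape[:2]
    if H < size or W < size:
        raise ShapeError(f"cannot crop {H}x{W} image to {size}x{size} (no padding)")
    r0 = (H - size) // 2
    c0 = (W - size) // 2
    return img[r0:r0 + size, c0:c0 + size]


def random_warp(img: np.ndarray, label: np.ndarray, amplitude: float, seed: int):
    """Non-rigid warp by a bilinearly upsampled 8x8x2 uniform displacement grid.

    The image is resampled bilinearly, the label by nearest neighbor, through
    the same displacement field; out-of-bounds samples clamp to the edge.
    """
    img = np.asarray(img)
    label = np.asarray(label)
    if img.shape[:2] != label.shape[:2]:
        raise ShapeError(f"image {img.shape} and label {label.shape} disagree")
    H, W = label.shape[:2]
    rng = np.random.default_rng(seed)
    grid = rng.uniform(-amplitude, amplitude, size=(8, 8, 2))
    field_hw2 = resize(grid, (H, W), order=1, mode="edge", anti_aliasing=False)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    coords = np.stack([yy + field_hw2[..., 0], xx + field_hw2[..., 1]])
    warp_img = map_coordinates(img.astype(np.float64), coords, order=1, mode="nearest")
    warp_lab = map_coordinates(label, coords, order=0, mode="nearest")
    return warp_img.astype(img.dtype, copy=False), warp_lab.astype(label.dtype, copy=False)


def random_rotate(img: np.ndarray, label: np.ndarray, seed: int):
    """Rotate image and label together by 90, 180 or 270 degrees (uniform)."""
    img = np.asarray(img)
    label = np.asarray(label)
    if img.shape[0] != img.shape[1] or label.shape[0] != label.shape[1]:
        raise ShapeError("right-angle rotation requires square inputs")
    k = int(np.random.default_rng(seed).integers(1, 4))
    return np.rot90(img, k).copy(), np.rot90(label, k).copy()


@dataclass
class DatasetSplit:
    cases: list                  # all PhantomCase objects
    train_idx: list
    test_idx: list
    folds: list                  # list of 5 disjoint index lists covering train+test


def make_dataset(spec: PhantomSpec, n_cases: int, split_ratio: float = 0.2,
                 seed: int = 0, n_folds: int = 5) -> DatasetSplit:
    """Generate `n_cases` phantoms with a deterministic 4:1 split and 5-fold
    partition by case (never by slice)."""
    if n_cases < n_folds:
        raise InvalidConfigError(f"need at least {n_folds} cases, got {n_cases}")
    cases = [generate_phantom(spec, case_seed=i) for i in range(n_cases)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cases)
    n_test = max(1, int(round(n_cases * split_ratio)))
    test_idx = sorted(int(i) for i in order[:n_test])
    train_idx = sorted(int(i) for i in order[n_test:])
    folds = [sorted(int(i) for i in order[f::n_folds]) for f in range(n_folds)]
    return DatasetSplit(cases=cases, train_idx=train_idx, test_idx=test_idx, folds=folds)
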
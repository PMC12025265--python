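"""Regional grayscale features of the vertebral ROI.

The vertebral region of interest is divided by a 3×3 grid into five named
regions — upper (entire top row of the grid, corners included), lower
(entire bottom row), left, central and right (the middle row) — a disjoint,
exhaustive partition consistent with horizontal plus vertical segmentation
of the vertebral body. Within each region the grayscale values are clipped
to three intervals around the region mean μ and standard deviation σ:

    Set 1: [μ − σ,      μ + 1.96σ]
    Set 2: [μ − 1.96σ,  μ + 1.96σ]
    Set 3: [μ − 1.96σ,  μ + σ]

and the mean of the clipped values is taken. The asymmetric sets emphasise
the bright (Set 1) or dark (Set 3) tail of the trabecular texture.

The regressor's 23-element input vector is, in order:
    f01–f15  clipped region means, region-major
             (upper, lower, left, central, right) × (Set 1, 2, 3)
    f16–f20  raw region means in the same region order
    f21      whole-ROI mean
    f22      body weight (kg)
    f23      vertebral bone area (cm²)
"""

from __future__ import annotations

import dataclasses

import numpy as np

REGION_ORDER = ("upper", "lower", "left", "central", "right")
THRESHOLD_MULTIPLIERS = {1: (-1.0, 1.96), 2: (-1.96, 1.96), 3: (-1.96, 1.0)}

N_FEATURES = 23


@dataclasses.dataclass(frozen=True)
class RegionPartition:
    """Boolean masks (over the ROI) for the five named regions."""

    upper: np.ndarray
    lower: np.ndarray
    left: np.ndarray
    central: np.ndarray
    right: np.ndarray

    def masks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in REGION_ORDER}


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    """Clipping interval [A1, A2] = [μ + k1·σ, μ + k2·σ] for one set."""

    mu: float
    sigma: float
    set_id: int
    a1: float
    a2: float

    @classmethod
    def from_region(cls, pixels: np.ndarray, set_id: int) -> "ThresholdSpec":
        if set_id not in THRESHOLD_MULTIPLIERS:
            raise ValueError(f"set_id must be 1, 2 or 3, got {set_id}")
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.size == 0:
            raise ValueError("empty region")
        mu = float(pixels.mean())
        sigma = float(pixels.std())
        k1, k2 = THRESHOLD_MULTIPLIERS[set_id]
        return cls(mu=mu, sigma=sigma, set_id=set_id, a1=mu + k1 * sigma, a2=mu + k2 * sigma)


def partition_regions(roi: np.ndarray) -> RegionPartition:
    """3×3 grid partition of the ROI into the five named regions.

    Grid boundaries fall at ``floor(i·H/3)`` / ``floor(i·W/3)``, so the
    partition is exact for any ROI of at least 3×3 pixels.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2 or roi.shape[0] < 3 or roi.shape[1] < 3:
        raise ValueError(f"ROI must be 2-D and at least 3x3, got shape {roi.shape}")
    h, w = roi.shape
    rb = [h * i // 3 for i in range(4)]
    cb = [w * i // 3 for i in range(4)]

    def cell_mask(rows: slice, cols: slice) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        m[rows, cols] = True
        return m

    upper = cell_mask(slice(rb[0], rb[1]), slice(0, w))
    lower = cell_mask(slice(rb[2], rb[3]), slice(0, w))
    left = cell_mask(slice(rb[1], rb[2]), slice(cb[0], cb[1]))
    central = cell_mask(slice(rb[1], rb[2]), slice(cb[1], cb[2]))
    right = cell_mask(slice(rb[1], rb[2]), slice(cb[2], cb[3]))
    return RegionPartition(upper=upper, lower=lower, left=left, central=central, right=right)


def clip_to_threshold(region_pixels: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Clamp each pixel into [A1, A2]; values inside the band pass unchanged."""
    pixels = np.asarray(region_pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty region")
    if spec.a1 > spec.a2:
        raise ValueError(f"invalid threshold interval: A1={spec.a1} > A2={spec.a2}")
    return np.clip(pixels, spec.a1, spec.a2)


def region_mean(region_pixels: np.ndarray) -> float:
    pixels = np.asarray(region_pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty region")
    return float(pixels.mean())


FEATURE_NAMES = (
    tuple(
        f"{region}_set{set_id}"
        for region in REGION_ORDER
        for set_id in (1, 2, 3)
    )
    + tuple(f"{region}_raw" for region in REGION_ORDER)
    + ("roi_mean", "weight", "area")
)


def extract_features(
    bone_image: np.ndarray,
    roi_box: tuple[int, int, int, int],
    weight: float,
    area: float,
) -> np.ndarray:
    """23-element feature vector for one (subtracted) bone image.

    ``roi_box`` is (row0, row1, col0, col1), half-open. μ and σ are computed
    per region on the raw ROI pixels before clipping.
    """
    bone_image = np.asarray(bone_image, dtype=np.float64)
    r0, r1, c0, c1 = roi_box
    if not (0 <= r0 < r1 <= bone_image.shape[0] and 0 <= c0 < c1 <= bone_image.shape[1]):
        raise ValueError(f"roi_box {roi_box} outside image of shape {bone_image.shape}")
    if weight <= 0 or area <= 0:
        raise ValueError("weight and area must be positive")
    roi = bone_image[r0:r1, c0:c1]
    if roi.shape[0] < 3 or roi.shape[1] < 3:
        raise ValueError(f"ROI too small: {roi.shape}")
    partition = partition_regions(roi)

    clipped_means = []
    raw_means = []
    for name in REGION_ORDER:
        pixels = roi[partition.masks()[name]]
        for set_id in (1, 2, 3):
            spec = ThresholdSpec.from_region(pixels, set_id)
            clipped_means.append(region_mean(clip_to_threshold(pixels, spec)))
        raw_means.append(region_mean(pixels))

    vec = np.array(
        clipped_means + raw_means + [region_mean(roi), weight, area], dtype=np.float64
    )
    assert vec.shape == (N_FEATURES,)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


def feature_table(rows: list[tuple[str, np.ndarray]], bmd: list[float] | None = None):
    """Assemble a feature DataFrame: sample_id, f01…f21, weight, area[, bmd]."""
    import pandas as pd

    columns = [f"f{i + 1:02d}" for i in range(21)] + ["weight", "area"]
    data = {"sample_id": [sid for sid, _ in rows]}
    mat = np.stack([vec for _, vec in rows])
    for j, col in enumerate(columns):
        data[col] = mat[:, j]
    if bmd is not None:
        data["bmd"] = list(bmd)
    return pd.DataFrame(data)
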
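"""Synthetic radiograph phantoms with known ground-truth decomposition.

A phantom sample is built additively: a smooth, inhomogeneous soft-tissue
background plus a centered vertebral body with trabecular texture whose mean
attenuation is an affine function of the true BMD. The composite input is
``clamp(soft + bone, 0, 1)`` with optional Gaussian noise. Four jittered
copies of the vertebra template (contrast / brightness / tilt) are averaged
into the bone layer, and right-angle rotations and flips provide lossless
augmentation. Body weight and vertebral area covariates are drawn from a
linear-Gaussian model in the true BMD, mimicking the correlation of those
physiological factors with density reported in the osteoporosis literature.

The affine density map used inside the vertebra mask is

    mean intensity = BONE_INTERCEPT + BONE_SLOPE * bmd

with BONE_INTERCEPT = 0.10 and BONE_SLOPE = 0.30, so BMD in [0.35, 1.35]
g/cm² spans mean attenuations of roughly 0.21 to 0.51 in normalized
grayscale — dense enough to stand out against the background yet leaving
headroom for the additive composite to stay clamp-free almost everywhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from spinebmd import imgio

# Affine map from BMD (g/cm²) to mean in-mask attenuation (normalized gray).
BONE_INTERCEPT = 0.10
BONE_SLOPE = 0.30
# Affine map from BMD to the sd of the trabecular texture inside the mask:
# denser bone has more mineralized trabeculae, hence higher local contrast.
TEXTURE_SD_INTERCEPT = 0.015
TEXTURE_SD_SLOPE = 0.045

# Linear-Gaussian covariate model: weight = 40 + 25*bmd + N(0, 4²) kg,
# area = 10 + 4*bmd + N(0, 1²) cm².
WEIGHT_INTERCEPT, WEIGHT_SLOPE, WEIGHT_SD = 40.0, 25.0, 4.0
AREA_INTERCEPT, AREA_SLOPE, AREA_SD = 10.0, 4.0, 1.0

_ROTATIONS = (0, 90, 180, 270)
_FLIPS = ("none", "horizontal", "vertical")


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation settings.

    ``image_size`` must be divisible by ``2**depth`` of the U-Net that will
    consume the images (depth 3 by default, so multiples of 8).
    """

    image_size: int = 128
    n_soft: int = 150
    n_bone: int = 150
    contrast_range: tuple[float, float] = (0.95, 1.05)
    brightness_range: tuple[float, float] = (-0.02, 0.02)
    tilt_range: tuple[float, float] = (-3.0, 3.0)
    bmd_range: tuple[float, float] = (0.35, 1.35)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        lo, hi = self.bmd_range
        if not (0.0 < lo <= hi < 2.0):
            raise ValueError(f"bmd_range must lie inside (0, 2): {self.bmd_range}")
        for name in ("contrast_range", "brightness_range", "tilt_range"):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"{name} has low > high: ({a}, {b})")


@dataclasses.dataclass(frozen=True)
class PhantomSample:
    """One training unit: the composite input and its known decomposition."""

    input_image: np.ndarray
    soft_label: np.ndarray
    bone_truth: np.ndarray
    bmd_true: float
    weight: float
    area: float
    sample_id: str


def _check_raster(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D raster, got shape {arr.shape}")
    return arr


def make_soft_background(size: int, seed: int) -> np.ndarray:
    """Inhomogeneous soft-tissue field in [0, 1].

    Sum of three seeded band-limited noise octaves (Gaussian-smoothed white
    noise at decreasing length scales), a lateral intensity gradient, a
    handful of soft-edged elliptical patches (overlapping organs, bowel
    gas) and several elongated soft bands crossing the frame (bowel loops,
    muscle margins, rib shadows). The patches and bands vary at the spatial
    scale of the vertebra itself, which is what makes raw abdominal
    radiographs hard to analyse region-by-region; the bands' coherent
    continuation across the frame is what a contextual model can exploit
    to infer the field behind the vertebra. Deterministic per seed.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    field = np.zeros((size, size))
    # octaves: (smoothing length as fraction of side, amplitude)
    for frac, amp in ((0.25, 1.0), (0.12, 0.5), (0.06, 0.25)):
        noise = rng.standard_normal((size, size))
        smooth = ndimage.gaussian_filter(noise, sigma=frac * size, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        field += amp * smooth
    field /= np.abs(field).max() + 1e-12
    # lateral gradient: organs overlap more toward one flank
    cols = np.linspace(-1.0, 1.0, size)
    tilt_dir = rng.uniform(-1.0, 1.0)
    gradient = 0.5 * tilt_dir * cols[np.newaxis, :]
    field = 0.45 + 0.20 * field + 0.15 * gradient
    # organ-scale overlap: soft-edged ellipses anywhere in frame
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    organs = np.zeros((size, size))
    for _ in range(rng.integers(8, 15)):
        cy, cx = rng.uniform(0, size, 2)
        ay, ax = rng.uniform(0.06 * size, 0.35 * size, 2)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.16, 0.16)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        ellipse = ((u / ay) ** 2 + (v / ax) ** 2 <= 1.0).astype(np.float64)
        organs += amp * ndimage.gaussian_filter(ellipse, sigma=0.03 * size)
    field += organs
    # elongated bands crossing the whole frame: Gaussian profile across a
    # randomly oriented axis, visible on both sides of the spine
    bands = np.zeros((size, size))
    for _ in range(rng.integers(4, 9)):
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.6 * size, 0.6 * size)
        width = rng.uniform(0.04 * size, 0.12 * size)
        amp = rng.uniform(-0.14, 0.14)
        u = (yy - size / 2) * np.cos(theta) + (xx - size / 2) * np.sin(theta)
        bands += amp * np.exp(-0.5 * ((u - offset) / width) ** 2)
    field += bands
    return np.clip(field, 0.0, 1.0)


def _vertebra_mask(size: int) -> np.ndarray:
    """Rounded-rectangle vertebral body mask centered in the frame."""
    h = int(round(0.40 * size))
    w = int(round(0.30 * size))
    r = max(2, int(round(0.06 * size)))
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    dy = np.abs(yy - cy) - (h / 2.0 - r)
    dx = np.abs(xx - cx) - (w / 2.0 - r)
    dy = np.maximum(dy, 0.0)
    dx = np.maximum(dx, 0.0)
    return np.hypot(dy, dx) <= r


def vertebra_roi_box(size: int) -> tuple[int, int, int, int]:
    """Interior analysis box (row0, row1, col0, col1), half-open.

    The box is inset 18% from the template mask's bounding box on every
    side, so it lies fully on trabecular bone for every sample despite
    tilt jitter and 180° augmentation — the standard placement for
    vertebral texture ROIs, which avoids cortical margins and edge pixels.
    """
    mask = _vertebra_mask(size)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    dr = max(1, int(round(0.18 * (r1 - r0))))
    dc = max(1, int(round(0.18 * (c1 - c0))))
    return r0 + dr, r1 - dr, c0 + dc, c1 - dc


def make_vertebra_template(
    size: int, bmd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vertebra template raster plus its boolean mask.

    Mean intensity inside the mask follows the documented affine map
    ``BONE_INTERCEPT + BONE_SLOPE * bmd``. Multi-scale trabecular texture
    is superimposed inside the mask with sd
    ``TEXTURE_SD_INTERCEPT + TEXTURE_SD_SLOPE * bmd`` — both the mean
    attenuation and the texture contrast rise with density. Pixels outside
    the mask are exactly zero.
    """
    if not (0.0 < bmd < 2.0):
        raise ValueError(f"bmd must lie in (0, 2), got {bmd}")
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    mask = _vertebra_mask(size)
    base = BONE_INTERCEPT + BONE_SLOPE * bmd
    texture = np.zeros((size, size))
    for frac, amp in ((0.03, 1.0), (0.015, 0.6)):
        noise = rng.standard_normal((size, size))
        smooth = ndimage.gaussian_filter(noise, sigma=max(frac * size, 0.8))
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        texture += amp * smooth
    texture_sd = TEXTURE_SD_INTERCEPT + TEXTURE_SD_SLOPE * bmd
    texture *= texture_sd / (texture[mask].std() + 1e-12)
    texture -= texture[mask].mean()  # keep in-mask mean exactly on the affine map
    raster = np.where(mask, np.clip(base + texture, 0.0, 1.0), 0.0)
    return raster, mask


def jitter_template(
    template: np.ndarray, contrast: float, brightness: float, tilt: float
) -> np.ndarray:
    """Contrast/brightness/tilt perturbation of a template.

    Returns ``clamp(contrast * template + brightness, 0, 1)`` rotated by
    ``tilt`` degrees about the image center with zero fill.
    """
    template = _check_raster(template)
    if contrast <= 0:
        raise ValueError(f"contrast must be > 0, got {contrast}")
    out = np.clip(contrast * template + brightness, 0.0, 1.0)
    if tilt != 0.0:
        out = ndimage.rotate(
            out, tilt, reshape=False, order=1, mode="constant", cval=0.0
        )
        out = np.clip(out, 0.0, 1.0)
    return out


def composite_bone_mask(jittered: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise mean of four jittered template variants, clamped to [0, 1]."""
    if len(jittered) != 4:
        raise ValueError(f"expected exactly four rasters, got {len(jittered)}")
    rasters = [_check_raster(r) for r in jittered]
    shape = rasters[0].shape
    for r in rasters[1:]:
        if r.shape != shape:
            raise ValueError(f"shape mismatch: {r.shape} vs {shape}")
    return np.clip(np.mean(rasters, axis=0), 0.0, 1.0)


def augment(raster: np.ndarray, rotation: int = 0, flip: str = "none") -> np.ndarray:
    """Exact lossless remap: right-angle rotation then axis flip."""
    raster = _check_raster(raster)
    if rotation not in _ROTATIONS:
        raise ValueError(f"rotation must be one of {_ROTATIONS}, got {rotation}")
    if flip not in _FLIPS:
        raise ValueError(f"flip must be one of {_FLIPS}, got {flip!r}")
    out = np.rot90(raster, k=rotation // 90)
    if flip == "horizontal":
        out = out[:, ::-1]
    elif flip == "vertical":
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def synthesize_sample(config: PhantomConfig, sample_seed: int) -> PhantomSample:
    """Draw one phantom: BMD, layers, composite input, covariates.

    The pre-noise input is exactly ``clamp(soft + bone, 0, 1)``; seeded
    Gaussian noise (sd ``config.noise_sd``) is then added and re-clamped.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, sample_seed, 0x5B])
    )
    size = config.image_size
    bmd = float(rng.uniform(*config.bmd_range))

    soft = make_soft_background(size, seed=int(rng.integers(2**31)))

    template, _ = make_vertebra_template(size, bmd, seed=int(rng.integers(2**31)))
    variants = [
        jitter_template(
            template,
            contrast=float(rng.uniform(*config.contrast_range)),
            brightness=float(rng.uniform(*config.brightness_range)),
            tilt=float(rng.uniform(*config.tilt_range)),
        )
        for _ in range(4)
    ]
    bone = composite_bone_mask(variants)
    # only upright orientations: a 90°-rotated vertebra would transpose the
    # ROI box and is anatomically implausible in an abdominal view
    bone = augment(
        bone,
        rotation=int(rng.choice([0, 180])),
        flip=str(rng.choice(_FLIPS)),
    )

    clean = np.clip(soft + bone, 0.0, 1.0)
    noisy = np.clip(clean + config.noise_sd * rng.standard_normal(clean.shape), 0.0, 1.0)

    weight = WEIGHT_INTERCEPT + WEIGHT_SLOPE * bmd + WEIGHT_SD * rng.standard_normal()
    area = AREA_INTERCEPT + AREA_SLOPE * bmd + AREA_SD * rng.standard_normal()

    return PhantomSample(
        input_image=noisy,
        soft_label=soft,
        bone_truth=bone,
        bmd_true=bmd,
        weight=float(weight),
        area=float(area),
        sample_id=f"phantom_{sample_seed:05d}",
    )


def covariate_correlations(config: PhantomConfig) -> dict[str, float]:
    """Analytic Pearson correlation of each covariate with BMD.

    For a linear-Gaussian covariate ``c = a + b*bmd + eps`` with BMD uniform
    on ``bmd_range``, ``corr = b*sd_bmd / sqrt((b*sd_bmd)² + sd_eps²)``.
    """
    lo, hi = config.bmd_range
    sd_bmd = (hi - lo) / np.sqrt(12.0)
    out = {}
    for name, slope, sd in (
        ("weight", WEIGHT_SLOPE, WEIGHT_SD),
        ("area", AREA_SLOPE, AREA_SD),
    ):
        signal = slope * sd_bmd
        out[name] = signal / np.hypot(signal, sd)
    return out


MANIFEST_COLUMNS = [
    "sample_id",
    "input_path",
    "soft_path",
    "bone_path",
    "bmd",
    "weight",
    "area",
]


def generate_cohort(
    config: PhantomConfig, n: int, out_dir: str | Path
) -> pd.DataFrame:
    """Write ``n`` phantom samples (input / soft / bone PNGs) plus a manifest.

    Returns the manifest DataFrame; a ``manifest.csv`` with columns
    ``sample_id,input_path,soft_path,bone_path,bmd,weight,area`` is written
    alongside the images. Paths in the manifest are relative to ``out_dir``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        s = synthesize_sample(config, sample_seed=i)
        paths = {}
        for kind, raster in (
            ("input", s.input_image),
            ("soft", s.soft_label),
            ("bone", s.bone_truth),
        ):
            rel = f"{s.sample_id}_{kind}.png"
            imgio.write_image(out_dir / rel, raster)
            paths[kind] = rel
        rows.append(
            {
                "sample_id": s.sample_id,
                "input_path": paths["input"],
                "soft_path": paths["soft"],
                "bone_path": paths["bone"],
                "bmd": s.bmd_true,
                "weight": s.weight,
                "area": s.area,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")
    return manifest


def load_cohort(out_dir: str | Path) -> pd.DataFrame:
    """Read back a cohort manifest written by :func:`generate_cohort`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest
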
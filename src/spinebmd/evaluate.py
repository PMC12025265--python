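"""Evaluation metrics and the raw-vs-subtracted pipeline comparison.

Prediction quality is summarised by the sample Pearson correlation r
between predicted and reference BMD, its square r² (the coefficient of
determination of the simple least-squares fit of prediction on truth),
and the mean absolute error in g/cm². ``compare_pipelines`` runs the full
estimation chain twice under identical seeds and data split — once on raw
composite radiographs and once on bone images recovered by U-Net
soft-tissue subtraction — and reports both arms plus their deltas, which
isolates the contribution of the subtraction stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats

from spinebmd import features as feat
from spinebmd import phantom, regressor, softnet


class UndefinedMetricError(ValueError):
    """Raised when a correlation is requested for a zero-variance input."""


@dataclasses.dataclass(frozen=True)
class EvalReport:
    pearson_r: float
    r_squared: float
    mae: float
    n: int
    subset: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def mae(true, pred) -> float:
    """Mean absolute error, in the units of the inputs (g/cm² for BMD)."""
    true = np.asarray(true, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {pred.shape}")
    if true.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(true - pred)))


def make_report(true, pred, subset: str) -> EvalReport:
    r = pearson_r(true, pred)
    return EvalReport(
        pearson_r=r,
        r_squared=r**2,
        mae=mae(true, pred),
        n=len(np.asarray(true)),
        subset=subset,
    )


def _predict_soft_batched(model: softnet.UNet, images, batch: int = 16) -> list[np.ndarray]:
    out = []
    stack = np.stack([np.asarray(im, dtype=np.float32) for im in images])[:, None]
    for start in range(0, len(stack), batch):
        pred = model.forward(stack[start : start + batch])
        out.extend(np.clip(p[0].astype(np.float64), 0.0, 1.0) for p in pred)
    return out


def run_pipeline(
    samples: list[phantom.PhantomSample],
    split: regressor.SplitIndex,
    ann_spec: regressor.AnnSpec,
    unet_spec: softnet.UNetSpec | None = None,
    use_subtraction: bool = True,
    unet_train_count: int = 64,
    roi_box: tuple[int, int, int, int] | None = None,
) -> dict:
    """Run subtraction (optional) → features → regressor on one cohort.

    ``split`` indexes positions in ``samples``. When subtraction is on, the
    U-Net is trained on the first ``unet_train_count`` training-split
    samples (input → soft label pairs) and applied to every image; the ROI
    defaults to the phantom template bounding box.

    Returns train/validation EvalReports, per-sample predictions, and the
    trained models.
    """
    size = samples[0].input_image.shape[0]
    if roi_box is None:
        roi_box = phantom.vertebra_roi_box(size)

    unet = None
    unet_state = None
    if use_subtraction:
        if unet_spec is None:
            unet_spec = softnet.UNetSpec()
        unet = softnet.build_unet(unet_spec)
        train_pairs = [samples[i] for i in split.train_ids[:unet_train_count]]
        unet_state = softnet.train_unet(unet, train_pairs, unet_spec)
        soft_preds = _predict_soft_batched(unet, [s.input_image for s in samples])
        bone_images = [
            softnet.subtract_soft_tissue(s.input_image, soft)
            for s, soft in zip(samples, soft_preds)
        ]
    else:
        bone_images = [s.input_image for s in samples]

    feature_rows = np.stack(
        [
            feat.extract_features(img, roi_box, s.weight, s.area)
            for img, s in zip(bone_images, samples)
        ]
    )
    targets = np.array([s.bmd_true for s in samples])

    ann, history = regressor.train_ann(feature_rows, targets, ann_spec, split)
    preds = ann.predict(feature_rows)

    tr = np.asarray(split.train_ids, dtype=int)
    va = np.asarray(split.val_ids, dtype=int)
    return {
        "train_report": make_report(targets[tr], preds[tr], "train"),
        "val_report": make_report(targets[va], preds[va], "validation"),
        "predictions": preds,
        "targets": targets,
        "ann": ann,
        "ann_history": history,
        "unet": unet,
        "unet_state": unet_state,
    }


def compare_pipelines(
    samples: list[phantom.PhantomSample],
    seed: int,
    ann_spec: regressor.AnnSpec | None = None,
    unet_spec: softnet.UNetSpec | None = None,
    unet_train_count: int = 64,
) -> dict:
    """Paired before/after-subtraction evaluation under identical seeds.

    Both arms share the same 80/20 split and ANN seed; only the image fed to
    the feature extractor differs (raw composite vs U-Net-subtracted bone).
    Returns per-arm EvalReports plus deltas (subtracted − raw) of the
    validation r and MAE.
    """
    ann_spec = ann_spec or regressor.AnnSpec(seed=seed)
    split = regressor.split_dataset(range(len(samples)), seed=seed)
    subtracted = run_pipeline(
        samples, split, ann_spec, unet_spec, use_subtraction=True,
        unet_train_count=unet_train_count,
    )
    raw = run_pipeline(samples, split, ann_spec, use_subtraction=False)
    return {
        "subtracted": subtracted,
        "raw": raw,
        "delta_r": subtracted["val_report"].pearson_r - raw["val_report"].pearson_r,
        "delta_mae": subtracted["val_report"].mae - raw["val_report"].mae,
        "split": split,
    }


def report_json(comparison: dict, path: str | Path) -> None:
    """Serialise a compare_pipelines result (metrics only) to JSON."""
    payload = {
        arm: {
            "train": comparison[arm]["train_report"].as_dict(),
            "validation": comparison[arm]["val_report"].as_dict(),
        }
        for arm in ("subtracted", "raw")
    }
    payload["delta_r"] = comparison["delta_r"]
    payload["delta_mae"] = comparison["delta_mae"]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def scatter_plot(true, pred, path: str | Path, title: str = "") -> None:
    """True-vs-predicted BMD scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    true = np.asarray(true)
    pred = np.asarray(pred)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(true, pred, s=12, alpha=0.7)
    lims = [min(true.min(), pred.min()), max(true.max(), pred.max())]
    ax.plot(lims, lims, "k--", lw=1)
    r = pearson_r(true, pred)
    ax.set_xlabel("reference BMD (g/cm²)")
    ax.set_ylabel("predicted BMD (g/cm²)")
    ax.set_title(f"{title} r={r:.3f}, MAE={mae(true, pred):.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
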
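"""Segmentation evaluation: DSC, JA, HD95, SE, SP, S-measure, E-measure, MAE.

Region metrics and HD95 are computed on binarized masks; the S-measure and
MAE use the raw probability map (standard for the structure measure).  The
S-measure (structural similarity; Fan et al.'s structure measure) and the
E-measure (enhanced-alignment measure) come from the salient-object
detection literature; self-contained definitions are implemented here (see
docs/methods.md) so no external code is needed.

Empty-mask conventions: for empty-vs-empty pairs DSC = JA = 1 (perfect
agreement on absence); SE is undefined and excluded; HD95 is undefined for
any empty operand and reported as NaN with a warning, excluded from
aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

_EPS = 1e-12

METRIC_COLUMNS = ["DSC", "JA", "HD95", "SE", "SP", "Sm", "Em", "MAE"]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_counts(s: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    s = s.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(int((s & gt).sum()), int((s & ~gt).sum()),
                           int((~s & gt).sum()), int((~s & ~gt).sum()))


def region_metrics(s: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """Overlap metrics DSC, JA, SE, SP between binary masks."""
    s = np.asarray(s)
    gt = np.asarray(gt)
    if s.shape != gt.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {gt.shape}")
    c = confusion_counts(s, gt)
    if c.TP + c.FP + c.FN == 0:      # both empty: perfect agreement on absence
        dsc = ja = 1.0
    else:
        dsc = 2 * c.TP / (2 * c.TP + c.FP + c.FN)
        ja = c.TP / (c.TP + c.FP + c.FN)
    se = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    return {"DSC": dsc, "JA": ja, "SE": se, "SP": sp}


def hd95(s: np.ndarray, gt: np.ndarray, spacing: float | tuple = 1.0) -> float:
    """95th percentile of the pooled directed point-to-set distances.

    Distances run from every pixel of S to the nearest pixel of GT and vice
    versa (Euclidean, isotropic spacing by default); the 95th percentile of
    the pooled distances is symmetric in its inputs and robust to outliers.
    Empty masks have no defined distance: NaN is returned with a warning.
    """
    s = np.asarray(s).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if s.shape != gt.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {gt.shape}")
    if not s.any() or not gt.any():
        warnings.warn("hd95: empty mask; distance undefined (NaN)")
        return float("nan")
    sampling = (spacing, spacing) if np.isscalar(spacing) else tuple(spacing)
    d_to_gt = distance_transform_edt(~gt, sampling=sampling)
    d_to_s = distance_transform_edt(~s, sampling=sampling)
    pooled = np.concatenate([d_to_gt[s], d_to_s[gt]])
    return float(np.percentile(pooled, 95))


# ---------------------------------------------------------------------------
# S-measure


def _s_object_score(p: np.ndarray, region: np.ndarray) -> float:
    if not region.any():
        return 0.0
    vals = p[region]
    x = vals.mean()
    sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
    return 2.0 * x / (x * x + 1.0 + sigma + _EPS)


def _s_object(p: np.ndarray, gt: np.ndarray) -> float:
    mu = gt.mean()
    fg = _s_object_score(p, gt.astype(bool))
    bg = _s_object_score(1.0 - p, ~gt.astype(bool))
    return mu * fg + (1.0 - mu) * bg


def _ssim_block(p: np.ndarray, g: np.ndarray) -> float:
    n = p.size
    if n <= 1:
        return 1.0 if np.allclose(p, g) else 0.0
    x, y = p.mean(), g.mean()
    sx = ((p - x) ** 2).sum() / (n - 1)
    sy = ((g - y) ** 2).sum() / (n - 1)
    sxy = ((p - x) * (g - y)).sum() / (n - 1)
    a = 4.0 * x * y * sxy
    b = (x * x + y * y) * (sx + sy)
    if a != 0:
        return a / (b + _EPS)
    return 1.0 if b == 0 else 0.0


def _s_region(p: np.ndarray, gt: np.ndarray) -> float:
    h, w = gt.shape
    if gt.any():
        ys, xs = np.nonzero(gt)
        cy = int(np.round(ys.mean())) + 1   # 1-based split point
        cx = int(np.round(xs.mean())) + 1
    else:
        cy, cx = h // 2 + 1, w // 2 + 1
    blocks = [(slice(0, cy), slice(0, cx)), (slice(0, cy), slice(cx, w)),
              (slice(cy, h), slice(0, cx)), (slice(cy, h), slice(cx, w))]
    total = h * w
    score = 0.0
    for sl in blocks:
        gtb = gt[sl]
        weight = gtb.size / total
        score += weight * _ssim_block(p[sl], gtb.astype(np.float64))
    return score


def s_measure(p: np.ndarray, gt: np.ndarray, balance: float = 0.5) -> float:
    """Structure measure Sm = balance·So + (1−balance)·Sr of a probability
    map against a binary mask; the balance coefficient defaults to 0.5."""
    p = np.asarray(p, dtype=np.float64)
    gt = np.asarray(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {gt.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map must lie in [0,1]")
    gtb = gt.astype(bool)
    mu = gtb.mean()
    if mu == 0:                      # no object: score the background only
        return 1.0 - p.mean()
    if mu == 1:                      # all object
        return float(p.mean())
    sm = balance * _s_object(p, gtb) + (1 - balance) * _s_region(p, gtb)
    return float(max(sm, 0.0))


# ---------------------------------------------------------------------------
# E-measure


def e_measure(s_bin: np.ndarray, gt: np.ndarray) -> float:
    """Enhanced-alignment measure between binarized prediction and GT.

    Both maps are mean-centred; the alignment matrix
    ξ = 2·(GT_c ⊙ S_c) / (GT_c² + S_c²) is mapped through the enhancement
    φ = (ξ+1)²/4 and averaged over pixels (M−1 normalization).
    """
    s = np.asarray(s_bin).astype(np.float64)
    gt = np.asarray(gt).astype(np.float64)
    if s.shape != gt.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {gt.shape}")
    m = gt.size
    if gt.sum() == 0:
        enhanced = 1.0 - s            # reward predicting nothing
    elif gt.sum() == m:
        enhanced = s
    else:
        sc = s - s.mean()
        gc = gt - gt.mean()
        align = 2.0 * gc * sc / (gc * gc + sc * sc + _EPS)
        enhanced = (align + 1.0) ** 2 / 4.0
    return float(np.clip(enhanced.sum() / (m - 1 + _EPS), 0.0, 1.0))


def mae(p: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute per-pixel error between the map and the mask."""
    p = np.asarray(p, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {gt.shape}")
    return float(np.abs(p - gt).mean())


# ---------------------------------------------------------------------------
# dataset-level reporting


@dataclass
class MetricsReport:
    """Per-image metric rows plus mean / SD / 95% CI aggregates."""

    per_image: pd.DataFrame
    aggregate: pd.DataFrame

    def to_csv(self, path) -> None:
        rows = self.per_image.copy()
        agg = self.aggregate.copy()
        agg.insert(0, "image_id", agg.index)
        pd.concat([rows, agg], ignore_index=True).to_csv(path, index=False)


def image_metrics(prob: np.ndarray, gt: np.ndarray,
                  threshold: float = 0.5, spacing: float = 1.0) -> dict[str, float]:
    """All eight metrics for one probability map vs binary ground truth."""
    s_bin = (prob >= threshold).astype(np.uint8)
    out = region_metrics(s_bin, gt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["HD95"] = hd95(s_bin, gt, spacing)
    out["Sm"] = s_measure(prob, gt)
    out["Em"] = e_measure(s_bin, gt)
    out["MAE"] = mae(prob, gt)
    return {k: out[k] for k in METRIC_COLUMNS}


def _aggregate(per_image: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for c in METRIC_COLUMNS:
        vals = per_image[c].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]     # undefined entries are excluded
        n = len(vals)
        mean = vals.mean() if n else float("nan")
        sd = vals.std(ddof=1) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n) if n else float("nan")
        cols[c] = {"mean": mean, "sd": sd,
                   "ci95_lower": mean - half, "ci95_upper": mean + half}
    return pd.DataFrame(cols)


def evaluate_pairs(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                   threshold: float = 0.5, spacing: float = 1.0) -> MetricsReport:
    """Evaluate (image_id, probability map, gt mask) triples."""
    rows = []
    for image_id, prob, gt in pairs:
        row = {"image_id": image_id}
        row.update(image_metrics(prob, gt, threshold, spacing))
        rows.append(row)
    per_image = pd.DataFrame(rows, columns=["image_id"] + METRIC_COLUMNS)
    return MetricsReport(per_image, _aggregate(per_image))


def evaluate_dataset(pred_dir, gt_dir, threshold: float = 0.5,
                     spacing: float = 1.0, out_csv=None) -> MetricsReport:
    """Evaluate paired PNG files (same filenames in the two directories).

    Prediction PNGs are read as 8-bit probability maps (value/255) and
    binarized at `threshold` for the region metrics, HD95 and Em; the raw
    probabilities feed Sm and MAE.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    preds = sorted(pred_dir.glob("*.png"))
    gts = sorted(gt_dir.glob("*.png"))
    if not preds:
        raise FileNotFoundError(f"no predictions found in {pred_dir}")
    pred_names = {p.name for p in preds}
    gt_names = {g.name for g in gts}
    unmatched = sorted(pred_names ^ gt_names)
    if unmatched:
        raise FileNotFoundError(f"unpaired files between {pred_dir} and "
                                f"{gt_dir}: {unmatched}")
    pairs = []
    for p in preds:
        prob = iio.imread(p).astype(np.float64) / 255.0
        gt = (iio.imread(gt_dir / p.name) > 127).astype(np.uint8)
        pairs.append((p.stem, prob, gt))
    report = evaluate_pairs(pairs, threshold, spacing)
    if out_csv is not None:
        report.to_csv(out_csv)
    return report
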
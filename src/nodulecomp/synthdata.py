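"""Synthetic CT-like nodule phantoms.

Real chest-CT cohorts cannot ship with the package, so every stage is
exercised on small generated scenes that mimic the clinically relevant
nodule presentations: isolated solid nodules, juxta-pleural nodules touching
a bright chest-wall band, juxta-vascular nodules crossed by a bright vessel,
low-contrast ground-glass opacities (GGO), cavitary nodules with an interior
lucency (whose reference mask stays filled, as radiologists contour them),
and near-saturating calcified nodules.  Nodule outlines are randomized
star-convex polygons — a radial perturbation of a disc — which gives
irregular, mildly spiculated shapes without modelling CT physics.

Generation is fully deterministic: one integer seed fixes the scene, and
disjoint seed ranges stand in for distinct synthetic patients so the
patient-level train/test split is meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize as sk_resize
from scipy.ndimage import gaussian_filter

NODULE_TYPES = ("isolated", "juxta_pleural", "juxta_vascular",
                "ggo", "cavitary", "calcified")

#: default nodule/background contrast per presentation; GGO is low-contrast
#: by definition (gap <= 0.3), calcified close to saturation.
DEFAULT_CONTRAST = {
    "isolated": 0.6,
    "juxta_pleural": 0.55,
    "juxta_vascular": 0.55,
    "ggo": 0.25,
    "cavitary": 0.6,
    "calcified": 0.95,
}

_BASE_INTENSITY = 0.15   # dark lung parenchyma
_WALL_INTENSITY = 0.80   # chest-wall band
_VESSEL_INTENSITY = 0.70
_RADIAL_AMP = 0.25       # star-convex radial perturbation amplitude


@dataclass(frozen=True)
class NoduleSpec:
    """One synthetic nodule: presentation type, size, contrast, scene, seed."""

    nodule_type: str
    diameter_px: int
    contrast: float | None = None
    scene_size: int = 192
    seed: int = 0
    noise_sigma: float = 0.05

    def resolved_contrast(self) -> float:
        c = self.contrast if self.contrast is not None else DEFAULT_CONTRAST[self.nodule_type]
        if not (0.0 < c <= 1.0):
            raise ValueError(f"contrast must be in (0, 1], got {c}")
        return c


@dataclass
class CTPatch:
    """A grayscale patch plus its binary mask and provenance identifiers."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str = ""
    nodule_id: str = ""
    crop_index: int = 0

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary (0/1)")


def _star_polygon(rng: np.random.Generator, cy: float, cx: float,
                  radius: float, n_vertices: int = 16) -> tuple[np.ndarray, np.ndarray]:
    # evenly spaced angles with jitter keep the outline star-convex and the
    # enclosed area close to the disc's, while radial perturbation adds the
    # irregular, mildly spiculated margin
    base = np.arange(n_vertices) * (2 * np.pi / n_vertices)
    angles = base + rng.uniform(-0.3, 0.3, n_vertices) * (2 * np.pi / n_vertices)
    radii = radius * (1.0 + _RADIAL_AMP * rng.uniform(-1, 1, n_vertices))
    return cy + radii * np.sin(angles), cx + radii * np.cos(angles)


def make_nodule_scene(spec: NoduleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene: (image in [0,1], binary mask), both scene_size².

    Identical specs (seed included) give bit-identical outputs.
    """
    if spec.nodule_type not in NODULE_TYPES:
        raise ValueError(f"unknown nodule_type {spec.nodule_type!r}; "
                         f"expected one of {NODULE_TYPES}")
    if spec.diameter_px < 3:
        raise ValueError("degenerate nodule: diameter_px must be >= 3")
    if spec.scene_size < 2 * spec.diameter_px:
        raise ValueError("scene_size must be at least 2 x diameter_px")

    rng = np.random.default_rng(spec.seed)
    size = spec.scene_size
    r = spec.diameter_px / 2.0
    contrast = spec.resolved_contrast()

    image = np.full((size, size), _BASE_INTENSITY, dtype=np.float64)
    wall = np.zeros((size, size), dtype=bool)
    margin = spec.diameter_px  # keep the nodule clear of the scene border

    if spec.nodule_type == "juxta_pleural":
        wall_t = max(4, size // 24)
        side = int(rng.integers(0, 4))
        lo = margin + int(np.ceil(r))
        hi = size - margin - int(np.ceil(r))
        along = float(rng.uniform(lo, hi))
        # centre sits closer to the wall than the minimum polygon radius,
        # so the mask always reaches (and crosses into) the band
        depth = wall_t + 0.7 * r
        if side == 0:
            wall[:wall_t, :] = True
            cy, cx = depth, along
        elif side == 1:
            wall[-wall_t:, :] = True
            cy, cx = size - 1 - depth, along
        elif side == 2:
            wall[:, :wall_t] = True
            cy, cx = along, depth
        else:
            wall[:, -wall_t:] = True
            cy, cx = along, size - 1 - depth
    else:
        lo = margin + r
        hi = size - margin - r
        cy = float(rng.uniform(lo, hi))
        cx = float(rng.uniform(lo, hi))

    ys, xs = _star_polygon(rng, cy, cx, r)
    rr, cc = draw_polygon(ys, xs, shape=(size, size))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[rr, cc] = 1
    if mask.sum() == 0:  # unreachable for diameter >= 3, guarded anyway
        raise RuntimeError("rendered mask is empty")

    image[wall] = _WALL_INTENSITY

    if spec.nodule_type == "juxta_vascular":
        theta = float(rng.uniform(0, np.pi))
        width = float(rng.uniform(1.5, 2.5))
        yy, xx = np.mgrid[0:size, 0:size]
        # distance from the line through the nodule centre at angle theta
        d = np.abs(-np.sin(theta) * (xx - cx) + np.cos(theta) * (yy - cy))
        image[d <= width] = _VESSEL_INTENSITY

    nodule_layer = gaussian_filter(mask.astype(np.float64), sigma=1.0)
    image = np.maximum(image, _BASE_INTENSITY + contrast * nodule_layer)

    if spec.nodule_type == "cavitary":
        # interior lucency: intensity drops back toward parenchyma while the
        # reference mask stays filled (clinical contouring convention)
        yy, xx = np.mgrid[0:size, 0:size]
        hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * r) ** 2
        hole_soft = gaussian_filter(hole.astype(np.float64), sigma=1.0)
        image -= contrast * 0.9 * hole_soft

    image += rng.normal(0.0, spec.noise_sigma, image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, mask


def wall_band_mask(spec: NoduleSpec) -> np.ndarray:
    """The chest-wall band region of a juxta-pleural scene (for analysis)."""
    if spec.nodule_type != "juxta_pleural":
        raise ValueError("wall band only exists for juxta_pleural scenes")
    rng = np.random.default_rng(spec.seed)
    size = spec.scene_size
    wall_t = max(4, size // 24)
    side = int(rng.integers(0, 4))
    wall = np.zeros((size, size), dtype=bool)
    if side == 0:
        wall[:wall_t, :] = True
    elif side == 1:
        wall[-wall_t:, :] = True
    elif side == 2:
        wall[:, :wall_t] = True
    else:
        wall[:, -wall_t:] = True
    return wall


def crop_variants(image: np.ndarray, mask: np.ndarray, n: int = 5,
                  min_margin: int = 4, seed: int = 0, *,
                  patient_id: str = "", nodule_id: str = "") -> list[CTPatch]:
    """Cut `n` distinct rectangular crops, each containing the whole mask.

    Crops are deliberately non-centred and non-square: margins on the four
    sides are drawn independently, so the nodule position and the aspect
    ratio vary between crops of the same scene.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mask.sum() == 0:
        raise ValueError("mask is empty; nothing to crop around")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    h, w = mask.shape
    if r0 < min_margin or c0 < min_margin or h - r1 < min_margin or w - c1 < min_margin:
        raise ValueError("scene too small to honor the requested margin")

    rng = np.random.default_rng(seed)
    seen: set[tuple[int, int, int, int]] = set()
    patches: list[CTPatch] = []
    for idx in range(n):
        for _ in range(200):
            top = int(rng.integers(min_margin, r0 + 1))
            bottom = int(rng.integers(min_margin, h - r1 + 1))
            left = int(rng.integers(min_margin, c0 + 1))
            right = int(rng.integers(min_margin, w - c1 + 1))
            rect = (r0 - top, r1 + bottom, c0 - left, c1 + right)
            if rect not in seen:
                seen.add(rect)
                break
        else:  # pragma: no cover - only for degenerate tiny scenes
            raise ValueError("could not find enough distinct crop rectangles")
        a, b, c, d = rect
        patches.append(CTPatch(image[a:b, c:d].copy(), mask[a:b, c:d].copy(),
                               patient_id, nodule_id, idx))
    return patches


def resize_patch(patch: CTPatch, size: int = 96) -> CTPatch:
    """Resize to size×size: bilinear for the image, nearest for the mask."""
    img = sk_resize(patch.image, (size, size), order=1, mode="reflect",
                    anti_aliasing=True).astype(np.float64)
    msk = sk_resize(patch.mask.astype(np.float64), (size, size), order=0,
                    mode="reflect", anti_aliasing=False)
    return CTPatch(np.clip(img, 0.0, 1.0), (msk > 0.5).astype(np.uint8),
                   patch.patient_id, patch.nodule_id, patch.crop_index)


# ---------------------------------------------------------------------------
# dataset building


DEFAULT_DATASET_CONFIG = {
    "n_patients": 10,
    "nodules_per_patient": 1,
    "crops_per_nodule": 5,          # five non-centred crops per nodule
    "scene_size": 192,
    "diameter_range": [12, 48],
    "types": list(NODULE_TYPES),
    "noise_sigma": 0.05,
    "min_margin": 4,
    "patch_size": 96,               # all patches resized to 96x96
    "seed": 0,
    "write_nifti": False,
}


def _save_png(path: Path, arr01: np.ndarray) -> None:
    try:
        iio.imwrite(path, np.round(arr01 * 255).astype(np.uint8))
    except OSError as e:  # pragma: no cover
        raise OSError(f"failed to write {path}: {e}") from e


def build_dataset(config: dict | None, out_dir: str | Path) -> pd.DataFrame:
    """Generate scenes, crop, resize and write a PNG dataset + manifest.

    Returns the manifest as a DataFrame; also written to
    ``out_dir/manifest.csv`` with columns
    patient_id,nodule_id,crop_index,image_path,mask_path (paths relative to
    ``out_dir``).  Rebuilding with the same config is byte-identical.
    """
    cfg = dict(DEFAULT_DATASET_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    types: Sequence[str] = cfg["types"]
    base_seed = int(cfg["seed"])
    rows = []
    counter = 0
    for p in range(int(cfg["n_patients"])):
        patient_id = f"P{p:03d}"
        for k in range(int(cfg["nodules_per_patient"])):
            # disjoint seed range per synthetic patient
            nodule_seed = base_seed + p * 10_000 + k * 100
            nodule_id = f"N{k}"
            rng = np.random.default_rng(nodule_seed)
            d_lo, d_hi = cfg["diameter_range"]
            diameter = int(rng.integers(d_lo, d_hi + 1))
            ntype = types[counter % len(types)]
            counter += 1
            spec = NoduleSpec(ntype, diameter, scene_size=int(cfg["scene_size"]),
                              seed=nodule_seed + 1,
                              noise_sigma=float(cfg["noise_sigma"]))
            image, mask = make_nodule_scene(spec)
            # wall-attached nodules can run to the scene border: clamp the
            # requested margin to the room the scene actually leaves
            rr = np.flatnonzero(mask.any(axis=1))
            cc = np.flatnonzero(mask.any(axis=0))
            avail = (rr[0], mask.shape[0] - rr[-1] - 1,
                     cc[0], mask.shape[1] - cc[-1] - 1)
            margin = min(int(cfg["min_margin"]), *avail)
            patches = crop_variants(image, mask, n=int(cfg["crops_per_nodule"]),
                                    min_margin=margin,
                                    seed=nodule_seed + 50,
                                    patient_id=patient_id, nodule_id=nodule_id)
            for patch in patches:
                patch = resize_patch(patch, int(cfg["patch_size"]))
                stem = f"{patient_id}_{nodule_id}_c{patch.crop_index}"
                img_rel = f"images/{stem}.png"
                msk_rel = f"masks/{stem}.png"
                _save_png(out / img_rel, patch.image)
                _save_png(out / msk_rel, patch.mask.astype(np.float64))
                if cfg["write_nifti"]:
                    import nibabel as nib
                    nib.save(nib.Nifti1Image(patch.image.astype(np.float32), np.eye(4)),
                             out / "images" / f"{stem}.nii.gz")
                    nib.save(nib.Nifti1Image(patch.mask.astype(np.uint8), np.eye(4)),
                             out / "masks" / f"{stem}.nii.gz")
                rows.append({"patient_id": patient_id, "nodule_id": nodule_id,
                             "crop_index": patch.crop_index,
                             "image_path": img_rel, "mask_path": msk_rel})

    manifest = pd.DataFrame(rows, columns=["patient_id", "nodule_id",
                                           "crop_index", "image_path", "mask_path"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_patch(dataset_dir: str | Path, row: pd.Series) -> CTPatch:
    """Read one manifest row back into a CTPatch (intensities in [0,1])."""
    root = Path(dataset_dir)
    img = iio.imread(root / row["image_path"]).astype(np.float64) / 255.0
    msk = (iio.imread(root / row["mask_path"]) > 127).astype(np.uint8)
    return CTPatch(img, msk, row["patient_id"], row["nodule_id"],
                   int(row["crop_index"]))
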
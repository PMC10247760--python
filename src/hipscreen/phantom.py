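"""Synthetic Graf-plane hip ultrasound phantoms with exact known geometry.

Every downstream module (segmentation, geometry, decision) is exercised on
frames produced here, so the phantom fixes the coordinate conventions for the
whole package:

* pixels are 0-based ``(row, col)`` indices, origin top-left;
* the iliac "baseline" echo runs approximately parallel to the image vertical
  (row) axis, as in a standard Graf-orientation coronal view;
* the medial (covered) side of the hip is toward increasing column index.

A frame is built from three analytic primitives: a bright near-vertical iliac
stroke ending at the bony rim, a bright acetabular-roof stroke leaving the rim
medially at the true alpha angle, and a hypoechoic (dark) femoral-head disk
whose signed offset from the baseline sets the true femoral head coverage
(FHC).  Ultrasound-like texture is layered on top: unit-mean multiplicative
gamma speckle, Gaussian blur, and acoustic shadowing beneath the bone echoes.

Out-of-plane frames (|plane_offset| beyond the adequate band) degrade the way
a real sweep does when the probe leaves the standard plane: bone echoes fade
and shorten linearly, and the femoral head loses contrast twice as fast.  The
ground-truth label mask applies a crisp version of the same rule — the head
class is present iff the frame is within the adequate band, and bone strokes
truncate progressively — so frame-adequacy gating has an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from . import pngio

#: Default half-width of the adequate band of plane offsets, in pixels.
ADEQUATE_BAND_DEFAULT = 16.0

# Scene intensities (echo brightness on the [0, 1] grayscale).
_BG_LEVEL = 0.35
_BONE_LEVEL = 0.95
_HEAD_LEVEL = 0.08
_STROKE_HALFWIDTH = 1.5
_SHADOW_ATTENUATION = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic hip frame.

    ``alpha_true`` is the Graf alpha angle (degrees) between the iliac
    baseline and the bony acetabular roof; ``head_offset_px`` is the signed
    displacement of the femoral-head center from the baseline along the
    baseline normal (positive = medial = covered side), which determines the
    true coverage ``fhc_true = clip((r + offset) / 2r, 0, 1)``.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    alpha_true: float = 60.0
    head_radius_px: float = 30.0
    head_offset_px: float = 0.0
    speckle_strength: float = 0.03
    blur_sigma_px: float = 0.8
    shadow_strength: float = 0.2
    rim_point: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValidationError("image_height_px/image_width_px must be positive")
        if not (30.0 <= self.alpha_true <= 90.0):
            raise ValidationError(f"alpha_true must be in [30, 90] degrees, got {self.alpha_true}")
        if self.head_radius_px <= 0:
            raise ValidationError(f"head_radius_px must be positive, got {self.head_radius_px}")
        if self.speckle_strength < 0:
            raise ValidationError("speckle_strength must be nonnegative")
        if self.blur_sigma_px < 0:
            raise ValidationError("blur_sigma_px must be nonnegative")
        if not (0.0 <= self.shadow_strength <= 1.0):
            raise ValidationError("shadow_strength must be in [0, 1]")

    @property
    def rim(self) -> np.ndarray:
        """Rim point (row, col); defaults to (0.25 H, 0.375 W)."""
        if self.rim_point is not None:
            return np.asarray(self.rim_point, dtype=float)
        return np.array([0.25 * self.image_height_px, 0.375 * self.image_width_px])

    @property
    def fhc_true(self) -> float:
        r = self.head_radius_px
        return float(np.clip((r + self.head_offset_px) / (2.0 * r), 0.0, 1.0))


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel landmark labels: 0 background, 1 acetabulum-ilium, 2 femoral head."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValidationError("labels must be drawn from {0, 1, 2}")
        object.__setattr__(self, "labels", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def classes_present(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


@dataclass(frozen=True)
class GroundTruth:
    """Exact construction parameters carried alongside a rendered frame."""

    label_mask: LabelMask
    alpha_true: float
    fhc_true: float
    baseline_true: tuple[np.ndarray, np.ndarray]  # (point, unit direction)
    roof_true: tuple[np.ndarray, np.ndarray]
    head_center_true: np.ndarray
    head_radius_true: float
    plane_offset: float = 0.0


@dataclass(frozen=True)
class SweepSpec:
    """An ordered cine sweep: one phantom scanned at a list of plane offsets."""

    phantom: PhantomSpec
    plane_offsets: Sequence[float]
    adequate_band_px: float = ADEQUATE_BAND_DEFAULT
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.adequate_band_px <= 0:
            raise ValidationError("adequate_band_px must be positive")
        if self.n_frames is None:
            object.__setattr__(self, "n_frames", len(self.plane_offsets))
        elif self.n_frames != len(self.plane_offsets):
            raise ValidationError(
                f"n_frames={self.n_frames} does not match len(plane_offsets)={len(self.plane_offsets)}"
            )


def _geometry(spec: PhantomSpec) -> dict:
    """Analytic scene geometry shared by the renderer and the ground truth."""
    rim = spec.rim
    a = np.deg2rad(spec.alpha_true)
    d_base = np.array([1.0, 0.0])          # baseline direction, pointing caudally (down)
    d_roof = np.array([np.cos(a), np.sin(a)])  # roof leaves the rim medially at alpha
    len_base = 0.8 * rim[0]
    len_roof = 0.30 * min(spec.image_height_px, spec.image_width_px)
    # Femoral head: column fixed by the coverage offset; row chosen so the
    # disk nestles just below the roof line without touching the bone stroke.
    clearance = _STROKE_HALFWIDTH + 2.5
    r, off = spec.head_radius_px, spec.head_offset_px
    sin_a, cos_a = np.sin(a), np.cos(a)
    dr = (r + clearance + off * cos_a) / max(sin_a, 1e-6)
    dr = max(dr, r + 6.0)
    center = rim + np.array([dr, off])
    return {
        "rim": rim,
        "d_base": d_base,
        "d_roof": d_roof,
        "len_base": len_base,
        "len_roof": len_roof,
        "head_center": center,
    }


def _segment_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
                  halfwidth: float) -> np.ndarray:
    """Pixels within ``halfwidth`` of the segment p0→p1 (distance transform free)."""
    rows, cols = np.indices(shape, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length < 1e-9:
        dist = np.hypot(rows - p0[0], cols - p0[1])
        return dist <= halfwidth
    d = d / length
    t = (rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]
    t = np.clip(t, 0.0, length)
    dist = np.hypot(rows - (p0[0] + t * d[0]), cols - (p0[1] + t * d[1]))
    return dist <= halfwidth


def _visibility(plane_offset: float, band: float) -> tuple[float, float]:
    """(bone, head) visibility in [0, 1]; both 1 inside the adequate band."""
    excess = max(0.0, abs(plane_offset) - band)
    v_bone = max(0.0, 1.0 - excess / band)
    v_head = max(0.0, 1.0 - 2.0 * excess / band)
    return v_bone, v_head


def _frame_rng(spec: PhantomSpec, plane_offset: float) -> np.random.Generator:
    off_bits = int(np.float64(plane_offset).view(np.int64)) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((spec.seed & 0x7FFFFFFF, off_bits)))


def render_frame(
    spec: PhantomSpec,
    plane_offset: float = 0.0,
    adequate_band_px: float = ADEQUATE_BAND_DEFAULT,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame and its exact ground truth.

    Returns ``(image, truth)`` where ``image`` is float64 in [0, 1] of shape
    (image_height_px, image_width_px).  Identical ``(spec, plane_offset)``
    yield bit-identical output.
    """
    geo = _geometry(spec)
    shape = (spec.image_height_px, spec.image_width_px)
    v_bone, v_head = _visibility(plane_offset, adequate_band_px)
    in_band = abs(plane_offset) <= adequate_band_px

    # Bone strokes, truncated toward the rim as the plane leaves the band.
    base_p0 = geo["rim"] - geo["d_base"] * geo["len_base"] * v_bone
    base_p1 = geo["rim"]
    roof_p1 = geo["rim"] + geo["d_roof"] * geo["len_roof"] * v_bone
    if v_bone > 0:
        base_stroke = _segment_mask(shape, base_p0, base_p1, _STROKE_HALFWIDTH)
        roof_stroke = _segment_mask(shape, geo["rim"], roof_p1, _STROKE_HALFWIDTH)
    else:
        base_stroke = np.zeros(shape, dtype=bool)
        roof_stroke = np.zeros(shape, dtype=bool)
    bone = base_stroke | roof_stroke

    rows, cols = np.indices(shape, dtype=float)
    cr, cc = geo["head_center"]
    disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= spec.head_radius_px**2

    scene = np.full(shape, _BG_LEVEL)
    if v_head > 0:
        scene[disk] = _BG_LEVEL - v_head * (_BG_LEVEL - _HEAD_LEVEL)
    if v_bone > 0:
        scene[bone] = _BG_LEVEL + v_bone * (_BONE_LEVEL - _BG_LEVEL)

    # Acoustic shadow: attenuate everything below a bone echo in its column.
    if spec.shadow_strength > 0 and bone.any():
        below = np.cumsum(bone, axis=0) > 0
        shadow = below & ~bone
        scene = scene * np.where(shadow, 1.0 - _SHADOW_ATTENUATION * spec.shadow_strength * v_bone, 1.0)

    if spec.speckle_strength > 0:
        rng = _frame_rng(spec, plane_offset)
        k = 1.0 / spec.speckle_strength
        scene = scene * rng.gamma(shape=k, scale=1.0 / k, size=shape)
    if spec.blur_sigma_px > 0:
        scene = ndimage.gaussian_filter(scene, sigma=spec.blur_sigma_px)
    image = np.clip(scene, 0.0, 1.0)

    labels = np.zeros(shape, dtype=np.uint8)
    if in_band:  # head class present iff the frame is in-plane
        labels[disk] = 2
    labels[bone] = 1

    a = np.deg2rad(spec.alpha_true)
    truth = GroundTruth(
        label_mask=LabelMask(labels),
        alpha_true=spec.alpha_true,
        fhc_true=spec.fhc_true,
        baseline_true=(geo["rim"].copy(), np.array([1.0, 0.0])),
        roof_true=(geo["rim"].copy(), np.array([np.cos(a), np.sin(a)])),
        head_center_true=geo["head_center"].copy(),
        head_radius_true=spec.head_radius_px,
        plane_offset=plane_offset,
    )
    return image, truth


def render_sweep(sweep: SweepSpec) -> tuple[list[np.ndarray], list[GroundTruth]]:
    """Render an ordered cine sweep; one (frame, truth) pair per plane offset."""
    frames: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    for off in sweep.plane_offsets:
        img, truth = render_frame(sweep.phantom, off, adequate_band_px=sweep.adequate_band_px)
        frames.append(img)
        truths.append(truth)
    return frames, truths


@dataclass
class PhantomDataset:
    """A rendered cohort: per-frame images, truth masks and a truth table."""

    images: list[np.ndarray]
    masks: list[LabelMask]
    table: pd.DataFrame  # columns: subject_id, frame_id, alpha_true_deg, fhc_true, plane_offset_px, seed
    specs: list[PhantomSpec] = field(default_factory=list)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def write(self, out_dir: str | Path) -> Path:
        """Write frames/masks as PNG plus a manifest CSV; returns manifest path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths_f, paths_m = [], []
        for i, row in self.table.iterrows():
            sub = out / str(row["subject_id"])
            sub.mkdir(exist_ok=True)
            fp = sub / f"frame_{int(row['frame_id']):03d}.png"
            mp = sub / f"mask_{int(row['frame_id']):03d}.png"
            pngio.write_frame(fp, self.images[i])
            pngio.write_mask(mp, self.masks[i].labels)
            paths_f.append(str(fp.relative_to(out)))
            paths_m.append(str(mp.relative_to(out)))
        manifest = self.table.copy()
        manifest["frame_path"] = paths_f
        manifest["mask_path"] = paths_m
        path = out / "manifest.csv"
        manifest.to_csv(path, index=False)
        return path


def make_dataset(
    n_subjects: int,
    alpha_range: tuple[float, float] = (43.0, 75.0),
    fhc_range: tuple[float, float] = (0.25, 0.75),
    frames_per_subject: int = 4,
    seed: int = 0,
    image_size_px: int = 128,
    speckle_strength: float = 0.03,
    blur_sigma_px: float = 0.8,
    shadow_strength: float = 0.2,
    adequate_band_px: float = ADEQUATE_BAND_DEFAULT,
) -> PhantomDataset:
    """Render a multi-subject phantom cohort for training and evaluation.

    Each subject gets one hip geometry (alpha, coverage, head radius) drawn
    uniformly from the stated ranges, scanned at ``frames_per_subject``
    in-band plane offsets.  Deterministic for a given seed.
    """
    if n_subjects <= 0:
        raise ValidationError("n_subjects must be positive")
    if frames_per_subject <= 0:
        raise ValidationError("frames_per_subject must be positive")
    for name, (lo, hi) in (("alpha_range", alpha_range), ("fhc_range", fhc_range)):
        if hi < lo:
            raise ValidationError(f"{name} is empty: {(lo, hi)}")
    if not (30.0 <= alpha_range[0] and alpha_range[1] <= 90.0):
        raise ValidationError("alpha_range must lie within [30, 90] degrees")
    if not (0.0 <= fhc_range[0] and fhc_range[1] <= 1.0):
        raise ValidationError("fhc_range must lie within [0, 1]")

    rng = np.random.default_rng(seed)
    scale = image_size_px / 256.0
    images, masks, specs, rows = [], [], [], []
    for s in range(n_subjects):
        subject_id = f"S{s:04d}"
        alpha = float(rng.uniform(*alpha_range))
        fhc = float(rng.uniform(*fhc_range))
        radius = float(rng.uniform(24.0, 34.0)) * scale
        offset = (2.0 * fhc - 1.0) * radius
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            image_height_px=image_size_px,
            image_width_px=image_size_px,
            alpha_true=alpha,
            head_radius_px=radius,
            head_offset_px=offset,
            speckle_strength=speckle_strength,
            blur_sigma_px=blur_sigma_px,
            shadow_strength=shadow_strength,
            seed=sub_seed,
        )
        offsets = rng.uniform(-0.7 * adequate_band_px, 0.7 * adequate_band_px,
                              size=frames_per_subject)
        for f, off in enumerate(offsets):
            img, truth = render_frame(spec, float(off), adequate_band_px=adequate_band_px)
            images.append(img)
            masks.append(truth.label_mask)
            specs.append(spec)
            rows.append(
                dict(subject_id=subject_id, frame_id=f, alpha_true_deg=alpha,
                     fhc_true=spec.fhc_true, plane_offset_px=float(off), seed=sub_seed)
            )
    return PhantomDataset(images=images, masks=masks, table=pd.DataFrame(rows), specs=specs)
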
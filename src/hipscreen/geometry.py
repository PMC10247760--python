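"""Graf-method geometric measurement from landmark label masks.

The two clinical indices are:

* **alpha angle** — the angle at the bony rim between the iliac baseline and
  the bony acetabular roof line (>= 60 degrees is conventionally normal);
* **femoral head coverage (FHC)** — the fraction of the femoral-head diameter
  lying medial to the baseline, ``clip((r + s) / 2r, 0, 1)`` with ``s`` the
  signed center-to-baseline distance (Morin-style d/D convention; >= 0.5 is
  conventionally normal).

Both lines are recovered by total-least-squares fits to bone-class pixels.
Because the iliac and roof echoes usually form a single connected component
meeting at the rim, they are first separated with a Hough-transform two-line
decomposition, then each line is refined by TLS on its assigned pixels.  The
femoral head is an algebraic (Kasa) least-squares circle through the
boundary pixels of the head class.

Coordinate convention (set by the phantom module and assumed for any input):
0-based (row, col), origin top-left, baseline approximately vertical, medial
side toward increasing column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure
from skimage import morphology
from skimage.transform import hough_line, hough_line_peaks

from .errors import DegenerateGeometryError, MissingLandmarkError, ValidationError
from .phantom import LabelMask

# Quality flags attached to a HipGeometry.
MISSING_CLASS = "MISSING_CLASS"
HIGH_LINE_RESIDUAL = "HIGH_LINE_RESIDUAL"
HIGH_CIRCLE_RESIDUAL = "HIGH_CIRCLE_RESIDUAL"
SMALL_HEAD = "SMALL_HEAD"
DEGENERATE_ANGLE = "DEGENERATE_ANGLE"


@dataclass(frozen=True)
class GeometryConfig:
    """Tunables for the fitting pipeline (pixel units throughout)."""

    min_roof_px: int = 10          # minimum pixel support for the roof line
    min_circle_px: int = 12        # minimum boundary support for the head circle
    assign_dist_px: float = 2.5    # pixel-to-line assignment radius in refinement
    max_line_residual_px: float = 1.5
    max_circle_residual_px: float = 2.0
    min_head_radius_px: float = 8.0
    hough_theta_step_deg: float = 0.5


@dataclass(frozen=True)
class LineFit:
    point: np.ndarray              # (row, col) on the line
    direction: np.ndarray          # unit (row, col) direction
    rms_residual_px: float
    n_support_px: int

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", d / n)

    def signed_distance(self, points: np.ndarray, medial_positive: bool = True) -> np.ndarray:
        """Signed distance of (row, col) points; positive on the medial side."""
        d = self.direction
        normal = np.array([-d[1], d[0]])
        if medial_positive:
            if abs(normal[1]) < 1e-12:
                raise DegenerateGeometryError(
                    "baseline is horizontal; medial side undefined under the "
                    "vertical-baseline convention"
                )
            if normal[1] < 0:
                normal = -normal
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ normal


@dataclass(frozen=True)
class CircleFit:
    center: np.ndarray
    radius_px: float
    rms_residual_px: float
    n_support_px: int

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValidationError(f"radius_px must be positive, got {self.radius_px}")


@dataclass(frozen=True)
class HipGeometry:
    """Fitted Graf construction with derived indices and quality flags."""

    alpha_deg: float | None
    fhc: float | None
    baseline: LineFit | None
    roof: LineFit | None
    head: CircleFit | None
    quality_flags: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        def line(l: LineFit | None):
            return None if l is None else dict(
                point=list(map(float, l.point)), direction=list(map(float, l.direction)),
                rms_residual_px=l.rms_residual_px, n_support_px=l.n_support_px)

        head = None if self.head is None else dict(
            center=list(map(float, self.head.center)), radius_px=self.head.radius_px,
            rms_residual_px=self.head.rms_residual_px, n_support_px=self.head.n_support_px)
        return json.dumps(dict(
            alpha_deg=self.alpha_deg, fhc=self.fhc, baseline=line(self.baseline),
            roof=line(self.roof), head=head, quality_flags=sorted(self.quality_flags)))


def _tls_line(points: np.ndarray) -> LineFit:
    """Total-least-squares (PCA) line through (row, col) points."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    w, v = np.linalg.eigh(cov)
    direction = v[:, np.argmax(w)]
    rms = float(np.sqrt(max(w[np.argmin(w)], 0.0)))
    return LineFit(point=centroid, direction=direction, rms_residual_px=rms,
                   n_support_px=len(pts))


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab = skmeasure.label(binary, connectivity=2)
    if lab.max() == 0:
        return binary
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == np.argmax(counts)


def _line_points(mask: LabelMask) -> np.ndarray:
    """Bone-class pixels after morphological cleaning (largest component)."""
    bone = _largest_component(np.asarray(mask.labels) == 1)
    return np.argwhere(bone)


def _hough_two_lines(pts: np.ndarray, shape: tuple[int, int],
                     config: GeometryConfig) -> list[LineFit]:
    """Detect up to two dominant lines among bone pixels via the Hough transform."""
    binary = np.zeros(shape, dtype=bool)
    binary[pts[:, 0], pts[:, 1]] = True
    thetas = np.deg2rad(np.arange(-90.0, 90.0, config.hough_theta_step_deg))
    h, theta, dist = hough_line(binary, theta=thetas)
    # A stroke of finite width votes for a fan of nearby (theta, dist) cells,
    # so take several peaks and pick two with real angular separation: the
    # most vertical peak is the baseline seed, the strongest peak at least
    # 15 degrees away (mod 180) is the roof seed.
    # Low explicit threshold: a near-diagonal stroke can out-vote a shorter
    # orthogonal one by more than 2x, and the default 0.5*max would drop it.
    _, angles, dists = hough_line_peaks(
        h, theta, dist, num_peaks=6,
        min_distance=max(5, int(0.02 * max(shape))),
        min_angle=int(5 / config.hough_theta_step_deg),
        threshold=max(5.0, 0.15 * float(h.max())))
    if len(angles) == 0:
        return []

    def to_fit(ang: float, d: float) -> LineFit:
        # Hough line x*cos(t) + y*sin(t) = d with x=col, y=row.
        point = np.array([d * np.sin(ang), d * np.cos(ang)])  # (row, col)
        direction = np.array([np.cos(ang), -np.sin(ang)])
        return LineFit(point=point, direction=direction, rms_residual_px=0.0,
                       n_support_px=0)

    verticality = np.abs(np.cos(angles))
    i_base = int(np.argmax(verticality))
    fits = [to_fit(angles[i_base], dists[i_base])]
    sep = np.abs(np.degrees(angles) - np.degrees(angles[i_base]))
    sep = np.minimum(sep, 180.0 - sep)
    for i in range(len(angles)):  # peaks come in decreasing-vote order
        if i != i_base and sep[i] >= 15.0:
            fits.append(to_fit(angles[i], dists[i]))
            break
    return fits


def _point_line_dist(pts: np.ndarray, line: LineFit) -> np.ndarray:
    d = line.direction
    normal = np.array([-d[1], d[0]])
    return np.abs((pts - line.point) @ normal)


def _decompose_bone(mask: LabelMask, config: GeometryConfig) -> tuple[LineFit, LineFit | None]:
    """Split the bone class into (baseline, roof) line fits.

    The baseline is the detected line closer to vertical; pixels are assigned
    to their nearest detected line and each fit is TLS-refined twice.
    """
    pts = _line_points(mask)
    if len(pts) == 0:
        raise MissingLandmarkError("acetabulum-ilium class (label 1) is empty")
    if len(pts) < 5:
        raise MissingLandmarkError("acetabulum-ilium class has too few pixels to fit")
    shape = mask.shape
    seeds = _hough_two_lines(pts, shape, config)
    if not seeds:
        seeds = [_tls_line(pts)]
    base = seeds[0]  # most vertical detected line
    roof = seeds[1] if len(seeds) == 2 else None
    # Nearest-line competition with a loose cap: strokes may be several
    # pixels wide (or upsampled), and a tight cap around an off-center Hough
    # seed would clip one flank and bias the refined line.
    cap = 2.0 * config.assign_dist_px
    for _ in range(3):  # alternate assignment / TLS refinement
        db = _point_line_dist(pts, base)
        if roof is not None:
            dr = _point_line_dist(pts, roof)
            base_pts = pts[(db <= dr) & (db <= cap)]
            roof_pts = pts[(dr < db) & (dr <= cap)]
        else:
            base_pts = pts[db <= cap]
            roof_pts = np.empty((0, 2))
        if len(base_pts) >= 5:
            base = _tls_line(base_pts)
        if len(roof_pts) >= config.min_roof_px:
            roof = _tls_line(roof_pts)
        elif roof is not None and len(roof_pts) < config.min_roof_px:
            roof = None
    return base, roof


def fit_baseline(mask: LabelMask, config: GeometryConfig = GeometryConfig()) -> LineFit:
    """Fit the iliac baseline (the near-vertical bone echo) by Hough + TLS."""
    base, _ = _decompose_bone(mask, config)
    return base


def fit_roof_line(mask: LabelMask, baseline: LineFit,
                  config: GeometryConfig = GeometryConfig()) -> LineFit:
    """Fit the bony-roof line: TLS on bone pixels away from the given baseline."""
    pts = _line_points(mask)
    if len(pts) == 0:
        raise MissingLandmarkError("acetabulum-ilium class (label 1) is empty")
    roof_pts = pts[_point_line_dist(pts, baseline) > config.assign_dist_px]
    if len(roof_pts) < config.min_roof_px:
        raise MissingLandmarkError(
            f"roof segment has {len(roof_pts)} px, below minimum {config.min_roof_px}")
    roof = _tls_line(roof_pts)
    # one re-assignment pass against the refined roof line
    sel = _point_line_dist(roof_pts, roof) <= config.assign_dist_px
    if sel.sum() >= config.min_roof_px:
        roof = _tls_line(roof_pts[sel])
    return roof


def fit_head_circle(mask: LabelMask, config: GeometryConfig = GeometryConfig()) -> CircleFit:
    """Algebraic least-squares circle through the femoral-head boundary pixels."""
    head = np.asarray(mask.labels) == 2
    if not head.any():
        raise MissingLandmarkError("femoral head class (label 2) is empty")
    head = _largest_component(head)
    boundary = head & ~morphology.erosion(head)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) < config.min_circle_px:
        raise MissingLandmarkError(
            f"head boundary has {len(pts)} px, below minimum {config.min_circle_px}")
    # Kasa fit: minimize ||A [a b c]^T - (x^2 + y^2)||
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    a, b, c = sol
    r2 = c + a**2 + b**2
    if r2 <= 0:
        raise MissingLandmarkError("degenerate circle fit for the femoral head")
    radius = float(np.sqrt(r2))
    dist = np.hypot(x - a, y - b)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return CircleFit(center=np.array([a, b]), radius_px=radius,
                     rms_residual_px=rms, n_support_px=len(pts))


def _canonical_directions(baseline: LineFit, roof: LineFit) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(baseline.direction, dtype=float).copy()
    r = np.asarray(roof.direction, dtype=float).copy()
    if b[0] < 0 or (b[0] == 0 and b[1] < 0):
        b = -b  # baseline points caudally (increasing row)
    if r[1] < 0 or (r[1] == 0 and r[0] < 0):
        r = -r  # roof points medially (increasing col)
    return b, r


def alpha_angle(baseline: LineFit, roof: LineFit) -> float:
    """Alpha angle (degrees) between the baseline and the roof on the roof side.

    Measured between the caudally-oriented baseline ray and the
    medially-oriented roof ray, so the result is invariant to sign flips of
    the stored direction vectors and can exceed 90 degrees.
    """
    b, r = _canonical_directions(baseline, roof)
    angle = float(np.degrees(np.arccos(np.clip(b @ r, -1.0, 1.0))))
    if angle < 1.0:
        raise DegenerateGeometryError(
            f"baseline and roof are near-parallel (angle {angle:.3f} deg)")
    return angle


def femoral_head_coverage(head: CircleFit, baseline: LineFit) -> float:
    """Femoral head coverage clip((r + s) / 2r, 0, 1), s = signed medial distance."""
    if head.radius_px <= 0:
        raise ValidationError("head radius must be positive")
    s = float(baseline.signed_distance(head.center, medial_positive=True)[0])
    return float(np.clip((head.radius_px + s) / (2.0 * head.radius_px), 0.0, 1.0))


def coverage_pixel_oracle(center: np.ndarray, radius: float, baseline: LineFit,
                          step: float = 0.5) -> float:
    """Independent coverage estimate by rasterized extreme-point projection.

    The head disk is rasterized on a grid of pitch ``step`` pixels; every grid
    point inside the disk is projected onto the baseline normal, and coverage
    is the medial extent of the projections divided by their total extent
    (i.e. the fraction of the head *diameter* medial to the baseline).  This
    is independent of the closed-form ``(r + s) / 2r`` path and converges to
    it as ``step`` shrinks.
    """
    cr, cc = float(center[0]), float(center[1])
    rr = np.arange(np.floor(cr - radius) - 1, np.ceil(cr + radius) + 1 + step, step)
    cols = np.arange(np.floor(cc - radius) - 1, np.ceil(cc + radius) + 1 + step, step)
    R, C = np.meshgrid(rr, cols, indexing="ij")
    inside = (R - cr) ** 2 + (C - cc) ** 2 <= radius**2
    pts = np.column_stack([R[inside], C[inside]]).astype(float)
    if len(pts) == 0:
        raise ValidationError("disk rasterized to zero pixels")
    s = baseline.signed_distance(pts, medial_positive=True)
    # project onto the baseline normal: medial extreme minus lateral extreme
    medial_extent = float(np.clip(s.max(), 0.0, None))
    total_extent = float(s.max() - s.min())
    if total_extent <= 0:
        raise ValidationError("degenerate rasterized disk")
    return medial_extent / total_extent


def measure(mask: LabelMask, config: GeometryConfig = GeometryConfig()) -> HipGeometry:
    """Run the full Graf measurement; never raises on missing landmarks.

    Landmark absence and poor fits are reported via ``quality_flags``; the
    corresponding index is left unset.
    """
    flags: set[str] = set()
    baseline = roof = None
    head = None
    try:
        baseline, roof = _decompose_bone(mask, config)
    except MissingLandmarkError:
        flags.add(MISSING_CLASS)
    if baseline is not None and roof is None:
        flags.add(MISSING_CLASS)
    try:
        head = fit_head_circle(mask, config)
    except MissingLandmarkError:
        flags.add(MISSING_CLASS)

    alpha = None
    if baseline is not None and roof is not None:
        if max(baseline.rms_residual_px, roof.rms_residual_px) > config.max_line_residual_px:
            flags.add(HIGH_LINE_RESIDUAL)
        try:
            alpha = alpha_angle(baseline, roof)
        except DegenerateGeometryError:
            flags.add(DEGENERATE_ANGLE)

    fhc = None
    if head is not None:
        if head.rms_residual_px > config.max_circle_residual_px:
            flags.add(HIGH_CIRCLE_RESIDUAL)
        if head.radius_px < config.min_head_radius_px:
            flags.add(SMALL_HEAD)
        if baseline is not None:
            try:
                fhc = femoral_head_coverage(head, baseline)
            except (DegenerateGeometryError, ValidationError):
                flags.add(DEGENERATE_ANGLE)
    return HipGeometry(alpha_deg=alpha, fhc=fhc, baseline=baseline, roof=roof,
                       head=head, quality_flags=flags)
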
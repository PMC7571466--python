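"""EM morphometry of kinetochore outer plates.

Operates on traced plate contours (ordered 2D point lists with a nm/pixel
calibration): polyline length, Pratt circular-arc fitting (curvature radius),
rotational/translational alignment of plates on their terminus chord, average
plate compositing, and simple population statistics.

Curvature is reported as the fitted circle *radius* in nm; a smaller radius
means a more strongly curved plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from skimage.draw import line as _draw_line

DEFAULT_CALIBRATION_NM_PER_PX = 1.88


@dataclass
class PlateContour:
    """Ordered trace of a plate: points in nm plus the pixel calibration it came from."""

    points_nm: np.ndarray  # (N, 2) float, ordered along the plate
    calibration: float = DEFAULT_CALIBRATION_NM_PER_PX  # nm per pixel
    source_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_nm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if len(pts) >= 2 and np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")
        self.points_nm = pts

    @classmethod
    def from_pixels(
        cls,
        points_px: np.ndarray,
        calibration: float = DEFAULT_CALIBRATION_NM_PER_PX,
        **kw,
    ) -> "PlateContour":
        return cls(np.asarray(points_px, dtype=float) * calibration, calibration, **kw)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.points_nm / self.calibration, columns=["x_px", "y_px"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, calibration: float = DEFAULT_CALIBRATION_NM_PER_PX, **kw):
        df = pd.read_csv(path)
        return cls.from_pixels(df[["x_px", "y_px"]].to_numpy(), calibration, **kw)

    def __len__(self) -> int:
        return len(self.points_nm)


@dataclass(frozen=True)
class CircleFitResult:
    center: tuple  # (x, y) nm; NaN for the collinear (infinite-radius) sentinel
    radius: float  # nm; math.inf for collinear input
    rms_residual: float  # nm

    @property
    def is_degenerate(self) -> bool:
        return not math.isfinite(self.radius)


@dataclass
class AveragedPlate:
    """Mean 32-bit image of rotationally aligned plates plus the arc fitted to its chord."""

    image: np.ndarray  # float32, (ny, nx), mean of aligned rasterized plates
    n_plates: int
    pixel_size: float  # nm per pixel
    origin: tuple  # nm coordinates of pixel (0, 0) centre
    chord_points_nm: np.ndarray  # (M, 2) sub-pixel ridge of the averaged plate
    fit: CircleFitResult


def contour_length(contour: PlateContour) -> float:
    """Polyline length of the trace in nm."""
    pts = contour.points_nm
    if len(pts) < 2:
        raise ValueError("contour length needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def fit_circle_pratt(contour) -> CircleFitResult:
    """Algebraic circle fit minimizing the Pratt-normalized algebraic distance.

    Solves the generalized eigenproblem M v = eta B v for the conic
    a(x^2+y^2) + b x + c y + d = 0 with the Pratt constraint
    b^2 + c^2 - 4 a d = 1.  Collinear points give a ~= 0 and are reported as
    an infinite-radius sentinel rather than an error.
    """
    pts = contour.points_nm if isinstance(contour, PlateContour) else np.asarray(contour, float)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T  # centred for conditioning
    z = x * x + y * y
    A = np.column_stack([z, x, y, np.ones_like(x)])
    M = A.T @ A / len(pts)
    B = np.zeros((4, 4))
    B[0, 3] = B[3, 0] = -2.0
    B[1, 1] = B[2, 2] = 1.0
    # eigenvectors of B^-1 M; the Pratt solution is the one with the smallest
    # nonnegative eigenvalue
    evals, evecs = np.linalg.eig(np.linalg.solve(B, M))
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(np.where(evals >= -1e-12, evals, np.inf))
    v = evecs[:, order[0]]
    a, b, c, d = v
    scale = float(np.hypot(x, y).max())
    if abs(a) * scale < 1e-12 * max(abs(b), abs(c), 1e-300):
        return CircleFitResult((math.nan, math.nan), math.inf, _line_rms(pts))
    cx = -b / (2 * a)
    cy = -c / (2 * a)
    radius = math.sqrt(max(b * b + c * c - 4 * a * d, 0.0)) / (2 * abs(a))
    centre = np.array([cx, cy]) + mean
    r = np.linalg.norm(pts - centre, axis=1)
    rms = float(np.sqrt(np.mean((r - radius) ** 2)))
    return CircleFitResult((float(centre[0]), float(centre[1])), float(radius), rms)


def _line_rms(pts: np.ndarray) -> float:
    # orthogonal distance to the best-fit line, for the degenerate sentinel
    centred = pts - pts.mean(axis=0)
    _, s, _ = np.linalg.svd(centred, full_matrices=False)
    return float(s[-1] / math.sqrt(len(pts)))


def align_plate(contour: PlateContour):
    """Rotate a plate so its termini lie on a horizontal line, apex at the origin.

    The termini are the first and last contour points; the apex is the contour
    point with maximal perpendicular distance from the terminus chord.  The
    plate is rotated about the chord direction, reflected if needed so the
    apex lies above the chord, and translated to put the apex at (0, 0).

    Returns ``(aligned_contour, rotation_deg, translation_nm)`` where applying
    the rotation then translation to the input reproduces the output.
    """
    pts = contour.points_nm
    if len(pts) < 3:
        raise ValueError("alignment needs at least 3 points")
    p0, p1 = pts[0], pts[-1]
    chord = p1 - p0
    if np.linalg.norm(chord) < 1e-9:
        raise ValueError("degenerate plate: termini coincide")
    angle = -math.atan2(chord[1], chord[0])
    rot = np.array(
        [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
    )
    rotated = pts @ rot.T
    # apex: farthest point from the (now horizontal) chord.  The deviation
    # series is lightly smoothed before taking the maximum: picking the raw
    # extremum of a jittered trace systematically overshoots outward and
    # biases the sagitta (hence the averaged curvature) of noisy plates.
    chord_y = rotated[0, 1]
    dev = rotated[:, 1] - chord_y
    from scipy.ndimage import gaussian_filter1d

    dev_s = gaussian_filter1d(dev, 2.5, mode="nearest") if len(dev) >= 9 else dev
    apex_idx = int(np.argmax(np.abs(dev_s)))
    if dev_s[apex_idx] < 0:  # reflect so the apex is above the chord
        rotated[:, 1] = 2 * chord_y - rotated[:, 1]
        dev_s = -dev_s
    translation = -np.array([rotated[apex_idx, 0], chord_y + dev_s[apex_idx]])
    aligned = PlateContour(
        rotated + translation,
        contour.calibration,
        contour.source_id,
        dict(contour.metadata, apex_index=apex_idx),
    )
    return aligned, math.degrees(angle), translation


def rasterize_contour(
    contour: PlateContour,
    pixel_size: float,
    origin: tuple,
    shape: tuple,
) -> np.ndarray:
    """Unit-intensity single-pixel polyline stroke of a contour on a fixed grid."""
    img = np.zeros(shape, dtype=np.float32)
    pts = contour.points_nm
    cols = np.round((pts[:, 0] - origin[0]) / pixel_size).astype(int)
    rows = np.round((pts[:, 1] - origin[1]) / pixel_size).astype(int)
    for i in range(len(pts) - 1):
        rr, cc = _draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        img[rr[ok], cc[ok]] = 1.0
    return img


def average_plates(
    contours,
    pixel_size: float = DEFAULT_CALIBRATION_NM_PER_PX,
    align: bool = True,
    pad_px: int = 4,
) -> AveragedPlate:
    """Align, rasterize and average plates; fit the averaged chord with a Pratt arc.

    The chord of the averaged 32-bit image is extracted per column as the
    intensity argmax with parabolic sub-pixel refinement, restricted to
    columns reaching at least half of the image maximum.
    """
    contours = list(contours)
    if not contours:
        raise ValueError("average_plates needs at least one plate")
    if align:
        contours = [align_plate(c)[0] for c in contours]
    allpts = np.vstack([c.points_nm for c in contours])
    lo = allpts.min(axis=0) - pad_px * pixel_size
    hi = allpts.max(axis=0) + pad_px * pixel_size
    shape = (
        int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1,
        int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1,
    )
    acc = np.zeros(shape, dtype=np.float32)
    for c in contours:
        acc += rasterize_contour(c, pixel_size, tuple(lo), shape)
    mean_img = acc / np.float32(len(contours))

    chord = _extract_chord(mean_img, pixel_size, tuple(lo))
    fit = fit_circle_pratt(chord)
    return AveragedPlate(mean_img, len(contours), pixel_size, tuple(lo), chord, fit)


def _extract_chord(image: np.ndarray, pixel_size: float, origin: tuple) -> np.ndarray:
    # Smooth lightly so the ridge of a population of jittered strokes is
    # coherent, then take a per-column argmax with parabolic sub-pixel
    # refinement over columns that carry meaningful intensity.
    from scipy.ndimage import gaussian_filter

    sm = gaussian_filter(np.asarray(image, float), 1.0)
    col_mass = sm.sum(axis=0)
    threshold = 0.7 * float(col_mass.max())
    if threshold <= 0:
        raise ValueError("averaged image is empty")
    cols = np.nonzero(col_mass >= threshold)[0]
    if len(cols) > 12:
        # drop arm tips: columns where only the longest plates contribute
        # systematically lift the chord and inflate shallow-arc radii
        cols = cols[3:-3]
    pts = []
    for col in cols:
        profile = sm[:, col]
        row = int(np.argmax(profile))
        sub = 0.0
        if 0 < row < len(profile) - 1:
            denom = profile[row - 1] - 2 * profile[row] + profile[row + 1]
            if denom < 0:
                sub = 0.5 * float(profile[row - 1] - profile[row + 1]) / float(denom)
                sub = float(np.clip(sub, -0.5, 0.5))
        pts.append(
            (origin[0] + col * pixel_size, origin[1] + (row + sub) * pixel_size)
        )
    return np.asarray(pts)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def student_t_test(a, b) -> TTestResult:
    """Two-tailed two-sample Student's t-test with pooled variance (textbook form)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("t-test needs at least 2 observations per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if denom == 0.0:
        t = 0.0 if a.mean() == b.mean() else math.inf
    else:
        t = (a.mean() - b.mean()) / denom
    p = 2.0 * float(_sstats.t.sf(abs(t), df))
    return TTestResult(float(t), p, float(df))


def _summary(values, bins) -> dict:
    values = np.asarray(values, float)
    counts, edges = np.histogram(values, bins=bins)
    return {
        "n": int(len(values)),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else math.nan,
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }


def summarize_population(lengths=None, radii=None, bins=10) -> dict:
    """Population statistics (mean, sd, median, histogram) for plate lengths and radii.

    Medians are reported alongside means because curvature-radius
    distributions of short, nearly straight plates are strongly skewed.
    """
    report: dict = {}
    if lengths is not None and len(lengths):
        report["length"] = _summary(lengths, bins)
    if radii is not None and len(radii):
        report["radius"] = _summary(radii, bins)
    if not report:
        raise ValueError("nothing to summarize")
    return report
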
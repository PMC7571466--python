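"""Synthetic kinetochore scenes with exact ground truth.

Builds "molecule clouds" — labelled 3D point sets — for kinetochore plates
(flat rectangular prisms or curved shell segments), antiparallel sister
pairs, microtubule line sources and bead point sources, plus EM-style plate
contours shaped as noisy circular arcs.  Every generated object carries the
specification that produced it, so downstream measurements can be compared
against analytic ground truth.

Conventions (canonical plate frame):

* the inner->outer axis (plate normal) is +x, with the inner (green) layer
  centroid at the origin and the outer (red) layer at positive x;
* the plate length runs along y and the plate width (depth) along z;
* curved plates are concave towards +x ("outward"), i.e. the curvature
  centre lies beyond the outer layer, so the outer (red) layer is the one
  closer to the curvature centre.

Channel mapping follows the labelling used for CenpA/Hec1 imaging: the inner
layer is "green", the outer layer is "red".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _geometry
from .plate_geometry import PlateContour

GREEN = "green"
RED = "red"

FLAT_PRISM = "flat-prism"
CURVED_SHELL = "curved-shell"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PlateSpec:
    """Parametric two-layer kinetochore plate.

    All lengths in nm.  ``plate_length`` is the arc length along the plate,
    ``plate_width`` the second lateral extent, ``layer_thickness`` the extent
    of each molecular layer along the inner-outer axis and
    ``layer_separation`` the centre-to-centre distance between the two layers.
    For ``curved-shell`` plates ``curvature_radius`` is the radius of the
    mid-surface between the two layer centres and ``curvature_mode`` selects a
    rotationally symmetric spherical cap or an in-plane cylindrical arc.
    """

    shape: str = FLAT_PRISM
    plate_length: float = 300.0
    plate_width: float = 250.0
    layer_thickness: float = 50.0
    layer_separation: float = 140.0
    curvature_radius: float = math.inf
    curvature_mode: str = "cap-3d"
    molecules_per_layer: int = 1000

    def __post_init__(self) -> None:
        if self.shape not in (FLAT_PRISM, CURVED_SHELL):
            raise ValueError(f"unknown plate shape {self.shape!r}")
        if self.plate_length <= 0:
            raise ValueError("plate_length must be positive")
        if self.plate_width < 0 or self.layer_thickness < 0 or self.layer_separation < 0:
            raise ValueError("plate_width, layer_thickness, layer_separation must be >= 0")
        if self.molecules_per_layer < 1:
            raise ValueError("molecules_per_layer must be >= 1")
        _geometry.normalize_mode(self.curvature_mode)
        if self.shape == CURVED_SHELL:
            if not math.isfinite(self.curvature_radius):
                raise ValueError("curved-shell requires a finite curvature_radius")
            if self.curvature_radius <= self.plate_length / math.pi:
                raise ValueError(
                    "invalid geometry: cap half-angle >= 90 deg "
                    f"(curvature_radius {self.curvature_radius} nm must exceed "
                    f"plate_length/pi = {self.plate_length / math.pi:.1f} nm)"
                )
            if self.curvature_radius - self.layer_separation / 2 - self.layer_thickness / 2 <= 0:
                raise ValueError("outer layer would reach the curvature centre")

    @property
    def half_angle(self) -> float:
        """Half-angle in radians subtended by the plate (0 for flat plates)."""
        if self.shape == FLAT_PRISM:
            return 0.0
        return _geometry.half_angle(self.plate_length, self.curvature_radius)

    @property
    def layer_mid_radii(self) -> tuple:
        """(green, red) layer mid-surface radii; the outer layer is closer to the centre."""
        r = self.curvature_radius
        return (r + self.layer_separation / 2, r - self.layer_separation / 2)

    def layer_centroids(self) -> np.ndarray:
        """Analytic (2, 3) centroids of the (inner, outer) layers in the canonical frame."""
        if self.shape == FLAT_PRISM or self.layer_separation == 0:
            return np.array([[0.0, 0, 0], [self.layer_separation, 0, 0]])
        mode = _geometry.normalize_mode(self.curvature_mode)
        alpha = self.half_angle
        f = _geometry.centroid_factor(alpha, mode)
        r_g, r_r = self.layer_mid_radii
        e_g = _geometry.effective_radius(r_g, self.layer_thickness, mode) * f
        e_r = _geometry.effective_radius(r_r, self.layer_thickness, mode) * f
        # curvature centre at x = e_g puts the inner centroid at the origin
        return np.array([[0.0, 0, 0], [e_g - e_r, 0, 0]])

    def curvature_center(self) -> np.ndarray:
        if self.shape == FLAT_PRISM:
            raise ValueError("flat plates have no curvature centre")
        mode = _geometry.normalize_mode(self.curvature_mode)
        f = _geometry.centroid_factor(self.half_angle, mode)
        e_g = _geometry.effective_radius(self.layer_mid_radii[0], self.layer_thickness, mode)
        return np.array([e_g * f, 0.0, 0.0])


@dataclass(frozen=True)
class SisterPairSpec:
    """Two plates arranged as sister kinetochores.

    ``inter_kinetochore_distance`` (IKD) is the distance between the inner
    (green) layer centroids.  With ``antiparallel=True`` the outer layers face
    away from each other along ``pair_axis``; ``swivel_angles`` rotate each
    plate in the XY plane about its inner-layer centroid, away from the
    sister-sister axis.
    """

    plates: tuple = (PlateSpec(), PlateSpec())
    inter_kinetochore_distance: float = 1000.0
    antiparallel: bool = True
    swivel_angles: tuple = (0.0, 0.0)
    pair_center: tuple = (0.0, 0.0, 0.0)
    pair_axis: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        plates = self.plates
        if isinstance(plates, PlateSpec):
            plates = (plates, plates)
        plates = tuple(plates)
        if len(plates) != 2:
            raise ValueError("a sister pair needs exactly two plates")
        object.__setattr__(self, "plates", plates)
        if self.inter_kinetochore_distance < 0:
            raise ValueError("inter_kinetochore_distance must be >= 0")
        axis = np.asarray(self.pair_axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("pair_axis must be a nonzero vector")
        object.__setattr__(self, "pair_axis", tuple(axis / n))
        object.__setattr__(self, "swivel_angles", tuple(float(a) for a in self.swivel_angles))

    @property
    def overlap_warning(self) -> bool:
        return any(
            self.inter_kinetochore_distance < p.layer_separation for p in self.plates
        )


@dataclass(frozen=True)
class ContourSpec:
    """EM-style plate contour: a circular arc traced at fixed pixel spacing.

    The radial jitter is smooth: white noise per point is filtered to a
    ``noise_correlation_nm`` correlation length (then rescaled so its
    marginal standard deviation is ``noise_sd``), mimicking hand-tracing
    wobble.  Uncorrelated jitter at ~2 nm point spacing would make the
    polyline length diverge from the arc length.
    """

    radius: float = 287.0
    arc_length: float = 301.0
    point_spacing: float = 1.88
    noise_sd: float = 0.0
    noise_correlation_nm: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.arc_length <= 0:
            raise ValueError("radius and arc_length must be positive")
        if self.point_spacing <= 0:
            raise ValueError("point_spacing must be positive")
        if self.arc_length > 2 * math.pi * self.radius:
            raise ValueError("arc_length exceeds the full circle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_correlation_nm < 0:
            raise ValueError("noise_correlation_nm must be >= 0")


# ---------------------------------------------------------------------------
# molecule clouds


@dataclass
class MoleculeCloud:
    """Labelled 3D point set realizing a scene spec (positions in nm)."""

    positions: np.ndarray  # (N, 3)
    channels: np.ndarray  # (N,) of str
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.channels = np.asarray(self.channels, dtype=object)
        if len(self.channels) != len(self.positions):
            raise ValueError("one channel label per position required")

    def select(self, channel: str) -> np.ndarray:
        return self.positions[self.channels == channel]

    def centroid(self, channel: str | None = None) -> np.ndarray:
        pts = self.positions if channel is None else self.select(channel)
        if len(pts) == 0:
            raise ValueError(f"no molecules in channel {channel!r}")
        return pts.mean(axis=0)

    @property
    def channel_names(self) -> tuple:
        return tuple(dict.fromkeys(self.channels))

    def transformed(self, rotation=None, translation=None) -> "MoleculeCloud":
        pts = self.positions
        if rotation is not None:
            pts = pts @ np.asarray(rotation, float).T
        if translation is not None:
            pts = pts + np.asarray(translation, float)
        return MoleculeCloud(pts, self.channels.copy(), dict(self.ground_truth))

    def __add__(self, other: "MoleculeCloud") -> "MoleculeCloud":
        gt = {"parts": []}
        for c in (self, other):
            gt["parts"].extend(c.ground_truth.get("parts", [c.ground_truth]))
        return MoleculeCloud(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.channels, other.channels]),
            gt,
        )

    def __len__(self) -> int:
        return len(self.positions)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _frame_from_axis(axis) -> np.ndarray:
    """Rotation matrix whose first column is ``axis`` (maps canonical +x there)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b = np.cross(helper, a)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.column_stack([a, b, c])


def _sample_flat_layer(spec: PlateSpec, x_center: float, n: int, rng) -> np.ndarray:
    t, L, W = spec.layer_thickness, spec.plate_length, spec.plate_width
    x = x_center + rng.uniform(-t / 2, t / 2, n) if t > 0 else np.full(n, x_center)
    y = rng.uniform(-L / 2, L / 2, n)
    z = rng.uniform(-W / 2, W / 2, n) if W > 0 else np.zeros(n)
    return np.column_stack([x, y, z])


def _sample_shell_layer(spec: PlateSpec, r_mid: float, n: int, rng) -> np.ndarray:
    mode = _geometry.normalize_mode(spec.curvature_mode)
    alpha = spec.half_angle
    t = spec.layer_thickness
    lo, hi = r_mid - t / 2, r_mid + t / 2
    cx = spec.curvature_center()[0]
    if mode == _geometry.CAP_3D:
        # uniform density in a spherical shell segment: r^3 and cos(theta) uniform
        if t > 0:
            r = np.cbrt(rng.uniform(lo**3, hi**3, n))
        else:
            r = np.full(n, r_mid)
        cos_t = rng.uniform(math.cos(alpha), 1.0, n)
        phi = rng.uniform(0.0, 2 * math.pi, n)
        sin_t = np.sqrt(1.0 - cos_t**2)
        x = cx - r * cos_t
        y = r * sin_t * np.cos(phi)
        z = r * sin_t * np.sin(phi)
    else:
        # cylindrical shell segment: r^2 uniform, angle uniform, width uniform
        if t > 0:
            r = np.sqrt(rng.uniform(lo**2, hi**2, n))
        else:
            r = np.full(n, r_mid)
        theta = rng.uniform(-alpha, alpha, n)
        x = cx - r * np.cos(theta)
        y = r * np.sin(theta)
        z = (
            rng.uniform(-spec.plate_width / 2, spec.plate_width / 2, n)
            if spec.plate_width > 0
            else np.zeros(n)
        )
    return np.column_stack([x, y, z])


def build_plate_molecules(
    spec: PlateSpec, seed=None, rng: np.random.Generator | None = None
) -> MoleculeCloud:
    """Sample molecules uniformly within the two layers of a plate.

    Returns a cloud with the inner layer labelled "green" and the outer layer
    "red", in the canonical plate frame (inner centroid at the origin).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.molecules_per_layer
    if spec.shape == FLAT_PRISM:
        inner = _sample_flat_layer(spec, 0.0, n, rng)
        outer = _sample_flat_layer(spec, spec.layer_separation, n, rng)
    else:
        r_g, r_r = spec.layer_mid_radii
        inner = _sample_shell_layer(spec, r_g, n, rng)
        outer = _sample_shell_layer(spec, r_r, n, rng)
    centroids = spec.layer_centroids()
    gt = {
        "spec": spec,
        "inner_centroid": centroids[0],
        "outer_centroid": centroids[1],
    }
    return MoleculeCloud(
        np.vstack([inner, outer]),
        np.array([GREEN] * n + [RED] * n, dtype=object),
        gt,
    )


def molecules_in_layer(spec: PlateSpec, layer: str, positions: np.ndarray, atol: float = 1e-9):
    """Analytic point-in-shape test for a plate layer ("inner" or "outer")."""
    pts = np.asarray(positions, float).reshape(-1, 3)
    t = spec.layer_thickness
    if spec.shape == FLAT_PRISM:
        x0 = 0.0 if layer == "inner" else spec.layer_separation
        return (
            (np.abs(pts[:, 0] - x0) <= t / 2 + atol)
            & (np.abs(pts[:, 1]) <= spec.plate_length / 2 + atol)
            & (np.abs(pts[:, 2]) <= spec.plate_width / 2 + atol)
        )
    mode = _geometry.normalize_mode(spec.curvature_mode)
    r_mid = spec.layer_mid_radii[0 if layer == "inner" else 1]
    centre = spec.curvature_center()
    alpha = spec.half_angle
    if mode == _geometry.CAP_3D:
        d = pts - centre
        r = np.linalg.norm(d, axis=1)
        cos_t = -d[:, 0] / np.where(r > 0, r, 1.0)
        return (
            (r >= r_mid - t / 2 - atol)
            & (r <= r_mid + t / 2 + atol)
            & (cos_t >= math.cos(alpha) - 1e-12)
        )
    dxy = pts[:, :2] - centre[:2]
    r = np.linalg.norm(dxy, axis=1)
    cos_t = -dxy[:, 0] / np.where(r > 0, r, 1.0)
    return (
        (r >= r_mid - t / 2 - atol)
        & (r <= r_mid + t / 2 + atol)
        & (cos_t >= math.cos(alpha) - 1e-12)
        & (np.abs(pts[:, 2]) <= spec.plate_width / 2 + atol)
    )


def build_sister_pair(spec: SisterPairSpec, seed=None, rng=None) -> MoleculeCloud:
    """Arrange two plates as (by default antiparallel) sister kinetochores.

    Ground truth records the analytic inner/outer layer centroids in world
    coordinates, the IKD and an ``overlap_warning`` flag for pairs whose IKD
    is smaller than the layer separation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    axis_frame = _frame_from_axis(spec.pair_axis)
    center = np.asarray(spec.pair_center, float)
    ikd = spec.inter_kinetochore_distance

    positions = []
    channels = []
    inner_world = []
    outer_world = []
    for plate, swivel, sign in zip(spec.plates, spec.swivel_angles, (-1.0, +1.0)):
        cloud = build_plate_molecules(plate, rng=rng)
        rot = _rot_z(swivel)
        if sign < 0 and spec.antiparallel:
            rot = rot @ _rot_z(180.0)
        offset = axis_frame @ np.array([sign * ikd / 2, 0.0, 0.0]) + center
        world = (axis_frame @ rot @ cloud.positions.T).T + offset
        positions.append(world)
        channels.append(cloud.channels)
        cents = (axis_frame @ rot @ plate.layer_centroids().T).T + offset
        inner_world.append(cents[0])
        outer_world.append(cents[1])

    gt = {
        "spec": spec,
        "ikd": ikd,
        "pair_center": center,
        "pair_axis": np.asarray(spec.pair_axis, float),
        "inner_centroids": np.array(inner_world),
        "outer_centroids": np.array(outer_world),
        "overlap_warning": spec.overlap_warning,
    }
    return MoleculeCloud(np.vstack(positions), np.concatenate(channels), gt)


def build_line_source(
    length: float,
    position=(0.0, 0.0, 0.0),
    orientation=(0.0, 1.0, 0.0),
    n_molecules: int = 1000,
    seed=None,
    radius: float = 0.0,
    channel: str = GREEN,
) -> MoleculeCloud:
    """Microtubule stand-in: points uniform on a segment (optionally a thin cylinder).

    ``radius`` = 12.5 nm approximates the 25 nm microtubule diameter; the
    default zero-width line is a purely diffraction-limited source.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    d = np.asarray(orientation, float)
    d = d / np.linalg.norm(d)
    t = rng.uniform(-length / 2, length / 2, n_molecules)
    pts = np.outer(t, d) + np.asarray(position, float)
    if radius > 0:
        frame = _frame_from_axis(d)  # columns: axis, two perpendiculars
        rr = radius * np.sqrt(rng.uniform(0, 1, n_molecules))
        phi = rng.uniform(0, 2 * math.pi, n_molecules)
        pts = pts + np.outer(rr * np.cos(phi), frame[:, 1]) + np.outer(
            rr * np.sin(phi), frame[:, 2]
        )
    gt = {"kind": "line", "length": length, "position": np.asarray(position, float),
          "orientation": d, "radius": radius}
    return MoleculeCloud(pts, np.array([channel] * n_molecules, dtype=object), gt)


def build_point_source(
    position=(0.0, 0.0, 0.0),
    channels=(GREEN, RED),
    diameter: float = 0.0,
    n_molecules: int = 1,
    seed=None,
) -> MoleculeCloud:
    """Bead stand-in: a dual-channel point (or uniform sphere of given diameter)."""
    rng = np.random.default_rng(seed)
    pos = np.asarray(position, float)
    all_pts = []
    all_ch = []
    for ch in channels:
        if diameter > 0:
            r = (diameter / 2) * np.cbrt(rng.uniform(0, 1, n_molecules))
            v = rng.normal(size=(n_molecules, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = pos + r[:, None] * v
        else:
            pts = np.tile(pos, (n_molecules, 1))
        all_pts.append(pts)
        all_ch.extend([ch] * n_molecules)
    gt = {"kind": "point", "position": pos, "diameter": diameter}
    return MoleculeCloud(np.vstack(all_pts), np.array(all_ch, dtype=object), gt)


def generate_em_contour(spec: ContourSpec) -> PlateContour:
    """Ordered points along a noisy circular arc, mimicking a traced EM plate.

    The arc is centred on the origin with its apex at (0, radius) and opens
    downward; radial Gaussian jitter of ``noise_sd`` is applied per point.
    The ground-truth radius is kept in the contour metadata.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.arc_length / spec.point_spacing)) + 1
    alpha = spec.arc_length / (2 * spec.radius)
    theta = np.linspace(-alpha, alpha, n)
    r = np.full(n, spec.radius)
    if spec.noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        white = rng.normal(0.0, 1.0, n)
        corr_pts = spec.noise_correlation_nm / spec.point_spacing
        if corr_pts > 0.5:
            smooth = gaussian_filter1d(white, corr_pts, mode="nearest")
            sd = smooth.std()
            noise = smooth / sd if sd > 0 else smooth
        else:
            noise = white
        r = r + spec.noise_sd * noise
    pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
    return PlateContour(
        pts,
        calibration=spec.point_spacing,
        metadata={"true_radius": spec.radius, "spec": spec},
    )


# ---------------------------------------------------------------------------
# study-condition presets


def im_plate(layer_separation: float = 100.0, molecules_per_layer: int = 1000) -> PlateSpec:
    """Indian-muntjac-style plate: >=1 um long, 50 nm layers.

    The ~100 nm default layer separation matches the CenpA-Hec1 delta range
    measured in untreated IM metaphases.
    """
    return PlateSpec(
        shape=FLAT_PRISM,
        plate_length=1000.0,
        plate_width=250.0,
        layer_thickness=50.0,
        layer_separation=layer_separation,
        molecules_per_layer=molecules_per_layer,
    )


def human_plate(
    layer_separation: float = 140.0, molecules_per_layer: int = 1000
) -> PlateSpec:
    """Human-style plate: 300 x 250 nm prism, 50 nm layers 140 nm apart."""
    return PlateSpec(
        shape=FLAT_PRISM,
        plate_length=300.0,
        plate_width=250.0,
        layer_thickness=50.0,
        layer_separation=layer_separation,
        molecules_per_layer=molecules_per_layer,
    )


def im_sister_pair(
    ikd: float = 1000.0,
    layer_separation: float = 100.0,
    swivel_angles=(0.0, 0.0),
    molecules_per_layer: int = 1000,
    **kw,
) -> SisterPairSpec:
    plate = im_plate(layer_separation, molecules_per_layer)
    return SisterPairSpec(
        plates=(plate, plate),
        inter_kinetochore_distance=ikd,
        swivel_angles=swivel_angles,
        **kw,
    )


def vary_plate(spec: PlateSpec, **changes) -> PlateSpec:
    """Copy of a plate spec with selected fields replaced."""
    return replace(spec, **changes)
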
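"""Closed-form geometry of curved shell layers.

A kinetochore plate bent with curvature radius ``R`` over arc length ``L``
subtends the half-angle ``alpha = L / (2 R)``.  Two curvature models are
supported:

``cap-3d``
    rotationally symmetric spherical-cap shell (curved in both lateral
    directions);
``arc-2d``
    cylindrical shell curved in one plane only.

For a thin shell of radius ``r`` the centroid sits on the symmetry axis at
distance ``r * f(alpha)`` from the curvature centre, with
``f = (1 + cos alpha) / 2`` for a spherical cap and ``f = sin(alpha)/alpha``
for a cylindrical arc.  Finite shell thickness enters through an effective
radius (radial moment of the uniform density).
"""

from __future__ import annotations

import math

CAP_3D = "cap-3d"
ARC_2D = "arc-2d"

_MODE_ALIASES = {
    "cap-3d": CAP_3D,
    "cap3d": CAP_3D,
    "cap": CAP_3D,
    "rotationally-symmetric-cap": CAP_3D,
    "arc-2d": ARC_2D,
    "arc2d": ARC_2D,
    "arc": ARC_2D,
    "in-plane-arc": ARC_2D,
}


def normalize_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode.lower()]
    except KeyError:
        raise ValueError(
            f"unknown curvature mode {mode!r}; expected one of {sorted(set(_MODE_ALIASES))}"
        ) from None


def half_angle(arc_length: float, radius: float) -> float:
    """Half-angle (radians) subtended by an arc of given length and radius."""
    if not math.isfinite(radius):
        return 0.0
    if radius <= 0:
        raise ValueError(f"curvature radius must be positive, got {radius}")
    return arc_length / (2.0 * radius)


def centroid_factor(alpha: float, mode: str) -> float:
    """Axial centroid offset of a thin shell segment, as a fraction of its radius.

    ``alpha`` is the half-angle in radians; ``alpha = 0`` is the flat limit
    where the factor is 1.
    """
    if alpha < 0 or alpha >= math.pi / 2:
        raise ValueError(f"half-angle must be in [0, pi/2), got {alpha}")
    if alpha == 0.0:
        return 1.0
    mode = normalize_mode(mode)
    if mode == CAP_3D:
        return (1.0 + math.cos(alpha)) / 2.0
    return math.sin(alpha) / alpha


def effective_radius(r_mid: float, thickness: float, mode: str) -> float:
    """Density-weighted radius of a shell of mid-radius ``r_mid`` and thickness ``thickness``.

    The uniform density inside a spherical (cylindrical) shell weights radii
    by r^2 (r), so the centroid of a thick shell sits at the corresponding
    radial moment rather than at the mid-radius.
    """
    if thickness < 0:
        raise ValueError("thickness must be nonnegative")
    if thickness == 0.0:
        return r_mid
    lo = r_mid - thickness / 2.0
    hi = r_mid + thickness / 2.0
    if lo <= 0:
        raise ValueError(
            f"shell extends to nonpositive radius: mid {r_mid}, thickness {thickness}"
        )
    mode = normalize_mode(mode)
    if mode == CAP_3D:
        return 0.75 * (hi**4 - lo**4) / (hi**3 - lo**3)
    return (2.0 / 3.0) * (hi**3 - lo**3) / (hi**2 - lo**2)
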
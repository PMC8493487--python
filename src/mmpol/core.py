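"""Exact Stokes--Mueller algebra for ideal polarization elements.

Conventions (used by every module in the package):

- Stokes basis ``(I, Q, U, V)`` with horizontal = +Q, +45 deg = +U and
  right-circular = +V.
- The reference axis is horizontal; positive angles are counterclockwise
  when viewed toward the source; axial (period-pi) angles are reported in
  ``(-pi/2, pi/2]``.
- All angles in the Python API are radians.
- Handedness: the linear retarder's V-coupling is
  ``m24 = -sin(delta) * sin(2*theta)``, and a positive circular
  retardance rotates Stokes vectors *clockwise* about the S3 axis of the
  Poincare sphere (a vector at azimuth phi in the S1-S2 plane moves to
  phi - delta_c).  This pair of sign choices makes the quarter-waveplate
  matrix agree element-for-element with its textbook theoretical form
  and is applied consistently in the forward model and the
  decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleConvention",
    "ANGLE_CONVENTION",
    "STOKES_UNIT",
    "unit_stokes",
    "fold_axial",
    "signed_axial_difference",
    "mueller_linear_retarder",
    "mueller_linear_polarizer",
    "mueller_circular_retarder",
    "stokes_rotation",
    "rotate_mueller",
    "apply_mueller",
    "degree_of_polarization",
]


@dataclass(frozen=True)
class AngleConvention:
    """Documented angle convention shared by all modules."""

    reference_axis: str = "horizontal"
    positive_sense: str = "counterclockwise viewed toward the source"
    axial_range: tuple[float, float] = (-np.pi / 2, np.pi / 2)  # half-open at left
    units: str = "radians"


ANGLE_CONVENTION = AngleConvention()

#: Normalized Stokes 3-vectors of the four instrument states:
#: linear horizontal (H), linear vertical (V), linear +45 deg (P) and
#: right circular (R).
STOKES_UNIT: dict[str, np.ndarray] = {
    "H": np.array([1.0, 0.0, 0.0]),
    "V": np.array([-1.0, 0.0, 0.0]),
    "P": np.array([0.0, 1.0, 0.0]),
    "R": np.array([0.0, 0.0, 1.0]),
}


def unit_stokes(state: str) -> np.ndarray:
    """Full Stokes 4-vector ``(1, s1, s2, s3)`` of a named unit state."""
    s = STOKES_UNIT[state.upper()]
    return np.concatenate(([1.0], s))


def fold_axial(theta):
    """Fold axial (period-pi) angles into ``(-pi/2, pi/2]``.

    NaN inputs propagate unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    a = np.mod(theta, np.pi)
    a = np.where(a > np.pi / 2, a - np.pi, a)
    return a if a.ndim else float(a)


def signed_axial_difference(a, b):
    """Signed axial difference ``a - b`` folded into ``[-pi/2, pi/2)``."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + np.pi / 2, np.pi) - np.pi / 2
    return d if d.ndim else float(d)


def mueller_linear_retarder(delta: float, theta: float = 0.0) -> np.ndarray:
    """Mueller matrix of an ideal linear retarder.

    Parameters
    ----------
    delta : float
        Retardance in radians.
    theta : float
        Fast-axis orientation in radians (reduced mod pi).

    Returns
    -------
    (4, 4) ndarray with ``m[0, 0] = 1``.
    """
    c2, s2 = np.cos(2.0 * theta), np.sin(2.0 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c2 * c2 + s2 * s2 * cd, c2 * s2 * (1.0 - cd), -s2 * sd],
            [0.0, c2 * s2 * (1.0 - cd), s2 * s2 + c2 * c2 * cd, c2 * sd],
            [0.0, s2 * sd, -c2 * sd, cd],
        ]
    )


def mueller_linear_polarizer(theta: float = 0.0) -> np.ndarray:
    """Ideal linear polarizer with transmission axis ``theta``, m11-normalized."""
    c2, s2 = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return np.array(
        [
            [1.0, c2, s2, 0.0],
            [c2, c2 * c2, c2 * s2, 0.0],
            [s2, c2 * s2, s2 * s2, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def mueller_circular_retarder(delta_c: float) -> np.ndarray:
    """Ideal circular retarder: rotation of the S1-S2 plane about S3.

    Positive ``delta_c`` rotates clockwise on the Poincare sphere: a
    Stokes vector at azimuth ``phi`` in the S1-S2 plane is carried to
    azimuth ``phi - delta_c``.
    """
    c, s = np.cos(delta_c), np.sin(delta_c)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def stokes_rotation(theta: float) -> np.ndarray:
    """Stokes frame-rotation matrix R(theta) for a physical angle ``theta``."""
    c, s = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def rotate_mueller(M: np.ndarray, theta: float) -> np.ndarray:
    """Rotate an element's frame: ``R(theta) M R(-theta)``."""
    R = stokes_rotation(theta)
    return R @ np.asarray(M, dtype=float) @ stokes_rotation(-theta)


def apply_mueller(M: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Apply a Mueller matrix to a Stokes vector (plain matrix product)."""
    return np.asarray(M, dtype=float) @ np.asarray(s, dtype=float)


def degree_of_polarization(s: np.ndarray) -> float:
    """``sqrt(s1^2 + s2^2 + s3^2) / s0`` of a Stokes 4-vector."""
    s = np.asarray(s, dtype=float)
    return float(np.linalg.norm(s[1:]) / s[0])
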
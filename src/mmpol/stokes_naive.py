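"""Naive Stokes-polarimeter estimator (pure-linear-retarder assumption).

A Stokes-only polarimeter illuminates the sample with right circularly
polarized light and interprets the output on the Poincare sphere as if
the sample were a pure linear retarder:

- linear retardance: the angle between the incident and measured
  normalized Stokes vectors, ``deltaL_S = arccos(s_i . s_m)``;
- fast-axis orientation: half the angle between ``s_m x s_i`` and the
  S1 unit vector, signed by the S2 component of ``s_m x s_i``.

The measured Stokes vector comes from the R-generator rows of the same
16-image stack the Mueller polarimeter uses: with
``I0 = I_RH + I_RV``,  ``s_m = (2 I_RH - I0, 2 I_RP - I0, 2 I_RR - I0) / I0``.

With circular illumination the retardance estimate is independent of
the sample's fast-axis orientation.  When the sample also carries a
circular retardance ``deltaC``, the measured vector is rotated about S3
and the estimated axis deviates from the true fast axis by exactly
``-deltaC / 2`` (Poincare angles are twice physical angles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmpol.core import fold_axial
from mmpol.simulate import IntensityStack

__all__ = [
    "S_INCIDENT_RCP",
    "StokesEstimate",
    "stokes_from_stack",
    "naive_retardance",
    "naive_fast_axis",
    "analyze_stack",
]

#: Incident state of the naive analysis: right circular polarization.
S_INCIDENT_RCP = np.array([0.0, 0.0, 1.0])


@dataclass
class StokesEstimate:
    """Per-pixel naive estimates and their validity mask.

    deltaL_S / thetaFA_S : naive linear retardance (rad, [0, pi)) and
        fast-axis orientation (rad, (-pi/2, pi/2]); NaN where masked.
    s_m : (H, W, 3) measured normalized Stokes vector.
    I0 : (H, W) total transmitted intensity for circular input.
    mask : bool plane, True where the estimate is defined (I0 above
        threshold, |s_m| above the depolarization floor, axis not
        degenerate).
    """

    deltaL_S: np.ndarray
    thetaFA_S: np.ndarray
    s_m: np.ndarray
    I0: np.ndarray
    mask: np.ndarray


def stokes_from_stack(
    stack: IntensityStack, eps_i0: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Measured normalized Stokes vector for circular illumination.

    Returns ``(s_m, I0, valid)`` where ``valid`` masks pixels whose
    total intensity ``I0 = I_RH + I_RV`` is at or below ``eps_i0``
    times the largest I0 in the image.
    """
    I0 = stack.get("R", "H") + stack.get("R", "V")
    full = float(I0.max()) if I0.size else 0.0
    valid = I0 > eps_i0 * max(full, 0.0)
    if full <= 0.0:
        valid = np.zeros_like(valid)
    denom = np.where(valid, I0, np.nan)
    s_m = np.stack(
        [
            2.0 * stack.get("R", "H") - I0,
            2.0 * stack.get("R", "P") - I0,
            2.0 * stack.get("R", "R") - I0,
        ],
        axis=-1,
    ) / denom[..., np.newaxis]
    return s_m, I0, valid


def naive_retardance(s_i: np.ndarray, s_m: np.ndarray) -> np.ndarray:
    """Naive linear retardance: angle between incident and measured vectors.

    Operates on 3-vectors or (..., 3) arrays; zero-length ``s_m`` gives
    NaN.
    """
    s_i = np.asarray(s_i, dtype=float)
    s_m = np.asarray(s_m, dtype=float)
    ni = np.linalg.norm(s_i, axis=-1)
    nm = np.linalg.norm(s_m, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(s_i * s_m, axis=-1) / (ni * nm)
        out = np.arccos(np.clip(cosang, -1.0, 1.0))
    out = np.where(nm > 0, out, np.nan)
    return out if np.ndim(out) else float(out)


def naive_fast_axis(s_i: np.ndarray, s_m: np.ndarray) -> np.ndarray:
    """Naive fast-axis orientation from the Poincare-sphere cross product.

    ``theta = +/- arccos((s_m x s_i) . s1_hat / |s_m x s_i|) / 2`` with
    the sign of the S2 component of ``s_m x s_i``, folded to
    ``(-pi/2, pi/2]``.  Parallel vectors (retardance 0 or pi) give NaN.
    """
    s_i = np.asarray(s_i, dtype=float)
    s_m = np.asarray(s_m, dtype=float)
    c = np.cross(s_m, s_i)
    nc = np.linalg.norm(c, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 0.5 * np.arccos(np.clip(c[..., 0] / nc, -1.0, 1.0))
    sign = np.where(c[..., 1] < 0, -1.0, 1.0)
    theta = fold_axial(sign * half)
    theta = np.where(nc > 0, theta, np.nan)
    return theta if np.ndim(theta) else float(theta)


def analyze_stack(
    stack: IntensityStack,
    s_i: np.ndarray = S_INCIDENT_RCP,
    depol_floor: float = 0.05,
    eps_i0: float = 1e-9,
) -> StokesEstimate:
    """Naive per-pixel retardance and fast-axis maps from a stack.

    Pixels whose measured degree of polarization ``|s_m|`` falls below
    ``depol_floor`` are masked: the pure-retarder model normalizes
    depolarization away and the axis becomes noise-dominated.
    """
    s_m, I0, valid = stokes_from_stack(stack, eps_i0)
    with np.errstate(invalid="ignore"):
        dop = np.linalg.norm(s_m, axis=-1)
        mask = valid & (dop >= depol_floor)
    deltaL_S = np.where(mask, naive_retardance(s_i, s_m), np.nan)
    thetaFA_S = np.where(mask, naive_fast_axis(s_i, s_m), np.nan)
    mask = mask & np.isfinite(thetaFA_S)
    return StokesEstimate(deltaL_S=deltaL_S, thetaFA_S=thetaFA_S, s_m=s_m, I0=I0, mask=mask)
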
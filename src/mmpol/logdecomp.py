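"""Logarithm decomposition of Mueller matrices.

A medium exhibiting simultaneous polarization effects is characterized
by the principal matrix logarithm ``L = log M`` of its (m11-normalized)
Mueller matrix.  Two physical eigenvalue cases are decomposed:

- *complex_pair*: M has a complex-conjugate eigenvalue pair
  (birefringent medium); the principal branch of the real logarithm
  places the rotation angle in (-pi, pi].
- *real_positive*: all eigenvalues of M are real and positive
  (no birefringence); the principal real logarithm applies.

If any eigenvalue is real and negative, zero, or the spectrum matches
neither case, the pixel's properties are *undefined* -- a value, not an
exception.  A linear retardance of exactly pi produces a double -1
eigenvalue and is therefore undefined; retardances just beyond pi
reappear wrapped into (0, pi) with the fast axis flipped by pi/2 (see
:func:`mmpol.anisotropy.unwrap_half_order` for the correction).

From the G-metric split ``L = Lm + Lu`` the seven accumulated
properties are::

    deltaL = hypot(LB, LB')            in [0, pi)
    thetaFA = atan2(LB', LB) / 2       in (-pi/2, pi/2]
    deltaC = CB                        in [-pi, pi)
    DL = tanh(hypot(LD, LD'))          in [0, 1]
    thetaTA = atan2(LD', LD) / 2       in (-pi/2, pi/2]
    DC = tanh(CD)                      in [-1, 1]
    Delta = 1 - |e^a1 + e^a2 + e^a3| / 3   in [0, 1]

Orientation angles are NaN sentinels when their magnitude (deltaL or
DL) vanishes, with the pixel still counted as defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, logm

from mmpol.core import fold_axial
from mmpol.differential import split_L
from mmpol.reconstruction import MuellerImage

__all__ = [
    "Case",
    "PropertySet",
    "PropertyMaps",
    "classify_eigenvalues",
    "mueller_log",
    "extract_properties",
    "decompose_matrix",
    "decompose_image",
]

#: Relative tolerance for the eigenvalue classification: imaginary parts
#: above ``CLASSIFY_TOL * ||M||_F`` count as complex; real eigenvalues
#: below it count as zero (hence undefined).
CLASSIFY_TOL = 1e-9

_ZERO_MAGNITUDE = 1e-12  # below this, an orientation angle is meaningless


class Case(str, enum.Enum):
    """Eigenvalue classification of a Mueller matrix."""

    REAL_POSITIVE = "real_positive"
    COMPLEX_PAIR = "complex_pair"
    UNDEFINED = "undefined"


@dataclass
class PropertySet:
    """The seven accumulated polarization properties of one pixel."""

    deltaL: float
    thetaFA: float
    deltaC: float
    DL: float
    thetaTA: float
    DC: float
    Delta: float
    defined: bool
    case: Case
    alphas: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def deltaT(self) -> float:
        """Total retardance ``sqrt(deltaL^2 + deltaC^2)``."""
        return float(np.hypot(self.deltaL, self.deltaC))

    @classmethod
    def undefined(cls) -> "PropertySet":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, False, Case.UNDEFINED, (nan,) * 3)


@dataclass
class PropertyMaps:
    """Image planes of the accumulated properties plus the undefined mask."""

    deltaL: np.ndarray
    thetaFA: np.ndarray
    deltaC: np.ndarray
    DL: np.ndarray
    thetaTA: np.ndarray
    DC: np.ndarray
    Delta: np.ndarray
    undefined: np.ndarray  # bool; True where properties are undefined
    case: np.ndarray  # '<U16' case labels
    pixel_pitch_mm: float = 8.90e-3

    PLANES = ("deltaL", "thetaFA", "deltaC", "DL", "thetaTA", "DC", "Delta")

    @property
    def deltaT(self) -> np.ndarray:
        return np.sqrt(self.deltaL**2 + self.deltaC**2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.undefined.shape

    @property
    def undefined_fraction(self) -> float:
        return float(np.mean(self.undefined))


def classify_eigenvalues(M: np.ndarray, tol: float = CLASSIFY_TOL) -> Case:
    """Classify the eigenvalue spectrum of a Mueller matrix.

    ``tol`` is relative to the Frobenius norm of M.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        return Case.UNDEFINED
    scale = np.linalg.norm(M)
    if scale == 0.0:
        return Case.UNDEFINED
    ev = np.linalg.eigvals(M)
    atol = tol * scale
    is_complex = np.abs(ev.imag) > atol
    real_parts = ev[~is_complex].real
    if np.any(real_parts <= atol):
        return Case.UNDEFINED  # real negative or zero eigenvalue
    if np.any(is_complex):
        return Case.COMPLEX_PAIR
    return Case.REAL_POSITIVE


def mueller_log(M: np.ndarray, case: Case | None = None) -> np.ndarray:
    """Principal real matrix logarithm of a physical Mueller matrix.

    ``case`` must not be UNDEFINED (classify first); when omitted it is
    computed here.  Raises ``ValueError`` on an undefined spectrum and
    ``ArithmeticError`` if the logarithm fails to invert the exponential
    to 1e-10 (relative).
    """
    M = np.asarray(M, dtype=float)
    if case is None:
        case = classify_eigenvalues(M)
    if case is Case.UNDEFINED:
        raise ValueError("matrix logarithm undefined for this eigenvalue spectrum")
    L = np.real(logm(M))
    resid = np.max(np.abs(expm(L) - M))
    if not np.isfinite(resid) or resid > 1e-10 * max(np.linalg.norm(M), 1.0):
        raise ArithmeticError("matrix logarithm did not converge")
    return L


def extract_properties(Lm: np.ndarray, Lu: np.ndarray, case: Case = Case.COMPLEX_PAIR) -> PropertySet:
    """Accumulated polarization properties from the split differential matrix."""
    LB = Lm[2, 3]
    LBp = Lm[3, 1]
    CB = Lm[1, 2]
    LD = Lm[0, 1]
    LDp = Lm[0, 2]
    CD = Lm[0, 3]
    # depolarization relative to the isotropic (absorption/normalization)
    # term: m11-normalizing M shifts the whole Lu diagonal by -log(m11),
    # which must not read as depolarization
    a1, a2, a3 = Lu[1, 1] - Lu[0, 0], Lu[2, 2] - Lu[0, 0], Lu[3, 3] - Lu[0, 0]

    deltaL = float(np.hypot(LB, LBp))
    thetaFA = fold_axial(0.5 * np.arctan2(LBp, LB)) if deltaL > _ZERO_MAGNITUDE else float("nan")
    ld_mag = float(np.hypot(LD, LDp))
    DL = float(np.tanh(ld_mag))
    thetaTA = fold_axial(0.5 * np.arctan2(LDp, LD)) if ld_mag > _ZERO_MAGNITUDE else float("nan")
    DC = float(np.tanh(CD))
    Delta = 1.0 - abs(np.exp(a1) + np.exp(a2) + np.exp(a3)) / 3.0
    # principal-branch circular retardance lives in [-pi, pi)
    deltaC = float(CB) if CB < np.pi else float(CB - 2.0 * np.pi)
    return PropertySet(
        deltaL=deltaL,
        thetaFA=thetaFA,
        deltaC=deltaC,
        DL=DL,
        thetaTA=thetaTA,
        DC=DC,
        Delta=float(np.clip(Delta, 0.0, 1.0)),
        defined=True,
        case=case,
        alphas=(float(a1), float(a2), float(a3)),
    )


def decompose_matrix(M: np.ndarray, tol: float = CLASSIFY_TOL) -> PropertySet:
    """classify -> log -> split -> extract for a single Mueller matrix."""
    case = classify_eigenvalues(M, tol)
    if case is Case.UNDEFINED:
        return PropertySet.undefined()
    try:
        L = mueller_log(M, case)
    except ArithmeticError:
        return PropertySet.undefined()
    Lm, Lu = split_L(L)
    return extract_properties(Lm, Lu, case)


def decompose_image(Mimg: MuellerImage | np.ndarray, tol: float = CLASSIFY_TOL) -> PropertyMaps:
    """Per-pixel logarithm decomposition of a Mueller image.

    Reconstruction-masked pixels propagate as undefined.
    """
    if isinstance(Mimg, MuellerImage):
        m, mask, pitch = Mimg.m, Mimg.mask, Mimg.pixel_pitch_mm
    else:
        m = np.asarray(Mimg, dtype=float)
        mask = np.ones(m.shape[:2], dtype=bool)
        pitch = 8.90e-3
    H, W = m.shape[:2]
    planes = {name: np.full((H, W), np.nan) for name in PropertyMaps.PLANES}
    undefined = np.ones((H, W), dtype=bool)
    case_map = np.full((H, W), Case.UNDEFINED.value, dtype="<U16")

    # identical matrices (piecewise-uniform scenes) are decomposed once
    flat = m.reshape(-1, 16)
    flat = np.where(np.isfinite(flat), flat, np.nan)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    results = [decompose_matrix(row.reshape(4, 4), tol) for row in uniq]

    inverse = inverse.reshape(H, W)
    for idx, props in enumerate(results):
        sel = (inverse == idx) & mask
        if not sel.any():
            continue
        case_map[sel] = props.case.value
        if props.defined:
            undefined[sel] = False
            for name in PropertyMaps.PLANES:
                planes[name][sel] = getattr(props, name)
    return PropertyMaps(undefined=undefined, case=case_map, pixel_pitch_mm=pitch, **planes)
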
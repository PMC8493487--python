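"""Differential Mueller formalism: generators of simultaneous media.

A homogeneous medium is represented by a 4x4 differential matrix ``L``
whose matrix exponential is the measured (m11-normalized) Mueller
matrix.  ``L`` splits under the Minkowski-like metric
``G = diag(1, -1, -1, -1)`` into a nondepolarizing part ``Lm``
(G-antisymmetric; birefringence and diattenuation) and a depolarizing
part ``Lu`` (G-symmetric).

Entry layout of ``Lm`` (all polarization effects acting simultaneously)::

    [[ 0,    LD,   LD',  CD ],
     [ LD,   0,    CB,  -LB'],
     [ LD', -CB,   0,    LB ],
     [ CD,   LB', -LB,   0  ]]

with LB/LB' the 0/45 deg linear-birefringence components (rad), CB the
circular birefringence (rad), LD/LD'/CD the diattenuation components
(dimensionless), and the generator's ``Lu = diag(0, a1, a2, a3)``
holding the anisotropic depolarization coefficients (a_i <= 0 for
passive media).  The CB sign is fixed so that the decomposed circular
retardance matches :func:`mmpol.core.mueller_circular_retarder`.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = [
    "G_METRIC",
    "build_differential",
    "split_L",
    "mueller_from_differential",
    "differential_from_properties",
]

G_METRIC = np.diag([1.0, -1.0, -1.0, -1.0])


def build_differential(
    LB: float = 0.0,
    LBp: float = 0.0,
    CB: float = 0.0,
    LD: float = 0.0,
    LDp: float = 0.0,
    CD: float = 0.0,
    alpha1: float = 0.0,
    alpha2: float = 0.0,
    alpha3: float = 0.0,
) -> np.ndarray:
    """Assemble the differential matrix ``L = Lm + Lu`` from its entries."""
    Lm = np.array(
        [
            [0.0, LD, LDp, CD],
            [LD, 0.0, CB, -LBp],
            [LDp, -CB, 0.0, LB],
            [CD, LBp, -LB, 0.0],
        ]
    )
    return Lm + np.diag([0.0, alpha1, alpha2, alpha3])


def split_L(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """G-metric split ``L = Lm + Lu``.

    ``Lm = (L - G L^T G) / 2`` is the nondepolarizing part (zero
    diagonal), ``Lu = (L + G L^T G) / 2`` the depolarizing part.
    """
    L = np.asarray(L, dtype=float)
    GLtG = G_METRIC @ L.T @ G_METRIC
    return 0.5 * (L - GLtG), 0.5 * (L + GLtG)


def mueller_from_differential(L: np.ndarray) -> np.ndarray:
    """Mueller matrix of the medium: ``expm(L)``."""
    return expm(np.asarray(L, dtype=float))


def differential_from_properties(
    deltaL: float = 0.0,
    thetaFA: float = 0.0,
    deltaC: float = 0.0,
    DL: float = 0.0,
    thetaTA: float = 0.0,
    DC: float = 0.0,
    Delta: float | None = None,
    alphas: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Differential matrix realizing a set of accumulated properties.

    ``Delta`` (net depolarization in [0, 1)) maps to isotropic
    ``alpha = log(1 - Delta)``; pass ``alphas`` instead for anisotropic
    depolarization.  Diattenuations are accumulated through ``atanh``
    so that the decomposition's ``tanh`` recovers them exactly.
    """
    if Delta is not None and alphas is not None:
        raise ValueError("give either Delta or alphas, not both")
    if alphas is None:
        a = np.log(1.0 - Delta) if Delta else 0.0
        alphas = (a, a, a)
    ld = np.arctanh(DL)
    return build_differential(
        LB=deltaL * np.cos(2.0 * thetaFA),
        LBp=deltaL * np.sin(2.0 * thetaFA),
        CB=deltaC,
        LD=ld * np.cos(2.0 * thetaTA),
        LDp=ld * np.sin(2.0 * thetaTA),
        CD=np.arctanh(DC),
        alpha1=alphas[0],
        alpha2=alphas[1],
        alpha3=alphas[2],
    )
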
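"""Scenes: per-pixel differential-matrix parameter fields.

A :class:`Scene` holds one H x W plane per differential-matrix entry
(LB, LB', CB, LD, LD', CD, a1..a3) plus the pixel pitch; its per-pixel
Mueller image is the matrix exponential of the per-pixel generator.
Scenes model *simultaneous* polarization properties.  For media built
by serial composition (used to study the Stokes-estimator deviation
law) see :func:`serial_retarder_image`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.linalg import expm

from mmpol.core import mueller_circular_retarder, mueller_linear_retarder

__all__ = ["Scene", "serial_retarder_image"]

_PLANES = ("LB", "LBp", "CB", "LD", "LDp", "CD", "a1", "a2", "a3")


@dataclass
class Scene:
    """Per-pixel differential-matrix parameters over an H x W grid.

    Every plane broadcasts against ``shape``; scalars are allowed and
    expanded on construction.  ``pixel_pitch_mm`` defaults to the
    8.90 um pixel resolution of the imaging geometry this package
    emulates.
    """

    shape: tuple[int, int]
    LB: np.ndarray = 0.0
    LBp: np.ndarray = 0.0
    CB: np.ndarray = 0.0
    LD: np.ndarray = 0.0
    LDp: np.ndarray = 0.0
    CD: np.ndarray = 0.0
    a1: np.ndarray = 0.0
    a2: np.ndarray = 0.0
    a3: np.ndarray = 0.0
    pixel_pitch_mm: float = 8.90e-3
    name: str = "scene"
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 2:
            raise ValueError("shape must be (H, W)")
        for key in _PLANES:
            plane = np.broadcast_to(np.asarray(getattr(self, key), dtype=float), self.shape)
            setattr(self, key, np.array(plane))

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def differential(self) -> np.ndarray:
        """Per-pixel differential matrices, shape (H, W, 4, 4)."""
        H, W = self.shape
        z = np.zeros(self.shape)
        L = np.empty((H, W, 4, 4))
        L[..., 0, 0] = z
        L[..., 0, 1] = self.LD
        L[..., 0, 2] = self.LDp
        L[..., 0, 3] = self.CD
        L[..., 1, 0] = self.LD
        L[..., 1, 1] = self.a1
        L[..., 1, 2] = self.CB
        L[..., 1, 3] = -self.LBp
        L[..., 2, 0] = self.LDp
        L[..., 2, 1] = -self.CB
        L[..., 2, 2] = self.a2
        L[..., 2, 3] = self.LB
        L[..., 3, 0] = self.CD
        L[..., 3, 1] = self.LBp
        L[..., 3, 2] = -self.LB
        L[..., 3, 3] = self.a3
        return L

    def mueller(self) -> np.ndarray:
        """Per-pixel Mueller image ``expm(L)``, shape (H, W, 4, 4).

        Identical generators are exponentiated once (piecewise-uniform
        scenes are the common case).
        """
        L = self.differential().reshape(-1, 16)
        uniq, inverse = np.unique(L, axis=0, return_inverse=True)
        Ms = np.stack([expm(row.reshape(4, 4)) for row in uniq])
        return Ms[inverse].reshape(self.shape + (4, 4))

    # -- accumulated-property views (generation ground truth) ----------
    @property
    def deltaL(self) -> np.ndarray:
        return np.hypot(self.LB, self.LBp)

    @property
    def thetaFA(self) -> np.ndarray:
        return 0.5 * np.arctan2(self.LBp, self.LB)

    @property
    def deltaC(self) -> np.ndarray:
        return np.array(self.CB)

    @property
    def deltaT(self) -> np.ndarray:
        return np.sqrt(self.deltaL**2 + self.CB**2)

    @property
    def DL(self) -> np.ndarray:
        return np.tanh(np.hypot(self.LD, self.LDp))

    @property
    def thetaTA(self) -> np.ndarray:
        return 0.5 * np.arctan2(self.LDp, self.LD)

    @property
    def DC(self) -> np.ndarray:
        return np.tanh(self.CD)

    @property
    def Delta(self) -> np.ndarray:
        return 1.0 - (np.exp(self.a1) + np.exp(self.a2) + np.exp(self.a3)) / 3.0


def serial_retarder_image(
    deltaL: np.ndarray, thetaFA: np.ndarray, deltaC: np.ndarray
) -> np.ndarray:
    """Mueller image of a circular retarder *after* a linear retarder.

    Per pixel, ``M = C(deltaC) @ R(deltaL, thetaFA)``: the serial
    composition for which the naive Stokes estimator's optic-axis
    deviation from the true axis equals exactly ``-deltaC / 2``.
    """
    deltaL, thetaFA, deltaC = np.broadcast_arrays(
        np.asarray(deltaL, float), np.asarray(thetaFA, float), np.asarray(deltaC, float)
    )
    out = np.empty(deltaL.shape + (4, 4))
    it = np.nditer(deltaL, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = mueller_circular_retarder(deltaC[idx]) @ mueller_linear_retarder(
            deltaL[idx], thetaFA[idx]
        )
    return out
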
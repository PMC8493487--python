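"""Per-pixel Mueller-matrix reconstruction from the 16-state stack.

Each Mueller element is an exact linear combination of the 16
polarization-state intensity images (first subscript = PSG state,
second = PSA state)::

    m11 = I_HH + I_HV + I_VH + I_VV      m12 = I_HH + I_HV - I_VH - I_VV
    m13 = 2 I_PH + 2 I_PV - m11          m14 = 2 I_RH + 2 I_RV - m11
    m21 = I_HH - I_HV + I_VH - I_VV      m22 = I_HH - I_HV - I_VH + I_VV
    m23 = 2 I_PH - 2 I_PV - m21          m24 = 2 I_RH - 2 I_RV - m21
    m31 = 2 I_HP + 2 I_VP - m11          m32 = 2 I_HP - 2 I_VP - m12
    m33 = 4 I_PP - 2 I_PH - 2 I_PV - m31 m34 = 4 I_RP - 2 I_RH - 2 I_RV - m31
    m41 = 2 I_HR + 2 I_VR - m11          m42 = 2 I_HR - 2 I_VR - m12
    m43 = 4 I_PR - 2 I_PH - 2 I_PV - m41 m44 = 4 I_RR - 2 I_RH - 2 I_RV - m41

The result is normalized to the transmission of unpolarized light (the
m11 element) at each pixel; dark pixels are masked, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmpol.simulate import IntensityStack

__all__ = ["MuellerImage", "reconstruct_mueller"]


@dataclass
class MuellerImage:
    """m11-normalized per-pixel Mueller matrices.

    m : (H, W, 4, 4) normalized matrices (NaN where masked).
    m11 : (H, W) unpolarized transmission before normalization.
    mask : (H, W) bool, True where the pixel is valid.
    """

    m: np.ndarray
    m11: np.ndarray
    mask: np.ndarray
    pixel_pitch_mm: float = 8.90e-3

    @property
    def shape(self) -> tuple[int, int]:
        return self.m.shape[:2]


def reconstruct_mueller(stack: IntensityStack, eps_m11: float = 1e-9) -> MuellerImage:
    """Reconstruct the Mueller image from a 16-state intensity stack.

    Pixels whose m11 is at or below ``eps_m11`` times the image's
    largest m11 are flagged invalid (their normalized matrix is NaN).
    An all-zero stack yields a fully masked image.
    """
    I = stack.get  # noqa: E741 - I is the field's symbol for intensity
    m = np.empty(stack.shape + (4, 4))
    m11 = I("H", "H") + I("H", "V") + I("V", "H") + I("V", "V")
    m12 = I("H", "H") + I("H", "V") - I("V", "H") - I("V", "V")
    m21 = I("H", "H") - I("H", "V") + I("V", "H") - I("V", "V")
    m22 = I("H", "H") - I("H", "V") - I("V", "H") + I("V", "V")
    m[..., 0, 0] = m11
    m[..., 0, 1] = m12
    m[..., 1, 0] = m21
    m[..., 1, 1] = m22
    m[..., 0, 2] = 2 * I("P", "H") + 2 * I("P", "V") - m11
    m[..., 0, 3] = 2 * I("R", "H") + 2 * I("R", "V") - m11
    m[..., 1, 2] = 2 * I("P", "H") - 2 * I("P", "V") - m21
    m[..., 1, 3] = 2 * I("R", "H") - 2 * I("R", "V") - m21
    m31 = 2 * I("H", "P") + 2 * I("V", "P") - m11
    m41 = 2 * I("H", "R") + 2 * I("V", "R") - m11
    m[..., 2, 0] = m31
    m[..., 2, 1] = 2 * I("H", "P") - 2 * I("V", "P") - m12
    m[..., 2, 2] = 4 * I("P", "P") - 2 * I("P", "H") - 2 * I("P", "V") - m31
    m[..., 2, 3] = 4 * I("R", "P") - 2 * I("R", "H") - 2 * I("R", "V") - m31
    m[..., 3, 0] = m41
    m[..., 3, 1] = 2 * I("H", "R") - 2 * I("V", "R") - m12
    m[..., 3, 2] = 4 * I("P", "R") - 2 * I("P", "H") - 2 * I("P", "V") - m41
    m[..., 3, 3] = 4 * I("R", "R") - 2 * I("R", "H") - 2 * I("R", "V") - m41

    full_scale = float(m11.max()) if m11.size else 0.0
    mask = m11 > eps_m11 * max(full_scale, 0.0)
    if full_scale <= 0.0:
        mask = np.zeros_like(mask)

    norm = np.where(mask, m11, np.nan)
    m = m / norm[..., np.newaxis, np.newaxis]
    return MuellerImage(m=m, m11=m11, mask=mask, pixel_pitch_mm=stack.pixel_pitch_mm)
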
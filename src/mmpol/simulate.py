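"""Forward simulation of the 16-state polarization intensity stack.

The instrument records one image per (PSG, PSA) pair over the states
H, V, P (+45 deg linear) and R (right circular).  For generator state
``g = (1, g_hat)`` and analyzer state ``a = (1, a_hat)`` the noiseless
intensity is ``I_ga = a^T M g / 4`` -- with this scale the stack's
reconstructed m11 equals the medium's unpolarized transmission (1 for
m11-normalized media).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmpol.core import unit_stokes
from mmpol.scene import Scene

__all__ = ["PSG_PSA_PAIRS", "IntensityStack", "NoiseSpec", "simulate_stack"]

STATE_ORDER = "HVPR"
#: Page order of stacks on disk and in memory: PSG-major over H, V, P, R.
PSG_PSA_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (g, a) for g in STATE_ORDER for a in STATE_ORDER
)
_PAIR_INDEX = {pair: i for i, pair in enumerate(PSG_PSA_PAIRS)}


@dataclass
class IntensityStack:
    """16 co-registered nonnegative images indexed by (PSG, PSA) state.

    ``images`` has shape (16, H, W) in PSG-major page order
    (``PSG_PSA_PAIRS``).
    """

    images: np.ndarray
    pixel_pitch_mm: float = 8.90e-3

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 16:
            raise ValueError("images must have shape (16, H, W)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def get(self, psg: str, psa: str) -> np.ndarray:
        """Image for generator state ``psg`` and analyzer state ``psa``."""
        return self.images[_PAIR_INDEX[(psg.upper(), psa.upper())]]

    @classmethod
    def from_dict(cls, images: dict, pixel_pitch_mm: float = 8.90e-3) -> "IntensityStack":
        """Build from a mapping ``{('H','V'): image, ...}`` or ``{'HV': image}``."""
        pages = []
        for pair in PSG_PSA_PAIRS:
            key = pair if pair in images else pair[0] + pair[1]
            pages.append(np.asarray(images[key], dtype=float))
        return cls(np.stack(pages), pixel_pitch_mm)


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model.

    gaussian_sigma : additive Gaussian noise std as a fraction of the
        stack's noiseless full scale (its maximum pixel value).
    poisson_photons : expected photon count at full scale for shot
        noise; ``None`` disables it.
    """

    gaussian_sigma: float = 0.0
    poisson_photons: float | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_photons is not None and self.poisson_photons <= 0:
            raise ValueError("poisson_photons must be > 0")


def simulate_stack(
    scene: Scene | np.ndarray,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> IntensityStack:
    """Simulate the 16-image stack of a scene or Mueller image.

    Parameters
    ----------
    scene
        A :class:`~mmpol.scene.Scene`, or an (H, W, 4, 4) Mueller image
        (a single 4x4 matrix is accepted and treated as a 1 x 1 scene).
    noise
        Optional :class:`NoiseSpec`; Poisson shot noise is applied
        first, then additive Gaussian noise, then the stack is clipped
        at zero (a camera records no negative counts).
    seed
        Seed for the noise generator; required semantics: the same seed
        yields the identical stack.
    """
    if isinstance(scene, Scene):
        M = scene.mueller()
        pitch = scene.pixel_pitch_mm
    else:
        M = np.asarray(scene, dtype=float)
        if M.shape == (4, 4):
            M = M[np.newaxis, np.newaxis]
        pitch = 8.90e-3
    if M.ndim != 4 or M.shape[-2:] != (4, 4):
        raise ValueError("scene must be a Scene or an (H, W, 4, 4) array")

    pages = np.empty((16,) + M.shape[:2])
    for i, (g, a) in enumerate(PSG_PSA_PAIRS):
        gv, av = unit_stokes(g), unit_stokes(a)
        pages[i] = 0.25 * np.einsum("i,hwij,j->hw", av, M, gv)

    if noise is not None and (noise.gaussian_sigma > 0 or noise.poisson_photons):
        rng = np.random.default_rng(seed)
        full_scale = float(pages.max())
        if full_scale <= 0:
            full_scale = 1.0
        if noise.poisson_photons:
            lam = np.clip(pages, 0.0, None) * noise.poisson_photons / full_scale
            pages = rng.poisson(lam) * full_scale / noise.poisson_photons
        if noise.gaussian_sigma > 0:
            pages = pages + rng.normal(0.0, noise.gaussian_sigma * full_scale, pages.shape)
        pages = np.clip(pages, 0.0, None)

    return IntensityStack(pages, pixel_pitch_mm=pitch)
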
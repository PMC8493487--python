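"""Synthetic phantoms and tissue-like scenes.

Three families of fixtures emulate the samples every pipeline stage is
validated against, with no external data:

- *transparent strain phantoms*: homogeneous strain-birefringent gels
  whose linear retardance follows ``deltaL = k * strain + b`` with the
  fast axis along the strain direction (defaults k = 28.2 rad/strain,
  b = 0.3 rad);
- *scattering strain phantoms*: the same plus isotropic depolarization
  (net depolarization ~0.4 at rest for the 1% lipid recipe, retardance
  slope 21.4 rad/strain) and a strain-proportional linear diattenuation
  with transmission axis orthogonal to the strain;
- *pericardium-like scenes*: piecewise-uniform slow-axis domains with
  small within-domain axis jitter, circular retardance in [-1, 0] rad,
  regional net depolarization in [0.31, 0.73] and linear diattenuation
  in [0.08, 0.16].

All scenes are seeded and reproducible; generation ground truth is
available through the :class:`~mmpol.scene.Scene` property views.
"""

from __future__ import annotations

import numpy as np

from mmpol.core import fold_axial
from mmpol.scene import Scene, serial_retarder_image

__all__ = [
    "transparent_phantom",
    "scattering_phantom",
    "pericardium_scene",
    "deviation_sweep",
]


def transparent_phantom(
    strain: float,
    k: float = 28.2,
    b: float = 0.3,
    theta_strain: float = 0.393,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch_mm: float = 8.90e-3,
) -> Scene:
    """Homogeneous strain-birefringent gel: a pure linear retarder.

    ``deltaL = k * strain + b`` (rad) with fast axis along the strain
    direction ``theta_strain`` (rad).
    """
    if strain < 0:
        raise ValueError("strain must be >= 0")
    deltaL = k * strain + b
    return Scene(
        shape=shape,
        LB=deltaL * np.cos(2 * theta_strain),
        LBp=deltaL * np.sin(2 * theta_strain),
        pixel_pitch_mm=pixel_pitch_mm,
        name=f"transparent(strain={strain:g})",
        metadata={"strain": strain, "k": k, "b": b, "theta_strain": theta_strain},
    )


def scattering_phantom(
    strain: float,
    k: float = 21.4,
    b: float = 0.03,
    theta_strain: float = 0.393,
    depol: float = 0.4,
    d_slope: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch_mm: float = 8.90e-3,
) -> Scene:
    """Lipid-scattering strain phantom: retarder + depolarizer + diattenuator.

    Adds to the transparent recipe an isotropic depolarization with net
    depolarization ``depol`` and a linear diattenuation
    ``DL = d_slope * strain`` whose transmission axis is orthogonal to
    the strain direction.
    """
    if not 0 <= depol < 1:
        raise ValueError("depol must be in [0, 1)")
    deltaL = k * strain + b
    DL = d_slope * strain
    if not 0 <= DL < 1:
        raise ValueError("d_slope * strain must be in [0, 1)")
    theta_TA = theta_strain + np.pi / 2
    alpha = np.log(1.0 - depol)
    ld = np.arctanh(DL)
    return Scene(
        shape=shape,
        LB=deltaL * np.cos(2 * theta_strain),
        LBp=deltaL * np.sin(2 * theta_strain),
        LD=ld * np.cos(2 * theta_TA),
        LDp=ld * np.sin(2 * theta_TA),
        a1=alpha,
        a2=alpha,
        a3=alpha,
        pixel_pitch_mm=pixel_pitch_mm,
        name=f"scattering(strain={strain:g})",
        metadata={
            "strain": strain,
            "k": k,
            "b": b,
            "theta_strain": theta_strain,
            "depol": depol,
            "d_slope": d_slope,
        },
    )


def pericardium_scene(
    n_regions: tuple[int, int] = (2, 2),
    region_px: int = 32,
    axis_layout: np.ndarray | None = None,
    deltaL_range: tuple[float, float] = (0.2, 2.8),
    deltaC_range: tuple[float, float] = (-1.0, 0.0),
    Delta_range: tuple[float, float] = (0.31, 0.73),
    DL_range: tuple[float, float] = (0.08, 0.16),
    axis_jitter_deg: float = 3.0,
    seed: int | None = 0,
    pixel_pitch_mm: float = 8.90e-3,
) -> Scene:
    """Pericardium-like scene of piecewise-uniform anisotropy domains.

    Each of the ``n_regions`` domains (``region_px`` pixels square)
    draws a slow-axis orientation (uniform over the axial range unless
    ``axis_layout`` gives one per region), a linear retardance,
    circular retardance, net depolarization and linear diattenuation
    uniformly from the stated ranges.  Within a domain the axis carries
    wrapped-normal jitter (sigma ``axis_jitter_deg``) on doubled
    angles; all other parameters are uniform per domain.  Fully seeded:
    the same seed reproduces the scene bit for bit.

    Note: the default ranges keep the total retardance below pi so the
    decomposition recovers the generation parameters; widen
    ``deltaL_range`` past pi to produce the wrap artifact (abrupt pi/2
    axis flips) on purpose.
    """
    rng = np.random.default_rng(seed)
    nr, nc = n_regions
    H, W = nr * region_px, nc * region_px
    if axis_layout is not None:
        axis_layout = np.asarray(axis_layout, dtype=float)
        if axis_layout.shape != (nr, nc):
            raise ValueError("axis_layout must match n_regions")
        slow = axis_layout
    else:
        slow = rng.uniform(-np.pi / 2, np.pi / 2, size=(nr, nc))
    dL = rng.uniform(*deltaL_range, size=(nr, nc))
    dC = rng.uniform(*deltaC_range, size=(nr, nc))
    Dl = rng.uniform(*Delta_range, size=(nr, nc))
    DLr = rng.uniform(*DL_range, size=(nr, nc))
    thTA = rng.uniform(-np.pi / 2, np.pi / 2, size=(nr, nc))

    sigma = np.deg2rad(axis_jitter_deg)
    planes = {k: np.empty((H, W)) for k in ("LB", "LBp", "CB", "LD", "LDp", "a")}
    region_id = np.empty((H, W), dtype=int)
    for i in range(nr):
        for j in range(nc):
            sl = np.s_[i * region_px : (i + 1) * region_px, j * region_px : (j + 1) * region_px]
            # fast axis = slow axis - pi/2; jitter is wrapped-normal on 2*theta
            theta_fast = fold_axial(
                slow[i, j]
                - np.pi / 2
                + 0.5 * rng.normal(0.0, 2.0 * sigma, size=(region_px, region_px))
            )
            planes["LB"][sl] = dL[i, j] * np.cos(2 * theta_fast)
            planes["LBp"][sl] = dL[i, j] * np.sin(2 * theta_fast)
            planes["CB"][sl] = dC[i, j]
            ld = np.arctanh(DLr[i, j])
            planes["LD"][sl] = ld * np.cos(2 * thTA[i, j])
            planes["LDp"][sl] = ld * np.sin(2 * thTA[i, j])
            planes["a"][sl] = np.log(1.0 - Dl[i, j])
            region_id[sl] = i * nc + j
    return Scene(
        shape=(H, W),
        LB=planes["LB"],
        LBp=planes["LBp"],
        CB=planes["CB"],
        LD=planes["LD"],
        LDp=planes["LDp"],
        a1=planes["a"],
        a2=planes["a"],
        a3=planes["a"],
        pixel_pitch_mm=pixel_pitch_mm,
        name="pericardium",
        seed=seed,
        metadata={
            "region_px": region_px,
            "n_regions": n_regions,
            "slow_axis": slow,
            "deltaL": dL,
            "deltaC": dC,
            "Delta": Dl,
            "DL": DLr,
            "thetaTA": thTA,
            "region_id": region_id,
        },
    )


def deviation_sweep(
    deltaC_values: np.ndarray,
    deltaL: float = 1.5,
    theta: float = 0.3,
    block_px: int = 8,
) -> tuple[np.ndarray, dict]:
    """Serially composed linear+circular retarder sweep.

    Builds a Mueller image of vertical stripes (one block column per
    ``deltaC`` value), each a circular retarder of that retardance
    composed *after* a linear retarder ``(deltaL, theta)``.  Against
    the true axis ``theta`` the naive Stokes estimator's deviation is
    exactly ``-deltaC / 2`` per stripe.

    Returns the (H, W, 4, 4) Mueller image and a ground-truth dict with
    per-pixel ``thetaFA`` and ``deltaC`` maps.
    """
    deltaC_values = np.asarray(deltaC_values, dtype=float)
    n = deltaC_values.size
    H, W = block_px, block_px * n
    dC_map = np.repeat(deltaC_values[np.newaxis, :], H, axis=0)
    dC_map = np.repeat(dC_map, block_px, axis=1)[:, : W]
    th_map = np.full((H, W), theta)
    dL_map = np.full((H, W), deltaL)
    M = serial_retarder_image(dL_map, th_map, dC_map)
    return M, {"thetaFA": th_map, "deltaC": dC_map, "deltaL": dL_map, "block_px": block_px}
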
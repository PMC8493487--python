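"""Structured text configuration: scene specs and run configs.

Scene specs are YAML files naming one entry per differential-matrix
parameter plane.  Each plane is a constant, a linear gradient, or a
per-pixel TIFF::

    name: demo
    shape: [32, 32]
    pixel_pitch_mm: 0.0089
    planes:
      LB: 0.8                                # constant (rad)
      CB: {gradient: {start: -1.0, stop: 0.0, axis: x}}
      a1: {tiff: alpha_plane.tif}

Run configs collect the knobs of a pipeline invocation (paths, page
order, thresholds, block size, half-order assignment, seed) and are
validated before any stage runs; they are persisted next to the
outputs through :func:`mmpol.io.write_provenance`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mmpol.scene import Scene

__all__ = ["RunConfig", "load_scene_config", "scene_from_dict"]

_PLANE_KEYS = ("LB", "LBp", "CB", "LD", "LDp", "CD", "a1", "a2", "a3")


def _resolve_plane(spec, shape: tuple[int, int], base: Path):
    """Resolve a plane spec: scalar, {'gradient': ...} or {'tiff': path}."""
    if isinstance(spec, (int, float)):
        return float(spec)
    if not isinstance(spec, dict) or len(spec) != 1:
        raise ValueError(f"plane spec must be a number or one-key mapping, got {spec!r}")
    (kind, value), = spec.items()
    if kind == "tiff":
        import tifffile

        plane = np.asarray(tifffile.imread(base / value), dtype=float)
        if plane.shape != shape:
            raise ValueError(f"TIFF plane {value} has shape {plane.shape}, scene is {shape}")
        return plane
    if kind == "gradient":
        start, stop = float(value["start"]), float(value["stop"])
        axis = value.get("axis", "x")
        H, W = shape
        if axis == "x":
            return np.broadcast_to(np.linspace(start, stop, W), (H, W)).copy()
        if axis == "y":
            return np.broadcast_to(np.linspace(start, stop, H)[:, None], (H, W)).copy()
        raise ValueError(f"gradient axis must be 'x' or 'y', got {axis!r}")
    raise ValueError(f"unknown plane kind {kind!r}")


def scene_from_dict(cfg: dict, base: Path | str = ".") -> Scene:
    """Build a :class:`~mmpol.scene.Scene` from a parsed scene spec."""
    base = Path(base)
    if "shape" not in cfg:
        raise ValueError("scene spec requires 'shape: [H, W]'")
    shape = tuple(int(v) for v in cfg["shape"])
    planes = cfg.get("planes", {})
    unknown = set(planes) - set(_PLANE_KEYS)
    if unknown:
        raise ValueError(f"unknown plane names: {sorted(unknown)}")
    kwargs = {k: _resolve_plane(v, shape, base) for k, v in planes.items()}
    return Scene(
        shape=shape,
        pixel_pitch_mm=float(cfg.get("pixel_pitch_mm", 8.90e-3)),
        name=str(cfg.get("name", "scene")),
        seed=cfg.get("seed"),
        **kwargs,
    )


def load_scene_config(path) -> Scene:
    """Load a YAML scene spec; relative TIFF planes resolve next to it."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    return scene_from_dict(cfg, base=path.parent)


@dataclass
class RunConfig:
    """Validated knobs of a pipeline run, persisted alongside outputs."""

    input: str | None = None
    order: str = "HVPR"
    pixel_pitch_mm: float = 8.90e-3
    block_px: int = 112
    eps_m11: float = 1e-9
    depol_floor: float = 0.05
    max_undef: float = 0.25
    half_order: str = "first"
    seed: int | None = None
    outdir: str = "."
    extras: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if sorted(self.order.upper()) != sorted("HVPR"):
            raise ValueError(f"order must be a permutation of 'HVPR', got {self.order!r}")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if self.block_px < 1:
            raise ValueError("block_px must be >= 1")
        if not 0 <= self.max_undef <= 1:
            raise ValueError("max_undef must be in [0, 1]")
        if self.eps_m11 < 0 or self.depol_floor < 0:
            raise ValueError("thresholds must be >= 0")
        if str(self.half_order).lower() not in {"first", "second"}:
            raise ValueError("half_order must be 'first' or 'second'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        extras = raw.pop("extras", None)
        extras = dict(extras) if isinstance(extras, dict) else {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras.update({k: v for k, v in raw.items() if k not in known})
        return cls(extras=extras, **kwargs).validate()

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
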
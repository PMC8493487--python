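"""TIFF/CSV input-output and provenance records.

Stacks are stored as 16-page float32 TIFFs, page order PSG-major over
H, V, P, R (declared in the file's ImageDescription); a named-file
dialect ``I_<g><a>.tif`` (first letter = PSG state, second = PSA state)
is also accepted.  Property maps are one float32 TIFF per plane plus a
mask TIFF and a CSV summary.  Every pipeline run can persist a
machine-readable provenance record (config + seed + versions).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from mmpol.anisotropy import axial_circular_stats
from mmpol.logdecomp import PropertyMaps
from mmpol.reconstruction import MuellerImage
from mmpol.simulate import PSG_PSA_PAIRS, IntensityStack

__all__ = [
    "STACK_DESCRIPTION",
    "read_stack",
    "write_stack",
    "write_mueller",
    "read_mueller",
    "write_maps",
    "read_maps",
    "maps_summary",
    "write_provenance",
]

STACK_DESCRIPTION = (
    "mmpol intensity stack; 16 pages, PSG-major order "
    "(PSG in H,V,P,R; PSA in H,V,P,R); I_<psg><psa>"
)

_ANGULAR_PLANES = {"thetaFA", "thetaTA"}


def write_stack(stack: IntensityStack, path) -> Path:
    """Write a 16-page float32 TIFF stack (PSG-major page order)."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.images.astype(np.float32),
        photometric="minisblack",
        description=STACK_DESCRIPTION,
        metadata={"pixel_pitch_mm": stack.pixel_pitch_mm},
    )
    return path


def read_stack(source, order: str = "HVPR", pixel_pitch_mm: float = 8.90e-3) -> IntensityStack:
    """Read an intensity stack.

    ``source`` is either a multi-page TIFF path, a directory holding
    the named-file dialect ``I_<g><a>.tif``/``.tiff``, or an explicit
    sequence of 16 paths in PSG-major page order.  ``order`` declares
    the PSG/PSA state sequence of the pages (default ``"HVPR"``); any
    permutation of those four letters is accepted.
    """
    order = order.upper()
    if sorted(order) != sorted("HVPR"):
        raise ValueError(f"order must be a permutation of 'HVPR', got {order!r}")

    if isinstance(source, (list, tuple)):
        pages = [np.asarray(tifffile.imread(p), dtype=float) for p in source]
    else:
        source = Path(source)
        if source.is_dir():
            images = {}
            for g in "HVPR":
                for a in "HVPR":
                    for ext in (".tif", ".tiff"):
                        p = source / f"I_{g}{a}{ext}"
                        if p.exists():
                            images[(g, a)] = np.asarray(tifffile.imread(p), dtype=float)
                            break
                    else:
                        raise FileNotFoundError(f"missing image I_{g}{a}.tif in {source}")
            return IntensityStack.from_dict(images, pixel_pitch_mm)
        pages = [np.asarray(p, dtype=float) for p in tifffile.imread(source)]

    if len(pages) != 16:
        raise ValueError(f"expected 16 pages, got {len(pages)}")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"page shapes differ: {shapes}")
    pairs = [(g, a) for g in order for a in order]
    images = {pair: page for pair, page in zip(pairs, pages)}
    return IntensityStack.from_dict(images, pixel_pitch_mm)


def write_mueller(Mimg: MuellerImage, outdir) -> Path:
    """Write a Mueller image: 16-page element TIFF + m11 plane + mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    elements = np.moveaxis(Mimg.m.reshape(Mimg.shape + (16,)), -1, 0)
    tifffile.imwrite(
        outdir / "mueller.tif",
        elements.astype(np.float32),
        photometric="minisblack",
        description="mmpol Mueller image; 16 pages row-major m11..m44, m11-normalized",
    )
    tifffile.imwrite(outdir / "m11.tif", Mimg.m11.astype(np.float32))
    tifffile.imwrite(outdir / "mask.tif", Mimg.mask.astype(np.uint8))
    return outdir


def read_mueller(outdir) -> MuellerImage:
    """Read back a Mueller image written by :func:`write_mueller`."""
    outdir = Path(outdir)
    elements = np.asarray(tifffile.imread(outdir / "mueller.tif"), dtype=float)
    m = np.moveaxis(elements, 0, -1).reshape(elements.shape[1:] + (4, 4))
    m11 = np.asarray(tifffile.imread(outdir / "m11.tif"), dtype=float)
    mask = np.asarray(tifffile.imread(outdir / "mask.tif")).astype(bool)
    return MuellerImage(m=m, m11=m11, mask=mask)


def write_maps(maps: PropertyMaps, outdir) -> Path:
    """Write property maps: one float32 TIFF per plane + mask + summary CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in PropertyMaps.PLANES:
        tifffile.imwrite(outdir / f"{name}.tif", getattr(maps, name).astype(np.float32))
    tifffile.imwrite(outdir / "deltaT.tif", maps.deltaT.astype(np.float32))
    tifffile.imwrite(outdir / "undefined_mask.tif", maps.undefined.astype(np.uint8))
    maps_summary(maps).to_csv(outdir / "summary.csv", index=False)
    return outdir


def read_maps(outdir) -> PropertyMaps:
    """Read back property maps written by :func:`write_maps`."""
    outdir = Path(outdir)
    planes = {
        name: np.asarray(tifffile.imread(outdir / f"{name}.tif"), dtype=float)
        for name in PropertyMaps.PLANES
    }
    undefined = np.asarray(tifffile.imread(outdir / "undefined_mask.tif")).astype(bool)
    case = np.where(undefined, "undefined", "")
    return PropertyMaps(undefined=undefined, case=case.astype("<U16"), **planes)


def maps_summary(maps: PropertyMaps, region_id: np.ndarray | None = None) -> pd.DataFrame:
    """Per-region summary of property maps.

    One row per (region, property): plain mean for magnitudes, axial
    circular mean and variance for orientation planes, and the
    fraction of undefined pixels.  Without ``region_id`` the whole
    image is one region.
    """
    if region_id is None:
        region_id = np.zeros(maps.shape, dtype=int)
    region_id = np.asarray(region_id)
    rows = []
    for rid in np.unique(region_id):
        sel = region_id == rid
        undef = float(np.mean(maps.undefined[sel]))
        for name in PropertyMaps.PLANES + ("deltaT",):
            plane = maps.deltaT if name == "deltaT" else getattr(maps, name)
            vals = plane[sel]
            vals = vals[np.isfinite(vals)]
            row = {
                "region": int(rid),
                "property": name,
                "n_defined": int(vals.size),
                "frac_undefined": undef,
            }
            if name in _ANGULAR_PLANES:
                cmean, cvar = axial_circular_stats(vals)
                row["mean"] = cmean
                row["circ_variance"] = cvar
            else:
                row["mean"] = float(np.mean(vals)) if vals.size else float("nan")
                row["circ_variance"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def write_provenance(outdir, config: dict, seed: int | None = None) -> Path:
    """Persist a machine-readable provenance record next to the outputs."""
    import mmpol

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "mmpol": mmpol.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
            "python": platform.python_version(),
        },
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
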
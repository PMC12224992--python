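"""Writers/readers: image stacks, STL, legacy VTK, NPZ fields, HU stacks.

Image stacks follow the print-file convention: one image per Z slice with
zero-padded indices, white = material. VTK output uses the legacy ASCII
STRUCTURED_POINTS format (readable by ParaView) and is written directly —
the format is a short text header plus one value per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread, imwrite

from .grids import RegularGrid
from .perfusion_analysis import HUConstants, HUStack


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_image_stack(occupancy: np.ndarray, outdir, fmt: str = "png",
                      prefix: str = "slice") -> list[Path]:
    """One black-and-white image per Z slice; white (255) = material."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nz = occupancy.shape[2]
    width = max(4, len(str(nz - 1)))
    paths = []
    for z in range(nz):
        img = (occupancy[:, :, z].T.astype(np.uint8)) * 255  # rows = Y
        path = outdir / f"{prefix}_{z:0{width}d}.{fmt}"
        if fmt in ("tif", "tiff"):
            tifffile.imwrite(path, img)
        else:
            imwrite(path, img)
        paths.append(path)
    return paths


def read_image_stack(indir, pattern: str = "slice_*") -> np.ndarray:
    files = sorted(Path(indir).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no slices matching {pattern} in {indir}")
    slices = []
    for f in files:
        img = tifffile.imread(f) if f.suffix in (".tif", ".tiff") else imread(f)
        slices.append(np.asarray(img).T > 127)
    return np.stack(slices, axis=2)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(verts: np.ndarray, faces: np.ndarray, path) -> Path:
    """Binary STL of a triangulated surface (via trimesh)."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path


# ---------------------------------------------------------------------------
# legacy VTK structured points
# ---------------------------------------------------------------------------

def write_vtk_structured(path, grid: RegularGrid, fields: dict[str, np.ndarray],
                         title: str = "gradedtpms field") -> Path:
    """Legacy-ASCII VTK STRUCTURED_POINTS file with point-data scalars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = grid.shape
    off = 0.5 if grid.centered else 0.0
    origin = [o + off * s for o, s in zip(grid.origin, grid.spacing)]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {grid.spacing[0]:.9g} {grid.spacing[1]:.9g} {grid.spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.shape == (*grid.shape, 3):
                fh.write(f"VECTORS {name} double\n")
                flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)  # VTK: x fastest
                for v in flat:
                    fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                flat = arr.transpose(2, 1, 0).reshape(-1)
                fh.write("\n".join(f"{v:.9g}" for v in flat))
                fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# gridded NPZ container
# ---------------------------------------------------------------------------

def save_field_npz(path, grid: RegularGrid, **fields) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        shape=np.array(grid.shape),
        spacing=np.array(grid.spacing),
        origin=np.array(grid.origin),
        centered=np.array(int(grid.centered)),
        **fields,
    )
    return path


def load_field_npz(path) -> tuple[RegularGrid, dict[str, np.ndarray]]:
    with np.load(path) as data:
        grid = RegularGrid(
            tuple(int(n) for n in data["shape"]),
            tuple(float(s) for s in data["spacing"]),
            tuple(float(o) for o in data["origin"]),
            centered=bool(int(data["centered"])),
        )
        fields = {k: data[k] for k in data.files
                  if k not in ("shape", "spacing", "origin", "centered")}
    return grid, fields


# ---------------------------------------------------------------------------
# HU stacks
# ---------------------------------------------------------------------------

def save_hu_stack(outdir, stack: HUStack) -> Path:
    """Write an HU stack as TIFF volumes + constants/times YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "air.tif", stack.air.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(outdir / "water.tif", stack.water.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(outdir / "frames.tif", stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "times_s": [float(t) for t in stack.times],
        "hu_constants": {
            "material": stack.constants.material,
            "water": stack.constants.water,
            "ca": stack.constants.ca,
            "air": stack.constants.air,
        },
    }
    (outdir / "stack.yaml").write_text(yaml.safe_dump(meta))
    return outdir


def load_hu_stack(indir) -> HUStack:
    indir = Path(indir)
    meta = yaml.safe_load((indir / "stack.yaml").read_text())
    c = meta["hu_constants"]
    constants = HUConstants(material=float(c["material"]), water=float(c["water"]),
                            ca=float(c["ca"]), air=float(c["air"]))
    return HUStack(
        tifffile.imread(indir / "air.tif").astype(float),
        tifffile.imread(indir / "water.tif").astype(float),
        tifffile.imread(indir / "frames.tif").astype(float),
        np.array(meta["times_s"], dtype=float),
        constants,
    )


def write_manifest(outdir, config: dict, seed: int | None = None) -> Path:
    """Run manifest: config echo + hash + version, for exact reproduction."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    import hashlib

    manifest = {
        "package": "gradedtpms",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
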
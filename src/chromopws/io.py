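"""File formats: image cubes (HDF5 / multi-page TIFF + JSON sidecar),
region scenes (TIFF), localization tables (ThunderSTORM CSV) and optics
configuration files (flat YAML key: value)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .optics import OpticsConfig
from .static import SpectralCube
from .dynamic import TemporalCube
from .synthetic import RegionScene

__all__ = [
    "save_spectral_cube", "load_spectral_cube",
    "save_temporal_cube", "load_temporal_cube",
    "save_scene", "load_scene",
    "save_optics", "load_optics",
]


# ---------------------------------------------------------------------------
# optics config
# ---------------------------------------------------------------------------

def save_optics(cfg: OpticsConfig, path) -> None:
    """Write the optics constants as a flat YAML mapping (keys = field names)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_optics(path) -> OpticsConfig:
    with open(path) as fh:
        return OpticsConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# spectral cubes
# ---------------------------------------------------------------------------

def save_spectral_cube(cube: SpectralCube, path) -> None:
    """HDF5 (``.h5``/``.hdf5``) or multi-page TIFF (λ pages) + JSON sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=cube.intensity)
            f.create_dataset("lambda_nm", data=cube.lambda_grid)
            if cube.reference is not None:
                f.create_dataset("reference", data=cube.reference)
            f.create_dataset("pixel_size_um", data=cube.pixel_size)
    else:
        tifffile.imwrite(path, np.moveaxis(cube.intensity, -1, 0)
                         .astype(np.float32))
        sidecar = {"lambda_nm": cube.lambda_grid.tolist(),
                   "pixel_size_um": cube.pixel_size}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
        if cube.reference is not None:
            tifffile.imwrite(str(path).replace(".tif", "_ref.tif"),
                             cube.reference.astype(np.float32))


def load_spectral_cube(path) -> SpectralCube:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ref = f["reference"][...] if "reference" in f else None
            return SpectralCube(intensity=f["intensity"][...],
                                lambda_grid=f["lambda_nm"][...],
                                reference=ref,
                                pixel_size=float(f["pixel_size_um"][()]))
    stack = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    ref_path = Path(str(path).replace(".tif", "_ref.tif"))
    ref = tifffile.imread(ref_path) if ref_path.exists() else None
    return SpectralCube(intensity=np.moveaxis(stack, 0, -1),
                        lambda_grid=np.asarray(sidecar["lambda_nm"]),
                        reference=ref,
                        pixel_size=float(sidecar["pixel_size_um"]))


# ---------------------------------------------------------------------------
# temporal cubes
# ---------------------------------------------------------------------------

def save_temporal_cube(cube: TemporalCube, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=cube.intensity)
            f.create_dataset("i0", data=cube.i0)
            f.create_dataset("frame_interval_s", data=cube.frame_interval)
            f.create_dataset("lambda_dyn_nm", data=cube.lambda_dyn)
            f.create_dataset("pixel_size_um", data=cube.pixel_size)
    else:
        tifffile.imwrite(path, np.moveaxis(cube.intensity, -1, 0)
                         .astype(np.float32))
        Path(str(path) + ".json").write_text(json.dumps(
            {"frame_interval_s": cube.frame_interval,
             "lambda_dyn_nm": cube.lambda_dyn,
             "pixel_size_um": cube.pixel_size}))
        tifffile.imwrite(str(path).replace(".tif", "_i0.tif"),
                         cube.i0.astype(np.float32))


def load_temporal_cube(path, i0_path=None) -> TemporalCube:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return TemporalCube(intensity=f["intensity"][...],
                                i0=f["i0"][...],
                                frame_interval=float(f["frame_interval_s"][()]),
                                lambda_dyn=float(f["lambda_dyn_nm"][()]),
                                pixel_size=float(f["pixel_size_um"][()]))
    stack = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    i0 = tifffile.imread(i0_path or str(path).replace(".tif", "_i0.tif"))
    return TemporalCube(intensity=np.moveaxis(stack, 0, -1), i0=i0,
                        frame_interval=float(sidecar["frame_interval_s"]),
                        lambda_dyn=float(sidecar["lambda_dyn_nm"]),
                        pixel_size=float(sidecar["pixel_size_um"]))


# ---------------------------------------------------------------------------
# region scenes
# ---------------------------------------------------------------------------

def save_scene(scene: RegionScene, path) -> None:
    """Labeled image as int16 TIFF + JSON sidecar with pairing/params."""
    tifffile.imwrite(path, scene.label_image.astype(np.int16))
    Path(str(path) + ".json").write_text(json.dumps(
        {"pairing": {str(k): v for k, v in scene.pairing.items()},
         "pixel_size_um": scene.pixel_size,
         "params": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in scene.params.items()}}))


def load_scene(path, pixel_size_um: float | None = None) -> RegionScene:
    label = tifffile.imread(path).astype(int)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        return RegionScene(label_image=label,
                           pairing={int(k): v
                                    for k, v in sc.get("pairing", {}).items()},
                           pixel_size=float(sc.get("pixel_size_um", 0.15)),
                           params=sc.get("params", {}))
    return RegionScene(label_image=label,
                       pixel_size=pixel_size_um or 0.15)
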
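"""File I/O: float32 TIFF, raw binary with text sidecar, YAML config, CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import ReconConfig
from .containers import Sinogram, uniform_angles

__all__ = [
    "read_sinogram",
    "write_sinogram",
    "read_image",
    "write_image",
    "load_config",
]

SIDECAR_KEYS = ("n_angles", "n_bins", "center")


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 2D array as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(pixels, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float32)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta")


def write_sinogram(path, sino: Sinogram, fmt: str = "tiff") -> None:
    """Write a sinogram (rows = angles) as float32 TIFF or raw binary.

    The raw format stores little-endian float32 and a plain-text sidecar
    ``<path>.meta`` with the keys n_angles, n_bins and center.
    """
    if fmt == "tiff":
        write_image(path, sino.data)
    elif fmt == "raw":
        np.asarray(sino.data, dtype="<f4").tofile(str(path))
        _sidecar_path(path).write_text(
            f"n_angles = {sino.n_angles}\n"
            f"n_bins = {sino.n_bins}\n"
            f"center = {sino.center}\n"
        )
    else:
        raise ValueError(f"unknown sinogram format {fmt!r}; expected tiff or raw")


def read_sinogram(path, fmt: str = None) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram`.

    With no format hint, ``.tif``/``.tiff`` suffixes select TIFF and
    anything else raw.  TIFF sinograms default to center (n_bins-1)/2
    and equispaced angles over [0, pi).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "raw"
    if fmt == "tiff":
        data = read_image(path).astype(float)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a 2D sinogram")
        return Sinogram(data)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"raw sinogram {path} is missing its sidecar {meta_path} "
            f"(required keys: {', '.join(SIDECAR_KEYS)})"
        )
    meta = {}
    for line in meta_path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = float(v)
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{meta_path}: missing required keys {missing}")
    n_angles, n_bins = int(meta["n_angles"]), int(meta["n_bins"])
    data = np.fromfile(str(path), dtype="<f4")
    if data.size != n_angles * n_bins:
        raise ValueError(
            f"{path}: {data.size} values, sidecar promises "
            f"{n_angles} x {n_bins}"
        )
    return Sinogram(
        data.reshape(n_angles, n_bins).astype(float),
        angles=uniform_angles(n_angles),
        center=meta["center"],
    )


def load_config(path, overrides: dict = None) -> ReconConfig:
    """Load a YAML reconstruction config; overrides win over the file."""
    d = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        d.update(loaded)
    if overrides:
        d.update({k: v for k, v in overrides.items() if v is not None})
    return ReconConfig.from_dict(d)
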
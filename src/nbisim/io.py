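"""Readers and writers for the pipeline's file formats.

All tabular data travels as headered CSV so synthetic fixtures and field
measurements are interchangeable:

* checker measurements — ``patch_id,R,G,B,r<λ>,...`` with one reflectance
  column per grid wavelength (e.g. ``r380`` … ``r780``);
* SPDs — ``wavelength_nm,power``; CMFs — ``wavelength_nm,xbar,ybar,zbar``;
* NBI targets — ``patch_id,L,a,b`` (Lab, D65) or ``patch_id,R,G,B`` (8-bit
  sRGB, converted to Lab on read);
* optimizer traces — ``evaluation,best_objective``.

Images are 8-bit RGB PNG/TIFF via Pillow; models are JSON documents handled
by their own classes.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .colorimetry import (
    SPD,
    ColorMatchingFunctions,
    WavelengthGrid,
    srgb_decode,
    srgb_to_xyz,
    xyz_to_lab,
)
from .errors import SchemaError
from .nbi import BandFitResult, NBITargetSet

__all__ = [
    "read_checker_csv",
    "write_checker_csv",
    "read_spd_csv",
    "write_spd_csv",
    "read_cmf_csv",
    "write_cmf_csv",
    "read_targets_csv",
    "write_targets_csv",
    "write_trace_csv",
    "read_image",
    "write_image",
]

_REFL_COL = re.compile(r"^r(\d+(?:\.\d+)?)$")


def _grid_from_columns(columns: list[str]) -> tuple[WavelengthGrid, list[str]]:
    refl_cols = [c for c in columns if _REFL_COL.match(c)]
    if len(refl_cols) < 2:
        raise SchemaError("checker CSV needs at least two reflectance columns r<λ>")
    wavelengths = np.array([float(_REFL_COL.match(c).group(1)) for c in refl_cols])
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    refl_cols = [refl_cols[i] for i in order]
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0]):
        raise SchemaError("reflectance columns are not on a uniform wavelength grid")
    grid = WavelengthGrid(float(wavelengths[0]), float(wavelengths[-1]), float(steps[0]))
    return grid, refl_cols


def _format_wavelength(wl: float) -> str:
    return f"{wl:g}"


def write_checker_csv(path, patch_ids, rgbs, reflectances, grid: WavelengthGrid) -> None:
    rgbs = np.asarray(rgbs)
    reflectances = grid.check_length(reflectances, "reflectances")
    frame = pd.DataFrame({"patch_id": np.asarray(patch_ids, dtype=int)})
    frame[["R", "G", "B"]] = rgbs.astype(int)
    refl = pd.DataFrame(
        np.asarray(reflectances, dtype=float),
        columns=[f"r{_format_wavelength(wl)}" for wl in grid.wavelengths],
    )
    pd.concat([frame, refl], axis=1).to_csv(path, index=False)


def read_checker_csv(path):
    """Returns ``(patch_ids, rgbs_uint8, reflectances, grid)``."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse checker CSV {path}: {exc}") from exc
    required = {"patch_id", "R", "G", "B"}
    if not required.issubset(frame.columns):
        raise SchemaError(
            f"checker CSV missing columns {sorted(required - set(frame.columns))}"
        )
    if frame[list(required)].isna().any().any():
        raise SchemaError("checker CSV contains missing values in id/RGB columns")
    grid, refl_cols = _grid_from_columns(list(frame.columns))
    if frame[refl_cols].isna().any().any():
        raise SchemaError("checker CSV contains missing reflectance values")
    patch_ids = frame["patch_id"].to_numpy(dtype=int)
    if len(set(patch_ids)) != len(patch_ids):
        raise SchemaError("checker CSV contains duplicate patch_ids")
    rgbs = frame[["R", "G", "B"]].to_numpy()
    if rgbs.min() < 0 or rgbs.max() > 255:
        raise SchemaError("checker CSV RGB values outside [0, 255]")
    reflectances = frame[refl_cols].to_numpy(dtype=float)
    if reflectances.min() < 0 or reflectances.max() > 1:
        raise SchemaError("checker CSV reflectance values outside [0, 1]")
    return patch_ids, rgbs.astype(np.uint8), reflectances, grid


def write_spd_csv(path, spd: SPD) -> None:
    pd.DataFrame(
        {"wavelength_nm": spd.grid.wavelengths, "power": spd.power}
    ).to_csv(path, index=False)


def _read_wavelength_table(path, columns: list[str]) -> tuple[WavelengthGrid, pd.DataFrame]:
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    missing = set(columns) - set(frame.columns)
    if missing:
        raise SchemaError(f"CSV {path} missing columns {sorted(missing)}")
    if frame[columns].isna().any().any():
        raise SchemaError(f"CSV {path} contains missing values")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    steps = np.diff(wl)
    if len(wl) < 2 or not np.allclose(steps, steps[0]):
        raise SchemaError(f"CSV {path} wavelengths are not a uniform grid")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    return grid, frame


def read_spd_csv(path) -> SPD:
    grid, frame = _read_wavelength_table(path, ["wavelength_nm", "power"])
    return SPD(grid=grid, power=frame["power"].to_numpy(dtype=float))


def write_cmf_csv(path, cmf: ColorMatchingFunctions) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": cmf.grid.wavelengths,
            "xbar": cmf.xbar,
            "ybar": cmf.ybar,
            "zbar": cmf.zbar,
        }
    ).to_csv(path, index=False)


def read_cmf_csv(path) -> ColorMatchingFunctions:
    grid, frame = _read_wavelength_table(path, ["wavelength_nm", "xbar", "ybar", "zbar"])
    return ColorMatchingFunctions(
        grid=grid,
        xbar=frame["xbar"].to_numpy(dtype=float),
        ybar=frame["ybar"].to_numpy(dtype=float),
        zbar=frame["zbar"].to_numpy(dtype=float),
    )


def write_targets_csv(path, targets: NBITargetSet) -> None:
    lab = targets.ordered_lab()
    pd.DataFrame(
        {
            "patch_id": np.arange(1, 25),
            "L": lab[:, 0],
            "a": lab[:, 1],
            "b": lab[:, 2],
        }
    ).to_csv(path, index=False)


def read_targets_csv(path) -> NBITargetSet:
    """Read NBI targets; accepts Lab columns or 8-bit sRGB columns."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse targets CSV {path}: {exc}") from exc
    if "patch_id" not in frame.columns:
        raise SchemaError("targets CSV missing patch_id column")
    if {"L", "a", "b"}.issubset(frame.columns):
        lab = frame[["L", "a", "b"]].to_numpy(dtype=float)
    elif {"R", "G", "B"}.issubset(frame.columns):
        rgb = frame[["R", "G", "B"]].to_numpy(dtype=float)
        if rgb.min() < 0 or rgb.max() > 255:
            raise SchemaError("targets CSV RGB values outside [0, 255]")
        lab = xyz_to_lab(srgb_to_xyz(srgb_decode(rgb / 255.0)))
    else:
        raise SchemaError("targets CSV needs either L,a,b or R,G,B columns")
    if frame[["patch_id"]].isna().any().any() or not np.all(np.isfinite(lab)):
        raise SchemaError("targets CSV contains missing values")
    return NBITargetSet(
        patch_ids=tuple(frame["patch_id"].to_numpy(dtype=int)), lab=lab
    )


def write_trace_csv(path, result: BandFitResult) -> None:
    pd.DataFrame(
        result.trace or [(0, result.objective)],
        columns=["evaluation", "best_objective"],
    ).to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    """Load an image as 8-bit RGB ``(H, W, 3)``."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"))
    return arr


def write_image(path, array: np.ndarray) -> None:
    array = np.asarray(array)
    if array.ndim != 3 or array.shape[2] != 3 or array.dtype != np.uint8:
        raise SchemaError(f"image must be uint8 (H, W, 3), got {array.dtype} {array.shape}")
    Image.fromarray(array, mode="RGB").save(Path(path))
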
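"""File formats: TIFF images, CSV marker tables, JSON reports, TOML configs.

All writes are atomic (temp file + rename in the target directory); all
reads validate shape and dtype and fail with the offending path/field in
the message.
"""

from __future__ import annotations

import json
import os
import tempfile
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "write_tiff",
    "read_tiff_u16",
    "read_tiff_f32",
    "write_complex_field",
    "read_complex_field",
    "write_markers_csv",
    "read_markers_csv",
    "write_json",
    "read_json",
    "read_toml",
    "write_toml",
    "interferogram_name",
]

MARKER_COLUMNS = ["sample_id", "group", "parameter", "phase_plane", "Z1", "Z2", "Z3", "Z4", "K"]


class FormatError(ValueError):
    """A file did not match the expected format."""


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def interferogram_name(sample_id: str, s: int, analyzer: int) -> str:
    return f"{sample_id}_s{s}_A{analyzer}.tif"


def write_tiff(path: Path | str, image: np.ndarray) -> None:
    """Write an image as TIFF (uint8/uint16 interferograms, float32 maps)."""
    image = np.asarray(image)
    if image.dtype not in (np.uint8, np.uint16, np.float32):
        if np.issubdtype(image.dtype, np.floating):
            image = image.astype(np.float32)
        else:
            raise FormatError(f"unsupported dtype {image.dtype} for {path}")
    _atomic_write(Path(path), lambda tmp: tifffile.imwrite(tmp, image))


def _read_tiff(path: Path | str, dtype) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if arr.dtype != dtype:
        raise FormatError(f"{path}: expected dtype {np.dtype(dtype).name}, found {arr.dtype.name}")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, found shape {arr.shape}")
    return arr


def read_tiff_u16(path: Path | str) -> np.ndarray:
    return _read_tiff(path, np.uint16)


def read_tiff_f32(path: Path | str) -> np.ndarray:
    return _read_tiff(path, np.float32)


def write_complex_field(path_stem: Path | str, field: np.ndarray) -> tuple[Path, Path]:
    """Write a complex map as a real/imag float32 TIFF pair."""
    field = np.asarray(field)
    re_path = Path(f"{path_stem}_re.tif")
    im_path = Path(f"{path_stem}_im.tif")
    write_tiff(re_path, field.real.astype(np.float32))
    write_tiff(im_path, field.imag.astype(np.float32))
    return re_path, im_path


def read_complex_field(path_stem: Path | str) -> np.ndarray:
    re = read_tiff_f32(Path(f"{path_stem}_re.tif"))
    im = read_tiff_f32(Path(f"{path_stem}_im.tif"))
    if re.shape != im.shape:
        raise FormatError(f"{path_stem}: real/imag shape mismatch {re.shape} vs {im.shape}")
    return re.astype(np.float64) + 1j * im.astype(np.float64)


def write_markers_csv(path: Path | str, table: pd.DataFrame) -> None:
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: marker table missing column(s) {missing}")
    _atomic_write(Path(path), lambda tmp: table[MARKER_COLUMNS].to_csv(tmp, index=False, float_format="%.17g"))


def read_markers_csv(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: marker CSV missing column(s) {missing}")
    return df


def write_json(path: Path | str, obj) -> None:
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n"))


def read_json(path: Path | str):
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc


def read_toml(path: Path | str) -> dict:
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise FormatError(f"{path}: invalid TOML ({exc})") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise FormatError(f"cannot serialize {type(v).__name__} to TOML")


def write_toml(path: Path | str, obj: dict) -> None:
    """Minimal TOML emitter for flat or one-level-nested config dicts."""
    lines: list[str] = []
    tables: list[str] = []
    for key, val in obj.items():
        if isinstance(val, dict):
            tables.append(f"[{key}]")
            for k2, v2 in val.items():
                if v2 is not None:
                    tables.append(f"{k2} = {_toml_value(v2)}")
            tables.append("")
        elif val is not None:
            lines.append(f"{key} = {_toml_value(val)}")
    text = "\n".join(lines + [""] + tables).rstrip() + "\n"
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(text))
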
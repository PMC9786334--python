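"""Image and table I/O.

Images: multi-page grayscale TIFF (page order blue, green, red), RGB
TIFF/PNG, or three single-channel files; 8- and 16-bit depths are read and
preserved as raw intensities.  Tables: CSV, comma-separated, UTF-8, one
comment line documenting the coordinate convention ((row, col), 0-based,
origin top-left) followed by a header row; every table carries a
``schema_version`` column so downstream parsing stays stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import ChannelStack

__all__ = [
    "SCHEMA_VERSION",
    "read_channel_stack",
    "write_channel_stack",
    "write_table",
    "read_table",
]

SCHEMA_VERSION = 1

#: page index per role for multi-page TIFFs written by this package
DEFAULT_PAGE_MAP = {"nuclei": 0, "viable": 1, "dead": 2}
#: channel index per role for RGB images (blue carries nuclei)
DEFAULT_RGB_MAP = {"nuclei": 2, "viable": 1, "dead": 0}

_ROLES = ("nuclei", "viable", "dead")


def _check_map(channel_map: Mapping[str, int]) -> None:
    unknown = set(channel_map) - set(_ROLES)
    if unknown:
        raise ValueError(f"unknown channel roles {sorted(unknown)}; expected {_ROLES}")
    if set(channel_map) != set(_ROLES):
        raise ValueError(f"channel map must assign all of {_ROLES}, got {sorted(channel_map)}")


def read_channel_stack(
    source: str | Path | Sequence[str | Path],
    channel_map: Mapping[str, int] | None = None,
) -> ChannelStack:
    """Load a three-channel stack from one multi-channel file or three files.

    ``channel_map`` maps roles (``nuclei``/``viable``/``dead``) to page,
    color, or file indices.  Defaults: page order blue, green, red for
    multi-page TIFFs; B/G/R color planes for RGB images; file order
    nuclei, viable, dead for triples.
    """
    if isinstance(source, (str, Path)):
        arr = _read_any(Path(source))
        if arr.ndim == 2:
            raise ValueError(
                f"{source}: single grayscale image; pass three files or a multi-channel image"
            )
        if arr.ndim != 3:
            raise ValueError(f"{source}: unsupported image dimensionality {arr.shape}")
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            cmap = dict(channel_map) if channel_map else DEFAULT_RGB_MAP
            _check_map(cmap)
            channels = {role: arr[..., idx] for role, idx in cmap.items()}
        else:
            cmap = dict(channel_map) if channel_map else DEFAULT_PAGE_MAP
            _check_map(cmap)
            channels = {role: arr[idx] for role, idx in cmap.items()}
    else:
        paths = [Path(p) for p in source]
        if len(paths) != 3:
            raise ValueError(f"expected exactly 3 channel files, got {len(paths)}")
        cmap = dict(channel_map) if channel_map else {"nuclei": 0, "viable": 1, "dead": 2}
        _check_map(cmap)
        images = [_read_any(p) for p in paths]
        for p, img in zip(paths, images):
            if img.ndim != 2:
                raise ValueError(f"{p}: expected a single-channel grayscale image")
        shapes = {img.shape for img in images}
        if len(shapes) > 1:
            detail = ", ".join(f"{p.name}: {img.shape}" for p, img in zip(paths, images))
            raise ValueError(f"channel images have mismatched shapes ({detail})")
        channels = {role: images[idx] for role, idx in cmap.items()}
    return ChannelStack(blue=channels["nuclei"], green=channels["viable"], red=channels["dead"])


def _read_any(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def write_channel_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write the stack as a 3-page grayscale TIFF (blue, green, red)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([stack.blue, stack.green, stack.red]))
    return path


_COORD_NOTE = "coordinates are (row, col), 0-based, origin at the top-left pixel"


def write_table(df: pd.DataFrame, path: str | Path, note: str = "") -> Path:
    """Write a CSV with a coordinate-convention comment line and schema column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if "schema_version" not in out.columns:
        out.insert(0, "schema_version", SCHEMA_VERSION)
    header = f"# {_COORD_NOTE}" + (f"; {note}" if note else "") + "\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        out.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines ignored)."""
    return pd.read_csv(path, comment="#")
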
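"""Volume containers and file I/O.

Axis convention
---------------
Arrays are indexed ``data[i, j, k]`` with ``(i, j, k) <-> (x, y, z)``,
0-based, and ``z`` is the longitudinal (bone-shaft) axis.  On disk a TIFF
stack stores one transverse (x, y) slice per page in ascending ``z``; a
page follows the usual raster layout (rows = y, columns = x), so reading
transposes each page back into ``(x, y)`` order.  No function reorders
axes silently.

Voxel spacing is carried in micrometres per voxel, one value per axis.
Spacing travels in a JSON sidecar written next to the image file
(``<stem>.meta.json``); a TIFF without a sidecar needs an explicit
``spacing_override``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GrayVolume",
    "LabelVolume",
    "BACKGROUND",
    "BONE",
    "CANAL",
    "read_gray_volume",
    "write_gray_volume",
    "read_label_volume",
    "write_label_volume",
    "write_report",
]

#: Label codes. Fixed by contract; never inferred from intensity.
BACKGROUND = 0
BONE = 1
CANAL = 2
_VALID_CODES = (BACKGROUND, BONE, CANAL)


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values in um, got {spacing!r}")
    return spacing


@dataclass
class GrayVolume:
    """3D scalar attenuation field with per-axis voxel spacing in um."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("GrayVolume needs a non-empty 3D array")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3D integer phase field: 0 background/matrix, 1 bone, 2 canal."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("LabelVolume needs a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        bad = np.setdiff1d(np.unique(self.labels), _VALID_CODES)
        if bad.size:
            raise ValueError(f"labels contain invalid codes {bad.tolist()}; allowed {_VALID_CODES}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.is_dir() else path.parent / (path.stem + ".meta.json")


def _write_sidecar(path: Path, vol: GrayVolume | LabelVolume) -> None:
    arr = vol.data if isinstance(vol, GrayVolume) else vol.labels
    meta = {
        "shape_xyz": list(arr.shape),
        "dtype": str(arr.dtype),
        "spacing_um": list(vol.spacing),
        "origin_um": list(vol.origin),
        "axis_order": "xyz, z longitudinal, pages are z slices",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict | None:
    sp = _sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return None


# ---------------------------------------------------------------------------
# gray volumes


def _to_pages(data: np.ndarray) -> np.ndarray:
    # (x, y, z) -> (z, y, x): one transverse raster page per z slice
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def _from_pages(pages: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(pages, (2, 1, 0)))


def write_gray_volume(vol: GrayVolume, path: str | Path) -> None:
    """Write a multi-page TIFF plus a JSON spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _to_pages(vol.data))
    _write_sidecar(path, vol)


_SLICE_RE = re.compile(r"(\d+)(?=\.[^.]+$)")


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
        key=lambda p: int(_SLICE_RE.search(p.name).group(1)) if _SLICE_RE.search(p.name) else -1,
    )
    if not files:
        raise FileNotFoundError(f"no TIFF slices in {path}")
    pages = []
    shape0 = None
    for f in files:
        page = tifffile.imread(f)
        if page.ndim != 2:
            raise ValueError(f"slice {f.name} is not a single 2D image")
        if shape0 is None:
            shape0 = page.shape
        elif page.shape != shape0:
            raise ValueError(
                f"slice {f.name} has shape {page.shape}, expected {shape0} from the first slice"
            )
        pages.append(page)
    return np.stack(pages)


def read_gray_volume(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
) -> GrayVolume:
    """Read a multi-page TIFF, a directory of numbered TIFF slices, or a
    raw binary file with sidecar metadata.

    Slice order is ascending z.  Spacing comes from the sidecar unless
    ``spacing_override`` is given; with neither, this is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)

    if path.is_dir():
        pages = _read_slice_dir(path)
        data = _from_pages(pages)
    elif path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        data = _from_pages(pages)
    elif path.suffix.lower() == ".raw":
        if meta is None:
            raise ValueError(f"raw volume {path} needs a {_sidecar_path(path).name} sidecar")
        shape = tuple(meta["shape_xyz"])
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(shape)
    else:
        raise ValueError(f"unrecognised volume format: {path}")

    if spacing_override is not None:
        spacing = _check_spacing(spacing_override)
    elif meta is not None and "spacing_um" in meta:
        spacing = _check_spacing(meta["spacing_um"])
    else:
        raise ValueError(
            f"voxel spacing for {path} is unknown: no sidecar metadata and no spacing_override"
        )
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0))) if meta else (0.0, 0.0, 0.0)
    return GrayVolume(data=data, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# label volumes


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write labels as an 8-bit multi-page TIFF (lossless) with sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _to_pages(vol.labels.astype(np.uint8)))
    _write_sidecar(path, vol)


def read_label_volume(path: str | Path, spacing_override: Sequence[float] | None = None) -> LabelVolume:
    gv = read_gray_volume(path, spacing_override=spacing_override)
    return LabelVolume(labels=gv.data.astype(np.int64), spacing=gv.spacing, origin=gv.origin)


# ---------------------------------------------------------------------------
# reports


def write_report(results: dict, path: str | Path) -> None:
    """Serialize a results mapping as JSON plus a flat CSV.

    ``results`` maps a row name (e.g. a canal-phase scenario) to a mapping
    of quantity name -> value; quantity names should carry units, e.g.
    ``"E_z [GPa]"``.  ``path`` is the output stem: ``<stem>.json`` and
    ``<stem>.csv`` are written.
    """
    import pandas as pd

    if not results:
        raise ValueError("nothing to report: results are empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".json").write_text(json.dumps(results, indent=1))
    df = pd.DataFrame.from_dict(results, orient="index")
    df.index.name = "case"
    df.to_csv(path.with_suffix(".csv"))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).with_suffix(".json").read_text())
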
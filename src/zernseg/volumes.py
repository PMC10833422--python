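"""Volume containers and TIFF/JSON I/O.

Axis convention throughout the package: ``(z, y, x)`` with ``z`` the slice
(tomographic reconstruction plane) index.  Gray volumes are float32 in
``[0, 1]``; label volumes are uint8 class codes into an ordered class set.
The canonical class codes are ``0=background, 1=bone, 2=shade_off, 3=lcn``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import ContractError, DomainError, FormatError

#: Canonical ordered class set; codes are positions in this tuple.
CLASSES: tuple[str, ...] = ("background", "bone", "shade_off", "lcn")

BACKGROUND, BONE, SHADE_OFF, LCN = 0, 1, 2, 3


@dataclass
class GrayVolume:
    """A 3D scalar field with isotropic voxel size in nanometres."""

    data: np.ndarray
    voxel_size_nm: float = 94.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ContractError(f"GrayVolume.data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("GrayVolume.data contains non-finite values")
        if self.voxel_size_nm <= 0:
            raise ContractError("GrayVolume.voxel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """A 3D categorical field over an ordered subset of :data:`CLASSES`."""

    data: np.ndarray
    class_set: tuple[str, ...] = CLASSES
    voxel_size_nm: float = 94.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        self.class_set = tuple(self.class_set)
        if self.data.ndim != 3:
            raise ContractError(f"LabelVolume.data must be 3D, got ndim={self.data.ndim}")
        if not set(self.class_set) <= set(CLASSES):
            raise ContractError(f"class_set must be a subset of {CLASSES}")
        if self.data.size and int(self.data.max()) >= len(self.class_set):
            raise ContractError(
                f"label code {int(self.data.max())} out of range for "
                f"{len(self.class_set)} classes"
            )
        if self.voxel_size_nm <= 0:
            raise ContractError("LabelVolume.voxel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.data.ravel(), minlength=len(self.class_set))
        return {name: int(counts[i]) for i, name in enumerate(self.class_set)}


@dataclass
class GroundTruthSet:
    """Labeled 2D slices used for training, with their z-indices and stage."""

    slice_indices: tuple[int, ...]
    gray: list[np.ndarray] = field(default_factory=list)
    labels: list[np.ndarray] = field(default_factory=list)
    stage: int = 1

    def __post_init__(self) -> None:
        self.slice_indices = tuple(int(i) for i in self.slice_indices)
        if len(set(self.slice_indices)) != len(self.slice_indices):
            raise ContractError("GroundTruthSet slice_indices must be unique")
        if len(self.gray) != len(self.labels) or len(self.gray) != len(self.slice_indices):
            raise ContractError("GroundTruthSet gray/label/index counts differ")

    def __len__(self) -> int:
        return len(self.slice_indices)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: GrayVolume, path: str | Path, meta: dict | None = None) -> Path:
    """Write a gray volume as a multi-page float32 TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    sidecar = {"kind": "gray", "voxel_size_nm": vol.voxel_size_nm, "provenance": vol.provenance}
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def write_labels(labels: LabelVolume, path: str | Path, meta: dict | None = None) -> Path:
    """Write a label volume as a multi-page uint8 TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, labels.data.astype(np.uint8), photometric="minisblack")
    sidecar = {
        "kind": "labels",
        "voxel_size_nm": labels.voxel_size_nm,
        "class_set": list(labels.class_set),
    }
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_stack(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # ragged pages, truncated/empty file, not a TIFF
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D/3D TIFF stack, got ndim={data.ndim}")
    return data


def read_volume(path: str | Path, voxel_size_nm: float | None = None) -> GrayVolume:
    """Read a multi-page TIFF as a :class:`GrayVolume`.

    The voxel size is taken from the JSON sidecar when present, else from
    the ``voxel_size_nm`` argument.
    """
    path = Path(path)
    data = _read_stack(path)
    if data.dtype.kind not in "fiu":
        raise FormatError(f"unsupported TIFF dtype {data.dtype} for a gray volume")
    meta = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    vs = meta.get("voxel_size_nm", voxel_size_nm)
    if vs is None:
        raise FormatError(f"voxel size unknown for {path}: no sidecar and no flag given")
    return GrayVolume(data.astype(np.float32), float(vs), meta.get("provenance", str(path)))


def read_labels(path: str | Path, voxel_size_nm: float | None = None) -> LabelVolume:
    """Read a multi-page uint8 TIFF as a :class:`LabelVolume`."""
    path = Path(path)
    data = _read_stack(path)
    if data.dtype != np.uint8:
        raise FormatError(f"label volumes must be uint8 TIFFs, got {data.dtype}")
    meta = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    vs = meta.get("voxel_size_nm", voxel_size_nm)
    if vs is None:
        raise FormatError(f"voxel size unknown for {path}: no sidecar and no flag given")
    class_set = tuple(meta.get("class_set", CLASSES))
    return LabelVolume(data, class_set, float(vs))


# ---------------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------------

def ground_truth_fraction(n_labeled: int, n_total: int) -> int:
    """Percentage of the stack that is labeled, rounded half-to-even.

    For a 420-slice stack: 20 slices -> 5 %, 50 slices -> 12 %.
    """
    if n_total <= 0:
        raise DomainError("n_total must be > 0")
    if not 0 <= n_labeled <= n_total:
        raise DomainError("require 0 <= n_labeled <= n_total")
    return int(round(100.0 * n_labeled / n_total))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def extract_slices(
    volume: GrayVolume, labels: LabelVolume, indices: Sequence[int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return ``(gray, label)`` 2D slice pairs at the given z-indices, in order."""
    if volume.shape != labels.shape:
        raise ContractError("volume and labels differ in shape")
    indices = [int(i) for i in indices]
    if len(set(indices)) != len(indices):
        raise ContractError("slice indices must be unique")
    nz = volume.shape[0]
    for i in indices:
        if not 0 <= i < nz:
            raise ContractError(f"slice index {i} out of range [0, {nz})")
    return [(volume.data[i], labels.data[i]) for i in indices]
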
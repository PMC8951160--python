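"""Discovery, ordering and loading of tomographic slice-image stacks.

A scan is stored on disk as a directory of numbered 2D greyscale images
(TIFF, PNG, BMP, JPEG).  This module orders them with a natural
(alphanumeric) sort, reads them into a :class:`SliceStack` and attaches the
physical voxel spacing supplied by the operator.  Spacing is never inferred
silently from image headers.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path, PurePath
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelSpacing",
    "SliceImage",
    "SliceStack",
    "natural_sort_filenames",
    "read_stack",
    "write_stack",
    "normalize_grey",
    "normalize_stack",
]


@dataclasses.dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel in micrometres.

    ``dx`` is the in-plane column step, ``dy`` the in-plane row step and
    ``dz`` the slice thickness (distance between consecutive slices).
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"spacing component {name} must be finite and > 0, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in cubic micrometres."""
        return self.dx * self.dy * self.dz


@dataclasses.dataclass
class SliceImage:
    """One greyscale slice: a pixel matrix, its bit depth and 1-based index."""

    pixels: np.ndarray
    bit_depth: int
    index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("slice pixels must form a non-empty 2D matrix")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}; expected 8 or 16")
        if self.index < 1:
            raise ValueError("slice index is 1-based and must be >= 1")
        vmax = (1 << self.bit_depth) - 1
        if self.pixels.min() < 0 or self.pixels.max() > vmax:
            raise ValueError(f"pixel values outside [0, {vmax}] for {self.bit_depth}-bit slice")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass
class SliceStack:
    """An ordered sequence of equally shaped slices plus physical spacing."""

    slices: list[SliceImage]
    spacing: VoxelSpacing
    name: str = ""

    def __post_init__(self) -> None:
        if not self.slices:
            return
        shape = self.slices[0].shape
        depth = self.slices[0].bit_depth
        for k, sl in enumerate(self.slices, start=1):
            if sl.shape != shape:
                raise ValueError("inconsistent slice geometry")
            if sl.bit_depth != depth:
                raise ValueError("inconsistent slice bit depth")
            if sl.index != k:
                raise ValueError("slice indices must be consecutive starting at 1")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def bit_depth(self) -> int:
        return self.slices[0].bit_depth

    def as_array(self) -> np.ndarray:
        """Stack the slice matrices into a (n_slices, rows, cols) array."""
        return np.stack([s.pixels for s in self.slices], axis=0)


_RUN_RE = re.compile(r"\d+|\D+")


def _alnum_key(text: str) -> tuple:
    # Digit runs compare numerically and sort before text runs; the raw run
    # string breaks ties between e.g. "01" and "1".
    return tuple(
        (0, int(run), run) if run.isdigit() else (1, run)
        for run in _RUN_RE.findall(text)
    )


def _path_key(name: str) -> tuple:
    parts = PurePath(name.replace("\\", "/")).parts
    key = [_alnum_key(p) for p in parts[:-1]]
    stem, dot, ext = parts[-1].rpartition(".")
    if not stem:  # no extension separator, or leading dot
        stem, ext = parts[-1], ""
    key.append((_alnum_key(stem), _alnum_key(ext)))
    return tuple(key)


def natural_sort_filenames(names: Sequence[str]) -> list[str]:
    """Order filenames alphanumerically, comparing embedded integers as numbers.

    The extension is compared separately from the stem and path components
    are compared per directory level, so shorter names sort before longer
    ones sharing a prefix (``s2.tif`` before ``s10.tif``).
    """
    if not names:
        raise ValueError("no slice files")
    return sorted(names, key=_path_key)


def _read_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"could not decode slice image {path.name}: {exc}") from exc
    return np.asarray(arr)


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported pixel type {arr.dtype} in {path.name}; expected uint8 or uint16")


def read_stack(
    directory: str | Path,
    pattern: str,
    spacing: VoxelSpacing,
    name: str | None = None,
) -> SliceStack:
    """Read every image matching ``pattern`` in natural-sort order.

    Slice indices are assigned from the sorted position (1-based), never
    from numbers parsed out of the filename, so gaps in the numbering are
    harmless.  Multi-channel (RGB) images are rejected.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"not a directory: {directory}")
    matches = [p.name for p in directory.glob(pattern) if p.is_file()]
    if not matches:
        raise ValueError("no slice files")
    ordered = natural_sort_filenames(matches)

    slices: list[SliceImage] = []
    for k, fname in enumerate(ordered, start=1):
        path = directory / fname
        arr = _read_image(path)
        if arr.ndim != 2:
            raise ValueError(f"multi-channel image not supported: {path.name}")
        depth = _bit_depth_of(arr, path)
        slices.append(SliceImage(pixels=arr, bit_depth=depth, index=k))

    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError("inconsistent slice geometry")
    return SliceStack(slices=slices, spacing=spacing, name=name or directory.name)


def write_stack(stack: SliceStack, directory: str | Path, prefix: str = "slice_") -> list[Path]:
    """Write each slice as a numbered TIFF (``slice_0001.tif`` ...)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sl in stack.slices:
        path = directory / f"{prefix}{sl.index:04d}.tif"
        dtype = np.uint8 if sl.bit_depth == 8 else np.uint16
        tifffile.imwrite(path, sl.pixels.astype(dtype))
        paths.append(path)
    return paths


def normalize_grey(slice_: SliceImage) -> SliceImage:
    """Return the slice on an 8-bit grey scale.

    8-bit input is returned unchanged.  16-bit input is mapped by the fixed
    ratio ``v -> v // 257`` (0 -> 0, 65535 -> 255); a per-stack min-max
    stretch is deliberately avoided so a grey window always means the same
    physical attenuation in every slice.
    """
    if slice_.bit_depth == 8:
        return slice_
    if slice_.bit_depth == 16:
        mapped = (slice_.pixels.astype(np.uint32) // 257).astype(np.uint8)
        return SliceImage(pixels=mapped, bit_depth=8, index=slice_.index)
    raise ValueError(f"unsupported bit depth {slice_.bit_depth}")


def normalize_stack(stack: SliceStack) -> SliceStack:
    """Apply :func:`normalize_grey` to every slice of a stack."""
    if stack.bit_depth == 8:
        return stack
    return SliceStack(
        slices=[normalize_grey(s) for s in stack.slices],
        spacing=stack.spacing,
        name=stack.name,
    )
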
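"""Image I/O and fixed-grid patch tiling.

Images are 2-D pixel grids with one or more named channels (e.g. the RGB
planes of an H&E brightfield scan, or CARS/TPEF/SHG channels of a multimodal
composite). All downstream analysis assumes that images being compared are
already co-registered; this module only validates that paired images share
dimensions and refuses mismatches — registration itself is a precondition,
not a feature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image as PILImage

__all__ = [
    "MultiChannelImage",
    "PatchSet",
    "read_image",
    "write_image",
    "select_channels",
    "split_into_patches",
    "stack_channels",
]

_MAX_CHANNELS = 8


class ImageValidationError(ValueError):
    """Raised when an image or patch request violates an invariant."""


@dataclass(frozen=True)
class MultiChannelImage:
    """A 2-D image with one or more named channels.

    Parameters
    ----------
    pixels : ndarray, shape (height, width, n_channels)
        Non-negative, finite intensities. Integer or float dtype.
    channel_names : tuple of str
        Unique, ordered channel labels (e.g. ``("CARS_2930", "TPEF", "SHG")``).
    modality_tag : str
        Free-text modality label, e.g. ``"HE"`` or ``"MM"``.
    bit_depth : int
        8 or 16; the nominal intensity range is ``[0, 2**bit_depth - 1]``.
    source_id : str
        Identifier of the originating slide or image pair.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    modality_tag: str = ""
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ImageValidationError(
                f"pixels must be (height, width, channels); got shape {px.shape}"
            )
        object.__setattr__(self, "pixels", px)
        names = tuple(str(n) for n in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(names) != px.shape[2]:
            raise ImageValidationError(
                f"{len(names)} channel names for {px.shape[2]} channels"
            )
        if len(set(names)) != len(names):
            raise ImageValidationError(f"channel names must be unique: {names}")
        if self.bit_depth not in (8, 16):
            raise ImageValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.all(np.isfinite(px)):
            raise ImageValidationError("pixel intensities must be finite")
        if px.size and px.min() < 0:
            raise ImageValidationError("pixel intensities must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 2-D array."""
        if name not in self.channel_names:
            raise ImageValidationError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            )
        return self.pixels[:, :, self.channel_names.index(name)]

    def select_channels(self, names: Sequence[str]) -> "MultiChannelImage":
        return select_channels(self, names)


@dataclass(frozen=True)
class PatchSet:
    """Non-overlapping tiles of one image on a fixed grid, row-major order."""

    patches: tuple[MultiChannelImage, ...]
    grid_shape: tuple[int, int]
    patch_ids: tuple[tuple[str, int, int], ...]
    crop_offset: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if len(self.patches) != rows * cols:
            raise ImageValidationError(
                f"{len(self.patches)} patches for a {rows}x{cols} grid"
            )
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise ImageValidationError("patch_ids must be unique")
        shapes = {p.pixels.shape for p in self.patches}
        if len(shapes) > 1:
            raise ImageValidationError(f"patches differ in shape: {shapes}")

    def __len__(self) -> int:
        return len(self.patches)

    def reassemble(self) -> np.ndarray:
        """Stitch the tiles back into the cropped region (test oracle)."""
        rows, cols = self.grid_shape
        band = [
            np.concatenate(
                [self.patches[r * cols + c].pixels for c in range(cols)], axis=1
            )
            for r in range(rows)
        ]
        return np.concatenate(band, axis=0)


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ImageValidationError(
        f"unsupported pixel dtype {arr.dtype}; expected 8- or 16-bit unsigned integers"
    )


def _channels_last(arr: np.ndarray) -> np.ndarray:
    """Normalise tifffile/PIL axis conventions to (H, W, C)."""
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim == 3:
        if arr.shape[2] <= _MAX_CHANNELS:
            return arr
        if arr.shape[0] <= _MAX_CHANNELS:  # multi-page TIFF: (pages, H, W)
            return np.moveaxis(arr, 0, 2)
    raise ImageValidationError(
        f"cannot interpret image of shape {arr.shape} as <= {_MAX_CHANNELS} channels"
    )


def read_image(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    modality_tag: str = "",
    source_id: str | None = None,
) -> MultiChannelImage:
    """Read a TIFF or PNG image into a :class:`MultiChannelImage`.

    Grayscale files yield one channel; multi-sample or multi-page files yield
    one channel per plane. Bit depth is inferred from the stored dtype.
    ``channel_names`` defaults to ``CH0, CH1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = np.asarray(PILImage.open(path))
        else:
            raise ImageValidationError(f"unsupported image format {suffix!r} for {path}")
    except ImageValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = _channels_last(np.asarray(arr))
    n_ch = arr.shape[2]
    if channel_names is None:
        channel_names = tuple(f"CH{i}" for i in range(n_ch))
    elif len(channel_names) != n_ch:
        raise ImageValidationError(
            f"{len(channel_names)} channel names given for a {n_ch}-channel file {path}"
        )
    return MultiChannelImage(
        pixels=arr,
        channel_names=tuple(channel_names),
        modality_tag=modality_tag,
        bit_depth=_infer_bit_depth(arr),
        source_id=source_id if source_id is not None else path.stem,
    )


def write_image(img: MultiChannelImage, path: str | Path) -> Path:
    """Write an image to TIFF or PNG, lossless at its stored bit depth."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = img.pixels.astype(dtype)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        if img.bit_depth == 16 and arr.ndim == 3:
            raise ImageValidationError(
                "16-bit multi-channel PNG is not supported; use TIFF"
            )
        mode = "I;16" if img.bit_depth == 16 else None
        PILImage.fromarray(arr, mode=mode).save(path)
    else:
        raise ImageValidationError(f"unsupported image format {suffix!r} for {path}")
    return path


def select_channels(img: MultiChannelImage, names: Sequence[str]) -> MultiChannelImage:
    """Return a new image containing exactly ``names``, in that order."""
    unknown = [n for n in names if n not in img.channel_names]
    if unknown:
        raise ImageValidationError(
            f"unknown channel(s) {unknown}; available: {list(img.channel_names)}"
        )
    idx = [img.channel_names.index(n) for n in names]
    return dataclasses.replace(
        img, pixels=img.pixels[:, :, idx], channel_names=tuple(names)
    )


def split_into_patches(
    img: MultiChannelImage, grid_rows: int = 10, grid_cols: int = 10
) -> PatchSet:
    """Tile an image into a ``grid_rows x grid_cols`` grid of equal patches.

    Patch size is ``floor(H/rows) x floor(W/cols)``; any remainder at the
    right/bottom edge is cropped (no resampling) and recorded in
    ``crop_offset``. Patches are ordered row-major from the top-left.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ImageValidationError("grid dimensions must be >= 1")
    if img.height < grid_rows or img.width < grid_cols:
        raise ImageValidationError(
            f"image {img.height}x{img.width} smaller than {grid_rows}x{grid_cols} grid"
        )
    ph, pw = img.height // grid_rows, img.width // grid_cols
    crop = (img.height - ph * grid_rows, img.width - pw * grid_cols)
    patches, ids = [], []
    for r in range(grid_rows):
        for c in range(grid_cols):
            tile = img.pixels[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw, :]
            patches.append(dataclasses.replace(img, pixels=tile))
            ids.append((img.source_id, r, c))
    return PatchSet(
        patches=tuple(patches),
        grid_shape=(grid_rows, grid_cols),
        patch_ids=tuple(ids),
        crop_offset=crop,
    )


def stack_channels(
    images: Sequence[MultiChannelImage], modality_tag: str = ""
) -> MultiChannelImage:
    """Stack co-registered images into one multi-channel composite.

    All inputs must share height and width (registration is assumed upstream);
    a dimension mismatch is refused, never resampled.
    """
    if not images:
        raise ImageValidationError("no images to stack")
    dims = {(im.height, im.width) for im in images}
    if len(dims) > 1:
        raise ImageValidationError(
            f"cannot stack images with mismatched dimensions {sorted(dims)}; "
            "inputs must be co-registered and equal-sized"
        )
    names: list[str] = []
    for im in images:
        names.extend(im.channel_names)
    if len(set(names)) != len(names):
        raise ImageValidationError(f"duplicate channel names after stacking: {names}")
    return MultiChannelImage(
        pixels=np.concatenate([im.pixels for im in images], axis=2),
        channel_names=tuple(names),
        modality_tag=modality_tag or "+".join(im.modality_tag for im in images),
        bit_depth=max(im.bit_depth for im in images),
        source_id=images[0].source_id,
    )
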
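"""Patch-image IO, colour-range foreground segmentation and summarization.

The proprietary colour-range selection of the original workflow is emulated
by nearest-seed Euclidean thresholding: a pixel is foreground iff its
minimum distance in RGB space to any seed colour is at most the threshold.
An optional HSB-space mode (with circular hue distance) is available.
Coordinates are row-major, origin top-left, 0-based; masks serialize as
0/255 PNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorspace import ChannelMeans
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "PatchImage",
    "ForegroundMask",
    "load_patch_images",
    "segment_foreground",
    "summarize_patch",
    "save_mask",
    "load_mask",
]

logger = logging.getLogger(__name__)

#: Default colour-range fuzziness, in RGB intensity units (free parameter;
#: not a claim about the original tool's setting).
DEFAULT_THRESHOLD = 60.0

#: Minimum foreground coverage below which a warning is emitted.
DEFAULT_COVERAGE_FLOOR = 0.01


@dataclass
class PatchImage:
    """One 8-bit RGB photograph of a seedling patch."""

    pixels: np.ndarray  # H x W x 3, uint8
    patch_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"patch {self.patch_id}: expected H x W x 3 pixel grid, got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"patch {self.patch_id}: expected uint8 pixels, got {px.dtype}")
        self.pixels = px


@dataclass
class ForegroundMask:
    """Boolean foreground mask congruent with its PatchImage."""

    mask: np.ndarray  # H x W, bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def _read_rgb(path: Path) -> np.ndarray:
    px = iio.imread(path)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError(f"not an 8-bit RGB image (shape {px.shape})")
    if px.dtype != np.uint8:
        raise ValueError(f"not 8-bit (dtype {px.dtype})")
    return px


def load_patch_images(
    source: str | Path, plate_map: pd.DataFrame | None = None
) -> tuple[list[PatchImage], list[dict]]:
    """Load patch images from a manifest CSV or a directory of PNG/TIFF files.

    A manifest must have columns ``patchId`` and ``path`` (paths resolved
    relative to the manifest). For a directory, the file stem becomes the
    patchId. Images are paired with ``plate_map`` rows by patchId when a
    plate map is given. Unreadable or non-RGB files are reported as error
    records, not raised.

    Returns
    -------
    (images, errors)
        ``errors`` is a list of ``{"path": ..., "reason": ...}`` dicts.

    Raises
    ------
    ConfigurationError
        If the manifest/directory yields no candidate files at all.
    """
    source = Path(source)
    if source.is_dir():
        entries = [
            (p.stem, p) for p in sorted(source.iterdir()) if p.suffix.lower() in {".png", ".tif", ".tiff"}
        ]
    elif source.is_file():
        manifest = pd.read_csv(source, comment="#")
        missing = {"patchId", "path"} - set(manifest.columns)
        if missing:
            raise ConfigurationError(f"manifest {source} lacks columns {sorted(missing)}")
        entries = [
            (str(row.patchId), source.parent / str(row.path)) for row in manifest.itertuples()
        ]
    else:
        raise ConfigurationError(f"image source {source} does not exist")
    if not entries:
        raise ConfigurationError(f"no patch images found in {source}")

    meta_by_id: dict[str, dict] = {}
    if plate_map is not None and "patchId" in plate_map.columns:
        meta_by_id = {
            str(r["patchId"]): {k: v for k, v in r.items() if k != "patchId"}
            for r in plate_map.to_dict("records")
        }

    images: list[PatchImage] = []
    errors: list[dict] = []
    for patch_id, path in entries:
        try:
            px = _read_rgb(path)
        except Exception as exc:  # unreadable / wrong format: record, keep going
            logger.warning("skipping %s: %s", path, exc)
            errors.append({"path": str(path), "reason": str(exc)})
            continue
        images.append(PatchImage(px, patch_id, metadata=meta_by_id.get(patch_id, {})))
    return images, errors


def _hsb_coords(rgb: np.ndarray) -> np.ndarray:
    """Map N x 3 RGB (0-255) to (hue_x, hue_y, brightness) so Euclidean
    distance respects hue circularity."""
    p = rgb.astype(np.float64) / 255.0
    mx = p.max(axis=-1)
    mn = p.min(axis=-1)
    chroma = mx - mn
    safe = np.where(chroma > 0, chroma, 1.0)
    r, g, b = p[..., 0], p[..., 1], p[..., 2]
    h = np.where(
        mx == r,
        (g - b) / safe,
        np.where(mx == g, 2.0 + (b - r) / safe, 4.0 + (r - g) / safe),
    )
    ang = np.where(chroma > 0, h * np.pi / 3.0, 0.0)
    sat = np.where(mx > 0, chroma / np.where(mx > 0, mx, 1.0), 0.0)
    return np.stack([sat * np.cos(ang), sat * np.sin(ang), mx], axis=-1) * 255.0


def segment_foreground(
    img: PatchImage,
    seeds: np.ndarray | list,
    threshold: float = DEFAULT_THRESHOLD,
    space: str = "rgb",
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> ForegroundMask:
    """Mark pixels within ``threshold`` of the nearest seed colour.

    ``seeds`` is an N x 3 array of reference RGB colours (0-255); the
    default palette for screening runs should include senescent
    (yellow/brown) tones so dead seedlings stay in the foreground.
    ``space='hsb'`` measures distance in a hue-circular HSB embedding.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.size == 0 or seeds.shape[1] != 3:
        raise ConfigurationError("at least one RGB seed colour is required")
    if threshold <= 0:
        raise ConfigurationError(f"threshold must be > 0, got {threshold}")
    if space not in {"rgb", "hsb"}:
        raise ConfigurationError(f"unknown colour space {space!r}")

    px = img.pixels.astype(np.float64)
    if space == "hsb":
        px = _hsb_coords(px)
        seeds = _hsb_coords(seeds)
    # min distance over seeds, vectorized: H x W x N
    d2 = ((px[:, :, None, :] - seeds[None, None, :, :]) ** 2).sum(axis=-1)
    mask = ForegroundMask(d2.min(axis=-1) <= threshold**2)
    if mask.coverage < coverage_floor:
        logger.warning(
            "patch %s: foreground coverage %.4f below floor %.4f",
            img.patch_id,
            mask.coverage,
            coverage_floor,
        )
    return mask


def summarize_patch(img: PatchImage, mask: ForegroundMask) -> ChannelMeans:
    """Arithmetic per-channel mean over masked pixels."""
    if mask.mask.shape != img.pixels.shape[:2]:
        raise ValueError(
            f"patch {img.patch_id}: mask shape {mask.mask.shape} != image {img.pixels.shape[:2]}"
        )
    if mask.n_foreground == 0:
        raise DegenerateInputError(f"patch {img.patch_id}: empty foreground mask")
    sel = img.pixels[mask.mask].astype(np.float64)
    means = sel.mean(axis=0)
    return ChannelMeans(float(means[0]), float(means[1]), float(means[2]), n_pixels=len(sel))


def save_mask(mask: ForegroundMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> ForegroundMask:
    return ForegroundMask(iio.imread(Path(path)) > 127)
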
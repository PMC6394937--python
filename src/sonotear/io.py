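"""Reading images, lesion ROIs and case manifests.

Shoulder ultrasound frames are 8-bit grayscale; lesions arrive either as a
polygon of delineated vertices or as a binary mask image.  Everything
downstream consumes a :class:`CaseRecord` — one image, one boolean lesion
mask and a class label (``tendinopathy`` or ``tear``).

Coordinates are 0-based ``(row, col)`` in pixel-index units.  Pixel
``(r, c)`` occupies the square whose center is ``(r + 0.5, c + 0.5)``;
polygon vertices are given in the same pixel-index units and are placed at
pixel centers, so a rectangle with corners ``(0, 0)`` and ``(3, 3)`` selects
the full 4x4 block of pixels it visually spans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

LABELS = ("tendinopathy", "tear")

MANIFEST_COLUMNS = ("case_id", "patient_id", "image_file", "roi_file", "label")


class ImageFormatError(ValueError):
    """Raised for unreadable, non-8-bit or genuinely colored inputs."""


@dataclass(frozen=True)
class CaseRecord:
    """One labelled case: grayscale image, lesion mask and ground truth."""

    case_id: str
    patient_id: str
    image: np.ndarray  # uint8, shape (H, W)
    mask: np.ndarray  # bool, shape (H, W)
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        if not self.mask.any():
            raise ValueError("lesion mask is empty")


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit grayscale image as a uint8 array.

    Color images whose channels are identical (a common export artifact of
    ultrasound workstations) are collapsed to a single channel; genuinely
    colored or non-8-bit inputs raise :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageFormatError(f"could not read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected 8-bit pixel data, got dtype {arr.dtype}"
        )
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise ImageFormatError(f"{path}: image has non-identical color channels")
        if arr.shape[-1] == 4 and not (arr[..., 3] == 255).all():
            raise ImageFormatError(f"{path}: image has a non-trivial alpha channel")
        arr = rgb[..., 0]
    elif arr.ndim != 2:
        raise ImageFormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    return np.ascontiguousarray(arr)


def write_gray_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a uint8 grayscale array as PNG/TIFF."""
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 2:
        raise ImageFormatError("expected a 2-D uint8 array")
    iio.imwrite(Path(path), image)


def _points_in_polygon(rr: np.ndarray, cc: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Boundary-inclusive even-odd test for points (rr, cc) against a polygon.

    `verts` is an (n, 2) array of (row, col) points in the same continuous
    coordinate frame as rr/cc.  Points exactly on an edge count as inside.
    """
    inside = np.zeros(rr.shape, dtype=bool)
    on_edge = np.zeros(rr.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        r1, c1 = verts[k]
        r2, c2 = verts[(k + 1) % n]
        # even-odd crossing of the horizontal ray towards +col
        straddles = (r1 <= rr) != (r2 <= rr)
        denom = r2 - r1
        with np.errstate(divide="ignore", invalid="ignore"):
            xc = c1 + (rr - r1) * (c2 - c1) / np.where(denom == 0.0, 1.0, denom)
        inside ^= straddles & (cc < xc)
        # exact on-segment test (cross product zero, within bounding box)
        cross = (r2 - r1) * (cc - c1) - (c2 - c1) * (rr - r1)
        within = (
            (rr >= min(r1, r2)) & (rr <= max(r1, r2))
            & (cc >= min(c1, c2)) & (cc <= max(c1, c2))
        )
        on_edge |= (cross == 0.0) & within
    return inside | on_edge


def rasterize_polygon(vertices: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Rasterize a delineated ROI polygon to a boolean lesion mask.

    A pixel belongs to the mask iff its center satisfies the even-odd rule
    for the polygon (vertices in pixel-index units, placed at pixel
    centers); centers exactly on the boundary are included.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    h, w = int(dims[0]), int(dims[1])
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be positive")
    if (verts[:, 0] < 0).any() or (verts[:, 0] > h - 1).any() \
            or (verts[:, 1] < 0).any() or (verts[:, 1] > w - 1).any():
        raise ValueError("polygon vertices fall outside the image bounds")
    rr, cc = np.meshgrid(
        np.arange(h, dtype=float) + 0.5, np.arange(w, dtype=float) + 0.5, indexing="ij"
    )
    return _points_in_polygon(rr, cc, verts + 0.5)


def masked_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Intensities of the lesion pixels, in row-major order."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} dimensions differ"
        )
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return image[mask]


def read_roi(path: str | os.PathLike, dims: tuple[int, int]) -> np.ndarray:
    """Read an ROI as a boolean mask.

    ``*.csv`` files are vertex lists (``row,col`` per line, header optional)
    rasterized against `dims`; anything else is read as a mask image where
    nonzero means inside.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        verts = np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#", ndmin=2))
        return rasterize_polygon(verts, dims)
    mask = read_gray_image(path) > 0
    if mask.shape != tuple(dims):
        raise ValueError(f"mask {path} dims {mask.shape} do not match image {dims}")
    return mask


def load_manifest(csv_path: str | os.PathLike, image_dir: str | os.PathLike | None = None) -> list[CaseRecord]:
    """Assemble case records from a manifest CSV.

    The manifest has columns ``case_id,patient_id,image_file,roi_file,label``
    with file names resolved relative to `image_dir` (default: the manifest's
    own directory).
    """
    csv_path = Path(csv_path)
    base = Path(image_dir) if image_dir is not None else csv_path.parent
    table = pd.read_csv(csv_path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        if row.label not in LABELS:
            raise ValueError(
                f"case {row.case_id}: unknown label {row.label!r}; expected one of {LABELS}"
            )
        image = read_gray_image(base / row.image_file)
        mask = read_roi(base / row.roi_file, image.shape)
        records.append(
            CaseRecord(
                case_id=row.case_id,
                patient_id=row.patient_id,
                image=image,
                mask=mask,
                label=row.label,
            )
        )
    return records
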
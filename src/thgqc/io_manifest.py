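"""Image containers, TIFF reading/writing and the case manifest.

Conventions: arrays are row-major with origin top-left, 0-based indices.
Class masks use integer codes {0: background, 1: normal, 2: tumor}.
Pixel size travels with every image; it is taken from the manifest
(``pixel_size_um`` column) when present, which wins over TIFF resolution
tags because acquisition-software metadata is unreliable across devices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

MASK_BACKGROUND = 0
MASK_NORMAL = 1
MASK_TUMOR = 2

LABEL_NORMAL = "normal"
LABEL_TUMOR = "tumor"
LABEL_UNLABELED = "unlabeled"

#: diagnosis string -> image label under weak labelling
DIAGNOSIS_TO_LABEL = {"epilepsy": LABEL_NORMAL, "glioma": LABEL_TUMOR}


class UnsupportedFormatError(ValueError):
    """Raised for TIFFs that are not grayscale 8/16-bit integer images."""


class MetadataError(ValueError):
    """Raised when required metadata (e.g. pixel size) is missing."""


class ManifestError(ValueError):
    """Raised when a case manifest violates its invariants."""


@dataclass
class ImageRecord:
    """A single 2-D grayscale image with physical pixel size and weak label.

    Parameters
    ----------
    pixels : 2-D integer array, non-negative, within the declared bit depth.
    pixel_size_um : micrometres per pixel, > 0.
    bit_depth : 16 for raw acquisitions, 8 after preprocessing.
    case_id : opaque identifier of the tissue case the image came from.
    depth_index : slice position within a z-stack, if any.
    label : "normal", "tumor" or "unlabeled".
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16
    case_id: str = ""
    depth_index: Optional[int] = None
    label: str = LABEL_UNLABELED

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise UnsupportedFormatError(
                f"pixels must be integer-typed, got {self.pixels.dtype}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values outside declared {self.bit_depth}-bit range"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.label not in (LABEL_NORMAL, LABEL_TUMOR, LABEL_UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, bit_depth: Optional[int] = None,
                    pixel_size_um: Optional[float] = None) -> "ImageRecord":
        """Copy of this record with new pixel data (metadata preserved)."""
        return replace(
            self,
            pixels=pixels,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
            pixel_size_um=(self.pixel_size_um if pixel_size_um is None
                           else pixel_size_um),
        )


@dataclass
class ZStack:
    """An ordered stack of slices of one field acquired at increasing depth."""

    slices: list[ImageRecord]
    depth_step_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a ZStack needs at least one slice")
        if not self.depth_step_um > 0:
            raise ValueError("depth_step_um must be > 0")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError("all slices must share one shape")
        if len({s.case_id for s in self.slices}) != 1:
            raise ValueError("all slices must share one case_id")
        if len({s.pixel_size_um for s in self.slices}) != 1:
            raise ValueError("all slices must share one pixel size")
        idx = [s.depth_index for s in self.slices]
        if any(i is None for i in idx) or any(
            b <= a for a, b in zip(idx, idx[1:])  # type: ignore[operator]
        ):
            raise ValueError("depth_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)


@dataclass
class Mosaic:
    """A large stitched field-of-view image, optionally with a reference mask.

    ``reference_mask`` uses the class codes {0 background, 1 normal, 2 tumor}
    and must match ``pixels`` in shape.
    """

    pixels: np.ndarray
    pixel_size_um: float
    case_id: str = ""
    reference_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mosaic pixels must be a non-empty 2-D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.reference_mask is not None:
            self.reference_mask = np.asarray(self.reference_mask)
            if self.reference_mask.shape != self.pixels.shape:
                raise ValueError("reference_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


MANIFEST_REQUIRED = ("image_path", "case_id", "diagnosis", "split_role")
MANIFEST_OPTIONAL = ("label", "pixel_size_um", "depth_index")


@dataclass
class CaseManifest:
    """Rows binding image files to cases, diagnoses and train/test roles.

    Weak labelling: every image inherits its case's diagnosis as label,
    unless an explicit image-level ``label`` column is present (used for
    test sets annotated at the image level).
    """

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        dup = df["image_path"].duplicated()
        if dup.any():
            raise ManifestError(
                f"duplicate image_path rows: {sorted(df.loc[dup, 'image_path'])}"
            )
        bad = ~df["diagnosis"].isin(DIAGNOSIS_TO_LABEL)
        if bad.any():
            rows = df.loc[bad, ["image_path", "diagnosis"]]
            raise ManifestError(f"unknown diagnosis values:\n{rows}")
        bad_role = ~df["split_role"].isin(("train", "test"))
        if bad_role.any():
            raise ManifestError("split_role must be 'train' or 'test'")
        # an image path maps to exactly one case: enforced by the duplicate
        # check; a case must have exactly one diagnosis
        per_case = df.groupby("case_id")["diagnosis"].nunique()
        multi = per_case[per_case > 1]
        if len(multi):
            raise ManifestError(
                f"cases with conflicting diagnoses: {list(multi.index)}"
            )
        if "label" not in df.columns:
            df = df.copy()
            df["label"] = df["diagnosis"].map(DIAGNOSIS_TO_LABEL)
        else:
            df = df.copy()
            derived = df["diagnosis"].map(DIAGNOSIS_TO_LABEL)
            df["label"] = df["label"].where(df["label"].notna(), derived)
            bad_lab = ~df["label"].isin((LABEL_NORMAL, LABEL_TUMOR))
            if bad_lab.any():
                raise ManifestError(
                    f"unknown label values:\n{df.loc[bad_lab, ['image_path', 'label']]}"
                )
        # canonical row order so parsing is order-independent
        self.table = df.sort_values("image_path", kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def case_ids(self) -> list[str]:
        return sorted(self.table["case_id"].unique())

    def subset(self, mask) -> "CaseManifest":
        return CaseManifest(self.table[mask].reset_index(drop=True), self.root)

    def rows_for_role(self, role: str) -> pd.DataFrame:
        return self.table[self.table["split_role"] == role]

    def case_label(self, case_id: str) -> str:
        rows = self.table[self.table["case_id"] == case_id]
        if rows.empty:
            raise KeyError(case_id)
        return DIAGNOSIS_TO_LABEL[rows["diagnosis"].iloc[0]]

    def load_image(self, row: pd.Series) -> ImageRecord:
        """Load one manifest row as an ImageRecord (2-D; stacks by row only)."""
        path = Path(row["image_path"])
        if not path.is_absolute():
            path = self.root / path
        px = row.get("pixel_size_um")
        px = None if px is None or pd.isna(px) else float(px)
        rec = read_image(path, pixel_size_um=px)
        if isinstance(rec, ZStack):
            di = row.get("depth_index")
            if di is None or pd.isna(di):
                raise ManifestError(
                    f"{path} is a stack; manifest row needs depth_index"
                )
            rec = rec.slices[int(di)]
        di = row.get("depth_index")
        return replace(
            rec,
            case_id=str(row["case_id"]),
            label=row["label"],
            depth_index=None if di is None or pd.isna(di) else int(di),
        )

    def load_images(self, role: Optional[str] = None) -> list[ImageRecord]:
        df = self.table if role is None else self.rows_for_role(role)
        return [self.load_image(row) for _, row in df.iterrows()]


def _check_grayscale_int(pages: np.ndarray, path) -> None:
    if pages.ndim not in (2, 3):
        raise UnsupportedFormatError(
            f"{path}: expected single-channel grayscale TIFF, got shape "
            f"{pages.shape}"
        )
    if pages.ndim == 3 and pages.shape[-1] in (3, 4) and pages.shape[-1] < 5:
        # heuristic: trailing small axis from an RGB(A) file
        raise UnsupportedFormatError(f"{path}: RGB TIFF is not supported")
    if not np.issubdtype(pages.dtype, np.integer):
        raise UnsupportedFormatError(
            f"{path}: float TIFF is not supported (dtype {pages.dtype})"
        )


def _tiff_pixel_size(tif: tifffile.TiffFile) -> Optional[float]:
    """Pixel size in µm from TIFF resolution tags, if stored."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0 or den == 0:
            return None
        per_unit = num / den
        unit_um = {2: 25400.0, 3: 10000.0}.get(
            getattr(unit, "value", None) and int(unit.value), None
        )
        if unit_um is None:
            return None
        return unit_um / per_unit
    except Exception:
        return None


def read_image(path, pixel_size_um: Optional[float] = None,
               depth_step_um: float = 1.0):
    """Read a grayscale TIFF as an :class:`ImageRecord` or :class:`ZStack`.

    Multi-page files become a ZStack with ``depth_index`` equal to page
    order. ``pixel_size_um`` (from the manifest) wins over any resolution
    tag embedded in the file; if neither is available a
    :class:`MetadataError` naming the file is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        _check_grayscale_int(arr, path)
        tag_px = _tiff_pixel_size(tif)
    px = pixel_size_um if pixel_size_um is not None else tag_px
    if px is None:
        raise MetadataError(
            f"{path}: pixel size not in manifest nor in TIFF metadata"
        )
    bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    if arr.ndim == 2:
        return ImageRecord(arr, px, bit_depth=bit_depth)
    slices = [
        ImageRecord(arr[k], px, bit_depth=bit_depth, depth_index=k)
        for k in range(arr.shape[0])
    ]
    return ZStack(slices, depth_step_um=depth_step_um)


def read_stack_directory(directory, pixel_size_um: float,
                         depth_step_um: float = 1.0) -> ZStack:
    """Assemble a ZStack from a directory of single-page TIFFs, lexically sorted."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in
                   (".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF files in {directory}")
    slices = []
    for k, p in enumerate(paths):
        rec = read_image(p, pixel_size_um=pixel_size_um)
        if isinstance(rec, ZStack):
            raise UnsupportedFormatError(f"{p}: expected single-page TIFF")
        slices.append(replace(rec, depth_index=k))
    return ZStack(slices, depth_step_um=depth_step_um)


def write_image(path, record: ImageRecord) -> None:
    """Write an ImageRecord to a TIFF with resolution tags (µm pixel size)."""
    dtype = np.uint8 if record.bit_depth == 8 else np.uint16
    per_cm = 10000.0 / record.pixel_size_um
    tifffile.imwrite(
        str(path),
        record.pixels.astype(dtype),
        resolution=(per_cm, per_cm),
        resolutionunit="CENTIMETER",
    )


def write_stack(path, stack: ZStack) -> None:
    dtype = np.uint8 if stack.slices[0].bit_depth == 8 else np.uint16
    arr = np.stack([s.pixels for s in stack.slices]).astype(dtype)
    per_cm = 10000.0 / stack.slices[0].pixel_size_um
    tifffile.imwrite(str(path), arr, resolution=(per_cm, per_cm),
                     resolutionunit="CENTIMETER")


def read_manifest(path) -> CaseManifest:
    """Read a CSV case manifest; relative image paths resolve next to it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    return CaseManifest(df, root=path.parent)


def write_manifest(path, manifest: CaseManifest) -> None:
    manifest.table.to_csv(path, index=False)


def write_overlay(path, score_map: np.ndarray,
                  mask: Optional[np.ndarray] = None) -> tuple[Path, Optional[Path]]:
    """Write a score map (and optional class mask) as 8-bit TIFFs.

    Scores in [0, 1] are scaled to [0, 255] with round-half-up and written
    to ``path``; the class mask, if given, is written losslessly as uint8
    class codes to ``<path stem>_mask.tif``. Returns the paths written.
    """
    path = Path(path)
    score_map = np.asarray(score_map, dtype=float)
    if np.isnan(score_map).any():
        raise ValueError("score map contains NaN")
    if score_map.min() < 0 or score_map.max() > 1:
        raise ValueError("score map values must lie in [0, 1]")
    scaled = np.floor(score_map * 255.0 + 0.5).astype(np.uint8)
    tifffile.imwrite(str(path), scaled)
    mask_path: Optional[Path] = None
    if mask is not None:
        mask_path = path.with_name(path.stem + "_mask.tif")
        tifffile.imwrite(str(mask_path), np.asarray(mask, dtype=np.uint8))
    return path, mask_path


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)
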
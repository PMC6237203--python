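"""Whole-slide patch preparation: grid cropping, resizing, tissue filtering,
and spatial sequence ordering.

A slide is tiled into non-overlapping fixed-size patches on a regular grid
(partial border cells are discarded), each patch is resized with a Lanczos
kernel, patches with too little tissue are rejected, and the survivors are
arranged into the spatial order consumed by the sequence model: row by row
from the top, right-to-left within each row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

#: HSV saturation above which a pixel counts as stained tissue.
SATURATION_THRESHOLD = 0.07
#: Grayscale intensity (fraction of dtype max) below which a pixel counts
#: as tissue even when unsaturated (e.g. dark hematoxylin).
INTENSITY_THRESHOLD = 0.8


@dataclass
class Patch:
    """One grid cell of a slide.

    ``grid_row``/``grid_col`` are 0-based with row 0 at the image top;
    ``center_x``/``center_y`` are pixel coordinates in slide space
    (x = column axis, y = row axis).
    """

    image: np.ndarray
    grid_row: int
    grid_col: int
    center_x: float
    center_y: float
    tissue_fraction: float | None = None


@dataclass
class PatchSequence:
    """Ordered patch list for one slide (the LSTM input sequence)."""

    patient_id: str
    patches: list[Patch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def insufficient(self) -> bool:
        return len(self.patches) == 0


def crop_patches(slide: np.ndarray, patch_size: int = 4096,
                 stride: int = 4096) -> list[Patch]:
    """Tile ``slide`` into patches of ``patch_size`` at the given stride.

    Returns one patch per full grid cell; border remainders smaller than
    ``patch_size`` are discarded.  A slide smaller than ``patch_size`` in
    either axis yields an empty list and a logged warning (the slide is
    considered to have insufficient tissue).
    """
    h, w = slide.shape[:2]
    if h < patch_size or w < patch_size:
        msg = (f"slide {w}x{h} smaller than patch size {patch_size}; "
               "flagged insufficient")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return []
    n_rows = (h - patch_size) // stride + 1
    n_cols = (w - patch_size) // stride + 1
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * stride, c * stride
            patches.append(Patch(
                image=slide[y0:y0 + patch_size, x0:x0 + patch_size],
                grid_row=r,
                grid_col=c,
                center_x=x0 + patch_size / 2,
                center_y=y0 + patch_size / 2,
            ))
    return patches


def resize_patch(image: np.ndarray, out_edge: int = 256) -> np.ndarray:
    """Resize a square patch to ``out_edge`` px with a Lanczos (a=3) kernel."""
    h, w = image.shape[:2]
    if h != w:
        raise ValueError(f"patch must be square, got {w}x{h}")
    if h == out_edge:
        return image.copy()
    pil = Image.fromarray(image)
    out = pil.resize((out_edge, out_edge), resample=Image.LANCZOS)
    return np.asarray(out)


def tissue_fraction(image: np.ndarray,
                    saturation_threshold: float = SATURATION_THRESHOLD,
                    intensity_threshold: float = INTENSITY_THRESHOLD) -> float:
    """Fraction of pixels classified as tissue.

    A pixel is tissue if its HSV saturation exceeds ``saturation_threshold``
    or its grayscale intensity falls below ``intensity_threshold`` of the
    dtype maximum — the standard background-vs-stain heuristic for slides
    scanned on a white background.  Grayscale images use the intensity rule
    only.
    """
    if image.size == 0:
        raise ValueError("empty image")
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
    else:
        scale = 1.0
    if arr.ndim == 3 and arr.shape[2] >= 3:
        rgb = arr[..., :3].astype(float) / scale
        sat = rgb2hsv(rgb)[..., 1]
        gray = rgb.mean(axis=2)
        mask = (sat > saturation_threshold) | (gray < intensity_threshold)
    else:
        gray = arr.astype(float) / scale
        mask = gray < intensity_threshold
    return float(mask.mean())


def compute_tissue_fractions(patches: list[Patch], **kwargs) -> list[Patch]:
    """Return patches with ``tissue_fraction`` filled in."""
    return [replace(p, tissue_fraction=tissue_fraction(p.image, **kwargs))
            for p in patches]


def select_patches(patches: list[Patch],
                   min_fraction: float = 0.2) -> list[Patch]:
    """Keep patches whose tissue fraction is at least ``min_fraction``.

    The threshold is inclusive.  An empty result flags the slide as having
    insufficient tissue.
    """
    for p in patches:
        if p.tissue_fraction is None:
            raise ValueError("tissue_fraction not computed; "
                             "run compute_tissue_fractions first")
    kept = [p for p in patches if p.tissue_fraction >= min_fraction]
    if not kept and patches:
        logger.warning("all %d patches below tissue threshold %.2f; "
                       "slide flagged insufficient", len(patches), min_fraction)
    return kept


def order_patches(patches: list[Patch],
                  patient_id: str = "") -> PatchSequence:
    """Arrange patches into the scan order used by the sequence model.

    Primary key: grid row ascending (top to bottom).  Secondary key: grid
    column descending (right to left), i.e. the sequence starts at the
    top-right patch and ends at the bottom-left one.
    """
    coords = [(p.grid_row, p.grid_col) for p in patches]
    if len(set(coords)) != len(coords):
        raise ValueError("duplicate grid coordinates")
    ordered = sorted(patches, key=lambda p: (p.grid_row, -p.grid_col))
    return PatchSequence(patient_id=patient_id, patches=ordered)


def prepare_slide(slide: np.ndarray, patient_id: str = "",
                  patch_size: int = 4096, stride: int | None = None,
                  out_edge: int = 256,
                  min_fraction: float = 0.2) -> PatchSequence:
    """Full two-step cropping-selection pipeline for one slide.

    ``stride`` defaults to ``patch_size`` (non-overlapping tiling).
    """
    patches = crop_patches(slide, patch_size=patch_size,
                           stride=stride or patch_size)
    patches = compute_tissue_fractions(patches)
    kept = select_patches(patches, min_fraction=min_fraction)
    kept = [replace(p, image=resize_patch(p.image, out_edge)) for p in kept]
    return order_patches(kept, patient_id=patient_id)


def manifest_frame(sequences: list[PatchSequence],
                   rejected: dict[str, list[Patch]] | None = None):
    """Patch manifest as a DataFrame (one row per patch, in sequence order).

    ``rejected`` optionally maps patient id to the patches dropped by the
    tissue filter, which are appended with ``kept = 0`` (and no sequence
    index) so the filter's effect is auditable.
    """
    import pandas as pd

    rows = []
    for seq in sequences:
        for i, p in enumerate(seq.patches):
            rows.append({
                "patient_id": seq.patient_id,
                "seq_index": i,
                "grid_row": p.grid_row,
                "grid_col": p.grid_col,
                "center_x": p.center_x,
                "center_y": p.center_y,
                "tissue_fraction": p.tissue_fraction,
                "kept": 1,
            })
        for p in (rejected or {}).get(seq.patient_id, []):
            rows.append({
                "patient_id": seq.patient_id,
                "seq_index": -1,
                "grid_row": p.grid_row,
                "grid_col": p.grid_col,
                "center_x": p.center_x,
                "center_y": p.center_y,
                "tissue_fraction": p.tissue_fraction,
                "kept": 0,
            })
    return pd.DataFrame(rows)
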
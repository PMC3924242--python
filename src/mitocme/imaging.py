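"""ROI-based image quantification of actin organisation and transferrin
uptake.

Mitotic cells round up, so an equatorial confocal section is close to a
disc with the actin cortex forming a bright ring at the border.  The
measurements reproduce a manual ImageJ workflow with a deterministic
analogue of the hand-drawn regions:

* a border ring of fixed width (24 px by default) inside the cell
  outline, for cortical F-actin;
* a 50 x 50 px box in the cytoplasm, placed at the point farthest from
  the border (the distance-transform pole), for cytoplasmic F- and
  G-actin;
* background taken as the median intensity outside all cells; all
  reported values are background-subtracted.

The cortex/cytoplasm F-actin ratio reports cortical enrichment, the
cytoplasmic G-actin mean reports monomeric actin availability, and
transferrin uptake is the integrated background-subtracted signal within
the cell (surface transferrin having been acid-stripped in the assay),
normalized to a designated reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = [
    "RoiSpec",
    "CellImageQuant",
    "derive_mask",
    "border_and_cytoplasm_rois",
    "estimate_background",
    "quantify_actin",
    "quantify_tf_uptake",
    "quantify_cell",
    "normalize_uptake",
]


@dataclass(frozen=True)
class RoiSpec:
    """ROI geometry: border ring width and cytoplasm box size (px)."""

    border_width: int = 24
    cytoplasm_box: tuple[int, int] = (50, 50)
    background_strategy: str = "outside_cells_median"

    def __post_init__(self) -> None:
        if self.border_width < 1:
            raise ValueError("border_width must be >= 1")
        if min(self.cytoplasm_box) < 1:
            raise ValueError("cytoplasm_box must be positive")
        if self.background_strategy not in ("outside_cells_median", "fixed_roi"):
            raise ValueError(f"unknown background strategy {self.background_strategy!r}")


@dataclass
class CellImageQuant:
    """Per-cell quantification record."""

    cell_id: str
    cortex_mean: float
    cytoplasm_mean: float
    background: float
    f_actin_ratio: float
    g_actin_mean: float = float("nan")
    tf_uptake_raw: float = float("nan")
    tf_uptake_normalized: float = float("nan")
    phase: str = ""
    condition: str = ""


def derive_mask(image: np.ndarray, provided_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary cell mask: the largest connected component above an Otsu
    threshold, holes filled.  A provided mask takes precedence and is
    returned unchanged (as bool)."""
    if provided_mask is not None:
        return np.asarray(provided_mask).astype(bool)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(image) == 0:
        raise ValueError("blank image: no cell found")
    thr = threshold_otsu(image)
    fg = image > thr
    if not fg.any():
        raise ValueError("empty mask after thresholding")
    labels = cc_label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(mask)


def border_and_cytoplasm_rois(
    mask: np.ndarray, spec: RoiSpec = RoiSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Construct the border ring and cytoplasm box for one cell mask.

    The ring is the mask minus its erosion by a ``border_width`` disc.
    The box is centred at the pole of the distance transform (the
    interior point farthest from the border), guaranteeing it sits at
    least ``border_width`` px from the mask boundary for any cell large
    enough to host it.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    eroded = ndimage.binary_erosion(mask, structure=disk(spec.border_width))
    ring = mask & ~eroded
    if not eroded.any():
        raise ValueError("cell too small: erosion by the border width removed it")

    edt = ndimage.distance_transform_edt(mask)
    cy, cx = np.unravel_index(int(np.argmax(edt * eroded)), mask.shape)
    bh, bw = spec.cytoplasm_box
    y0, x0 = cy - bh // 2, cx - bw // 2
    y1, x1 = y0 + bh, x0 + bw
    if y0 < 0 or x0 < 0 or y1 > mask.shape[0] or x1 > mask.shape[1]:
        raise ValueError("cell too small: cytoplasm box exceeds image bounds")
    box = np.zeros_like(mask)
    box[y0:y1, x0:x1] = True
    if not (box <= eroded).all():
        raise ValueError("cell too small: cytoplasm box does not fit inside the eroded mask")
    return ring, box


def estimate_background(
    image: np.ndarray,
    masks: np.ndarray | Sequence[np.ndarray],
    strategy: str = "outside_cells_median",
    margin: int = 3,
) -> float:
    """Background level: median intensity outside all cell masks (each
    dilated by ``margin`` px to exclude the blurred cell edge)."""
    if strategy != "outside_cells_median":
        raise ValueError(f"unsupported strategy {strategy!r}")
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks]
    excluded = np.zeros(np.asarray(image).shape, dtype=bool)
    for m in masks:
        excluded |= ndimage.binary_dilation(np.asarray(m).astype(bool), structure=disk(margin))
    outside = ~excluded
    if not outside.any():
        raise ValueError("no pixels outside cells to estimate background from")
    return float(np.median(np.asarray(image, dtype=float)[outside]))


def quantify_actin(
    f_channel: np.ndarray,
    g_channel: np.ndarray | None,
    rois: tuple[np.ndarray, np.ndarray],
    background: float | tuple[float, float],
) -> dict:
    """Cortex/cytoplasm F-actin ratio and cytoplasmic G-actin mean.

    ``background`` may be a single level or ``(f_background,
    g_background)`` when the channels differ.
    """
    ring, box = rois
    if isinstance(background, (tuple, list)):
        f_bg, g_bg = background
    else:
        f_bg = g_bg = float(background)
    cortex_mean = float(np.asarray(f_channel, dtype=float)[ring].mean())
    cyto_mean = float(np.asarray(f_channel, dtype=float)[box].mean())
    denom = cyto_mean - f_bg
    if denom <= 0:
        raise ValueError("background-subtracted cytoplasm mean is not positive")
    out = {
        "cortex_mean": cortex_mean,
        "cytoplasm_mean": cyto_mean,
        "f_actin_ratio": (cortex_mean - f_bg) / denom,
    }
    if g_channel is not None:
        out["g_actin_mean"] = float(np.asarray(g_channel, dtype=float)[box].mean()) - g_bg
    return out


def quantify_tf_uptake(
    tf_channel: np.ndarray,
    mask: np.ndarray,
    background: float,
    normalizer: float | None = None,
) -> tuple[float, float]:
    """Integrated transferrin signal within the cell.

    ``raw`` sums background-subtracted intensity (clipped at 0) over the
    mask; ``normalized`` divides by ``normalizer``, the mean raw uptake
    of the designated reference group.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.clip(np.asarray(tf_channel, dtype=float) - background, 0.0, None)
    raw = float(vals[mask].sum())
    if normalizer is None:
        return raw, float("nan")
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    return raw, raw / normalizer


def quantify_cell(
    channels: Mapping[str, np.ndarray],
    mask: np.ndarray | None = None,
    spec: RoiSpec = RoiSpec(),
    cell_id: str = "",
    phase: str = "",
    condition: str = "",
) -> CellImageQuant:
    """Full per-cell quantification from named channels.

    ``channels`` maps ``f_actin`` (required), ``g_actin`` and ``tf``
    (optional) to 2-D arrays.  The mask is derived from the F-actin
    channel when not provided.
    """
    f = np.asarray(channels["f_actin"], dtype=float)
    mask = derive_mask(f, mask)
    rois = border_and_cytoplasm_rois(mask, spec)
    f_bg = estimate_background(f, mask)
    g = channels.get("g_actin")
    g_bg = estimate_background(g, mask) if g is not None else f_bg
    actin = quantify_actin(f, g, rois, (f_bg, g_bg))
    quant = CellImageQuant(
        cell_id=cell_id,
        cortex_mean=actin["cortex_mean"],
        cytoplasm_mean=actin["cytoplasm_mean"],
        background=f_bg,
        f_actin_ratio=actin["f_actin_ratio"],
        g_actin_mean=actin.get("g_actin_mean", float("nan")),
        phase=phase,
        condition=condition,
    )
    tf = channels.get("tf")
    if tf is not None:
        tf_bg = estimate_background(tf, mask)
        quant.tf_uptake_raw, _ = quantify_tf_uptake(tf, mask, tf_bg)
    return quant


def normalize_uptake(
    quants: pd.DataFrame,
    reference: tuple[str, str],
) -> pd.DataFrame:
    """Normalize ``tf_uptake_raw`` to the mean of the reference
    ``(condition, phase)`` group; the reference group's normalized mean
    is exactly 1."""
    cond, phase = reference
    ref = quants[(quants["condition"] == cond) & (quants["phase"] == phase)]
    if ref.empty:
        raise ValueError(f"reference group {reference} has no cells")
    norm = float(ref["tf_uptake_raw"].mean())
    if norm <= 0:
        raise ValueError("reference group mean uptake is not positive")
    out = quants.copy()
    out["tf_uptake_normalized"] = out["tf_uptake_raw"] / norm
    return out
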
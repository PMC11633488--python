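"""Size-classified ROI segmentation and astrocyte morphology metrics.

Candidate regions are 8-connected components of a binary active mask (or of
a grayscale detection image thresholded at an absolute intensity). Each
component is classified purely by its area: somata are >= 30 um^2,
microdomains lie in the closed interval [0.5, 10] um^2, and blobs in the
unassigned 10-30 um^2 gap (or below 0.5 um^2) are kept but labelled
"unclassified" and excluded from event statistics. Components are grouped
into cells by a seeded watershed grown from the soma markers, and a cell's
territory is the convex hull of all of its components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_segmentation

SOMA = "soma"
MICRODOMAIN = "microdomain"
TERRITORY = "territory"
UNCLASSIFIED = "unclassified"

SOMA_MIN_UM2 = 30.0
MICRODOMAIN_MIN_UM2 = 0.5
MICRODOMAIN_MAX_UM2 = 10.0


def classify_roi(area_um2: float) -> str:
    """Total size classification: soma >= 30 um^2, microdomain in
    [0.5, 10] um^2 (closed bounds), everything else unclassified."""
    if area_um2 < 0:
        raise ValueError(f"area must be non-negative, got {area_um2}")
    if area_um2 >= SOMA_MIN_UM2:
        return SOMA
    if MICRODOMAIN_MIN_UM2 <= area_um2 <= MICRODOMAIN_MAX_UM2:
        return MICRODOMAIN
    return UNCLASSIFIED


@dataclass
class ROISet:
    """Labelled regions plus a per-ROI table and per-cell territory masks.

    ``table`` columns: roi_id, roi_class, cell_id, area_um2, area_px,
    centroid_y, centroid_x, bbox_min_row, bbox_min_col, bbox_max_row,
    bbox_max_col. ``territories`` maps cell id -> boolean hull mask
    (territories of neighbouring cells may overlap, so they are kept
    outside the flat label image).
    """

    label_image: np.ndarray
    table: pd.DataFrame
    pixel_size_um: float
    territories: dict[int, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.label_image == roi_id

    def ids_of_class(self, roi_class: str) -> list[int]:
        sel = self.table[self.table["roi_class"] == roi_class]
        return [int(i) for i in sel["roi_id"]]


def _group_cells(mask: np.ndarray, label_image: np.ndarray,
                 table: pd.DataFrame) -> tuple[pd.Series, dict[int, np.ndarray]]:
    """Assign each component to a cell by a watershed seeded at the somata;
    return per-ROI cell ids and the convex-hull territory of each cell."""
    soma_rows = table[table["roi_class"] == SOMA]
    if soma_rows.empty:
        return pd.Series([-1] * len(table), index=table.index), {}
    markers = np.zeros_like(label_image)
    for cell_idx, roi_id in enumerate(soma_rows["roi_id"], start=1):
        markers[label_image == roi_id] = cell_idx
    # watershed on the distance away from the soma markers: every pixel of
    # the frame falls in the basin of its nearest soma
    distance = ndimage.distance_transform_edt(markers == 0)
    basins = sk_segmentation.watershed(distance, markers=markers)
    cell_ids = []
    for _, row in table.iterrows():
        cy, cx = int(round(row["centroid_y"])), int(round(row["centroid_x"]))
        cell_ids.append(int(basins[cy, cx]) - 1)
    cell_series = pd.Series(cell_ids, index=table.index)
    territories: dict[int, np.ndarray] = {}
    for cell_idx in sorted(cell_series.unique()):
        members = table.loc[cell_series == cell_idx, "roi_id"]
        cell_mask = np.isin(label_image, list(members)) & mask
        if cell_mask.any():
            territories[int(cell_idx)] = morphology.convex_hull_image(cell_mask)
    return cell_series, territories


def segment_rois(image: np.ndarray, pixel_size_um: float,
                 threshold: Optional[float] = None,
                 group_cells: bool = True) -> ROISet:
    """Segment an active mask (or detection image) into classified ROIs.

    Parameters
    ----------
    image:
        2-D boolean active mask, or a grayscale detection image (e.g. the
        temporal median projection) together with ``threshold``.
    pixel_size_um:
        Pixel side length; areas are pixel counts times its square.
    threshold:
        Absolute intensity cut applied when ``image`` is grayscale.
    group_cells:
        Whether to group components into cells (watershed from soma
        markers) and compute convex-hull territories.

    An empty mask yields an empty ROISet.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segmentation input must be 2-D")
    if image.dtype == bool:
        mask = image
    else:
        if threshold is None:
            raise ValueError("grayscale input requires a threshold")
        mask = image > threshold

    label_image, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    rows = []
    for region in measure.regionprops(label_image):
        area_um2 = region.area * pixel_size_um ** 2
        rows.append({
            "roi_id": int(region.label),
            "roi_class": classify_roi(area_um2),
            "cell_id": -1,
            "area_um2": float(area_um2),
            "area_px": int(region.area),
            "centroid_y": float(region.centroid[0]),
            "centroid_x": float(region.centroid[1]),
            "bbox_min_row": int(region.bbox[0]),
            "bbox_min_col": int(region.bbox[1]),
            "bbox_max_row": int(region.bbox[2]),
            "bbox_max_col": int(region.bbox[3]),
        })
    columns = ["roi_id", "roi_class", "cell_id", "area_um2", "area_px",
               "centroid_y", "centroid_x", "bbox_min_row", "bbox_min_col",
               "bbox_max_row", "bbox_max_col"]
    table = pd.DataFrame(rows, columns=columns)
    territories: dict[int, np.ndarray] = {}
    if group_cells and not table.empty:
        cell_series, territories = _group_cells(mask, label_image, table)
        table["cell_id"] = cell_series.values
    return ROISet(label_image=label_image.astype(np.int32), table=table,
                  pixel_size_um=pixel_size_um, territories=territories)


@dataclass
class MorphologyRecord:
    """Single-cell morphology summary (all lengths in um, areas in um^2)."""

    territory_um2: float
    soma_um2: float
    territory_to_soma_ratio: float
    height_um: float
    width_um: float
    perimeter_um: float


def morphology_metrics(cell_mask: np.ndarray, soma_mask: np.ndarray,
                       pixel_size_um: float) -> MorphologyRecord:
    """Territory area, soma area, their ratio, bounding-box extents and
    perimeter of one cell.

    The territory is the full cell mask; height and width are the vertical
    and horizontal bounding-box extents; the perimeter uses the Crofton
    estimator, which is less biased than counting pixel edges.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if not soma_mask.any():
        raise ValueError("soma mask is empty; territory-to-soma ratio "
                         "is undefined")
    if (soma_mask & ~cell_mask).any():
        raise ValueError("soma mask must lie within the cell mask")
    px2 = pixel_size_um ** 2
    territory_um2 = float(cell_mask.sum() * px2)
    soma_um2 = float(soma_mask.sum() * px2)
    ys, xs = np.nonzero(cell_mask)
    height_um = float((ys.max() - ys.min() + 1) * pixel_size_um)
    width_um = float((xs.max() - xs.min() + 1) * pixel_size_um)
    perimeter_px = measure.perimeter_crofton(cell_mask, directions=4)
    return MorphologyRecord(
        territory_um2=territory_um2,
        soma_um2=soma_um2,
        territory_to_soma_ratio=territory_um2 / soma_um2,
        height_um=height_um,
        width_um=width_um,
        perimeter_um=float(perimeter_px * pixel_size_um),
    )
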
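"""Cell detection in the cell-body channel and geometry measurement.

Cells are found by global Otsu thresholding, hole filling and 8-connected
component labeling; components outside an area window or touching the image
border are discarded.  Geometry (length, area, orientation, pole tips) is
measured on the principal axis of the pixel mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

log = logging.getLogger(__name__)


@dataclass
class CellROI:
    """One detected cell in one frame: a local mask plus its bounding box."""

    cell_id: int
    frame: int
    bbox: Tuple[int, int, int, int]       # (r0, c0, r1, c1), half-open
    mask: np.ndarray                      # bool, local to bbox
    centroid_um: Tuple[float, float]      # (x, y) in um

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def pixel_coords(self):
        """(rows, cols) of mask pixels in full-image coordinates."""
        rr, cc = np.nonzero(self.mask)
        return rr + self.bbox[0], cc + self.bbox[1]


@dataclass
class CellGeometry:
    length_um: float
    area_um2: float
    orientation: float                    # radians, major axis vs. column axis
    pole1_um: Tuple[float, float]         # (x, y)
    pole2_um: Tuple[float, float]


def segment_cells(
    cell_body_image: np.ndarray,
    pixel_size: float,
    min_area: float = 0.5,
    max_area: float = 20.0,
    discard_border: bool = True,
) -> List[CellROI]:
    """Segment one frame of the cell-body channel into cell ROIs.

    Otsu global threshold -> hole filling -> 8-connected labeling -> area
    filter in um^2 -> optional removal of border-touching components.  ROIs
    are returned sorted by centroid in row-major order.  A blank (zero
    variance) image yields an empty list with a logged warning.
    """
    img = np.asarray(cell_body_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a 2-D image")
    if min_area >= max_area:
        raise ValueError("min_area must be below max_area")
    if float(img.max()) == float(img.min()):
        log.warning("blank image: no cells segmented")
        return []
    thr = threshold_otsu(img)
    binary = ndi.binary_fill_holes(img > thr)
    labels = sk_label(binary, connectivity=2)
    rois: List[CellROI] = []
    H, W = img.shape
    for rp in regionprops(labels):
        area_um2 = rp.area * pixel_size**2
        if not (min_area <= area_um2 <= max_area):
            continue
        r0, c0, r1, c1 = rp.bbox
        if discard_border and (r0 == 0 or c0 == 0 or r1 == H or c1 == W):
            continue
        cy, cx = rp.centroid
        rois.append(
            CellROI(
                cell_id=-1,
                frame=0,
                bbox=(r0, c0, r1, c1),
                mask=rp.image.copy(),
                centroid_um=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
            )
        )
    rois.sort(key=lambda r: (r.centroid_um[1], r.centroid_um[0]))
    for i, roi in enumerate(rois):
        roi.cell_id = i
    return rois


def measure_cell_geometry(roi: CellROI, pixel_size: float) -> CellGeometry:
    """Length, area, orientation and pole tips of one cell mask.

    Length is the extent of the mask projected on its principal axis plus one
    pixel (so a single-pixel mask has length = pixel_size); the pole tips are
    the extremal projected mask points.
    """
    rr, cc = np.nonzero(roi.mask)
    if rr.size == 0:
        raise ValueError("empty cell mask")
    ys = rr + roi.bbox[0] + 0.5
    xs = cc + roi.bbox[1] + 0.5
    area_um2 = rr.size * pixel_size**2
    if rr.size == 1:
        x, y = xs[0] * pixel_size, ys[0] * pixel_size
        return CellGeometry(pixel_size, area_um2, 0.0, (x, y), (x, y))
    pts = np.column_stack([xs - xs.mean(), ys - ys.mean()])
    cov = pts.T @ pts / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    proj = pts @ axis
    i_min, i_max = int(np.argmin(proj)), int(np.argmax(proj))
    length = (proj[i_max] - proj[i_min] + 1.0) * pixel_size
    p1 = (xs[i_min] * pixel_size, ys[i_min] * pixel_size)
    p2 = (xs[i_max] * pixel_size, ys[i_max] * pixel_size)
    return CellGeometry(
        length_um=float(length),
        area_um2=float(area_um2),
        orientation=float(np.arctan2(axis[1], axis[0])),
        pole1_um=p1,
        pole2_um=p2,
    )


def _jaccard(a: CellROI, b: CellROI) -> float:
    r0 = max(a.bbox[0], b.bbox[0])
    c0 = max(a.bbox[1], b.bbox[1])
    r1 = min(a.bbox[2], b.bbox[2])
    c1 = min(a.bbox[3], b.bbox[3])
    if r0 >= r1 or c0 >= c1:
        return 0.0
    ma = a.mask[r0 - a.bbox[0]: r1 - a.bbox[0], c0 - a.bbox[1]: c1 - a.bbox[1]]
    mb = b.mask[r0 - b.bbox[0]: r1 - b.bbox[0], c0 - b.bbox[1]: c1 - b.bbox[1]]
    inter = np.logical_and(ma, mb).sum()
    if inter == 0:
        return 0.0
    union = a.area_px + b.area_px - inter
    return inter / union


def link_rois(
    rois_per_frame: Sequence[List[CellROI]],
) -> Tuple[List[CellROI], Dict[int, dict]]:
    """Link per-frame ROIs into persistent cell identities.

    ROIs in consecutive frames are matched by maximum mask overlap (Jaccard),
    ties broken by smaller centroid distance.  When one ROI at frame t
    overlaps two unmatched ROIs at t+1, a division is declared: the daughters
    get fresh ids, mutual sister links and a parent link.

    Returns the flat list of ROIs (with ``cell_id``/``frame`` assigned) and a
    lineage dict: cell_id -> {parent_id, sister_id, birth_frame, division_frame}.
    """
    lineage: Dict[int, dict] = {}
    next_id = 0
    linked: List[CellROI] = []
    prev: List[CellROI] = []
    for f, frame_rois in enumerate(rois_per_frame):
        for roi in frame_rois:
            roi.frame = f
            roi.cell_id = -1
        if not prev:
            for roi in frame_rois:
                roi.cell_id = next_id
                lineage[next_id] = dict(parent_id=-1, sister_id=-1,
                                        birth_frame=f, division_frame=-1)
                next_id += 1
        else:
            # overlap matrix prev x current
            pairs = []
            for i, p in enumerate(prev):
                for j, c in enumerate(frame_rois):
                    jac = _jaccard(p, c)
                    if jac > 0.05:
                        d = np.hypot(p.centroid_um[0] - c.centroid_um[0],
                                     p.centroid_um[1] - c.centroid_um[1])
                        pairs.append((-jac, d, i, j))
            pairs.sort()
            matched_prev: Dict[int, List[int]] = {}
            used_cur = set()
            for njac, d, i, j in pairs:
                if j in used_cur:
                    continue
                matched_prev.setdefault(i, [])
                if len(matched_prev[i]) >= 2:
                    continue
                matched_prev[i].append(j)
                used_cur.add(j)
            for i, p in enumerate(prev):
                js = matched_prev.get(i, [])
                if len(js) == 1:
                    frame_rois[js[0]].cell_id = p.cell_id
                elif len(js) == 2:
                    # division: two fresh daughters
                    lineage[p.cell_id]["division_frame"] = f
                    d_ids = (next_id, next_id + 1)
                    next_id += 2
                    for k, j in enumerate(sorted(js)):
                        frame_rois[j].cell_id = d_ids[k]
                        lineage[d_ids[k]] = dict(
                            parent_id=p.cell_id, sister_id=d_ids[1 - k],
                            birth_frame=f, division_frame=-1)
            for c in frame_rois:
                if c.cell_id == -1:
                    c.cell_id = next_id
                    lineage[next_id] = dict(parent_id=-1, sister_id=-1,
                                            birth_frame=f, division_frame=-1)
                    next_id += 1
        linked.extend(frame_rois)
        prev = frame_rois
    return linked, lineage
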
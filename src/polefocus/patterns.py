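"""Four-way classification of cluster localization dynamics.

Each cell is assigned one of: non-Dyn (a static cluster), Dyn-1P (cluster
mobile within one pole's zone), Dyn-OP (cluster visits the other pole or the
midcell band), UC (no detectable cluster), from the per-frame primary-cluster
detections over a short classification window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

PATTERN_ORDER = ("non-Dyn", "Dyn-1P", "Dyn-OP", "UC")


@dataclass
class PoleZones:
    """Pole and midcell intervals on the normalized cell axis [0, 1]."""

    pole1: tuple
    pole2: tuple
    midcell: tuple
    pole_zone_fraction: float

    def zone_of(self, s: float) -> Optional[str]:
        if self.pole1[0] <= s <= self.pole1[1]:
            return "pole1"
        if self.pole2[0] <= s <= self.pole2[1]:
            return "pole2"
        if self.midcell[0] <= s <= self.midcell[1]:
            return "midcell"
        return None


@dataclass
class PatternLabel:
    cell_id: int
    label: str
    presence_fraction: float
    max_displacement_um: float
    left_start_zone: bool


def assign_pole_zones(pole_zone_fraction: float = 0.25) -> PoleZones:
    """Zones on the normalized axis: poles [0, f] and [1-f, 1], midcell band
    [0.5 - f/2, 0.5 + f/2].  Normalized coordinates make the zones scale with
    the cell as it elongates."""
    f = pole_zone_fraction
    if not (0.0 < f < 0.5):
        raise ValueError("pole_zone_fraction must be in (0, 0.5)")
    return PoleZones(
        pole1=(0.0, f),
        pole2=(1.0 - f, 1.0),
        midcell=(0.5 - f / 2.0, 0.5 + f / 2.0),
        pole_zone_fraction=f,
    )


def classify_pattern(
    track: pd.DataFrame,
    zones: PoleZones,
    d_static: float = 0.2,
    presence_min: float = 0.2,
) -> PatternLabel:
    """Classify one cell track.

    ``track`` needs per-frame columns ``cluster_present``, and for frames
    with a cluster: ``cluster_x_um``, ``cluster_y_um``, ``axial_s`` (primary
    cluster only).  Rules, in order: UC when the cluster is present in fewer
    than ``presence_min`` of frames; non-Dyn when the maximum pairwise
    centroid displacement is below ``d_static``; Dyn-OP when any centroid
    enters the other pole's zone or the midcell band (a midcell start counts
    as leaving immediately); otherwise Dyn-1P.
    """
    if len(track) < 4:
        raise ValueError("track must cover >= 4 frames to be classifiable")
    cell_id = int(track["cell_id"].iloc[0]) if "cell_id" in track else -1
    present = track["cluster_present"].to_numpy(dtype=bool)
    presence = present.mean()
    if presence < presence_min:
        return PatternLabel(cell_id, "UC", float(presence), 0.0, False)
    sub = track[present]
    pts = sub[["cluster_x_um", "cluster_y_um"]].to_numpy(dtype=float)
    if len(pts) >= 2:
        diffs = pts[:, None, :] - pts[None, :, :]
        max_disp = float(np.sqrt((diffs**2).sum(-1)).max())
    else:
        max_disp = 0.0
    if max_disp < d_static:
        return PatternLabel(cell_id, "non-Dyn", float(presence), max_disp, False)
    s = sub["axial_s"].to_numpy(dtype=float)
    start_zone = zones.zone_of(s[0])
    if start_zone not in ("pole1", "pole2"):
        return PatternLabel(cell_id, "Dyn-OP", float(presence), max_disp, True)
    other = "pole2" if start_zone == "pole1" else "pole1"
    left = any(zones.zone_of(v) in (other, "midcell") for v in s)
    label = "Dyn-OP" if left else "Dyn-1P"
    return PatternLabel(cell_id, label, float(presence), max_disp, bool(left))


def classify_tracks(
    tracks: pd.DataFrame,
    zones: Optional[PoleZones] = None,
    d_static: float = 0.2,
    presence_min: float = 0.2,
) -> List[PatternLabel]:
    """Classify every cell in a tidy per-cell-per-frame table."""
    if zones is None:
        zones = assign_pole_zones()
    labels = []
    for cell_id, sub in tracks.groupby("cell_id"):
        if len(sub) < 4:
            continue
        labels.append(
            classify_pattern(sub.sort_values("frame"), zones, d_static, presence_min)
        )
    return labels


def population_fractions(labels: Sequence[PatternLabel]) -> pd.Series:
    """Fractions over the four classes (summing to 1) plus the fraction of
    cells with detectable clusters (= 1 - UC fraction)."""
    if len(labels) == 0:
        raise ValueError("no labels to summarize")
    counts: Dict[str, int] = {k: 0 for k in PATTERN_ORDER}
    for lab in labels:
        counts[lab.label] += 1
    n = len(labels)
    out = {k: counts[k] / n for k in PATTERN_ORDER}
    out["detectable"] = 1.0 - out["UC"]
    return pd.Series(out)
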
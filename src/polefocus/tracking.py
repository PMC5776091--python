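"""Linking per-frame cluster observations into trajectories and speeds.

Within each cell, detections in consecutive frames are linked greedily by
nearest centroid, accepting links below a displacement gate.  Average speed
is path length over elapsed time, matching the jagged, zigzag paths the
clusters trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .cluster_quant import ClusterObservation


@dataclass
class Trajectory:
    cell_id: int
    observations: List[ClusterObservation] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.observations[0].frame

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def mean_area_um2(self) -> float:
        return float(np.mean([o.area_um2 for o in self.observations]))

    def path_length_um(self) -> float:
        pts = np.array([o.centroid_um for o in self.observations])
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def link_clusters(
    observations: Sequence[ClusterObservation],
    max_step: float = 1.0,
    max_gap: int = 0,
) -> List[Trajectory]:
    """Link observations into per-cell trajectories.

    Greedy nearest-neighbor matching between consecutive frames; ties are
    broken by smallest distance, then smallest observation index, so the
    result is independent of input order.  A detection miss longer than
    ``max_gap`` frames closes the trajectory (the default 0 tolerates none).
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    by_cell: Dict[int, List[ClusterObservation]] = {}
    for obs in observations:
        by_cell.setdefault(obs.cell_id, []).append(obs)
    trajectories: List[Trajectory] = []
    for cell_id in sorted(by_cell):
        obs = sorted(by_cell[cell_id],
                     key=lambda o: (o.frame, o.centroid_um[0], o.centroid_um[1]))
        frames: Dict[int, List[ClusterObservation]] = {}
        for o in obs:
            frames.setdefault(o.frame, []).append(o)
        open_trajs: List[Trajectory] = []
        for f in sorted(frames):
            cur = frames[f]
            candidates = []
            for ti, t in enumerate(open_trajs):
                if f - t.end_frame > max_gap + 1:
                    continue
                tx, ty = t.observations[-1].centroid_um
                for oi, o in enumerate(cur):
                    d = math.hypot(o.centroid_um[0] - tx, o.centroid_um[1] - ty)
                    if d <= max_step:
                        candidates.append((d, oi, ti))
            candidates.sort()
            used_o, used_t = set(), set()
            for d, oi, ti in candidates:
                if oi in used_o or ti in used_t:
                    continue
                open_trajs[ti].observations.append(cur[oi])
                used_o.add(oi)
                used_t.add(ti)
            for oi, o in enumerate(cur):
                if oi not in used_o:
                    open_trajs.append(Trajectory(cell_id=cell_id, observations=[o]))
            # retire trajectories whose gap budget ran out
            still_open = []
            for t in open_trajs:
                if f - t.end_frame > max_gap:
                    trajectories.append(t)
                else:
                    still_open.append(t)
            open_trajs = still_open
        trajectories.extend(open_trajs)
    trajectories.sort(key=lambda t: (t.cell_id, t.start_frame))
    return trajectories


def trajectory_speed(traj: Trajectory, frame_interval: float) -> float:
    """Average speed (um/s): path length / elapsed time between the first
    and last linked frame.  Singleton trajectories have undefined speed
    (returns NaN)."""
    if traj.n_obs < 2:
        return math.nan
    elapsed = (traj.end_frame - traj.start_frame) * frame_interval
    return traj.path_length_um() / elapsed
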
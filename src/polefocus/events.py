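"""Formation/dispersal event detection, quiescence-exit sub-populations and
sister-cell inheritance scoring on per-cell SDI time series."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)


@dataclass
class EventRecord:
    cell_id: int
    type: str                     # formation | dispersal | division
    time_min: float               # from track start
    frame: int
    sdi_ratio: float = math.nan   # SDI at event / baseline (formation)
    rel_drop: float = math.nan    # relative SDI drop (dispersal)


def _smooth3(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x.astype(float)
    return np.convolve(np.pad(x.astype(float), 1, mode="edge"),
                       np.ones(3) / 3.0, mode="valid")


def detect_formation_event(
    track: pd.DataFrame,
    jump_factor: float = 2.0,
    baseline_window: int = 3,
) -> Optional[EventRecord]:
    """First frame where the SDI jumps ``jump_factor``-fold over the median
    of the trailing baseline window AND a cluster is detected for at least
    two consecutive frames from that point on.  Returns None if no frame
    qualifies."""
    if len(track) < baseline_window + 1:
        raise ValueError("track too short for the baseline window")
    track = track.sort_values("frame")
    sdi = track["sdi"].to_numpy(dtype=float)
    present = track["cluster_present"].to_numpy(dtype=bool)
    times = track["time_min"].to_numpy(dtype=float)
    t0 = times[0]
    for i in range(baseline_window, len(sdi)):
        base = float(np.median(sdi[i - baseline_window: i]))
        if base <= 0:
            continue
        if sdi[i] < jump_factor * base:
            continue
        # presence must hold for two consecutive frames from the jump
        if not (present[i] and i + 1 < len(present) and present[i + 1]):
            continue
        return EventRecord(
            cell_id=int(track["cell_id"].iloc[0]),
            type="formation",
            time_min=float(times[i] - t0),
            frame=int(track["frame"].iloc[i]),
            sdi_ratio=float(sdi[i] / base),
        )
    return None


def detect_dispersal(
    track: pd.DataFrame,
    slope_window: int = 5,
    min_rel_drop: float = 0.4,
) -> Optional[EventRecord]:
    """Gradual-dispersal detector.

    Declares dispersal when a monotone-declining run of the (3-point
    smoothed) SDI spanning at least ``slope_window`` frames accumulates a
    relative drop of ``min_rel_drop``, or when the cluster disappears for at
    least two consecutive frames.  The event time is the end of the run.
    """
    track = track.sort_values("frame")
    if not bool(track["cluster_present"].iloc[0]):
        raise ValueError("dispersal detection expects a track starting with a cluster")
    sdi = _smooth3(track["sdi"].to_numpy(dtype=float))
    present = track["cluster_present"].to_numpy(dtype=bool)
    times = track["time_min"].to_numpy(dtype=float)
    frames = track["frame"].to_numpy()
    t0 = times[0]
    cell_id = int(track["cell_id"].iloc[0])
    # absence rule
    for i in range(1, len(present) - 1):
        if not present[i] and not present[i + 1]:
            return EventRecord(cell_id, "dispersal", float(times[i] - t0),
                               int(frames[i]), rel_drop=1.0)
    # monotone-decline rule
    start = 0
    for i in range(1, len(sdi)):
        if sdi[i] <= sdi[i - 1]:
            if i - start + 1 >= slope_window and sdi[start] > 0:
                drop = (sdi[start] - sdi[i]) / sdi[start]
                if drop >= min_rel_drop:
                    return EventRecord(cell_id, "dispersal",
                                       float(times[i] - t0), int(frames[i]),
                                       rel_drop=float(drop))
        else:
            start = i
    return None


def classify_quiescence_subpopulations(
    time0_stats: pd.DataFrame,
    sdi_big_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Split cells at time 0 into no-cluster / small-cluster / big-cluster.

    Cells without a detected cluster are "no-cluster"; the rest are split at
    ``sdi_big_threshold`` on the SDI, defaulting to Otsu's threshold on the
    SDI values of cluster-bearing cells.  Returns a per-cell table with a
    ``qx_class`` column; class fractions are attached as ``.attrs['fractions']``.
    """
    df = time0_stats.copy()
    clustered = df[df.cluster_present]
    if sdi_big_threshold is None:
        if len(clustered) >= 2 and clustered.sdi.nunique() > 1:
            sdi_big_threshold = float(threshold_otsu(clustered.sdi.to_numpy()))
        else:
            sdi_big_threshold = math.inf
    def _cls(row):
        if not row.cluster_present:
            return "no-cluster"
        return "big" if row.sdi > sdi_big_threshold else "small"
    df["qx_class"] = df.apply(_cls, axis=1)
    fr = df.qx_class.value_counts(normalize=True)
    df.attrs["fractions"] = {k: float(fr.get(k, 0.0))
                             for k in ("no-cluster", "small", "big")}
    df.attrs["sdi_big_threshold"] = sdi_big_threshold
    return df


def presence_matrix(tracks: pd.DataFrame) -> pd.DataFrame:
    """Cells x time matrix of cluster presence (0/1), rows sorted by the
    cells' time-0 SDI — the layout of a cluster-occupancy heat map."""
    mat = tracks.pivot_table(index="cell_id", columns="frame",
                             values="cluster_present", aggfunc="first")
    t0 = tracks[tracks.frame == tracks.frame.min()].set_index("cell_id").sdi
    order = t0.reindex(mat.index).sort_values(ascending=False).index
    return mat.loc[order].astype(float)


def sister_cluster_status(
    tracks: pd.DataFrame,
    lineage: Dict[int, dict],
    at_frame: Optional[int] = None,
) -> pd.Series:
    """Score cluster inheritance across completed divisions.

    For every sister pair, evaluates ``cluster_present`` at ``at_frame``
    (default: the pair's last common frame) and returns the fractions of
    pairs with only one vs. both sisters carrying a cluster, plus the
    fraction of all end-of-movie cells with a cluster.
    """
    pairs = set()
    for cid, info in lineage.items():
        sid = info.get("sister_id", -1)
        if sid >= 0:
            pairs.add((min(cid, sid), max(cid, sid)))
    one = both = neither = 0
    for a, b in sorted(pairs):
        ta = tracks[tracks.cell_id == a]
        tb = tracks[tracks.cell_id == b]
        if ta.empty or tb.empty:
            continue
        f_eval = at_frame
        if f_eval is None:
            f_eval = min(ta.frame.max(), tb.frame.max())
        pa = ta[ta.frame == f_eval]
        pb = tb[tb.frame == f_eval]
        if pa.empty or pb.empty:
            continue
        ca = bool(pa.cluster_present.iloc[0])
        cb = bool(pb.cluster_present.iloc[0])
        if ca and cb:
            both += 1
        elif ca or cb:
            one += 1
        else:
            neither += 1
    total = one + both
    if total == 0:
        log.warning("no completed divisions with both daughters tracked")
        return pd.Series({"one_sister_only": math.nan, "both_sisters": math.nan,
                          "n_pairs": 0, "final_cluster_fraction": math.nan})
    last = tracks.loc[tracks.groupby("cell_id").frame.idxmax()]
    return pd.Series({
        "one_sister_only": one / total,
        "both_sisters": both / total,
        "n_pairs": total,
        "final_cluster_fraction": float(last.cluster_present.mean()),
    })


def formation_timing_stats(
    events: Sequence[EventRecord],
    tracks: pd.DataFrame,
    cells_meta: Optional[pd.DataFrame] = None,
) -> dict:
    """Distributions and association tests around cluster-formation events.

    Returns the formation-time and cell-length-at-formation distributions,
    the Spearman correlation of formation time with cell length at birth
    (a cell-cycle-phase proxy), an exponential goodness-of-fit test on the
    formation times (Lilliefors), and, when lineage metadata is supplied, a
    comparison of cell-cycle durations for cells born with vs. without a
    cluster (Welch t-test).
    """
    forms = [e for e in events if e is not None and e.type == "formation"]
    if len(forms) < 10:
        raise ValueError("need >= 10 formation events for timing statistics")
    times = np.array([e.time_min for e in forms], dtype=float)
    lengths = []
    birth_lengths = []
    for e in forms:
        sub = tracks[(tracks.cell_id == e.cell_id)]
        row = sub[sub.frame == e.frame]
        lengths.append(float(row.length_um.iloc[0]) if not row.empty else math.nan)
        first = sub.sort_values("frame").iloc[0] if not sub.empty else None
        birth_lengths.append(float(first.length_um) if first is not None else math.nan)
    lengths = np.array(lengths)
    birth_lengths = np.array(birth_lengths)
    ok = np.isfinite(times) & np.isfinite(birth_lengths)
    rho, p = sps.spearmanr(times[ok], birth_lengths[ok])
    from statsmodels.stats.diagnostic import lilliefors

    ksstat, gof_p = lilliefors(times[times > 0], dist="exp")
    out = dict(
        formation_times_min=times,
        lengths_at_formation_um=lengths,
        time_vs_birth_length=dict(rho=float(rho), p=float(p), n=int(ok.sum())),
        exponential_gof=dict(stat=float(ksstat), p=float(gof_p)),
    )
    if cells_meta is not None and "born_with_cluster" in cells_meta:
        merged = cells_meta.dropna(subset=["cycle_duration_min"]) \
            if "cycle_duration_min" in cells_meta else None
        if merged is not None and not merged.empty:
            a = merged[merged.born_with_cluster].cycle_duration_min
            b = merged[~merged.born_with_cluster].cycle_duration_min
            if len(a) >= 2 and len(b) >= 2:
                t, pt = sps.ttest_ind(a, b, equal_var=False)
                out["cycle_duration_by_birth_status"] = dict(
                    t=float(t), p=float(pt), n_with=len(a), n_without=len(b))
    return out
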
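"""End-to-end pipelines: stack in, tidy tables and summary statistics out.

``run_analysis`` chains segmentation -> cluster detection -> per-cell
statistics -> tracking -> classification on an image stack.
``run_figure_suite`` runs preconfigured simulate-and-analyze recipes for each
of the main experiment layouts (pattern census, formation kinetics, FRAP,
growth-phase census, quiescence exit, reporter correlation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import FrapSettings, SimulationConfig
from .stack import ImageStack
from .simulate import (
    GroundTruth,
    simulate_frap_stack,
    simulate_population,
    simulate_quiescence_exit,
)
from .segmentation import link_rois, measure_cell_geometry, segment_cells
from .cluster_quant import cell_intensity_stats, detect_clusters
from .tracking import Trajectory, link_clusters, trajectory_speed
from .patterns import assign_pole_zones, classify_tracks, population_fractions
from .events import (
    classify_quiescence_subpopulations,
    detect_formation_event,
    sister_cluster_status,
)
from .frap import analyze_frap_stack, mean_recovery_at
from .stats import correlation, reporter_vs_clustering

log = logging.getLogger(__name__)


def derive_seed(seed: int, stream: int) -> int:
    """Fan one global seed out into independent per-recipe streams."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


@dataclass
class AnalysisParams:
    min_cell_area: float = 0.5        # um^2
    max_cell_area: float = 20.0
    k_sigma: float = 2.0
    min_cluster_area: float = 0.04    # um^2
    homogenize_radius_um: float = 0.5
    max_step: float = 1.0             # um of displacement per 10 s of frame interval
    max_gap: int = 0
    pole_zone_fraction: float = 0.25
    d_static: float = 0.2             # um
    presence_min: float = 0.2


@dataclass
class AnalysisResult:
    tracks: pd.DataFrame              # per cell per frame
    trajectories: List[Trajectory]
    trajectory_summary: pd.DataFrame
    labels: list
    fractions: Optional[pd.Series]
    lineage: Dict[int, dict]
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.trajectory_summary.to_csv(out / "trajectories.csv", index=False)
        if self.labels:
            pd.DataFrame([vars(l) for l in self.labels]).to_csv(
                out / "labels.csv", index=False)
        if self.fractions is not None:
            self.fractions.to_csv(out / "fractions.csv", header=["fraction"])
        pd.DataFrame.from_dict(self.lineage, orient="index").rename_axis(
            "cell_id").to_csv(out / "lineage.csv")
        if not self.tracks.empty:
            from .events import presence_matrix

            presence_matrix(self.tracks).to_csv(out / "presence_matrix.csv")
        manifest_path = out / "manifest.json"
        if manifest_path.exists():
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_hash") != self.manifest.get("config_hash"):
                log.warning("overwriting results produced with a different "
                            "configuration (hash mismatch)")
        manifest_path.write_text(json.dumps(self.manifest, indent=2))


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_analysis(
    stack: ImageStack,
    params: Optional[AnalysisParams] = None,
    classify: bool = True,
    reporter_channel: Optional[str] = None,
) -> AnalysisResult:
    """Run the full measurement chain on a stack.

    Produces the per-cell-per-frame table (MI, SDI, cluster presence,
    primary-cluster centroid/area/axial position, geometry), linked cluster
    trajectories with speeds, and — when the movie is long enough — pattern
    labels and population fractions.
    """
    from . import __version__

    p = params or AnalysisParams()
    if reporter_channel is None and "reporter" in stack.channels:
        reporter_channel = "reporter"
    phase = stack.channel("phase")
    fluor = stack.channel("mcherry")
    rois_per_frame = []
    for f in range(stack.n_frames):
        rois = segment_cells(phase[f], stack.pixel_size,
                             p.min_cell_area, p.max_cell_area)
        rois_per_frame.append(rois)
    linked, lineage = link_rois(rois_per_frame)

    rows = []
    observations = []
    for roi in linked:
        geom = measure_cell_geometry(roi, stack.pixel_size)
        clusters = detect_clusters(
            roi, fluor[roi.frame], stack.pixel_size, p.k_sigma,
            p.min_cluster_area, p.homogenize_radius_um, geometry=geom)
        primary = next((c for c in clusters if c.is_primary), None)
        stats = cell_intensity_stats(roi, fluor[roi.frame],
                                     cluster_present=primary is not None)
        row = dict(
            cell_id=roi.cell_id, frame=roi.frame,
            time_min=roi.frame * stack.frame_interval / 60.0,
            centroid_x_um=roi.centroid_um[0], centroid_y_um=roi.centroid_um[1],
            length_um=geom.length_um, area_um2=geom.area_um2,
            mi=stats.mi, sdi=stats.sdi,
            cluster_present=stats.cluster_present,
            cluster_x_um=primary.centroid_um[0] if primary else math.nan,
            cluster_y_um=primary.centroid_um[1] if primary else math.nan,
            axial_s=primary.axial_s if primary else math.nan,
            cluster_area_um2=primary.area_um2 if primary else math.nan,
            n_clusters=len(clusters),
        )
        if reporter_channel is not None:
            rep = stack.channel(reporter_channel)[roi.frame]
            r0, c0, r1, c1 = roi.bbox
            row["reporter_mi"] = float(rep[r0:r1, c0:c1][roi.mask].mean())
        rows.append(row)
        observations.extend(c for c in clusters if c.is_primary)
    track_cols = ["cell_id", "frame", "time_min", "centroid_x_um",
                  "centroid_y_um", "length_um", "area_um2", "mi", "sdi",
                  "cluster_present", "cluster_x_um", "cluster_y_um",
                  "axial_s", "cluster_area_um2", "n_clusters"]
    if rows:
        tracks = pd.DataFrame.from_records(rows).sort_values(
            ["cell_id", "frame"]).reset_index(drop=True)
    else:
        tracks = pd.DataFrame(columns=track_cols)

    gate_um = p.max_step * stack.frame_interval / 10.0
    trajectories = link_clusters(observations, gate_um, p.max_gap)
    traj_rows = [
        dict(trajectory_id=i, cell_id=t.cell_id, start_frame=t.start_frame,
             end_frame=t.end_frame, n_obs=t.n_obs, mean_area_um2=t.mean_area_um2,
             speed_um_s=trajectory_speed(t, stack.frame_interval))
        for i, t in enumerate(trajectories)
    ]
    traj_summary = pd.DataFrame.from_records(traj_rows) if traj_rows else \
        pd.DataFrame(columns=["trajectory_id", "cell_id", "start_frame",
                              "end_frame", "n_obs", "mean_area_um2", "speed_um_s"])

    labels, fractions = [], None
    if classify and stack.n_frames >= 4 and not tracks.empty:
        zones = assign_pole_zones(p.pole_zone_fraction)
        labels = classify_tracks(tracks, zones, p.d_static, p.presence_min)
        if labels:
            fractions = population_fractions(labels)

    manifest = dict(
        version=__version__,
        config_hash=_config_hash(vars(p)),
        n_frames=stack.n_frames,
        n_cells=int(tracks.cell_id.nunique()) if not tracks.empty else 0,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )
    return AnalysisResult(tracks=tracks, trajectories=trajectories,
                          trajectory_summary=traj_summary, labels=labels,
                          fractions=fractions, lineage=lineage,
                          manifest=manifest)


def match_cells_to_truth(tracks: pd.DataFrame, truth: GroundTruth,
                         frame: int = 0) -> Dict[int, int]:
    """Map analysis cell ids to ground-truth cell ids by nearest centroid at
    one frame (cells sit on a fixed non-overlapping grid)."""
    obs = tracks[tracks.frame == frame]
    tru = truth.frames[truth.frames.frame == frame]
    mapping = {}
    tx = tru.cx_um.to_numpy()
    ty = tru.cy_um.to_numpy()
    tids = tru.cell_id.to_numpy()
    for row in obs.itertuples():
        d2 = (tx - row.centroid_x_um) ** 2 + (ty - row.centroid_y_um) ** 2
        mapping[int(row.cell_id)] = int(tids[int(np.argmin(d2))])
    return mapping


# ----------------------------------------------------------------------
# figure recipes


def _fig1_classification(seed: int, n_cells: int = 1000) -> dict:
    """Pattern census: the canonical 10-minute, 1-minute-interval protocol."""
    cfg = SimulationConfig(
        n_cells=n_cells, n_frames=11, frame_interval=60.0,
        nucleation_rate=0.0, seed=derive_seed(seed, 11),
    )
    stack, truth = simulate_population(cfg)
    res = run_analysis(stack)
    truth_fracs = truth.cells.pattern.value_counts(normalize=True)
    return dict(config=cfg, truth=truth, result=res,
                fractions=res.fractions,
                truth_fractions={k: float(truth_fracs.get(k, 0.0))
                                 for k in ("non-Dyn", "Dyn-1P", "Dyn-OP", "UC")})


def _fig1_speed_size(seed: int, n_cells: int = 120, rank_corr: float = -0.78,
                     motility_suppressed: bool = False) -> dict:
    """Speed-vs-size protocol: 10 s frames for 5 min, copula-matched pairs.

    Carrier cells are kept uniform (narrow length range, low brightness
    scatter): the quantity under test is the (speed, area) joint
    distribution of the clusters, and the within-cell detection threshold
    makes the measured area depend on the carrier's size and brightness,
    which would corrupt the ranks being recovered.
    """
    cfg = SimulationConfig(
        n_cells=n_cells, n_frames=31, frame_interval=10.0,
        speed_area_rank_corr=rank_corr,
        cell_length_range=(3.0, 3.4), total_intensity_cv=0.10,
        motility_suppressed=motility_suppressed,
        nucleation_rate=0.0,
        seed=derive_seed(seed, 13 if not motility_suppressed else 14),
    )
    stack, truth = simulate_population(cfg)
    res = run_analysis(stack, classify=False)
    ts = res.trajectory_summary
    # one primary trajectory per cell: the longest
    ts = ts.sort_values(["cell_id", "n_obs"], ascending=[True, False]) \
           .drop_duplicates("cell_id")
    ts = ts[(ts.n_obs >= 5) & np.isfinite(ts.speed_um_s)]
    corr = correlation(ts.speed_um_s, ts.mean_area_um2, "spearman")
    return dict(config=cfg, truth=truth, result=res, pairs=ts, spearman=corr)


def _fig2_formation(seed: int, n_cells: int = 150, n_frames: int = 21) -> dict:
    """Formation kinetics: clusterless cells watched at 3-minute intervals."""
    cfg = SimulationConfig(
        n_cells=n_cells, n_frames=n_frames, frame_interval=180.0,
        pattern_weights=(0.0, 0.0, 0.0, 1.0), nucleation_rate=0.008,
        seed=derive_seed(seed, 21),
    )
    stack, truth = simulate_population(cfg)
    res = run_analysis(stack, classify=False)
    events = []
    for cell_id, sub in res.tracks.groupby("cell_id"):
        if len(sub) >= 4:
            ev = detect_formation_event(sub)
            if ev is not None:
                events.append(ev)
    return dict(config=cfg, truth=truth, result=res, events=events)


def _fig3_frap(seed: int, endpoint_pct: float, n_cells: int,
               chloramphenicol: bool) -> dict:
    fs = FrapSettings.for_endpoint(
        endpoint_pct,
        synthesis_fraction=0.0 if chloramphenicol else 1.0 / 3.0)
    cfg = SimulationConfig(
        n_cells=n_cells, frame_interval=10.0, frap=fs, n_frames=63,
        seed=derive_seed(seed, 31 if not chloramphenicol else 32),
    )
    stack, truth = simulate_frap_stack(cfg)
    boxes = [(r.r0, r.r1, r.c0, r.c1) for r in truth.frap_rois.itertuples()]
    curves = analyze_frap_stack(stack, boxes, fs.bleach_frame)
    mean600, se600 = mean_recovery_at(curves, 600.0)
    return dict(config=cfg, truth=truth, curves=curves,
                recovery_600s=mean600, se_600s=se600)


def _fig4b_census(seed: int, n_cells: int = 300) -> dict:
    """Fraction of cells with detectable clusters across growth phases."""
    presets = {
        "EL": (0.09, 0.43, 0.11, 0.37),
        "ML": (0.12, 0.44, 0.11, 0.33),
        "SP": (0.14, 0.43, 0.10, 0.33),
        "ON": (0.40, 0.37, 0.10, 0.13),
    }
    out = {}
    for i, (phase_name, weights) in enumerate(presets.items()):
        cfg = SimulationConfig(
            n_cells=n_cells, n_frames=11, pattern_weights=weights,
            nucleation_rate=0.0, seed=derive_seed(seed, 41 + i),
        )
        stack, truth = simulate_population(cfg)
        res = run_analysis(stack)
        out[phase_name] = dict(fractions=res.fractions,
                               detectable=float(res.fractions["detectable"]))
    return out


def _fig5a_quiescence(seed: int, n_cells: int = 269) -> dict:
    """Time-0 sub-population census of a quiescence-exit population."""
    cfg = SimulationConfig(
        n_cells=n_cells, n_frames=1, frame_interval=60.0, growth_rate=0.0,
        cell_length_range=(2.3, 3.0), total_intensity_cv=0.12,
        seed=derive_seed(seed, 51),
    )
    stack, truth = simulate_quiescence_exit(cfg)
    res = run_analysis(stack, classify=False)
    t0 = res.tracks[res.tracks.frame == 0]
    classified = classify_quiescence_subpopulations(t0)
    return dict(config=cfg, truth=truth, result=res, classified=classified,
                fractions=classified.attrs["fractions"])


def _fig5_sisters(seed: int, n_divisions: int = 200) -> dict:
    """Division experiment: inheritance of the cluster by one or both sisters."""
    cfg = SimulationConfig(
        n_cells=n_divisions, n_frames=12, frame_interval=180.0,
        cell_length_range=(4.2, 4.8), growth_rate=0.05,
        allow_division=True, nucleate_after_division=False,
        pattern_weights=(0.0, 1.0, 0.0, 0.0), nucleation_rate=0.0,
        seed=derive_seed(seed, 52),
    )
    stack, truth = simulate_population(cfg)
    res = run_analysis(stack, classify=False)
    status = sister_cluster_status(res.tracks, res.lineage)
    return dict(config=cfg, truth=truth, result=res, status=status)


def _fig5cd_reporter(seed: int, n_cells: int = 500,
                     rank_corr: float = -0.16) -> dict:
    """Reporter-uptake vs. clustering correlation on a quiescence population."""
    cfg = SimulationConfig(
        n_cells=n_cells, n_frames=1, growth_rate=0.0,
        cell_length_range=(2.3, 3.0), total_intensity_cv=0.12,
        qx_phi_continuous=(0.05, 0.70), reporter_rank_corr=rank_corr,
        seed=derive_seed(seed, 53 if rank_corr != 0 else 54),
    )
    stack, truth = simulate_quiescence_exit(cfg)
    res = run_analysis(stack, classify=False)
    t0 = res.tracks[res.tracks.frame == 0]
    corr = reporter_vs_clustering(t0)
    return dict(config=cfg, truth=truth, result=res, pearson=corr)


FIGURE_IDS = ("fig1", "fig2", "fig3", "fig4b", "fig5a", "fig5cd")


def run_figure_suite(which: str, seed: int = 0, out=None, **kwargs) -> dict:
    """Run the preconfigured simulate-and-analyze recipe for one figure
    analogue and return its summary quantities."""
    if which == "fig1":
        census = _fig1_classification(seed, kwargs.get("n_cells", 1000))
        speed = _fig1_speed_size(seed)
        dnp = _fig1_speed_size(seed, motility_suppressed=True)
        bundle = dict(
            fractions={k: float(census["fractions"][k])
                       for k in ("non-Dyn", "Dyn-1P", "Dyn-OP", "UC")},
            speed_size_spearman=speed["spearman"].coefficient,
            dnp_spearman=dnp["spearman"].coefficient,
            dnp_p=dnp["spearman"].p_value,
        )
    elif which == "fig2":
        r = _fig2_formation(seed)
        bundle = dict(n_events=len(r["events"]),
                      formation_times=[e.time_min for e in r["events"]])
    elif which == "fig3":
        unt = _fig3_frap(seed, 6.0, 14, chloramphenicol=False)
        cm = _fig3_frap(seed, 4.0, 12, chloramphenicol=True)
        bundle = dict(untreated_600s=unt["recovery_600s"],
                      chloramphenicol_600s=cm["recovery_600s"])
    elif which == "fig4b":
        r = _fig4b_census(seed)
        bundle = {phase: v["detectable"] for phase, v in r.items()}
    elif which == "fig5a":
        r = _fig5a_quiescence(seed)
        bundle = dict(fractions=r["fractions"])
    elif which == "fig5cd":
        anti = _fig5cd_reporter(seed, 500, -0.16)
        null = _fig5cd_reporter(seed, 222, 0.0)
        bundle = dict(pearson=anti["pearson"].coefficient,
                      pearson_null=null["pearson"].coefficient)
    else:
        raise ValueError(f"unknown figure id {which!r}; choose from {FIGURE_IDS}")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{which}_summary.json").write_text(
            json.dumps(bundle, indent=2, default=float))
    return bundle
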
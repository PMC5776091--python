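"""Ground-truthed synthetic time-lapse generator.

The generative model: rod-shaped cells (rectangle with semicircular caps) laid
out on a non-overlapping grid, each carrying a per-cell fluorophore budget
split between a uniform diffuse cytoplasmic pool and at most one compact
polar cluster rendered as a 2-D Gaussian spot.  The split is exact, so the
per-cell summed intensity is conserved across cluster formation and motion in
noise-free renders.  Cluster centroids perform a confined random walk whose
per-step expected speed follows the power law v0 * (A_ref / A)**alpha, with
reflection inside a pole zone (Dyn-1P), the whole cell (Dyn-OP), or no motion
at all (non-Dyn).  Clusterless (UC) cells nucleate a new cluster after an
exponential waiting time, independent of cell length, with the cluster
fraction ramping up linearly over ``formation_duration`` so that the diffuse
pool is depleted exactly as the cluster grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    PATTERNS,
    ConfigurationError,
    GeometryError,
    SimulationConfig,
)
from .stack import ImageStack

PRESENCE_EPS = 1e-6  # phi above this counts as "a cluster exists" in truth
DIVISION_GAP = 0.3   # um of clear space between newborn sisters


class StateError(ValueError):
    """Raised when a cell state cannot be rendered (overlap, spot outside)."""


# ----------------------------------------------------------------------
# small utilities


def _fold(x: np.ndarray | float, lo: float, hi: float):
    """Reflect ``x`` into [lo, hi] (handles excursions beyond one width)."""
    if hi <= lo:
        return np.clip(x, lo, hi) if np.ndim(x) else min(max(x, lo), hi)
    width = hi - lo
    y = np.mod(np.asarray(x, dtype=float) - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    out = lo + y
    return float(out) if np.ndim(x) == 0 else out


def latent_corr_for_spearman(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula that yields a target
    Spearman rank correlation (rho_lat = 2 sin(pi * rho_s / 6))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def gaussian_copula_pair(
    x: np.ndarray, rank_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal scores with the requested rank correlation against x.

    At |rank_corr| == 1 the pairing is exactly (anti)monotone.
    """
    n = len(x)
    ranks = pd.Series(x).rank(method="average").to_numpy()
    u = (ranks - 0.5) / n
    z1 = norm.ppf(u)
    if abs(rank_corr) >= 1.0:
        return np.sign(rank_corr) * z1
    rho = latent_corr_for_spearman(rank_corr)
    return rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)


def _largest_remainder_counts(weights, n: int) -> np.ndarray:
    """Integer class counts summing to n, proportional to weights."""
    w = np.asarray(weights, dtype=float)
    raw = w * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def rod_area_um2(length: float, width: float) -> float:
    """Area of a rod silhouette (rectangle plus semicircular caps)."""
    return (length - width) * width + math.pi * (width / 2.0) ** 2


def cluster_footprint_area(sigma: float) -> float:
    """Ground-truth cluster area (um^2): the bright-core footprint
    pi*(1.5*sigma)^2 of a Gaussian spot of width sigma."""
    return math.pi * (1.5 * sigma) ** 2


def sigma_for_area(area: float) -> float:
    return math.sqrt(area / math.pi) / 1.5


# ----------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Everything the generator knows: per-cell metadata, per-frame state,
    the configuration echo and the seed."""

    cells: pd.DataFrame
    frames: pd.DataFrame
    config: SimulationConfig
    seed: int
    frap_truth: Optional[pd.DataFrame] = None
    frap_rois: Optional[pd.DataFrame] = None
    reporter: Optional[pd.DataFrame] = None

    def true_mask(self, cell_id: int, frame: int, shape: Tuple[int, int]) -> np.ndarray:
        """Regenerate the boolean pixel mask of one cell at one frame."""
        row = self.frames[
            (self.frames.cell_id == cell_id) & (self.frames.frame == frame)
        ]
        if row.empty:
            raise KeyError(f"cell {cell_id} not present at frame {frame}")
        row = row.iloc[0]
        ps = self.config.pixel_size
        mask = np.zeros(shape, dtype=bool)
        sl, m = _rod_mask(
            row.cx_um, row.cy_um, row.length_um, self.config.cell_width, ps, shape
        )
        mask[sl] = m
        return mask

    def to_csvs(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.frames.to_csv(out / "frames.csv", index=False)
        if self.frap_truth is not None:
            self.frap_truth.to_csv(out / "frap_truth.csv", index=False)
        if self.reporter is not None:
            self.reporter.to_csv(out / "reporter_truth.csv", index=False)
        self.config.to_yaml(out / "config_echo.yaml")


# ----------------------------------------------------------------------
# geometry and rendering


def _rod_mask(cx, cy, length, width, ps, shape):
    """Boolean rod mask (rectangle + caps) on the pixel grid.

    Returns (slices, local_mask); pixel centers sit at (i + 0.5) * ps.
    """
    H, W = shape
    half = length / 2.0 + ps
    r0 = max(int((cy - width / 2 - ps) / ps), 0)
    r1 = min(int((cy + width / 2 + ps) / ps) + 2, H)
    c0 = max(int((cx - half) / ps), 0)
    c1 = min(int((cx + half) / ps) + 2, W)
    ys = (np.arange(r0, r1) + 0.5) * ps
    xs = (np.arange(c0, c1) + 0.5) * ps
    X, Y = np.meshgrid(xs, ys)
    seg_half = max(length - width, 0.0) / 2.0
    dx = X - np.clip(X, cx - seg_half, cx + seg_half)
    dy = Y - cy
    mask = dx * dx + dy * dy <= (width / 2.0) ** 2
    return (slice(r0, r1), slice(c0, c1)), mask


def render_cell_frame(cell_state: dict, config: SimulationConfig):
    """Render one cell into a local patch pair (cell-body, fluorophore).

    ``cell_state`` needs: cx_um, cy_um, length_um, phi, budget, and, when
    phi > 0, cluster_x_um / cluster_y_um / sigma_um.  Coordinates are
    patch-local micrometers.  The fluorophore patch integrates (noise-free)
    to the cell's budget; a cluster centroid outside the cell mask raises
    :class:`StateError`.
    """
    ps = config.pixel_size
    length = cell_state["length_um"]
    cx, cy = cell_state["cx_um"], cell_state["cy_um"]
    H = int(np.ceil((cy + config.cell_width) / ps)) + 2
    W = int(np.ceil((cx + length / 2 + config.cell_width) / ps)) + 2
    phase = np.zeros((H, W), dtype=np.float32)
    fluor = np.zeros((H, W), dtype=np.float32)
    _paint_cell(phase, fluor, cell_state, config)
    return phase, fluor


def _paint_cell(phase, fluor, st, config, label_canvas=None, label=0):
    ps = config.pixel_size
    sl, mask = _rod_mask(
        st["cx_um"], st["cy_um"], st["length_um"], config.cell_width, ps, phase.shape
    )
    npx = int(mask.sum())
    if npx == 0:
        raise GeometryError("cell fell outside the image")
    if label_canvas is not None:
        region = label_canvas[sl]
        if np.any(region[mask] != 0):
            raise StateError("cell masks overlap")
        region[mask] = label
    phase[sl][mask] += config.phase_amplitude
    budget = st["budget"]
    phi = float(st.get("phi", 0.0))
    fluor_patch = fluor[sl]
    fluor_patch[mask] += (1.0 - phi) * budget / npx
    if phi > PRESENCE_EPS:
        r0, c0 = sl[0].start, sl[1].start
        ys = (np.arange(sl[0].start, sl[0].stop) + 0.5) * ps
        xs = (np.arange(sl[1].start, sl[1].stop) + 0.5) * ps
        X, Y = np.meshgrid(xs, ys)
        clx, cly = st["cluster_x_um"], st["cluster_y_um"]
        # centroid must sit on a mask pixel
        ri = int(cly / ps) - r0
        ci = int(clx / ps) - c0
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
            raise StateError("cluster centroid outside the cell mask")
        sig = st["sigma_um"]
        g = np.exp(-((X - clx) ** 2 + (Y - cly) ** 2) / (2.0 * sig * sig))
        g = np.where(mask, g, 0.0)
        g_sum = g.sum()
        fluor_patch += (phi * budget / g_sum * g).astype(np.float32)


def _render_frames(records: pd.DataFrame, config: SimulationConfig,
                   shape: Tuple[int, int], rng: np.random.Generator,
                   reporter_means: Optional[dict] = None) -> ImageStack:
    n_frames = int(records.frame.max()) + 1
    channels = ["phase", "mcherry"] + (["reporter"] if reporter_means else [])
    data = np.zeros((n_frames, len(channels), *shape), dtype=np.float32)
    for f in range(n_frames):
        phase = data[f, 0]
        fluor = data[f, 1]
        labels = np.zeros(shape, dtype=np.int32)
        sub = records[records.frame == f]
        for row in sub.itertuples():
            st = {
                "cx_um": row.cx_um, "cy_um": row.cy_um, "length_um": row.length_um,
                "phi": row.phi, "budget": row.budget,
                "cluster_x_um": row.cluster_x_um, "cluster_y_um": row.cluster_y_um,
                "sigma_um": row.sigma_um,
            }
            _paint_cell(phase, fluor, st, config, labels, int(row.cell_id) + 1)
            if reporter_means:
                sl, mask = _rod_mask(row.cx_um, row.cy_um, row.length_um,
                                     config.cell_width, config.pixel_size, shape)
                data[f, 2][sl][mask] += reporter_means.get(int(row.cell_id), 0.0)
        fluor += config.background_level
        phase += config.background_level
        if reporter_means:
            data[f, 2] += config.background_level
    if config.read_noise_sd > 0:
        data += rng.normal(0.0, config.read_noise_sd, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)
    return ImageStack(data=data, pixel_size=config.pixel_size,
                      frame_interval=config.frame_interval, channels=channels)


def _grid_layout(config: SimulationConfig, n_cells: int, total_min: float):
    ps = config.pixel_size
    pad = 6  # px of clear background around every slot
    if config.allow_division:
        max_len = config.division_length + config.growth_rate * total_min + DIVISION_GAP
    else:
        max_len = config.cell_length_range[1] + config.growth_rate * total_min
    slot_w = int(np.ceil(max_len / ps)) + 2 * pad
    slot_h = int(np.ceil(config.cell_width / ps)) + 2 * pad
    cols = int(np.ceil(np.sqrt(n_cells * slot_h / slot_w)))
    cols = max(cols, 1)
    rows = int(np.ceil(n_cells / cols))
    shape = (rows * slot_h, cols * slot_w)
    if config.image_shape is not None:
        if config.image_shape[0] < shape[0] or config.image_shape[1] < shape[1]:
            raise GeometryError(
                f"image_shape {config.image_shape} too small for "
                f"{n_cells} cells (need >= {shape})"
            )
        shape = tuple(config.image_shape)
    centers = []
    for i in range(n_cells):
        r, c = divmod(i, cols)
        centers.append(((c + 0.5) * slot_w * ps, (r + 0.5) * slot_h * ps))
    return shape, centers


# ----------------------------------------------------------------------
# population simulation


def _assign_patterns(config: SimulationConfig, rng: np.random.Generator) -> List[str]:
    counts = _largest_remainder_counts(config.pattern_weights, config.n_cells)
    labels = np.repeat(np.array(PATTERNS, dtype=object), counts)
    rng.shuffle(labels)
    return list(labels)


def _cell_speed(config: SimulationConfig, area: float, rng) -> float:
    if config.motility_suppressed:
        # DNP: small size-independent residual, same cell-to-cell scatter
        v = 0.05 * config.speed_coefficient
    else:
        v = config.speed_coefficient * (
            config.reference_area / area) ** config.speed_exponent
    if config.speed_noise_cv > 0:
        v *= float(np.exp(rng.normal(0.0, config.speed_noise_cv)))
    return v


def _step_cluster(x, y, cx, cy, length, width, speed, dt, lo, hi, rng, moving):
    """One random-walk step of the cluster centroid, reflected into the axial
    window [lo, hi] (absolute um) and a narrow transverse band."""
    if moving and speed > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = speed * dt
        x = x + step * math.cos(theta)
        y = y + step * math.sin(theta)
    x = _fold(x, lo, hi)
    y = _fold(y, cy - width / 4.0, cy + width / 4.0)
    return x, y


def simulate_population(config: SimulationConfig):
    """Simulate a population and render it; returns (ImageStack, GroundTruth).

    Pattern labels follow ``pattern_weights`` (exact largest-remainder
    allocation, shuffled).  UC cells nucleate with exponential waiting times
    at ``nucleation_rate`` independent of cell length; formation transfers
    intensity from the diffuse pool so the per-cell budget is conserved
    within each frame.  With ``allow_division`` a mother splits at
    ``division_length``, the cluster going to a single daughter with
    probability ``inherit_single_prob``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n0 = config.n_cells
    dt_min = config.frame_interval / 60.0
    total_min = (config.n_frames - 1) * dt_min
    shape, centers = _grid_layout(config, n0, total_min)

    copula_mode = config.speed_area_rank_corr is not None
    patterns = (["Dyn-OP"] * n0) if copula_mode else _assign_patterns(config, rng)

    if copula_mode:
        mu_a, sd_a = config.area_lognorm
        areas = np.exp(rng.normal(mu_a, sd_a, size=n0))
        z2 = gaussian_copula_pair(areas, config.speed_area_rank_corr, rng)
        mu_v, sd_v = config.speed_lognorm
        speeds = np.exp(mu_v + sd_v * z2)
        if config.motility_suppressed:
            speeds = 0.05 * config.speed_coefficient * np.exp(
                rng.normal(0.0, config.speed_noise_cv, size=n0))

    f_lo, f_hi = config.cluster_fraction_range

    cells: List[dict] = []
    for i, pat in enumerate(patterns):
        cx, cy = centers[i]
        L0 = rng.uniform(*config.cell_length_range)
        budget = max(
            rng.normal(config.total_intensity_mean,
                       config.total_intensity_mean * config.total_intensity_cv),
            0.1 * config.total_intensity_mean,
        )
        side = -1 if rng.random() < 0.5 else 1
        if copula_mode:
            area = float(areas[i])
            sigma = sigma_for_area(area)
            phi = 0.4
            speed = float(speeds[i])
        elif pat == "UC":
            # phenotype of the cluster that forms if/when the cell nucleates
            pc = config.pattern_clusters["Dyn-1P"]
            phi = float(np.clip(pc["phi"] * rng.uniform(0.85, 1.15), f_lo, f_hi))
            sigma = pc["sigma"] * rng.uniform(0.9, 1.1)
            area = cluster_footprint_area(sigma)
            speed = _cell_speed(config, area, rng)
        else:
            pc = config.pattern_clusters[pat]
            phi = float(np.clip(pc["phi"] * rng.uniform(0.85, 1.15), f_lo, f_hi))
            sigma = pc["sigma"] * rng.uniform(0.9, 1.1)
            area = cluster_footprint_area(sigma)
            speed = 0.0 if pat == "non-Dyn" else _cell_speed(config, area, rng)
        t_nuc = math.inf
        if pat == "UC" and config.nucleation_rate > 0:
            t_nuc = rng.exponential(1.0 / config.nucleation_rate)
        cells.append(dict(
            cell_id=i, pattern=pat, parent_id=-1, sister_id=-1,
            birth_frame=0, birth_min=0.0, division_frame=-1,
            cx=cx, cy=cy, L0=L0, budget=budget, phi_target=phi,
            sigma=sigma, area=area, speed=speed, side=side,
            nucleation_min=t_nuc, qx_class="",
            born_with_cluster=(pat != "UC") or copula_mode,
            anchor_x=None, grow_dir=0,
            x_c=math.nan, y_c=cy, alive=True,
        ))

    records: List[dict] = []
    next_id = n0
    w = config.cell_width
    m = w / 2.0  # axial margin keeping the spot inside the caps

    def center_at(cell, L):
        # daughters keep their septum-side pole fixed and elongate outward
        anchor = cell.get("anchor_x")
        if anchor is None:
            return cell["cx"]
        return anchor + cell["grow_dir"] * L / 2.0

    def axial_window(cell, L, cx):
        if cell["pattern"] == "Dyn-1P" or (cell["pattern"] == "UC"):
            f = config.pole_zone_fraction
            if cell["side"] < 0:
                return cx - L / 2 + m, cx - L / 2 + f * L
            return cx + L / 2 - f * L, cx + L / 2 - m
        return cx - L / 2 + m, cx + L / 2 - m

    for f_idx in range(config.n_frames):
        t_min = f_idx * dt_min
        # --- divisions first, so daughters are recorded this frame
        if config.allow_division:
            for cell in list(cells):
                if not cell["alive"] or cell["parent_id"] >= 0:
                    continue
                L = cell["L0"] + config.growth_rate * (t_min - cell["birth_min"])
                if L < config.division_length:
                    continue
                cell["alive"] = False
                cell["division_frame"] = f_idx
                budget_now = cell["budget"] * (rod_area_um2(L, config.cell_width)
                                               / rod_area_um2(cell["L0"],
                                                              config.cell_width))
                Ld = (L - DIVISION_GAP) / 2.0
                d_ids = (next_id, next_id + 1)
                next_id += 2
                phi_m = _phi_at(cell, t_min, config)
                carriers: Tuple[float, float]
                if phi_m > PRESENCE_EPS:
                    if rng.random() < config.inherit_single_prob:
                        which = 0 if rng.random() < 0.5 else 1
                        carriers = (phi_m if which == 0 else 0.0,
                                    phi_m if which == 1 else 0.0)
                        split_sigma = cell["sigma"]
                    else:
                        carriers = (phi_m / 2.0, phi_m / 2.0)
                        split_sigma = cell["sigma"] * 0.8
                else:
                    carriers = (0.0, 0.0)
                    split_sigma = cell["sigma"]
                for d in (0, 1):
                    off = (-(Ld + DIVISION_GAP) / 2.0, (Ld + DIVISION_GAP) / 2.0)[d]
                    dcx = cell["cx"] + off
                    septum = cell["cx"] + (-DIVISION_GAP / 2.0 if d == 0
                                           else DIVISION_GAP / 2.0)
                    amount = carriers[d] * budget_now
                    d_budget = budget_now / 2.0
                    d_phi = min(amount / d_budget, 0.85) if amount > 0 else 0.0
                    side = -1 if d == 0 else 1
                    t_nuc = math.inf
                    if (d_phi == 0.0 and config.nucleate_after_division
                            and config.nucleation_rate > 0):
                        t_nuc = t_min + rng.exponential(1.0 / config.nucleation_rate)
                    d_sigma = split_sigma if d_phi > 0 else 0.12
                    d_area = cluster_footprint_area(d_sigma)
                    cells.append(dict(
                        cell_id=d_ids[d],
                        pattern="Dyn-1P" if d_phi > 0 else "UC",
                        parent_id=cell["cell_id"], sister_id=d_ids[1 - d],
                        birth_frame=f_idx, birth_min=t_min, division_frame=-1,
                        cx=dcx, cy=cell["cy"], L0=Ld, budget=d_budget,
                        phi_target=d_phi, sigma=d_sigma, area=d_area,
                        speed=_cell_speed(config, d_area, rng) if d_phi > 0 else 0.0,
                        side=side, nucleation_min=t_nuc, qx_class="",
                        born_with_cluster=d_phi > 0,
                        anchor_x=septum, grow_dir=(-1 if d == 0 else 1),
                        x_c=dcx + side * (Ld / 2.0 - m), y_c=cell["cy"], alive=True,
                    ))
        # --- record living cells
        for cell in cells:
            if not cell["alive"]:
                continue
            age = t_min - cell["birth_min"]
            L = cell["L0"] + config.growth_rate * age
            cx_t = center_at(cell, L)
            # synthesis keeps the concentration constant during growth
            # (the measured mean intensity stays flat, as in real cells)
            budget_t = cell["budget"] * (rod_area_um2(L, w)
                                         / rod_area_um2(cell["L0"], w))
            phi_t = _phi_at(cell, t_min, config)
            if phi_t > PRESENCE_EPS and math.isnan(cell["x_c"]):
                # cluster just nucleated: place it at the cell's pole
                cell["x_c"] = cx_t + cell["side"] * (L / 2.0 - m)
                cell["y_c"] = cell["cy"]
            if phi_t > PRESENCE_EPS:
                lo, hi = axial_window(cell, L, cx_t)
                moving = cell["pattern"] != "non-Dyn" and f_idx > cell["birth_frame"]
                cell["x_c"], cell["y_c"] = _step_cluster(
                    cell["x_c"], cell["y_c"], cx_t, cell["cy"], L, w,
                    cell["speed"], config.frame_interval, lo, hi, rng, moving)
            tip = cx_t - L / 2.0
            axial = (cell["x_c"] - tip) / L if phi_t > PRESENCE_EPS else math.nan
            records.append(dict(
                cell_id=cell["cell_id"], frame=f_idx, time_min=t_min,
                cx_um=cx_t, cy_um=cell["cy"], length_um=L,
                budget=budget_t, phi=phi_t,
                cluster_present=phi_t > PRESENCE_EPS,
                cluster_x_um=cell["x_c"] if phi_t > PRESENCE_EPS else math.nan,
                cluster_y_um=cell["y_c"] if phi_t > PRESENCE_EPS else math.nan,
                sigma_um=cell["sigma"], cluster_area_um2=cell["area"]
                if phi_t > PRESENCE_EPS else math.nan,
                axial_s=axial, speed_um_s=cell["speed"],
            ))

    frames = pd.DataFrame.from_records(records)
    meta = pd.DataFrame.from_records([
        dict(
            cell_id=c["cell_id"], pattern=c["pattern"], qx_class=c["qx_class"],
            parent_id=c["parent_id"], sister_id=c["sister_id"],
            birth_frame=c["birth_frame"], division_frame=c["division_frame"],
            budget=c["budget"], phi_target=c["phi_target"], sigma_um=c["sigma"],
            cluster_area_um2=c["area"], speed_um_s=c["speed"],
            nucleation_min=(c["nucleation_min"] - c["birth_min"])
            if math.isfinite(c["nucleation_min"]) else math.nan,
            formation_complete_min=(c["nucleation_min"] - c["birth_min"]
                                    + config.formation_duration)
            if math.isfinite(c["nucleation_min"]) else math.nan,
            born_with_cluster=c["born_with_cluster"],
            birth_length_um=c["L0"],
        )
        for c in cells
    ])
    truth = GroundTruth(cells=meta, frames=frames, config=config, seed=config.seed)

    reporter_means = None
    if config.reporter_rank_corr is not None:
        rep = simulate_reporter_channel(truth, config)
        truth.reporter = rep
        reporter_means = dict(zip(rep.cell_id, rep.reporter_mean))

    stack = _render_frames(frames, config, shape, rng, reporter_means)
    return stack, truth


def _phi_at(cell: dict, t_min: float, config: SimulationConfig) -> float:
    """Current cluster fraction of one cell, honoring formation ramps and
    (for quiescence-exit cells) linear dispersal and optional re-formation."""
    cls = cell.get("qx_class", "")
    if cls == "":
        if cell["born_with_cluster"]:
            return cell["phi_target"]
        t_n = cell["nucleation_min"]
        if not math.isfinite(t_n) or t_min < t_n:
            return 0.0
        ramp = min((t_min - t_n) / config.formation_duration, 1.0) \
            if config.formation_duration > 0 else 1.0
        return cell["phi_target"] * ramp
    # quiescence-exit kinetics
    if cls == "no-cluster":
        t_n = cell["nucleation_min"]
        if not math.isfinite(t_n) or t_min < t_n:
            return 0.0
        ramp = min((t_min - t_n) / config.formation_duration, 1.0) \
            if config.formation_duration > 0 else 1.0
        return cell["phi_target"] * ramp
    if cls == "big" or not cell["disperses"]:
        return cell["phi_target"]
    # small, dispersing: linear loss from time 0
    phi = cell["phi_target"] * max(0.0, 1.0 - config.dispersal_rate * t_min)
    if phi <= 0.0 and cell.get("reform_min") is not None:
        t_r = cell["reform_min"]
        if math.isfinite(t_r) and t_min >= t_r:
            ramp = min((t_min - t_r) / config.formation_duration, 1.0) \
                if config.formation_duration > 0 else 1.0
            return cell["reform_phi"] * ramp
    return phi


# ----------------------------------------------------------------------
# quiescence-exit (overnight) population


def simulate_quiescence_exit(config: SimulationConfig):
    """Simulate cells exiting quiescence: three sub-populations at time 0
    (no cluster / small cluster / big cluster at ``qx_class_weights``), with
    small clusters dispersing linearly at ``dispersal_rate`` in a
    ``qx_disperse_prob`` fraction of cells and optionally re-forming."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    dt_min = config.frame_interval / 60.0
    total_min = (config.n_frames - 1) * dt_min
    shape, centers = _grid_layout(config, n, total_min)

    if config.qx_phi_continuous is not None:
        classes = np.array(["continuous"] * n, dtype=object)
    else:
        counts = _largest_remainder_counts(config.qx_class_weights, n)
        classes = np.repeat(np.array(["no-cluster", "small", "big"], dtype=object),
                            counts)
        rng.shuffle(classes)

    cells = []
    for i, cls in enumerate(classes):
        cx, cy = centers[i]
        L0 = rng.uniform(*config.cell_length_range)
        budget = max(
            rng.normal(config.total_intensity_mean,
                       config.total_intensity_mean * config.total_intensity_cv),
            0.1 * config.total_intensity_mean,
        )
        side = -1 if rng.random() < 0.5 else 1
        if cls == "continuous":
            lo, hi = config.qx_phi_continuous
            phi = float(rng.uniform(lo, hi))
            # droplet-like scaling: footprint grows with cluster content
            # (area ~ content^(2/3), i.e. sigma ~ phi^(1/3))
            sigma = max(0.08, 0.22 * (phi / 0.7) ** (1.0 / 3.0)
                        * rng.uniform(0.95, 1.05))
        elif cls == "no-cluster":
            phi, sigma = 0.0, 0.13
        elif cls == "small":
            phi = float(np.clip(rng.normal(config.qx_phi_small, 0.02), 0.08, 0.30))
            sigma = 0.12 * rng.uniform(0.95, 1.05)
        else:
            phi = float(np.clip(rng.normal(config.qx_phi_big, 0.04), 0.55, 0.85))
            sigma = 0.22 * rng.uniform(0.95, 1.05)
        area = cluster_footprint_area(sigma)
        disperses = bool(cls == "small" and rng.random() < config.qx_disperse_prob)
        t_nuc = math.inf
        if cls == "no-cluster" and config.nucleation_rate > 0:
            t_nuc = rng.exponential(1.0 / config.nucleation_rate)
        reform_min = math.inf
        if disperses and config.qx_reform and config.dispersal_rate > 0:
            t_zero = 1.0 / config.dispersal_rate
            reform_min = t_zero + rng.exponential(1.0 / max(config.nucleation_rate, 1e-9))
        cells.append(dict(
            cell_id=i, pattern="Dyn-1P" if phi > 0 else "UC", qx_class=cls,
            parent_id=-1, sister_id=-1, birth_frame=0, birth_min=0.0,
            division_frame=-1, cx=cx, cy=cy, L0=L0, budget=budget,
            phi_target=phi, sigma=sigma, area=area,
            speed=_cell_speed(config, area, rng) if phi > 0 else 0.0,
            side=side, nucleation_min=t_nuc, disperses=disperses,
            reform_min=reform_min, reform_phi=0.3, born_with_cluster=phi > 0,
            x_c=cx + side * (L0 / 2 - config.cell_width / 2) if phi > 0 else math.nan,
            y_c=cy, alive=True,
        ))

    records = []
    w = config.cell_width
    m = w / 2.0
    for f_idx in range(config.n_frames):
        t_min = f_idx * dt_min
        for cell in cells:
            L = cell["L0"] + config.growth_rate * t_min
            phi_t = _phi_at(cell, t_min, config)
            if phi_t > PRESENCE_EPS and math.isnan(cell["x_c"]):
                cell["x_c"] = cell["cx"] + cell["side"] * (L / 2.0 - m)
                cell["y_c"] = cell["cy"]
            if phi_t > PRESENCE_EPS:
                f = config.pole_zone_fraction
                if cell["side"] < 0:
                    lo, hi = cell["cx"] - L / 2 + m, cell["cx"] - L / 2 + f * L
                else:
                    lo, hi = cell["cx"] + L / 2 - f * L, cell["cx"] + L / 2 - m
                cell["x_c"], cell["y_c"] = _step_cluster(
                    cell["x_c"], cell["y_c"], cell["cx"], cell["cy"], L, w,
                    cell["speed"], config.frame_interval, lo, hi, rng, f_idx > 0)
            tip = cell["cx"] - L / 2.0
            budget_t = cell["budget"] * (rod_area_um2(L, w)
                                         / rod_area_um2(cell["L0"], w))
            records.append(dict(
                cell_id=cell["cell_id"], frame=f_idx, time_min=t_min,
                cx_um=cell["cx"], cy_um=cell["cy"], length_um=L,
                budget=budget_t, phi=phi_t,
                cluster_present=phi_t > PRESENCE_EPS,
                cluster_x_um=cell["x_c"] if phi_t > PRESENCE_EPS else math.nan,
                cluster_y_um=cell["y_c"] if phi_t > PRESENCE_EPS else math.nan,
                sigma_um=cell["sigma"],
                cluster_area_um2=cell["area"] if phi_t > PRESENCE_EPS else math.nan,
                axial_s=(cell["x_c"] - tip) / L if phi_t > PRESENCE_EPS else math.nan,
                speed_um_s=cell["speed"],
            ))

    frames = pd.DataFrame.from_records(records)
    meta = pd.DataFrame.from_records([
        dict(cell_id=c["cell_id"], pattern=c["pattern"], qx_class=c["qx_class"],
             parent_id=-1, sister_id=-1, birth_frame=0, division_frame=-1,
             budget=c["budget"], phi_target=c["phi_target"], sigma_um=c["sigma"],
             cluster_area_um2=c["area"], speed_um_s=c["speed"],
             nucleation_min=c["nucleation_min"]
             if math.isfinite(c["nucleation_min"]) else math.nan,
             formation_complete_min=(c["nucleation_min"] + config.formation_duration)
             if math.isfinite(c["nucleation_min"]) else math.nan,
             disperses=c["disperses"],
             reform_min=c["reform_min"] if math.isfinite(c["reform_min"]) else math.nan,
             born_with_cluster=c["born_with_cluster"], birth_length_um=c["L0"])
        for c in cells
    ])
    truth = GroundTruth(cells=meta, frames=frames, config=config, seed=config.seed)

    reporter_means = None
    if config.reporter_rank_corr is not None:
        rep = simulate_reporter_channel(truth, config)
        truth.reporter = rep
        reporter_means = dict(zip(rep.cell_id, rep.reporter_mean))
    stack = _render_frames(frames, config, shape, rng, reporter_means)
    return stack, truth


# ----------------------------------------------------------------------
# reporter channel


def simulate_reporter_channel(ground_truth: GroundTruth,
                              config: SimulationConfig) -> pd.DataFrame:
    """Per-cell reporter means with the configured rank correlation against
    the cell's true clustering level (cluster fraction at time 0).

    Uses a Gaussian copula; the marginal is Normal(reporter_mean,
    reporter_cv * reporter_mean), clipped at zero.
    """
    if config.reporter_rank_corr is None:
        raise ConfigurationError("reporter_rank_corr is not set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7115]))
    t0 = ground_truth.frames[ground_truth.frames.frame == 0]
    phi = t0.set_index("cell_id").phi
    z2 = gaussian_copula_pair(phi.to_numpy(), config.reporter_rank_corr, rng)
    means = config.reporter_mean + config.reporter_cv * config.reporter_mean * z2
    means = np.clip(means, 0.0, None)
    return pd.DataFrame({"cell_id": phi.index.to_numpy(),
                         "clustering_level": phi.to_numpy(),
                         "reporter_mean": means})


# ----------------------------------------------------------------------
# FRAP


def simulate_frap_stack(config: SimulationConfig):
    """Render a photobleaching experiment on static polar-cluster cells.

    Each of ``n_cells`` cells carries one static polar cluster.  At
    ``frap.bleach_frame`` the pole region of interest loses
    ``bleach_efficiency`` of its signal; afterwards the pole recovers by
    exchange with the unbleached diffuse pool (plus the configured de novo
    synthesis component) such that the pipeline's double-normalized recovery
    equals A_total * (1 - exp(-k t)).  Frames are ``frame_interval`` apart
    (10 s by default) and ground truth stores the analytic curve.
    """
    if config.frap is None:
        raise ConfigurationError("config.frap must be set for a FRAP simulation")
    fs = config.frap
    fs.validate()
    n_frames = fs.bleach_frame + fs.n_postbleach_frames
    config = config.replace(n_frames=n_frames, allow_division=False)
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    shape, centers = _grid_layout(config, n, 0.0)
    ps = config.pixel_size
    w = config.cell_width

    cells = []
    for i, (cx, cy) in enumerate(centers):
        L0 = rng.uniform(*config.cell_length_range)
        budget = max(
            rng.normal(config.total_intensity_mean,
                       config.total_intensity_mean * config.total_intensity_cv),
            0.1 * config.total_intensity_mean,
        )
        phi = 0.6
        sigma = 0.2
        cells.append(dict(cell_id=i, cx=cx, cy=cy, L0=L0, budget=budget,
                          phi=phi, sigma=sigma,
                          x_c=cx - (L0 / 2 - w / 2), y_c=cy))

    # noise-free signal image of the static scene + per-cell masks/ROIs
    signal = np.zeros(shape, dtype=np.float64)
    phase = np.zeros(shape, dtype=np.float32)
    masks = []
    rois = []
    for c in cells:
        st = dict(cx_um=c["cx"], cy_um=c["cy"], length_um=c["L0"], phi=c["phi"],
                  budget=c["budget"], cluster_x_um=c["x_c"],
                  cluster_y_um=c["y_c"], sigma_um=c["sigma"])
        buf = np.zeros(shape, dtype=np.float32)
        _paint_cell(phase, buf, st, config)
        signal += buf
        sl, mk = _rod_mask(c["cx"], c["cy"], c["L0"], w, ps, shape)
        full = np.zeros(shape, dtype=bool)
        full[sl] = mk
        masks.append(full)
        # bleach box: the pole quarter of the cell, full width plus margin
        tip = c["cx"] - c["L0"] / 2.0
        r0 = int((c["cy"] - w / 2 - ps) / ps)
        r1 = int((c["cy"] + w / 2 + ps) / ps) + 1
        c0 = int((tip - ps) / ps)
        c1 = int((tip + 0.3 * c["L0"]) / ps) + 1
        rois.append((max(r0, 0), min(r1, shape[0]), max(c0, 0), min(c1, shape[1])))

    e = fs.bleach_efficiency
    times_post = np.arange(fs.n_postbleach_frames) * config.frame_interval
    analytic = fs.analytic_recovery(times_post)

    data = np.zeros((n_frames, 2, *shape), dtype=np.float32)
    bg = config.background_level
    for f_idx in range(n_frames):
        fluor = signal.copy()
        if f_idx >= fs.bleach_frame:
            tau_idx = f_idx - fs.bleach_frame
            R = analytic[tau_idx]  # target normalized recovery, %
            for c, mask, (r0, r1, c0, c1) in zip(cells, masks, rois):
                roi = np.zeros(shape, dtype=bool)
                roi[r0:r1, c0:c1] = True
                n_roi = roi.sum()
                s_roi = signal[roi]
                pre_mean = (bg * n_roi + s_roi.sum()) / n_roi
                T_pre = bg * mask.sum() + signal[mask].sum()
                bleached = signal[roi] * (1 - e)
                post0_mean = (bg * n_roi + bleached.sum()) / n_roi
                T_post = T_pre - e * signal[roi & mask].sum()
                f_pre_hat = pre_mean / T_pre
                f0_hat = post0_mean / T_post
                f_hat = f0_hat + R / 100.0 * (f_pre_hat - f0_hat)
                target_mean = f_hat * T_post
                delta_tot = (target_mean - post0_mean) * n_roi
                # bleach the ROI
                fluor[roi] = bleached
                # add recovered signal inside the ROI, proportional to the
                # prebleach shape; remove the same amount from the rest of
                # the cell (exchange conserves the cell total)
                if delta_tot > 0 and s_roi.sum() > 0:
                    fluor[roi] += delta_tot * (s_roi / s_roi.sum())
                    donor = mask & ~roi
                    donor_sum = signal[donor].sum()
                    take = min(delta_tot, 0.5 * donor_sum)
                    fluor[donor] -= take * (signal[donor] / donor_sum)
        data[f_idx, 0] = phase + bg
        data[f_idx, 1] = fluor + bg
    if config.read_noise_sd > 0:
        data += rng.normal(0.0, config.read_noise_sd, size=data.shape).astype(np.float32)
    np.clip(data, 0.0, None, out=data)
    stack = ImageStack(data=data, pixel_size=ps,
                       frame_interval=config.frame_interval,
                       channels=["phase", "mcherry"])

    frames = pd.DataFrame.from_records([
        dict(cell_id=c["cell_id"], frame=0, time_min=0.0, cx_um=c["cx"],
             cy_um=c["cy"], length_um=c["L0"], budget=c["budget"], phi=c["phi"],
             cluster_present=True, cluster_x_um=c["x_c"], cluster_y_um=c["y_c"],
             sigma_um=c["sigma"],
             cluster_area_um2=cluster_footprint_area(c["sigma"]),
             axial_s=(c["x_c"] - (c["cx"] - c["L0"] / 2)) / c["L0"],
             speed_um_s=0.0)
        for c in cells
    ])
    meta = pd.DataFrame.from_records([
        dict(cell_id=c["cell_id"], pattern="non-Dyn", qx_class="", parent_id=-1,
             sister_id=-1, birth_frame=0, division_frame=-1, budget=c["budget"],
             phi_target=c["phi"], sigma_um=c["sigma"],
             cluster_area_um2=cluster_footprint_area(c["sigma"]),
             speed_um_s=0.0, nucleation_min=math.nan,
             formation_complete_min=math.nan, born_with_cluster=True,
             birth_length_um=c["L0"])
        for c in cells
    ])
    truth = GroundTruth(
        cells=meta, frames=frames, config=config, seed=config.seed,
        frap_truth=pd.DataFrame({"time_s": times_post, "recovery_pct": analytic}),
        frap_rois=pd.DataFrame(
            [dict(cell_id=c["cell_id"], r0=r[0], r1=r[1], c0=r[2], c1=r[3])
             for c, r in zip(cells, rois)]
        ),
    )
    return stack, truth
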
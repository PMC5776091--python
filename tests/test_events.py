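"""Formation/dispersal event detection, quiescence classes, sister scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from polefocus import SimulationConfig
from polefocus.events import (
    classify_quiescence_subpopulations,
    detect_dispersal,
    detect_formation_event,
    sister_cluster_status,
)


def _track(sdi, present=None, cell_id=0, dt_min=1.0):
    n = len(sdi)
    present = present if present is not None else [True] * n
    return pd.DataFrame(dict(
        cell_id=[cell_id] * n, frame=range(n),
        time_min=np.arange(n) * dt_min, sdi=sdi,
        cluster_present=present,
    ))


class TestFormationDetector:
    def test_jump_rule_oracle(self):
        # (10,10,10,25,30), window 3, factor 2 -> event at index 3, ratio 2.5
        track = _track([10, 10, 10, 25, 30],
                       present=[False, False, False, True, True])
        ev = detect_formation_event(track, jump_factor=2.0, baseline_window=3)
        assert ev is not None
        assert ev.frame == 3
        assert ev.sdi_ratio == pytest.approx(2.5)

    def test_constant_series_yields_none(self):
        assert detect_formation_event(_track([10] * 8)) is None

    def test_jump_without_persistent_cluster_ignored(self):
        track = _track([10, 10, 10, 25, 10],
                       present=[False, False, False, True, False])
        assert detect_formation_event(track) is None

    def test_translation_invariance_in_time(self):
        base = [10, 10, 10, 25, 30, 30]
        pres = [False, False, False, True, True, True]
        e1 = detect_formation_event(_track(base, pres))
        shifted = _track([10, 10] + base, [False, False] + pres)
        shifted["time_min"] = np.arange(len(shifted)) * 1.0
        e2 = detect_formation_event(shifted)
        assert e2.frame - e1.frame == 2
        assert e2.time_min - e1.time_min == pytest.approx(2.0)


class TestDispersalDetector:
    def test_linear_decay_oracle(self):
        sdi = np.linspace(40, 10, 10)  # 75% relative drop
        ev = detect_dispersal(_track(list(sdi)), slope_window=5,
                              min_rel_drop=0.5)
        assert ev is not None
        assert ev.rel_drop >= 0.5

    def test_constant_track_yields_none(self):
        assert detect_dispersal(_track([30] * 10)) is None

    def test_cluster_disappearance_counts_as_dispersal(self):
        present = [True] * 5 + [False] * 3
        ev = detect_dispersal(_track([30] * 8, present=present))
        assert ev is not None
        assert ev.rel_drop == pytest.approx(1.0)

    def test_track_must_start_with_cluster(self):
        with pytest.raises(ValueError):
            detect_dispersal(_track([5] * 6, present=[False] * 6))


class TestQuiescenceClasses:
    def _stats(self, sdi, present):
        return pd.DataFrame(dict(cell_id=range(len(sdi)), sdi=sdi,
                                 cluster_present=present))

    def test_all_uniform_cells_are_no_cluster(self):
        df = classify_quiescence_subpopulations(
            self._stats([0.1] * 10, [False] * 10))
        assert (df.qx_class == "no-cluster").all()
        assert df.attrs["fractions"]["no-cluster"] == 1.0

    def test_explicit_threshold_splits_small_and_big(self):
        df = classify_quiescence_subpopulations(
            self._stats([1, 5, 20], [False, True, True]), sdi_big_threshold=10)
        assert list(df.qx_class) == ["no-cluster", "small", "big"]

    def test_class_is_monotone_in_sdi(self):
        base = self._stats([1, 5, 20, 30], [False, True, True, True])
        df = classify_quiescence_subpopulations(base, sdi_big_threshold=10)
        raised = base.copy()
        raised.loc[3, "sdi"] = 50  # raising a big cell never demotes it
        df2 = classify_quiescence_subpopulations(raised, sdi_big_threshold=10)
        assert df.loc[3, "qx_class"] == "big"
        assert df2.loc[3, "qx_class"] == "big"


class TestSisterStatus:
    def _tracks(self, statuses, frame=5):
        rows = []
        for cid, present in statuses.items():
            rows.append(dict(cell_id=cid, frame=frame, cluster_present=present))
        return pd.DataFrame(rows)

    def test_deterministic_single_inheritance(self):
        lineage = {1: dict(parent_id=0, sister_id=2),
                   2: dict(parent_id=0, sister_id=1),
                   3: dict(parent_id=0, sister_id=4),
                   4: dict(parent_id=0, sister_id=3)}
        tracks = self._tracks({1: True, 2: False, 3: True, 4: False})
        st = sister_cluster_status(tracks, lineage)
        assert st["one_sister_only"] == pytest.approx(1.0)
        assert st["n_pairs"] == 2

    def test_fractions_partition_divided_pairs(self):
        lineage = {1: dict(parent_id=0, sister_id=2),
                   2: dict(parent_id=0, sister_id=1),
                   3: dict(parent_id=0, sister_id=4),
                   4: dict(parent_id=0, sister_id=3)}
        tracks = self._tracks({1: True, 2: True, 3: True, 4: False})
        st = sister_cluster_status(tracks, lineage)
        assert st["one_sister_only"] + st["both_sisters"] == pytest.approx(1.0)

    def test_no_divisions_returns_empty_with_warning(self, caplog):
        st = sister_cluster_status(self._tracks({0: True}), {})
        assert st["n_pairs"] == 0
        assert math.isnan(st["one_sister_only"])


class TestFormationTimingStats:
    def _make(self, times, birth_lengths, lengths_at):
        from polefocus.events import EventRecord

        events, rows = [], []
        for cid, (t, bl, la) in enumerate(zip(times, birth_lengths,
                                              lengths_at)):
            frame = int(round(t))
            events.append(EventRecord(cell_id=cid, type="formation",
                                      time_min=float(t), frame=frame))
            for f in range(frame + 2):
                rows.append(dict(cell_id=cid, frame=f, time_min=float(f),
                                 length_um=bl + (la - bl) * f / max(frame, 1)))
        return events, pd.DataFrame(rows)

    def test_fixed_phase_formation_gives_perfect_association(self):
        """If every cell forms its cluster on reaching one target length,
        formation time is a deterministic function of birth length."""
        from polefocus.events import formation_timing_stats

        rng = np.random.default_rng(0)
        births = rng.uniform(2.0, 4.0, size=30)
        times = (4.5 - births) / 0.05   # fixed growth to a fixed length
        ev, tracks = self._make(times, births, [4.5] * 30)
        out = formation_timing_stats(ev, tracks)
        assert abs(out["time_vs_birth_length"]["rho"]) > 0.99

    def test_stochastic_formation_is_length_independent(self):
        from polefocus.events import formation_timing_stats

        rng = np.random.default_rng(1)
        n = 200
        births = rng.uniform(2.0, 4.0, size=n)
        times = rng.exponential(20.0, size=n)
        ev, tracks = self._make(times, births, births + 0.02 * times)
        out = formation_timing_stats(ev, tracks)
        assert abs(out["time_vs_birth_length"]["rho"]) < 3.0 / math.sqrt(n)
        assert out["exponential_gof"]["p"] > 0.01

    def test_cycle_duration_same_growth_law_not_significant(self):
        from polefocus.events import formation_timing_stats

        rng = np.random.default_rng(2)
        n = 100
        births = rng.uniform(2.0, 4.0, size=2 * n)
        times = rng.exponential(20.0, size=2 * n)
        ev, tracks = self._make(times, births, births + 0.5)
        meta = pd.DataFrame(dict(
            cell_id=range(2 * n),
            born_with_cluster=[True] * n + [False] * n,
            cycle_duration_min=rng.normal(60.0, 8.0, size=2 * n),
        ))
        out = formation_timing_stats(ev, tracks, cells_meta=meta)
        assert out["cycle_duration_by_birth_status"]["p"] > 0.05

    def test_too_few_events_rejected(self):
        from polefocus.events import formation_timing_stats

        ev, tracks = self._make([5.0] * 4, [3.0] * 4, [3.5] * 4)
        with pytest.raises(ValueError):
            formation_timing_stats(ev, tracks)


def test_mean_intensity_stable_across_detected_formation():
    """Detected formations are assemblies of pre-existing molecules: the
    cell's MI before vs after the event differs by < 5%."""
    from polefocus.pipeline import _fig2_formation

    r = _fig2_formation(seed=2, n_cells=60)
    res = r["result"]
    checked = 0
    for ev in r["events"]:
        sub = res.tracks[res.tracks.cell_id == ev.cell_id].sort_values("frame")
        pre = sub[sub.frame < ev.frame - 1].mi
        post = sub[sub.frame > ev.frame].mi
        if len(pre) >= 2 and len(post) >= 2:
            checked += 1
            assert abs(post.mean() - pre.mean()) / pre.mean() < 0.05
    assert checked >= 5


def test_dispersal_fraction_recovered_on_quiescence_exit_movie():
    """Detected dispersal fraction tracks the ground-truth dispersing
    fraction within 5 percentage points on an ON-exit movie."""
    from polefocus.pipeline import match_cells_to_truth, run_analysis
    from polefocus.simulate import simulate_quiescence_exit

    cfg = SimulationConfig(n_cells=120, n_frames=21, frame_interval=180.0,
                           cell_length_range=(2.3, 3.0),
                           total_intensity_cv=0.12, growth_rate=0.01,
                           qx_reform=False, seed=7)
    stack, truth = simulate_quiescence_exit(cfg)
    res = run_analysis(stack, classify=False)
    mapping = match_cells_to_truth(res.tracks, truth)
    meta = truth.cells.set_index("cell_id")
    det = {}
    for cid, sub in res.tracks.groupby("cell_id"):
        sub = sub.sort_values("frame")
        if not bool(sub.cluster_present.iloc[0]):
            continue
        det[mapping[cid]] = detect_dispersal(sub) is not None
    truth_frac = meta.loc[list(det)].disperses.mean()
    detected_frac = np.mean(list(det.values()))
    assert abs(detected_frac - truth_frac) <= 0.05


def test_disperse_then_reform_phenotype_recovered():
    """Cells that disperse and later re-form are flagged by running the
    formation detector after the detected dispersal."""
    from polefocus.pipeline import match_cells_to_truth, run_analysis
    from polefocus.simulate import simulate_quiescence_exit

    cfg = SimulationConfig(n_cells=100, n_frames=31, frame_interval=180.0,
                           cell_length_range=(2.3, 3.0),
                           total_intensity_cv=0.12, growth_rate=0.01,
                           nucleation_rate=0.05, qx_reform=True, seed=13)
    stack, truth = simulate_quiescence_exit(cfg)
    res = run_analysis(stack, classify=False)
    mapping = match_cells_to_truth(res.tracks, truth)
    meta = truth.cells.set_index("cell_id")
    total_min = (cfg.n_frames - 1) * 3.0
    reform_pred = {}
    for cid, sub in res.tracks.groupby("cell_id"):
        sub = sub.sort_values("frame")
        if not bool(sub.cluster_present.iloc[0]):
            continue
        ev = detect_dispersal(sub)
        reformed = False
        if ev is not None:
            tail = sub[sub.frame >= ev.frame]
            if len(tail) >= 4:
                reformed = detect_formation_event(tail) is not None
        reform_pred[mapping[cid]] = reformed
    truth_reform = meta.loc[list(reform_pred)]
    truth_flag = (truth_reform.disperses
                  & (truth_reform.reform_min < total_min - 9.0)).astype(bool)
    pred = pd.Series(reform_pred)
    assert abs(pred.mean() - truth_flag.mean()) <= 0.05
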
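"""Transmission statistics, episode classification, motif reports."""

import numpy as np
import pandas as pd
import pytest

import stasnet as sn
from oracles import transmission_brute
from stasnet.motif_analysis import (
    BranchWindow,
    TransmissionStats,
    branch_episodes,
    motif_report,
    pool_crossings,
    transmission,
    transmission_per_seed,
)
from stasnet.sequence_detection import DetectionSpot, Sequence


def _table(entries):
    """entries: sequence_id -> {spot: t_first}."""
    rows = []
    spots = sorted({s for v in entries.values() for s in v})
    for sid, crossed in entries.items():
        for spot in spots:
            rows.append(
                {
                    "sequence_id": sid,
                    "spot": spot,
                    "crossed": spot in crossed,
                    "t_first": crossed.get(spot, np.nan),
                }
            )
    return pd.DataFrame(rows)


class TestTransmission:
    def test_direct_counting_example(self):
        table = _table(
            {
                "s1": {"pre": 10.0, "post": 20.0},
                "s2": {"pre": 5.0},
                "s3": {"post": 7.0},
            }
        )
        s = transmission(table, "pre", "post")
        assert (s.n_pre, s.n_post, s.n_both, s.n_ordered_both) == (2, 2, 1, 1)
        assert s.p_post_given_pre == 0.5 and s.p_pre_given_post == 0.5

    def test_perfect_transmission(self):
        table = _table({i: {"pre": 1.0 * i, "post": 1.0 * i + 5} for i in range(7)})
        s = transmission(table, "pre", "post")
        assert s.p_post_given_pre == 1.0 and s.p_pre_given_post == 1.0

    def test_reverse_order_not_counted_as_transmission(self):
        table = _table({"s": {"pre": 30.0, "post": 10.0}})
        s = transmission(table, "pre", "post")
        assert s.n_both == 1 and s.n_ordered_both == 0

    def test_undefined_ratio_is_none_not_zero(self):
        table = _table({"s": {"post": 3.0}})
        s = transmission(table, "pre", "post")
        assert s.p_post_given_pre is None
        assert s.p_pre_given_post == 0.0

    def test_pooling_tags_runs_and_matches_enumeration(self):
        rng = np.random.default_rng(7)
        by_run = {}
        for run in range(4):
            entries = {}
            for sid in range(30):
                crossed = {}
                if rng.random() < 0.7:
                    crossed["pre"] = float(rng.uniform(0, 100))
                if rng.random() < 0.5:
                    crossed["post"] = float(rng.uniform(0, 100))
                entries[sid] = crossed
            by_run[run] = _table(entries)
        pooled = pool_crossings(by_run)
        s = transmission(pooled, "pre", "post")
        brute = transmission_brute(pooled.to_dict("records"), "pre", "post")
        assert (s.n_pre, s.n_post, s.n_both, s.n_ordered_both) == brute

    def test_pooled_vs_per_seed_estimators_agree_on_balanced_runs(self):
        # 1,000-sequence synthetic catalog split over 10 equally sized runs
        rng = np.random.default_rng(0)
        by_run = {}
        for run in range(10):
            entries = {}
            for sid in range(100):
                t0 = float(rng.uniform(0, 100))
                crossed = {"pre": t0}
                if rng.random() < 0.4:
                    crossed["post"] = t0 + 10
                entries[sid] = crossed
            by_run[run] = _table(entries)
        pooled = transmission(pool_crossings(by_run), "pre", "post")
        per_seed = transmission_per_seed(by_run, "pre", "post")
        assert per_seed["n_runs_pre"] == 10
        assert pooled.p_post_given_pre == pytest.approx(
            per_seed["p_post_given_pre_mean"], abs=1e-12
        )


def _seq(sid, pts):
    """pts: list of (x, y, t); neuron id derived from a 40-grid position."""
    pts = np.asarray(pts, dtype=float)
    return Sequence(
        id=sid,
        x=pts[:, 0],
        y=pts[:, 1],
        t=pts[:, 2],
        neuron=(pts[:, 1].astype(np.int64) * 40 + pts[:, 0].astype(np.int64)),
        extent=10.0,
    )


@pytest.fixture
def window():
    return BranchWindow(
        spots={
            "B1": DetectionSpot("B1", (10.0, 10.0)),
            "B2": DetectionSpot("B2", (10.0, 30.0)),
            "M": DetectionSpot("M", (32.0, 20.0)),
        },
        t_window=200.0,
    )


class TestBranchEpisodes:
    def test_single_branch_episode(self, window):
        g = sn.build_grid(40)
        seq = _seq(0, [(10, 30, 0.0), (18, 25, 20.0), (32, 20, 40.0)])
        crossings = sn.spot_crossings([seq], list(window.spots.values()), g)
        episodes = branch_episodes([seq], window, crossings, g)
        assert len(episodes) == 1
        assert episodes[0].classification == "single"

    def test_competition_between_distinct_sequences(self, window):
        g = sn.build_grid(40)
        s1 = _seq(0, [(10, 10, 0.0), (16, 14, 30.0)])
        s2 = _seq(1, [(10, 30, 50.0), (18, 25, 70.0), (32, 20, 90.0)])
        crossings = sn.spot_crossings([s1, s2], list(window.spots.values()), g)
        episodes = branch_episodes([s1, s2], window, crossings, g)
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.classification == "competition"
        assert sorted(ep.sequence_ids) == [0, 1]
        assert ep.t_max_competition is not None

    def test_cooperation_merged_cloud_and_merge_time(self, window):
        g = sn.build_grid(40)
        # one merged sequence: two arms converge and continue over M
        arm1 = [(10, 10, 0.0), (14, 14, 20.0), (18, 18, 40.0)]
        arm2 = [(10, 30, 0.0), (14, 26, 20.0), (18, 22, 40.0)]
        trunk = [(24, 20, 60.0), (32, 20, 80.0)]
        seq = _seq(0, arm1 + arm2 + trunk)
        crossings = sn.spot_crossings([seq], list(window.spots.values()), g)
        episodes = branch_episodes([seq], window, crossings, g, merge_eps=6.0)
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.classification == "cooperation"
        # arms come within merge_eps at t = 40 by construction
        assert ep.merge_time == 40.0

    def test_episodes_are_disjoint_and_anchored_at_earliest_crossing(self, window):
        g = sn.build_grid(40)
        early = _seq(0, [(10, 10, 0.0)])
        late = _seq(1, [(10, 10, 500.0)])
        crossings = sn.spot_crossings([early, late], list(window.spots.values()), g)
        episodes = branch_episodes([early, late], window, crossings, g)
        assert len(episodes) == 2
        assert [sorted(e.sequence_ids) for e in episodes] == [[0], [1]]

    def test_counts_are_per_branch_active_neurons(self, window):
        g = sn.build_grid(40)
        seq = _seq(0, [(10, 10, 0.0), (10, 11, 0.0), (32, 20, 10.0)])
        crossings = sn.spot_crossings([seq], list(window.spots.values()), g)
        ep = branch_episodes([seq], window, crossings, g)[0]
        b1_row = ep.counts[(ep.counts.branch == "B1") & (ep.counts.time == 0.0)]
        assert b1_row.n_active.iloc[0] == 2

    def test_window_requires_all_three_spots(self):
        with pytest.raises(ValueError):
            BranchWindow(spots={"B1": DetectionSpot("B1", (0, 0))})


class TestMotifReport:
    def test_identity_inputs_give_zero_deltas(self):
        s = TransmissionStats(10, 8, 5, 4)
        report = motif_report({"repeat": s}, {"repeat": s})
        assert (report["delta"].dropna() == 0).all()
        assert (report["direction"] == "none").all()

    def test_known_shift_signs(self):
        base = TransmissionStats(n_pre=10, n_post=10, n_both=4, n_ordered_both=4)
        patch = TransmissionStats(n_pre=10, n_post=10, n_both=7, n_ordered_both=7)
        report = motif_report({"repeat": base}, {"repeat": patch}).set_index("quantity")
        assert report.loc["p_post_given_pre", "direction"] == "increase"
        assert report.loc["n_pre", "direction"] == "none"

    def test_mismatched_motif_sets_rejected(self):
        s = TransmissionStats(1, 1, 1, 1)
        with pytest.raises(ValueError):
            motif_report({"a": s}, {"b": s})

    def test_invariant_n_both_bounded_by_margins(self):
        s = TransmissionStats(10, 8, 5, 4)
        assert s.n_both <= min(s.n_pre, s.n_post)
        assert 0.0 <= s.p_post_given_pre <= 1.0


class TestCompetitionAsymmetry:
    def test_earlier_cloud_suppresses_the_later_one(self):
        """Seeded two-bump episodes on a converging-Y circuit: the bump that
        reaches the junction first trails an inhibitory shadow that shortens
        the later bump's survival (paired against the later bump alone)."""
        from stasnet.experiments import NetworkConfig
        from stasnet.fixtures import converging_y_task
        from stasnet.task_network import compile_task_field

        net = NetworkConfig.scaled(40)
        g = sn.build_grid(40)
        spec = converging_y_task()
        conn = sn.build_connectome(
            g, compile_task_field(spec, g), net.kernel(), net.J, net.g, seed=10
        )

        def on_branch(frac, sign):
            # branch polylines run from (6, 27)/(6, 13) to the junction (20, 20)
            return (6 + frac * 14, (27 if sign > 0 else 13) + sign * (-7) * frac)

        def far_region(sign):
            ids = set()
            for frac in np.linspace(0.3, 0.85, 12):
                ids |= set(sn.neurons_in_disk(on_branch(frac, sign), 2.5, g).tolist())
            ids -= set(sn.neurons_in_disk((20, 20), 5.0, g).tolist())
            return np.array(sorted(ids))

        def last_active(trace, region):
            act = (trace.rates[:, region] >= 0.4).sum(axis=1) >= 5
            idx = np.flatnonzero(act)
            return float(idx[-1]) if idx.size else 0.0

        cfg = sn.SimConfig(t_sim=250.0, t_warmup=0.0, n_seeds=1)
        deltas = []
        for seed in range(24):
            s_near, s_far = (-1, 1) if seed % 2 else (1, -1)
            region = far_region(s_far)
            r0_far = np.zeros(conn.n_total)
            r0_far[sn.neurons_in_disk(on_branch(0.30, s_far), 2.5, g)] = 0.8
            r0_both = r0_far.copy()
            r0_both[sn.neurons_in_disk(on_branch(0.62, s_near), 2.5, g)] = 0.8
            noise = sn.NoiseParams(seed=1000 + seed)
            t_alone = last_active(
                sn.simulate(conn, sn.NeuronParams(), noise, cfg, record="exc", r0=r0_far),
                region,
            )
            t_comp = last_active(
                sn.simulate(conn, sn.NeuronParams(), noise, cfg, record="exc", r0=r0_both),
                region,
            )
            deltas.append(t_alone - t_comp)
        deltas = np.array(deltas)
        assert len(deltas) >= 20
        assert (deltas > 0).sum() > len(deltas) / 2
        assert deltas.mean() > 0
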
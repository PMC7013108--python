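"""Event parsing, interval reconstruction and co-location networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from greganet.colocation import (
    colocation_edges,
    daily_degrees,
    daily_networks,
    day_windows,
    read_events,
    reconstruct_intervals,
)

from oracles import brute_force_edges

T0 = pd.Timestamp("2019-12-20")


def _events(rows):
    """rows: (tag, box, hours, direction)"""
    return pd.DataFrame(
        {
            "timestamp": [T0 + pd.Timedelta(hours=r[2]) for r in rows],
            "tag_id": [r[0] for r in rows],
            "box_id": [r[1] for r in rows],
            "reader_id": "r",
            "direction": [r[3] for r in rows],
        }
    )


# ---------------------------------------------------------------- read_events
class TestReadEvents:
    def test_well_formed_file_sorted(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "timestamp,tag_id,box_id,reader_id,direction\n"
            "2019-12-20T10:30:00,A,B01,r1,out\n"
            "2019-12-20T10:00:00,A,B01,r1,in\n"
            "2019-12-20T09:00:00,B,B02,r2,in\n"
        )
        log = read_events(p)
        assert len(log.events) == 3
        assert log.events["tag_id"].tolist() == ["A", "A", "B"]
        assert log.events.groupby("tag_id")["timestamp"].is_monotonic_increasing.all()
        assert log.anomalies["rejected_rows"] == 0

    def test_bad_timestamp_rejected_not_dropped_silently(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "timestamp,tag_id,box_id,reader_id,direction\n"
            "2019-12-20T10:00:00,A,B01,r1,in\n"
            "not-a-time,A,B01,r1,out\n"
            "2019-12-20T11:00:00,B,B01,r1,in\n"
        )
        log = read_events(p)
        assert len(log.events) == 2
        assert len(log.rejected) == 1
        assert log.rejected["reason"].iloc[0] == "unparseable timestamp"
        assert log.anomalies["rejected_rows"] == 1

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("timestamp,tag_id,box_id,reader_id,direction\n")
        with pytest.warns(UserWarning, match="no data rows"):
            log = read_events(p)
        assert log.events.empty

    def test_missing_required_column_raises(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("timestamp,tag_id\n2019-12-20T10:00:00,A\n")
        with pytest.raises(ValueError, match="box_id"):
            read_events(p)

    def test_missing_direction_column_tolerated(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("timestamp,tag_id,box_id\n2019-12-20T10:00:00,A,B01\n")
        log = read_events(p)
        assert log.events["direction"].tolist() == ["unknown"]


# ------------------------------------------------------- reconstruct_intervals
class TestReconstructIntervals:
    def test_in_out_pair_becomes_paired_interval(self):
        iv, anom = reconstruct_intervals(_events([("A", "B01", 10.0, "in"),
                                                  ("A", "B01", 10.5, "out")]))
        assert len(iv) == 1
        row = iv.iloc[0]
        assert row["quality"] == "paired"
        assert (row["t_end"] - row["t_start"]) == pd.Timedelta(minutes=30)
        assert not anom

    def test_reentry_at_other_box_imputes_end(self):
        iv, anom = reconstruct_intervals(
            _events([("A", "B01", 10.0, "in"), ("A", "B02", 10.33, "in"),
                     ("A", "B02", 11.0, "out")])
        )
        assert iv["quality"].tolist() == ["imputed_end", "paired"]
        assert iv.iloc[0]["t_end"] == iv.iloc[1]["t_start"]
        assert anom["missing_out"] == 1

    def test_orphan_out_discarded_and_counted(self):
        iv, anom = reconstruct_intervals(_events([("A", "B01", 10.0, "out")]))
        assert iv.empty
        assert anom["orphan_out"] == 1

    def test_unknown_direction_alternation(self):
        iv, _ = reconstruct_intervals(
            _events([("A", "B01", 10.0, "unknown"), ("A", "B01", 10.5, "unknown"),
                     ("A", "B01", 12.0, "unknown"), ("A", "B01", 12.25, "unknown")])
        )
        assert len(iv) == 2
        assert iv["quality"].tolist() == ["paired", "paired"]

    def test_unclosed_interval_capped_at_max_residence(self):
        ev = _events([("A", "B01", 0.0, "in"), ("B", "B02", 30.0, "in"),
                      ("B", "B02", 30.5, "out")])
        iv, anom = reconstruct_intervals(ev, max_residence=pd.Timedelta(hours=12))
        a = iv[iv["tag_id"] == "A"].iloc[0]
        assert a["t_end"] - a["t_start"] == pd.Timedelta(hours=12)
        assert a["quality"] == "imputed_end"
        assert anom["unclosed_at_end"] == 1

    @given(st.lists(
        st.tuples(st.sampled_from(["in", "out", "unknown"]),
                  st.sampled_from(["B01", "B02", "B03"]),
                  st.floats(0, 100, allow_nan=False)),
        max_size=40,
    ))
    def test_one_animal_never_in_two_boxes_at_once(self, raw):
        ev = _events([("A", box, h, d) for d, box, h in raw])
        ev = ev.sort_values("timestamp")
        iv, _ = reconstruct_intervals(ev)
        iv = iv.sort_values("t_start")
        assert (iv["t_start"] < iv["t_end"]).all()
        # consecutive intervals for the same animal must not overlap
        assert (iv["t_start"].iloc[1:].to_numpy()
                >= iv["t_end"].iloc[:-1].to_numpy()).all()


# ------------------------------------------------------------ colocation_edges
DAY = (T0, T0 + pd.Timedelta(days=1))


class TestColocationEdges:
    def test_half_hour_overlap_in_same_box(self, interval_factory):
        iv = interval_factory([("A", "B01", 10.0, 11.0), ("B", "B01", 10.5, 11.5)])
        net = colocation_edges(iv, DAY)
        assert net.edge_set() == {frozenset(("A", "B"))}
        assert net.edges["overlap_s"].iloc[0] == pytest.approx(1800.0)

    def test_identical_times_in_different_boxes_no_edge(self, interval_factory):
        iv = interval_factory([("A", "B01", 10.0, 11.0), ("B", "B02", 10.0, 11.0)])
        net = colocation_edges(iv, DAY)
        assert net.edge_set() == set()
        assert net.nodes == ["A", "B"]

    def test_touching_endpoints_do_not_overlap(self, interval_factory):
        iv = interval_factory([("A", "B01", 10.0, 11.0), ("B", "B01", 11.0, 12.0)])
        assert colocation_edges(iv, DAY).edge_set() == set()

    def test_bad_window_rejected(self, interval_factory):
        iv = interval_factory([("A", "B01", 10.0, 11.0)])
        with pytest.raises(ValueError, match="window"):
            colocation_edges(iv, (DAY[1], DAY[0]))

    @given(st.integers(0, 10_000))
    def test_sweep_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_instance

        iv = random_instance(rng, rng.integers(2, 60), n_animals=8, n_boxes=4)
        net = colocation_edges(iv, DAY, min_overlap=1.0)
        edges, seconds = brute_force_edges(iv, DAY, min_overlap=1.0)
        assert net.edge_set() == edges
        got = {frozenset((a, b)): s for a, b, s in
               zip(net.edges["a"], net.edges["b"], net.edges["overlap_s"])}
        for pair, s in seconds.items():  # 0.1 ms slack for float summation order
            assert got[pair] == pytest.approx(s, abs=1e-4)

    def test_window_splitting_conserves_residence_and_overlap(self, rng):
        from conftest import random_instance

        iv = random_instance(rng, 80, n_animals=6, n_boxes=3, span_hours=72.0)
        whole = (T0, T0 + pd.Timedelta(hours=72))
        _, sec_whole = brute_force_edges(iv, whole, min_overlap=1e-9)
        total_by_window: dict = {}
        for k in range(3):
            w = (T0 + pd.Timedelta(days=k), T0 + pd.Timedelta(days=k + 1))
            net = colocation_edges(iv, w, min_overlap=1e-9)
            for a, b, s in zip(net.edges["a"], net.edges["b"], net.edges["overlap_s"]):
                key = frozenset((a, b))
                total_by_window[key] = total_by_window.get(key, 0.0) + s
        for pair, s in sec_whole.items():
            assert total_by_window[pair] == pytest.approx(s, abs=1e-3)
        # residence seconds conserved across the splits
        res_whole = (iv["t_end"] - iv["t_start"]).dt.total_seconds().sum()
        res_split = 0.0
        for k in range(3):
            w0 = T0 + pd.Timedelta(days=k)
            w1 = w0 + pd.Timedelta(days=1)
            res_split += (
                (iv["t_end"].clip(upper=w1) - iv["t_start"].clip(lower=w0))
                .dt.total_seconds()
                .clip(lower=0)
                .sum()
            )
        assert res_split == pytest.approx(res_whole, abs=1e-6)


# --------------------------------------------------------------- daily_degrees
class TestDegrees:
    def test_star_graph(self, interval_factory):
        iv = interval_factory(
            [("C", "B01", 0.0, 10.0), ("L1", "B01", 1.0, 2.0),
             ("L2", "B01", 3.0, 4.0), ("L3", "B01", 5.0, 6.0)]
        )
        deg = daily_degrees(colocation_edges(iv, DAY))
        assert dict(zip(deg["tag_id"], deg["degree"])) == {"C": 3, "L1": 1, "L2": 1, "L3": 1}

    def test_isolated_animals_get_degree_zero(self, interval_factory):
        iv = interval_factory(
            [("A", "B01", 0.0, 1.0), ("B", "B02", 0.0, 1.0), ("C", "B03", 5.0, 6.0)]
        )
        deg = daily_degrees(colocation_edges(iv, DAY))
        assert deg["degree"].tolist() == [0, 0, 0]

    def test_degree_symmetry_and_monotonicity(self, rng):
        from conftest import random_instance

        iv = random_instance(rng, 50, n_animals=8, n_boxes=4)
        net = colocation_edges(iv, DAY)
        g = net.to_networkx()
        for a, b in g.edges:
            assert g.has_edge(b, a)
        deg0 = dict(zip(*[daily_degrees(net)[c] for c in ("tag_id", "degree")]))
        extra = iv.iloc[:1].assign(tag_id="ZZ")  # overlaps whoever row 0 overlapped
        net2 = colocation_edges(pd.concat([iv, extra], ignore_index=True), DAY)
        deg1 = dict(zip(*[daily_degrees(net2)[c] for c in ("tag_id", "degree")]))
        for tag, d in deg0.items():
            assert deg1[tag] >= d


def test_day_windows_cover_and_anchor():
    ws = day_windows(T0 + pd.Timedelta(hours=5), T0 + pd.Timedelta(hours=40), "00:00")
    assert ws[0][0] == T0
    assert len(ws) == 2
    ws = day_windows(T0 + pd.Timedelta(hours=5), T0 + pd.Timedelta(hours=40), "12:00")
    assert ws[0][0] == T0 - pd.Timedelta(hours=12)


def test_daily_networks_splits_boundary_interval(interval_factory):
    iv = interval_factory([("A", "B01", 23.0, 25.0), ("B", "B01", 23.5, 24.5)])
    nets, deg = daily_networks(iv)
    assert len(nets) == 2
    for net in nets:
        assert net.edge_set() == {frozenset(("A", "B"))}
    assert sorted(deg["degree"]) == [1, 1, 1, 1]
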
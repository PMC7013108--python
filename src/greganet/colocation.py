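"""From raw antenna reads to residence intervals, co-location networks and
daily degree.

The tracking hardware records a timestamped read whenever a tagged animal
passes the antennas of a nest-box entrance tunnel.  This module turns that
event stream into, per animal, the spans spent inside each box
(*residence intervals*), then into an undirected *co-location network* per
24 h window: two animals are connected when their residence intervals in
the same box overlap in time.  An animal's *degree* in that network — the
number of distinct partners met that day — is the behavioural phenotype
used downstream.

Conventions
-----------
* Intervals are half-open ``[t_start, t_end)``; touching endpoints do not
  count as overlap.
* Windows are consecutive 24 h spans anchored at a configurable local
  clock time (default midnight); an interval crossing a boundary is split
  and contributes to both windows.
* Field event streams are messy: orphan reads and missed antenna
  registrations are counted and reported, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_COLUMNS",
    "EventLog",
    "DailyNetwork",
    "read_events",
    "reconstruct_intervals",
    "colocation_edges",
    "daily_degrees",
    "day_windows",
    "daily_networks",
]

EVENT_COLUMNS = ["timestamp", "tag_id", "box_id", "reader_id", "direction"]
_DIRECTIONS = {"in", "out", "unknown"}


@dataclass
class EventLog:
    """Parsed antenna events plus a record of rejected rows."""

    events: pd.DataFrame
    rejected: pd.DataFrame
    anomalies: Counter = field(default_factory=Counter)


def read_events(path) -> EventLog:
    """Read an antenna-event CSV (timestamp, tag_id, box_id, reader_id, direction).

    Events are returned sorted by ``(tag_id, timestamp)``.  Rows with an
    unparseable timestamp or an empty tag are collected in ``rejected``
    with a reason, and counted in ``anomalies``.  A missing ``direction``
    column is tolerated (all reads become ``unknown``); any other missing
    required column raises ``ValueError``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"timestamp", "tag_id", "box_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event file missing required columns: {sorted(missing)}")
    if "direction" not in df.columns:
        df["direction"] = "unknown"
    if "reader_id" not in df.columns:
        df["reader_id"] = ""

    anomalies: Counter = Counter()
    if df.empty:
        warnings.warn(f"event file {path} contains no data rows", stacklevel=2)
        empty = pd.DataFrame(columns=EVENT_COLUMNS)
        empty["timestamp"] = pd.to_datetime(empty["timestamp"])
        return EventLog(empty, pd.DataFrame(columns=[*EVENT_COLUMNS, "reason"]), anomalies)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    bad_tag = df["tag_id"].str.strip() == ""
    bad = bad_ts | bad_tag
    rejected = df.loc[bad, EVENT_COLUMNS].copy()
    rejected["reason"] = np.where(bad_ts[bad], "unparseable timestamp", "empty tag_id")
    anomalies["rejected_rows"] = int(bad.sum())
    if bad.any():
        logger.warning("rejected %d malformed event rows", int(bad.sum()))

    events = df.loc[~bad, EVENT_COLUMNS].copy()
    events["timestamp"] = ts[~bad]
    direction = events["direction"].str.strip().str.lower()
    unknown_dir = ~direction.isin(_DIRECTIONS)
    if unknown_dir.any():
        anomalies["nonstandard_direction"] = int(unknown_dir.sum())
    events["direction"] = direction.where(~unknown_dir, "unknown")
    events = events.sort_values(["tag_id", "timestamp"], kind="mergesort")
    return EventLog(events.reset_index(drop=True), rejected.reset_index(drop=True), anomalies)


def reconstruct_intervals(
    events: pd.DataFrame,
    max_residence: pd.Timedelta | str = pd.Timedelta(hours=12),
    study_end: pd.Timestamp | None = None,
) -> tuple[pd.DataFrame, Counter]:
    """Pair in/out reads into residence intervals, one animal at a time.

    Scanning each animal's reads chronologically: an ``in`` at box *b*
    opens an interval there; the next event closes it — an ``out`` at *b*
    closes it normally (quality ``paired``), while any read at a different
    box closes it at that read's timestamp (``imputed_end``).  ``unknown``
    directions are treated as enter/exit alternation within a box.  An
    interval still open at the end of the data is closed at
    ``min(open + max_residence, study_end)``; any imputed closure is also
    capped at ``open + max_residence`` so a missed exit read cannot create
    a multi-day residence.  ``out`` reads with no matching open interval
    are discarded and counted as orphans.

    Returns ``(intervals, anomalies)`` where intervals has columns
    ``tag_id, box_id, t_start, t_end, quality``.
    """
    max_residence = pd.Timedelta(max_residence)
    if max_residence <= pd.Timedelta(0):
        raise ValueError("max_residence must be positive")
    anomalies: Counter = Counter()
    rows: list[tuple] = []
    if events.empty:
        return _intervals_frame(rows), anomalies
    if study_end is None:
        study_end = events["timestamp"].max()

    for tag, grp in events.groupby("tag_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        open_box = None
        open_t = None

        def close(t_end, quality):
            nonlocal open_box, open_t
            t_end = min(t_end, open_t + max_residence)
            if t_end > open_t:
                rows.append((tag, open_box, open_t, t_end, quality))
            else:
                anomalies["zero_length_interval"] += 1
            open_box = None
            open_t = None

        for ts, box, direction in zip(grp["timestamp"], grp["box_id"], grp["direction"]):
            if direction == "in":
                if open_box is not None:
                    close(ts, "imputed_end")
                    anomalies["missing_out"] += 1
                open_box, open_t = box, ts
            elif direction == "out":
                if open_box is None:
                    anomalies["orphan_out"] += 1
                elif open_box == box:
                    close(ts, "paired")
                else:
                    close(ts, "imputed_end")
                    anomalies["missing_out"] += 1
                    anomalies["orphan_out"] += 1
            else:  # unknown: same-box alternation, cross-box handover
                if open_box is None:
                    open_box, open_t = box, ts
                elif open_box == box:
                    close(ts, "paired")
                else:
                    close(ts, "imputed_end")
                    anomalies["missing_out"] += 1
                    open_box, open_t = box, ts
        if open_box is not None:
            close(max(study_end, open_t), "imputed_end")
            anomalies["unclosed_at_end"] += 1
    return _intervals_frame(rows), anomalies


def _intervals_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["tag_id", "box_id", "t_start", "t_end", "quality"])
    if df.empty:
        df["t_start"] = pd.to_datetime(df["t_start"])
        df["t_end"] = pd.to_datetime(df["t_end"])
    return df


@dataclass
class DailyNetwork:
    """Undirected co-location graph over one 24 h window.

    ``edges`` has columns ``a, b, overlap_s, boxes`` with ``a < b``
    lexicographically; ``nodes`` lists every animal with positive residence
    time inside the window, so isolated animals still receive a degree.
    """

    window: tuple[pd.Timestamp, pd.Timestamp]
    nodes: list[str]
    edges: pd.DataFrame

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in zip(self.edges["a"], self.edges["b"])}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.a, row.b, overlap_s=row.overlap_s, boxes=row.boxes)
        return g


def colocation_edges(
    intervals: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    min_overlap: float = 1.0,
) -> DailyNetwork:
    """Build the co-location network for one time window.

    An edge joins two animals when, in some box, a residence interval of
    one intersects a residence interval of the other (clipped to the
    window) for at least ``min_overlap`` seconds; qualifying intersection
    seconds are summed over all interval pairs and boxes.  Uses a per-box
    sweep over start-sorted intervals, so expected cost is near-linear in
    the number of concurrent residents.
    """
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if w1 <= w0:
        raise ValueError("window must have positive length")
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")

    if intervals.empty:
        return DailyNetwork((w0, w1), [], _edges_frame({}))

    start = intervals["t_start"].clip(lower=w0)
    end = intervals["t_end"].clip(upper=w1)
    keep = start < end
    clipped = pd.DataFrame(
        {
            "tag_id": intervals.loc[keep, "tag_id"],
            "box_id": intervals.loc[keep, "box_id"],
            "t0": start[keep],
            "t1": end[keep],
        }
    )
    nodes = sorted(clipped["tag_id"].unique())

    pair_overlap: dict[tuple[str, str], float] = {}
    pair_boxes: dict[tuple[str, str], set] = {}
    min_overlap_ns = min_overlap * 1e9
    for box, grp in clipped.groupby("box_id", sort=True):
        grp = grp.sort_values(["t0", "t1", "tag_id"], kind="mergesort")
        t0s = grp["t0"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        t1s = grp["t1"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        tags = grp["tag_id"].to_numpy()
        active: list[int] = []  # indices of intervals that may still overlap
        for i in range(len(grp)):
            active = [j for j in active if t1s[j] > t0s[i]]
            for j in active:
                if tags[j] == tags[i]:
                    continue
                ov_ns = min(t1s[i], t1s[j]) - t0s[i]
                if ov_ns >= min_overlap_ns:
                    key = (tags[i], tags[j]) if tags[i] < tags[j] else (tags[j], tags[i])
                    pair_overlap[key] = pair_overlap.get(key, 0.0) + ov_ns / 1e9
                    pair_boxes.setdefault(key, set()).add(box)
            active.append(i)

    edges = _edges_frame(pair_overlap, pair_boxes)
    return DailyNetwork((w0, w1), nodes, edges)


def _edges_frame(pair_overlap: dict, pair_boxes: dict | None = None) -> pd.DataFrame:
    rows = [
        {
            "a": a,
            "b": b,
            "overlap_s": s,
            "boxes": ";".join(sorted(pair_boxes[(a, b)])) if pair_boxes else "",
        }
        for (a, b), s in sorted(pair_overlap.items())
    ]
    return pd.DataFrame(rows, columns=["a", "b", "overlap_s", "boxes"])


def daily_degrees(network: DailyNetwork, day: object = None) -> pd.DataFrame:
    """Per-animal partner counts for one network.

    Animals present in the window but meeting nobody get degree 0.  Returns
    columns ``tag_id, day, degree``.
    """
    counts = {tag: 0 for tag in network.nodes}
    for a, b in zip(network.edges["a"], network.edges["b"]):
        counts[a] += 1
        counts[b] += 1
    if day is None:
        day = network.window[0]
    return pd.DataFrame(
        {"tag_id": list(counts), "day": day, "degree": list(counts.values())}
    ).sort_values("tag_id", ignore_index=True)


def day_windows(
    t_min: pd.Timestamp,
    t_max: pd.Timestamp,
    anchor: str = "00:00",
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Consecutive 24 h windows covering [t_min, t_max], anchored at a local
    clock time (default midnight)."""
    t_min, t_max = pd.Timestamp(t_min), pd.Timestamp(t_max)
    if t_max < t_min:
        raise ValueError("t_max precedes t_min")
    h, m = (int(x) for x in anchor.split(":"))
    first = t_min.normalize() + pd.Timedelta(hours=h, minutes=m)
    if first > t_min:
        first -= pd.Timedelta(days=1)
    windows = []
    w0 = first
    while w0 <= t_max:
        windows.append((w0, w0 + pd.Timedelta(days=1)))
        w0 += pd.Timedelta(days=1)
    return windows


def daily_networks(
    intervals: pd.DataFrame,
    anchor: str = "00:00",
    min_overlap: float = 1.0,
) -> tuple[list[DailyNetwork], pd.DataFrame]:
    """Split intervals into anchored 24 h windows and build each network.

    Returns the list of networks and the concatenated degree table with a
    ``day`` column (the window start date).
    """
    if intervals.empty:
        return [], pd.DataFrame(columns=["tag_id", "day", "degree"])
    nets = []
    degs = []
    for w0, w1 in day_windows(intervals["t_start"].min(), intervals["t_end"].max(), anchor):
        net = colocation_edges(intervals, (w0, w1), min_overlap)
        if not net.nodes:
            continue
        nets.append(net)
        degs.append(daily_degrees(net, day=w0.date().isoformat()))
    deg = (
        pd.concat(degs, ignore_index=True)
        if degs
        else pd.DataFrame(columns=["tag_id", "day", "degree"])
    )
    return nets, deg
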
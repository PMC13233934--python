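"""Transmission probabilities at detection spots and branch-interaction analysis.

A motif's effect is read out from spot-crossing tables: how many sequences
cross a *pre* spot, a *post* spot, and both in temporal order.  Conditional
transmission probabilities are ratios of counts pooled across noise seeds
(per-seed averaging is available as a cross-check).  Around an intersection of
branches B1, B2 and a main pathway M, sequences arriving within a common time
window form episodes that are classified as competition, cooperation, single
or none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .sequence_detection import DetectionSpot, Sequence
from .topology import GridGeometry, toroidal_distance

__all__ = [
    "TransmissionStats",
    "BranchWindow",
    "BranchEpisode",
    "pool_crossings",
    "transmission",
    "transmission_per_seed",
    "branch_episodes",
    "motif_report",
]


@dataclass(frozen=True)
class TransmissionStats:
    """Spot-crossing counts and conditional probabilities, pooled over runs.

    ``n_ordered_both`` counts sequences whose first crossing at *pre* is not
    later than at *post*.  Probabilities are ``None`` (not 0) when the
    conditioning count is zero.
    """

    n_pre: int
    n_post: int
    n_both: int
    n_ordered_both: int

    @property
    def p_post_given_pre(self) -> float | None:
        return self.n_ordered_both / self.n_pre if self.n_pre else None

    @property
    def p_pre_given_post(self) -> float | None:
        return self.n_ordered_both / self.n_post if self.n_post else None


@dataclass(frozen=True)
class BranchWindow:
    """Episode alignment window (ms) and the three intersection spots."""

    spots: dict[str, DetectionSpot]
    t_window: float = 200.0

    def __post_init__(self) -> None:
        if self.t_window <= 0:
            raise ValueError("t_window must be positive")
        missing = {"M", "B1", "B2"} - set(self.spots)
        if missing:
            raise ValueError(f"missing branch spots: {sorted(missing)}")


@dataclass(frozen=True)
class BranchEpisode:
    """Sequences interacting at an intersection within one time window."""

    sequence_ids: list
    classification: str  # competition | cooperation | single | none
    counts: pd.DataFrame = field(repr=False)  # columns: time, branch, n_active
    merge_time: float | None = None
    t_max_competition: float | None = None


def pool_crossings(crossings_by_run: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-run crossing tables, tagging rows with their run id."""
    frames = []
    for run, df in crossings_by_run.items():
        tagged = df.copy()
        tagged["run"] = run
        frames.append(tagged)
    return pd.concat(frames, ignore_index=True)


def _crossing_matrix(crossings: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    keys = ["run", "sequence_id"] if "run" in crossings.columns else ["sequence_id"]
    sub = crossings[crossings["spot"].isin(labels)]
    t = sub.pivot_table(index=keys, columns="spot", values="t_first", aggfunc="min")
    for lab in labels:
        if lab not in t.columns:
            t[lab] = np.nan
    return t[labels]


def transmission(crossings: pd.DataFrame, pre: str, post: str) -> TransmissionStats:
    """Tally crossings of two spots over a (pooled) crossing table.

    ``crossings`` is the output of ``spot_crossings`` for one run or of
    ``pool_crossings`` for many; sequences are identified per run.
    """
    t = _crossing_matrix(crossings, [pre, post])
    has_pre = t[pre].notna()
    has_post = t[post].notna()
    both = has_pre & has_post
    ordered = both & (t[pre] <= t[post])
    return TransmissionStats(
        n_pre=int(has_pre.sum()),
        n_post=int(has_post.sum()),
        n_both=int(both.sum()),
        n_ordered_both=int(ordered.sum()),
    )


def transmission_per_seed(
    crossings_by_run: dict[int, pd.DataFrame], pre: str, post: str
) -> dict:
    """Average of per-run conditional probabilities (undefined runs skipped).

    Cross-check for the pooled estimator; the pooled ratio is more robust
    when per-run denominators are small.
    """
    fwd, bwd = [], []
    for df in crossings_by_run.values():
        s = transmission(df, pre, post)
        if s.p_post_given_pre is not None:
            fwd.append(s.p_post_given_pre)
        if s.p_pre_given_post is not None:
            bwd.append(s.p_pre_given_post)
    return {
        "p_post_given_pre_mean": float(np.mean(fwd)) if fwd else None,
        "p_pre_given_post_mean": float(np.mean(bwd)) if bwd else None,
        "n_runs_pre": len(fwd),
        "n_runs_post": len(bwd),
    }


def _nearest_branch(
    x: NDArray, y: NDArray, window: BranchWindow, nrows: int
) -> NDArray:
    labels = list(window.spots)
    centers = np.array([window.spots[lab].center for lab in labels], dtype=float)
    pts = np.column_stack([x, y])
    d = toroidal_distance(pts[:, None, :], centers[None, :, :], nrows)
    return np.asarray(labels, dtype=object)[np.argmin(d, axis=1)]


def branch_episodes(
    sequences: list[Sequence],
    window: BranchWindow,
    crossings: pd.DataFrame,
    geometry: GridGeometry,
    bin_ms: float = 1.0,
    merge_eps: float = 4.0,
) -> list[BranchEpisode]:
    """Group intersection-crossing sequences into classified episodes.

    The earliest branch crossing opens an episode; sequences whose first
    relevant crossing falls within ``t_window`` of the anchor join it
    (episodes are disjoint).  Classification: *cooperation* — one sequence
    crosses B1, B2 and M (branches merged into a single cluster);
    *competition* — distinct sequences cross B1 and B2 and at most one
    reaches M; *single* — only one branch is active; *none* otherwise.

    Per-ms active-neuron counts are tallied per branch region (events are
    assigned to the nearest of the three spots).  For cooperation episodes
    ``merge_time`` is the first time bin at which the B1- and B2-side clouds
    come within ``merge_eps`` grid points; for competition episodes
    ``t_max_competition`` is the time of minimum summed branch activity
    between the two branch crossings (descriptive only).
    """
    t = _crossing_matrix(crossings, ["B1", "B2", "M"])
    if "run" in crossings.columns:
        raise ValueError("branch_episodes expects a single run's crossings")
    t = t[t.notna().any(axis=1)]
    anchors = t.min(axis=1).sort_values()
    seq_by_id = {s.id: s for s in sequences}

    episodes: list[BranchEpisode] = []
    taken: set = set()
    for seq_id, t0 in anchors.items():
        if seq_id in taken:
            continue
        group = [
            sid
            for sid, ta in anchors.items()
            if sid not in taken and t0 <= ta <= t0 + window.t_window
        ]
        taken.update(group)
        sub = t.loc[group]
        crossed = {lab: sub[lab].notna() for lab in ("B1", "B2", "M")}

        single_seq_all = any(
            crossed["B1"][sid] and crossed["B2"][sid] and crossed["M"][sid]
            for sid in group
        )
        b1_ids = set(sub.index[crossed["B1"]])
        b2_ids = set(sub.index[crossed["B2"]])
        m_ids = set(sub.index[crossed["M"]])
        if single_seq_all:
            label = "cooperation"
        elif b1_ids and b2_ids and b1_ids.isdisjoint(b2_ids) and len(m_ids) <= 1:
            label = "competition"
        elif bool(b1_ids) != bool(b2_ids):
            label = "single"
        else:
            label = "none"

        ex = np.concatenate([seq_by_id[s].x for s in group])
        ey = np.concatenate([seq_by_id[s].y for s in group])
        et = np.concatenate([seq_by_id[s].t for s in group])
        en = np.concatenate([seq_by_id[s].neuron for s in group])
        branch = _nearest_branch(ex, ey, window, geometry.nrows)
        bins = np.floor(et / bin_ms).astype(int)
        counts = (
            pd.DataFrame({"bin": bins, "branch": branch, "neuron": en})
            .groupby(["bin", "branch"], sort=True)["neuron"]
            .nunique()
            .reset_index()
            .rename(columns={"neuron": "n_active", "bin": "time"})
        )
        counts["time"] = counts["time"] * bin_ms

        merge_time = None
        if label == "cooperation":
            merge_time = _first_merge_time(
                ex, ey, et, branch, bin_ms, merge_eps, geometry.nrows
            )
        t_max_comp = None
        if label == "competition":
            t_max_comp = _max_competition_time(counts, sub)
        episodes.append(
            BranchEpisode(
                sequence_ids=group,
                classification=label,
                counts=counts,
                merge_time=merge_time,
                t_max_competition=t_max_comp,
            )
        )
    return episodes


def _first_merge_time(
    x: NDArray,
    y: NDArray,
    t: NDArray,
    branch: NDArray,
    bin_ms: float,
    merge_eps: float,
    nrows: int,
) -> float | None:
    bins = np.floor(t / bin_ms).astype(int)
    for b in np.unique(bins):
        in_bin = bins == b
        a = in_bin & (branch == "B1")
        c = in_bin & (branch == "B2")
        if not (a.any() and c.any()):
            continue
        pa = np.column_stack([x[a], y[a]])
        pc = np.column_stack([x[c], y[c]])
        d = toroidal_distance(pa[:, None, :], pc[None, :, :], nrows)
        if d.min() <= merge_eps:
            return float(b * bin_ms)
    return None


def _max_competition_time(counts: pd.DataFrame, sub: pd.DataFrame) -> float | None:
    t1, t2 = sub["B1"].min(), sub["B2"].min()
    if not (np.isfinite(t1) and np.isfinite(t2)):
        return None
    lo, hi = sorted((t1, t2))
    branches = counts[counts["branch"].isin(["B1", "B2"])]
    total = branches.groupby("time")["n_active"].sum()
    total = total[(total.index >= lo) & (total.index <= hi)]
    if total.empty:
        return None
    return float(total.idxmin())


def _stat_row(name: str, base, patch) -> dict:
    if base is None or patch is None:
        delta, direction = None, "undefined"
    else:
        delta = patch - base
        direction = "increase" if delta > 0 else "decrease" if delta < 0 else "none"
    return {
        "quantity": name,
        "baseline": base,
        "patch": patch,
        "delta": delta,
        "direction": direction,
    }


def motif_report(
    baseline_stats: dict[str, TransmissionStats],
    patch_stats: dict[str, TransmissionStats],
) -> pd.DataFrame:
    """Side-by-side motif effect table with direction-of-effect flags.

    Both inputs map motif names to pooled ``TransmissionStats`` over matched
    spot definitions and seed sets.
    """
    if set(baseline_stats) != set(patch_stats):
        raise ValueError("baseline and patch stats must cover the same motifs")
    rows = []
    for motif in baseline_stats:
        b, p = baseline_stats[motif], patch_stats[motif]
        for row in (
            _stat_row("n_pre", b.n_pre, p.n_pre),
            _stat_row("n_post", b.n_post, p.n_post),
            _stat_row("n_ordered_both", b.n_ordered_both, p.n_ordered_both),
            _stat_row("p_post_given_pre", b.p_post_given_pre, p.p_post_given_pre),
            _stat_row("p_pre_given_post", b.p_pre_given_post, p.p_pre_given_post),
        ):
            row["motif"] = motif
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["motif", "quantity", "baseline", "patch", "delta", "direction"]
    )
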
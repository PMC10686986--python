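"""Per-sow-period feature engineering.

Turns the raw streams (feeder visits, ethogram tallies, group posture
summaries, schedule) into one row per sow and period holding

* the three behavior indices used for clustering, each of the form
  ``(pos − neg)/(pos + neg)`` in [−1, 1]: activity (active vs. passive
  time), giving and receiving (positive vs. agonistic interactions);
* seven feeder features: counts, total minutes and mean durations of
  nutritive (NV) and non-nutritive (NNV) visits, plus the feeder rank
  (order of first nutritive visit, a social-hierarchy proxy);
* six group-level posture percentages, repeated on every sow row of
  the group.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Visits longer than this are sensor artifacts and are discarded.
MAX_VISIT_MINUTES = 360.0

INDEX_FEATURES = ["index_activity", "index_giving", "index_receiving"]
FEEDER_FEATURES = ["nb_nv", "nb_nnv", "time_nv", "time_nnv", "avg_nv", "avg_nnv", "rank_cat"]
POSTURE_FEATURES = ["side_lying", "ventral_lying", "standing", "sitting", "eating", "drinking"]
ALL_FEATURES = INDEX_FEATURES + FEEDER_FEATURES + POSTURE_FEATURES


class DataError(ValueError):
    """Raw data violates a hard precondition (e.g. negative duration)."""


def filter_visits(visits: pd.DataFrame, max_duration: float = MAX_VISIT_MINUTES) -> pd.DataFrame:
    """Drop outlier visits longer than `max_duration` minutes.

    Order is preserved; the removed fraction is logged. Negative
    durations are data corruption, not outliers, and raise.
    """
    if (visits["duration_min"] < 0).any():
        raise DataError("negative visit duration")
    kept = visits.loc[visits["duration_min"] <= max_duration].copy()
    removed = len(visits) - len(kept)
    if len(visits):
        log.info("filtered %d/%d visits (%.4f%%) over %.0f min",
                 removed, len(visits), 100.0 * removed / len(visits), max_duration)
    return kept


def compute_index(pos_quantity, neg_quantity):
    """Valence index (pos − neg)/(pos + neg); 0 when both are 0.

    Works on scalars or array-likes; output is in [−1, 1].
    """
    pos = np.asarray(pos_quantity, dtype=float)
    neg = np.asarray(neg_quantity, dtype=float)
    if (pos < 0).any() or (neg < 0).any():
        raise DataError("index inputs must be non-negative")
    total = pos + neg
    out = np.divide(pos - neg, np.where(total > 0, total, 1.0))
    out = np.where(total > 0, out, 0.0)
    return float(out) if out.ndim == 0 else out


def aggregate_feeder(visits: pd.DataFrame, sow_id: str, period: int) -> dict[str, float]:
    """Per-period feeder aggregates for one sow: nb/time/avg × NV/NNV.

    Averages are time/count, defined as 0 when the count is 0. Input
    visits are expected to be already filtered.
    """
    sub = visits[(visits["sow_id"] == sow_id) & (visits["period"] == period)]
    out = {}
    for kind, flag in (("nv", True), ("nnv", False)):
        k = sub[sub["nutritive"] == flag]
        nb = len(k)
        time = float(k["duration_min"].sum())
        out[f"nb_{kind}"] = nb
        out[f"time_{kind}"] = time
        out[f"avg_{kind}"] = time / nb if nb else 0.0
    return out


def compute_feeder_rank(
    visits: pd.DataFrame,
    group_id: str,
    period: int,
    roster: list[str] | None = None,
) -> pd.Series:
    """Mean daily feeder rank per sow of one group-period.

    Each day, sows are ranked 1..N by the time of their first nutritive
    visit (ties broken by sow id); sows with no nutritive visit that day
    receive rank N+1. The period rank is the mean of the daily ranks.
    """
    sub = visits[(visits["group_id"] == group_id) & (visits["period"] == period)]
    if roster is None:
        roster = sorted(sub["sow_id"].unique())
    n = len(roster)
    days = sorted(sub["day"].unique())
    if n == 0 or not days:
        return pd.Series(dtype=float, name="rank_cat")
    ranks = pd.DataFrame(index=pd.Index(roster, name="sow_id"), columns=days, dtype=float)
    for day in days:
        nv = sub[(sub["day"] == day) & sub["nutritive"]]
        firsts = nv.groupby("sow_id")["start_time"].min()
        fed = sorted((s for s in roster if s in firsts.index), key=lambda s: (firsts[s], s))
        for r, s in enumerate(fed, start=1):
            ranks.loc[s, day] = float(r)
        for s in roster:
            if s not in firsts.index:
                ranks.loc[s, day] = float(n + 1)
    return ranks.mean(axis=1).rename("rank_cat")


def build_feature_table(
    visits: pd.DataFrame,
    ethogram: pd.DataFrame,
    postures: pd.DataFrame,
    schedule: pd.DataFrame,
    sow_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One feature row per sow×period (the clustering/classification table).

    Rows are anchored on the ethogram (sow-periods without an ethogram
    tally, or whose group-period lacks a posture summary, are dropped
    with a warning); feeder aggregates default to zero for sows that
    never visited. `sow_groups` maps sow ids to groups; if omitted it is
    derived from the visit log.
    """
    visits = filter_visits(visits)
    if sow_groups is None:
        sow_groups = (
            visits.groupby("sow_id")["group_id"].agg(lambda s: s.mode().iloc[0]).to_dict()
        )
    feats = ethogram.copy()
    feats["index_activity"] = compute_index(feats["active_min"], feats["passive_min"])
    feats["index_giving"] = compute_index(feats["giv_pos"], feats["giv_neg"])
    feats["index_receiving"] = compute_index(feats["rec_pos"], feats["rec_neg"])
    feats["group_id"] = feats["sow_id"].map(sow_groups)
    unmapped = feats["group_id"].isna()
    if unmapped.any():
        log.warning("dropping %d sow-periods with unknown group", int(unmapped.sum()))
        feats = feats[~unmapped]

    # feeder aggregates, vectorized over all sow-periods
    agg_rows = []
    for (sow, period), sub in visits.groupby(["sow_id", "period"]):
        row = {"sow_id": sow, "period": period}
        for kind, flag in (("nv", True), ("nnv", False)):
            k = sub[sub["nutritive"] == flag]
            row[f"nb_{kind}"] = len(k)
            row[f"time_{kind}"] = float(k["duration_min"].sum())
            row[f"avg_{kind}"] = row[f"time_{kind}"] / len(k) if len(k) else 0.0
        agg_rows.append(row)
    agg = pd.DataFrame(
        agg_rows,
        columns=["sow_id", "period", "nb_nv", "time_nv", "avg_nv", "nb_nnv", "time_nnv", "avg_nnv"],
    )
    feats = feats.merge(agg, on=["sow_id", "period"], how="left")
    for c in ("nb_nv", "nb_nnv", "time_nv", "time_nnv", "avg_nv", "avg_nnv"):
        feats[c] = feats[c].fillna(0.0)

    # feeder ranks, per group-period, over the roster of sows with ethogram rows
    rank_frames = []
    for (group, period), sub in feats.groupby(["group_id", "period"]):
        roster = sorted(sub["sow_id"].unique())
        r = compute_feeder_rank(visits, group, period, roster=roster)
        if r.empty:  # no visits at all in this group-period
            r = pd.Series(float(len(roster) + 1), index=pd.Index(roster, name="sow_id"),
                          name="rank_cat")
        rank_frames.append(r.reset_index().assign(group_id=group, period=period))
    ranks = pd.concat(rank_frames, ignore_index=True)
    feats = feats.merge(ranks, on=["sow_id", "group_id", "period"], how="left")

    before = len(feats)
    feats = feats.merge(postures, on=["group_id", "period"], how="inner")
    if len(feats) < before:
        log.warning("dropped %d sow-periods without posture summary", before - len(feats))
    feats = feats.merge(
        schedule[["group_id", "period", "week_type"]], on=["group_id", "period"], how="left"
    )
    cols = ["sow_id", "group_id", "period", "week_type"] + ALL_FEATURES
    return feats[cols].sort_values(["group_id", "sow_id", "period"]).reset_index(drop=True)
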
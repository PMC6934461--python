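"""Dyadic associations from visits (gambit of the group).

Encounters are temporal overlaps of two foxes' visits at one patch;
grouping events are connected chains of pairwise-overlapping visits;
daily contact counts are the per-fox number of dyadic encounters per
patch per survey day, with presence-without-encounter counting as zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENCOUNTER_COLUMNS = [
    "fox_a", "fox_b", "patch", "territory", "season", "survey_day",
    "overlap_start", "overlap_end", "duration_s", "start_only", "before_midnight",
]

GROUPING_EVENT_COLUMNS = [
    "patch", "territory", "season", "survey_day", "span_start", "span_end", "foxes",
]


def before_midnight(timestamp) -> bool:
    """True if a timestamp falls in the noon-to-midnight half of a survey day.

    Householders provision in the afternoon/evening and food is generally
    gone by midnight, so "before midnight" proxies food availability.
    Encounters spanning midnight are attributed by their start.
    """
    return pd.Timestamp(timestamp).hour >= 12


def detect_encounters(visits: pd.DataFrame) -> pd.DataFrame:
    """One encounter per overlapping visit pair at a patch.

    duration_s = max(0, min(end_a, end_b) - max(start_a, start_b)); visits
    that merely touch (end_a == start_b) overlap for 0 s.  If either visit
    has an unobserved end (``start_only``), the duration is set to zero and
    the encounter flagged.  Self-pairs are excluded; a dyad overlapping via
    several visit pairs yields several encounters.
    """
    rows = []
    if visits.empty:
        return pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    for (terr, season, patch), grp in visits.groupby(
            ["territory", "season", "patch"], sort=True):
        grp = grp.sort_values(["start", "end", "fox"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        foxes = grp["fox"].to_numpy()
        days = grp["survey_day"].to_numpy()
        so = grp["start_only"].to_numpy()
        n = len(grp)
        for i in range(n):
            for j in range(i + 1, n):
                if starts[j] > ends[i]:
                    break  # sorted by start: nothing later can touch visit i
                if foxes[i] == foxes[j]:
                    continue
                ov_start = max(starts[i], starts[j])
                ov_end = min(ends[i], ends[j])
                truncated = bool(so[i] or so[j])
                dur = 0.0 if truncated else (ov_end - ov_start) / np.timedelta64(1, "s")
                a, b = sorted((foxes[i], foxes[j]))
                day = days[j] if starts[j] >= starts[i] else days[i]
                rows.append((a, b, patch, terr, season, int(day),
                             ov_start, ov_end, float(dur), truncated,
                             before_midnight(ov_start)))
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def encounter_duration_split(encounters: pd.DataFrame) -> pd.DataFrame:
    """Attribute each encounter to before/after midnight by its overlap start."""
    out = encounters.copy()
    out["before_midnight"] = [before_midnight(t) for t in out["overlap_start"]]
    return out


def build_grouping_events(visits: pd.DataFrame) -> pd.DataFrame:
    """Connected components of the visit interval-overlap graph, per patch.

    Members of one event form a chain of pairwise temporally overlapping
    visits (A-B and B-C overlapping chains A, B, C together even if A and C
    are disjoint).  Lone visits form singleton events.  Touching intervals
    (0 s overlap) chain.  The event day is the survey day of its earliest
    visit.
    """
    rows = []
    if visits.empty:
        return pd.DataFrame(columns=GROUPING_EVENT_COLUMNS)
    for (terr, season, patch), grp in visits.groupby(
            ["territory", "season", "patch"], sort=True):
        grp = grp.sort_values(["start", "end", "fox"], kind="mergesort")
        cur_members: set = set()
        cur_start = cur_end = None
        cur_day = None
        for start, end, fox, day in zip(grp["start"], grp["end"], grp["fox"], grp["survey_day"]):
            if cur_members and start <= cur_end:
                cur_members.add(fox)
                cur_end = max(cur_end, end)
            else:
                if cur_members:
                    rows.append((patch, terr, season, int(cur_day),
                                 cur_start, cur_end, tuple(sorted(cur_members))))
                cur_members = {fox}
                cur_start, cur_end, cur_day = start, end, day
        if cur_members:
            rows.append((patch, terr, season, int(cur_day),
                         cur_start, cur_end, tuple(sorted(cur_members))))
    return pd.DataFrame(rows, columns=GROUPING_EVENT_COLUMNS)


def daily_contact_counts(encounters: pd.DataFrame, visits: pd.DataFrame,
                         eligible: dict | set) -> pd.DataFrame:
    """Per-fox daily association counts at each patch.

    For every eligible fox present (>= 1 visit) at a patch on a survey day,
    count the dyadic encounters it had there that day with other eligible
    foxes.  Days present without encounters contribute zero — those zeros
    are real observations.  ``eligible`` is either one set of fox ids or a
    mapping ``(territory, season) -> set``.
    """
    def is_eligible(fox, terr, season):
        if isinstance(eligible, dict):
            return fox in eligible.get((terr, season), ())
        return fox in eligible

    cols = ["fox", "patch", "territory", "season", "survey_day", "n_contacts"]
    if visits.empty:
        return pd.DataFrame(columns=cols)
    present = visits[[ "fox", "patch", "territory", "season", "survey_day"]].drop_duplicates()
    mask = [is_eligible(f, t, s) for f, t, s in
            zip(present["fox"], present["territory"], present["season"])]
    present = present[np.asarray(mask, dtype=bool)]
    if encounters.empty:
        counts = pd.DataFrame(columns=cols[:-1] + ["n_contacts"])
    else:
        ok = [is_eligible(a, t, s) and is_eligible(b, t, s) for a, b, t, s in
              zip(encounters["fox_a"], encounters["fox_b"],
                  encounters["territory"], encounters["season"])]
        enc = encounters[np.asarray(ok, dtype=bool)]
        melted = pd.concat([
            enc[["fox_a", "patch", "territory", "season", "survey_day"]]
            .rename(columns={"fox_a": "fox"}),
            enc[["fox_b", "patch", "territory", "season", "survey_day"]]
            .rename(columns={"fox_b": "fox"}),
        ])
        counts = (melted.groupby(["fox", "patch", "territory", "season", "survey_day"])
                  .size().rename("n_contacts").reset_index())
    out = present.merge(counts, how="left",
                        on=["fox", "patch", "territory", "season", "survey_day"])
    out["n_contacts"] = pd.to_numeric(out["n_contacts"], errors="coerce").fillna(0).astype(int)
    return out.sort_values(cols[:-1], kind="mergesort").reset_index(drop=True)


def provisioning_covariates(log: pd.DataFrame,
                            survey_length_days: int = 40) -> pd.DataFrame:
    """Per patch-survey provisioning covariates.

    frequency = mean feeding days per week = distinct feeding days /
    (survey length / 7); energy = mean MJ supplied per feeding day.
    An empty log yields zero covariates with a warning.
    """
    cols = ["territory", "patch", "season", "provisioning_frequency", "energy_mj_per_day"]
    if log.empty:
        logger.warning("empty provisioning log: covariates set to 0")
        return pd.DataFrame(columns=cols)
    per_day = (log.groupby(["territory", "patch", "season", "survey_day"])["energy_mj"]
               .sum().reset_index())
    agg = (per_day.groupby(["territory", "patch", "season"])
           .agg(n_days=("survey_day", "nunique"), energy_mj_per_day=("energy_mj", "mean"))
           .reset_index())
    agg["provisioning_frequency"] = agg["n_days"] / (survey_length_days / 7.0)
    return agg[cols]
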
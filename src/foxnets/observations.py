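"""Detection-stream processing.

Turns raw camera-trap detection records (one row per identified photograph)
into visits, survey-day indices, sighting frequencies, residency assignments
and the eligibility filters used downstream.

Conventions
-----------
* Survey "days" run noon to noon; day 1 starts at the survey start (a noon).
* A gap of >= ``gap_minutes`` (default 15) between photographs of the same
  fox at the same patch splits two visits; the boundary itself splits.
* Residency: seen on >= 20 distinct days in a territory-season and sharing
  >= 2 associations with other residents, resolved by a monotone fixed
  point (see :func:`classify_residency`).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical detection-table header
DETECTION_COLUMNS = ["timestamp", "territory", "patch", "fox", "season"]

#: canonical visit-table columns
VISIT_COLUMNS = [
    "fox", "patch", "territory", "season", "start", "end", "survey_day", "start_only",
]

DEFAULT_GAP_MINUTES = 15.0
DEFAULT_MIN_RESIDENT_DAYS = 20
DEFAULT_MIN_RESIDENT_ASSOCIATIONS = 2
DEFAULT_MIN_DAYS = 5


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV strictly; malformed rows are reported by line number."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection file {path} missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        # +2: one for the header, one for 0-based indexing
        lines = (df.index[ts.isna()] + 2).tolist()
        raise ValueError(f"malformed timestamps in {path} at lines {lines[:20]}")
    out = df[DETECTION_COLUMNS].copy()
    out["timestamp"] = ts
    return out


def read_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("fox", "sex", "status", "age_class"):
        if col not in df.columns:
            raise ValueError(f"attribute file {path} missing column {col!r}")
    return df


def assign_survey_day(timestamps, survey_start, n_days: int | None = None,
                      context: str = "") -> int | np.ndarray:
    """Map timestamps to 1-based noon-to-noon survey-day indices.

    ``day = floor((t - survey_start) / 24 h) + 1``, so 11:59:59 belongs to the
    previous day and 12:00:00 opens the next.  When ``n_days`` is given,
    timestamps outside ``[start, start + n_days)`` are rejected.
    """
    scalar = np.ndim(timestamps) == 0 and not isinstance(timestamps, (pd.Series, pd.Index))
    ts = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(timestamps, dtype=object))))
    start = pd.Timestamp(survey_start)
    frac = (ts - start) / pd.Timedelta(days=1)
    day = np.floor(frac.to_numpy()).astype(int) + 1
    if n_days is not None:
        bad = (day < 1) | (day > n_days)
        if bad.any():
            first = ts[bad].iloc[0]
            raise ValueError(
                f"{int(bad.sum())} timestamp(s) outside the {n_days}-day survey window "
                f"starting {start}{' (' + context + ')' if context else ''}; first: {first}"
            )
    return int(day[0]) if scalar else day


def collapse_to_visits(detections: pd.DataFrame,
                       gap_minutes: float = DEFAULT_GAP_MINUTES,
                       survey_starts: Mapping | None = None,
                       n_days: int | None = None,
                       survey_end: Mapping | None = None) -> pd.DataFrame:
    """Collapse photographs into visits per fox x patch.

    A gap >= ``gap_minutes`` between consecutive photographs starts a new
    visit (the boundary splits: exactly 15 min -> two visits).  Visit start
    and end are the first and last photograph; a single photograph gives a
    zero-length visit.  Input need not be sorted; duplicates are allowed.

    Parameters
    ----------
    survey_starts : mapping, optional
        ``(territory, season) -> noon timestamp``; when given, a
        ``survey_day`` column is added from the visit start.
    survey_end : mapping, optional
        ``(territory, season) -> timestamp``; visits whose last photograph
        falls at or beyond it are flagged ``start_only`` (end unobserved).
    """
    if detections.empty:
        return pd.DataFrame(columns=VISIT_COLUMNS)
    gap = pd.Timedelta(minutes=gap_minutes)
    df = detections.sort_values(["territory", "season", "patch", "fox", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    keys = ["fox", "patch", "territory", "season"]
    same_stream = (df[keys] == df[keys].shift()).all(axis=1)
    gap_split = df["timestamp"].diff() >= gap
    new_visit = (~same_stream) | gap_split
    visit_id = new_visit.cumsum()
    visits = (
        df.groupby(visit_id)
        .agg(fox=("fox", "first"), patch=("patch", "first"),
             territory=("territory", "first"), season=("season", "first"),
             start=("timestamp", "min"), end=("timestamp", "max"))
        .reset_index(drop=True)
    )
    visits["survey_day"] = -1
    if survey_starts is not None:
        for (terr, season), grp in visits.groupby(["territory", "season"], sort=False):
            start0 = survey_starts[(terr, season)]
            visits.loc[grp.index, "survey_day"] = assign_survey_day(
                grp["start"], start0, n_days=n_days, context=f"{terr}/{season}")
    visits["start_only"] = False
    if survey_end is not None:
        for (terr, season), grp in visits.groupby(["territory", "season"], sort=False):
            end_ts = pd.Timestamp(survey_end[(terr, season)])
            visits.loc[grp.index, "start_only"] = grp["end"] >= end_ts
    return visits[VISIT_COLUMNS]


def filter_independent(attributes: pd.DataFrame,
                       include_missing: bool = True) -> set:
    """Return the fox ids old enough to leave the natal den (age >= 5 months).

    Cubs (< 5 months) are excluded.  Foxes with missing/unknown age are
    included by default (configurable) and logged.
    """
    attrs = attributes.drop_duplicates("fox")
    age = attrs["age_class"].astype("string")
    is_cub = age == "cub"
    is_missing = age.isna() | ~age.isin(["cub", "independent"])
    if is_missing.any():
        action = "included" if include_missing else "excluded"
        logger.warning("%d fox(es) with missing age_class %s",
                       int(is_missing.sum()), action)
    keep = ~is_cub if include_missing else (age == "independent")
    return set(attrs.loc[keep.fillna(include_missing), "fox"])


def sighting_frequency(visits: pd.DataFrame, by_patch: bool = False) -> pd.DataFrame:
    """Distinct survey days seen, per fox x survey (or per fox x patch x survey).

    A survey is one territory-season; multiple visits on one day count once.
    """
    if visits.empty:
        cols = ["fox", "territory", "season"] + (["patch"] if by_patch else []) + ["days_seen"]
        return pd.DataFrame(columns=cols)
    keys = ["fox", "territory", "season"] + (["patch"] if by_patch else [])
    out = (visits.groupby(keys, sort=True)["survey_day"]
           .nunique().rename("days_seen").reset_index())
    return out


def classify_residency(visits: pd.DataFrame, associations: pd.DataFrame,
                       min_days: int = DEFAULT_MIN_RESIDENT_DAYS,
                       min_associations: int = DEFAULT_MIN_RESIDENT_ASSOCIATIONS,
                       ) -> pd.DataFrame:
    """Assign residents per territory-season by a monotone fixed point.

    Seed set: foxes seen on >= ``min_days`` distinct days in the
    territory-season.  Then repeatedly remove any member having fewer than
    ``min_associations`` associations with current members, until stable
    (the set only shrinks, so this terminates).  A fox qualifying in more
    than one territory in a season keeps the territory where it was seen on
    more days; ties break alphabetically by territory id.

    ``associations`` needs columns fox_a, fox_b, territory, season — one row
    per dyadic association (encounter).
    """
    freq = sighting_frequency(visits, by_patch=False)
    rows = []
    for (terr, season), grp in freq.groupby(["territory", "season"], sort=True):
        members = set(grp.loc[grp["days_seen"] >= min_days, "fox"])
        if associations.empty:
            pairs = []
        else:
            assoc = associations[(associations["territory"] == terr)
                                 & (associations["season"] == season)]
            pairs = list(zip(assoc["fox_a"], assoc["fox_b"]))
        while True:
            counts = {f: 0 for f in members}
            for a, b in pairs:
                if a in members and b in members:
                    counts[a] += 1
                    counts[b] += 1
            keep = {f for f in members if counts[f] >= min_associations}
            if keep == members:
                break
            members = keep
        days = dict(zip(grp["fox"], grp["days_seen"]))
        rows.extend({"fox": f, "territory": terr, "season": season,
                     "days_seen": int(days[f])} for f in sorted(members))
    res = pd.DataFrame(rows, columns=["fox", "territory", "season", "days_seen"])
    if res.empty:
        return res
    # one territory of residency per fox-season: most days seen, then territory id
    res = (res.sort_values(["fox", "season", "days_seen", "territory"],
                           ascending=[True, True, False, True], kind="mergesort")
           .drop_duplicates(["fox", "season"], keep="first")
           .reset_index(drop=True))
    return res


def min_days_filter(days_seen: pd.DataFrame, threshold: int = DEFAULT_MIN_DAYS) -> pd.DataFrame:
    """Foxes seen on >= ``threshold`` distinct days in a survey.

    Apply to frequencies from the full patch set for contact-rate
    eligibility, or from the standardised patch set for network eligibility.
    """
    out = days_seen[days_seen["days_seen"] >= threshold]
    return out.reset_index(drop=True)


def eligible_sets(days_seen: pd.DataFrame, threshold: int = DEFAULT_MIN_DAYS) -> dict:
    """``(territory, season) -> set of eligible fox ids`` from :func:`min_days_filter`."""
    kept = min_days_filter(days_seen, threshold)
    return {key: set(grp["fox"])
            for key, grp in kept.groupby(["territory", "season"], sort=True)}


def standardise_patches(visits: pd.DataFrame,
                        monitored: Mapping | None = None,
                        max_patches: int | None = None) -> pd.DataFrame:
    """Restrict each territory to the patches monitored in all four seasons.

    The standardised patch set is the intersection of per-season patch sets
    (from ``monitored``, a mapping ``(territory, season) -> iterable of
    patches``, or inferred from the visits).  If ``max_patches`` is given and
    the intersection is larger, patches with the fewest total visits are
    dropped (ties break by patch id).  An empty intersection raises, advising
    an explicit patch list.
    """
    if visits.empty:
        return visits.copy()
    keep_frames = []
    for terr, grp in visits.groupby("territory", sort=True):
        seasons = sorted(grp["season"].unique())
        if monitored is not None:
            sets = [set(monitored[(terr, s)]) for s in seasons]
        else:
            sets = [set(grp.loc[grp["season"] == s, "patch"]) for s in seasons]
        common = set.intersection(*sets) if sets else set()
        if not common:
            raise ValueError(
                f"territory {terr}: no patch was monitored in every season; "
                "pass an explicit standardised patch list via `monitored`")
        if max_patches is not None and len(common) > max_patches:
            totals = grp[grp["patch"].isin(common)].groupby("patch").size()
            ranked = sorted(common, key=lambda p: (-totals.get(p, 0), p))
            common = set(ranked[:max_patches])
        keep_frames.append(grp[grp["patch"].isin(common)])
    return pd.concat(keep_frames, ignore_index=True)
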
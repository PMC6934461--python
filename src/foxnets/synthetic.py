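"""Seeded synthetic detection streams with known social structure.

Generates territories of foxes (one dominant pair each), per-fox visit
point processes with log-linear sex/status/season rate structure, shared
grouping events that induce dyadic association preferences, non-resident
intrusions, provisioning logs and the photograph stream a camera trap
would record.  Every downstream stage of the pipeline can be validated
against the returned ground truth.

Design notes
------------
* Solo visits: homogeneous Poisson per fox x patch x day with rate
  ``base_visit_rate * exp(effects)``.
* Social structure: a patch-level "grouping event" process; a seed fox is
  drawn (weighted by its rate multiplier) and every other resident joins
  with probability ``join_probability * preference(seed, fox) * mult``,
  so co-visiting probability rises monotonically with dyadic preference.
* Durations: exponential with the configured mean, truncated at 2 h.
* Photographs: one at visit start and end plus interior photos every
  14 min (and Poisson extras), so gaps within a visit stay under the
  15-min collapse threshold and visit reconstruction is exact.
* All times are integer seconds; consecutive visits of one fox at one
  patch are forced >= 15 min apart by dropping violators.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400
GAP_SECONDS = 900            # 15-min visit separation contract
MAX_VISIT_SECONDS = 7200     # durations truncated at 2 h

SEASONS = ("spring", "summer", "autumn", "winter")

#: survey calendars: each seasonal survey starts at noon
DEFAULT_SEASON_STARTS = {
    "spring": "2014-03-01 12:00:00",
    "summer": "2014-06-01 12:00:00",
    "autumn": "2014-09-01 12:00:00",
    "winter": "2014-12-01 12:00:00",
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study (seven territories, four 40-day surveys)."""

    n_territories: int = 7
    patches_per_territory: int = 4
    group_size_range: tuple = (4, 10)
    survey_length_days: int = 40
    seasons: tuple = SEASONS
    base_visit_rate: float = 0.3          # solo visits / fox / patch / day
    grouping_event_rate: float = 1.0      # events / patch / day
    join_probability: float = 0.6         # baseline event-joining probability
    sex_effects: dict = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    status_effects: dict = field(default_factory=lambda: {"dominant": 0.0,
                                                          "subordinate": 0.0})
    season_effects: dict = field(default_factory=lambda: {s: 0.0 for s in SEASONS})
    # (sex, season) -> additional log-rate effect, e.g. {("M","winter"): -0.5}
    interaction_effects: dict = field(default_factory=dict)
    # (sex, season) -> log-rate effect on event joining ONLY (sociality):
    # changes per-day contact rates without changing overall visiting
    sociality_effects: dict = field(default_factory=dict)
    default_preference: float = 0.5
    # frozenset({fox_a, fox_b}) -> weight in [0, 1]
    preference_overrides: dict = field(default_factory=dict)
    nonresident_rate: dict = field(default_factory=lambda: {s: 0.1 for s in SEASONS})
    provisioning_days_per_week: int = 7
    provisioning_energy_mj: float = 1.0
    provisioning_energy_sd: float = 0.2
    mean_visit_duration_s: float = 600.0
    n_cubs_per_territory: int = 0
    season_starts: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_STARTS))
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.seasons) != 4:
            raise ValueError("exactly four seasons are required")
        if self.group_size_range[0] < 2:
            raise ValueError("group_size_range lower bound must be >= 2 "
                             "(a dominant pair is required)")
        for name in ("base_visit_rate", "grouping_event_rate",
                     "mean_visit_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.nonresident_rate.values()):
            raise ValueError("nonresident rates must be >= 0")
        for w in self.preference_overrides.values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("preference weights must lie in [0, 1]")
        if not 0.0 <= self.default_preference <= 1.0:
            raise ValueError("default_preference must lie in [0, 1]")

    def rate_multiplier(self, sex: str, status: str, season: str) -> float:
        eta = (self.sex_effects.get(sex, 0.0)
               + self.status_effects.get(status, 0.0)
               + self.season_effects.get(season, 0.0)
               + self.interaction_effects.get((sex, season), 0.0))
        return float(np.exp(eta))

    def sociality_multiplier(self, sex: str, season: str) -> float:
        return float(np.exp(self.sociality_effects.get((sex, season), 0.0)))

    def preference(self, fox_a: str, fox_b: str) -> float:
        return self.preference_overrides.get(frozenset((fox_a, fox_b)),
                                             self.default_preference)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["preference_overrides"] = {"|".join(sorted(k)): v
                                     for k, v in self.preference_overrides.items()}
        d["interaction_effects"] = {f"{sex}|{season}": v
                                    for (sex, season), v in self.interaction_effects.items()}
        d["sociality_effects"] = {f"{sex}|{season}": v
                                  for (sex, season), v in self.sociality_effects.items()}
        return d


@dataclass
class GroundTruth:
    dyad_preference: dict                 # frozenset dyad -> realised weight
    true_effects: dict                    # the log-rate effects used
    residency_truth: pd.DataFrame         # fox, season, territory


def _streams(config: ScenarioConfig):
    ss = np.random.SeedSequence(config.rng_seed)
    pop, vis, prov = ss.spawn(3)
    return (np.random.default_rng(pop), np.random.default_rng(vis),
            np.random.default_rng(prov))


def generate_population(config: ScenarioConfig):
    """Territory groups with exactly one dominant male and female each.

    Returns ``(attributes, GroundTruth)``.  Remaining residents are
    subordinate with sexes split as evenly as the group size allows (odd
    remainders assigned at random), mirroring groups of up to ten adults
    with roughly equal sex ratios.
    """
    rng, _, _ = _streams(config)
    lo, hi = config.group_size_range
    rows = []
    for t in range(config.n_territories):
        terr = f"T{t + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        sexes = ["M", "F"]
        statuses = ["dominant", "dominant"]
        n_sub = size - 2
        half = n_sub // 2
        sub_sexes = ["M"] * half + ["F"] * half
        if n_sub % 2:
            sub_sexes.append("M" if rng.random() < 0.5 else "F")
        sexes += list(rng.permutation(sub_sexes))
        statuses += ["subordinate"] * n_sub
        for k, (sex, status) in enumerate(zip(sexes, statuses)):
            rows.append({"fox": f"{terr}-F{k + 1:02d}", "territory": terr,
                         "sex": sex, "status": status, "age_class": "independent"})
        for c in range(config.n_cubs_per_territory):
            rows.append({"fox": f"{terr}-C{c + 1:02d}", "territory": terr,
                         "sex": "M" if rng.random() < 0.5 else "F",
                         "status": "subordinate", "age_class": "cub"})
    attrs = pd.DataFrame(rows, columns=["fox", "territory", "sex", "status", "age_class"])
    adults = attrs[attrs["age_class"] == "independent"]
    residency = pd.concat(
        [adults[["fox", "territory"]].assign(season=s) for s in config.seasons],
        ignore_index=True)[["fox", "season", "territory"]]
    prefs = {}
    for terr, grp in adults.groupby("territory"):
        foxes = sorted(grp["fox"])
        for i, a in enumerate(foxes):
            for b in foxes[i + 1:]:
                prefs[frozenset((a, b))] = config.preference(a, b)
    truth = GroundTruth(
        dyad_preference=prefs,
        true_effects={"sex": dict(config.sex_effects),
                      "status": dict(config.status_effects),
                      "season": dict(config.season_effects),
                      "sex_season": dict(config.interaction_effects),
                      "sociality": dict(config.sociality_effects)},
        residency_truth=residency)
    return attrs, truth


def _emit_photos(start_s: int, end_s: int, rng: np.random.Generator) -> np.ndarray:
    dur = end_s - start_s
    offsets = {0, dur}
    offsets.update(range(840, dur, 840))  # 14-min lattice keeps gaps < 15 min
    n_extra = rng.poisson(dur / 600.0)
    if n_extra:
        offsets.update(int(x) for x in rng.integers(0, dur + 1, size=n_extra))
    return start_s + np.array(sorted(offsets), dtype=np.int64)


def simulate_visits(config: ScenarioConfig, attributes: pd.DataFrame):
    """Simulate the visit process and the photographs a camera would record.

    Returns ``(detections, visits)``: the detection stream (timestamp,
    territory, patch, fox, season) and the ground-truth visit table.
    Setting a fox's rate multipliers/joining to zero removes it entirely;
    zero rates overall yield empty frames.
    """
    _, rng, _ = _streams(config)
    adults = attributes[attributes["age_class"] == "independent"]
    horizon = config.survey_length_days * SECONDS_PER_DAY
    mean_dur = config.mean_visit_duration_s

    def draw_duration() -> int:
        if mean_dur <= 0:
            return 0
        return int(min(rng.exponential(mean_dur), MAX_VISIT_SECONDS))

    visit_rows = []  # (territory, season, patch, fox, start_s, end_s)
    by_terr = {t: g for t, g in adults.groupby("territory")}
    territories = sorted(by_terr)
    for terr in territories:
        grp = by_terr[terr].sort_values("fox")
        foxes = grp["fox"].to_numpy()
        sex = dict(zip(grp["fox"], grp["sex"]))
        status = dict(zip(grp["fox"], grp["status"]))
        patches = [f"{terr}-P{p + 1}" for p in range(config.patches_per_territory)]
        others = adults[adults["territory"] != terr]
        for season in config.seasons:
            mult = np.array([config.rate_multiplier(sex[f], status[f], season)
                             for f in foxes])
            soc = np.array([config.sociality_multiplier(sex[f], season)
                            for f in foxes])
            for day in range(1, config.survey_length_days + 1):
                day0 = (day - 1) * SECONDS_PER_DAY
                for patch in patches:
                    # solo visits
                    lam = config.base_visit_rate * mult
                    n_solo = rng.poisson(lam)
                    for fi in np.nonzero(n_solo)[0]:
                        for _ in range(n_solo[fi]):
                            s = day0 + int(rng.integers(0, SECONDS_PER_DAY))
                            visit_rows.append((terr, season, patch, foxes[fi],
                                               s, s + draw_duration()))
                    # grouping events
                    if len(foxes) >= 2 and config.grouping_event_rate > 0:
                        for _ in range(rng.poisson(config.grouping_event_rate)):
                            if mult.sum() <= 0:
                                continue
                            t0 = day0 + int(rng.integers(0, SECONDS_PER_DAY))
                            seed_i = rng.choice(len(foxes), p=mult / mult.sum())
                            attend = [seed_i]
                            for fi in range(len(foxes)):
                                if fi == seed_i:
                                    continue
                                p_join = min(1.0, config.join_probability
                                             * config.preference(foxes[seed_i], foxes[fi])
                                             * mult[fi] * soc[fi])
                                if rng.random() < p_join:
                                    attend.append(fi)
                            for fi in attend:
                                s = t0 + int(rng.integers(0, 121))
                                visit_rows.append((terr, season, patch, foxes[fi],
                                                   s, s + draw_duration()))
                # non-resident intrusions (male-biased in winter)
                rate = config.nonresident_rate.get(season, 0.0)
                if rate > 0 and len(others):
                    for _ in range(rng.poisson(rate)):
                        p_male = 0.8 if season == "winter" else 0.5
                        want = "M" if rng.random() < p_male else "F"
                        pool = others[others["sex"] == want]
                        if pool.empty:
                            pool = others
                        fox = pool["fox"].iloc[int(rng.integers(len(pool)))]
                        patch = patches[int(rng.integers(len(patches)))]
                        s = day0 + int(rng.integers(0, SECONDS_PER_DAY))
                        visit_rows.append((terr, season, patch, fox,
                                           s, s + draw_duration()))

    # enforce the 15-min separation contract per fox x patch x season
    visit_rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4], r[5]))
    kept = []
    prev_key, prev_end = None, -np.inf
    for terr, season, patch, fox, s, e in visit_rows:
        e = min(e, horizon - 1)
        s = min(s, e)
        key = (terr, season, patch, fox)
        if key == prev_key and s < prev_end + GAP_SECONDS:
            continue
        kept.append((terr, season, patch, fox, s, e))
        prev_key, prev_end = key, e

    det_rows, vis_rows = [], []
    starts = {s: pd.Timestamp(config.season_starts[s]) for s in config.seasons}
    for terr, season, patch, fox, s, e in kept:
        base = starts[season]
        start_ts = base + pd.Timedelta(seconds=int(s))
        end_ts = base + pd.Timedelta(seconds=int(e))
        day = s // SECONDS_PER_DAY + 1
        truncated = e >= horizon - 1
        vis_rows.append((fox, patch, terr, season, start_ts, end_ts,
                         int(day), bool(truncated)))
        for off in _emit_photos(int(s), int(e), rng):
            det_rows.append((base + pd.Timedelta(seconds=int(off)),
                             terr, patch, fox, season))
    detections = pd.DataFrame(det_rows, columns=["timestamp", "territory",
                                                 "patch", "fox", "season"])
    detections = detections.sort_values(
        ["timestamp", "territory", "patch", "fox"], kind="mergesort").reset_index(drop=True)
    visits = pd.DataFrame(vis_rows, columns=["fox", "patch", "territory", "season",
                                             "start", "end", "survey_day", "start_only"])
    visits = visits.sort_values(["territory", "season", "patch", "fox", "start"],
                                kind="mergesort").reset_index(drop=True)
    return detections, visits


def simulate_provisioning(config: ScenarioConfig) -> pd.DataFrame:
    """Householder provisioning log: per patch-season feeding days and energy.

    Feeding happens ``provisioning_days_per_week`` days per week at 18:00
    (afternoon/evening, consistent with the before-midnight food proxy);
    per-day energy is Normal(mean, sd) truncated at zero.
    """
    _, _, rng = _streams(config)
    rows = []
    starts = {s: pd.Timestamp(config.season_starts[s]) for s in config.seasons}
    for t in range(config.n_territories):
        terr = f"T{t + 1:02d}"
        for p in range(config.patches_per_territory):
            patch = f"{terr}-P{p + 1}"
            for season in config.seasons:
                weekdays = sorted(rng.permutation(7)[:config.provisioning_days_per_week])
                for day in range(1, config.survey_length_days + 1):
                    if (day - 1) % 7 not in weekdays:
                        continue
                    energy = config.provisioning_energy_mj
                    if config.provisioning_energy_sd > 0:
                        energy = max(0.0, rng.normal(energy, config.provisioning_energy_sd))
                    date = (starts[season] + pd.Timedelta(days=day - 1)
                            + pd.Timedelta(hours=6))  # 18:00, before midnight
                    rows.append({"territory": terr, "patch": patch, "season": season,
                                 "survey_day": day, "date": date,
                                 "energy_mj": float(energy)})
    return pd.DataFrame(rows, columns=["territory", "patch", "season",
                                       "survey_day", "date", "energy_mj"])


def survey_starts(config: ScenarioConfig, territories=None) -> dict:
    """``(territory, season) -> noon start timestamp`` for the scenario calendar."""
    terrs = territories or [f"T{t + 1:02d}" for t in range(config.n_territories)]
    return {(terr, s): pd.Timestamp(config.season_starts[s])
            for terr in terrs for s in config.seasons}


def simulate_scenario(config: ScenarioConfig):
    """Convenience wrapper: population, detections, visits, provisioning, truth."""
    attrs, truth = generate_population(config)
    detections, visits = simulate_visits(config, attrs)
    provisioning = simulate_provisioning(config)
    return {"attributes": attrs, "detections": detections, "visits": visits,
            "provisioning": provisioning, "ground_truth": truth, "config": config}


def write_scenario(scenario: dict, outdir):
    """Write a scenario as delimited text plus a JSON manifest (seed + config)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scenario["detections"].to_csv(out / "detections.csv", index=False,
                                  date_format="%Y-%m-%dT%H:%M:%S")
    scenario["attributes"].to_csv(out / "attributes.csv", index=False)
    scenario["visits"].to_csv(out / "visits_truth.csv", index=False,
                              date_format="%Y-%m-%dT%H:%M:%S")
    scenario["provisioning"].to_csv(out / "provisioning.csv", index=False,
                                    date_format="%Y-%m-%dT%H:%M:%S")
    manifest = {"seed": scenario["config"].rng_seed,
                "config": scenario["config"].to_manifest()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
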
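"""Simulation experiments for validating the permutation pipeline.

These routines wire the synthetic generator to the permutation machinery to
measure type-I error, power and effect-sign recovery — the quantitative
checks that the restricted data-stream null model behaves as advertised.
They back the heavier end of the test suite; scenario sizes are parameters
so callers can trade precision for runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .associations import build_grouping_events
from .inference import _ols_fit, _poisson_irls
from .networks import GBI, daily_cooccurrence, day_row_index, sri_from_gbi, strength
from .permutation import PermutationConfig, _dispersion, permutation_chain


def _scenario_gbi(config: synthetic.ScenarioConfig):
    """Simulate a scenario and pool its grouping events into one GBI."""
    attrs, _ = synthetic.generate_population(config)
    _, visits = synthetic.simulate_visits(config, attrs)
    events = build_grouping_events(visits)
    gbi = daily_cooccurrence(events)
    return gbi, attrs


def null_scenario_config(seed: int, n_territories: int = 1,
                         survey_length_days: int = 20) -> synthetic.ScenarioConfig:
    """Preference-free scenario: every dyad shares the same attraction.

    Grouping events with equal joining probability for every fox keep group
    membership exchangeable given the margins, which is the implicit null of
    the restricted-swap test.  Solo visits are kept sparse and durations
    short: singleton-dominated streams mix poorly under checkerboard swaps,
    and chance interval-chaining of independent visits is *not* uniform
    given margins — both measurably inflate coefficient P_rand rejection
    (see the calibration notes in the test suite).
    """
    return synthetic.ScenarioConfig(
        n_territories=n_territories, patches_per_territory=4,
        group_size_range=(8, 8), survey_length_days=survey_length_days,
        base_visit_rate=0.03, grouping_event_rate=0.25, join_probability=0.5,
        default_preference=0.5, mean_visit_duration_s=600.0,
        nonresident_rate={s: 0.0 for s in synthetic.SEASONS}, rng_seed=seed)


def modular_scenario_config(seed: int, survey_length_days: int = 20,
                            ) -> synthetic.ScenarioConfig:
    """Two strongly-bonded cliques inside one territory (modular preference)."""
    foxes = [f"T01-F{k:02d}" for k in range(1, 9)]
    cliques = [set(foxes[:4]), set(foxes[4:])]
    overrides = {}
    for i, a in enumerate(foxes):
        for b in foxes[i + 1:]:
            same = any(a in c and b in c for c in cliques)
            overrides[frozenset((a, b))] = 0.9 if same else 0.02
    return synthetic.ScenarioConfig(
        n_territories=1, patches_per_territory=4, group_size_range=(8, 8),
        survey_length_days=survey_length_days, base_visit_rate=0.15,
        grouping_event_rate=1.5, join_probability=1.0,
        default_preference=0.0, preference_overrides=overrides,
        nonresident_rate={s: 0.0 for s in synthetic.SEASONS}, rng_seed=seed)


def strength_sex_coefficient_metric(gbi: GBI, attrs: pd.DataFrame):
    """Metric factory: (OLS sex coefficient of node strength, SD of SRI).

    Both statistics are computed per chain step from the permuted GBI, so a
    single chain yields the coefficient null and the Manly/Bejder null.
    """
    rows = day_row_index(gbi.day_codes)
    sex = attrs.set_index("fox")["sex"].reindex(gbi.ids)
    X = np.column_stack([np.ones(len(gbi.ids)), (sex == "M").to_numpy(float)])

    def metric(g: GBI) -> np.ndarray:
        sri = sri_from_gbi(g.matrix, g.day_codes, rows)
        beta, _, _, _ = _ols_fit(X, strength(sri))
        return np.array([beta[1], _dispersion(sri, "sd_sri")])

    return metric


def coefficient_calibration(n_replicates: int = 200, n_permutations: int = 500,
                            seed: int = 0, survey_length_days: int = 30) -> dict:
    """Type-I error of the P_rand pipeline under preference-free scenarios.

    Per replicate: simulate a null scenario, chain ``n_permutations`` x 10
    swaps, and test (a) the sex coefficient of node strength (two-tailed
    P_rand outside [0.025, 0.975]) and (b) the Manly/Bejder SD statistic
    (one-tailed P < 0.05).  Returns the two rejection rates.
    """
    root = np.random.SeedSequence(seed)
    coef_sig = mb_sig = 0
    used = 0
    for k, child in enumerate(root.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = null_scenario_config(rep_seed, survey_length_days=survey_length_days)
        gbi, attrs = _scenario_gbi(cfg)
        if gbi.n_individuals < 2:
            continue
        metric = strength_sex_coefficient_metric(gbi, attrs)
        chain = permutation_chain(
            gbi, PermutationConfig(n_permutations=n_permutations, seed=rep_seed),
            metric)
        used += 1
        coef_obs, sd_obs = chain.observed
        vals = chain.values[~np.isnan(chain.values[:, 0])]
        p_coef = float(np.mean(vals[:, 0] > coef_obs))
        coef_sig += (p_coef < 0.025) or (p_coef > 0.975)
        p_mb = float(np.mean(vals[:, 1] >= sd_obs))
        mb_sig += p_mb < 0.05
    return {"n": used, "coef_rejection_rate": coef_sig / used,
            "mb_rejection_rate": mb_sig / used}


def manly_bejder_power(n_replicates: int = 100, n_permutations: int = 250,
                       seed: int = 0, survey_length_days: int = 20) -> dict:
    """Rejection rate of the Manly/Bejder test under modular preference."""
    root = np.random.SeedSequence(seed + 1)
    rejected = 0
    for child in root.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = modular_scenario_config(rep_seed, survey_length_days=survey_length_days)
        gbi, _ = _scenario_gbi(cfg)
        rows = day_row_index(gbi.day_codes)

        def stat(g: GBI) -> float:
            return _dispersion(sri_from_gbi(g.matrix, g.day_codes, rows), "sd_sri")

        chain = permutation_chain(
            gbi, PermutationConfig(n_permutations=n_permutations, seed=rep_seed),
            stat)
        vals = chain.values[~np.isnan(chain.values)]
        p = float(np.mean(vals >= chain.observed))
        rejected += p < 0.05
    return {"n": n_replicates, "power": rejected / n_replicates}


# ---------------------------------------------------------------------------
# effect-sign recovery with P_rand (winter deficit for males)
# ---------------------------------------------------------------------------

def deficit_scenario_config(seed: int, effect: float = -0.5,
                            n_territories: int = 2,
                            survey_length_days: int = 40) -> synthetic.ScenarioConfig:
    """Scenario with a log-rate winter deficit for males (sex x season effect)."""
    return synthetic.ScenarioConfig(
        n_territories=n_territories, patches_per_territory=3,
        group_size_range=(8, 8), survey_length_days=survey_length_days,
        base_visit_rate=0.8, grouping_event_rate=0.8, join_probability=0.9,
        default_preference=1.0, mean_visit_duration_s=120.0,
        sociality_effects={("M", "winter"): effect},
        nonresident_rate={s: 0.0 for s in synthetic.SEASONS}, rng_seed=seed)


def _contact_design(gbi: GBI, attrs: pd.DataFrame):
    """Precompute the (patch-day x fox) design pieces for contact-count refits.

    Response per permutation: for every fox x patch x day cell with at least
    one group membership, contacts = sum over its groups of (group size - 1).
    The design matrix (intercept, sex, status, season dummies, sex:season)
    depends only on the cell's season and the fox, so it is built once.
    """
    pd_keys = pd.factorize(pd.Index(
        [f"{t}|{s}|{d}|{p}" for t, s, d, p in
         zip(gbi.territory, gbi.season, gbi.survey_day, gbi.patch)]))[0]
    n_keys = pd_keys.max() + 1
    key_season = np.empty(n_keys, dtype=object)
    key_season[pd_keys] = gbi.season
    sex = attrs.set_index("fox")["sex"].reindex(gbi.ids).to_numpy()
    status = attrs.set_index("fox")["status"].reindex(gbi.ids).to_numpy()
    seasons = list(dict.fromkeys(synthetic.SEASONS))
    n_fox = len(gbi.ids)
    male = (sex == "M").astype(float)
    dom = (status == "dominant").astype(float)
    cols = ["Intercept", "sexM", "statusdom"]
    blocks = [np.ones((n_keys, n_fox)),
              np.tile(male, (n_keys, 1)),
              np.tile(dom, (n_keys, 1))]
    for s in seasons[1:]:
        ind = (key_season == s).astype(float)[:, None]
        blocks.append(np.tile(ind, (1, n_fox)))
        cols.append(f"season{s}")
        blocks.append(ind * male[None, :])
        cols.append(f"sexM:season{s}")
    X_full = np.stack([b.reshape(-1) for b in blocks], axis=1)
    return pd_keys, n_keys, X_full, cols


def contact_count_metric(gbi: GBI, attrs: pd.DataFrame, coef_name: str):
    """Metric factory: Poisson coefficient of daily contact counts.

    Counts are rebuilt from the (permuted) GBI under the gambit of the
    group: a fox in a group of size k has k-1 associations from that group.
    Group sizes and the patch-day keys never change under swaps, so the
    per-cell aggregation runs as a segment sum over a pre-sorted row order.
    """
    pd_keys, n_keys, X_full, cols = _contact_design(gbi, attrs)
    j = cols.index(coef_name)
    order = np.argsort(pd_keys, kind="stable")
    sorted_keys = pd_keys[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_keys) > 0])
    key_of_segment = sorted_keys[starts]

    def metric(g: GBI) -> float:
        sizes = g.matrix.sum(axis=1).astype(np.int64)
        arr = (g.matrix * (sizes - 1)[:, None])[order]
        seg_contacts = np.add.reduceat(arr, starts, axis=0)
        seg_present = np.add.reduceat(g.matrix[order], starts, axis=0) > 0
        contacts = np.zeros((n_keys, arr.shape[1]))
        present = np.zeros((n_keys, arr.shape[1]), dtype=bool)
        contacts[key_of_segment] = seg_contacts
        present[key_of_segment] = seg_present
        mask = present.reshape(-1)
        y = contacts.reshape(-1)[mask]
        X = X_full[mask]
        beta, _, _, conv = _poisson_irls(X, y)
        if not conv:
            raise RuntimeError("IRLS did not converge on null sample")
        return float(beta[j])

    return metric


def winter_deficit_recovery(n_replicates: int = 50, n_permutations: int = 500,
                            seed: int = 0, effect: float = -0.5,
                            swaps_per_step: int = 250) -> dict:
    """Share of replicates where the male x winter Poisson coefficient is
    recovered with the right (negative) sign and a significant P_rand.

    The deficit scenario's GBI has several thousand rows, so the default 10
    swaps between samples cannot move the chain away from the observed data
    (the null would hug the observed coefficient and power would collapse);
    the swap budget is scaled up so total mixing matches the matrix size.
    """
    root = np.random.SeedSequence(seed + 2)
    hits = 0
    observed = []
    for child in root.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = deficit_scenario_config(rep_seed, effect=effect)
        gbi, attrs = _scenario_gbi(cfg)
        metric = contact_count_metric(gbi, attrs, "sexM:seasonwinter")
        chain = permutation_chain(
            gbi, PermutationConfig(n_permutations=n_permutations,
                                   swaps_per_step=swaps_per_step, seed=rep_seed),
            metric)
        vals = chain.values[~np.isnan(chain.values)]
        p = float(np.mean(vals > chain.observed))
        observed.append(float(chain.observed))
        hits += (chain.observed < 0) and (p < 0.025 or p > 0.975)
    return {"n": n_replicates, "success_rate": hits / n_replicates,
            "mean_observed_coef": float(np.mean(observed))}


def icc_recovery(fraction: float, seed: int = 0, n_individuals: int = 200,
                 n_seasons: int = 4, n_territories: int = 20) -> float:
    """Estimated ICC on data simulated with an exact individual variance share.

    Effect vectors are standardised to their nominal variance exactly, so
    the target fraction is the realised truth, not just its expectation.
    """
    from .inference import icc_repeatability

    rng = np.random.default_rng(seed)
    var_terr = 0.5
    var_resid = 1.0
    var_ind = (fraction * (var_terr + var_resid) / (1 - fraction)
               if fraction < 1 else np.nan)

    fox = np.repeat(np.arange(n_individuals), n_seasons)
    terr = fox % n_territories

    def demean_by(v, groups):
        means = np.zeros(int(groups.max()) + 1)
        np.add.at(means, groups, v)
        counts = np.bincount(groups, minlength=means.size)
        return v - (means / np.maximum(counts, 1))[groups]

    def scaled(v, var, df):
        # scale so the mean square over the component's residual df hits the
        # nominal variance: that is the quantity the variance components see
        if var == 0:
            return np.zeros_like(v)
        v = v - v.mean()
        return v / np.sqrt((v @ v) / df) * np.sqrt(var)

    # Orthogonalise the strata (residuals demeaned per fox, fox effects per
    # territory) so seed luck cannot move the realised decomposition, and
    # give each stratum the mean square a balanced ANOVA expects there —
    # e.g. per-fox means must carry var_ind + var_resid/n_seasons.  REML
    # then recovers the nominal components up to optimisation error.
    n_obs = n_individuals * n_seasons
    per_terr = n_individuals / n_territories
    v_ind = var_ind if fraction > 0 else 0.0
    ms_fox = v_ind + var_resid / n_seasons
    ms_terr = var_terr + ms_fox / per_terr
    fox_eff = scaled(demean_by(rng.normal(size=n_individuals),
                               np.arange(n_individuals) % n_territories),
                     ms_fox, n_individuals - n_territories)
    terr_eff = scaled(rng.normal(size=n_territories), ms_terr,
                      n_territories - 1)
    resid = scaled(demean_by(rng.normal(size=n_obs), fox), var_resid,
                   n_obs - n_individuals)
    y = fox_eff[fox] + terr_eff[terr] + resid
    df = pd.DataFrame({"v": y, "fox": fox.astype(str),
                       "territory": terr.astype(str)})
    return icc_repeatability(df, "v").icc
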
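"""Restricted data-stream permutations and permutation-based inference.

Null models are generated by swapping individuals between groups observed
in the same territory on the same day, which preserves every group's size
and every individual's daily sighting history.  Observed statistics (model
coefficients, the SD of the association indices, assortativity, contrasts)
are compared against the chain of null values; ``P_rand`` is the proportion
of null values exceeding the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .networks import GBI, day_row_index, sri_from_gbi

logger = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    n_permutations: int = 2000
    swaps_per_step: int = 10
    seed: int | None = None
    statistic: str = "sd_sri"       # Manly/Bejder dispersion statistic: sd_sri | cv_sri
    max_retries: int = 200
    independent_restarts: bool = False  # re-randomise from observed each step

    def __post_init__(self):
        if self.n_permutations < 1 or self.swaps_per_step < 1:
            raise ValueError("n_permutations and swaps_per_step must be >= 1")


@dataclass
class NullDistribution:
    statistic: str
    observed: np.ndarray      # scalar or 1-d array of statistics
    values: np.ndarray        # (n_permutations,) or (n_permutations, k)
    labels: list = field(default_factory=list)
    n_failed: int = 0
    seed: int | None = None

    def __len__(self) -> int:
        return self.values.shape[0]


def _stratum_index(strata: np.ndarray):
    """Per-stratum group lists plus pair-count sampling weights.

    Sampling a stratum with probability proportional to its number of
    ordered group pairs, then a uniform pair inside it, is equivalent to a
    uniform random same-stratum pair — without rejection over all pairs.
    """
    groups = []
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        if idx.size >= 2:
            groups.append(idx)
    if not groups:
        return None
    weights = np.array([len(g) * (len(g) - 1) for g in groups], dtype=float)
    return groups, np.cumsum(weights / weights.sum())


def restricted_swap(matrix: np.ndarray, strata: np.ndarray,
                    rng: np.random.Generator, max_retries: int = 200,
                    index=None) -> bool:
    """One checkerboard swap between two groups of the same territory-day.

    Samples a random same-stratum pair of groups, picks individuals i (in
    the first only) and j (in the second only) and exchanges them.  Row
    sums and per-stratum column sums are invariant.  Returns False (after
    ``max_retries`` resamples) when no swap was found.  ``index`` is an
    optional precomputed :func:`_stratum_index` (chains reuse it).
    """
    if index is None:
        index = _stratum_index(strata)
    if index is None:
        return False
    groups, cumw = index
    for _ in range(max_retries):
        idx = groups[np.searchsorted(cumw, rng.random())]
        g1, g2 = idx[rng.integers(idx.size)], idx[rng.integers(idx.size)]
        if g1 == g2:
            continue
        r1, r2 = matrix[g1], matrix[g2]
        cand_i = np.nonzero(r1 & ~r2)[0]
        cand_j = np.nonzero(r2 & ~r1)[0]
        if cand_i.size == 0 or cand_j.size == 0:
            continue
        i = cand_i[rng.integers(cand_i.size)]
        j = cand_j[rng.integers(cand_j.size)]
        matrix[g1, i] = 0
        matrix[g2, i] = 1
        matrix[g2, j] = 0
        matrix[g1, j] = 1
        return True
    logger.debug("no checkerboard found in %d resamples; swap skipped", max_retries)
    return False


def permutation_chain(gbi: GBI, config: PermutationConfig, metric_fn) -> NullDistribution:
    """Sequential data-stream permutation chain.

    Starting from the observed GBI, performs ``swaps_per_step`` restricted
    swaps, records ``metric_fn(gbi)``, and repeats ``n_permutations`` times
    (cumulative Markov chain, the standard data-stream practice).  With
    ``independent_restarts`` each step instead restarts from the observed
    matrix.  ``metric_fn`` may return a scalar or a 1-d array; failures are
    recorded as NaN and counted.
    """
    rng = np.random.default_rng(config.seed)
    observed = np.atleast_1d(np.asarray(metric_fn(gbi), dtype=float))
    work = gbi.copy()
    strata = work.strata
    index = _stratum_index(strata)
    values = np.full((config.n_permutations, observed.size), np.nan)
    n_failed = 0
    degenerate_warned = False
    for step in range(config.n_permutations):
        if config.independent_restarts:
            work.matrix[:] = gbi.matrix
        swapped = 0
        for _ in range(config.swaps_per_step):
            swapped += restricted_swap(work.matrix, strata, rng,
                                       config.max_retries, index)
        if swapped == 0 and not degenerate_warned:
            logger.warning("permutation step performed no swaps; "
                           "chain may be degenerate (identity permutation)")
            degenerate_warned = True
        try:
            values[step] = np.atleast_1d(np.asarray(metric_fn(work), dtype=float))
        except Exception as exc:  # noqa: BLE001 - null-sample failures are data
            n_failed += 1
            logger.debug("metric failed on null sample %d: %s", step, exc)
    if observed.size == 1:
        observed = observed[0]
        values = values[:, 0]
    return NullDistribution(statistic=getattr(metric_fn, "__name__", "metric"),
                            observed=observed, values=values,
                            n_failed=n_failed, seed=config.seed)


def p_rand(null: NullDistribution | None = None, *, observed=None, values=None):
    """Two-tailed permutation P-value and significance flag.

    ``P_rand = #{beta_rand > beta_obs} / n`` (ties count as not-greater).
    Significant at the 0.05 level when P_rand falls outside [0.025, 0.975].
    Also returns the one-tailed conversion ``1 - P_rand``.
    """
    if null is not None:
        observed, values = null.observed, null.values
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("empty null distribution")
    p = float(np.mean(vals > observed))
    return {"p_rand": p,
            "significant": p < 0.025 or p > 0.975,
            "one_tailed": 1.0 - p,
            "n_used": int(vals.size)}


def _dispersion(sri: np.ndarray, statistic: str) -> float:
    iu = np.triu_indices(sri.shape[0], k=1)
    w = sri[iu]
    if statistic == "cv_sri":
        mean = w.mean()
        return float(w.std() / mean) if mean > 0 else float("nan")
    return float(w.std())


def manly_bejder_test(gbi: GBI, config: PermutationConfig | None = None) -> dict:
    """Test for non-random association (preferred/avoided companions).

    Statistic: SD (or CV) of the off-diagonal association indices; preferred
    and avoided companions inflate it relative to the swap-generated null.
    One-tailed: P = proportion of null statistics >= observed; the network
    is non-random when P < 0.05.  Degenerate (all-zero) matrices are skipped
    and flagged random.
    """
    config = config or PermutationConfig()
    if gbi.n_individuals < 2 or len(np.unique(gbi.day_codes)) < 2:
        raise ValueError("Manly/Bejder test needs >= 2 individuals and >= 2 days")
    observed_sri = sri_from_gbi(gbi.matrix, gbi.day_codes)
    if not np.any(observed_sri > 0):
        logger.warning("all-zero association matrix: test skipped, network flagged random")
        return {"statistic_obs": 0.0, "p": float("nan"), "nonrandom": False,
                "skipped": True}

    rows = day_row_index(gbi.day_codes)

    def stat(g: GBI) -> float:
        return _dispersion(sri_from_gbi(g.matrix, g.day_codes, rows), config.statistic)

    null = permutation_chain(gbi, config, stat)
    vals = null.values[~np.isnan(null.values)]
    p = float(np.mean(vals >= null.observed))
    return {"statistic_obs": float(null.observed), "p": p,
            "nonrandom": p < 0.05, "skipped": False, "null": null}


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment; adjusted P-values are monotone in the raw order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def posthoc_prand(observed: dict, null_values: dict) -> "pd.DataFrame":
    """One-tailed, Holm-adjusted permutation P-values for a contrast family.

    ``observed`` maps contrast label -> observed estimate; ``null_values``
    maps label -> array of null estimates (NaN entries — inestimable null
    samples — are dropped and counted).  The raw ``P_rand`` is converted to
    one-tailed by taking ``1 - P`` when it exceeds 0.5; significance is
    adjusted-P < 0.05.
    """
    import pandas as pd

    rows = []
    for label, obs in observed.items():
        vals = np.asarray(null_values[label], dtype=float)
        dropped = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        p = float(np.mean(vals > obs)) if vals.size else float("nan")
        p_one = 1.0 - p if p > 0.5 else p
        rows.append({"contrast": label, "estimate": float(obs),
                     "p_rand": p, "p_one_tailed": p_one, "n_dropped": dropped})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["p_one_tailed"].to_numpy())
    out["significant"] = out["p_adjusted"] < 0.05
    return out


def write_null_distribution(null: NullDistribution, path, config: PermutationConfig | None = None):
    """Persist a null distribution as delimited text with a reproducibility header."""
    vals = np.atleast_2d(null.values.T).T
    labels = null.labels or [f"stat_{k}" for k in range(vals.shape[1])]
    with open(path, "w") as fh:
        fh.write(f"# statistic: {null.statistic}\n")
        fh.write(f"# observed: {np.atleast_1d(null.observed).tolist()}\n")
        fh.write(f"# seed: {null.seed}\n")
        if config is not None:
            fh.write(f"# n_permutations: {config.n_permutations} "
                     f"swaps_per_step: {config.swaps_per_step}\n")
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, vals, delimiter="\t")
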
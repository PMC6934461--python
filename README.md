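# foxnets

Camera-trap social-network analysis for territorial canid groups.

The pipeline turns a stream of identified camera-trap photographs at
provisioned food patches into:

1. **Visits** — photographs of a fox at a patch collapsed with a 15-minute
   gap rule; survey "days" run noon to noon.
2. **Associations** — gambit of the group: temporally overlapping visits
   become dyadic encounters (with durations) and chained grouping events;
   daily per-patch contact counts treat presence without encounters as a
   real zero.
3. **Networks** — simple-ratio-index (SRI) association matrices per
   territory-season over one-day sampling periods, with global metrics
   (unweighted/weighted density, transitivity), node metrics (strength,
   eigenvector centrality, Onnela weighted clustering) and weighted
   discrete assortment by sex and social status.
4. **Permutation inference** — restricted data-stream permutations
   (checkerboard swaps within territory-days, preserving group sizes and
   individual daily sighting histories), the Manly/Bejder non-randomness
   test, `P_rand` coefficient tests and Holm-adjusted post-hoc contrasts.
5. **Models** — Poisson/Gaussian/Gamma (G)LMMs for contact rates and
   centrality, a negative-binomial hurdle model for encounter durations,
   Tukey/Šidák contrasts, prediction grids, and ICC repeatability of
   network position across seasons.
6. **Synthetic data** — a seeded generator (territory groups with dominant
   pairs, per-fox visit point processes with sex/status/season log-linear
   rate structure, preference-driven grouping events, non-resident
   intrusions, provisioning logs) with full ground truth, so every stage is
   testable without field data.

## CLI

```bash
foxnets simulate --seed 1 --territories 7 --days 40 --out scenario/
foxnets visits --detections scenario/detections.csv --out visits.csv
foxnets associate --visits scenario/visits_truth.csv --out assoc/
foxnets run --seed 1 --n-permutations 2000 --out results/   # end to end
foxnets report --bundle results/
```

`foxnets run` simulates a scenario, builds all territory-season networks,
runs the Manly/Bejder test on each, computes node metrics and assortment
for residents of non-random networks, and fits the ICC repeatability
models. Outputs are delimited text plus GraphML networks and a JSON
manifest with the seed and every threshold applied.

## Library entry points

```python
from foxnets import (
    ScenarioConfig, simulate_scenario,           # synthetic data
    collapse_to_visits, classify_residency,      # observations
    detect_encounters, build_grouping_events,    # associations
    daily_cooccurrence, sri_matrix, node_metrics,  # networks
    PermutationConfig, permutation_chain, p_rand, manly_bejder_test,
    ModelSpec, fit_model, fit_hurdle_duration, icc_repeatability,
)
```

See the module docstrings for the precise definitions (gap rule, SRI
tallies, swap restrictions, `P_rand` conventions, ICC thresholds).
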
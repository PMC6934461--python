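"""Association networks: group-by-individual matrices, simple-ratio-index
matrices and global / node-level connectivity metrics.

The simple ratio index (SRI) for a dyad over one-day sampling periods is
``x / (x + yAB + yA + yB)`` where, per day, x counts days together (sharing
at least one grouping event at any included patch), yAB days both seen but
never together, and yA / yB days only one was seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# group-by-individual matrix
# ---------------------------------------------------------------------------

@dataclass
class GBI:
    """Group-by-individual incidence matrix with per-group metadata.

    One row per grouping event (or singleton sighting); one column per fox.
    ``territory``/``season``/``survey_day``/``patch`` are per-row arrays;
    restricted permutations swap individuals only between rows sharing a
    territory and day.
    """

    matrix: np.ndarray            # (n_groups, n_individuals) of 0/1
    ids: list
    territory: np.ndarray
    season: np.ndarray
    survey_day: np.ndarray
    patch: np.ndarray
    _strata: np.ndarray | None = field(default=None, repr=False)
    _day_codes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    @property
    def strata(self) -> np.ndarray:
        """Integer codes for (territory, season, survey_day) — the swap restriction."""
        if self._strata is None:
            keys = [f"{t}|{s}|{d}" for t, s, d in
                    zip(self.territory, self.season, self.survey_day)]
            self._strata = pd.factorize(pd.Index(keys))[0]
        return self._strata

    @property
    def day_codes(self) -> np.ndarray:
        """Integer codes for (season, survey_day) — the one-day sampling period."""
        if self._day_codes is None:
            keys = [f"{s}|{d}" for s, d in zip(self.season, self.survey_day)]
            self._day_codes = pd.factorize(pd.Index(keys))[0]
        return self._day_codes

    def copy(self) -> "GBI":
        return GBI(self.matrix.copy(), list(self.ids), self.territory,
                   self.season, self.survey_day, self.patch,
                   self._strata, self._day_codes)


def daily_cooccurrence(events: pd.DataFrame, eligible=None) -> GBI:
    """Build a GBI from grouping events (one row per event, one-day periods).

    Members outside ``eligible`` (an iterable of fox ids, optional) are
    dropped; events left empty disappear.  Singleton events keep foxes seen
    alone in the sampling record, so SRI denominators count them.
    """
    members = []
    meta = []
    for patch, terr, season, day, foxes in zip(
            events["patch"], events["territory"], events["season"],
            events["survey_day"], events["foxes"]):
        fx = tuple(f for f in foxes if eligible is None or f in eligible)
        if not fx:
            continue
        members.append(fx)
        meta.append((terr, season, int(day), patch))
    ids = sorted({f for fx in members for f in fx})
    idx = {f: i for i, f in enumerate(ids)}
    mat = np.zeros((len(members), len(ids)), dtype=np.uint8)
    for r, fx in enumerate(members):
        for f in fx:
            mat[r, idx[f]] = 1
    meta = np.asarray(meta, dtype=object).reshape(len(members), 4)
    return GBI(mat, ids,
               territory=meta[:, 0], season=meta[:, 1],
               survey_day=meta[:, 2].astype(int) if len(members) else meta[:, 2],
               patch=meta[:, 3])


# ---------------------------------------------------------------------------
# simple ratio index
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    ids: list
    sri: np.ndarray
    x: np.ndarray        # days together
    yab: np.ndarray      # days both seen, never together
    ya: np.ndarray       # days only the row fox seen
    yb: np.ndarray       # days only the column fox seen
    sampling_periods: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)


def day_row_index(day_codes: np.ndarray) -> list:
    """Row indices per sampling day; precompute once for permutation chains."""
    return [np.nonzero(day_codes == d)[0] for d in np.unique(day_codes)]


def pair_day_counts(matrix: np.ndarray, day_codes: np.ndarray, rows: list | None = None):
    """Per-dyad day tallies (x, both-seen, seen_i) from a GBI matrix."""
    n = matrix.shape[1]
    x = np.zeros((n, n))
    if rows is None:
        rows = day_row_index(day_codes)
    seen = np.zeros((len(rows), n), dtype=np.int64)
    m = matrix.astype(np.int64)
    for k, idx in enumerate(rows):
        sub = m[idx]
        x += (sub.T @ sub) > 0
        seen[k] = sub.any(axis=0)
    both = seen.T @ seen
    np.fill_diagonal(x, 0)
    return x, both, seen.sum(axis=0)


def sri_from_gbi(matrix: np.ndarray, day_codes: np.ndarray,
                 rows: list | None = None) -> np.ndarray:
    """SRI matrix only (fast path used inside permutation chains)."""
    x, both, totals = pair_day_counts(matrix, day_codes, rows)
    either = totals[:, None] + totals[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, x / np.where(either > 0, either, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    return sri


def sri_matrix(gbi: GBI) -> AssociationMatrix:
    """Full SRI association matrix with the underlying dyadic tallies."""
    x, both, totals = pair_day_counts(gbi.matrix, gbi.day_codes)
    yab = both - x
    ya = totals[:, None] - both
    yb = totals[None, :] - both
    denom = x + yab + ya + yb
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, x / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    return AssociationMatrix(list(gbi.ids), sri, x, yab, ya, yb,
                             sampling_periods=len(np.unique(gbi.day_codes)))


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    n_nodes: int
    unweighted_density: float
    weighted_density: float
    transitivity: float  # NaN when no connected triples exist


def global_metrics(sri: np.ndarray) -> GlobalMetrics:
    """Unweighted/weighted density and transitivity of an SRI network.

    Weighted density is the sum of edge weights over the number of possible
    edges, i.e. the mean association index.  Transitivity is computed on the
    binarised (w > 0) graph: closed triads over connected triples.
    """
    n = sri.shape[0]
    if n < 2:
        raise ValueError("global metrics need at least two nodes")
    iu = np.triu_indices(n, k=1)
    w = sri[iu]
    possible = n * (n - 1) / 2
    a = (sri > 0).astype(float)
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    triples = float((deg * (deg - 1)).sum())
    closed = float(np.trace(a @ a @ a))
    transitivity = closed / triples if triples > 0 else float("nan")
    return GlobalMetrics(n_nodes=n,
                         unweighted_density=float((w > 0).sum() / possible),
                         weighted_density=float(w.sum() / possible),
                         transitivity=transitivity)


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------

def strength(sri: np.ndarray) -> np.ndarray:
    """Weighted degree: sum of a node's incident edge weights (row sums).

    Foxes only ever seen alone have strength zero.  A before/after-midnight
    variant is obtained by rebuilding the SRI from window-restricted
    grouping events and calling this on the result.
    """
    return sri.sum(axis=1)


def strength_transform(values) -> np.ndarray:
    """log10(v + 1), the modelling scale for the split-day strength model."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("strength values must be non-negative")
    return np.log10(v + 1.0)


def _components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def eigenvector_centrality(sri: np.ndarray) -> np.ndarray:
    """Leading-eigenvector centrality of the weighted SRI matrix.

    Computed per connected component; the component with the largest leading
    eigenvalue carries the scores (absolute values, scaled so the maximum
    entry is 1) and all other nodes score zero.  An all-zero matrix returns
    all zeros.
    """
    n = sri.shape[0]
    out = np.zeros(n)
    if n == 0 or not np.any(sri > 0):
        return out
    best_lam, best = -np.inf, None
    for comp in _components(sri > 0):
        sub = sri[np.ix_(comp, comp)]
        lam, vecs = np.linalg.eigh(sub)
        if lam[-1] > best_lam:
            best_lam, best = lam[-1], (comp, np.abs(vecs[:, -1]))
    comp, vec = best
    if vec.max() > 0:
        vec = vec / vec.max()
    out[np.asarray(comp)] = vec
    return out


def clustering_onnela(sri: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient (geometric-mean triangle intensity).

    ``C_i = [k_i (k_i - 1)]^{-1} sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3}`` with
    weights normalised by the network maximum.  Nodes of degree < 2 get NaN
    (undefined; excluded from models downstream).
    """
    n = sri.shape[0]
    wmax = sri.max()
    if n == 0:
        return np.zeros(0)
    if wmax <= 0:
        return np.full(n, np.nan)
    w = (sri / wmax) ** (1.0 / 3.0)
    np.fill_diagonal(w, 0.0)
    num = np.diagonal(w @ w @ w).copy()
    deg = (sri > 0).sum(axis=1)
    denom = deg * (deg - 1)
    out = np.full(n, np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


@dataclass
class NodeMetrics:
    ids: list
    strength: np.ndarray
    eigenvector: np.ndarray
    clustering: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fox": self.ids, "strength": self.strength,
                             "eigenvector": self.eigenvector,
                             "clustering": self.clustering})


def node_metrics(assoc: AssociationMatrix) -> NodeMetrics:
    return NodeMetrics(list(assoc.ids), strength(assoc.sri),
                       eigenvector_centrality(assoc.sri),
                       clustering_onnela(assoc.sri))


# ---------------------------------------------------------------------------
# assortment
# ---------------------------------------------------------------------------

def assortativity(sri: np.ndarray, attributes) -> float:
    """Weighted discrete assortativity coefficient (range -1 to 1).

    From the edge-weight mixing matrix ``e`` (normalised to sum 1),
    ``r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)`` with a, b the
    marginals.  Positive: nodes associate with similar phenotypes.  Raises
    on single-category networks (undefined).
    """
    attrs = np.asarray(attributes)
    cats, codes = np.unique(attrs, return_inverse=True)
    if len(cats) < 2:
        raise ValueError("assortativity undefined for a single-category network")
    k = len(cats)
    z = np.zeros((len(attrs), k))
    z[np.arange(len(attrs)), codes] = 1.0
    e = z.T @ sri @ z
    total = e.sum()
    if total <= 0:
        raise ValueError("assortativity undefined for an empty network")
    e = e / total
    ab = float(e.sum(axis=1) @ e.sum(axis=0))
    if ab >= 1.0:
        raise ValueError("assortativity undefined: degenerate mixing")
    return float((np.trace(e) - ab) / (1.0 - ab))


def to_networkx(assoc: AssociationMatrix):
    """Export as a weighted undirected networkx graph (for GraphML etc.)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(assoc.ids)
    n = len(assoc.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if assoc.sri[i, j] > 0:
                g.add_edge(assoc.ids[i], assoc.ids[j], weight=float(assoc.sri[i, j]))
    return g
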
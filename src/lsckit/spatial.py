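"""Structural clustering and rate-uniformity statistics.

The clustering test conditions on the observed rate-shift (type I) sites:
only the assignment of sites to the two quartet edges is permuted, so the
null hypothesis is "type I transitions are exchangeable between edges", not
"type I sites are uniform on the structure" — rate shifts may well be
concentrated in particular regions under the null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core_io import InputError, StructureMap, logger

DEFAULT_CONTACT_THRESHOLD = 4.0  # Å, α-carbon rule


# ---------------------------------------------------------------------------
# contact graph
# ---------------------------------------------------------------------------


def build_contact_graph(
    structmap: StructureMap,
    typed_columns: list[int],
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    atom_mode: str = "CA",
) -> nx.Graph:
    """Graph over typed alignment columns; edges join residues within threshold.

    ``atom_mode`` "CA"/"CB" measures representative-atom distance (whatever
    representative the structure reader extracted); "any-atom-min" uses the
    minimum distance over all heavy-atom pairs of the two residues.  Typed
    columns without a structure mapping (gapped in the reference row) are
    dropped with a warning.
    """
    mapped, unmapped = [], []
    for col in sorted(set(typed_columns)):
        (mapped if col in structmap.col_to_residue else unmapped).append(col)
    if unmapped:
        logger.warning(
            "%d typed columns are unmapped in the reference structure "
            "and were dropped: %s", len(unmapped), unmapped,
        )
    graph = nx.Graph()
    graph.add_nodes_from(mapped)
    if threshold <= 0 or len(mapped) < 2:
        return graph
    records = [structmap.residue(c) for c in mapped]
    reps = np.vstack([r.coord for r in records])
    if atom_mode in ("CA", "CB"):
        tree = cKDTree(reps)
        for i, j in tree.query_pairs(threshold):
            d = float(np.linalg.norm(reps[i] - reps[j]))
            graph.add_edge(mapped[i], mapped[j], distance=d)
    elif atom_mode == "any-atom-min":
        spans = np.array(
            [np.linalg.norm(r.atom_coords - r.coord, axis=1).max() for r in records]
        )
        tree = cKDTree(reps)
        margin = threshold + 2.0 * float(spans.max())
        for i, j in tree.query_pairs(margin):
            d = float(cdist(records[i].atom_coords, records[j].atom_coords).min())
            if d <= threshold:
                graph.add_edge(mapped[i], mapped[j], distance=d)
    else:
        raise InputError(f"unknown atom_mode {atom_mode!r}")
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"column_i": u, "column_j": v, "distance": d.get("distance", np.nan)}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["column_i", "column_j", "distance"]).to_csv(
        path, sep="\t", index=False, float_format="%.3f"
    )


# ---------------------------------------------------------------------------
# quartet clustering test
# ---------------------------------------------------------------------------


@dataclass
class QuartetConfig:
    """Configuration of the quartet clustering permutation test."""

    quartet: tuple[tuple[str, str], tuple[str, str]] | None = None
    n_sites: int = 25  # sites selected per quartet edge
    n_perm: int = 100_000
    seed: int = 0
    exact_threshold: int = 16  # pool size at or below which we enumerate

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise InputError("n_sites must be at least 2")
        if self.n_perm < 1:
            raise InputError("n_perm must be at least 1")


def select_quartet_sites(
    posteriors_ab: pd.DataFrame,
    posteriors_cd: pd.DataFrame,
    n_sites: int = 25,
) -> tuple[list[int], list[int]]:
    """Top-N columns per quartet edge by type I posterior; common sites dropped.

    Sites appearing in both top lists are discarded from both, so the two
    returned sets are disjoint and of equal size N' = N − |common|.
    """

    def top(df: pd.DataFrame) -> list[int]:
        if len(df) < n_sites:
            raise InputError(
                f"only {len(df)} callable sites on an edge; "
                f"reduce n_sites from {n_sites} (clade pair may have too "
                "little tree length to exhibit that many type I sites)"
            )
        ranked = df.sort_values(
            ["posterior", "column"], ascending=[False, True], kind="mergesort"
        )
        return ranked["column"].head(n_sites).astype(int).tolist()

    top_ab, top_cd = top(posteriors_ab), top(posteriors_cd)
    common = set(top_ab) & set(top_cd)
    e1 = sorted(set(top_ab) - common)
    e2 = sorted(set(top_cd) - common)
    if not e1 or not e2:
        raise InputError("quartet site pools empty after removing common sites")
    return e1, e2


def clustering_statistic(
    sites_e1: list[int], sites_e2: list[int], graph: nx.Graph
) -> int:
    """Number of same-edge site pairs that are contact-graph neighbors."""
    s = 0
    for group in (sites_e1, sites_e2):
        for a, b in itertools.combinations(group, 2):
            if graph.has_edge(a, b):
                s += 1
    return s


def consecutive_statistic(
    sites_e1: list[int], sites_e2: list[int], structmap: StructureMap
) -> int:
    """Number of same-edge site pairs mapping to sequence-adjacent residues."""
    s = 0
    for group in (sites_e1, sites_e2):
        idx = sorted(
            structmap.residue_index(c) for c in group if c in structmap.col_to_residue
        )
        s += sum(1 for a, b in zip(idx, idx[1:]) if b - a == 1)
    return s


@dataclass
class ClusterTestResult:
    statistic: int
    p_value: float
    mode: str  # "exact" | "monte-carlo"
    per_edge: tuple[int, int]
    pool_size: int
    n_perm: int | None
    seed: int | None


def _pair_adjacency(pool: list[int], graph: nx.Graph) -> np.ndarray:
    n = len(pool)
    A = np.zeros((n, n), dtype=np.float32)
    for i, j in itertools.combinations(range(n), 2):
        if graph.has_edge(pool[i], pool[j]):
            A[i, j] = A[j, i] = 1.0
    return A


def clustering_permutation_test(
    sites_e1: list[int],
    sites_e2: list[int],
    graph: nx.Graph,
    config: QuartetConfig | None = None,
) -> ClusterTestResult:
    """Permutation test of spatial clustering of type I transitions.

    Null draws re-assign the pooled 2N' sites at random into two labeled
    groups of N' and recompute the statistic.  When the pool is small enough
    (``exact_threshold``) all C(2N', N') assignments are enumerated and the
    exact upper-tail proportion is reported; otherwise Monte-Carlo sampling
    with the add-one correction p = (1 + #{S* ≥ S}) / (1 + n_perm).
    """
    config = config or QuartetConfig()
    if set(sites_e1) & set(sites_e2):
        raise InputError("quartet site sets must be disjoint")
    if len(sites_e1) != len(sites_e2):
        raise InputError("quartet site sets must have equal size")
    pool = sorted(sites_e1) + sorted(sites_e2)
    k = len(sites_e1)
    A = _pair_adjacency(pool, graph)
    z_obs = np.zeros(len(pool), dtype=np.float32)
    z_obs[:k] = 1.0

    def stat(Z: np.ndarray) -> np.ndarray:
        # Z: (batch, pool) 0/1 membership of group 1
        s1 = np.einsum("bi,ij,bj->b", Z, A, Z) / 2.0
        W = 1.0 - Z
        s2 = np.einsum("bi,ij,bj->b", W, A, W) / 2.0
        return s1 + s2

    s_obs = int(round(float(stat(z_obs[None, :])[0])))
    s1_obs = int(round(float(np.einsum("i,ij,j->", z_obs, A, z_obs) / 2.0)))
    per_edge = (s1_obs, s_obs - s1_obs)

    if len(pool) <= config.exact_threshold:
        total = comb(len(pool), k)
        count = 0
        for combo in itertools.combinations(range(len(pool)), k):
            z = np.zeros(len(pool), dtype=np.float32)
            z[list(combo)] = 1.0
            if stat(z[None, :])[0] >= s_obs - 1e-9:
                count += 1
        return ClusterTestResult(
            statistic=s_obs, p_value=count / total, mode="exact",
            per_edge=per_edge, pool_size=len(pool), n_perm=None, seed=None,
        )

    rng = np.random.default_rng(config.seed)
    n_perm = config.n_perm
    hits = 0
    batch = 20_000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        order = rng.random((b, len(pool))).argsort(axis=1)
        Z = np.zeros((b, len(pool)), dtype=np.float32)
        np.put_along_axis(Z, order[:, :k], 1.0, axis=1)
        hits += int((stat(Z) >= s_obs - 1e-9).sum())
        done += b
    p = (1 + hits) / (1 + n_perm)
    return ClusterTestResult(
        statistic=s_obs, p_value=p, mode="monte-carlo",
        per_edge=per_edge, pool_size=len(pool), n_perm=n_perm, seed=config.seed,
    )


# ---------------------------------------------------------------------------
# region rate tests
# ---------------------------------------------------------------------------


def _region_resample_p(
    values: np.ndarray,
    region_idx: np.ndarray,
    n_resample: int,
    seed: int,
    alternative: str,
    exact_limit: int = 50_000,
) -> tuple[float, str]:
    n, k = values.size, region_idx.size
    if k == 0:
        raise InputError("empty region")
    if k >= n:
        raise InputError("region must be strictly inside the column set")
    obs = float(values[region_idx].sum())

    def tail(sums: np.ndarray, total: int) -> float:
        lo = float((sums <= obs + 1e-9).sum())
        hi = float((sums >= obs - 1e-9).sum())
        if alternative == "less":
            cnt = lo
        elif alternative == "greater":
            cnt = hi
        elif alternative == "two-sided":
            return min(1.0, 2.0 * min(lo, hi) / total)
        else:
            raise InputError(f"unknown alternative {alternative!r}")
        return cnt / total

    if comb(n, k) <= exact_limit:
        sums = np.array(
            [values[list(c)].sum() for c in itertools.combinations(range(n), k)]
        )
        return tail(sums, sums.size), "exact"
    rng = np.random.default_rng(seed)
    sums = np.empty(n_resample)
    batch = 20_000
    done = 0
    while done < n_resample:
        b = min(batch, n_resample - done)
        idx = rng.random((b, n)).argsort(axis=1)[:, :k]
        sums[done : done + b] = values[idx].sum(axis=1)
        done += b
    # add-one correction: the observed subset is one more draw from the null
    if alternative == "two-sided":
        lo = 1 + int((sums <= obs + 1e-9).sum())
        hi = 1 + int((sums >= obs - 1e-9).sum())
        return min(1.0, 2.0 * min(lo, hi) / (1 + n_resample)), "monte-carlo"
    cnt = (
        (sums <= obs + 1e-9) if alternative == "less" else (sums >= obs - 1e-9)
    ).sum()
    return (1 + int(cnt)) / (1 + n_resample), "monte-carlo"


def _region_indices(site_counts: np.ndarray, region_columns) -> np.ndarray:
    idx = np.asarray(sorted(set(int(c) for c in region_columns)), dtype=int) - 1
    if idx.size and (idx.min() < 0 or idx.max() >= site_counts.size):
        raise InputError("region columns outside the alignment")
    return idx


def region_location_test(
    site_counts: np.ndarray,
    region_columns,
    n_resample: int = 100_000,
    seed: int = 0,
    alternative: str = "less",
) -> float:
    """Resampling test that a region's mean substitution count is low.

    Compares the mean count over the region's columns with means of random
    same-size column subsets; the default lower tail matches the question
    "does this region evolve more slowly than the remainder?".  Small pools
    are enumerated exactly; otherwise 100,000 resamples.
    """
    values = np.asarray(site_counts, dtype=float)
    idx = _region_indices(values, region_columns)
    p, _ = _region_resample_p(values, idx, n_resample, seed, alternative)
    return p


def region_distribution_test(
    site_counts: np.ndarray,
    region_columns,
    n_resample: int = 100_000,
    seed: int = 0,
    alternative: str = "less",
) -> float:
    """Rank-sum resampling test that a region's count distribution differs.

    Ranks (mid-ranks for ties) are computed once over all columns; the
    statistic is the region's rank sum, compared against random same-size
    subsets — a permutation Wilcoxon test against the remainder.
    """
    values = np.asarray(site_counts, dtype=float)
    idx = _region_indices(values, region_columns)
    ranks = stats.rankdata(values)
    p, _ = _region_resample_p(ranks, idx, n_resample, seed, alternative)
    return p


# ---------------------------------------------------------------------------
# Poisson rate-uniformity likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class RateUniformityResult:
    statistic: float  # -2 log Λ
    df: int
    p_value: float
    rates: np.ndarray  # per-tree λ̂_i = x_i / t_i
    pooled_rate: float


def poisson_lrt(x_list, t_list) -> RateUniformityResult:
    """Likelihood-ratio test that one Poisson rate is shared by n trees.

    Totals x_i over tree lengths t_i; under H0 the pooled rate is
    λ̂ = Σx/Σt and −2 log Λ = 2 Σ x_i log(x_i / (λ̂ t_i)) (0·log 0 = 0),
    asymptotically chi-square with n−1 degrees of freedom.
    """
    x = np.asarray(x_list, dtype=float)
    t = np.asarray(t_list, dtype=float)
    if x.size != t.size or x.size < 2:
        raise InputError("need matched x and t for at least two trees")
    if (t <= 0).any():
        raise InputError("tree lengths must be positive")
    if (x < 0).any():
        raise InputError("counts must be non-negative")
    pooled = float(x.sum() / t.sum())
    if x.sum() == 0:
        return RateUniformityResult(0.0, x.size - 1, 1.0, x / t, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(x / (pooled * t)), 0.0)
    stat = max(0.0, 2.0 * float(terms.sum()))
    df = x.size - 1
    return RateUniformityResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
        rates=x / t, pooled_rate=pooled,
    )


def replicate_tree_rate_tests(
    subtree_counts: dict[str, float],
    subtree_lengths: dict[str, float],
    stem_counts: dict[str, float],
    stem_lengths: dict[str, float],
) -> tuple[RateUniformityResult, RateUniformityResult]:
    """Rate-uniformity LRTs over replicate subtrees and over their stem edges.

    The replicate design: several subtrees spanning the same organism set
    hang off a common ancestor; uniformity is tested separately for whole
    subtree totals and for the stem edges connecting them to the ancestor.
    """
    keys = sorted(subtree_counts)
    for d, name in (
        (subtree_lengths, "subtree_lengths"),
        (stem_counts, "stem_counts"),
        (stem_lengths, "stem_lengths"),
    ):
        if sorted(d) != keys:
            raise InputError(f"replicate membership mismatch in {name}")
    subtree = poisson_lrt([subtree_counts[k] for k in keys],
                          [subtree_lengths[k] for k in keys])
    stem = poisson_lrt([stem_counts[k] for k in keys],
                       [stem_lengths[k] for k in keys])
    return subtree, stem
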
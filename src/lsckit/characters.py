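"""Latent structural characters (LSCs) and parsimony over their states.

An LSC is a connected subgraph of the typed-column contact graph with at
least two members, at least one of which is a rate-shift (type I) or
preference-shift (type II) site.  Each LSC receives one categorical state
per clade; the clade × character state table is then searched exhaustively
under maximum parsimony (unordered states, Fitch counting) over all unrooted
binary topologies, which is feasible up to nine taxa (135,135 topologies).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, GAP, CladePartition, InputError, MultipleAlignment
from .divergence import GROUP_OF

TYPED_CLASSES = ("type0", "typeI", "typeII")


@dataclass
class LSC:
    """One latent structural character."""

    lsc_id: int
    columns: list[int]
    residues: list[str] = field(default_factory=list)
    type_counts: dict[str, int] = field(default_factory=dict)
    states: dict[str, int | None] = field(default_factory=dict)
    annotation: str = ""
    intransitive: bool = False

    @property
    def name(self) -> str:
        return f"LSC{self.lsc_id}"


def find_lscs(
    site_classes: dict[int, str],
    graph: nx.Graph,
    structmap=None,
) -> list[LSC]:
    """Extract LSCs as connected components of typed vertices.

    ``site_classes`` maps alignment column → class; only columns classed
    type0/typeI/typeII are vertices.  Components of size one, or containing
    no type I/II member, are discarded.  Ordering (and numbering) is by
    smallest member column, so output is deterministic.
    """
    typed = {c: k for c, k in site_classes.items() if k in TYPED_CLASSES}
    sub = graph.subgraph([c for c in typed if c in graph])
    components = []
    for comp in nx.connected_components(sub):
        members = sorted(comp)
        if len(members) < 2:
            continue
        if not any(typed[c] in ("typeI", "typeII") for c in members):
            continue
        components.append(members)
    components.sort(key=lambda m: m[0])
    out = []
    for i, members in enumerate(components, start=1):
        counts = {k: 0 for k in TYPED_CLASSES}
        for c in members:
            counts[typed[c]] += 1
        residues = []
        if structmap is not None:
            residues = [
                structmap.residue(c).label()
                for c in members
                if c in structmap.col_to_residue
            ]
        out.append(LSC(lsc_id=i, columns=members, residues=residues, type_counts=counts))
    return out


def lsc_state_profiles(
    lsc: LSC, aln: MultipleAlignment, partition: CladePartition
) -> pd.DataFrame:
    """Per-clade consensus profile over the LSC's member columns.

    Columns of the returned frame: clade, column, consensus (one-letter, ""
    when the clade is entirely gapped there), consensus_freq (fraction of the
    clade's rows carrying the consensus residue), gap_fraction.
    """
    rows = []
    for clade in partition.clades:
        leaf_ids = partition.leaves_of(clade)
        seqs = [aln.row(s) for s in leaf_ids]
        for col in lsc.columns:
            chars = [s[col - 1] for s in seqs]
            residues = [c for c in chars if c != GAP and c in AMINO_ACIDS]
            gap_fraction = 1.0 - len(residues) / len(chars)
            if residues:
                counts = {}
                for c in residues:
                    counts[c] = counts.get(c, 0) + 1
                consensus = min(sorted(counts), key=lambda c: -counts[c])
                freq = counts[consensus] / len(chars)
            else:
                consensus, freq = "", 0.0
            rows.append(
                {
                    "clade": clade,
                    "column": col,
                    "consensus": consensus,
                    "consensus_freq": freq,
                    "gap_fraction": gap_fraction,
                }
            )
    return pd.DataFrame(rows)


def assign_states(
    profiles: pd.DataFrame,
    conservation: float = 0.7,
    override: dict[str, int | None] | None = None,
) -> tuple[dict[str, int | None], bool]:
    """Group clades into character states from their consensus profiles.

    Two clades share a state iff, at every member column, their conservation
    status matches (consensus frequency ≥ ``conservation`` in both or in
    neither) and, where both are conserved, the consensus residues fall in
    the same radical group.  States are the single-linkage components of this
    similarity relation, labeled 0, 1, ... in order of the alphabetically
    first member clade; if the relation is intransitive the character is
    flagged (second return value).  A clade gapped across all member columns
    gets state ``None`` (missing).  ``override`` replaces the automatic
    assignment wholesale, so published manual state tables can be encoded
    verbatim.
    """
    if override is not None:
        return dict(override), False
    clades = sorted(profiles["clade"].unique())
    cols = sorted(profiles["column"].unique())
    prof = profiles.set_index(["clade", "column"])

    def status(clade, col):
        row = prof.loc[(clade, col)]
        conserved = bool(row["consensus"]) and row["consensus_freq"] >= conservation
        group = GROUP_OF[AMINO_ACIDS.index(row["consensus"])] if conserved else -1
        return conserved, group

    missing = {
        c: all(prof.loc[(c, col)]["gap_fraction"] >= 1.0 for col in cols)
        for c in clades
    }
    present = [c for c in clades if not missing[c]]

    def similar(a, b) -> bool:
        for col in cols:
            ca, ga = status(a, col)
            cb, gb = status(b, col)
            if ca != cb:
                return False
            if ca and ga != gb:
                return False
        return True

    sim = nx.Graph()
    sim.add_nodes_from(present)
    intransitive = False
    for a, b in itertools.combinations(present, 2):
        if similar(a, b):
            sim.add_edge(a, b)
    comps = sorted(nx.connected_components(sim), key=lambda s: min(s))
    states: dict[str, int | None] = {c: None for c in clades}
    for label, comp in enumerate(comps):
        members = sorted(comp)
        for a, b in itertools.combinations(members, 2):
            if not sim.has_edge(a, b):
                intransitive = True
        for c in members:
            states[c] = label
    return states, intransitive


# ---------------------------------------------------------------------------
# exhaustive maximum parsimony
# ---------------------------------------------------------------------------

MAX_EXHAUSTIVE_TAXA = 9


def n_unrooted_topologies(n_taxa: int) -> int:
    out = 1
    for k in range(4, n_taxa + 1):
        out *= 2 * k - 5
    return out


def enumerate_topologies(n_taxa: int):
    """Yield every unrooted binary topology on taxa 0..n_taxa-1 exactly once.

    Topologies are edge lists; leaves are 0..n_taxa-1, internal nodes follow.
    Generation is by stepwise addition: taxon k is attached to each edge of
    each (k-1)-taxon topology, which enumerates the (2n−5)!! trees without
    duplication.
    """
    if not 3 <= n_taxa <= MAX_EXHAUSTIVE_TAXA:
        raise InputError(
            f"exhaustive enumeration supports 3..{MAX_EXHAUSTIVE_TAXA} taxa "
            f"(got {n_taxa}); larger problems need a heuristic search, which "
            "is out of scope"
        )

    def rec(edges: list[tuple[int, int]], next_leaf: int, next_internal: int):
        if next_leaf == n_taxa:
            yield tuple(edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, next_leaf)]
            yield from rec(new_edges, next_leaf + 1, next_internal + 1)

    start = [(0, n_taxa), (1, n_taxa), (2, n_taxa)]
    yield from rec(start, 3, n_taxa + 1)


def _rooted_traversal(edges, n_taxa: int):
    """Root the unrooted tree on the edge to leaf 0.

    Returns (order, children) where order is a preorder list starting at the
    neighbor of leaf 0; reversed it is a valid postorder.
    """
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = adj[0][0]
    order = []
    children: dict[int, list[int]] = {}
    stack = [(root, 0)]
    while stack:
        node, parent = stack.pop()
        order.append(node)
        kids = [n for n in adj[node] if n != parent]
        children[node] = kids
        for k in kids:
            stack.append((k, node))
    return order, children


def _fitch_masks_score(order, children, masks: dict[int, int], full: int) -> int:
    """Fitch union count given leaf bitmasks (missing taxa = full mask)."""
    state = {}
    score = 0
    for node in reversed(order):
        kids = children[node]
        if not kids:
            state[node] = masks.get(node, full)
            continue
        m = full
        for k in kids:
            m &= state[k]
        if m == 0:
            m = 0
            for k in kids:
                m |= state[k]
            score += 1
        state[node] = m
    top = state[order[0]]
    leaf0 = masks.get(0, full)
    if top & leaf0 == 0:
        score += 1
    return score


def fitch_score(edges, taxon_states: list) -> int:
    """Minimum number of unordered state changes for one character.

    ``taxon_states`` lists one state per taxon (index = leaf id); ``None``
    (or NaN) marks a missing taxon, which constrains nothing.
    """
    observed = sorted(
        {s for s in taxon_states if s is not None and not _is_nan(s)}
    )
    if len(observed) <= 1:
        return 0
    bit = {s: 1 << i for i, s in enumerate(observed)}
    full = (1 << len(observed)) - 1
    masks = {
        i: bit[s]
        for i, s in enumerate(taxon_states)
        if s is not None and not _is_nan(s)
    }
    n_taxa = len(taxon_states)
    order, children = _rooted_traversal(edges, n_taxa)
    return _fitch_masks_score(order, children, masks, full)


def _is_nan(x) -> bool:
    return isinstance(x, float) and np.isnan(x)


def topology_newick(edges, taxon_names: list[str]) -> str:
    """Newick for an unrooted topology, drawn rooted at leaf 0's neighbor."""
    order, children = _rooted_traversal(edges, len(taxon_names))

    def key(s: str):
        return (s.startswith("("), s)

    def rec(node: int) -> str:
        kids = children[node]
        if not kids:
            return taxon_names[node]
        return "(" + ",".join(sorted((rec(k) for k in kids), key=key)) + ")"

    root = order[0]
    parts = sorted([taxon_names[0]] + [rec(k) for k in children[root]], key=key)
    return "(" + ",".join(parts) + ");"


@dataclass
class ParsimonyResult:
    best_score: int
    topologies: list[str]  # Newick, all optimal (capped)
    n_optimal: int
    n_evaluated: int
    per_character_scores: dict[str, int]  # on the first optimal topology


def mp_search(matrix: pd.DataFrame, max_reported: int = 10_000) -> ParsimonyResult:
    """Exhaustive maximum-parsimony search over LSC characters.

    ``matrix`` is clades × characters; entries are small integer states, with
    NaN / None / "?" for missing.  Every unrooted binary topology on the
    clades is scored by summed Fitch length; all score-minimal topologies are
    returned (as Newick), with a per-character change count on the first.
    """
    taxa = list(matrix.index)
    n = len(taxa)
    if n < 3:
        raise InputError("parsimony needs at least three taxa")
    chars = []
    for col in matrix.columns:
        vals = [None if _is_missing(v) else v for v in matrix[col]]
        observed = sorted({v for v in vals if v is not None})
        if len(observed) <= 1:
            chars.append((col, None, 0, {}))
            continue
        bit = {s: 1 << i for i, s in enumerate(observed)}
        masks = {i: bit[v] for i, v in enumerate(vals) if v is not None}
        chars.append((col, masks, (1 << len(observed)) - 1, {}))

    best_score = None
    best_edges: list[tuple] = []
    n_eval = 0
    n_opt = 0
    for edges in enumerate_topologies(n):
        n_eval += 1
        order, children = _rooted_traversal(edges, n)
        score = 0
        for _, masks, full, _ in chars:
            if masks is None:
                continue
            score += _fitch_masks_score(order, children, masks, full)
            if best_score is not None and score > best_score:
                break
        if best_score is None or score < best_score:
            best_score = score
            best_edges = [edges]
            n_opt = 1
        elif score == best_score:
            n_opt += 1
            if len(best_edges) < max_reported:
                best_edges.append(edges)

    per_char = {}
    first = best_edges[0]
    for col, masks, full, _ in chars:
        if masks is None:
            per_char[col] = 0
        else:
            order, children = _rooted_traversal(first, n)
            per_char[col] = _fitch_masks_score(order, children, masks, full)
    return ParsimonyResult(
        best_score=int(best_score),
        topologies=[topology_newick(e, taxa) for e in best_edges],
        n_optimal=n_opt,
        n_evaluated=n_eval,
        per_character_scores=per_char,
    )


def _is_missing(v) -> bool:
    return v is None or v == "?" or _is_nan(v)


def character_matrix(lscs: list[LSC], clades: list[str]) -> pd.DataFrame:
    """Assemble the clade × character state table from assigned LSC states."""
    if len(clades) < 3:
        raise InputError("character matrix needs at least three clades")
    data = {}
    for lsc in lscs:
        data[lsc.name] = [lsc.states.get(c) for c in clades]
    return pd.DataFrame(data, index=clades)
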
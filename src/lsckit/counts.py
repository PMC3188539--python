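"""Per-site substitution counting on subfamily trees.

The substitution model throughout is the equal-exchangeability (Poisson)
amino-acid model: all 20 states exchange at equal rates, stationary
frequencies uniform, branch lengths in expected substitutions per site.  Its
transition probability has the closed form

    P(same | t)  = 1/20 + (19/20) * exp(-20 t / 19)
    P(other | t) = (1/20) * (1 - exp(-20 t / 19))      (per target state)

which lets every pruning pass be vectorized across alignment columns.

Counting follows the ancestral-state route: infer one amino-acid state per
internal node per column, count tree edges whose endpoint states differ, and
charge one substitution for every gapped leaf (ancestors are never gaps, so a
gap always mismatches its parent).  Hence a column with N gaps in a clade is
assigned at least N substitutions in that clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GAP_CODE,
    CladePartition,
    InputError,
    MultipleAlignment,
    Phylogeny,
)

_POISSON_C = 20.0 / 19.0  # rate normalization of the 20-state Poisson model
_LAMBDA_MAX = 50.0


def _leaf_codes(aln: MultipleAlignment, tree: Phylogeny) -> np.ndarray:
    """(n_nodes, n_cols) int8; leaf rows filled with alignment codes."""
    enc = aln.encoded()
    row_of = {sid: i for i, sid in enumerate(aln.ids)}
    codes = np.full((tree.n_nodes, aln.n_cols), GAP_CODE, dtype=np.int8)
    for node, label in tree.leaf_labels.items():
        if label not in row_of:
            raise InputError(f"tree leaf {label!r} missing from alignment")
        codes[node] = enc[row_of[label]]
    return codes


def _edge_decay(lam, t_edge: float, n_cols: int) -> np.ndarray:
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n_cols,))
    return np.exp(-_POISSON_C * lam * t_edge)


def _pruning_logliks(
    tree: Phylogeny, leaf_codes: np.ndarray, lam
) -> np.ndarray:
    """Per-column log-likelihood of the column patterns at rate multiplier lam.

    Gapped leaves are missing data (all-ones partial likelihood).
    """
    n_cols = leaf_codes.shape[1]
    L = np.empty((tree.n_nodes, n_cols, 20))
    logscale = np.zeros(n_cols)
    for node in tree.postorder:
        if not tree.children[node]:
            codes = leaf_codes[node]
            vec = np.zeros((n_cols, 20))
            gap = codes == GAP_CODE
            vec[gap] = 1.0
            idx = np.where(~gap)[0]
            vec[idx, codes[idx]] = 1.0
            L[node] = vec
            continue
        acc = np.ones((n_cols, 20))
        for c in tree.children[node]:
            e = _edge_decay(lam, tree.edge_length[c], n_cols)[:, None]
            s = L[c].sum(axis=1, keepdims=True)
            acc *= e * L[c] + (1.0 - e) * s / 20.0
        mx = acc.max(axis=1)
        mx[mx == 0.0] = 1.0
        L[node] = acc / mx[:, None]
        logscale += np.log(mx)
    root = tree.root
    return logscale + np.log(L[root].sum(axis=1) / 20.0)


@dataclass
class AncestralAssignment:
    """One amino-acid state per node per column (gap code only at leaves)."""

    tree: Phylogeny
    states: np.ndarray  # (n_nodes, n_cols) int8
    uninformative: np.ndarray  # (n_cols,) bool: all clade leaves gapped
    model: str

    def root_states(self) -> np.ndarray:
        return self.states[self.tree.root]


def _overall_mode_state(aln: MultipleAlignment) -> int:
    enc = aln.encoded()
    counts = np.bincount(enc[enc != GAP_CODE].ravel(), minlength=20)
    return int(np.argmax(counts))


def _marginal_ml_states(tree: Phylogeny, leaf_codes: np.ndarray) -> np.ndarray:
    """Marginal posterior argmax state per node (lam = 1, lengths as given)."""
    n_cols = leaf_codes.shape[1]
    L = np.empty((tree.n_nodes, n_cols, 20))  # product of child messages
    M = np.empty((tree.n_nodes, n_cols, 20))  # message node -> parent
    for node in tree.postorder:
        if not tree.children[node]:
            codes = leaf_codes[node]
            vec = np.zeros((n_cols, 20))
            gap = codes == GAP_CODE
            vec[gap] = 1.0
            idx = np.where(~gap)[0]
            vec[idx, codes[idx]] = 1.0
            L[node] = vec
        else:
            acc = np.ones((n_cols, 20))
            for c in tree.children[node]:
                acc *= M[c]
            mx = acc.max(axis=1)
            mx[mx == 0.0] = 1.0
            L[node] = acc / mx[:, None]
        e = _edge_decay(1.0, tree.edge_length[node], n_cols)[:, None]
        s = L[node].sum(axis=1, keepdims=True)
        M[node] = e * L[node] + (1.0 - e) * s / 20.0

    states = np.full((tree.n_nodes, n_cols), -1, dtype=np.int8)
    D = np.empty((tree.n_nodes, n_cols, 20))
    D[tree.root] = 1.0
    order = [n for n in tree.postorder[::-1]]  # preorder
    for node in order:
        if tree.children[node]:
            post = D[node] * L[node]
            states[node] = np.argmax(post, axis=1).astype(np.int8)
        for c in tree.children[node]:
            B = D[node].copy()
            for sib in tree.children[node]:
                if sib != c:
                    B *= M[sib]
            mx = B.max(axis=1)
            mx[mx == 0.0] = 1.0
            B /= mx[:, None]
            e = _edge_decay(1.0, tree.edge_length[c], n_cols)[:, None]
            s = B.sum(axis=1, keepdims=True)
            D[c] = e * B + (1.0 - e) * s / 20.0
    return states


_BIG = np.float32(1e9)


def _sankoff_states(tree: Phylogeny, leaf_codes: np.ndarray) -> np.ndarray:
    """Minimum-change (unit cost) ancestral states; ties broken alphabetically.

    Gapped leaves are wildcards (zero cost in every state), so the resulting
    edge-difference count over ungapped leaves equals the exact parsimony
    minimum with gaps treated as missing.
    """
    n_cols = leaf_codes.shape[1]
    C = np.empty((tree.n_nodes, n_cols, 20), dtype=np.float32)
    for node in tree.postorder:
        if not tree.children[node]:
            codes = leaf_codes[node]
            vec = np.full((n_cols, 20), _BIG, dtype=np.float32)
            gap = codes == GAP_CODE
            vec[gap] = 0.0
            idx = np.where(~gap)[0]
            vec[idx, codes[idx]] = 0.0
            C[node] = vec
            continue
        acc = np.zeros((n_cols, 20), dtype=np.float32)
        for c in tree.children[node]:
            child_min = C[c].min(axis=1, keepdims=True)
            acc += np.minimum(C[c], child_min + 1.0)
        C[node] = acc
    states = np.full((tree.n_nodes, n_cols), -1, dtype=np.int8)
    states[tree.root] = np.argmin(C[tree.root], axis=1).astype(np.int8)
    cols = np.arange(n_cols)
    for node in tree.postorder[::-1]:  # preorder
        for c in tree.children[node]:
            if not tree.children[c]:
                continue
            penal = C[c] + 1.0
            penal[cols, states[node]] -= 1.0
            states[c] = np.argmin(penal, axis=1).astype(np.int8)
    return states


def reconstruct_ancestral_states(
    aln: MultipleAlignment,
    tree: Phylogeny,
    model: str = "marginal",
) -> AncestralAssignment:
    """Assign one amino-acid state to every internal node at every column.

    ``model="marginal"`` uses marginal maximum-likelihood posteriors under the
    Poisson amino-acid model with the tree's branch lengths; ``model="fitch"``
    uses unit-cost parsimony (Sankoff DP, exact minimum).  Gapped leaves carry
    no information but ancestors always receive amino-acid states.  Columns in
    which every leaf of the tree is gapped are flagged uninformative and their
    ancestors set to the most common residue of the whole alignment.
    """
    if model not in ("marginal", "fitch"):
        raise InputError(f"unknown reconstruction model {model!r}")
    codes = _leaf_codes(aln, tree)
    leaves = tree.leaves
    uninformative = np.all(codes[leaves] == GAP_CODE, axis=0)
    if model == "marginal":
        states = _marginal_ml_states(tree, codes)
    else:
        states = _sankoff_states(tree, codes)
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    if uninformative.any():
        states[np.ix_(internal, np.where(uninformative)[0])] = _overall_mode_state(aln)
    # leaves keep their observed codes (gap code included)
    states[leaves] = codes[leaves]
    return AncestralAssignment(tree, states, uninformative, model)


def count_substitutions(anc: AncestralAssignment) -> np.ndarray:
    """Raw per-column substitution count: edges whose endpoint states differ.

    A gapped leaf (code 20) always differs from its amino-acid parent, so the
    count is bounded below by the number of gapped leaves in the clade.
    """
    tree = anc.tree
    m = np.zeros(anc.states.shape[1], dtype=np.int64)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        m += anc.states[node] != anc.states[p]
    return m


def correct_counts(
    aln: MultipleAlignment,
    tree: Phylogeny,
    raw: np.ndarray,
    mode: str = "ml",
    grid_size: int = 33,
    refine_iter: int = 30,
) -> np.ndarray:
    """Multiple-hit corrected substitution counts.

    Default mode ``"ml"`` estimates a per-column rate multiplier λ̂ by
    maximizing the Poisson-model pruning likelihood of the column pattern
    (gaps as missing data) and reports ``λ̂ · T + G`` where T is the clade
    tree length and G the number of gapped leaves at the column — the expected
    number of substitutions implied by the pattern, which accounts for
    multiple hits that parsimony-style edge counts miss.  Mode ``"identity"``
    returns the raw counts unchanged.
    """
    if mode == "identity":
        return raw.astype(float)
    if mode != "ml":
        raise InputError(f"unknown correction mode {mode!r}")
    codes = _leaf_codes(aln, tree)
    leaves = tree.leaves
    n_cols = codes.shape[1]
    gaps = (codes[leaves] == GAP_CODE).sum(axis=0)
    n_ungapped = len(leaves) - gaps
    variable = raw - gaps > 0  # any observed change among ungapped leaves

    lam_hat = np.zeros(n_cols)
    if variable.any():
        grid = np.concatenate([[1e-5], np.geomspace(1e-3, _LAMBDA_MAX, grid_size - 1)])
        lls = np.stack([_pruning_logliks(tree, codes, g) for g in grid])
        best = np.argmax(lls, axis=0)
        lo = np.log(grid[np.maximum(best - 1, 0)])
        hi = np.log(grid[np.minimum(best + 1, grid_size - 1)])
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo.copy(), hi.copy()
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _pruning_logliks(tree, codes, np.exp(c))
        fd = _pruning_logliks(tree, codes, np.exp(d))
        for _ in range(refine_iter):
            take_c = fc > fd  # keep [a, d] when the left probe is better
            b = np.where(take_c, d, b)
            a = np.where(take_c, a, c)
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fc = _pruning_logliks(tree, codes, np.exp(c))
            fd = _pruning_logliks(tree, codes, np.exp(d))
        lam = np.exp((a + b) / 2.0)
        lam_hat = np.where(variable, lam, 0.0)
    lam_hat[n_ungapped <= 1] = 0.0
    corrected = lam_hat * tree.tree_length + gaps
    corrected[raw == 0] = 0.0
    return corrected


def clade_site_counts(
    aln: MultipleAlignment,
    trees: dict[str, Phylogeny],
    partition: CladePartition,
    model: str = "marginal",
    correction: str = "ml",
    min_leaves: int = 4,
) -> pd.DataFrame:
    """Per (column, clade) raw and corrected counts plus clade tree length.

    Returns a tidy frame with columns ``column`` (1-based), ``clade``,
    ``raw_count``, ``corrected_count``, ``tree_length``.
    """
    partition.validate(aln, min_leaves=min_leaves)
    frames = []
    for clade in partition.clades:
        if clade not in trees:
            raise InputError(f"no tree supplied for clade {clade!r}")
        tree = trees[clade]
        clade_leaves = set(partition.leaves_of(clade))
        if set(tree.labels) != clade_leaves:
            raise InputError(
                f"tree leaves for clade {clade!r} do not match the clade map"
            )
        sub = aln.subalignment(sorted(clade_leaves))
        anc = reconstruct_ancestral_states(sub, tree, model=model)
        raw = count_substitutions(anc)
        corrected = correct_counts(sub, tree, raw, mode=correction)
        frames.append(
            pd.DataFrame(
                {
                    "column": np.arange(1, aln.n_cols + 1),
                    "clade": clade,
                    "raw_count": raw,
                    "corrected_count": corrected,
                    "tree_length": tree.tree_length,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def relative_rates(counts: pd.DataFrame, value: str = "corrected_count") -> pd.DataFrame:
    """Normalize per-column counts to mean 1.0 within each clade.

    Returns a (column × clade) frame of relative rates, the scale used for
    per-region rate summaries and cross-clade rate scatter plots.
    """
    wide = counts.pivot(index="column", columns="clade", values=value)
    means = wide.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise InputError(f"clade(s) with all-zero counts: {bad}")
    return wide / means


def rate_correlation(rates_a: np.ndarray, rates_b: np.ndarray) -> float:
    """Pearson correlation of per-column rates between two clades."""
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    if rates_a.shape != rates_b.shape:
        raise InputError("rate vectors must cover the same columns")
    if np.std(rates_a) == 0 or np.std(rates_b) == 0:
        raise InputError("rate correlation undefined: zero variance")
    return float(stats.pearsonr(rates_a, rates_b).statistic)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read an externally produced per-site counts table.

    Expected columns: column_index/column, clade, raw_count, corrected_count,
    tree_length — the import path for users who run their own ancestral
    reconstruction (e.g. PAML) upstream.
    """
    df = pd.read_csv(path, sep="\t")
    if "column_index" in df.columns:
        df = df.rename(columns={"column_index": "column"})
    required = {"column", "clade", "raw_count", "corrected_count", "tree_length"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"counts TSV missing columns: {sorted(missing)}")
    return df
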
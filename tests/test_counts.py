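import itertools

import numpy as np
import pandas as pd
import pytest

from lsckit import (
    InputError,
    MultipleAlignment,
    rate_correlation,
    read_counts_tsv,
    reconstruct_ancestral_states,
    relative_rates,
    tree_from_newick,
    write_counts_tsv,
)
from lsckit.core_io import AMINO_ACIDS, GAP_CODE
from lsckit.counts import (
    _leaf_codes,
    clade_site_counts,
    correct_counts,
    count_substitutions,
)
from lsckit.core_io import CladePartition
from lsckit.synthetic import balanced_tree, simulate_alignment, SimulationSpec
from lsckit.synthetic import _evolve

from conftest import random_phylogeny


def exhaustive_min_changes(tree, leaf_codes_col):
    """Brute-force minimum edge changes over all internal labelings.

    Gapped leaves always mismatch their parent; internal labels range over
    the states observed among ungapped leaves (sufficient for the unit-cost
    minimum).
    """
    leaves = tree.leaves
    observed = sorted({int(leaf_codes_col[n]) for n in leaves
                       if leaf_codes_col[n] != GAP_CODE})
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    if not observed:
        return len(leaves)
    best = None
    for assign in itertools.product(observed, repeat=len(internal)):
        lab = dict(zip(internal, assign))
        changes = 0
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p < 0:
                continue
            if tree.children[node]:
                changes += lab[node] != lab[p]
            elif leaf_codes_col[node] == GAP_CODE:
                changes += 1
            else:
                changes += leaf_codes_col[node] != lab[p]
        if best is None or changes < best:
            best = changes
    return best


class TestReconstruction:
    @pytest.mark.parametrize("model", ["marginal", "fitch"])
    def test_unanimous_column(self, quartet_tree, model):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["A", "A", "A", "A"])
        anc = reconstruct_ancestral_states(aln, quartet_tree, model=model)
        internal = [n for n in range(quartet_tree.n_nodes)
                    if quartet_tree.children[n]]
        assert all(anc.states[n, 0] == 0 for n in internal)

    def test_fitch_quartet_root_tie_lexicographic(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["K", "K", "D", "D"])
        anc = reconstruct_ancestral_states(aln, quartet_tree, model="fitch")
        # root may be K or D at one change; the tie breaks alphabetically (D)
        assert AMINO_ACIDS[anc.root_states()[0]] == "D"
        assert count_substitutions(anc)[0] == 1

    def test_models_agree_on_unanimous_columns(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"],
                                ["AK", "AK", "AK", "AK"])
        s1 = reconstruct_ancestral_states(aln, quartet_tree, "marginal").states
        s2 = reconstruct_ancestral_states(aln, quartet_tree, "fitch").states
        np.testing.assert_array_equal(s1, s2)

    def test_all_gap_column_flagged_and_assigned(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["K-", "K-", "K-", "K-"])
        anc = reconstruct_ancestral_states(aln, quartet_tree)
        assert not anc.uninformative[0] and anc.uninformative[1]
        # ancestors get the overall most common residue (K), never gaps
        assert AMINO_ACIDS[anc.states[quartet_tree.root, 1]] == "K"
        # every terminal edge counts one substitution at the all-gap column
        assert count_substitutions(anc)[1] == 4


class TestCounting:
    def test_gap_rule_example(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["A", "A", "-", "-"])
        anc = reconstruct_ancestral_states(aln, quartet_tree, model="fitch")
        assert count_substitutions(anc)[0] >= 2

    def test_unanimous_ungapped_column_zero(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["C", "C", "C", "C"])
        anc = reconstruct_ancestral_states(aln, quartet_tree, model="fitch")
        assert count_substitutions(anc)[0] == 0

    def test_gap_rule_property_random_columns(self, quartet_tree):
        rng = np.random.default_rng(7)
        n_cols = 300
        rows = []
        for _ in range(4):
            chars = rng.integers(0, 21, size=n_cols)
            rows.append("".join(
                "-" if c == 20 else AMINO_ACIDS[c] for c in chars))
        aln = MultipleAlignment(["a", "b", "c", "d"], rows)
        anc = reconstruct_ancestral_states(aln, quartet_tree, model="fitch")
        m = count_substitutions(anc)
        gaps = np.sum([[ch == "-" for ch in r] for r in rows], axis=0)
        assert (m >= gaps).all()

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_fitch_matches_exhaustive_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        tree = random_phylogeny(rng, n_leaves)
        n_cols = 40
        rows = []
        for _ in range(n_leaves):
            chars = rng.integers(0, 6, size=n_cols)  # small alphabet + gaps
            chars[rng.random(n_cols) < 0.15] = 20
            rows.append("".join(
                "-" if c == 20 else AMINO_ACIDS[c] for c in chars))
        aln = MultipleAlignment(sorted(tree.labels), rows)
        anc = reconstruct_ancestral_states(aln, tree, model="fitch")
        m = count_substitutions(anc)
        codes = _leaf_codes(aln, tree)
        for j in range(n_cols):
            assert m[j] == exhaustive_min_changes(tree, codes[:, j]), f"col {j}"


class TestCorrection:
    def test_zero_raw_gives_zero(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["C", "C", "C", "C"])
        raw = np.array([0])
        assert correct_counts(aln, quartet_tree, raw)[0] == 0.0

    def test_identity_mode(self, quartet_tree, tiny_alignment):
        raw = np.array([1, 1, 0, 1])
        out = correct_counts(tiny_alignment, quartet_tree, raw, mode="identity")
        np.testing.assert_array_equal(out, raw.astype(float))

    def test_nonnegative_and_monotone_trend(self):
        rng = np.random.default_rng(3)
        tree = balanced_tree("c", 8, 8.0)
        rates = np.concatenate([np.full(60, r) for r in (0.1, 0.5, 1.0, 3.0)])
        states = _evolve(tree, rng.integers(0, 20, rates.size, dtype=np.int8),
                         rates, rng)
        rows = ["".join(AMINO_ACIDS[s] for s in states[n]) for n in tree.leaves]
        aln = MultipleAlignment(sorted(tree.labels), rows)
        anc = reconstruct_ancestral_states(aln, tree, model="fitch")
        raw = count_substitutions(anc)
        corr = correct_counts(aln, tree, raw)
        assert (corr >= 0).all()
        # corrected counts increase with raw counts on average
        from scipy.stats import spearmanr
        assert spearmanr(raw, corr).statistic > 0.9

    def test_mean_corrected_converges_to_expected(self):
        # rate 1 on a tree of length 5: mean corrected count near 5
        rng = np.random.default_rng(11)
        tree = balanced_tree("c", 16, 5.0)
        n_cols = 200
        rates = np.ones(n_cols)
        states = _evolve(tree, rng.integers(0, 20, n_cols, dtype=np.int8),
                         rates, rng)
        rows = ["".join(AMINO_ACIDS[s] for s in states[n]) for n in tree.leaves]
        aln = MultipleAlignment(sorted(tree.labels), rows)
        anc = reconstruct_ancestral_states(aln, tree, model="fitch")
        corr = correct_counts(aln, tree, count_substitutions(anc))
        assert abs(corr.mean() - 5.0) / 5.0 < 0.10


class TestCladeCounts:
    def test_constant_alignment_all_zero(self):
        trees = {c: balanced_tree(c, 4, 2.0) for c in ("A", "B")}
        leaves = [l for t in trees.values() for l in t.labels]
        aln = MultipleAlignment(leaves, ["AAAA"] * 8)
        part = CladePartition({l: l.split("_")[0] for l in leaves})
        df = clade_site_counts(aln, trees, part, min_leaves=2)
        assert (df["raw_count"] == 0).all()
        assert (df["corrected_count"] == 0).all()

    def test_tree_length_column_constant(self, standard_counts):
        for clade, grp in standard_counts.groupby("clade"):
            assert grp["tree_length"].nunique() == 1

    def test_fast_clade_has_larger_mean_counts(self):
        rng = np.random.default_rng(5)
        trees = {c: balanced_tree(c, 8, 4.0) for c in ("slow", "fast")}
        ids, rows = [], []
        for clade, rate in (("slow", 1.0), ("fast", 4.0)):
            tree = trees[clade]
            states = _evolve(tree, rng.integers(0, 20, 150, dtype=np.int8),
                             np.full(150, rate), rng)
            for n in tree.leaves:
                ids.append(tree.leaf_labels[n])
                rows.append("".join(AMINO_ACIDS[s] for s in states[n]))
        aln = MultipleAlignment(ids, rows)
        part = CladePartition({i: i.split("_")[0] for i in ids})
        df = clade_site_counts(aln, trees, part, min_leaves=2)
        means = df.groupby("clade")["corrected_count"].mean()
        assert means["fast"] > 2.0 * means["slow"]

    def test_missing_leaf_rejected(self, quartet_tree):
        aln = MultipleAlignment(["a", "b", "c"], ["A", "A", "A"])
        part = CladePartition({l: "X" for l in "abcd"})
        with pytest.raises(InputError):
            clade_site_counts(aln, {"X": quartet_tree}, part, min_leaves=2)


class TestRates:
    def test_relative_rates_normalization(self):
        df = pd.DataFrame({
            "column": [1, 2, 3] * 2,
            "clade": ["A"] * 3 + ["B"] * 3,
            "corrected_count": [2.0, 2.0, 2.0, 0.0, 2.0, 4.0],
            "raw_count": 0, "tree_length": 1.0,
        })
        rates = relative_rates(df)
        np.testing.assert_allclose(rates["A"], [1, 1, 1])
        np.testing.assert_allclose(rates["B"], [0, 1, 2])
        assert rates.mean(axis=0).sub(1.0).abs().max() < 1e-9

    def test_all_zero_clade_rejected(self):
        df = pd.DataFrame({
            "column": [1, 2], "clade": ["A", "A"],
            "corrected_count": [0.0, 0.0], "raw_count": 0, "tree_length": 1.0,
        })
        with pytest.raises(InputError, match="all-zero"):
            relative_rates(df)

    def test_rate_correlation(self):
        assert rate_correlation([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)
        assert rate_correlation([0, 1, 2], [2, 1, 0]) == pytest.approx(-1.0)
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        # hand value: r = cov(x,y) / (sd_x sd_y)
        r_hand = (((x - 3) * (y - 3)).sum()
                  / np.sqrt(((x - 3) ** 2).sum() * ((y - 3) ** 2).sum()))
        assert rate_correlation(x, y) == pytest.approx(r_hand)
        with pytest.raises(InputError, match="variance"):
            rate_correlation([1, 1, 1], [0, 1, 2])


def test_counts_tsv_round_trip(tmp_path, standard_counts):
    p = tmp_path / "counts.tsv"
    write_counts_tsv(standard_counts, p)
    back = read_counts_tsv(p)
    assert (back == read_counts_tsv(p)).all().all()  # bit-stable reread
    np.testing.assert_allclose(
        back["corrected_count"], standard_counts["corrected_count"], atol=5e-7
    )
    assert (back["raw_count"] == standard_counts["raw_count"]).all()
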
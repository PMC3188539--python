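"""Synthetic datasets with known rate-shift structure.

The generator mirrors the inference assumptions: per-column rates are drawn
from a gamma distribution (mean 1); residues evolve along each clade tree
under the equal-exchangeability Poisson amino-acid model; a fraction θ of
columns redraw an independent rate in the shifted clade (type I truth); a
small fraction of columns are fixed for radically different residues between
clades (type II truth); gaps are injected as contiguous per-sequence blocks.
Coordinates place the reference sequence on a 3.8 Å-spaced backbone line with
designated column sets lifted into tight off-chain clusters, so structural
clustering of planted sites is geometrically guaranteed and everything else
(except chain-consecutive pairs) is beyond the contact threshold.

Defaults are the standard study conditions used throughout the test-bench:
two 16-leaf balanced clades, 500 columns, gamma shape 1.0, θ = 0.5, shift
ratio 8, type II fraction 0.05, gap fraction 0.05.  Clade tree length
defaults to 6.0, which at 30 edges reproduces the per-edge divergence
(≈0.2 substitutions/site) typical of real subfamily trees; per-edge length,
not total length, controls reconstruction difficulty when leaf counts
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .core_io import (
    AMINO_ACIDS,
    CladePartition,
    InputError,
    MultipleAlignment,
    Phylogeny,
    ResidueCoordinates,
    ResidueRecord,
    tree_from_newick,
)
from .divergence import GROUP_OF

_POISSON_C = 20.0 / 19.0


@dataclass
class SimulationSpec:
    """Fully determined description of one synthetic dataset."""

    seed: int
    clades: tuple[str, ...] = ("A", "B")
    n_leaves: int = 16
    tree_length: float = 6.0
    n_columns: int = 500
    gamma_shape: float = 1.0
    theta: float = 0.5  # fraction of type I (rate-shifted) columns
    shift_ratio: float = 8.0
    type2_fraction: float = 0.05
    gap_fraction: float = 0.05
    contact_threshold: float = 4.0
    planted_clusters: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is mandatory")
        for name in ("theta", "type2_fraction", "gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.theta + self.type2_fraction > 1.0:
            raise InputError("theta + type2_fraction exceeds 1: infeasible spec")
        if self.gamma_shape <= 0 or self.shift_ratio <= 0:
            raise InputError("gamma_shape and shift_ratio must be positive")
        if len(self.clades) < 2:
            raise InputError("need at least two clades")


@dataclass
class SyntheticDataset:
    """A simulated alignment plus every ingredient downstream modules need."""

    aln: MultipleAlignment
    trees: dict[str, Phylogeny]
    partition: CladePartition
    coords: ResidueCoordinates
    truth: pd.DataFrame  # per column: class + true rate per clade
    reference_id: str
    spec: SimulationSpec


def balanced_tree(clade: str, n_leaves: int, total_length: float) -> Phylogeny:
    """Balanced binary tree with equal edge lengths summing to total_length."""
    if n_leaves < 2:
        raise InputError("a clade tree needs at least two leaves")
    counter = iter(range(n_leaves))

    def rec(k: int) -> str:
        if k == 1:
            return f"{clade}_{next(counter):02d}:1"
        left = rec(k // 2)
        right = rec(k - k // 2)
        return f"({left},{right}):1"

    newick = rec(n_leaves).rsplit(":", 1)[0] + ";"
    tree = tree_from_newick(newick)
    tree.edge_length *= total_length / tree.edge_length.sum()
    return tree


def _evolve(
    tree: Phylogeny, root_states: np.ndarray, rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate states at all nodes under the Poisson model; returns int8."""
    n_cols = root_states.size
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int8)
    states[tree.root] = root_states
    for node in tree.postorder[::-1]:  # preorder
        p = tree.parent[node]
        if p < 0:
            continue
        e = np.exp(-_POISSON_C * rates * tree.edge_length[node])
        redraw = rng.random(n_cols) > e
        fresh = rng.integers(0, 20, size=n_cols, dtype=np.int8)
        states[node] = np.where(redraw, fresh, states[p])
    return states


def _radically_different(code: int, rng: np.random.Generator) -> int:
    choices = np.where(GROUP_OF[:20] != GROUP_OF[code])[0]
    return int(rng.choice(choices))


def simulate_alignment(spec: SimulationSpec) -> SyntheticDataset:
    """Generate a full dataset under the spec; same spec + seed is bit-stable.

    The first clade keeps the base rate at every column; at type I columns the
    last clade's rate is an independent gamma draw scaled by the shift ratio
    (up or down with equal probability).  Type II columns are invariant within
    every clade and fixed for radically different residues between the first
    clade and the rest.  The first leaf of the first clade is the structure
    reference and is never gapped.
    """
    rng = np.random.default_rng(spec.seed)
    n_cols = spec.n_columns
    clades = list(spec.clades)
    trees = {c: balanced_tree(c, spec.n_leaves, spec.tree_length) for c in clades}
    partition = CladePartition(
        {label: c for c in clades for label in trees[c].labels}
    )

    u = rng.random(n_cols)
    classes = np.where(
        u < spec.type2_fraction, "typeII",
        np.where(u < spec.type2_fraction + spec.theta, "typeI", "background"),
    )
    scale = 1.0 / spec.gamma_shape  # mean rate 1
    base = rng.gamma(spec.gamma_shape, scale, size=n_cols)
    rates = {c: base.copy() for c in clades}
    is_t1 = classes == "typeI"
    redraw = rng.gamma(spec.gamma_shape, scale, size=n_cols)
    direction = np.where(rng.random(n_cols) < 0.5, spec.shift_ratio,
                         1.0 / spec.shift_ratio)
    rates[clades[-1]] = np.where(is_t1, redraw * direction, base)
    is_t2 = classes == "typeII"
    for c in clades:
        rates[c] = np.where(is_t2, 0.0, rates[c])

    roots = {c: rng.integers(0, 20, size=n_cols, dtype=np.int8) for c in [clades[0]]}
    shared_root = roots[clades[0]]
    for c in clades[1:]:
        roots[c] = shared_root.copy()
    # radical fixed differences at type II columns
    t2_cols = np.where(is_t2)[0]
    alt = shared_root.copy()
    for j in t2_cols:
        alt[j] = _radically_different(int(shared_root[j]), rng)
    for c in clades[1:]:
        roots[c][t2_cols] = alt[t2_cols]

    ids: list[str] = []
    rows: list[str] = []
    for c in clades:
        tree = trees[c]
        states = _evolve(tree, roots[c], rates[c], rng)
        for node in tree.leaves:
            ids.append(tree.leaf_labels[node])
            rows.append("".join(AMINO_ACIDS[s] for s in states[node]))
    reference_id = ids[0]

    block = int(round(spec.gap_fraction * n_cols))
    if block > 0:
        for i in range(len(rows)):
            if ids[i] == reference_id:
                continue
            start = int(rng.integers(0, n_cols - block + 1))
            row = list(rows[i])
            row[start : start + block] = "-" * block
            rows[i] = "".join(row)

    aln = MultipleAlignment(ids, rows)
    coords = simulate_coordinates(
        n_cols,
        spec.planted_clusters,
        threshold=spec.contact_threshold,
        residue_letters=aln.row(reference_id),
    )
    truth = pd.DataFrame({"column": np.arange(1, n_cols + 1), "class": classes})
    for c in clades:
        truth[f"rate_{c}"] = rates[c]
    return SyntheticDataset(
        aln=aln, trees=trees, partition=partition, coords=coords,
        truth=truth, reference_id=reference_id, spec=spec,
    )


_CHAIN_SPACING = 3.8  # Å, consecutive α-carbons


def simulate_coordinates(
    n_residues: int,
    planted_clusters=(),
    threshold: float = 4.0,
    residue_letters: str | None = None,
) -> ResidueCoordinates:
    """Backbone-like coordinates with designated residues forming 3D clusters.

    The chain lies on a line with 3.8 Å spacing (so chain-consecutive pairs
    are genuine contacts at a 4 Å threshold, mirroring real backbones).  Each
    planted cluster is lifted onto a compact off-chain grid whose diameter is
    at most ``threshold``; clusters sit 40 Å from the chain and from each
    other, so no spurious contacts arise.
    """
    clusters = [tuple(sorted(set(int(c) for c in cl))) for cl in planted_clusters]
    seen: set[int] = set()
    for cl in clusters:
        if any(not 1 <= c <= n_residues for c in cl):
            raise InputError("planted cluster positions outside the chain")
        if seen & set(cl):
            raise InputError("planted clusters must be disjoint")
        seen |= set(cl)
    xyz = np.zeros((n_residues, 3))
    xyz[:, 0] = np.arange(n_residues) * _CHAIN_SPACING
    for k, cl in enumerate(clusters):
        size = len(cl)
        g = int(np.ceil(size ** (1.0 / 3.0)))
        spacing = threshold / (np.sqrt(3.0) * max(g - 1, 1))
        if spacing < 0.5:
            raise InputError(
                f"cluster of {size} residues cannot fit within {threshold} Å "
                "at a physically sensible spacing"
            )
        center = np.array(
            [xyz[[c - 1 for c in cl], 0].mean(), 40.0 * (k + 1), 40.0 * (k + 1)]
        )
        grid = [
            (i, j, l) for i in range(g) for j in range(g) for l in range(g)
        ][:size]
        offsets = (np.array(grid, dtype=float) - (g - 1) / 2.0) * spacing
        for pos, off in zip(cl, offsets):
            xyz[pos - 1] = center + off
    letters = residue_letters or "A" * n_residues
    if len(letters) != n_residues:
        raise InputError("residue_letters length does not match n_residues")
    records = [
        ResidueRecord(
            chain_id="A", resseq=i + 1, icode=" ",
            aa=letters[i] if letters[i] in AMINO_ACIDS else "X",
            coord=xyz[i], atom_coords=xyz[i : i + 1],
        )
        for i in range(n_residues)
    ]
    return ResidueCoordinates(records)


def write_pdb(coords: ResidueCoordinates, path: str | Path) -> None:
    """Write coordinates as a single-chain Cα-only PDB file."""
    builder = StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for rec in coords.records:
        resname = protein_letters_1to3.get(rec.aa, "Unk").upper()
        builder.init_residue(resname, " ", rec.resseq, " ")
        builder.init_atom("CA", rec.coord, 0.0, 1.0, " ", " CA ", None, "C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


@dataclass
class QuartetFixture:
    dataset: SyntheticDataset
    sites_edge1: tuple[int, ...]  # type I truth for the (A,B) pair
    sites_edge2: tuple[int, ...]  # type I truth for the (C,D) pair
    expected_significant: bool


def simulate_quartet_fixture(
    spec: SimulationSpec,
    n_shift_sites: int = 25,
    planted: bool = True,
) -> QuartetFixture:
    """Four-clade dataset for the quartet clustering test.

    Type I columns for the (A,B) pair occupy one contiguous column block and
    those for the (C,D) pair another; with ``planted=True`` the two blocks
    are lifted into spatial clusters so the clustering test should reject,
    with ``planted=False`` the shifted columns are scattered along the chain
    and it should not.
    """
    if len(spec.clades) != 4:
        raise InputError("quartet fixture needs exactly four clades")
    rng = np.random.default_rng(spec.seed)
    n_cols = spec.n_columns
    if 2 * n_shift_sites > n_cols:
        raise InputError("too many shift sites for the column count")
    if planted:
        s1 = tuple(range(1, n_shift_sites + 1))
        s2 = tuple(range(n_shift_sites + 1, 2 * n_shift_sites + 1))
        clusters = (s1, s2)
    else:
        chosen = rng.choice(n_cols, size=2 * n_shift_sites, replace=False) + 1
        s1 = tuple(sorted(int(c) for c in chosen[:n_shift_sites]))
        s2 = tuple(sorted(int(c) for c in chosen[n_shift_sites:]))
        clusters = ()

    base_spec = SimulationSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        clades=spec.clades,
        n_leaves=spec.n_leaves,
        tree_length=spec.tree_length,
        n_columns=n_cols,
        gamma_shape=spec.gamma_shape,
        theta=0.0,  # shifts are planted explicitly below
        shift_ratio=spec.shift_ratio,
        type2_fraction=0.0,
        gap_fraction=spec.gap_fraction,
        contact_threshold=spec.contact_threshold,
        planted_clusters=clusters,
    )
    ds = simulate_alignment(base_spec)
    # replant: redraw rates for the designated columns in clades B and D
    clades = list(spec.clades)
    scale = 1.0 / spec.gamma_shape
    for shifted_clade, cols in ((clades[1], s1), (clades[3], s2)):
        tree = ds.trees[shifted_clade]
        idx = np.array(cols) - 1
        redraw = rng.gamma(spec.gamma_shape, scale, size=idx.size)
        direction = np.where(
            rng.random(idx.size) < 0.5, spec.shift_ratio, 1.0 / spec.shift_ratio
        )
        rates_full = ds.truth[f"rate_{shifted_clade}"].to_numpy().copy()
        rates_full[idx] = redraw * direction
        # re-evolve the whole clade under the new rates
        states = _evolve(tree, _clade_root_states(ds, shifted_clade, rng), rates_full, rng)
        for node in tree.leaves:
            label = tree.leaf_labels[node]
            i = ds.aln.ids.index(label)
            old = ds.aln.rows[i]
            new = "".join(AMINO_ACIDS[s] for s in states[node])
            merged = "".join(
                o if o == "-" else n for o, n in zip(old, new)
            )  # preserve gap blocks
            ds.aln.rows[i] = merged
        ds.truth[f"rate_{shifted_clade}"] = rates_full
        ds.truth.loc[idx, "class"] = "typeI"
    return QuartetFixture(
        dataset=ds, sites_edge1=s1, sites_edge2=s2, expected_significant=planted
    )


def _clade_root_states(
    ds: SyntheticDataset, clade: str, rng: np.random.Generator
) -> np.ndarray:
    """Fresh root draw for re-evolving one clade (root identity is nuisance)."""
    return rng.integers(0, 20, size=ds.spec.n_columns, dtype=np.int8)


def simulate_poisson_counts(lambda_: float, t_list, seed: int) -> np.ndarray:
    """Independent Poisson draws with means λ·t_i."""
    if lambda_ < 0:
        raise InputError("lambda must be non-negative")
    t = np.asarray(t_list, dtype=float)
    if (t < 0).any():
        raise InputError("tree lengths must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(lambda_ * t)
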
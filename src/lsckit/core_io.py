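"""Input/output and validation for alignments, trees, clade maps and structures.

Alignment columns are 1-based everywhere a column index is reported, matching
the "position" convention of structural biology.  Internally columns are
0-based numpy axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lsckit")

#: the 20 standard amino acids, alphabetical by one-letter code
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: integer code used for gaps and unknown residues in encoded alignments
GAP_CODE = 20

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: letters normalized to 'X' and treated as gaps when counting substitutions
AMBIGUOUS = set("BZJUOX")


class InputError(ValueError):
    """Raised when an input file violates a documented invariant."""


def _normalize_row(row: str) -> str:
    out = []
    for ch in row.upper():
        if ch in _AA_INDEX or ch == GAP:
            out.append(ch)
        elif ch in ".~*":
            out.append(GAP)
        else:
            out.append("X")
    return "".join(out)


@dataclass
class MultipleAlignment:
    """A gapped protein multiple sequence alignment.

    ``ids`` are unique sequence identifiers; ``rows`` are equal-length strings
    over the 20 amino acids, ``-`` and ``X`` (unknown).  Columns are indexed
    1-based in all public reports.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        if not self.rows:
            raise InputError("empty alignment")
        self.rows = [_normalize_row(r) for r in self.rows]
        n = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise InputError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, expected {n}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """Return column ``col`` (1-based) as a string, one char per row."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside 1..{self.n_cols}")
        return "".join(r[col - 1] for r in self.rows)

    def encoded(self) -> np.ndarray:
        """(n_rows, n_cols) int8 matrix; amino acids 0..19, gap/unknown 20."""
        mat = np.full((self.n_rows, self.n_cols), GAP_CODE, dtype=np.int8)
        for i, row in enumerate(self.rows):
            mat[i] = [_AA_INDEX.get(ch, GAP_CODE) for ch in row]
        return mat

    def subalignment(self, seq_ids: list[str]) -> "MultipleAlignment":
        return MultipleAlignment(list(seq_ids), [self.row(s) for s in seq_ids])

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        )
        AlignIO.write(msa, str(path), fmt)


def read_alignment(path: str | Path, fmt: str = "fasta") -> MultipleAlignment:
    """Read and validate a FASTA or Clustal protein alignment."""
    if fmt not in ("fasta", "clustal"):
        raise InputError(f"unsupported alignment format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # biopython rejects ragged fasta before we can; surface as InputError
        raise InputError(f"could not parse {path}: {exc}") from exc
    return MultipleAlignment([r.id for r in msa], [str(r.seq) for r in msa])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """An array-backed rooted phylogeny with branch lengths.

    Nodes are 0..n_nodes-1; ``parent[root] == -1`` and ``edge_length[root]``
    is 0.  ``postorder`` lists every node with children before parents, so a
    single pass supports pruning algorithms.  Branch lengths are expected
    substitutions per site.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]]
    postorder: np.ndarray
    leaf_labels: dict[int, str]  # node id -> label

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    @property
    def labels(self) -> list[str]:
        return [self.leaf_labels[n] for n in self.leaves]

    @property
    def tree_length(self) -> float:
        return float(self.edge_length.sum())

    def node_of(self, label: str) -> int:
        for node, lab in self.leaf_labels.items():
            if lab == label:
                return node
        raise KeyError(f"leaf {label!r} not in tree")

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self.children[node]:
                return f"{self.leaf_labels[node]}:{self.edge_length[node]:.6g}"
            inner = ",".join(rec(c) for c in self.children[node])
            if self.parent[node] == -1:
                return f"({inner})"
            return f"({inner}):{self.edge_length[node]:.6g}"

        return rec(self.root) + ";"


def _phylogeny_from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    children: list[list[int]] = [[] for _ in nodes]
    leaf_labels: dict[int, str] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise InputError("tree has an edge without a branch length")
            if nd.edge.length < 0:
                raise InputError(f"negative branch length {nd.edge.length}")
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise InputError("unlabeled leaf in tree")
            leaf_labels[i] = nd.taxon.label.replace(" ", "_")
    labels = list(leaf_labels.values())
    if len(set(labels)) != len(labels):
        raise InputError("duplicate leaf labels in tree")
    post = np.array(
        [index[id(nd)] for nd in tree.postorder_node_iter()], dtype=np.int64
    )
    return Phylogeny(parent, lengths, children, post, leaf_labels)


def read_tree(path: str | Path) -> Phylogeny:
    """Read a Newick tree with branch lengths (substitutions/site)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"tree file not found: {path}")
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return _phylogeny_from_dendropy(tree)


def tree_from_newick(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _phylogeny_from_dendropy(tree)


# ---------------------------------------------------------------------------
# clade partitions
# ---------------------------------------------------------------------------


@dataclass
class CladePartition:
    """Map from leaf (sequence) id to subfamily / clade label."""

    mapping: dict[str, str]

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def leaves_of(self, clade: str) -> list[str]:
        return sorted(k for k, v in self.mapping.items() if v == clade)

    def validate(self, aln: MultipleAlignment, min_leaves: int = 4) -> None:
        missing = sorted(set(self.mapping) - set(aln.ids))
        if missing:
            raise InputError(f"clade map leaves absent from alignment: {missing}")
        for clade in self.clades:
            n = len(self.leaves_of(clade))
            if n < min_leaves:
                raise InputError(
                    f"clade {clade!r} has {n} leaves, below the floor of {min_leaves}"
                )


def read_clade_map(path: str | Path) -> CladePartition:
    """Read a two-column TSV (sequence_id, clade); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise InputError("clade map must have two tab-separated columns")
    if list(df.iloc[0, :2]) == ["sequence_id", "clade"]:
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise InputError("duplicate sequence ids in clade map")
    return CladePartition(mapping)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass
class ResidueRecord:
    chain_id: str
    resseq: int
    icode: str
    aa: str
    coord: np.ndarray  # representative atom, Å
    atom_coords: np.ndarray  # (k, 3) all heavy atoms

    def label(self) -> str:
        return f"{self.aa}{self.resseq}{self.icode.strip()}"


@dataclass
class ResidueCoordinates:
    """Ordered resolved residues of one chain of the reference structure."""

    records: list[ResidueRecord]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def coord_matrix(self) -> np.ndarray:
        return np.vstack([r.coord for r in self.records])


ATOM_MODES = ("CA", "CB", "any-atom-min")


def read_structure(
    path: str | Path, chain: str, atom_mode: str = "CA"
) -> ResidueCoordinates:
    """Extract per-residue coordinates from the first model of a PDB file.

    ``atom_mode`` selects the representative atom: ``CA``, ``CB`` (α-carbon
    fallback for glycine), or ``any-atom-min`` (representative is Cα but all
    heavy atoms are retained for minimum-distance contact rules).
    """
    if atom_mode not in ATOM_MODES:
        raise InputError(f"atom_mode must be one of {ATOM_MODES}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    model = next(structure.get_models())  # first model only
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise InputError(f"chain {chain!r} not in structure (has {chain_ids})")
    records: list[ResidueRecord] = []
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag != " ":
            continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        rep_name = "CA" if atom_mode != "CB" else "CB"
        if rep_name == "CB" and res.get_resname() == "GLY":
            rep_name = "CA"
        if rep_name not in res:
            logger.warning(
                "residue %s%s in chain %s lacks atom %s; skipped",
                res.get_resname(), resseq, chain, rep_name,
            )
            continue
        heavy = [a.coord for a in res if a.element != "H"]
        records.append(
            ResidueRecord(
                chain_id=chain,
                resseq=int(resseq),
                icode=icode,
                aa=aa,
                coord=np.asarray(res[rep_name].coord, dtype=float),
                atom_coords=np.asarray(heavy, dtype=float),
            )
        )
    if not records:
        raise InputError(f"no resolved residues in chain {chain!r}")
    return ResidueCoordinates(records)


@dataclass
class StructureMap:
    """Partial injective map: alignment column (1-based) → residue record."""

    col_to_residue: dict[int, int]  # column -> index into coords.records
    coords: ResidueCoordinates
    mismatches: list[int] = field(default_factory=list)

    @property
    def mapped_columns(self) -> list[int]:
        return sorted(self.col_to_residue)

    def residue(self, col: int) -> ResidueRecord:
        return self.coords.records[self.col_to_residue[col]]

    def residue_index(self, col: int) -> int:
        return self.col_to_residue[col]


def map_alignment_to_structure(
    aln: MultipleAlignment,
    ref_id: str,
    coords: ResidueCoordinates,
    max_mismatch_frac: float = 0.05,
) -> StructureMap:
    """Map alignment columns onto structure residues via the reference row.

    The k-th non-gap column of the reference row is paired with the k-th
    resolved residue.  When the ungapped reference and the structure sequence
    differ in length, the shorter is slid along the longer and the offset with
    the fewest mismatches is used.  Residue identity mismatches are tolerated
    up to ``max_mismatch_frac`` of the overlap (crystallized constructs often
    differ from database sequences) and logged.
    """
    ref_row = aln.row(ref_id)
    cols = [i + 1 for i, ch in enumerate(ref_row) if ch != GAP]
    if not cols:
        raise InputError(f"reference row {ref_id!r} is entirely gaps")
    u = "".join(ref_row[c - 1] for c in cols)
    s = coords.sequence

    def mismatches_at(offset: int) -> tuple[int, list[tuple[int, int]]]:
        """Pairs (u index, s index) for this offset of s within u (may be <0)."""
        pairs = [
            (i, i - offset)
            for i in range(len(u))
            if 0 <= i - offset < len(s)
        ]
        mm = sum(1 for i, j in pairs if u[i] != s[j] and "X" not in (u[i], s[j]))
        return mm, pairs

    best = None
    if len(u) >= len(s):
        offsets = range(0, len(u) - len(s) + 1)
    else:
        offsets = range(len(u) - len(s), 1)
    for off in offsets:
        mm, pairs = mismatches_at(off)
        if best is None or mm < best[0]:
            best = (mm, pairs)
    mm, pairs = best
    if not pairs or mm > max_mismatch_frac * len(pairs):
        raise InputError(
            "reference row does not match structure sequence "
            f"({mm} mismatches over {len(pairs)} aligned residues)\n"
            f"alignment ref: {u}\nstructure seq: {s}"
        )
    mismatch_cols = []
    mapping = {}
    for i, j in pairs:
        mapping[cols[i]] = j
        if u[i] != s[j]:
            mismatch_cols.append(cols[i])
    if mismatch_cols:
        logger.warning(
            "%d residue identity mismatches between alignment reference and "
            "structure at columns %s", len(mismatch_cols), mismatch_cols,
        )
    return StructureMap(mapping, coords, mismatch_cols)
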
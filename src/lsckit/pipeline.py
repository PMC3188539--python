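"""End-to-end scan orchestration.

Every number the scan reports is produced by a library operation on the same
inputs; this module only wires stages together, writes the External
Interface files and assembles a provenance block.  Reports carry no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characters import (
    assign_states,
    character_matrix,
    find_lscs,
    lsc_state_profiles,
    mp_search,
)
from .core_io import (
    InputError,
    MultipleAlignment,
    read_alignment,
    read_clade_map,
    read_structure,
    read_tree,
    map_alignment_to_structure,
    logger,
)
from .counts import (
    clade_site_counts,
    read_counts_tsv,
    reconstruct_ancestral_states,
    relative_rates,
    write_counts_tsv,
)
from .divergence import (
    CladeData,
    clade_consensus,
    classify_sites,
    classify_type_II,
    fit_type_I,
    pairwise_theta_table,
    type_I_posteriors,
)
from .spatial import (
    QuartetConfig,
    build_contact_graph,
    clustering_permutation_test,
    clustering_statistic,
    consecutive_statistic,
    poisson_lrt,
    region_distribution_test,
    region_location_test,
    select_quartet_sites,
    write_edge_list,
)

_CLASS_SEVERITY = {"none": 0, "type0": 1, "typeI": 2, "typeII": 3}


@dataclass
class ScanConfig:
    """One JSON-serializable configuration drives the whole scan."""

    alignment: str
    clade_map: str
    trees: dict[str, str]  # clade -> newick path
    output_dir: str
    structure: str | None = None
    chain: str = "A"
    reference_id: str | None = None
    alignment_format: str = "fasta"
    counts_tsv: str | None = None
    atom_mode: str = "CA"
    contact_threshold: float = 4.0
    posterior_cutoff: float = 0.90
    conservation_ceiling: float = 0.5
    model: str = "marginal"
    correction: str = "ml"
    min_clade_leaves: int = 4
    pairs: list[list[str]] | None = None  # default: all unordered pairs
    quartets: list[dict] = field(default_factory=list)
    regions: dict[str, dict] = field(default_factory=dict)
    n_resample: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.posterior_cutoff < 1.0:
            raise InputError("posterior_cutoff must lie in (0.5, 1)")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "ScanConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _region_columns(spec: dict, n_cols: int) -> list[int]:
    if "columns" in spec:
        cols = [int(c) for c in spec["columns"]]
    else:
        cols = list(range(int(spec["start"]), int(spec["end"]) + 1))
    if not cols or min(cols) < 1 or max(cols) > n_cols:
        raise InputError(f"region outside the alignment: {spec}")
    return cols


def build_clade_data(
    aln: MultipleAlignment,
    trees: dict,
    partition,
    counts: pd.DataFrame,
    model: str = "marginal",
) -> dict[str, CladeData]:
    """Assemble per-clade inputs for the divergence scan from count tables."""
    out = {}
    for clade in partition.clades:
        sub = counts[counts["clade"] == clade].sort_values("column")
        tree = trees[clade]
        sub_aln = aln.subalignment(sorted(partition.leaves_of(clade)))
        anc = reconstruct_ancestral_states(sub_aln, tree, model=model)
        out[clade] = CladeData(
            clade=clade,
            counts=sub["corrected_count"].to_numpy(),
            tree_length=float(sub["tree_length"].iloc[0]),
            root_states=anc.root_states(),
            consensus=clade_consensus(aln, partition.leaves_of(clade)),
            raw_counts=sub["raw_count"].to_numpy(),
        )
    return out


def run_full_scan(config: ScanConfig) -> dict:
    """Run counts → divergence → contacts → quartet → regions → LSC → MP.

    Writes the External Interface files under ``config.output_dir`` and
    returns the report dict (also written as ``report.json``).  Any stage
    failure writes a FAILED marker naming the stage and re-raises.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}
    stage = "load"
    try:
        aln = read_alignment(config.alignment, config.alignment_format)
        partition = read_clade_map(config.clade_map)
        partition.validate(aln, min_leaves=config.min_clade_leaves)
        trees = {c: read_tree(p) for c, p in config.trees.items()}

        stage = "counts"
        if config.counts_tsv:
            counts = read_counts_tsv(config.counts_tsv)
        else:
            counts = clade_site_counts(
                aln, trees, partition,
                model=config.model, correction=config.correction,
                min_leaves=config.min_clade_leaves,
            )
        write_counts_tsv(counts, outdir / "counts.tsv")
        rates = relative_rates(counts)
        report["counts"] = {
            "n_columns": int(aln.n_cols),
            "clades": partition.clades,
            "tree_lengths": {
                c: float(counts.loc[counts["clade"] == c, "tree_length"].iloc[0])
                for c in partition.clades
            },
        }

        stage = "divergence"
        clade_data = build_clade_data(aln, trees, partition, counts, config.model)
        theta = pairwise_theta_table(clade_data, config.conservation_ceiling)
        theta.to_csv(outdir / "theta_table.tsv", sep="\t", float_format="%.4f")
        pairs = config.pairs or [
            list(p) for p in itertools.combinations(partition.clades, 2)
        ]
        all_calls = []
        posteriors = {}
        for a, b in pairs:
            da, db = clade_data[a], clade_data[b]
            fit = fit_type_I(da.counts, db.counts, da.tree_length, db.tree_length)
            post = type_I_posteriors(fit, da.counts, db.counts,
                                     da.tree_length, db.tree_length)
            posteriors[(a, b)] = post
            t2_flags, _ = classify_type_II(
                da.root_states, db.root_states, da.counts, db.counts,
                config.conservation_ceiling,
            )
            calls = classify_sites(
                post, t2_flags, da.counts, db.counts,
                da.consensus, db.consensus, a, b, config.posterior_cutoff,
            )
            all_calls.append(calls)
        calls_df = pd.concat(all_calls, ignore_index=True)
        calls_df.to_csv(outdir / "site_calls.tsv", sep="\t", index=False,
                        float_format="%.6f")
        report["divergence"] = {
            "theta_table": json.loads(theta.to_json(orient="index")),
            "n_pairs": len(pairs),
        }

        structmap = None
        graph = None
        merged_classes: dict[int, str] = {}
        for _, row in calls_df.iterrows():
            c, k = int(row["column"]), row["site_class"]
            if _CLASS_SEVERITY[k] > _CLASS_SEVERITY.get(merged_classes.get(c, "none"), 0):
                merged_classes[c] = k
        typed_columns = [c for c, k in merged_classes.items() if k != "none"]

        if config.structure:
            stage = "contacts"
            coords = read_structure(config.structure, config.chain, config.atom_mode)
            ref = config.reference_id or aln.ids[0]
            structmap = map_alignment_to_structure(aln, ref, coords)
            graph = build_contact_graph(
                structmap, typed_columns,
                threshold=config.contact_threshold, atom_mode=config.atom_mode,
            )
            write_edge_list(graph, outdir / "contact_edges.tsv")
            report["contacts"] = {
                "n_typed_columns": len(typed_columns),
                "n_vertices": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "threshold": config.contact_threshold,
                "atom_mode": config.atom_mode,
            }

        if config.quartets and graph is not None:
            stage = "quartet"
            results = []
            for i, q in enumerate(config.quartets):
                (a, b), (c, d) = q["clades"]
                qc = QuartetConfig(
                    quartet=((a, b), (c, d)),
                    n_sites=int(q.get("n_sites", 25)),
                    n_perm=int(q.get("n_perm", config.n_resample)),
                    seed=config.seed + i,
                )
                for pair in ((a, b), (c, d)):
                    if tuple(pair) not in posteriors:
                        da, db = clade_data[pair[0]], clade_data[pair[1]]
                        fit = fit_type_I(da.counts, db.counts,
                                         da.tree_length, db.tree_length)
                        posteriors[tuple(pair)] = type_I_posteriors(
                            fit, da.counts, db.counts, da.tree_length, db.tree_length
                        )
                e1, e2 = select_quartet_sites(
                    posteriors[(a, b)], posteriors[(c, d)], qc.n_sites
                )
                e1 = [c_ for c_ in e1 if c_ in structmap.col_to_residue]
                e2 = [c_ for c_ in e2 if c_ in structmap.col_to_residue]
                n = min(len(e1), len(e2))
                e1, e2 = e1[:n], e2[:n]
                res = clustering_permutation_test(e1, e2, graph, qc)
                results.append(
                    {
                        "quartet": [[a, b], [c, d]],
                        "statistic": res.statistic,
                        "per_edge": list(res.per_edge),
                        "p_value": res.p_value,
                        "mode": res.mode,
                        "pool_size": res.pool_size,
                        "consecutive_statistic": consecutive_statistic(
                            e1, e2, structmap
                        ),
                    }
                )
            report["quartet_tests"] = results

        if config.regions:
            stage = "regions"
            report["regions"] = run_table1_analysis(
                config, counts=counts, rates=rates
            )

        lscs = []
        if graph is not None:
            stage = "lsc"
            lscs = find_lscs(merged_classes, graph, structmap)
            lsc_rows = []
            for lsc in lscs:
                profiles = lsc_state_profiles(lsc, aln, partition)
                states, flagged = assign_states(profiles)
                lsc.states = states
                lsc.intransitive = flagged
                lsc_rows.append(
                    {
                        "lsc": lsc.name,
                        "columns": ",".join(map(str, lsc.columns)),
                        "residues": ",".join(lsc.residues),
                        "n_type0": lsc.type_counts.get("type0", 0),
                        "n_typeI": lsc.type_counts.get("typeI", 0),
                        "n_typeII": lsc.type_counts.get("typeII", 0),
                        "states": ",".join(
                            f"{c}:{'?' if s is None else s}"
                            for c, s in sorted(states.items())
                        ),
                        "intransitive": flagged,
                    }
                )
            pd.DataFrame(
                lsc_rows,
                columns=["lsc", "columns", "residues", "n_type0", "n_typeI",
                         "n_typeII", "states", "intransitive"],
            ).to_csv(outdir / "lsc.tsv", sep="\t", index=False)
            report["lscs"] = {"n_lscs": len(lscs), "names": [l.name for l in lscs]}

        if lscs and len(partition.clades) >= 3:
            stage = "mptree"
            matrix = character_matrix(lscs, partition.clades)
            matrix_out = matrix.fillna("?")
            matrix_out.to_csv(outdir / "character_matrix.tsv", sep="\t")
            if len(partition.clades) <= 9:
                mp = mp_search(matrix)
                (outdir / "mp_trees.nwk").write_text("\n".join(mp.topologies) + "\n")
                report["parsimony"] = {
                    "best_score": mp.best_score,
                    "n_optimal": mp.n_optimal,
                    "n_evaluated": mp.n_evaluated,
                    "per_character": mp.per_character_scores,
                }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_table1_analysis(
    config: ScanConfig,
    counts: pd.DataFrame | None = None,
    rates: pd.DataFrame | None = None,
) -> dict:
    """Per-clade region rate summary and tests, plus the cross-clade LRT.

    For each named region and clade: clade tree length, mean relative rate
    inside and outside the region, lower-tail location p (mean statistic) and
    distribution p (rank sum); across clades, the Poisson LRT that the
    region's summary rate is uniform.
    """
    if counts is None:
        aln = read_alignment(config.alignment, config.alignment_format)
        partition = read_clade_map(config.clade_map)
        partition.validate(aln, min_leaves=config.min_clade_leaves)
        trees = {c: read_tree(p) for c, p in config.trees.items()}
        counts = clade_site_counts(
            aln, trees, partition, model=config.model,
            correction=config.correction, min_leaves=config.min_clade_leaves,
        )
    if rates is None:
        rates = relative_rates(counts)
    n_cols = int(counts["column"].max())
    clades = sorted(counts["clade"].unique())
    out: dict = {}
    for name, spec in config.regions.items():
        cols = _region_columns(spec, n_cols)
        idx = np.array(cols) - 1
        rows = []
        region_totals, lengths = [], []
        for j, clade in enumerate(clades):
            x = counts.loc[counts["clade"] == clade].sort_values("column")
            xc = x["corrected_count"].to_numpy()
            t = float(x["tree_length"].iloc[0])
            rel = rates[clade].to_numpy()
            mask = np.zeros(n_cols, dtype=bool)
            mask[idx] = True
            rows.append(
                {
                    "clade": clade,
                    "tree_length": t,
                    "rate_region": float(rel[mask].mean()),
                    "rate_remainder": float(rel[~mask].mean()),
                    "p_location": region_location_test(
                        xc, cols, config.n_resample, config.seed + j
                    ),
                    "p_distribution": region_distribution_test(
                        xc, cols, config.n_resample, config.seed + j
                    ),
                }
            )
            region_totals.append(float(xc[mask].sum()))
            lengths.append(t)
        lrt = poisson_lrt(region_totals, lengths)
        out[name] = {
            "per_clade": rows,
            "lrt": {
                "statistic": lrt.statistic,
                "df": lrt.df,
                "p_value": lrt.p_value,
                "pooled_rate": lrt.pooled_rate,
            },
        }
    return out


def _provenance(config: ScanConfig) -> dict:
    import Bio
    import networkx
    import scipy

    return {
        "lsckit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "biopython": Bio.__version__,
        "seed": config.seed,
        "config": config.echo(),
    }
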
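"""Post-inference network statistics.

Degrees of the predicted interaction network, overlap of predicted edges
with an external reference pair list, and the homolog-conservation
partition of complex members (proteins grouped by whether they have
homologs in one, both, or neither of two reference species). Homology
detection itself is out of scope: homolog maps are inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import UsageError
from .reference_complexes import Pair, canonical_pair

CONSERVATION_GROUPS = ("unique", "a_only", "b_only", "both")


def degree_distribution(
    graph: nx.Graph, homolog_map: Mapping[str, bool] | None = None
) -> tuple[pd.DataFrame, dict | None]:
    """Per-protein degree table, optionally split into conserved vs unique.

    With a homolog map (protein -> has any homolog), proteins are grouped and
    the two degree samples are compared with a one-sided Wilcoxon rank-sum
    test (conserved > unique), reporting medians and the p value.
    """
    rows = []
    for node in sorted(graph.nodes):
        group = None
        if homolog_map is not None:
            group = "conserved" if homolog_map.get(node, False) else "unique"
        rows.append((node, graph.degree(node), group))
    table = pd.DataFrame(rows, columns=["protein_id", "degree", "group"])
    comparison = None
    if homolog_map is not None:
        conserved = table.loc[table["group"] == "conserved", "degree"]
        unique = table.loc[table["group"] == "unique", "degree"]
        if len(conserved) and len(unique):
            stat = stats.mannwhitneyu(conserved, unique, alternative="greater")
            comparison = {
                "median_conserved": float(conserved.median()),
                "median_unique": float(unique.median()),
                "u_statistic": float(stat.statistic),
                "p_value": float(stat.pvalue),
            }
    return table, comparison


def overlap_with_reference(
    edges: Iterable[Pair], reference_pairs: Iterable[Pair]
) -> dict:
    """Fraction of predicted edges present in a reference pair list."""
    edge_set = {canonical_pair(*e) for e in edges}
    if not edge_set:
        raise UsageError("empty edge set")
    ref_set = {canonical_pair(*p) for p in reference_pairs}
    inter = sorted(edge_set & ref_set)
    return {
        "fraction": len(inter) / len(edge_set),
        "n_edges": len(edge_set),
        "n_overlap": len(inter),
        "intersection": inter,
    }


def conservation_partition(
    complexes: Mapping[str, Iterable[str]],
    homolog_map_a: Mapping[str, bool],
    homolog_map_b: Mapping[str, bool],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-way conservation grouping of complex members.

    Each member of each complex is assigned to exactly one of
    {unique, a_only, b_only, both} based on the two species' homolog flags
    (missing proteins count as no homolog). Returns the per-member table and
    a per-complex composition summary.
    """
    rows = []
    for name in sorted(complexes):
        for protein in sorted(complexes[name]):
            in_a = bool(homolog_map_a.get(protein, False))
            in_b = bool(homolog_map_b.get(protein, False))
            if in_a and in_b:
                group = "both"
            elif in_a:
                group = "a_only"
            elif in_b:
                group = "b_only"
            else:
                group = "unique"
            rows.append((name, protein, group))
    table = pd.DataFrame(rows, columns=["complex", "protein_id", "group"])
    summary = (
        table.pivot_table(
            index="complex", columns="group", values="protein_id", aggfunc="count"
        )
        .reindex(columns=CONSERVATION_GROUPS)
        .fillna(0)
        .astype(int)
    )
    return table, summary


def write_pair_list(pairs: Iterable[Pair], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(canonical_pair(*p) for p in pairs):
            fh.write(f"{a}\t{b}\n")


def read_pair_list(path) -> list[Pair]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return [canonical_pair(a, b) for a, b in zip(df["protein_a"], df["protein_b"])]


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Three-column weighted edge list (protein_a, protein_b, probability)."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", dtype={"protein_a": str, "protein_b": str})
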
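"""Cohesiveness-based complex detection on the weighted PPI network.

Greedy growth of overlapping clusters that maximize the cohesiveness
objective

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + p * |V|)

where w_in is the total weight of edges inside V, w_bound the total weight
of edges crossing the boundary, and p a per-node penalty modelling unseen
connections. Seeds are taken in decreasing weighted-degree order (skipping
nodes already covered); each cluster grows by the single best strictly
improving move (add an adjacent external node or remove an internal one);
highly overlapping clusters (omega = |A&B|^2 / (|A||B|) above a threshold)
are merged; small or sparse clusters are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import UsageError


@dataclass(frozen=True)
class PredictedComplex:
    members: frozenset[str]
    cohesiveness: float
    density: float
    seed_node: str

    @property
    def size(self) -> int:
        return len(self.members)


def _in_bound_weights(graph: nx.Graph, nodes: set) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, data in graph[u].items():
            w = float(data.get("weight", 1.0))
            if v in nodes:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(graph: nx.Graph, node_set: Iterable[str], penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + p|V|); empty set is a domain error."""
    nodes = set(node_set)
    if not nodes:
        raise UsageError("cohesiveness of the empty set is undefined")
    missing = nodes - set(graph.nodes)
    if missing:
        raise UsageError(f"nodes not in network: {sorted(missing)}")
    w_in, w_bound = _in_bound_weights(graph, nodes)
    denom = w_in + w_bound + penalty * len(nodes)
    if denom == 0:
        return 0.0
    return w_in / denom


def density(graph: nx.Graph, node_set: Iterable[str]) -> float:
    """Weighted density 2*w_in / (|V| (|V|-1))."""
    nodes = set(node_set)
    n = len(nodes)
    if n < 2:
        return 0.0
    w_in, _ = _in_bound_weights(graph, nodes)
    return 2.0 * w_in / (n * (n - 1))


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A&B|^2 / (|A| |B|), in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise UsageError("overlap score of an empty set is undefined")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


def grow_cluster(graph: nx.Graph, seed_node: str, penalty: float = 2.0) -> PredictedComplex:
    """Greedy cohesiveness maximization from a single seed.

    At each step the single move (add an adjacent external node, or remove an
    internal node) that most increases cohesiveness is applied; ties break to
    the smallest node id; growth stops when no move strictly improves.
    Deterministic.
    """
    if seed_node not in graph:
        raise UsageError(f"seed node {seed_node!r} not in network")
    members: set[str] = {seed_node}
    current = cohesiveness(graph, members, penalty)
    while True:
        candidates: list[tuple[float, str, str]] = []  # (score, node, action)
        boundary = {
            v for u in members for v in graph[u] if v not in members
        }
        for v in sorted(boundary):
            score = cohesiveness(graph, members | {v}, penalty)
            candidates.append((score, v, "add"))
        if len(members) > 1:
            for u in sorted(members):
                score = cohesiveness(graph, members - {u}, penalty)
                candidates.append((score, u, "remove"))
        if not candidates:
            break
        best_score = max(s for s, _, _ in candidates)
        if best_score <= current:
            break
        score, node, action = min(
            (c for c in candidates if c[0] == best_score), key=lambda c: c[1]
        )
        if action == "add":
            members.add(node)
        else:
            members.remove(node)
        current = score
    return PredictedComplex(
        members=frozenset(members),
        cohesiveness=current,
        density=density(graph, members),
        seed_node=seed_node,
    )


def _merge_pass(clusters: list[frozenset[str]], threshold: float) -> list[frozenset[str]]:
    """Merge cluster pairs with omega >= threshold until fixed point."""
    merged = True
    clusters = sorted(set(clusters), key=lambda c: tuple(sorted(c)))
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if overlap_score(clusters[i], clusters[j]) >= threshold:
                    union = clusters[i] | clusters[j]
                    clusters = [
                        c for k, c in enumerate(clusters) if k not in (i, j)
                    ]
                    clusters.append(union)
                    clusters = sorted(set(clusters), key=lambda c: tuple(sorted(c)))
                    merged = True
                    break
            if merged:
                break
    return clusters


def detect_complexes(
    graph: nx.Graph,
    penalty: float = 2.0,
    merge_threshold: float = 0.8,
    min_size: int = 3,
    min_density: float = 0.3,
) -> list[PredictedComplex]:
    """Full detection pass: seed, grow, merge, filter, rank.

    Seeds are nodes in decreasing weighted-degree order (ties by id),
    skipping nodes already inside a grown cluster. Overlapping clusters with
    omega >= `merge_threshold` are unioned until a fixed point; clusters
    smaller than `min_size` or sparser than `min_density` are discarded.
    Output is sorted by cohesiveness, descending.
    """
    if graph.number_of_nodes() == 0:
        raise UsageError("empty network")
    wdeg = {n: float(d) for n, d in graph.degree(weight="weight")}
    seeds = sorted(graph.nodes, key=lambda n: (-wdeg[n], n))
    covered: set[str] = set()
    grown: list[PredictedComplex] = []
    seed_of: dict[frozenset[str], str] = {}
    for s in seeds:
        if s in covered:
            continue
        cluster = grow_cluster(graph, s, penalty)
        covered |= cluster.members
        if cluster.members not in seed_of:
            seed_of[cluster.members] = s
            grown.append(cluster)

    merged_sets = _merge_pass([c.members for c in grown], merge_threshold)
    out: list[PredictedComplex] = []
    for members in merged_sets:
        coh = cohesiveness(graph, members, penalty)
        dens = density(graph, members)
        if len(members) < min_size or dens < min_density:
            continue
        out.append(
            PredictedComplex(
                members=members,
                cohesiveness=coh,
                density=dens,
                seed_node=seed_of.get(members, min(members)),
            )
        )
    return sorted(out, key=lambda c: (-c.cohesiveness, tuple(sorted(c.members))))


def complex_supported_pairs(
    graph: nx.Graph, complexes: Sequence[PredictedComplex]
) -> list[tuple[str, str]]:
    """Within-complex pairs that are edges of the network (the reported PPIs)."""
    pairs: set[tuple[str, str]] = set()
    for cpx in complexes:
        members = sorted(cpx.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if graph.has_edge(a, b):
                    pairs.add((a, b))
    return sorted(pairs)


def complex_recovery(
    predicted: Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    min_size: int = 3,
    min_jaccard: float = 0.5,
) -> tuple[float, dict[str, float]]:
    """Fraction of reference complexes (size >= min_size) matched by a
    predicted complex at member-set Jaccard >= min_jaccard.

    Returns the recovery rate and the best Jaccard per evaluated reference
    complex.
    """
    pred_sets = [set(p) for p in predicted]
    best: dict[str, float] = {}
    for name, members in reference.items():
        ref = set(members)
        if len(ref) < min_size:
            continue
        best[name] = max(
            (len(ref & p) / len(ref | p) for p in pred_sets), default=0.0
        )
    if not best:
        return 0.0, {}
    matched = sum(1 for j in best.values() if j >= min_jaccard)
    return matched / len(best), best


def write_complexes(complexes: Sequence[PredictedComplex], path) -> None:
    """One complex per line: rank name, cohesiveness, density, members."""
    with open(path, "w") as fh:
        for i, cpx in enumerate(complexes, start=1):
            fh.write(
                "\t".join(
                    [
                        f"C{i:04d}",
                        f"{cpx.cohesiveness:.6f}",
                        f"{cpx.density:.6f}",
                        *sorted(cpx.members),
                    ]
                )
                + "\n"
            )
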
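"""Sparse-graph hierarchical clustering into gene families.

Nodes are sequence ids, edges carry integer similarity weights.  The
default mode is greedy agglomeration: starting from singletons, the pair
of clusters with the highest average cross-edge weight is merged, subject
to a minimum cross-edge density and a maximum cluster size, until no
permissible merge remains.  Absent edges count 0 toward the average.
Ties break on higher cross-edge count, then on the lexicographically
smallest (min-member-a, min-member-b) pair, so the result is
deterministic.  A merge log is kept so the clustering is auditable.

Single-link mode instead takes connected components of the thresholded
graph, splitting oversized components by repeatedly deleting the
globally lightest edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .edge_weights import WeightedEdge
from .preparation import SequenceRecord


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds (defaults follow the relaxed pipeline preset)."""

    min_edge_weight: int = 0
    min_density: float = 0.34
    max_size: int = 500
    single_link: bool = False
    min_cluster_size: int = 3
    max_cluster_size_filter: int | None = None

    def __post_init__(self) -> None:
        if self.max_size < 1:
            raise ClusterError("max_size must be >= 1")
        if not 0 <= self.min_density <= 1:
            raise ClusterError("min_density must be in [0, 1]")


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ClusterError("empty cluster")

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class MergeEvent:
    """One agglomeration step, for auditing the clustering."""

    left: frozenset[str]
    right: frozenset[str]
    avg_weight: float
    cross_edges: int
    density: float


def _components(nodes: set[str], adj: dict[str, set[str]]) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def _single_link(nodes: set[str], edges: list[WeightedEdge], max_size: int) -> list[set[str]]:
    live = sorted(edges, key=lambda e: (e.weight, e.a, e.b))
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for e in live:
        adj[e.a].add(e.b)
        adj[e.b].add(e.a)
    comps = _components(nodes, adj)
    while any(len(c) > max_size for c in comps) and live:
        lightest = live.pop(0)
        adj[lightest.a].discard(lightest.b)
        adj[lightest.b].discard(lightest.a)
        comps = _components(nodes, adj)
    return comps


def hcluster(
    edges: list[WeightedEdge],
    params: ClusterParams | None = None,
    merge_log: list[MergeEvent] | None = None,
) -> list[Cluster]:
    """Cluster the similarity graph; isolated nodes become singletons.

    The node set is every id appearing in *edges*.  Edges lighter than
    ``min_edge_weight`` are dropped first.  Returns clusters sorted by
    descending size, then smallest member id.
    """
    params = params or ClusterParams()
    nodes: set[str] = set()
    for e in edges:
        nodes.update((e.a, e.b))
    surviving = [e for e in edges if e.weight >= params.min_edge_weight]

    if params.single_link:
        comps = _single_link(nodes, surviving, params.max_size)
        clusters = [Cluster(frozenset(c)) for c in comps]
    else:
        weight: dict[tuple[str, str], int] = {}
        for e in surviving:
            key = (min(e.a, e.b), max(e.a, e.b))
            weight[key] = max(weight.get(key, 0), e.weight)

        groups: dict[str, frozenset[str]] = {n: frozenset([n]) for n in nodes}

        def cross_stats(x: frozenset[str], y: frozenset[str]) -> tuple[float, int]:
            total = 0
            count = 0
            for u in x:
                for v in y:
                    w = weight.get((min(u, v), max(u, v)))
                    if w is not None:
                        total += w
                        count += 1
            return total / (len(x) * len(y)), count

        while True:
            best_key = None
            best_merge = None
            reps = sorted(groups)
            for i, ra in enumerate(reps):
                for rb in reps[i + 1 :]:
                    x, y = groups[ra], groups[rb]
                    if len(x) + len(y) > params.max_size:
                        continue
                    avg, count = cross_stats(x, y)
                    if count == 0:
                        continue
                    density = count / (len(x) * len(y))
                    if density < params.min_density:
                        continue
                    # maximize avg weight; ties: more cross edges, then
                    # lexicographically smallest member-id pair
                    key = (-avg, -count, min(ra, rb), max(ra, rb))
                    if best_key is None or key < best_key:
                        best_key = key
                        best_merge = (ra, rb, avg, count, density)
            if best_merge is None:
                break
            ra, rb, avg, count, density = best_merge
            x, y = groups.pop(ra), groups.pop(rb)
            if merge_log is not None:
                merge_log.append(MergeEvent(x, y, avg, count, density))
            groups[min(ra, rb)] = x | y
        clusters = [Cluster(g) for g in groups.values()]

    clusters.sort(key=lambda c: (-len(c), min(c.members)))
    return clusters


def split_and_filter(
    clusters: list[Cluster], params: ClusterParams | None = None
) -> tuple[list[list[str]], list[str]]:
    """Partition clusters into kept id-lists and discarded ids by size.

    Clusters smaller than ``min_cluster_size`` (default 3: a gene tree
    needs at least 3 genes) or larger than ``max_cluster_size_filter``
    are discarded; their member ids are pooled, sorted, for the orphan
    workflow.
    """
    params = params or ClusterParams()
    kept: list[list[str]] = []
    discarded: list[str] = []
    for c in clusters:
        too_small = len(c) < params.min_cluster_size
        too_big = (
            params.max_cluster_size_filter is not None
            and len(c) > params.max_cluster_size_filter
        )
        if too_small or too_big:
            discarded.extend(c.members)
        else:
            kept.append(c.sorted_members())
    kept.sort(key=lambda ids: ids[0])
    return kept, sorted(set(discarded))


def subset_fasta(
    records: list[SequenceRecord], ids: list[str], strict: bool = True
) -> list[SequenceRecord]:
    """Records for *ids*, in ids order; unknown ids error (or warn)."""
    if len(set(ids)) != len(ids):
        raise ClusterError("duplicate ids in subset request")
    by_id = {r.id: r for r in records}
    missing = [i for i in ids if i not in by_id]
    if missing:
        msg = f"ids not present in FASTA: {missing}"
        if strict:
            raise ClusterError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    return [by_id[i] for i in ids if i in by_id]
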
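"""Median-joining haplotype networks and lineage partitions.

The network is built over coded state vectors: Hamming distance counts
differing characters, so an indel or inversion character contributes exactly
one mutation step. The median-joining construction follows Bandelt's scheme:
iterate a minimum-spanning network (union of all minimum spanning trees plus
links within ``epsilon`` of feasibility) over the current node set, propose
median vectors (per-character majority of connected triplets), add the
cheapest ones, and prune unobserved nodes of degree <= 2 until a fixpoint.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coding import MISSING, HaplotypeCatalog

log = logging.getLogger(__name__)


def hamming_matrix(catalog: HaplotypeCatalog, kinds: set[str] | None = None) -> np.ndarray:
    """Pairwise mutation counts between haplotypes (label order).

    ``kinds`` restricts the distance to a subset of character kinds, e.g.
    ``{"substitution"}`` for the per-site nucleotide diversity.
    """
    vectors = catalog.vectors()
    if vectors.size and (vectors == MISSING).any():
        raise ValueError("missing state in haplotype vectors")
    if kinds is not None:
        cols = [i for i, c in enumerate(catalog.characters) if c.kind in kinds]
        vectors = vectors[:, cols] if cols else vectors[:, :0]
    return _pairwise_hamming(vectors)


def _pairwise_hamming(vectors: np.ndarray) -> np.ndarray:
    n = vectors.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1 :] = (vectors[i + 1 :] != vectors[i]).sum(axis=1)
    return d + d.T


def minimum_spanning_network(dist: np.ndarray, epsilon: int = 0) -> nx.Graph:
    """Union of all minimum spanning trees, relaxed by ``epsilon``.

    An edge (i, j) is kept iff i and j are not already connected using only
    strictly cheaper links (cheaper by more than ``epsilon``); with
    ``epsilon = 0`` this is exactly the union of all MSTs, so every tie link
    survives.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    n = dist.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n <= 1:
        return g
    pairs = [(int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    for w, i, j in sorted(pairs):
        sub = nx.Graph()
        sub.add_nodes_from(range(n))
        sub.add_edges_from(
            (a, b) for ww, a, b in pairs if ww < w - epsilon and g.has_edge(a, b)
        )
        # components of the graph restricted to strictly cheaper accepted links
        if not nx.has_path(sub, i, j):
            g.add_edge(i, j, weight=w)
    return g


@dataclass
class HaploNetwork:
    """Graph over observed haplotypes and inferred median vectors."""

    graph: nx.Graph
    epsilon: int
    catalog: HaplotypeCatalog

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]


@dataclass
class LineagePartition:
    labels: dict[str, str]  # node -> lineage label
    diagnostic_characters: list[int]


def _median_vector(u: tuple, v: tuple, w: tuple) -> tuple:
    """Per-character majority of three vectors; three-way ties keep u's state."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)  # covers a==b, a==c and the all-distinct tie
    return tuple(out)


def median_joining(
    catalog: HaplotypeCatalog, epsilon: int = 0, max_iter: int = 50
) -> HaploNetwork:
    """Build the median-joining network over the catalog's haplotypes.

    Deterministic given the catalog order: nodes are processed observed
    before median, then by label, and candidate medians in lexicographic
    state order.
    """
    if not catalog.haplotypes:
        raise ValueError("empty catalog")
    vectors: list[tuple] = [tuple(h.vector) for h in catalog.haplotypes]
    names: list[str] = [h.label for h in catalog.haplotypes]
    observed = [True] * len(vectors)
    known = set(vectors)
    n_median = 0

    for iteration in range(max_iter):
        dist = _pairwise_hamming(np.array([list(v) for v in vectors], dtype="<U1"))
        msn = minimum_spanning_network(dist, epsilon)

        candidates: dict[tuple, int] = {}
        for i in range(len(vectors)):
            for j, k in itertools.combinations(sorted(msn.neighbors(i)), 2):
                med = _median_vector(vectors[i], vectors[j], vectors[k])
                if med in known:
                    continue
                cost = sum(
                    sum(a != b for a, b in zip(med, vectors[x])) for x in (i, j, k)
                )
                if med not in candidates or cost < candidates[med]:
                    candidates[med] = cost

        added = False
        if candidates:
            best = min(candidates.values())
            for med in sorted(m for m, c in candidates.items() if c <= best + epsilon):
                n_median += 1
                vectors.append(med)
                names.append(f"mv{n_median}")
                observed.append(False)
                known.add(med)
                added = True

        # prune unobserved nodes that ended up peripheral
        dist = _pairwise_hamming(np.array([list(v) for v in vectors], dtype="<U1"))
        msn = minimum_spanning_network(dist, epsilon)
        drop = sorted(
            (i for i in range(len(vectors)) if not observed[i] and msn.degree(i) <= 2),
            reverse=True,
        )
        for i in drop:
            known.discard(vectors[i])
            del vectors[i], names[i]
            del observed[i]
        if not added and not drop:
            break
    else:
        raise RuntimeError(
            f"median-joining did not converge in {max_iter} rounds; "
            f"{len(vectors)} nodes ({n_median} medians proposed)"
        )

    dist = _pairwise_hamming(np.array([list(v) for v in vectors], dtype="<U1"))
    msn = minimum_spanning_network(dist, epsilon)
    graph = nx.Graph()
    count_of = {h.label: h.total for h in catalog.haplotypes}
    for i, name in enumerate(names):
        graph.add_node(
            name,
            observed=bool(observed[i]),
            vector=vectors[i],
            count=count_of.get(name, 0),
        )
    for i, j in msn.edges():
        diff = tuple(
            k for k, (a, b) in enumerate(zip(vectors[i], vectors[j])) if a != b
        )
        graph.add_edge(names[i], names[j], mutations=len(diff), diff_chars=diff)
    return HaploNetwork(graph, epsilon, catalog)


def cut_lineages(
    network: HaploNetwork,
    diagnostic_characters: list[int],
    labels: list[str] | None = None,
) -> LineagePartition:
    """Partition the network by removing edges crossing diagnostic characters.

    ``diagnostic_characters`` are character indices into the catalog's coded
    matrix (e.g. the A/G transition column, the 8-bp indel character).
    Components are ordered by descending observed sample count (ties by
    smallest node label) and labelled with ``labels`` (defaults A, B, C, ...).
    """
    node_states: dict[str, set] = {}
    for char in diagnostic_characters:
        states = {d["vector"][char] for _, d in network.graph.nodes(data=True)}
        if len(states) < 2:
            raise ValueError(f"diagnostic character {char} is monomorphic in the network")

    cut = network.graph.copy()
    cut.remove_edges_from(
        [
            (a, b)
            for a, b, d in network.graph.edges(data=True)
            if set(d["diff_chars"]) & set(diagnostic_characters)
        ]
    )
    components = list(nx.connected_components(cut))
    node_count = {n: d["count"] for n, d in network.graph.nodes(data=True)}
    components.sort(key=lambda c: (-sum(node_count[n] for n in c), min(c)))
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(len(components))]
    if len(labels) < len(components):
        raise ValueError(
            f"{len(components)} components but only {len(labels)} lineage labels"
        )
    mapping = {}
    for label, comp in zip(labels, components):
        for node in comp:
            mapping[node] = label
    return LineagePartition(mapping, list(diagnostic_characters))


def apply_lineages(catalog: HaplotypeCatalog, partition: LineagePartition) -> None:
    """Write lineage labels back onto the catalog's haplotypes."""
    for hap in catalog.haplotypes:
        hap.lineage = partition.labels.get(hap.label)
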
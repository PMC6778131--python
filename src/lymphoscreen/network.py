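"""BCR repertoire networks: clonality, cluster-preserving subsampling, trees.

A repertoire of heavy-chain reads is summarized as a graph: each vertex is a
unique nucleotide sequence weighted by its read multiplicity; edges join
vertices that differ by a single nucleotide substitution (equal length,
Hamming distance exactly 1 — no indel-tolerant edges); clusters are the
connected components, which under somatic hypermutation correspond to
clonal expansions.

Three analyses operate on this graph:

- clonality summaries (percentage of unique sequences, cluster sizes);
- cluster-enforced linkage (CC) subsampling, which downsamples the vertex
  set while keeping every cluster represented and internally connected, so
  plots of large repertoires preserve the clonal structure;
- per-cluster unrooted maximum-parsimony trees with integer branch lengths
  (exhaustive search over topologies for small clusters, stepwise addition
  plus nearest-neighbour interchange beyond that).

Sequences containing N are kept as vertices but excluded from edge building
(ambiguity is not evidence of relatedness); they are reported in QC.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

Edge = tuple[str, str]


@dataclass
class RepertoireGraph:
    """Vertices (sequence -> read multiplicity), Hamming-1 edges, clusters.

    Clusters are ordered by (size descending, lexicographically smallest
    member) and each cluster lists its members lexicographically, so cluster
    ids are stable across runs.
    """

    vertices: dict[str, int]
    edges: set[Edge]
    clusters: list[list[str]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def max_cluster_size(self) -> int:
        return max((len(c) for c in self.clusters), default=0)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.vertices}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for v in adj:
            adj[v].sort()
        return adj

    def cluster_of(self) -> dict[str, int]:
        return {v: i for i, cluster in enumerate(self.clusters) for v in cluster}

    def to_networkx(self) -> nx.Graph:
        """Graph with per-node ``size`` and ``cluster_id`` attributes, for
        GraphML export."""
        g = nx.Graph()
        cluster_id = self.cluster_of()
        for seq, size in sorted(self.vertices.items()):
            g.add_node(seq, size=size, cluster_id=cluster_id[seq])
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class ClonalityReport:
    n_reads: int
    n_unique: int
    pct_unique: float
    max_cluster_size: int
    cluster_sizes: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_unique": self.n_unique,
            "pct_unique": self.pct_unique,
            "max_cluster_size": self.max_cluster_size,
            "cluster_sizes": list(self.cluster_sizes),
        }


# ---------------------------------------------------------------------------
# graph construction


def collapse_reads(reads: list[str]) -> dict[str, int]:
    """Unique sequence -> multiplicity; order-invariant."""
    if not reads:
        raise ValueError("no reads to collapse")
    return dict(Counter(reads))


def build_edges(vertices: dict[str, int] | list[str]) -> set[Edge]:
    """All pairs of vertices at substitution distance exactly 1.

    Equal-length sequences only (the non-indel rule). Implemented by
    bucketing each sequence under its L one-position-masked keys: two
    distinct sequences share a masked key iff they differ exactly at the
    masked position, so each bucket's pairs are exactly the Hamming-1 pairs.
    Sequences containing N are skipped (ambiguous positions are not counted
    as single-substitution evidence).
    """
    seqs = list(vertices)
    if not seqs:
        raise ValueError("empty vertex set")
    edges: set[Edge] = set()
    buckets: dict[tuple[int, int, str], list[str]] = defaultdict(list)
    for seq in seqs:
        if "N" in seq:
            continue
        for pos in range(len(seq)):
            buckets[(len(seq), pos, seq[:pos] + seq[pos + 1 :])].append(seq)
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for u, v in itertools.combinations(bucket, 2):
            edges.add((u, v) if u < v else (v, u))
    return edges


def ambiguous_vertices(vertices: dict[str, int] | list[str]) -> list[str]:
    """Vertices excluded from edge building because they contain N (QC)."""
    return sorted(seq for seq in vertices if "N" in seq)


def find_clusters(
    vertices: dict[str, int] | list[str], edges: set[Edge]
) -> list[list[str]]:
    """Connected components, ordered by (size desc, smallest member)."""
    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    components = [sorted(comp) for comp in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return components


def build_graph(reads: list[str]) -> RepertoireGraph:
    """Collapse reads, build Hamming-1 edges, find clusters."""
    vertices = collapse_reads(reads)
    edges = build_edges(vertices)
    clusters = find_clusters(vertices, edges)
    return RepertoireGraph(vertices=vertices, edges=edges, clusters=clusters)


def clonality(reads: list[str], graph: RepertoireGraph | None = None) -> ClonalityReport:
    """Clonality summary; lower pct_unique means stronger clonal expansion."""
    if graph is None:
        graph = build_graph(reads)
    n_reads = len(reads)
    n_unique = graph.n_vertices
    sizes = tuple(sorted((len(c) for c in graph.clusters), reverse=True))
    return ClonalityReport(
        n_reads=n_reads,
        n_unique=n_unique,
        pct_unique=100.0 * n_unique / n_reads,
        max_cluster_size=graph.max_cluster_size,
        cluster_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# cluster-enforced linkage (CC) subsampling


def _weighted_sample(
    rng: np.random.Generator, items: list[str], weights: list[int], k: int
) -> list[str]:
    p = np.asarray(weights, dtype=float)
    p /= p.sum()
    idx = rng.choice(len(items), size=k, replace=False, p=p)
    return [items[i] for i in sorted(idx)]


def _select_vertices(
    graph: RepertoireGraph,
    n_target: int,
    rng: np.random.Generator,
    weighted: bool,
) -> set[str]:
    """Step 1, vertex selection: size-proportional sampling followed by a
    repair pass guaranteeing every cluster >=1 selected vertex (largest
    clusters first when n_target is below the cluster count)."""
    clusters = graph.clusters

    def weight(seq: str) -> int:
        return graph.vertices[seq] if weighted else 1

    if n_target < len(clusters):
        # cannot represent every cluster: prioritize the largest
        selected: set[str] = set()
        for cluster in clusters[:n_target]:
            pick = _weighted_sample(rng, cluster, [weight(s) for s in cluster], 1)
            selected.update(pick)
        return selected

    all_vertices = sorted(graph.vertices)
    selected = set(
        _weighted_sample(rng, all_vertices, [weight(s) for s in all_vertices], n_target)
    )
    # repair: move selections from over-represented clusters into empty ones
    per_cluster = [sum(1 for s in c if s in selected) for c in clusters]
    empty = [i for i, n in enumerate(per_cluster) if n == 0]
    for i in empty:
        donor = max(range(len(clusters)), key=lambda j: per_cluster[j])
        donor_selected = sorted(
            (s for s in clusters[donor] if s in selected),
            key=lambda s: (weight(s), s),
        )
        selected.remove(donor_selected[0])
        per_cluster[donor] -= 1
        cluster = clusters[i]
        pick = _weighted_sample(rng, cluster, [weight(s) for s in cluster], 1)
        selected.update(pick)
        per_cluster[i] += 1
    return selected


def _migrate_cluster(
    cluster: list[str],
    selected: set[str],
    adjacency: dict[str, list[str]],
    sizes: dict[str, int],
) -> set[str]:
    """Step 2, cluster-vertex migration: replace a disconnected selection of
    size k with a connected one of the same size, grown from the heaviest
    selected vertex and preferring originally selected vertices."""
    chosen = selected & set(cluster)
    if len(chosen) < 2:
        return chosen
    sub = nx.Graph()
    sub.add_nodes_from(chosen)
    sub.add_edges_from(
        (u, v) for u in chosen for v in adjacency[u] if v in chosen and u < v
    )
    if nx.is_connected(sub):
        return chosen
    k = len(chosen)
    seed_vertex = max(chosen, key=lambda s: (sizes[s], s))
    connected = {seed_vertex}
    while len(connected) < k:
        frontier = sorted(
            {v for u in connected for v in adjacency[u]} - connected
        )
        preferred = [v for v in frontier if v in chosen]
        pool = preferred if preferred else frontier
        connected.add(max(pool, key=lambda s: (sizes[s], s)))
    return connected


def _induce(graph: RepertoireGraph, selected: set[str]) -> RepertoireGraph:
    """Step 3, total graph induction: keep every original edge whose two
    endpoints are both sampled."""
    vertices = {s: graph.vertices[s] for s in sorted(selected)}
    edges = {(u, v) for u, v in graph.edges if u in selected and v in selected}
    return RepertoireGraph(
        vertices=vertices, edges=edges, clusters=find_clusters(vertices, edges)
    )


def cc_subsample(
    graph: RepertoireGraph,
    n_target: int,
    repeats: int = 20,
    seed: int = 0,
    weighted: bool = True,
) -> RepertoireGraph:
    """Cluster-enforced linkage sampling of the repertoire graph.

    Each of ``repeats`` attempts runs three steps — vertex selection
    (read-weighted, every original cluster represented), cluster-vertex
    migration (each cluster's selection made internally connected), and
    total graph induction. The attempt whose maximum cluster size lies
    closest to the original maximum rescaled by the sampling fraction
    ``n_target / |V|`` is retained (ties: earliest attempt). Deterministic
    given ``seed``.
    """
    if not 1 <= n_target <= graph.n_vertices:
        raise ValueError(
            f"n_target must be in [1, {graph.n_vertices}], got {n_target}"
        )
    rng = np.random.default_rng(seed)
    adjacency = graph.adjacency()
    target_max = graph.max_cluster_size * n_target / graph.n_vertices
    best: RepertoireGraph | None = None
    best_diff = float("inf")
    for _ in range(max(1, repeats)):
        selected = _select_vertices(graph, n_target, rng, weighted)
        migrated: set[str] = set()
        for cluster in graph.clusters:
            migrated |= _migrate_cluster(cluster, selected, adjacency, graph.vertices)
        sample = _induce(graph, migrated)
        diff = abs(sample.max_cluster_size - target_max)
        if diff < best_diff:
            best, best_diff = sample, diff
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# maximum-parsimony clonal trees


@dataclass
class ClonalTree:
    """Unrooted tree over a cluster's unique sequences.

    ``tree``: networkx Graph; leaves carry ``label`` and ``sequence``
    attributes, edges an integer ``length`` (substitution count). ``score``
    is the parsimony score; branch lengths sum to it.
    """

    tree: nx.Graph
    score: int

    @property
    def leaves(self) -> list:
        return [n for n in self.tree.nodes if self.tree.degree(n) <= 1]


def _site_patterns(sequences: list[str]) -> tuple[list[tuple[str, ...]], list[int]]:
    """Variable columns collapsed to unique patterns with multiplicities.

    Constant columns score 0 under any topology and are dropped here (they
    are restored implicitly: they never contribute changes)."""
    counts: Counter[tuple[str, ...]] = Counter()
    for column in zip(*sequences):
        if len(set(column)) > 1:
            counts[column] += 1
    patterns = sorted(counts)
    return patterns, [counts[p] for p in patterns]


def _postorder(tree: nx.Graph, root) -> list[tuple]:
    """(node, parent) pairs, children before parents."""
    order: list[tuple] = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for child in tree.neighbors(node):
            if child != parent:
                stack.append((child, node))
    order.reverse()
    return order


def _fitch_score(
    tree: nx.Graph,
    patterns: list[tuple[str, ...]],
    weights: list[int],
    n_leaves: int,
) -> int:
    """Fitch small-parsimony score over the given site patterns. Leaves are
    integer nodes < n_leaves; pattern[i] is leaf i's state.

    The unrooted binary tree is rooted at its smallest leaf, which leaves
    every internal node with exactly two children; the edge above the root
    leaf is scored by a final intersection."""
    if not patterns:
        return 0
    root = min(n for n in tree.nodes if n < n_leaves)
    top_child = next(iter(tree.neighbors(root)))
    order = _postorder(tree, root)
    total = 0
    for pattern, w in zip(patterns, weights):
        state: dict = {}
        changes = 0
        for node, parent in order:
            if node < n_leaves:
                state[node] = frozenset((pattern[node],))
                continue
            children = [c for c in tree.neighbors(node) if c != parent]
            acc = state[children[0]]
            for child in children[1:]:
                inter = acc & state[child]
                if inter:
                    acc = inter
                else:
                    acc = acc | state[child]
                    changes += 1
            state[node] = acc
        if not (state[root] & state[top_child]):
            changes += 1
        total += changes * w
    return total


def _fitch_branch_lengths(tree: nx.Graph, sequences: list[str]) -> int:
    """Assign ancestral sequences by Fitch refinement and set integer edge
    ``length`` attributes; returns the total (the parsimony score)."""
    n_leaves = len(sequences)
    length = len(sequences[0])
    root = min(n for n in tree.nodes if n < n_leaves)
    order = _postorder(tree, root)
    assigned: dict = {i: sequences[i] for i in range(n_leaves)}
    if tree.number_of_nodes() > 1:
        sets: dict = {}
        for node, parent in order:
            if node < n_leaves:
                sets[node] = [frozenset((sequences[node][j],)) for j in range(length)]
                continue
            children = [c for c in tree.neighbors(node) if c != parent]
            merged = []
            for j in range(length):
                acc = sets[children[0]][j]
                for child in children[1:]:
                    inter = acc & sets[child][j]
                    acc = inter if inter else acc | sets[child][j]
                merged.append(acc)
            sets[node] = merged
        # top-down refinement: keep the parent's state when allowed
        for node, parent in reversed(order):
            if node < n_leaves:
                continue
            chars = []
            for j in range(length):
                options = sets[node][j]
                parent_char = assigned[parent][j] if parent is not None else None
                chars.append(
                    parent_char
                    if parent_char is not None and parent_char in options
                    else min(options)
                )
            assigned[node] = "".join(chars)
    total = 0
    for u, v in tree.edges:
        d = sum(a != b for a, b in zip(assigned[u], assigned[v]))
        tree.edges[u, v]["length"] = d
        total += d
    return total


def _enumerate_topologies(n_leaves: int):
    """All unrooted (multifurcation-free beyond the 3-star core) topologies
    on leaves 0..n-1, by stepwise leaf insertion: 1, 3, 15, 105, ... trees."""
    base = nx.Graph()
    if n_leaves == 2:
        base.add_edge(0, 1)
        yield base
        return
    center = n_leaves  # internal node ids start at n_leaves
    base.add_edges_from([(0, center), (1, center), (2, center)])

    def extend(tree: nx.Graph, next_leaf: int, next_internal: int):
        if next_leaf == n_leaves:
            yield tree
            return
        for u, v in list(tree.edges):
            grown = tree.copy()
            grown.remove_edge(u, v)
            grown.add_edges_from(
                [(u, next_internal), (v, next_internal), (next_leaf, next_internal)]
            )
            yield from extend(grown, next_leaf + 1, next_internal + 1)

    yield from extend(base, 3, n_leaves + 1)


def _nni_neighbours(tree: nx.Graph, n_leaves: int):
    """The two nearest-neighbour-interchange rearrangements of every
    internal edge."""
    for u, v in list(tree.edges):
        if u < n_leaves or v < n_leaves:
            continue
        u_side = [x for x in tree.neighbors(u) if x != v]
        v_side = [x for x in tree.neighbors(v) if x != u]
        for swap_v in v_side:
            neighbour = tree.copy()
            neighbour.remove_edge(u, u_side[1])
            neighbour.remove_edge(v, swap_v)
            neighbour.add_edge(v, u_side[1])
            neighbour.add_edge(u, swap_v)
            yield neighbour


def _stepwise_addition(
    patterns, weights, n_leaves: int, order: list[int]
) -> nx.Graph:
    """Greedy stepwise leaf addition: each leaf goes on the edge that
    minimizes the Fitch score (ties: first edge in iteration order)."""
    tree = nx.Graph()
    center = n_leaves
    tree.add_edges_from([(order[0], center), (order[1], center), (order[2], center)])
    next_internal = n_leaves + 1
    for leaf in order[3:]:
        best_tree, best_score = None, None
        for u, v in sorted(tree.edges):
            trial = tree.copy()
            trial.remove_edge(u, v)
            trial.add_edges_from(
                [(u, next_internal), (v, next_internal), (leaf, next_internal)]
            )
            score = _fitch_score(trial, patterns, weights, n_leaves)
            if best_score is None or score < best_score:
                best_tree, best_score = trial, score
        tree = best_tree
        next_internal += 1
    return tree


def parsimony_tree(
    sequences: list[str],
    labels: list[str] | None = None,
    method: str = "auto",
    max_exhaustive: int = 8,
    seed: int = 0,
) -> ClonalTree:
    """Minimum-parsimony unrooted tree for one cluster's sequences.

    For ``len(sequences) <= max_exhaustive`` (default 8) every unrooted
    topology is scored with the Fitch algorithm and a minimum retained; for
    larger clusters a stepwise-addition start is refined by steepest-descent
    nearest-neighbour interchange (the result scores no worse than a star
    tree). Branch lengths are integer substitution counts from a Fitch
    ancestral-state refinement and sum to the parsimony score. Deterministic
    given ``seed``.

    ``method``: "auto", "exhaustive" or "heuristic".
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need >=2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    if labels is None:
        labels = [f"seq{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels/sequences length mismatch")

    patterns, weights = _site_patterns(sequences)
    if method == "auto":
        method = "exhaustive" if n <= max_exhaustive else "heuristic"

    if n == 2:
        best = nx.Graph()
        best.add_edge(0, 1)
    elif method == "exhaustive":
        best, best_score = None, None
        for topology in _enumerate_topologies(n):
            score = _fitch_score(topology, patterns, weights, n)
            if best_score is None or score < best_score:
                best, best_score = topology, score
    elif method == "heuristic":
        rng = np.random.default_rng(seed)
        addition_order = list(rng.permutation(n))
        best = _stepwise_addition(patterns, weights, n, addition_order)
        best_score = _fitch_score(best, patterns, weights, n)
        improved = True
        while improved:
            improved = False
            for neighbour in _nni_neighbours(best, n):
                score = _fitch_score(neighbour, patterns, weights, n)
                if score < best_score:
                    best, best_score = neighbour, score
                    improved = True
                    break
    else:
        raise ValueError(f"unknown method {method!r}")

    score = _fitch_branch_lengths(best, sequences)
    for i in range(n):
        best.nodes[i]["label"] = labels[i]
        best.nodes[i]["sequence"] = sequences[i]
    return ClonalTree(tree=best, score=score)


# ---------------------------------------------------------------------------
# persistence (vertex/edge tables as TSV)


def write_graph_tables(graph: RepertoireGraph, out_dir) -> None:
    """Write vertices.tsv (sequence, size, cluster_id) and edges.tsv."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    cluster_id = graph.cluster_of()
    vertices = pd.DataFrame(
        [
            {"sequence": seq, "size": size, "cluster_id": cluster_id[seq]}
            for seq, size in sorted(graph.vertices.items())
        ]
    )
    vertices.to_csv(out / "vertices.tsv", sep="\t", index=False)
    edges = pd.DataFrame(sorted(graph.edges), columns=["source", "target"])
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)


def read_graph_tables(graph_dir) -> RepertoireGraph:
    """Rebuild a RepertoireGraph from write_graph_tables output."""
    import pandas as pd
    from pathlib import Path

    path = Path(graph_dir)
    vtable = pd.read_csv(path / "vertices.tsv", sep="\t")
    etable = pd.read_csv(path / "edges.tsv", sep="\t")
    vertices = dict(zip(vtable["sequence"], vtable["size"].astype(int)))
    edges = {
        (u, v) if u < v else (v, u)
        for u, v in zip(etable["source"], etable["target"])
    }
    return RepertoireGraph(
        vertices=vertices, edges=edges, clusters=find_clusters(vertices, edges)
    )


def star_tree_score(sequences: list[str]) -> int:
    """Parsimony score of the star topology (all leaves joined to one
    centre with majority-state assignment); an upper bound any sensible
    tree search must beat or match."""
    total = 0
    for column in zip(*sequences):
        counts = Counter(column)
        total += len(column) - max(counts.values())
    return total
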
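"""Repertoire graphs: edges, clusters, clonality, CC subsampling, trees."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lymphoscreen as ls
from lymphoscreen.network import ambiguous_vertices


def brute_force_edges(sequences):
    edges = set()
    for u, v in itertools.combinations(sorted(sequences), 2):
        if "N" in u or "N" in v:
            continue
        if len(u) == len(v) and sum(a != b for a, b in zip(u, v)) == 1:
            edges.add((u, v))
    return edges


# ---------------------------------------------------------------------------
# construction


def test_collapse_counts_multiplicities():
    assert ls.collapse_reads(["ACGT", "ACGT", "ACGG"]) == {"ACGT": 2, "ACGG": 1}


def test_collapse_distinct_and_order_invariant():
    reads = ["AAAA", "CCCC", "GGGG"]
    assert all(v == 1 for v in ls.collapse_reads(reads).values())
    assert ls.collapse_reads(reads) == ls.collapse_reads(reads[::-1])


def test_collapse_empty_errors():
    with pytest.raises(ValueError):
        ls.collapse_reads([])


def test_edges_basic_cases():
    assert ls.build_edges({"ACGT": 1, "ACGG": 1}) == {("ACGG", "ACGT")}
    assert ls.build_edges({"AAAA": 1, "TTTT": 1}) == set()
    # non-indel rule: a length mismatch is never an edge
    assert ls.build_edges({"ACGT": 1, "ACG": 1}) == set()


def test_edges_skip_ambiguous_sequences():
    vertices = {"ACGT": 1, "ACGN": 1}
    assert ls.build_edges(vertices) == set()
    assert ambiguous_vertices(vertices) == ["ACGN"]


@given(st.data())
@settings(max_examples=30, derandomize=True, deadline=None)
def test_edges_match_brute_force_oracle(data):
    n = data.draw(st.integers(min_value=2, max_value=60))
    seed = data.draw(st.integers(min_value=0, max_value=2**16))
    rng = np.random.default_rng(seed)
    # short alphabet + short strings force plenty of Hamming-1 collisions
    seqs = {
        "".join(rng.choice(list("ACGT"), int(rng.choice([5, 6]))))
        for _ in range(n)
    }
    assert ls.build_edges(dict.fromkeys(seqs, 1)) == brute_force_edges(seqs)


def test_find_clusters_ordering_and_sizes():
    vertices = {"ACGT": 1, "ACGG": 1, "TTTT": 1}
    edges = ls.build_edges(vertices)
    clusters = ls.find_clusters(vertices, edges)
    assert [len(c) for c in clusters] == [2, 1]
    assert clusters[0] == ["ACGG", "ACGT"]


def test_path_graph_is_one_cluster():
    vertices = {"AAAA": 1, "AAAT": 1, "AATT": 1}
    clusters = ls.find_clusters(vertices, ls.build_edges(vertices))
    assert len(clusters) == 1 and len(clusters[0]) == 3


# ---------------------------------------------------------------------------
# clonality


def test_clonality_all_distinct():
    reads = ["AAAA", "CCCC", "GGGG", "TGCA"]
    report = ls.clonality(reads)
    assert report.pct_unique == 100.0


def test_clonality_single_expanded_clone():
    reads = ["ACGT"] * 10
    report = ls.clonality(reads)
    assert report.pct_unique == pytest.approx(10.0)
    assert report.max_cluster_size == 1


def test_duplicate_read_never_increases_pct_unique():
    reads = ["AAAA", "CCCC", "GGGG"]
    before = ls.clonality(reads).pct_unique
    after = ls.clonality(reads + ["AAAA"]).pct_unique
    assert after <= before


def test_heavier_clone_tail_lowers_pct_unique():
    """Power-law exponent 1.5 (heavy tail, strong expansion) must yield a
    lower percentage of unique sequences than exponent 3.0."""
    pcts = {}
    for exponent in (1.5, 3.0):
        config = ls.RepertoireSimConfig(
            n_clones=60, clone_size_distribution=exponent, shm_rate=0.001,
            seed=21,
        )
        reads, _, _ = ls.simulate_repertoire(config)
        pcts[exponent] = ls.clonality([s for _, s in reads]).pct_unique
    assert pcts[1.5] < pcts[3.0]


# ---------------------------------------------------------------------------
# CC subsampling


@pytest.fixture(scope="module")
def expanded_graph():
    config = ls.RepertoireSimConfig(
        n_clones=30, clone_size_distribution=1.8, shm_rate=0.004, seed=11
    )
    reads, _, _ = ls.simulate_repertoire(config)
    return ls.build_graph([s for _, s in reads])


def test_subsample_full_size_is_identity(expanded_graph):
    sample = ls.cc_subsample(expanded_graph, expanded_graph.n_vertices, seed=1)
    assert sample.vertices == expanded_graph.vertices
    assert sample.edges == expanded_graph.edges


def test_subsample_singletons_all_represented():
    vertices = {s: 1 for s in ["AAAA", "CCCC", "GGGG", "TTTT"]}
    graph = ls.RepertoireGraph(
        vertices=vertices, edges=set(),
        clusters=ls.find_clusters(vertices, set()),
    )
    sample = ls.cc_subsample(graph, 4, seed=0)
    assert set(sample.vertices) == set(vertices)


def test_subsample_invariants_many_seeds(expanded_graph):
    graph = expanded_graph
    n_clusters = len(graph.clusters)
    n_target = max(n_clusters, graph.n_vertices // 2)
    for seed in range(50):
        sample = ls.cc_subsample(graph, n_target, repeats=3, seed=seed)
        assert set(sample.vertices) <= set(graph.vertices)
        assert sample.edges <= graph.edges
        assert sample.max_cluster_size <= graph.max_cluster_size
        # cluster-enforced: every original cluster survives as exactly one
        # connected component whenever the budget allows it
        assert len(sample.clusters) == n_clusters


def test_subsample_below_cluster_count_prioritizes_largest(expanded_graph):
    graph = expanded_graph
    n_target = len(graph.clusters) - 5
    sample = ls.cc_subsample(graph, n_target, seed=3)
    assert sample.n_vertices == n_target
    # the retained vertices must come from the n_target largest clusters
    allowed = {v for c in graph.clusters[:n_target] for v in c}
    assert set(sample.vertices) <= allowed


def test_subsample_deterministic(expanded_graph):
    a = ls.cc_subsample(expanded_graph, 40, seed=9)
    b = ls.cc_subsample(expanded_graph, 40, seed=9)
    assert a.vertices == b.vertices and a.edges == b.edges


def test_subsample_rejects_bad_target(expanded_graph):
    with pytest.raises(ValueError):
        ls.cc_subsample(expanded_graph, 0)
    with pytest.raises(ValueError):
        ls.cc_subsample(expanded_graph, expanded_graph.n_vertices + 1)


# ---------------------------------------------------------------------------
# parsimony trees


def test_two_sequences_single_branch():
    tree = ls.parsimony_tree(["ACGTACGT", "ACGAACGA"])
    assert tree.score == 2
    (u, v, data), = tree.tree.edges(data=True)
    assert data["length"] == 2


def test_three_taxa_chain_score():
    tree = ls.parsimony_tree(["AAAA", "AAAT", "AATT"])
    assert tree.score == 2
    lengths = sorted(d["length"] for _, _, d in tree.tree.edges(data=True))
    assert sum(lengths) == 2


def test_branch_lengths_sum_to_score():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
    tree = ls.parsimony_tree(seqs, method="exhaustive")
    assert sum(d["length"] for _, _, d in tree.tree.edges(data=True)) == tree.score


def test_heuristic_matches_exhaustive_small():
    rng = np.random.default_rng(7)
    for _ in range(15):
        root = "".join(rng.choice(list("ACGT"), 40))
        seqs = set()
        for _ in range(int(rng.integers(3, 7))):
            s = list(root)
            for _ in range(int(rng.integers(1, 4))):
                p = int(rng.integers(40))
                s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
            seqs.add("".join(s))
        seqs = sorted(seqs)
        if len(seqs) < 3:
            continue
        ex = ls.parsimony_tree(seqs, method="exhaustive")
        he = ls.parsimony_tree(seqs, method="heuristic")
        assert he.score == ex.score
        assert he.score <= ls.star_tree_score(seqs)


def test_score_invariant_to_leaf_and_column_permutation():
    rng = np.random.default_rng(9)
    seqs = ["AACGT", "AACGA", "TACGA", "TACTA"]
    base = ls.parsimony_tree(seqs).score
    perm = rng.permutation(len(seqs))
    assert ls.parsimony_tree([seqs[i] for i in perm]).score == base
    cols = rng.permutation(5)
    shuffled = ["".join(s[c] for c in cols) for s in seqs]
    assert ls.parsimony_tree(shuffled).score == base


def test_segregating_sites_lower_bound():
    seqs = ["AAAA", "AATT", "TTAA", "TTTT"]
    n_segregating = sum(len(set(col)) > 1 for col in zip(*seqs))
    assert ls.parsimony_tree(seqs).score >= n_segregating


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        ls.parsimony_tree(["ACGT", "ACG"])
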
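"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: codon arithmetic goes
through Bio.Seq translation, tree topologies are enumerated exhaustively,
and entropies are computed directly from column counts.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------- NG86 oracle

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous sites by exhaustive single-mutation trials;
    changes producing stops count as non-synonymous."""
    if codon in _STOPS:
        return 0.0, 0.0
    syn = non = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant not in _STOPS and _aa(mutant) == _aa(codon):
            syn += 1
        else:
            non += 1
    return syn / 3.0, non / 3.0


def _paths(codon_a: str, codon_b: str):
    """All mutation orderings as lists of (from_codon, to_codon) steps."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in itertools.permutations(diff):
        steps, current = [], codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            current = nxt
        yield steps


def oracle_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged differences; pathways with stop intermediates dropped
    (all kept, stop steps non-synonymous, if none survive)."""
    all_paths = list(_paths(codon_a, codon_b))
    if not all_paths:
        return 0.0, 0.0
    clean = [
        p
        for p in all_paths
        if not any(c2 in _STOPS and c2 != codon_b for _, c2 in p)
    ]
    used = clean or all_paths
    syn = non = 0.0
    for steps in used:
        for c1, c2 in steps:
            if c1 not in _STOPS and c2 not in _STOPS and _aa(c1) == _aa(c2):
                syn += 1
            else:
                non += 1
    return syn / len(used), non / len(used)


def oracle_ng86(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(dN, dS) for a codon-aligned pair, from the oracle primitives."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        for c in (ca, cb):
            s, n = oracle_codon_sites(c)
            S += s / 2
            N += n / 2
        sd, nd = oracle_codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    def jc(p):
        return 0.0 if p == 0 else (math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3))
    return jc(Nd / N), jc(Sd / S)


# ------------------------------------------------- exhaustive tree topologies


def enumerate_unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies as edge lists (1, 3, 15, 105... trees)."""
    first = [("int0", taxa[0]), ("int0", taxa[1]), ("int0", taxa[2])]
    trees = [first]
    for k, taxon in enumerate(taxa[3:], start=1):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = f"int{k}"
                new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, taxon)]
                new_trees.append(new_edges)
        trees = new_trees
    return trees


def topology_bipartitions(edges, taxa: list[str]) -> frozenset[frozenset[str]]:
    """Canonical non-trivial bipartitions (side not containing taxa[0])."""
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    taxa_set = set(taxa)
    out = set()
    for u, v in edges:
        side = _component(adj, v, {u})
        leaves = frozenset(side & taxa_set)
        if 1 < len(leaves) < len(taxa) - 1:
            if taxa[0] in leaves:
                leaves = frozenset(taxa_set - leaves)
            out.add(leaves)
    return frozenset(out)


def _component(adj, start, blocked):
    seen, stack = set(), [start]
    while stack:
        node = stack.pop()
        if node in seen or node in blocked:
            continue
        seen.add(node)
        stack.extend(adj.get(node, ()))
    return seen


def ols_tree_length(edges, taxa: list[str], d: np.ndarray) -> float:
    """Total tree length of the OLS branch-length fit for one topology."""
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def path_edges(a, b):
        prev = {a: None}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nb in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        path, node = [], b
        while prev[node] is not None:
            path.append(frozenset((node, prev[node])))
            node = prev[node]
        return set(path)

    edge_keys = [frozenset(e) for e in edges]
    rows, y = [], []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        on_path = path_edges(taxa[i], taxa[j])
        rows.append([1.0 if k in on_path else 0.0 for k in edge_keys])
        y.append(d[i, j])
    b, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    return float(b.sum())


def minimum_evolution_topology(taxa: list[str], d: np.ndarray) -> frozenset:
    """Bipartitions of the exhaustive minimum-evolution (OLS) topology."""
    best, best_len = None, math.inf
    for edges in enumerate_unrooted_topologies(taxa):
        length = ols_tree_length(edges, taxa, d)
        if length < best_len - 1e-12:
            best, best_len = edges, length
    return topology_bipartitions(best, taxa)


def random_additive_matrix(taxa: list[str], rng: np.random.Generator):
    """Random binary topology with positive lengths and its exact leaf
    distance matrix.  Returns (bipartitions, matrix)."""
    topologies = None
    # random stepwise construction (not enumeration) for independence from size
    edges = [("int0", taxa[0]), ("int0", taxa[1]), ("int0", taxa[2])]
    for k, taxon in enumerate(taxa[3:], start=1):
        i = int(rng.integers(len(edges)))
        u, v = edges.pop(i)
        w = f"int{k}"
        edges += [(u, w), (w, v), (w, taxon)]
    lengths = {frozenset(e): float(rng.uniform(0.1, 1.0)) for e in edges}
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        # BFS path length
        prev = {taxa[i]: None}
        stack = [taxa[i]]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        total, node = 0.0, taxa[j]
        while prev[node] is not None:
            total += lengths[frozenset((node, prev[node]))]
            node = prev[node]
        d[i, j] = d[j, i] = total
    return topology_bipartitions(edges, taxa), d


def newick_bipartitions(newick: str, taxa: list[str]) -> frozenset[frozenset[str]]:
    """Canonical bipartitions of a Newick tree (rooted or unrooted)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick if newick.endswith(";") else newick + ";",
                             schema="newick")
    taxa_set = set(taxa)
    out = set()
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(leaves) < len(taxa) - 1:
            if taxa[0] in leaves:
                leaves = frozenset(taxa_set - leaves)
            out.add(leaves)
    return frozenset(out)


# ------------------------------------------------------------- misc oracles


def column_entropy_bits(column: str) -> float:
    """log2(20) minus Shannon entropy of the residue counts (gaps and
    ambiguity codes dropped), computed directly."""
    counts = Counter(ch for ch in column if ch in "ACDEFGHIKLMNPQRSTVWY")
    n = sum(counts.values())
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return math.log2(20) - h
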
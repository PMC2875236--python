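"""Independent brute-force oracles used only by the test suite.

These re-derive the counting statistics directly from Biopython's codon
table with naive enumeration, sharing no code with the package's
implementation.
"""

from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TAB = unambiguous_dna_by_id[1]
CODE = dict(_TAB.forward_table)
STOPS = set(_TAB.stop_codons)
SENSE = sorted(CODE)
BASES = "ACGT"


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            tot += 1
            syn += CODE[alt] == CODE[codon]
        s += syn / tot if tot else 0.0
    return s, 3.0 - s


def oracle_differences(a, b):
    diff = [k for k in range(3) if a[k] != b[k]]
    if not diff:
        return 0.0, 0.0
    ok, fallback = [], []
    for order in permutations(diff):
        cur, syn, non, hit_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                hit_stop = True
                non += 1
            elif cur not in STOPS and CODE[nxt] == CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        (fallback if hit_stop else ok).append((syn, non))
    paths = ok or fallback
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_pair_counts(codons_a, codons_b):
    """Totals (n, S, N, Sd, Nd) over codon pairs, skipping non-sense codons."""
    n = S = N = Sd = Nd = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca not in CODE or cb not in CODE:
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        sd, nd = oracle_differences(ca, cb)
        n += 1
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
    return n, S, N, Sd, Nd


def random_sense_codons(rng, n):
    return [SENSE[i] for i in rng.integers(0, len(SENSE), size=n)]


def mutate_codons(rng, codons, p):
    """Point-mutate each base with probability p, avoiding stop codons."""
    out = []
    for c in codons:
        for _ in range(20):
            new = "".join(BASES[rng.integers(0, 4)] if rng.random() < p else ch
                          for ch in c)
            if new not in STOPS:
                break
        else:
            new = c
        out.append(new)
    return out


def random_additive_tree(rng, n_taxa):
    """A random binary tree; returns (ids, distance matrix, set of splits)."""
    ids = [f"t{k}" for k in range(n_taxa)]
    # start from a star over three leaves, attach remaining leaves to random edges
    # represent tree as adjacency with edge lengths on a node graph
    import networkx as nx

    g = nx.Graph()
    g.add_node("root")
    for k in range(3):
        g.add_edge("root", ids[k], length=float(rng.uniform(0.05, 1.0)))
    next_internal = 0
    for k in range(3, n_taxa):
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        L = g[u][v]["length"]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        a = float(rng.uniform(0.2, 0.8)) * L
        g.add_edge(u, mid, length=a)
        g.add_edge(mid, v, length=L - a)
        g.add_edge(mid, ids[k], length=float(rng.uniform(0.05, 1.0)))
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            path = nx.shortest_path(g, ids[i], ids[j])
            d = sum(g[a][b]["length"] for a, b in zip(path, path[1:]))
            D[i, j] = D[j, i] = d
    ref = min(ids)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nx2

        comp = nx2.node_connected_component(h, u)
        side = frozenset(x for x in comp if x in ids)
        if ref in side:
            side = frozenset(ids) - side
        if 1 < len(side) < n_taxa - 1:
            splits.add(side)
    return ids, D, splits
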
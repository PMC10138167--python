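"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or naive
iteration, deliberately sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def brute_force_global_score(a: str, b: str, gap_open: float = 10.0,
                             gap_extend: float = 0.5) -> float:
    """Maximum global alignment score by enumerating every alignment.

    An alignment is a monotone path of match/insert/delete operations; a
    maximal gap run of length k costs gap_open + gap_extend * (k - 1).
    Exponential: only for sequences of length <= 8.
    """
    def sub(x: str, y: str) -> float:
        return float(_BLOSUM[x, y])

    best = -math.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last == "D" else gap_open
            rec(i + 1, j, score - cost, "D")
        if j < len(b):  # gap in a
            cost = gap_extend if last == "I" else gap_open
            rec(i, j + 1, score - cost, "I")

    rec(0, 0, 0.0, "M")
    return best


def ng86_oracle(cds_a: str, cds_b: str) -> dict:
    """Nei-Gojobori quantities by direct enumeration.

    Site fractions: each of a codon's nine single-base neighbours counts
    1/3 of a site, synonymous only when it is not a stop and codes the
    same amino acid. Differences: average over all orderings of the
    changed positions, skipping orderings that pass through a stop (all
    orderings kept if every one hits a stop). Jukes-Cantor applied to
    both proportions.
    """
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]

    def syn_sites(codon: str) -> float:
        aa = GENETIC_CODE[codon]
        count = 0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1:]
                if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == aa:
                    count += 1
        return count / 3.0

    s_sites = (sum(map(syn_sites, codons_a)) + sum(map(syn_sites, codons_b))) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites

    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if not positions:
            continue
        results = []
        fallback = []
        for order in permutations(positions):
            cur = ca
            syn = non = 0
            hit_stop = False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if GENETIC_CODE[nxt] == "*":
                    hit_stop = True
                if GENETIC_CODE[nxt] != "*" and GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            (fallback if hit_stop else results).append((syn, non))
        chosen = results or fallback
        sd += sum(r[0] for r in chosen) / len(chosen)
        nd += sum(r[1] for r in chosen) / len(chosen)

    def jc(p: float) -> float:
        return -0.75 * math.log(1 - 4 * p / 3)

    ps, pn = sd / s_sites, nd / n_sites
    return {"s_sites": s_sites, "n_sites": n_sites, "sd": sd, "nd": nd,
            "ks": jc(ps), "ka": jc(pn)}


def naive_average_linkage(dist: np.ndarray) -> list:
    """O(n^3) average-linkage agglomeration; merge heights in order.

    Mirrors scipy's UPGMA recurrence: cluster distance = unweighted mean
    of all cross-pair original distances.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


def random_additive_tree(n_taxa: int, rng) -> tuple:
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf distance matrix. Returns (labels, matrix)."""
    # Start from 3-star, then attach remaining taxa to random edges.
    # Distances maintained directly: attaching taxon t to edge (u, v) at a
    # new internal point is equivalent to joining via a random existing
    # leaf-path; simpler: build tree structure explicitly.
    center = "c0"
    lengths = {}
    labels = [f"t{i}" for i in range(n_taxa)]
    adjacency = {center: []}
    for i in range(3):
        adjacency[labels[i]] = [center]
        adjacency[center].append(labels[i])
        lengths[frozenset((center, labels[i]))] = rng.uniform(0.5, 2.0)
    internal = 1
    for i in range(3, n_taxa):
        # pick a random edge, split it with a new internal node
        edge = list(lengths)[rng.integers(len(lengths))]
        u, v = tuple(edge)
        w = lengths.pop(edge)
        new = f"c{internal}"
        internal += 1
        adjacency[u].remove(v)
        adjacency[v].remove(u)
        adjacency[new] = [u, v, labels[i]]
        adjacency[u].append(new)
        adjacency[v].append(new)
        adjacency[labels[i]] = [new]
        f1 = rng.uniform(0.2, 0.8)
        lengths[frozenset((u, new))] = w * f1
        lengths[frozenset((v, new))] = w * (1 - f1)
        lengths[frozenset((labels[i], new))] = rng.uniform(0.5, 2.0)
    # BFS distances between all leaves
    import collections
    m = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        q = collections.deque([src])
        while q:
            x = q.popleft()
            for y in adjacency[x]:
                if y not in dist:
                    dist[y] = dist[x] + lengths[frozenset((x, y))]
                    q.append(y)
        for j, dst in enumerate(labels):
            m[i, j] = dist[dst]
    m = np.triu(m)  # exact symmetry despite float path-sum ordering
    m = m + m.T
    return labels, m
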
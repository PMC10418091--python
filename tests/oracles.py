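"""Independent reference implementations used only as test oracles."""

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = -1e9


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Quadratic-time Gotoh DP for the optimal local affine-gap score.

    First gapped residue costs open+extend (the NCBI 11/1 convention),
    matching what the production aligner is configured to do — but
    computed with an explicit three-matrix recurrence.
    """
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(
                0.0,
                M[i - 1, j - 1] + s,
                Ix[i - 1, j - 1] + s,
                Iy[i - 1, j - 1] + s,
            )
            Ix[i, j] = max(M[i - 1, j] - first, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - first, Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def bfs_components(nodes, edges):
    """Hand-rolled connected components (adjacency BFS), independent of networkx."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        comp, queue = set(), [n]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
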
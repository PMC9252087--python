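"""Independent brute-force oracles used to check the alignment engine.

These are deliberately naive O(nm) dynamic programs written from the
affine-gap (Gotoh) recurrences, sharing no code with the package's
alignment path.  Gap cost convention: a gap of length k costs
open + (k-1) * extend, applied to terminal gaps as well.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
OPEN = -11.0
EXTEND = -1.0
NEG = -1e9


def _sub(a: str, b: str) -> float:
    return float(_B62[a, b])


def global_score(a: str, b: str) -> float:
    """Optimal end-to-end affine-gap alignment score."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Iy[0, j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + OPEN, Ix[i - 1, j] + EXTEND,
                           Iy[i - 1, j] + OPEN)
            Iy[i, j] = max(M[i, j - 1] + OPEN, Iy[i, j - 1] + EXTEND,
                           Ix[i, j - 1] + OPEN)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def local_score(a: str, b: str) -> float:
    """Optimal Smith-Waterman affine-gap local alignment score."""
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = max(0.0,
                          M[i - 1, j - 1] + s,
                          Ix[i - 1, j - 1] + s,
                          Iy[i - 1, j - 1] + s)
            Ix[i, j] = max(M[i - 1, j] + OPEN, Ix[i - 1, j] + EXTEND)
            Iy[i, j] = max(M[i, j - 1] + OPEN, Iy[i, j - 1] + EXTEND)
            best = max(best, M[i, j])
    return best


def all_pairs_identity(seqs: dict[str, str], identity_fn) -> dict[tuple[str, str], float]:
    """Exhaustive identity matrix using the provided identity function."""
    ids = sorted(seqs)
    out = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            out[(x, y)] = out[(y, x)] = identity_fn(seqs[x], seqs[y])
    return out


def connected_components_at(seqs: dict[str, str], pairs, threshold: float) -> list[set[str]]:
    """Single-linkage components of the >= threshold identity graph."""
    parent = {i: i for i in seqs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (x, y), ident in pairs.items():
        if ident >= threshold:
            parent[find(x)] = find(y)
    groups: dict[str, set[str]] = {}
    for i in seqs:
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
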
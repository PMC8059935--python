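"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: BFS on the explicit
adjacency graph, the literal step-up definition of Benjamini-Hochberg, and
exhaustive prefix scans.
"""

from collections import deque

import numpy as np

AXIAL_DIRECTIONS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


def bfs_distances(array, start):
    """Shortest-path distances from ``start`` on a bounded hex array."""
    dist = {(start.q, start.r): 0}
    queue = deque([(start.q, start.r)])
    while queue:
        q, r = queue.popleft()
        for dq, dr in AXIAL_DIRECTIONS:
            nxt = (q + dq, r + dr)
            if array.at_axial(*nxt) is not None and nxt not in dist:
                dist[nxt] = dist[(q, r)] + 1
                queue.append(nxt)
    return dist


def bh_stepup(p):
    """Literal BH: q_(i) = min_{j >= i} min(1, m p_(j) / j) on sorted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def longest_dominating_prefix(basis, sorted_genes, m):
    """Scan all prefixes of module m's ranking; return the longest one whose
    every gene loads strictly highest on m."""
    best = []
    for end in range(1, len(sorted_genes) + 1):
        prefix = sorted_genes[:end]
        ok = all(
            basis.loc[g].iloc[m] > np.delete(basis.loc[g].to_numpy(), m).max()
            for g in prefix)
        if ok:
            best = prefix
        else:
            break
    return best


def best_overlap_match(tops_a, tops_b, top_n):
    """Exhaustive module matching: for each A module the argmax-overlap B
    module (smallest index on ties)."""
    out = []
    for ma, ta in enumerate(tops_a):
        counts = [len(set(ta) & set(tb)) for tb in tops_b]
        best = int(np.argmax(counts))
        out.append((ma, best, counts[best]))
    return out
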
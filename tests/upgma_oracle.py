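"""Brute-force O(n^3) textbook UPGMA, independent of scipy's linkage."""

import numpy as np


def upgma_heights(dist: np.ndarray) -> list[float]:
    """Merge heights, in merge order, of average-linkage clustering.

    ``dist`` is a symmetric leaf-by-leaf distance matrix. Ties break on the
    smaller node pair. The inter-cluster distance is the mean over all
    leaf pairs, maintained as a size-weighted average.
    """
    n = dist.shape[0]
    active = {i: 1 for i in range(n)}  # node id -> leaf count
    d = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    heights = []
    next_id = n
    while len(active) > 1:
        (a, b) = min(d, key=lambda k: (d[k], k))
        h = d[(a, b)]
        heights.append(h)
        size_a, size_b = active.pop(a), active.pop(b)
        new_d = {k: v for k, v in d.items() if a not in k and b not in k}
        for c in active:
            dac = d[(min(a, c), max(a, c))]
            dbc = d[(min(b, c), max(b, c))]
            new_d[(c, next_id)] = (size_a * dac + size_b * dbc) / (
                size_a + size_b
            )
        active[next_id] = size_a + size_b
        d = new_d
        next_id += 1
    return heights
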
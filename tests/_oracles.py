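"""Independent brute-force oracles for the constrained dendrogram cut.

Deliberately naive: exhaustive enumeration, no reuse of the code under
test beyond the linkage matrix it consumes.
"""

from __future__ import annotations

import numpy as np


def volunteers_distinct(members, volunteers) -> bool:
    vols = [volunteers[i] for i in members]
    return len(set(vols)) == len(vols)


def tree_partitions(tree: np.ndarray | None, n: int):
    """All tree-respecting partitions (antichains covering the leaves)."""
    if tree is None or n == 1:
        return [[(0,)]]
    leaves: list[list[int]] = [[i] for i in range(n)]
    for j in range(n - 1):
        leaves.append(leaves[int(tree[j, 0])] + leaves[int(tree[j, 1])])

    def parts(node):
        out = [[tuple(sorted(leaves[node]))]]
        if node >= n:
            j = node - n
            for pl in parts(int(tree[j, 0])):
                for pr in parts(int(tree[j, 1])):
                    out.append(pl + pr)
        return out

    return parts(2 * n - 2)


def coarsest_admissible_tree_partition(tree, volunteers):
    """Among constraint-satisfying tree partitions, the one with fewest
    clusters (unique: admissibility is inherited by descendants, so every
    admissible antichain refines the coarsest one)."""
    n = len(volunteers)
    admissible = [
        p
        for p in tree_partitions(tree, n)
        if all(volunteers_distinct(c, volunteers) for c in p)
    ]
    assert admissible, "singleton partition is always admissible"
    best = min(admissible, key=len)
    assert sum(len(p) == len(best) for p in admissible) == 1
    return {frozenset(c) for c in best}


def set_partitions(items):
    """All set partitions (Bell number growth; keep n <= 9)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1:]
        yield [[first]] + partial


def min_variance_partition(coords: np.ndarray, volunteers):
    """Constraint-satisfying set partition (not tree-restricted) with the
    fewest clusters, breaking ties by total within-cluster sum of squared
    deviations from cluster means.  Raw SSE alone would trivially favour
    all-singletons; maximising clicks per cluster is the primary objective
    and spatial tightness the secondary one."""
    n = len(volunteers)
    best, best_key = None, (np.inf, np.inf)
    for partition in set_partitions(range(n)):
        if not all(volunteers_distinct(c, volunteers) for c in partition):
            continue
        sse = 0.0
        for cluster in partition:
            pts = coords[list(cluster)]
            sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
        key = (len(partition), sse)
        if key < (best_key[0], best_key[1] - 1e-12):
            best_key, best = key, partition
    return {frozenset(c) for c in best}, best_key[1]


def labels_to_partition(labels):
    out: dict[int, set] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(i)
    return {frozenset(c) for c in out.values()}
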
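"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive enumeration and
breadth-first search, sharing no code with the package's algorithms.
"""

from __future__ import annotations

import itertools
from collections import deque


# ----------------------------------------------------------------------
# rooted binary topologies (independent recursive enumeration)
# ----------------------------------------------------------------------
def all_rooted_trees(leaves: list):
    """Every rooted binary tree over ``leaves`` as nested 2-tuples.

    Recursive bipartition: the root splits the leaf set into two
    non-empty halves; each half is enumerated recursively.  To avoid
    double counting, the half containing the first leaf is the left one.
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(0, len(rest)):
        for right in itertools.combinations(rest, len(rest) - k):
            right = list(right)
            left = [first] + [x for x in rest if x not in right]
            if not right:
                continue
            for lt in all_rooted_trees(left):
                for rt in all_rooted_trees(right):
                    yield (lt, rt)


def _tree_edges(shape, counter=None, parent=None, edges=None, labels=None):
    """Flatten a nested-tuple tree into (parent, child) edges and leaf map."""
    if edges is None:
        edges, labels, counter = [], {}, [0]
        root = f"i{counter[0]}"
        counter[0] += 1
        _tree_edges(shape, counter, root, edges, labels)
        return root, edges, labels
    if isinstance(shape, tuple):
        me = f"i{counter[0]}"
        counter[0] += 1
        edges.append((parent, me))
        for part in shape:
            _tree_edges(part, counter, me, edges, labels)
    else:
        me = f"L{shape}"
        edges.append((parent, me))
        labels[me] = shape
    return None


def dollo_char_losses(shape, present: set, absent: set) -> int:
    """Minimum losses for one binary character under Dollo parsimony.

    Enumerates every 0/1 assignment to internal nodes (and to missing
    leaves), keeps those with at most one 0->1 edge anywhere and state 1
    at every present leaf / 0 at every absent leaf, and returns the
    minimum number of 1->0 edges.  The root is the all-absent ancestor
    (state 0).
    """
    root, edges, leaf_of = _tree_edges(shape)
    internal = sorted({p for p, _ in edges} | {c for _, c in edges
                                              if c not in leaf_of})
    missing = [n for n, lab in leaf_of.items()
               if lab not in present and lab not in absent]
    free = internal + missing
    if not present:
        return 0
    best = None
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = dict(zip(free, bits))
        state[root] = state.get(root, 0)
        ok = True
        for n, lab in leaf_of.items():
            if lab in present:
                state[n] = 1
            elif lab in absent:
                state[n] = 0
        gains = losses = 0
        # implicit edge from the all-zero outgroup ancestor to the root
        if state[root] == 1:
            gains += 1
        for p, c in edges:
            if state[p] == 0 and state[c] == 1:
                gains += 1
            elif state[p] == 1 and state[c] == 0:
                losses += 1
        if gains <= 1 and ok:
            if best is None or losses < best:
                best = losses
    return best if best is not None else 0


def dollo_tree_score(shape, chars: list[tuple[set, set]]) -> int:
    """Total Dollo losses of one topology over a list of characters."""
    return sum(dollo_char_losses(shape, p, a) for p, a in chars)


def dollo_brute_force(labels: list, chars: list[tuple[set, set]]) -> int:
    """Minimum Dollo score over every rooted binary topology."""
    return min(dollo_tree_score(shape, chars)
               for shape in all_rooted_trees(labels))


import functools


@functools.lru_cache(maxsize=8)
def _topology_structures(n_leaves: int):
    """Edge arrays for every rooted topology on ``n_leaves`` labelled leaves.

    Returns a list of (parents, children, leaf_index, internal_index, root)
    where node ids are integers, suitable for vectorised state enumeration.
    """
    import numpy as np

    structures = []
    for shape in all_rooted_trees(list(range(n_leaves))):
        root, edges, leaf_of = _tree_edges(shape)
        names = sorted({p for p, _ in edges} | {c for _, c in edges} | {root})
        idx = {name: i for i, name in enumerate(names)}
        parents = np.array([idx[p] for p, _ in edges])
        children = np.array([idx[c] for _, c in edges])
        leaf_idx = {leaf_of[name]: idx[name] for name in leaf_of}
        internal = np.array([idx[n] for n in names if n not in leaf_of])
        structures.append((parents, children, leaf_idx, internal, idx[root],
                           len(names)))
    return structures


def dollo_brute_force_fast(n_leaves: int, char_matrix) -> int:
    """Vectorised assignment-enumeration oracle for full binary matrices.

    Same semantics as :func:`dollo_brute_force` (minimum total losses over
    all rooted topologies, each character allowed at most one gain with
    the outgroup fixed at 0), but enumerates the 0/1 internal-state
    assignments as a bit table and scores them with numpy.
    """
    import numpy as np

    char_matrix = np.asarray(char_matrix, dtype=int)  # (n_leaves, n_chars)
    n_chars = char_matrix.shape[1]
    best_total = None
    for parents, children, leaf_idx, internal, root, n_nodes in \
            _topology_structures(n_leaves):
        k = len(internal)
        bits = ((np.arange(2 ** k)[:, None] >> np.arange(k)) & 1)  # (2^k, k)
        states = np.zeros((2 ** k, n_nodes), dtype=int)
        states[:, internal] = bits
        total = 0
        for j in range(n_chars):
            for leaf, node in leaf_idx.items():
                states[:, node] = char_matrix[leaf, j]
            sp = states[:, parents]
            sc = states[:, children]
            gains = ((sp == 0) & (sc == 1)).sum(axis=1) + states[:, root]
            losses = ((sp == 1) & (sc == 0)).sum(axis=1)
            valid = gains <= 1
            total += int(losses[valid].min()) if valid.any() else 0
        if best_total is None or total < best_total:
            best_total = total
    return best_total


# ----------------------------------------------------------------------
# segmental event distance by breadth-first search
# ----------------------------------------------------------------------
def bfs_event_distance(a: tuple, b: tuple, cap: int | None = None) -> float:
    """Shortest segmental-event path from vector ``a`` to ``b``.

    Moves: +/-1 on any contiguous run; a run containing a zero cannot be
    changed (no gain from zero, no negative copies).  States are capped
    at ``cap`` to keep the search finite.
    """
    a, b = tuple(a), tuple(b)
    if cap is None:
        cap = max(max(a), max(b)) + 2
    if a == b:
        return 0.0
    n = len(a)
    seen = {a}
    queue = deque([(a, 0)])
    while queue:
        state, d = queue.popleft()
        for i in range(n):
            for j in range(i, n):
                for delta in (1, -1):
                    run = state[i:j + 1]
                    if any(v == 0 for v in run):
                        continue  # zeros block both gains and losses
                    new = (state[:i]
                           + tuple(v + delta for v in run)
                           + state[j + 1:])
                    if any(v < 0 or v > cap for v in new):
                        continue
                    if new == b:
                        return float(d + 1)
                    if new not in seen:
                        seen.add(new)
                        queue.append((new, d + 1))
    return float("inf")
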
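"""Minimum-event phylogenies from allele-specific integer copy numbers.

Copy-number evolution is modelled as segmental events: one event adds or
removes one copy of one allele over a contiguous run of loci, and an
allele lost to zero copies can never be regained.  The directed distance
between two profiles is the minimum number of such events; it decomposes,
per allele, into the run-length encoding of the positive and negative
parts of the difference vector, with zero-copy loci acting as barriers.

Trees are searched exhaustively over rooted topologies, scoring each by a
per-locus, per-allele dynamic programme (Sankoff-style, states 0..8,
``|parent - child|`` edge cost, 0-to-positive transitions forbidden) with
the root fixed at the outgroup profile — a pure diploid 1/1 per allele
for near-diploid patients.  For tetraploid patients the root is chosen
among the four post-duplication ancestral states 6/4, 4/2, 4/4 and 2/2
(total/major); ties between candidates are broken by the number of
events needed *before* the duplication, i.e. the event distance from
diploid 2/1 to the halved states 3/2, 2/1, 2/2 and 1/1 — costs 1, 0, 2
and 1 respectively.

Counting events per locus treats an aberration spanning several adjacent
segments as one event per segment; this is the documented approximation
relative to a full multi-locus transducer alignment.

Support values come from rebuilding neighbour-joining trees on the
pairwise dissimilarity matrix perturbed by Gaussian noise.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import Node, RootedTree, enumerate_rooted_topologies

__all__ = [
    "directed_event_distance",
    "profile_event_distance",
    "pairwise_dissimilarity",
    "dissimilarity_matrix",
    "CnaTreeResult",
    "build_cna_tree",
    "WgdRooting",
    "wgd_root",
    "resampling_support",
    "WGD_CANDIDATES",
    "PRE_WGD_COST",
]

OUTGROUP = "N"
MAX_STATE = 8
MAX_EXHAUSTIVE_LEAVES = 7

# tetraploid ancestral candidates as (major, minor), keyed "total/major"
WGD_CANDIDATES: dict[str, tuple[int, int]] = {
    "6/4": (4, 2),
    "4/2": (2, 2),
    "4/4": (4, 0),
    "2/2": (2, 0),
}
# events from diploid 1/1 (per allele) to the halved pre-WGD counterparts
# 3/2, 2/1, 2/2 and 1/1
PRE_WGD_COST: dict[str, int] = {"6/4": 1, "4/2": 0, "4/4": 2, "2/2": 1}


# ----------------------------------------------------------------------
# event distances
# ----------------------------------------------------------------------
def directed_event_distance(a, b) -> float:
    """Minimum segmental +/-1 events turning allele vector ``a`` into ``b``.

    Returns ``math.inf`` when infeasible (some locus must rise from zero).
    Gains and losses decompose independently; each part costs the sum of
    the increases of its difference profile along the vector.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("copy numbers must be non-negative")
    if np.any((a == 0) & (b > 0)):
        return math.inf
    d = b - a
    pos = np.maximum(d, 0)
    neg = np.maximum(-d, 0)
    cost = 0
    prev_p = prev_n = 0
    for dp, dn in zip(pos, neg):
        cost += max(dp - prev_p, 0) + max(dn - prev_n, 0)
        prev_p, prev_n = dp, dn
    return float(cost)


def profile_event_distance(p_major, p_minor, q_major, q_minor) -> float:
    """Directed distance between two profiles, summed over both alleles."""
    return (directed_event_distance(p_major, q_major)
            + directed_event_distance(p_minor, q_minor))


def _allele_local_cost(c_prev: int, c_cur: int, x_prev: int, x_cur: int,
                       first: bool) -> float:
    """Run-increment contribution of one locus to d(c -> x)."""
    if c_cur == 0 and x_cur > 0:
        return math.inf
    dp_prev = 0 if first else max(x_prev - c_prev, 0)
    dn_prev = 0 if first else max(c_prev - x_prev, 0)
    dp = max(x_cur - c_cur, 0)
    dn = max(c_cur - x_cur, 0)
    return max(dp - dp_prev, 0) + max(dn - dn_prev, 0)


def _min_common_ancestor_cost(x: np.ndarray, y: np.ndarray) -> float:
    """min over ancestor vectors c of d(c->x) + d(c->y), one allele.

    Exact chain dynamic programme: the directed distance is a sum of
    local terms in consecutive ancestor states, so the minimisation runs
    over the ancestor state (0..8) locus by locus.
    """
    L = len(x)
    states = range(MAX_STATE + 1)
    best = {s: (_allele_local_cost(0, s, 0, x[0], True)
                + _allele_local_cost(0, s, 0, y[0], True)) for s in states}
    for i in range(1, L):
        new = {}
        for s in states:
            new[s] = min(
                best[t]
                + _allele_local_cost(t, s, x[i - 1], x[i], False)
                + _allele_local_cost(t, s, y[i - 1], y[i], False)
                for t in states)
        best = new
    return min(best.values())


def pairwise_dissimilarity(p_major, p_minor, q_major, q_minor) -> float:
    """Symmetric dissimilarity between two profiles.

    Minimises, over a common ancestor profile, the events from the
    ancestor to each of the two profiles, summed over major and minor
    alleles; symmetric by construction.
    """
    p_major = np.asarray(p_major, int)
    p_minor = np.asarray(p_minor, int)
    q_major = np.asarray(q_major, int)
    q_minor = np.asarray(q_minor, int)
    return (_min_common_ancestor_cost(p_major, q_major)
            + _min_common_ancestor_cost(p_minor, q_minor))


def _profiles_to_vectors(profiles: pd.DataFrame
                         ) -> tuple[list[str], np.ndarray, np.ndarray, pd.DataFrame]:
    """Pivot a SEG-like table into per-sample major/minor vectors.

    All samples must share identical segment boundaries.
    """
    required = {"sample", "chrom", "start", "end", "total", "major", "minor"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")
    key = (profiles["chrom"].astype(str) + ":" + profiles["start"].astype(str)
           + "-" + profiles["end"].astype(str))
    prof = profiles.assign(_key=key)
    major = prof.pivot_table(index="sample", columns="_key", values="major",
                             aggfunc="first", sort=False)
    minor = prof.pivot_table(index="sample", columns="_key", values="minor",
                             aggfunc="first", sort=False)
    if major.isna().any().any() or minor.isna().any().any():
        raise ValueError("samples do not share identical segment boundaries")
    # order segments genomically
    seg_order = (prof[["_key", "chrom", "start"]].drop_duplicates("_key")
                 .sort_values(["chrom", "start"], key=lambda s: (
                     s.astype(int) if s.name != "chrom"
                     else s.astype(str).str.zfill(8))))
    cols = list(seg_order["_key"])
    major = major[cols]
    minor = minor[cols]
    segments = seg_order.rename(columns={"_key": "segment"}).reset_index(drop=True)
    samples = list(major.index)
    return samples, major.to_numpy(int), minor.to_numpy(int), segments


def dissimilarity_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise dissimilarity matrix over a patient's samples."""
    samples, major, minor, _ = _profiles_to_vectors(profiles)
    n = len(samples)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_dissimilarity(major[i], minor[i], major[j], minor[j])
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


# ----------------------------------------------------------------------
# tree building by per-locus dynamic programming
# ----------------------------------------------------------------------
def _edge_cost_matrix() -> np.ndarray:
    states = np.arange(MAX_STATE + 1)
    w = np.abs(states[:, None] - states[None, :]).astype(float)  # w[parent, child]
    w[0, 1:] = math.inf  # a lost allele cannot be regained
    return w


_EDGE_COST = _edge_cost_matrix()


def _shape_children(shape, n_leaves):
    """Flatten a nested-tuple shape into postorder (left, right) index lists.

    Leaves are 0..n_leaves-1; internal nodes get indices from n_leaves up.
    Returns (children array, root index, total nodes).
    """
    children = []
    counter = [n_leaves]

    def _rec(sub):
        if isinstance(sub, tuple):
            l = _rec(sub[0])
            r = _rec(sub[1])
            idx = counter[0]
            counter[0] += 1
            children.append((idx, l, r))
            return idx
        return sub

    root = _rec(shape)
    return children, root, counter[0]


def _score_topology(shape, leaf_states: np.ndarray, root_state: np.ndarray,
                    state_mask: np.ndarray | None = None):
    """Minimum total event count of a rooted shape, plus a state backtrace.

    ``leaf_states``: (n_leaves, L) integer matrix, each column one
    locus/allele; ``root_state``: (L,) fixed root profile.  Returns
    (score, assign) where ``assign`` maps node index -> (L,) states.
    """
    n_leaves, L = leaf_states.shape
    children, root, n_nodes = _shape_children(shape, n_leaves)
    S = MAX_STATE + 1
    INF = 1e18
    cost = np.empty((n_nodes, S, L))
    for i in range(n_leaves):
        cost[i] = INF
        cost[i, leaf_states[i], np.arange(L)] = 0.0
    w = np.where(np.isinf(_EDGE_COST), INF, _EDGE_COST)
    if state_mask is not None:
        state_penalty = np.where(state_mask, 0.0, INF)  # (S, L)
    for idx, l, r in children:
        # min over child state v of cost[child][v] + w[u, v], for each u
        lmin = (w[:, :, None] + cost[l][None, :, :]).min(axis=1)
        rmin = (w[:, :, None] + cost[r][None, :, :]).min(axis=1)
        cost[idx] = lmin + rmin
        if state_mask is not None:
            cost[idx] += state_penalty
    # trunk edge: the fixed outgroup-ancestor profile sits above the
    # cancer MRCA, whose state is free
    trunk_opts = w[root_state, :].T + cost[root][:, np.arange(L)]  # (S, L)
    total_per_locus = trunk_opts.min(axis=0)
    score = float(total_per_locus.sum())

    # backtrace an optimal assignment (ties -> state closest to parent)
    assign = np.empty((n_nodes, L), dtype=int)
    assign[:n_leaves] = leaf_states
    assign[root] = np.argmin(
        trunk_opts + 1e-9 * np.abs(np.arange(S)[:, None] - root_state[None, :]),
        axis=0)
    order = {idx: (l, r) for idx, l, r in children}

    def _descend(idx):
        if idx < n_leaves:
            return
        l, r = order[idx]
        u = assign[idx]
        for child in (l, r):
            opts = w[u, :].T + cost[child][:, np.arange(L)]  # (S, L)
            v = np.argmin(opts + 1e-9 * np.abs(np.arange(S)[:, None] - u[None, :]),
                          axis=0)
            assign[child] = v
            _descend(child)

    _descend(root)
    return score, assign, children, root


@dataclass
class CnaTreeResult:
    tree: RootedTree
    total_events: float
    root_profile: pd.DataFrame          # segment, major, minor at the root
    exhaustive: bool = True
    root_mode: str = "diploid"
    wgd: "WgdRooting | None" = None


def build_cna_tree(profiles: pd.DataFrame, root_mode: str = "diploid",
                   heuristic: bool = False,
                   max_exhaustive: int = MAX_EXHAUSTIVE_LEAVES
                   ) -> CnaTreeResult:
    """Minimum-event rooted phylogeny for one patient's masked profiles.

    ``root_mode='diploid'`` roots at an aberration-free 2/1 outgroup;
    ``root_mode='wgd'`` first builds the diploid-rooted intermediate tree
    for its topology, then re-roots at the best tetraploid ancestor (see
    :func:`wgd_root`).  Exhaustive topology search up to
    ``max_exhaustive`` leaves; beyond that a neighbour-joining topology
    is refitted by the same dynamic programme and flagged non-exhaustive.
    """
    samples, major, minor, segments = _profiles_to_vectors(profiles)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples passing QC")
    if root_mode not in ("diploid", "wgd"):
        raise ValueError("root_mode must be 'diploid' or 'wgd'")
    if root_mode == "wgd":
        inter = build_cna_tree(profiles, root_mode="diploid",
                               heuristic=heuristic,
                               max_exhaustive=max_exhaustive)
        rooting = wgd_root(profiles, inter.tree)
        result = rooting.tree_result
        result.wgd = rooting
        return result

    n = len(samples)
    L = major.shape[1]
    leaf_states = np.hstack([major, minor])          # (n, 2L)
    root_state = np.hstack([np.ones(L, int), np.ones(L, int)])

    best_shape, best_assign, best_children, best_root = None, None, None, None
    best = math.inf
    exhaustive = True
    if n > max_exhaustive:
        if not heuristic:
            raise ValueError(
                f"{n} leaves exceeds the exhaustive-search limit of "
                f"{max_exhaustive}; pass heuristic=True")
        shapes = [_nj_shape(dissimilarity_matrix(profiles), samples)]
        exhaustive = False
    else:
        shapes = enumerate_rooted_topologies(list(range(n)))
    for shape in shapes:
        score, assign, children, root = _score_topology(
            shape, leaf_states, root_state)
        if score < best:
            best = score
            best_shape, best_assign = shape, assign
            best_children, best_root = children, root

    tree = _finish_tree(best_shape, samples, best_assign, best_children,
                        best_root, n, root_state)
    root_profile = pd.DataFrame(dict(segment=segments["segment"],
                                     major=1, minor=1))
    return CnaTreeResult(tree=tree, total_events=best,
                         root_profile=root_profile, exhaustive=exhaustive,
                         root_mode="diploid")


def _finish_tree(shape, samples, assign, children, root, n_leaves,
                 root_state) -> RootedTree:
    kids = {idx: (l, r) for idx, l, r in children} if children else {}

    def _build(idx) -> Node:
        if idx < n_leaves:
            return Node(samples[idx])
        node = Node()
        for c in kids[idx]:
            child = _build(c)
            child.length = float(np.abs(assign[idx] - assign[c]).sum())
            node.add_child(child)
        return node

    rootnode = Node("root")
    out = Node(OUTGROUP)
    out.length = 0.0
    rootnode.add_child(out)
    cancer = _build(root) if isinstance(shape, tuple) else Node(samples[shape])
    cancer.length = float(np.abs(root_state - assign[root]).sum()) \
        if isinstance(shape, tuple) else float(np.abs(root_state
                                                      - assign[shape]).sum())
    rootnode.add_child(cancer)
    return RootedTree(rootnode)


def _nj_shape(dissim: pd.DataFrame, samples: list[str]):
    """Neighbour-joining topology as a nested-tuple shape over sample indices."""
    tree = _nj_tree(dissim)
    index = {s: i for i, s in enumerate(samples)}

    def _to_shape(node: Node):
        if node.is_leaf:
            return index[node.name]
        shapes = [_to_shape(c) for c in node.children]
        out = shapes[0]
        for s in shapes[1:]:
            out = (out, s)
        return out

    return _to_shape(tree.root)


def _nj_tree(dissim: pd.DataFrame) -> RootedTree:
    csv = io.StringIO()
    dissim.to_csv(csv)
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(csv, delimiter=",")
    nj = pdm.nj_tree()
    return RootedTree.from_newick(nj.as_string(schema="newick"))


# ----------------------------------------------------------------------
# WGD-aware rooting
# ----------------------------------------------------------------------
@dataclass
class WgdRooting:
    scores: dict[str, float]            # candidate -> intermediate-tree score
    pre_wgd_cost: dict[str, int]
    selected: str
    tie_broken: bool
    tree_result: CnaTreeResult | None = None
    excluded_loci: list[str] = field(default_factory=list)


def wgd_root(profiles: pd.DataFrame, intermediate_tree: RootedTree
             ) -> WgdRooting:
    """Choose the tetraploid ancestral state that roots a WGD patient.

    The intermediate tree supplies the topology only.  For each candidate
    ancestor (6/4, 4/2, 4/4, 2/2 as total/major) the per-locus dynamic
    programme re-scores the tree with the root fixed at that state,
    internal states restricted to the integer range spanned by the
    observed copy numbers (and the root), and 0-to-positive transitions
    forbidden.  The candidate with the minimum score wins; ties add the
    pre-duplication event cost (1, 0, 2, 1).  Loci infeasible under every
    candidate are excluded with a warning.
    """
    samples, major, minor, segments = _profiles_to_vectors(profiles)
    index = {s: i for i, s in enumerate(samples)}

    # extract the cancer-clade shape from the intermediate tree
    def _to_shape(node: Node):
        kids = [c for c in node.children if not (c.is_leaf and c.name == OUTGROUP)]
        if node.is_leaf:
            return index[node.name]
        if len(kids) == 1:
            return _to_shape(kids[0])
        out = _to_shape(kids[0])
        for k in kids[1:]:
            out = (out, _to_shape(k))
        return out

    shape = _to_shape(intermediate_tree.root)
    n = len(samples)
    L = major.shape[1]
    leaf_states = np.hstack([major, minor])
    S = MAX_STATE + 1

    per_locus: dict[str, np.ndarray] = {}
    assigns: dict[str, tuple] = {}
    for cand, (cmaj, cmin) in WGD_CANDIDATES.items():
        root_state = np.hstack([np.full(L, cmaj), np.full(L, cmin)])
        lo = np.minimum(leaf_states.min(axis=0), root_state)
        hi = np.maximum(leaf_states.max(axis=0), root_state)
        states = np.arange(S)[:, None]
        mask = (states >= lo[None, :]) & (states <= hi[None, :])  # (S, 2L)
        score, assign, children, root = _score_topology(
            shape, leaf_states, root_state, state_mask=mask)
        per_locus[cand] = _per_locus_cost(shape, leaf_states, root_state, mask)
        assigns[cand] = (assign, children, root, root_state)

    seg_names = list(segments["segment"]) * 2
    feasible_any = np.zeros(2 * L, dtype=bool)
    for cand in WGD_CANDIDATES:
        feasible_any |= per_locus[cand] < 1e17
    excluded = sorted({seg_names[i] for i in range(2 * L) if not feasible_any[i]})
    if excluded:
        warnings.warn(f"loci infeasible under every WGD candidate excluded: "
                      f"{excluded}", stacklevel=2)

    scores = {}
    for cand in WGD_CANDIDATES:
        vals = per_locus[cand][feasible_any]
        scores[cand] = float(vals.sum()) if np.all(vals < 1e17) else math.inf

    best = min(scores.values())
    tied = [c for c in WGD_CANDIDATES if scores[c] == best]
    tie_broken = len(tied) > 1
    selected = min(tied, key=lambda c: (scores[c] + PRE_WGD_COST[c],
                                        list(WGD_CANDIDATES).index(c)))

    assign, children, root, root_state = assigns[selected]
    tree = _finish_tree(shape, samples, assign, children, root, n, root_state)
    cmaj, cmin = WGD_CANDIDATES[selected]
    root_profile = pd.DataFrame(dict(segment=segments["segment"],
                                     major=cmaj, minor=cmin))
    result = CnaTreeResult(tree=tree, total_events=scores[selected],
                           root_profile=root_profile, exhaustive=True,
                           root_mode="wgd")
    return WgdRooting(scores=scores, pre_wgd_cost=dict(PRE_WGD_COST),
                      selected=selected, tie_broken=tie_broken,
                      tree_result=result, excluded_loci=excluded)


def _per_locus_cost(shape, leaf_states, root_state, mask) -> np.ndarray:
    n_leaves, L = leaf_states.shape
    children, root, n_nodes = _shape_children(shape, n_leaves)
    S = MAX_STATE + 1
    INF = 1e18
    cost = np.empty((n_nodes, S, L))
    for i in range(n_leaves):
        cost[i] = INF
        cost[i, leaf_states[i], np.arange(L)] = 0.0
    w = np.where(np.isinf(_EDGE_COST), INF, _EDGE_COST)
    penalty = np.where(mask, 0.0, INF)
    for idx, l, r in children:
        lmin = (w[:, :, None] + cost[l][None, :, :]).min(axis=1)
        rmin = (w[:, :, None] + cost[r][None, :, :]).min(axis=1)
        cost[idx] = np.minimum(lmin + rmin + penalty, INF)
    if not children:
        raise ValueError("WGD rooting needs at least two cancer samples")
    trunk_opts = w[root_state, :].T + cost[root][:, np.arange(L)]
    return trunk_opts.min(axis=0)


# ----------------------------------------------------------------------
# resampling support
# ----------------------------------------------------------------------
def resampling_support(dissim: pd.DataFrame, tree: RootedTree,
                       n_resamples: int = 100, noise_sd: float = 1.0,
                       seed: int = 0) -> dict[frozenset, float]:
    """Bipartition support by Gaussian perturbation of the distance matrix.

    Each resample adds i.i.d. Gaussian noise (s.d. ``noise_sd`` events) to
    the off-diagonal entries, re-symmetrises, floors at zero, rebuilds a
    neighbour-joining tree and records which of the original tree's
    non-trivial bipartitions it contains.  Support is the containment
    fraction over ``n_resamples`` resamples.
    """
    rng = np.random.default_rng(seed)
    labels = [s for s in dissim.index]
    base = dissim.to_numpy(float)
    cancer_leaves = [s for s in tree.leaf_names() if s != OUTGROUP]
    ref_splits = _restricted_splits(tree, set(labels) & set(cancer_leaves))
    counts = {split: 0 for split in ref_splits}
    for _ in range(n_resamples):
        noise = rng.normal(0.0, noise_sd, size=base.shape)
        noise = (noise + noise.T) / np.sqrt(2.0)
        np.fill_diagonal(noise, 0.0)
        mat = np.maximum(base + noise, 0.0)
        np.fill_diagonal(mat, 0.0)
        resampled = _nj_tree(pd.DataFrame(mat, index=labels, columns=labels))
        splits = _restricted_splits(resampled, set(labels))
        for split in counts:
            if split in splits:
                counts[split] += 1
    return {split: counts[split] / n_resamples for split in counts}


def _restricted_splits(tree: RootedTree, common: set[str]) -> set[frozenset]:
    if len(common) < 4:
        # fewer than 4 shared leaves -> no non-trivial unrooted splits
        return set()
    ref = min(common)
    out = set()
    for side in tree.bipartitions(trivial=True):
        side = frozenset(side & common)
        if ref in side:
            side = frozenset(common - side)
        if 1 < len(side) < len(common) - 1:
            out.add(side)
    return out
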
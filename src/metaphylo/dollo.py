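"""Dollo-parsimony phylogenies from binary SNV presence/absence calls.

A somatic point mutation arises once in a patient's tumour lineage but can
disappear again when a copy-number loss deletes the mutated allele.  Dollo
parsimony encodes exactly that: each character is gained on a single
branch, and the tree minimising the total number of subsequent losses
(*reversions*) is preferred.  The search is exhaustive — stepwise leaf
addition with branch-and-bound, pruned by the (admissible) partial-tree
score — and returns *all* co-optimal rooted topologies; ties are broken
against the patient's CNA tree.

Ancestral states are reconstructed under an accelerated-transformation
rule: the single gain is pushed as far rootward as it can go without
creating extra losses, and losses cover the maximal all-absent clades
below it.  Missing calls are uninformative: they never force a loss and
never anchor a gain.

Predicted reversions are then cross-examined against the allele-specific
copy-number profiles: a reversion is only *supported* when the affected
samples show an overlapping allele loss, and an absence call made with
low detection power is reported as a possible false negative rather than
a reversion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from .tiers import CharacterMatrix
from .trees import Node, RootedTree, rf_distance, tuples_to_tree

__all__ = [
    "DolloResult",
    "AncestralReconstruction",
    "ReversionCall",
    "dollo_score",
    "dollo_search",
    "break_ties_with_cna",
    "acctran_reconstruct",
    "verify_reversions",
]

OUTGROUP = "N"
MAX_EXHAUSTIVE_LEAVES = 9


# ----------------------------------------------------------------------
# scoring on nested-tuple shapes with leaf bitmasks
# ----------------------------------------------------------------------
def _flatten(shape, nodes):
    """Append (mask, left, right) postorder; return node index and mask."""
    if isinstance(shape, tuple):
        l_idx, l_mask = _flatten(shape[0], nodes)
        r_idx, r_mask = _flatten(shape[1], nodes)
        mask = l_mask | r_mask
        nodes.append((mask, l_idx, r_idx))
    else:
        mask = 1 << shape
        nodes.append((mask, -1, -1))
    return len(nodes) - 1, mask


def _char_losses(nodes, root, present, absent):
    """Loss count for one character on a flattened shape.

    The gain sits at the smallest clade containing every present leaf;
    each maximal subtree below it holding absent but no present leaves
    costs one loss.  Missing leaves (neither mask) are free.
    """
    if present == 0:
        return 0
    # descend to the minimal clade containing all present leaves
    idx = root
    while True:
        mask, left, right = nodes[idx]
        if left < 0:
            break
        if nodes[left][0] & present == present:
            idx = left
        elif nodes[right][0] & present == present:
            idx = right
        else:
            break
    losses = 0
    stack = [idx]
    while stack:
        i = stack.pop()
        mask, left, right = nodes[i]
        if mask & present == 0:
            if mask & absent:
                losses += 1
            continue
        if left >= 0:
            stack.append(left)
            stack.append(right)
    return losses


def _score_shape(shape, chars):
    nodes: list = []
    root, _ = _flatten(shape, nodes)
    return sum(_char_losses(nodes, root, p, a) for p, a in chars)


def _matrix_to_chars(matrix: CharacterMatrix, labels: list[str]):
    chars = []
    for snv in matrix.snvs:
        col = matrix.calls[snv]
        present = absent = 0
        for i, s in enumerate(labels):
            v = col.get(s)
            if pd.isna(v):
                continue
            if v >= 0.5:
                present |= 1 << i
            else:
                absent |= 1 << i
        chars.append((present, absent))
    return chars


def dollo_score(tree: RootedTree, matrix: CharacterMatrix) -> int:
    """Dollo score (total losses) of an existing tree against a matrix."""
    labels = [s for s in matrix.samples if s != OUTGROUP]
    order = {s: i for i, s in enumerate(labels)}

    def _to_shape(node: Node):
        kids = [c for c in node.children if not (c.is_leaf and c.name == OUTGROUP)]
        if node.is_leaf:
            return order[node.name]
        if len(kids) == 1:
            return _to_shape(kids[0])
        shape = _to_shape(kids[0])
        for k in kids[1:]:
            shape = (shape, _to_shape(k))
        return shape

    shape = _to_shape(tree.root)
    chars = _matrix_to_chars(matrix, labels)
    return _score_shape(shape, chars)


@dataclass
class DolloResult:
    trees: list[RootedTree]
    score: int
    exhaustive: bool = True


def _insert_everywhere(shape, leaf):
    yield (shape, leaf)
    if isinstance(shape, tuple):
        left, right = shape
        for nl in _insert_everywhere(left, leaf):
            yield (nl, right)
        for nr in _insert_everywhere(right, leaf):
            yield (left, nr)


def dollo_search(matrix: CharacterMatrix, heuristic: bool = False,
                 max_exhaustive: int = MAX_EXHAUSTIVE_LEAVES) -> DolloResult:
    """All minimum-loss rooted topologies for one patient's call matrix.

    Leaves are the cancer samples; the germline outgroup (all characters
    absent) is attached at the root of every returned tree.  Exhaustive
    branch-and-bound is used up to ``max_exhaustive`` leaves; beyond that
    an explicit ``heuristic=True`` switches to greedy stepwise addition
    (result flagged ``exhaustive=False``), otherwise the search refuses.
    """
    labels = [s for s in matrix.samples if s != OUTGROUP]
    if len(labels) < 3:
        raise ValueError("need at least 3 cancer samples for tree search")
    if len(labels) > max_exhaustive and not heuristic:
        raise ValueError(
            f"{len(labels)} leaves exceeds the exhaustive-search limit of "
            f"{max_exhaustive}; pass heuristic=True for greedy search")
    chars = _matrix_to_chars(matrix, labels)

    # characters restricted to the first k leaves, for scoring partial
    # trees during stepwise addition (the restricted score is a lower
    # bound: pruning on it is admissible)
    n = len(labels)
    chars_at = []
    for k in range(n + 1):
        mask = (1 << k) - 1
        chars_at.append([(p & mask, a & mask) for p, a in chars])

    if n > max_exhaustive:
        shape = (0, 1)
        for nxt in range(2, n):
            shape = min(_insert_everywhere(shape, nxt),
                        key=lambda s: _score_shape(s, chars_at[nxt + 1]))
        best_shapes, best = [shape], _score_shape(shape, chars)
        exhaustive = False
    else:
        best = np.inf
        best_shapes: list = []

        def _extend(shape, nxt):
            nonlocal best, best_shapes
            score = _score_shape(shape, chars_at[nxt])
            if score > best:
                return
            if nxt == n:
                if score < best:
                    best = score
                    best_shapes = [shape]
                else:
                    best_shapes.append(shape)
                return
            for new_shape in _insert_everywhere(shape, nxt):
                _extend(new_shape, nxt + 1)

        _extend((0, 1), 2)
        best = int(best)
        exhaustive = True

    trees = [tuples_to_tree(s, outgroup=OUTGROUP,
                            name_of=lambda i: labels[i]) for s in best_shapes]
    trees.sort(key=lambda t: t.to_newick(lengths=False))
    return DolloResult(trees=trees, score=int(best), exhaustive=exhaustive)


def break_ties_with_cna(trees: list[RootedTree], cna_tree: RootedTree
                        ) -> RootedTree:
    """Pick the co-optimal SNV tree closest (Robinson-Foulds) to the CNA tree.

    Residual ties fall back to lexicographic Newick order so the choice is
    deterministic.
    """
    if not trees:
        raise ValueError("empty tie set")
    if len(trees) == 1:
        return trees[0]
    shared = ((set(trees[0].leaf_names()) - {OUTGROUP})
              & (set(cna_tree.leaf_names()) - {OUTGROUP}))
    if not shared:
        raise ValueError("SNV and CNA trees share no leaves")
    scored = sorted(
        trees, key=lambda t: (rf_distance(t, cna_tree),
                              t.to_newick(lengths=False)))
    return scored[0]


# ----------------------------------------------------------------------
# ancestral reconstruction
# ----------------------------------------------------------------------
@dataclass
class AncestralReconstruction:
    tree: RootedTree                       # copy with event-count branch lengths
    node_states: pd.DataFrame              # nodes x characters, 0/1
    gain_branch: dict[str, str]            # character -> node name
    loss_branches: dict[str, list[str]]    # character -> node names
    score: int = 0

    def events_on_branch(self, branch: str) -> int:
        gains = sum(1 for b in self.gain_branch.values() if b == branch)
        losses = sum(b.count(branch) for b in self.loss_branches.values())
        return gains + losses


def _name_internal(tree: RootedTree) -> None:
    counter = itertools.count(1)
    for node in tree.preorder():
        if node.name is None:
            node.name = (f"n{next(counter)}" if node.parent is not None
                         else "root")


def acctran_reconstruct(tree: RootedTree, matrix: CharacterMatrix
                        ) -> AncestralReconstruction:
    """Accelerated-transformation ancestral states under Dollo parsimony.

    Each character's gain is placed at the MRCA of its present leaves,
    then pushed rootward through any siblings consisting only of missing
    calls (acceleration is free there); losses cut the maximal all-absent
    clades below the gain.  Branch lengths of the returned tree copy are
    the per-branch event counts (gains plus losses).
    """
    tree = tree.copy()
    _name_internal(tree)
    nodes = {n.name: n for n in tree.preorder()}
    leaf_names = set(tree.leaf_names())

    below: dict[str, set[str]] = {}
    for n in tree.postorder():
        below[n.name] = ({n.name} if n.is_leaf else
                         set().union(*(below[c.name] for c in n.children)))

    gain_branch: dict[str, str] = {}
    loss_branches: dict[str, list[str]] = {}
    states: dict[str, dict[str, int]] = {n: {} for n in nodes}

    for snv in matrix.snvs:
        col = matrix.calls[snv]
        present = {s for s in matrix.samples
                   if s in leaf_names and not pd.isna(col.get(s)) and col[s] >= 0.5}
        absent = {s for s in matrix.samples
                  if s in leaf_names and not pd.isna(col.get(s)) and col[s] < 0.5}
        if not present:
            warnings.warn(f"character {snv} absent everywhere; excluded",
                          stacklevel=2)
            for n in nodes:
                states[n][snv] = 0
            continue
        gain = tree.mrca(present)
        # accelerate: climb while every sibling subtree is pure missing
        while gain.parent is not None and gain.parent.parent is not None:
            sibs = [c for c in gain.parent.children if c is not gain]
            if all(not (below[s.name] & (present | absent)) and s.name != OUTGROUP
                   for s in sibs):
                gain = gain.parent
            else:
                break
        gain_branch[snv] = gain.name

        losses: list[str] = []

        def _assign(node: Node, state: int) -> None:
            states[node.name][snv] = state
            for c in node.children:
                _assign(c, state)

        def _walk(node: Node) -> None:
            has_present = bool(below[node.name] & present)
            if not has_present:
                if below[node.name] & absent:
                    losses.append(node.name)
                    _assign(node, 0)
                else:
                    _assign(node, 1)  # pure missing inherits the gained state
                return
            states[node.name][snv] = 1
            for c in node.children:
                _walk(c)

        for n in nodes:  # default: ungained everywhere
            states[n][snv] = 0
        _walk(gain)
        loss_branches[snv] = losses

    # branch lengths = events assigned to each branch
    for node in tree.preorder():
        if node.parent is None:
            continue
        gains = sum(1 for b in gain_branch.values() if b == node.name)
        losses_n = sum(bs.count(node.name) for bs in loss_branches.values())
        node.length = gains + losses_n

    node_states = pd.DataFrame(states).T  # nodes x characters
    node_states = node_states.reindex(columns=matrix.snvs)
    score = sum(len(v) for v in loss_branches.values())
    return AncestralReconstruction(tree=tree, node_states=node_states,
                                   gain_branch=gain_branch,
                                   loss_branches=loss_branches, score=score)


# ----------------------------------------------------------------------
# reversion verification
# ----------------------------------------------------------------------
@dataclass
class ReversionCall:
    snv: str
    loss_branch: str
    affected_samples: list[str]
    status: str                      # supported | unexplained | possible_false_negative | unannotated
    supporting_loss: dict | None = None
    power: dict[str, float] = field(default_factory=dict)


def _segment_at(profiles: pd.DataFrame, sample: str, chrom: str, pos: int):
    rows = profiles[(profiles["sample"] == sample)
                    & (profiles["chrom"].astype(str) == str(chrom))
                    & (profiles["start"] <= pos) & (profiles["end"] >= pos)]
    return None if rows.empty else rows.iloc[0]


def verify_reversions(rec: AncestralReconstruction,
                      profiles: pd.DataFrame,
                      snv_positions: pd.DataFrame,
                      depths: pd.DataFrame,
                      sample_ccf: dict[str, float],
                      power_threshold: float = 0.95,
                      e: float = ccf_mod.DEFAULT_ERROR) -> list[ReversionCall]:
    """Annotate every predicted reversion with copy-number evidence.

    ``snv_positions`` maps characters to genomic loci (columns ``snv_id,
    chrom, pos``); ``depths`` is the samples x SNVs read-depth table used
    for the detection-power calculation; ``profiles`` is the matched
    allele-specific segment table.  A reversion is *supported* when an
    affected sample lost copies (total or minor decrease, or an allele at
    zero) relative to present samples at the SNV's locus.  If the power
    to detect the mutation in an affected sample falls below
    ``power_threshold``, the call is downgraded to a possible false
    negative instead of being asserted.
    """
    pos_of = snv_positions.set_index("snv_id")
    tree = rec.tree
    nodes = {n.name: n for n in tree.preorder()}
    below: dict[str, list[str]] = {}
    for n in tree.postorder():
        below[n.name] = ([n.name] if n.is_leaf else
                         [x for c in n.children for x in below[c.name]])

    calls: list[ReversionCall] = []
    for snv, branches in rec.loss_branches.items():
        if snv not in pos_of.index:
            for branch in branches:
                calls.append(ReversionCall(snv=snv, loss_branch=branch,
                                           affected_samples=below[branch],
                                           status="unannotated"))
            continue
        chrom = str(pos_of.loc[snv, "chrom"])
        pos = int(pos_of.loc[snv, "pos"])
        present_samples = [s for s in tree.leaf_names()
                           if s != OUTGROUP
                           and rec.node_states.loc[s, snv] == 1]
        # counterfactual copy state: what the locus looks like where the
        # mutation is present (the absence call is only trusted if a
        # present-like mutation would have been seen)
        ref_totals = []
        for s in present_samples:
            seg = _segment_at(profiles, s, chrom, pos)
            if seg is not None and seg["total"] > 0:
                ref_totals.append(int(seg["total"]))
        q_t_ref = int(np.median(ref_totals)) if ref_totals else 2

        for branch in branches:
            affected = [s for s in below[branch] if s != OUTGROUP]

            # detection power in each affected sample, assuming the SNV
            # would have been a single-copy clonal mutation there
            power: dict[str, float] = {}
            underpowered = False
            for s in affected:
                n_reads = depths.loc[s, snv] if (s in depths.index
                                                 and snv in depths.columns) else np.nan
                if np.isnan(n_reads):
                    underpowered = True
                    continue
                alpha = sample_ccf.get(s, 1.0)
                f = ccf_mod.expected_vaf(1, q_t_ref, alpha)
                power[s] = ccf_mod.detection_power(int(n_reads), f, e=e)
                if power[s] < power_threshold:
                    underpowered = True

            if underpowered:
                calls.append(ReversionCall(snv=snv, loss_branch=branch,
                                           affected_samples=affected,
                                           status="possible_false_negative",
                                           power=power))
                continue

            supporting = None
            ref_segs = [_segment_at(profiles, s, chrom, pos)
                        for s in present_samples]
            ref_segs = [r for r in ref_segs if r is not None]
            annotatable = False
            for s in affected:
                seg = _segment_at(profiles, s, chrom, pos)
                if seg is None:
                    continue
                annotatable = True
                lost_allele = seg["minor"] == 0 and seg["total"] < 2 * seg["major"]
                for ref in ref_segs:
                    if (seg["total"] < ref["total"]
                            or seg["minor"] < ref["minor"]
                            or (seg["minor"] == 0 and ref["minor"] > 0)):
                        supporting = dict(sample=s, chrom=chrom,
                                          start=int(seg["start"]),
                                          end=int(seg["end"]),
                                          total=int(seg["total"]),
                                          major=int(seg["major"]),
                                          minor=int(seg["minor"]))
                        break
                if supporting is None and lost_allele and not ref_segs:
                    supporting = dict(sample=s, chrom=chrom,
                                      start=int(seg["start"]),
                                      end=int(seg["end"]),
                                      total=int(seg["total"]),
                                      major=int(seg["major"]),
                                      minor=int(seg["minor"]))
                if supporting is not None:
                    break
            if not annotatable:
                status = "unannotated"
            elif supporting is not None:
                status = "supported"
            else:
                status = "unexplained"
            calls.append(ReversionCall(snv=snv, loss_branch=branch,
                                       affected_samples=affected,
                                       status=status,
                                       supporting_loss=supporting,
                                       power=power))
    return calls
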
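"""Ground-truth clone-tree simulator for multi-sample tumour sequencing.

The generator emulates the data a multi-region autopsy study produces: a
rooted clone tree whose leaves are tumour samples (primary plus
metastases), truncal and branch SNVs, allele-specific copy-number events,
LOH events that can delete a mutated allele (planting a *reversion*), an
optional whole-genome duplication, and optional cross-seeding of one lesion
by another.  Read counts are drawn binomially at ultra-deep targeted
coverage with a uniform per-base error model, so the downstream tier
filters, CCF estimator and phylogeny builders see data with the noise
structure they assume.

Every random choice flows from ``SimulationConfig.seed``; identical
configurations reproduce identical bundles byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .trees import Node, RootedTree

__all__ = [
    "SimulationConfig",
    "CnaEvent",
    "TruthBundle",
    "simulate_patient",
    "emit_read_counts",
    "emit_cna_profiles",
    "emit_flank_counts",
    "emit_log2_track",
    "write_truth_yaml",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
# pyrimidine-strand substitution classes used throughout the package
SUBSTITUTION_CLASSES = ("AT>CG", "AT>GC", "AT>TA", "CG>AT", "CG>GC", "CG>TA")

_SEGMENT_LENGTH = 50_000_000


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated patient.

    Defaults mirror the targeted-resequencing regime the pipeline is built
    for: a handful of lesions per patient, tens of validated SNVs, median
    coverage in the thousands, and per-base error around 1%.
    """

    n_samples: int = 4
    n_truncal_snvs: int = 30
    n_branch_snvs: float = 8.0  # Poisson mean per non-trunk branch
    n_truncal_cnas: int = 5
    n_branch_cnas: float = 1.5  # Poisson mean per non-trunk branch
    n_segments: int = 20
    depth_mean: float = 9000.0
    error_rate: float = 0.01
    ccf_range: tuple[float, float] = (0.4, 1.0)
    loh_probability: float = 0.0
    wgd: bool = False
    cross_seed: bool = False
    cross_seed_fraction: float = 0.3
    late_apobec_fraction: float = 0.0
    seed: int = 0
    patient_id: str = "SIM"

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two tumour samples")
        for name in ("error_rate", "loh_probability", "cross_seed_fraction",
                     "late_apobec_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.error_rate >= 1.0:
            raise ValueError("error_rate must be < 1")
        lo, hi = self.ccf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"ccf_range must satisfy 0 < lo <= hi <= 1, got {self.ccf_range}")
        for name in ("n_truncal_snvs", "n_segments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class CnaEvent:
    """One planted segmental copy-number event (or a WGD)."""

    branch: str            # name of the node whose parent edge carries the event
    segment: int           # segment index; -1 for WGD
    allele: str            # "A" or "B"; "" for WGD
    delta: int             # signed copy change; 0 for WGD
    is_wgd: bool = False
    deletes_snv: str | None = None  # snv_id whose mutated allele this loss removes


@dataclass
class TruthBundle:
    """Everything the generator knows about one simulated patient."""

    patient_id: str
    tree: RootedTree
    snv_meta: pd.DataFrame          # snv_id, chrom, pos, ref, alt, context, segment, allele
    snv_gain_branch: dict[str, str]
    snv_loss_branches: dict[str, list[str]]
    cna_assignments: list[CnaEvent]
    sample_ccf: dict[str, float]
    cross_seed: tuple[str, str, float] | None
    presence: pd.DataFrame          # samples x snvs, bool
    multiplicity: pd.DataFrame      # samples x snvs, int mutated-copy count
    profiles: pd.DataFrame          # sample, chrom, start, end, total, major, minor
    samples: list[str]

    def truncal_snvs(self) -> list[str]:
        trunk = _cancer_mrca(self.tree).name
        return [s for s, b in self.snv_gain_branch.items() if b == trunk]


def _cancer_mrca(tree: RootedTree) -> Node:
    """The cancer clade ancestor: the non-outgroup child of the root."""
    for child in tree.root.children:
        if not (child.is_leaf and child.name == "N"):
            return child
    raise ValueError("tree has no cancer clade")


def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random rooted binary shape by sequential random insertion."""
    shape = labels[0] if len(labels) == 1 else (labels[0], labels[1])
    for leaf in labels[2:]:
        edges = _count_insertions(shape)
        shape = _insert_at(shape, leaf, int(rng.integers(edges)))[0]
    return shape


def _count_insertions(shape) -> int:
    if isinstance(shape, tuple):
        return 1 + _count_insertions(shape[0]) + _count_insertions(shape[1])
    return 1


def _insert_at(shape, leaf, k):
    """Insert ``leaf`` at the k-th insertion point (preorder numbering)."""
    if k == 0:
        return (shape, leaf), -1
    k -= 1
    if isinstance(shape, tuple):
        left, right = shape
        new_left, k = _insert_at(left, leaf, k)
        if k < 0:
            return (new_left, right), -1
        new_right, k = _insert_at(right, leaf, k)
        if k < 0:
            return (left, new_right), -1
    return shape, k


def _shape_to_tree(shape, outgroup: str) -> RootedTree:
    counter = [0]

    def _build(sub) -> Node:
        if isinstance(sub, tuple):
            counter[0] += 1
            node = Node(name=f"n{counter[0]}")
            for part in sub:
                node.add_child(_build(part))
            return node
        return Node(str(sub))

    root = Node("root")
    root.add_child(Node(outgroup))
    if isinstance(shape, tuple):
        root.add_child(_build(shape))
    else:  # single cancer sample: trunk leads straight to it
        root.add_child(Node(str(shape)))
    return RootedTree(root)


def _draw_substitution(rng: np.random.Generator, apobec: bool) -> tuple[str, str, str, str]:
    """Return (class, ref, alt, trinucleotide context) on the pyrimidine strand."""
    if apobec:
        cls = "CG>TA"
        ref, alt = "C", "T"
        ctx = rng.choice(list("ACGT")) + "CG"
        return cls, ref, alt, ctx
    cls = SUBSTITUTION_CLASSES[int(rng.integers(len(SUBSTITUTION_CLASSES)))]
    ref = cls[0] if cls[0] == "A" else "C"
    # class encodes the pyrimidine/purine pair; alt follows from the class name
    alt = {"AT>CG": "C", "AT>GC": "G", "AT>TA": "T",
           "CG>AT": "A", "CG>GC": "G", "CG>TA": "T"}[cls]
    ctx = rng.choice(list("ACGT")) + ref + rng.choice(list("ACGT"))
    return cls, ref, alt, ctx


def simulate_patient(config: SimulationConfig) -> TruthBundle:
    """Draw one patient's ground truth: tree, SNVs, CNAs, CCFs.

    The clone tree is a uniform-at-random binary topology over the samples,
    rooted through a germline outgroup ``N``.  Truncal events sit on the
    trunk (root to cancer MRCA); every other branch receives Poisson
    numbers of private SNVs and CNA events.  With probability
    ``loh_probability`` each SNV that has a strict descendant branch gets a
    planted LOH event there that deletes its mutated allele — a reversion
    the downstream phylogeny should recover.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = ["P"] + [f"M{i}" for i in range(1, config.n_samples)]
    tree = _shape_to_tree(_random_topology(samples, rng), outgroup="N")
    mrca = _cancer_mrca(tree)

    # branches = every node except the root and the outgroup leaf; the
    # branch named after a node is the edge from its parent.
    branches = [n for n in tree.preorder()
                if n.parent is not None and n.name != "N"]
    trunk = mrca.name
    non_trunk = [b.name for b in branches if b.name != trunk]

    # --- assign SNVs to branches -----------------------------------------
    snv_branch: dict[str, str] = {}
    rows = []
    counts = {trunk: config.n_truncal_snvs}
    for b in non_trunk:
        counts[b] = int(rng.poisson(config.n_branch_snvs))
    idx = 0
    used_positions: set[tuple[int, int]] = set()
    for bname, k in counts.items():
        for _ in range(k):
            snv_id = f"s{idx:04d}"
            idx += 1
            seg = int(rng.integers(config.n_segments))
            while True:
                pos = int(rng.integers(1, _SEGMENT_LENGTH))
                if (seg, pos) not in used_positions:
                    used_positions.add((seg, pos))
                    break
            apobec = (bname != trunk
                      and rng.random() < config.late_apobec_fraction)
            cls, ref, alt, ctx = _draw_substitution(rng, apobec)
            allele = "A" if rng.random() < 0.5 else "B"
            rows.append(dict(snv_id=snv_id, chrom=str(seg + 1), pos=pos,
                             ref=ref, alt=alt, context=ctx,
                             substitution_class=cls, segment=seg,
                             allele=allele))
            snv_branch[snv_id] = bname
    snv_meta = pd.DataFrame(rows, columns=["snv_id", "chrom", "pos", "ref", "alt",
                                           "context", "substitution_class",
                                           "segment", "allele"])

    # --- assign CNA events -----------------------------------------------
    events: list[CnaEvent] = []
    if config.wgd:
        events.append(CnaEvent(branch=trunk, segment=-1, allele="", delta=0,
                               is_wgd=True))
    cna_counts = {trunk: config.n_truncal_cnas}
    for b in non_trunk:
        cna_counts[b] = int(rng.poisson(config.n_branch_cnas))
    for bname, k in cna_counts.items():
        for _ in range(k):
            seg = int(rng.integers(config.n_segments))
            allele = "A" if rng.random() < 0.5 else "B"
            delta = 1 if rng.random() < 0.7 else -1
            events.append(CnaEvent(branch=bname, segment=seg, allele=allele,
                                   delta=delta))

    # --- pre-walk: allele counts at every node under the ordinary events --
    nodes = {n.name: n for n in tree.preorder()}
    node_alleles: dict[str, np.ndarray] = {}

    def _prewalk(node: Node, alleles: np.ndarray) -> None:
        alleles = alleles.copy()
        if node.parent is not None and node.name != "N":
            for ev in events:
                if ev.branch != node.name:
                    continue
                if ev.is_wgd:
                    alleles *= 2
                    continue
                ai = 0 if ev.allele == "A" else 1
                cn = alleles[ev.segment, ai]
                if cn + ev.delta >= 0 and not (cn == 0 and ev.delta > 0):
                    alleles[ev.segment, ai] = cn + ev.delta
        node_alleles[node.name] = alleles
        for child in node.children:
            _prewalk(child, alleles)

    _prewalk(tree.root, np.ones((config.n_segments, 2), dtype=int))

    # --- resolve each SNV onto an allele that exists in its gain lineage --
    resolved: dict[str, str] = {}
    for snv_id, gain in snv_branch.items():
        meta_row = snv_meta.index[snv_meta["snv_id"] == snv_id][0]
        seg = int(snv_meta.at[meta_row, "segment"])
        want = str(snv_meta.at[meta_row, "allele"])
        counts = node_alleles[gain][seg]
        if counts[0 if want == "A" else 1] > 0:
            resolved[snv_id] = want
        elif counts[1 if want == "A" else 0] > 0:
            resolved[snv_id] = "B" if want == "A" else "A"
            snv_meta.at[meta_row, "allele"] = resolved[snv_id]
        else:
            resolved[snv_id] = ""  # segment fully deleted: unobservable
            snv_meta.at[meta_row, "allele"] = ""

    # --- planted reversions: LOH deleting a mutated allele ---------------
    descendants: dict[str, list[str]] = {}
    for b in branches:
        sub = []
        stack = list(nodes[b.name].children)
        while stack:
            n = stack.pop()
            if n.name != "N":
                sub.append(n.name)
            stack.extend(n.children)
        descendants[b.name] = sub
    leaves_below: dict[str, set[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            leaves_below[n.name] = {n.name} if n.name != "N" else set()
        else:
            leaves_below[n.name] = set().union(
                *(leaves_below[c.name] for c in n.children))

    def _identifiable(gain: str, loss: str) -> bool:
        # the surviving carriers must still straddle >= 2 children of the
        # gain node, otherwise parsimony prefers a later gain over a loss
        remaining = leaves_below[gain] - leaves_below[loss]
        if not remaining:
            return False
        children = nodes[gain].children
        covering = [c for c in children if leaves_below[c.name] & remaining]
        return len(covering) >= 2 or (len(children) == 0)

    snv_loss: dict[str, list[str]] = {s: [] for s in snv_branch}
    meta_by_id = snv_meta.set_index("snv_id")
    slot_count: dict[tuple[int, str], int] = {}
    for sid in snv_branch:
        key = (int(meta_by_id.loc[sid, "segment"]), resolved[sid])
        slot_count[key] = slot_count.get(key, 0) + 1
    for snv_id, gain in snv_branch.items():
        if not descendants[gain] or not resolved[snv_id]:
            continue
        # an LOH event deletes every mutation on its allele; keeping the
        # planted reversions to singly-occupied slots means each planted
        # event creates exactly one reversion character
        if slot_count[(int(meta_by_id.loc[snv_id, "segment"]),
                       resolved[snv_id])] != 1:
            continue
        if rng.random() >= config.loh_probability:
            continue
        candidates = [b for b in descendants[gain]
                      if node_alleles[b][int(meta_by_id.loc[snv_id, "segment"]),
                                         0 if resolved[snv_id] == "A" else 1] > 0
                      and _identifiable(gain, b)]
        if not candidates:
            continue
        loss_branch = candidates[int(rng.integers(len(candidates)))]
        events.append(CnaEvent(branch=loss_branch,
                               segment=int(meta_by_id.loc[snv_id, "segment"]),
                               allele=resolved[snv_id], delta=-99,
                               deletes_snv=snv_id))
        snv_loss[snv_id].append(loss_branch)

    # --- replay events down the tree; record leaf states ------------------
    # state: per-segment {"A": n, "B": n}; per-snv mutated-copy count
    events_by_branch: dict[str, list[CnaEvent]] = {}
    for ev in events:
        events_by_branch.setdefault(ev.branch, []).append(ev)
    snv_ids = list(snv_meta["snv_id"])
    seg_of = dict(zip(snv_meta["snv_id"], snv_meta["segment"]))
    allele_of = dict(zip(snv_meta["snv_id"], snv_meta["allele"]))

    leaf_alleles: dict[str, np.ndarray] = {}
    leaf_mult: dict[str, np.ndarray] = {}

    def _walk(node: Node, alleles: np.ndarray, mult: np.ndarray) -> None:
        alleles = alleles.copy()
        mult = mult.copy()
        if node.parent is not None and node.name != "N":
            # SNV gains on this branch happen before its CNA events
            for j, sid in enumerate(snv_ids):
                if snv_branch[sid] == node.name and allele_of[sid]:
                    ai = 0 if allele_of[sid] == "A" else 1
                    if alleles[seg_of[sid], ai] > 0:
                        mult[j] = 1
            for ev in events_by_branch.get(node.name, ()):
                if ev.is_wgd:
                    alleles *= 2
                    mult *= 2
                    continue
                ai = 0 if ev.allele == "A" else 1
                cn = alleles[ev.segment, ai]
                if ev.delta == -99:  # planted LOH: wipe the allele
                    alleles[ev.segment, ai] = 0
                    for j, sid in enumerate(snv_ids):
                        if seg_of[sid] == ev.segment and allele_of[sid] == ev.allele:
                            mult[j] = 0
                    continue
                new_cn = cn + ev.delta
                if new_cn < 0 or (cn == 0 and ev.delta > 0):
                    # gains from zero are never planted; clamp instead of raise
                    continue
                alleles[ev.segment, ai] = new_cn
                for j, sid in enumerate(snv_ids):
                    if seg_of[sid] != ev.segment or allele_of[sid] != ev.allele:
                        continue
                    s = mult[j]
                    if s == 0 or cn == 0:
                        continue
                    if ev.delta > 0 and rng.random() < s / cn:
                        mult[j] = s + 1
                    elif ev.delta < 0 and rng.random() < s / cn:
                        mult[j] = s - 1
        if node.is_leaf and node.name != "N":
            leaf_alleles[node.name] = alleles
            leaf_mult[node.name] = mult
        for child in node.children:
            _walk(child, alleles, mult)

    base_alleles = np.ones((config.n_segments, 2), dtype=int)
    base_mult = np.zeros(len(snv_ids), dtype=int)
    _walk(tree.root, base_alleles, base_mult)

    presence = pd.DataFrame(
        {sid: [leaf_mult[s][j] > 0 for s in samples]
         for j, sid in enumerate(snv_ids)}, index=samples).astype(bool)
    multiplicity = pd.DataFrame(
        {sid: [int(leaf_mult[s][j]) for s in samples]
         for j, sid in enumerate(snv_ids)}, index=samples)

    prof_rows = []
    for s in samples:
        for seg in range(config.n_segments):
            a, b = int(leaf_alleles[s][seg, 0]), int(leaf_alleles[s][seg, 1])
            prof_rows.append(dict(sample=s, chrom=str(seg + 1), start=1,
                                  end=_SEGMENT_LENGTH, total=a + b,
                                  major=max(a, b), minor=min(a, b)))
    profiles = pd.DataFrame(prof_rows)

    lo, hi = config.ccf_range
    sample_ccf = {s: float(rng.uniform(lo, hi)) for s in samples}

    cross = None
    if config.cross_seed:
        donors = [s for s in samples
                  if snv_meta.loc[[snv_branch[sid] == s for sid in snv_ids]].shape[0] > 0]
        donors = [s for s in donors if any(snv_branch[sid] == s for sid in snv_ids)]
        if donors:
            donor = donors[int(rng.integers(len(donors)))]
            others = [s for s in samples if s != donor]
            recipient = others[int(rng.integers(len(others)))]
            cross = (donor, recipient, config.cross_seed_fraction)

    # branch lengths on the truth tree = number of SNVs gained on the branch
    for node in tree.preorder():
        if node.parent is not None:
            node.length = sum(1 for sid in snv_ids if snv_branch[sid] == node.name) \
                if node.name != "N" else 0

    return TruthBundle(
        patient_id=config.patient_id, tree=tree, snv_meta=snv_meta,
        snv_gain_branch=snv_branch, snv_loss_branches=snv_loss,
        cna_assignments=events, sample_ccf=sample_ccf, cross_seed=cross,
        presence=presence, multiplicity=multiplicity, profiles=profiles,
        samples=samples)


def _expected_vaf(s: float, q_t: float, ccf: float) -> float:
    denom = q_t * ccf + 2.0 * (1.0 - ccf)
    return 0.0 if denom <= 0 else s * ccf / denom


def emit_read_counts(truth: TruthBundle, config: SimulationConfig) -> pd.DataFrame:
    """Binomial read counts for every SNV in every sample.

    The success probability is the error-adjusted expected VAF
    ``f(1-e) + (1-f)e/3`` given the sample's CCF, local total copy number
    and the SNV's mutated-copy count; absent SNVs see error-only reads.
    Depth is Poisson around ``depth_mean``, floored at 100.  Cross-seeded
    SNVs (donor-private mutations in the recipient) are diluted by the
    seeding fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    e = config.error_rate
    prof = truth.profiles.set_index(["sample", "chrom"])
    rows = []
    donor_private: set[str] = set()
    recipient = None
    frac = 0.0
    if truth.cross_seed is not None:
        donor, recipient, frac = truth.cross_seed
        donor_private = {sid for sid, b in truth.snv_gain_branch.items() if b == donor}
    for sample in truth.samples:
        ccf = truth.sample_ccf[sample]
        for _, meta in truth.snv_meta.iterrows():
            sid = meta["snv_id"]
            q_t = int(prof.loc[(sample, meta["chrom"]), "total"])
            s = int(truth.multiplicity.loc[sample, sid])
            if s > 0:
                f = _expected_vaf(s, q_t, ccf)
            elif sample == recipient and sid in donor_private:
                f = _expected_vaf(frac * 1.0, q_t, ccf)
            else:
                f = 0.0
            p = f * (1.0 - e) + (1.0 - f) * e / 3.0
            depth = max(100, int(rng.poisson(config.depth_mean)))
            alt_reads = int(rng.binomial(depth, p))
            rows.append(dict(patient=truth.patient_id, sample=sample,
                             chrom=meta["chrom"], pos=int(meta["pos"]),
                             ref=meta["ref"], alt=meta["alt"],
                             ref_reads=depth - alt_reads, alt_reads=alt_reads,
                             snv_id=sid))
    return pd.DataFrame(rows)


def emit_cna_profiles(truth: TruthBundle) -> pd.DataFrame:
    """Allele-specific integer segment table (sample, chrom, start, end,
    total, major, minor), one row per shared segment per sample."""
    return truth.profiles.copy()


def emit_flank_counts(config: SimulationConfig, n_positions: int = 1000,
                      class_error: dict[str, float] | None = None) -> pd.DataFrame:
    """Simulated flanking-position read counts for background-noise estimation.

    Each row is one flank position: its substitution class, depth and
    non-reference read count, with per-class error rates given by
    ``class_error`` (default: ``error_rate`` for every class).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    for cls in SUBSTITUTION_CLASSES:
        err = config.error_rate if class_error is None else class_error.get(cls, 0.0)
        for _ in range(n_positions):
            depth = max(100, int(rng.poisson(config.depth_mean)))
            nonref = int(rng.binomial(depth, err))
            rows.append(dict(substitution_class=cls, depth=depth,
                             nonref_reads=nonref))
    return pd.DataFrame(rows)


def emit_log2_track(n_probes: int = 10000, noise_sd: float = 0.2,
                    wave_amplitude: float = 0.0, wave_period: int = 500,
                    n_chromosomes: int = 10, seed: int = 0) -> pd.DataFrame:
    """Probe-level log2-ratio track with white noise and an optional long
    wave, for exercising the array QC metrics."""
    rng = np.random.default_rng(seed)
    per_chrom = n_probes // n_chromosomes
    rows = []
    for c in range(n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=per_chrom,
                                 replace=False))
        vals = rng.normal(0.0, noise_sd, size=per_chrom)
        if wave_amplitude > 0:
            vals = vals + wave_amplitude * np.sin(2 * np.pi * np.arange(per_chrom)
                                                  / wave_period)
        for p, v in zip(pos, vals):
            rows.append(dict(chrom=str(c + 1), pos=int(p), log2=float(v)))
    return pd.DataFrame(rows)


def write_truth_yaml(truth: TruthBundle, path) -> None:
    """Serialise the ground truth as a YAML sidecar."""
    doc = dict(
        patient_id=truth.patient_id,
        tree=truth.tree.to_newick(),
        samples=truth.samples,
        sample_ccf={k: float(v) for k, v in truth.sample_ccf.items()},
        snv_gain_branch=truth.snv_gain_branch,
        snv_loss_branches={k: v for k, v in truth.snv_loss_branches.items() if v},
        cross_seed=list(truth.cross_seed) if truth.cross_seed else None,
        cna_events=[dataclasses.asdict(ev) for ev in truth.cna_assignments],
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
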
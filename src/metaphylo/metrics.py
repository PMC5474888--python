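"""Progression metrics: branch-length dynamics, substitution spectra and
pairwise clonal-frequency configurations.

Three read-outs summarise how a patient's disease progressed once the
trees and clonal frequencies are in hand:

* **Normalized branch lengths** — for each lesion, the path length from
  the cancer samples' most recent common ancestor (the first divergence,
  i.e. the earliest metastasising event) down to the lesion, divided by
  the trunk (root to MRCA).  Long normalized branches mean most change
  accumulated *late*; across patients the mean tracks overall survival.

* **Substitution spectra** — six pyrimidine-strand substitution classes
  split into *early* (truncal) and *late* (branch) phases, with the
  fraction of C>T changes at NpCpG trinucleotides as an APOBEC-style
  signal.

* **Pairwise configurations** — each SNV, for an ordered pair of
  samples, is clonal, subclonal or absent in each; the seven-way
  classification separates tree-compatible patterns from the
  tree-incompatible ones (fully clonal in one sample, subclonal in the
  other) that indicate horizontal cross-seeding between lesions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trees import RootedTree

__all__ = [
    "BranchLengthSummary",
    "normalized_branch_lengths",
    "survival_correlation",
    "SubstitutionSpectrum",
    "substitution_spectrum",
    "classify_pairwise",
    "PairwiseResult",
]

OUTGROUP = "N"
CLONAL_CUTOFF = 0.8
SUBCLONAL_FLOOR = 0.1
MIN_SEEDING_SNVS = 5

_CLASS_OF = {
    ("A", "C"): "AT>CG", ("A", "G"): "AT>GC", ("A", "T"): "AT>TA",
    ("C", "A"): "CG>AT", ("C", "G"): "CG>GC", ("C", "T"): "CG>TA",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ----------------------------------------------------------------------
# normalized branch lengths
# ----------------------------------------------------------------------
@dataclass
class BranchLengthSummary:
    trunk_length: float
    per_leaf: dict[str, float]       # leaf -> path(MRCA, leaf) / trunk

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_leaf.values())))


def normalized_branch_lengths(tree: RootedTree) -> BranchLengthSummary:
    """Per-lesion evolutionary distance since the first divergence.

    The trunk is the path from the root (outgroup attachment) to the MRCA
    of the cancer leaves; each leaf's normalized length is its path from
    that MRCA divided by the trunk.  A zero-length trunk leaves the ratio
    undefined and raises.
    """
    cancer = [s for s in tree.leaf_names() if s != OUTGROUP]
    if len(cancer) < 2:
        raise ValueError("need at least two cancer leaves")
    mrca = tree.mrca(cancer)
    trunk = tree.path_length(tree.root, mrca)
    if trunk <= 0:
        raise ValueError("trunk length is zero; normalized distances undefined")
    per_leaf = {}
    for name in cancer:
        leaf = tree.find(name)
        per_leaf[name] = tree.path_length(mrca, leaf) / trunk
    return BranchLengthSummary(trunk_length=trunk, per_leaf=per_leaf)


def survival_correlation(patient_means: dict[str, float],
                         survival: dict[str, float]) -> tuple[float, float]:
    """Spearman correlation of mean normalized branch length with survival.

    Patients present in both mappings are used; requires at least 4.
    Degenerate (constant) inputs return (nan, nan).
    """
    patients = sorted(set(patient_means) & set(survival))
    if len(patients) < 4:
        raise ValueError("need at least 4 patients with both metrics")
    x = [patient_means[p] for p in patients]
    y = [survival[p] for p in patients]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ----------------------------------------------------------------------
# substitution spectra
# ----------------------------------------------------------------------
@dataclass
class SubstitutionSpectrum:
    phase: str
    counts: dict[str, int]
    n_total: int
    npcpg_ct: int            # C>T substitutions in an NpCpG context
    npcpg_known_context: int  # C>T substitutions with a usable context

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_total for k, v in self.counts.items()}

    @property
    def npcpg_ct_fraction(self) -> float:
        return (self.npcpg_ct / self.npcpg_known_context
                if self.npcpg_known_context else float("nan"))


def _normalize_substitution(ref: str, alt: str, context: str | None
                            ) -> tuple[str | None, str | None]:
    """Pyrimidine-strand class and normalized trinucleotide context."""
    ref, alt = ref.upper(), alt.upper()
    if ref in ("G", "T"):
        ref, alt = _COMPLEMENT.get(ref, "?"), _COMPLEMENT.get(alt, "?")
        if context and len(context) == 3 and all(c in _COMPLEMENT for c in context):
            context = "".join(_COMPLEMENT[c] for c in reversed(context))
        else:
            context = None
    elif not (context and len(context) == 3
              and all(c in _COMPLEMENT for c in context.upper())):
        context = None
    cls = _CLASS_OF.get((ref, alt))
    return cls, context


def substitution_spectrum(snvs: pd.DataFrame, phase_of: dict[str, str]
                          ) -> dict[str, SubstitutionSpectrum]:
    """Early/late substitution spectra for one patient.

    ``snvs`` needs columns ``snv_id, ref, alt`` and optionally
    ``context`` (trinucleotide around the ref base); ``phase_of`` maps
    SNV ids to ``early`` (truncal) or ``late``.  Substitutions are
    normalized to the pyrimidine strand; SNVs with unknown context still
    count in their class but are excluded from the NpCpG fraction.
    """
    spectra = {}
    for phase in ("early", "late"):
        counts = {c: 0 for c in sorted(set(_CLASS_OF.values()))}
        npcpg = known = 0
        total = 0
        for _, row in snvs.iterrows():
            if phase_of.get(row["snv_id"]) != phase:
                continue
            ctx = row["context"] if "context" in snvs.columns else None
            cls, context = _normalize_substitution(row["ref"], row["alt"], ctx)
            if cls is None:
                continue
            counts[cls] += 1
            total += 1
            if cls == "CG>TA":
                if context is not None:
                    known += 1
                    if context[2] == "G":
                        npcpg += 1
        spectra[phase] = SubstitutionSpectrum(phase=phase, counts=counts,
                                              n_total=total, npcpg_ct=npcpg,
                                              npcpg_known_context=known)
    return spectra


def phase_from_reconstruction(gain_branch: dict[str, str],
                              tree: RootedTree) -> dict[str, str]:
    """Early = gained on the trunk (at the cancer MRCA); late = below it."""
    cancer = [s for s in tree.leaf_names() if s != OUTGROUP]
    trunk = tree.mrca(cancer).name
    return {snv: ("early" if b == trunk else "late")
            for snv, b in gain_branch.items()}


# ----------------------------------------------------------------------
# pairwise clonal-frequency configurations and cross-seeding
# ----------------------------------------------------------------------
@dataclass
class PairwiseResult:
    table: pd.DataFrame                      # snv, sample1, sample2, states, configuration
    cross_seeding: list[dict] = field(default_factory=list)


def _state(freq: float, clonal_cutoff: float, floor: float) -> str:
    if pd.isna(freq) or freq < floor:
        return "absent"
    if freq >= clonal_cutoff:
        return "clonal"
    return "subclonal"


_CONFIG = {
    ("clonal", "clonal"): "i",
    ("clonal", "absent"): "ii",
    ("absent", "clonal"): "iii",
    ("subclonal", "absent"): "iv",
    ("absent", "subclonal"): "v",
    ("clonal", "subclonal"): "vi",
    ("subclonal", "clonal"): "vii",
    ("subclonal", "subclonal"): "*",
    ("absent", "absent"): "-",
}


def classify_pairwise(freqs: pd.DataFrame, tree: RootedTree | None = None,
                      clonal_cutoff: float = CLONAL_CUTOFF,
                      subclonal_floor: float = SUBCLONAL_FLOOR,
                      min_support: int = MIN_SEEDING_SNVS) -> PairwiseResult:
    """Assign every SNV x ordered sample pair to a clonality configuration.

    ``freqs`` is a samples x SNVs clonal-frequency matrix (NaN or values
    below ``subclonal_floor`` mean absent).  Configurations i-v are
    compatible with a strict tree; vi and vii (fully clonal in one
    sample, subclonal in the other) are not.  A cross-seeding call
    (donor, recipient) is emitted when at least ``min_support`` SNVs are
    clonal in the donor, subclonal in the recipient, private to that pair
    (absent elsewhere), while the recipient also carries private clonal
    SNVs of its own — which rules out simple shared ancestry.
    """
    samples = list(freqs.index)
    rows = []
    vi_support: dict[tuple[str, str], list[str]] = {}
    for s1, s2 in itertools.permutations(samples, 2):
        for snv in freqs.columns:
            st1 = _state(freqs.loc[s1, snv], clonal_cutoff, subclonal_floor)
            st2 = _state(freqs.loc[s2, snv], clonal_cutoff, subclonal_floor)
            config = _CONFIG[(st1, st2)]
            if config == "-":
                continue
            rows.append(dict(snv=snv, sample1=s1, sample2=s2,
                             state1=st1, state2=st2, configuration=config))
            if config == "vi":
                others = [s for s in samples if s not in (s1, s2)]
                private = all(
                    _state(freqs.loc[o, snv], clonal_cutoff, subclonal_floor)
                    == "absent" for o in others)
                if private:
                    vi_support.setdefault((s1, s2), []).append(snv)
    table = pd.DataFrame(rows, columns=["snv", "sample1", "sample2",
                                        "state1", "state2", "configuration"])

    calls = []
    for (donor, recipient), snvs in sorted(vi_support.items()):
        if len(snvs) < min_support:
            continue
        # the recipient must have its own private clonal mutations,
        # otherwise it could simply descend from the donor's clone
        recipient_private = 0
        for snv in freqs.columns:
            if _state(freqs.loc[recipient, snv], clonal_cutoff,
                      subclonal_floor) != "clonal":
                continue
            if all(_state(freqs.loc[o, snv], clonal_cutoff, subclonal_floor)
                   == "absent" for o in samples if o != recipient):
                recipient_private += 1
        if recipient_private == 0:
            continue
        calls.append(dict(donor=donor, recipient=recipient,
                          n_support=len(snvs), snvs=sorted(snvs)))
    return PairwiseResult(table=table, cross_seeding=calls)
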
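"""Tiered filtering of deep-resequencing SNV calls.

Targeted amplicon sequencing of FFPE material shows all four bases at low
frequency at many loci, so presence calls need a noise floor.  The tier
system encodes increasing confidence: tier 0-2 are provenance flags set
upstream (exome call, somatic status, orthogonal validation); tier 3 means
the SNV survived the deep-sequencing presence/coverage filters in the
patient's matched sample set; tier 4 additionally requires the sample to
have an adequate cancer cell fraction for CCF modelling.

The default thresholds are the ones the pipeline was designed around: a 3%
VAF presence cut-off (chosen as a conservative margin above observed
background noise), coverage above 1,500x, at least 75% non-missing cells
per sample, at most one missing cell per SNV, more than 20% of SNVs
present per sample, and a 30% CCF floor for tier 4.

Boundary conventions: presence and CCF thresholds are inclusive
(vaf >= 3%, ccf >= 30%); the coverage rule is exclusive (a cell needs
depth strictly above 1,500x to count as observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NoiseEstimate",
    "CharacterMatrix",
    "estimate_background_noise",
    "call_presence",
    "apply_tier3_filters",
    "promote_tier4",
]

PRESENT_CUTOFF = 0.03
MIN_DEPTH = 1500
MIN_SAMPLE_NONMISSING = 0.75
MAX_SNV_MISSING = 1
MIN_SAMPLE_PRESENT = 0.20
MIN_CCF = 0.30


@dataclass
class NoiseEstimate:
    """Background non-reference signal for one substitution class."""

    substitution_class: str
    mean_background: float
    sd_background: float
    max_observed: float
    n_positions: int


@dataclass
class CharacterMatrix:
    """Samples x SNVs presence/absence matrix with a missing mask.

    ``calls`` holds 1.0 (present), 0.0 (absent) or NaN (missing).
    ``sample_tier`` records the tier level each sample's calls reached.
    """

    calls: pd.DataFrame
    sample_tier: dict[str, int] = field(default_factory=dict)
    tier: int = 3

    def __post_init__(self):
        if not self.sample_tier:
            self.sample_tier = {s: self.tier for s in self.calls.index}

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snvs(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def is_empty(self) -> bool:
        return self.calls.shape[0] == 0 or self.calls.shape[1] == 0

    def with_outgroup(self, name: str = "N") -> "CharacterMatrix":
        """Attach an all-absent germline outgroup row for rooting."""
        calls = self.calls.copy()
        calls.loc[name] = 0.0
        return CharacterMatrix(calls, dict(self.sample_tier, **{name: self.tier}),
                               self.tier)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#tier={self.tier}\n")
            fh.write("#sample_tier=" + ",".join(
                f"{s}:{t}" for s, t in self.sample_tier.items()) + "\n")
            self.calls.to_csv(fh, sep="\t", na_rep="NA", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        tier, sample_tier = 3, {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#tier="):
                tier = int(line.strip().split("=", 1)[1])
            elif line.startswith("#sample_tier="):
                spec = line.strip().split("=", 1)[1]
                sample_tier = {k: int(v) for k, v in
                               (item.split(":") for item in spec.split(",") if item)}
            else:
                body.append(line)
        from io import StringIO
        calls = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="sample",
                            na_values="NA")
        calls.index.name = None
        calls.columns.name = None
        return cls(calls.astype(float), sample_tier, tier)


def estimate_background_noise(flank_counts: pd.DataFrame,
                              exclude_above: float = 0.10
                              ) -> tuple[dict[str, NoiseEstimate], float]:
    """Per-substitution-class background noise from flanking positions.

    ``flank_counts`` has one row per flank position with columns
    ``substitution_class``, ``depth`` and ``nonref_reads``.  Positions with
    more than ``exclude_above`` (default 10%) non-reference reads are
    dropped as likely germline SNPs or secondary SNVs; the rest are pooled
    per class.  Returns the per-class estimates and the maximum class mean
    observed (the number the presence cut-off should comfortably exceed).
    Classes whose positions are all excluded are absent from the result,
    not reported as zero.
    """
    required = {"substitution_class", "depth", "nonref_reads"}
    if not required.issubset(flank_counts.columns):
        raise ValueError(f"flank table needs columns {sorted(required)}")
    if (flank_counts["depth"] <= 0).any():
        raise ValueError("every flank position must have positive depth")
    frac = flank_counts["nonref_reads"] / flank_counts["depth"]
    keep = frac <= exclude_above
    out: dict[str, NoiseEstimate] = {}
    for cls, grp in flank_counts[keep].groupby("substitution_class"):
        f = (grp["nonref_reads"] / grp["depth"]).to_numpy(float)
        if f.size == 0:
            continue
        out[cls] = NoiseEstimate(
            substitution_class=cls,
            mean_background=float(f.mean()),
            sd_background=float(f.std(ddof=1)) if f.size > 1 else 0.0,
            max_observed=float(f.max()),
            n_positions=int(f.size),
        )
    max_mean = max((e.mean_background for e in out.values()), default=float("nan"))
    return out, max_mean


def call_presence(vaf, threshold: float = PRESENT_CUTOFF):
    """Binary presence call: present iff VAF >= threshold (inclusive)."""
    arr = np.asarray(vaf, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("VAF outside [0, 1]")
    result = arr >= threshold
    return bool(result) if np.isscalar(vaf) else result


def _pivot(obs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    obs = obs.copy()
    if "snv_id" in obs.columns:
        key = obs["snv_id"].astype(str)
    else:
        key = (obs["chrom"].astype(str) + ":" + obs["pos"].astype(str)
               + obs["ref"] + ">" + obs["alt"])
    obs["_key"] = key
    obs["_depth"] = obs["ref_reads"] + obs["alt_reads"]
    depth = obs.pivot_table(index="sample", columns="_key", values="_depth",
                            aggfunc="first")
    alt = obs.pivot_table(index="sample", columns="_key", values="alt_reads",
                          aggfunc="first")
    vaf = alt / depth
    return depth, vaf


def apply_tier3_filters(obs: pd.DataFrame,
                        min_depth: int = MIN_DEPTH,
                        present_cutoff: float = PRESENT_CUTOFF,
                        min_sample_nonmissing: float = MIN_SAMPLE_NONMISSING,
                        max_snv_missing: int = MAX_SNV_MISSING,
                        min_sample_present: float = MIN_SAMPLE_PRESENT
                        ) -> CharacterMatrix:
    """Tier-3 coverage/missingness/presence filters for one patient.

    All matched samples of the patient must be passed jointly.  Applied in
    order: (1) cells with depth not exceeding ``min_depth`` become missing;
    (2) samples with under ``min_sample_nonmissing`` observed cells are
    dropped; (3) SNVs with more than ``max_snv_missing`` missing cells
    across the retained samples are dropped; (4) SNVs absent (VAF below
    ``present_cutoff``) in every retained sample are dropped; (5) samples
    in which at most ``min_sample_present`` of the remaining SNVs are
    present are dropped (a guard against low-cellularity samples).

    An empty result (no samples or no SNVs survive) is returned as an
    empty matrix with a warning; check :attr:`CharacterMatrix.is_empty`.
    """
    depth, vaf = _pivot(obs)
    missing = ~(depth > min_depth)
    vaf = vaf.mask(missing)

    # (2) sample-level missingness
    keep_samples = (~missing).mean(axis=1) >= min_sample_nonmissing
    vaf = vaf.loc[keep_samples]

    # (3) SNV-level missingness
    keep_snvs = vaf.isna().sum(axis=0) <= max_snv_missing
    vaf = vaf.loc[:, keep_snvs]

    # (4) SNVs absent everywhere
    present = vaf >= present_cutoff
    keep_snvs = present.any(axis=0)
    vaf = vaf.loc[:, keep_snvs]
    present = present.loc[:, keep_snvs]

    # (5) samples with too few present SNVs (fraction of non-missing cells)
    if vaf.shape[1] > 0:
        frac_present = present.sum(axis=1) / vaf.notna().sum(axis=1).clip(lower=1)
        vaf = vaf.loc[frac_present > min_sample_present]
        present = present.loc[vaf.index]

    if vaf.shape[0] == 0 or vaf.shape[1] == 0:
        warnings.warn("tier-3 filtering left an empty matrix", stacklevel=2)

    calls = present.astype(float).mask(vaf.isna())
    return CharacterMatrix(calls, tier=3)


def promote_tier4(matrix: CharacterMatrix, sample_ccf: dict[str, float],
                  min_ccf: float = MIN_CCF) -> CharacterMatrix:
    """Flag samples whose CCF reaches ``min_ccf`` (inclusive) as tier 4.

    Samples without a CCF estimate (no matched array) keep tier 3, with a
    warning.  The call matrix itself is unchanged; tier 4 is a per-sample
    confidence flag consumed by the CCF and clonal-frequency stages.
    """
    sample_tier = {}
    for s in matrix.samples:
        ccf = sample_ccf.get(s)
        if ccf is None:
            warnings.warn(f"no CCF available for sample {s}; left at tier 3",
                          stacklevel=2)
            sample_tier[s] = 3
        elif ccf >= min_ccf:
            sample_tier[s] = 4
        else:
            sample_tier[s] = 3
    tier = 4 if any(t == 4 for t in sample_tier.values()) else 3
    return CharacterMatrix(matrix.calls.copy(), sample_tier, tier)
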
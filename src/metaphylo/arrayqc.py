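"""SNP-array quality control and copy-number profile hygiene.

FFPE-derived DNA produces wavy log2-ratio profiles that mimic copy-number
aberrations, so arrays are gated on two noise metrics before any
phylogenetics: MAPD (median absolute pairwise deviation of adjacent probe
log2 ratios, a spikiness measure) and MAC (median across chromosomes of
the lag-1 autocorrelation of the log2 track, a waviness measure).  Arrays
with MAPD > 0.7 or MAC > 0.3 fail.

Segment tables arrive pre-segmented with integer allele-specific calls
(segmentation and integer calling are external); this module merges
statistically indistinguishable neighbouring segments and applies the
high-copy masking rule imposed by the integer caller's cap of eight
copies: outside high-ploidy patients, a segment reaching total copy 8 or
major allele > 4 in any sample is removed from all matched samples, and
SNVs at such loci are excluded from CCF estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCMetrics",
    "compute_mapd",
    "compute_mac",
    "qc_sample",
    "merge_close_segments",
    "mask_high_copy",
    "masked_loci",
]

MAPD_MAX = 0.7
MAC_MAX = 0.3
TOTAL_CAP = 8
MAJOR_CAP = 4


@dataclass
class QCMetrics:
    mapd: float
    mac: float

    @property
    def passed(self) -> bool:
        return not (self.mapd > MAPD_MAX or self.mac > MAC_MAX)


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "log2"}
    if not required.issubset(track.columns):
        raise ValueError(f"log2 track needs columns {sorted(required)}")
    for _, grp in track.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("probe positions must be strictly increasing "
                             "within each chromosome")
    return track


def compute_mapd(track: pd.DataFrame) -> float:
    """Median absolute deviation between adjacent probe log2 ratios.

    Adjacent pairs are taken within chromosomes and the median is computed
    genome-wide over the pooled differences.
    """
    _check_track(track)
    diffs = []
    for _, grp in track.groupby("chrom"):
        x = grp["log2"].to_numpy(float)
        if x.size >= 2:
            diffs.append(np.abs(np.diff(x)))
    if not diffs:
        raise ValueError("MAPD needs at least two probes on one chromosome")
    return float(np.median(np.concatenate(diffs)))


def compute_mac(track: pd.DataFrame) -> float:
    """Median across chromosomes of the lag-1 Pearson autocorrelation.

    Zero-variance chromosomes carry no waviness information and are
    excluded from the median with a warning.
    """
    _check_track(track)
    acs = []
    for chrom, grp in track.groupby("chrom"):
        x = grp["log2"].to_numpy(float)
        if x.size < 3:
            continue
        a, b = x[:-1], x[1:]
        if a.std() < 1e-12 or b.std() < 1e-12:
            warnings.warn(f"chromosome {chrom} has zero variance; "
                          "excluded from MAC", stacklevel=2)
            continue
        acs.append(float(np.corrcoef(a, b)[0, 1]))
    if not acs:
        raise ValueError("MAC needs at least one chromosome with >= 3 probes "
                         "and non-zero variance")
    return float(np.median(acs))


def qc_sample(track: pd.DataFrame) -> QCMetrics:
    """Both array QC metrics for one sample's log2 track."""
    return QCMetrics(mapd=compute_mapd(track), mac=compute_mac(track))


def merge_close_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge neighbouring segments whose probe-level means are within 3 s.d.

    ``segments`` needs columns ``chrom, start, end, mean_log2, sd_log2,
    n_probes`` and must be sorted and non-overlapping within chromosomes.
    Two immediate neighbours merge when their mean difference is below
    three pooled standard deviations; merging repeats left-to-right until
    a fixed point, recomputing pooled statistics each time.  The genome
    span is preserved (merging only coarsens the partition).
    """
    required = {"chrom", "start", "end", "mean_log2", "sd_log2", "n_probes"}
    if not required.issubset(segments.columns):
        raise ValueError(f"segment table needs columns {sorted(required)}")
    out = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        segs = grp.sort_values("start").to_dict("records")
        changed = True
        while changed:
            changed = False
            i = 0
            while i + 1 < len(segs):
                a, b = segs[i], segs[i + 1]
                na, nb = a["n_probes"], b["n_probes"]
                pooled_var = (((na - 1) * a["sd_log2"] ** 2
                               + (nb - 1) * b["sd_log2"] ** 2)
                              / max(na + nb - 2, 1))
                pooled_sd = float(np.sqrt(pooled_var))
                if abs(a["mean_log2"] - b["mean_log2"]) < 3 * pooled_sd:
                    mean = (na * a["mean_log2"] + nb * b["mean_log2"]) / (na + nb)
                    # pooled variance about the combined mean
                    ss = ((na - 1) * a["sd_log2"] ** 2
                          + (nb - 1) * b["sd_log2"] ** 2
                          + na * (a["mean_log2"] - mean) ** 2
                          + nb * (b["mean_log2"] - mean) ** 2)
                    segs[i] = dict(chrom=chrom, start=a["start"], end=b["end"],
                                   mean_log2=mean,
                                   sd_log2=float(np.sqrt(ss / max(na + nb - 1, 1))),
                                   n_probes=na + nb)
                    del segs[i + 1]
                    changed = True
                else:
                    i += 1
        out.extend(segs)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "mean_log2",
                                      "sd_log2", "n_probes"])


def _segment_key(profiles: pd.DataFrame) -> pd.Series:
    return (profiles["chrom"].astype(str) + ":" + profiles["start"].astype(str)
            + "-" + profiles["end"].astype(str))


def masked_loci(profiles: pd.DataFrame) -> pd.DataFrame:
    """Segments hitting the integer-caller cap (total 8 or major > 4) in any
    sample: (chrom, start, end) rows to exclude."""
    seg = profiles.assign(_key=_segment_key(profiles))
    bad = seg[(seg["total"] >= TOTAL_CAP) | (seg["major"] > MAJOR_CAP)]
    return (bad[["chrom", "start", "end"]]
            .drop_duplicates()
            .reset_index(drop=True))


def mask_high_copy(profiles: pd.DataFrame, high_ploidy: bool = False
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove capped segments from every matched sample of one patient.

    For a non-high-ploidy patient, any segment with total copy number 8
    (the caller's cap) or major allele count > 4 in any sample is removed
    from all samples, since the capped value hides the true state.  For
    high-ploidy patients the rule is skipped (their genomes legitimately
    live near the cap) and the table is returned unchanged.

    Returns ``(masked_profiles, masked_segments)``; the second table lists
    the excluded loci so SNVs falling inside them can be dropped from CCF
    estimation.
    """
    required = {"sample", "chrom", "start", "end", "total", "major", "minor"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")
    if high_ploidy:
        return profiles.copy(), profiles.iloc[0:0][["chrom", "start", "end"]]
    bad = masked_loci(profiles)
    if bad.empty:
        return profiles.copy(), bad
    bad_keys = set(_segment_key(bad))
    keep = ~_segment_key(profiles).isin(bad_keys)
    return profiles[keep].reset_index(drop=True), bad
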
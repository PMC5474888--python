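"""Cancer cell fraction estimation from deep read counts.

For an SNV on ``s_q`` of the ``q_2`` major copies at a locus with total
tumour copy number ``q_t``, in a sample with cancer cell fraction
``alpha``, the expected variant allele fraction is

    f(s_q, alpha) = s_q * alpha / (q_t * alpha + 2 * (1 - alpha))

(the denominator counts alleles per cell averaged over tumour and diploid
normal cells).  Sequencing error ``e`` misreads a base to one specific
alternate with probability ``e/3``, giving the observation success
probability ``f*(1-e) + (1-f)*e/3``.  Read counts are modelled binomially
(an optional beta-binomial switch adds overdispersion).

Two estimators are provided: a pointwise per-SNV estimate (posterior over
s_q with a uniform prior and inversion of the VAF relation at the
posterior mode), and a global per-sample alpha maximising a mixture
likelihood over all usable tier-4 SNVs, where mixture weights over s_q
are iterated to convergence at each alpha on a grid (0.02..1.00, step
0.01 by default).  Clonal frequency of an SNV is the ratio of its
pointwise alpha to the sample's global alpha, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnvCopyState",
    "PointwiseEstimate",
    "CCFEstimate",
    "expected_vaf",
    "error_adjusted",
    "pointwise_ccf",
    "global_ccf",
    "weight_iteration_trace",
    "clonal_frequency",
    "detection_power",
    "PatientClonality",
    "estimate_clonal_frequencies",
    "pyclone_export",
]

DEFAULT_ERROR = 0.01
DEFAULT_GRID = np.round(np.arange(0.02, 1.0 + 1e-9, 0.01), 2)
MAX_ITER = 100
LOGLIK_TOL = 1e-6


@dataclass
class SnvCopyState:
    """Read counts plus local allele-specific copy state for one SNV."""

    x: int          # variant reads
    n: int          # total reads
    q_t: int        # total copies
    q1: int         # minor
    q2: int         # major

    def __post_init__(self):
        if not 0 <= self.x <= self.n:
            raise ValueError("need 0 <= X <= n")
        if self.q2 < self.q1 or self.q1 < 0:
            raise ValueError("need q2 >= q1 >= 0")
        if self.q_t != self.q1 + self.q2:
            raise ValueError("need q_t = q1 + q2")
        if self.q2 < 1:
            raise ValueError("an SNV needs at least one major copy (q2 >= 1)")


@dataclass
class PointwiseEstimate:
    posterior: np.ndarray      # over s_q = 1..q2, sums to 1
    s_mode: int
    alpha_point: float
    saturated: bool = False


@dataclass
class CCFEstimate:
    """Global per-sample CCF with its likelihood trace over the alpha grid."""

    alpha: float
    grid: np.ndarray
    loglik: np.ndarray          # converged log-likelihood per grid point
    n_snvs: int
    pointwise: list[PointwiseEstimate] = field(default_factory=list)


def expected_vaf(s_q: float, q_t: float, alpha: float) -> float:
    """Expected VAF of a mutation on ``s_q`` copies at CCF ``alpha``."""
    if alpha <= 0 or alpha > 1:
        raise ValueError("alpha must lie in (0, 1]")
    denom = q_t * alpha + 2.0 * (1.0 - alpha)
    if denom <= 0:
        raise ValueError("degenerate copy state: no sequenceable alleles")
    return s_q * alpha / denom


def error_adjusted(f, e: float = DEFAULT_ERROR):
    """Success probability after uniform sequencing error: misreads hit the
    specific alternate base with probability e/3."""
    f = np.asarray(f, dtype=float)
    out = f * (1.0 - e) + (1.0 - f) * e / 3.0
    return float(out) if out.ndim == 0 else out


def invert_vaf(f_hat: float, s_q: int, q_t: int) -> tuple[float, bool]:
    """Solve f = s*a / (q_t*a + 2(1-a)) for alpha; returns (alpha, saturated)."""
    denom = s_q - f_hat * q_t + 2.0 * f_hat
    if denom <= 0:
        return 1.0, True
    alpha = 2.0 * f_hat / denom
    if alpha > 1.0:
        return 1.0, True
    return max(alpha, 0.0), False


def _log_binom(x: int, n: int, p: np.ndarray, overdispersion: float | None
               ) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if overdispersion is None:
        return stats.binom.logpmf(x, n, p)
    # beta-binomial with precision parameter rho: a = p*rho, b = (1-p)*rho
    rho = overdispersion
    return stats.betabinom.logpmf(x, n, p * rho, (1 - p) * rho)


def pointwise_ccf(snv: SnvCopyState, alpha_plugin: float,
                  e: float = DEFAULT_ERROR,
                  overdispersion: float | None = None) -> PointwiseEstimate:
    """Per-SNV multiplicity posterior and point CCF.

    With a uniform prior over s_q in {1..q2}, the posterior is the
    normalised binomial likelihood of the read counts at the
    error-adjusted expected VAF given the plug-in ``alpha_plugin`` (from
    the matched array or the global estimate).  The point CCF inverts the
    VAF relation at the posterior-mode s_q, using the de-noised observed
    VAF; an infeasible inversion saturates at alpha = 1 with a flag.
    """
    s_values = np.arange(1, snv.q2 + 1)
    f = np.array([expected_vaf(s, snv.q_t, alpha_plugin) for s in s_values])
    loglik = _log_binom(snv.x, snv.n, error_adjusted(f, e), overdispersion)
    post = np.exp(loglik - loglik.max())
    post /= post.sum()
    s_mode = int(s_values[int(np.argmax(post))])

    raw = snv.x / snv.n
    scale = 1.0 - e - e / 3.0
    f_hat = min(max((raw - e / 3.0) / scale, 0.0), 1.0) if scale > 0 else raw
    alpha_point, saturated = invert_vaf(f_hat, s_mode, snv.q_t)
    return PointwiseEstimate(posterior=post, s_mode=s_mode,
                             alpha_point=alpha_point, saturated=saturated)


def weight_iteration_trace(snvs: list[SnvCopyState], alpha: float,
                           e: float = DEFAULT_ERROR,
                           overdispersion: float | None = None,
                           max_iter: int = MAX_ITER) -> list[float]:
    """Log-likelihood after each weight-update round at fixed alpha.

    The responsibilities update never decreases the mixture likelihood,
    so the returned sequence is non-decreasing (up to float noise).
    """
    trace: list[float] = []
    _converged_loglik(snvs, alpha, e, overdispersion, max_iter, trace)
    return trace


def _converged_loglik(snvs: list[SnvCopyState], alpha: float, e: float,
                      overdispersion: float | None,
                      max_iter: int = MAX_ITER,
                      trace: list[float] | None = None) -> float:
    """Mixture log-likelihood at ``alpha`` after iterating the s_q weights.

    Weights start uniform per SNV and are replaced by the normalised
    responsibilities each round, which never decreases the likelihood;
    iteration stops when the change drops below 1e-6 or after
    ``max_iter`` rounds.
    """
    logB = []   # per-SNV array of component log-likelihoods
    for snv in snvs:
        s_values = np.arange(1, snv.q2 + 1)
        f = np.array([expected_vaf(s, snv.q_t, alpha) for s in s_values])
        logB.append(_log_binom(snv.x, snv.n, error_adjusted(f, e),
                               overdispersion))
    # single-multiplicity loci (q2 = 1) have no mixture to iterate
    fixed = sum(float(lb[0]) for lb in logB if len(lb) == 1)
    mixed = [lb for lb in logB if len(lb) > 1]
    if not mixed:
        if trace is not None:
            trace.append(fixed)
        return fixed
    weights = [np.full(len(lb), 1.0 / len(lb)) for lb in mixed]
    total = fixed
    prev = -np.inf
    for _ in range(max_iter):
        total = fixed
        new_weights = []
        for w, lb in zip(weights, mixed):
            m = lb.max()
            mix = w * np.exp(lb - m)
            z = mix.sum()
            total += m + np.log(z)
            new_weights.append(mix / z)
        weights = new_weights
        if trace is not None:
            trace.append(total)
        if abs(total - prev) < LOGLIK_TOL:
            break
        prev = total
    return total


def global_ccf(snvs: list[SnvCopyState],
               alpha_grid: np.ndarray | None = None,
               e: float = DEFAULT_ERROR,
               overdispersion: float | None = None,
               min_snvs: int = 5) -> CCFEstimate:
    """Global sample CCF maximising the mixture likelihood over its SNVs.

    SNVs at masked loci must be excluded by the caller (see
    :func:`metaphylo.arrayqc.mask_high_copy`).  Requires at least
    ``min_snvs`` usable SNVs.
    """
    if len(snvs) < min_snvs:
        raise ValueError(f"global CCF needs >= {min_snvs} usable SNVs, "
                         f"got {len(snvs)}")
    grid = DEFAULT_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    loglik = np.array([_converged_loglik(snvs, a, e, overdispersion)
                       for a in grid])
    alpha = float(grid[int(np.argmax(loglik))])
    pointwise = [pointwise_ccf(snv, alpha, e, overdispersion) for snv in snvs]
    return CCFEstimate(alpha=alpha, grid=grid, loglik=loglik,
                       n_snvs=len(snvs), pointwise=pointwise)


def clonal_frequency(alpha_point: float, alpha_global: float) -> float:
    """Fraction of cancer cells carrying the SNV: min(1, alpha_point/alpha)."""
    if alpha_global <= 0:
        raise ValueError("global alpha must be positive")
    return min(1.0, alpha_point / alpha_global)


@dataclass
class PatientClonality:
    """Per-sample global CCFs plus the samples x SNVs clonal-frequency matrix."""

    alpha: dict[str, float]
    frequencies: pd.DataFrame           # NaN where the SNV had no usable state
    estimates: dict[str, CCFEstimate] = field(default_factory=dict)


def _locate_segment(profiles: pd.DataFrame, sample: str, chrom: str, pos: int):
    rows = profiles[(profiles["sample"] == sample)
                    & (profiles["chrom"].astype(str) == str(chrom))
                    & (profiles["start"] <= pos) & (profiles["end"] >= pos)]
    return None if rows.empty else rows.iloc[0]


def estimate_clonal_frequencies(variants: pd.DataFrame,
                                profiles: pd.DataFrame,
                                e: float = DEFAULT_ERROR,
                                present_cutoff: float = 0.03,
                                alpha_grid: np.ndarray | None = None,
                                overdispersion: float | None = None
                                ) -> PatientClonality:
    """Full CCF chain for one patient's tier-4 variant table.

    ``variants`` is the long read-count table (columns ``sample, chrom,
    pos, ref_reads, alt_reads`` and ``snv_id`` or locus columns);
    ``profiles`` the matched allele-specific segment table, already
    masked for capped loci.  Per sample, the global alpha is fitted on
    the SNVs called present, then every present SNV gets a pointwise CCF
    and a clonal frequency; absent SNVs get frequency 0 and SNVs with no
    usable copy state get NaN.
    """
    variants = variants.copy()
    if "snv_id" not in variants.columns:
        variants["snv_id"] = (variants["chrom"].astype(str) + ":"
                              + variants["pos"].astype(str))
    snv_ids = list(dict.fromkeys(variants["snv_id"]))
    samples = list(dict.fromkeys(variants["sample"]))
    freqs = pd.DataFrame(np.nan, index=samples, columns=snv_ids)
    alphas: dict[str, float] = {}
    estimates: dict[str, CCFEstimate] = {}
    for sample, grp in variants.groupby("sample", sort=False):
        usable: list[tuple[str, SnvCopyState, bool]] = []
        for _, row in grp.iterrows():
            depth = int(row["ref_reads"] + row["alt_reads"])
            if depth == 0:
                continue
            seg = _locate_segment(profiles, sample, row["chrom"], int(row["pos"]))
            if seg is None or seg["major"] < 1:
                continue
            state = SnvCopyState(x=int(row["alt_reads"]), n=depth,
                                 q_t=int(seg["total"]), q1=int(seg["minor"]),
                                 q2=int(seg["major"]))
            present = state.x / state.n >= present_cutoff
            usable.append((row["snv_id"], state, present))
        present_states = [s for _, s, p in usable if p]
        if len(present_states) < 5:
            warnings.warn(f"sample {sample}: fewer than 5 present SNVs with "
                          "copy states; no global CCF", stacklevel=2)
            continue
        est = global_ccf(present_states, alpha_grid=alpha_grid, e=e,
                         overdispersion=overdispersion)
        alphas[sample] = est.alpha
        estimates[sample] = est
        for snv_id, state, present in usable:
            if not present:
                freqs.loc[sample, snv_id] = 0.0
                continue
            pw = pointwise_ccf(state, est.alpha, e, overdispersion)
            freqs.loc[sample, snv_id] = clonal_frequency(pw.alpha_point,
                                                         est.alpha)
    return PatientClonality(alpha=alphas, frequencies=freqs,
                            estimates=estimates)


def pyclone_export(variants: pd.DataFrame, profiles: pd.DataFrame
                   ) -> pd.DataFrame:
    """Variant table in the TSV layout expected by external DP-clustering
    tools (mutation_id, ref/var counts, normal and parental copy numbers)."""
    rows = []
    for _, row in variants.iterrows():
        seg = _locate_segment(profiles, row["sample"], row["chrom"],
                              int(row["pos"]))
        if seg is None:
            continue
        rows.append(dict(mutation_id=row.get("snv_id",
                                             f"{row['chrom']}:{row['pos']}"),
                         sample_id=row["sample"],
                         ref_counts=int(row["ref_reads"]),
                         var_counts=int(row["alt_reads"]),
                         normal_cn=2, minor_cn=int(seg["minor"]),
                         major_cn=int(seg["major"])))
    return pd.DataFrame(rows)


def detection_power(n: int, expected_f: float,
                    present_threshold: float = 0.03,
                    e: float = DEFAULT_ERROR) -> float:
    """Probability a present mutation clears the VAF presence cut-off.

    The chance that Binomial(n, error-adjusted expected_f) reads reach a
    VAF of ``present_threshold``.  Used to decide whether an absence call
    is trustworthy: a predicted reversion is only asserted where the power
    to detect the mutation, had it been present, is high.
    """
    if n < 1:
        raise ValueError("need at least one read")
    p = error_adjusted(expected_f, e)
    k = int(np.ceil(present_threshold * n))
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))
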
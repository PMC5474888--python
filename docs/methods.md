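# Methods

`metaphylo` reconstructs the dissemination history of a metastatic cancer
from multi-sample data of two kinds: ultra-deep targeted read counts at
validated somatic SNVs, and allele-specific integer copy-number segments
from SNP arrays.  This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Evolutionary model

Each patient's samples (primary tumour regions and metastases) are leaves
of a rooted clone tree whose root is the germline.  Somatic SNVs arise
once on a branch and are inherited below it; a mutation can only
*disappear* again when a copy-number loss deletes the mutated allele
(a reversion).  Copy-number aberrations are segmental: an event adds or
removes one copy of one allele over a contiguous run of segments, and an
allele at zero copies can never be regained.  A whole-genome duplication
doubles every allele at one point on one branch.

## SNV presence calls and the tier filters (`tiers`)

Ultra-deep amplicon sequencing of FFPE material shows every base at low
frequency, so presence calls need a floor.  The background is estimated
from flanking positions around validated SNVs: positions with more than
10% non-reference reads are treated as SNPs/secondary variants and
excluded, and the rest are pooled per substitution class (AT>CG, AT>GC,
AT>TA, CG>AT, CG>GC, CG>TA).  The presence cut-off itself is a fixed
configuration value, 3% VAF by default — a deliberately conservative
margin above backgrounds this kind of assay produces — rather than a
per-run derived quantity.

The tier-3 filters are applied jointly to all matched samples of one
patient, in a fixed order: (1) cells with coverage not **exceeding**
1,500× become missing (the rule is exclusive: exactly 1,500× is
missing); (2) samples with under 75% observed cells are dropped; (3)
SNVs missing in more than one retained sample are dropped; (4) SNVs
absent (<3%) in every retained sample are dropped; (5) samples with at
most 20% of the surviving SNVs present are dropped, as a guard against
very low cellularity.  Presence (≥3%) and the tier-4 CCF floor (≥30%)
are inclusive thresholds.  The filter order is applied once, not
re-iterated after SNV removal.  Tier 0–2 (exome indexing, somatic
status, orthogonal validation) are provenance flags carried on input
records, not recomputed.

## CCF and clonal frequencies (`ccf`)

For a mutation on `s_q` of the `q_2` major copies at a locus with total
tumour copy `q_t`, in a sample with cancer cell fraction `α`, the
expected VAF is

    f(s_q, α) = s_q·α / (q_t·α + 2·(1 − α)),

the denominator being the mean number of allele copies per cell over
tumour and diploid normal cells.  Sequencing error `e` (default 0.01)
misreads a base to one *specific* alternate with probability `e/3`, so
the observation probability is `f·(1−e) + (1−f)·e/3`.  Read counts are
modelled binomially on counts; an optional beta-binomial precision
parameter adds overdispersion for noisier assays (off by default, and
off in all tests).

* **Pointwise estimate** — uniform prior over `s_q ∈ {1..q_2}`, posterior
  ∝ binomial likelihood; the point CCF inverts the VAF relation at the
  posterior-mode multiplicity, `α̂ = 2f̂/(s_q − f̂·q_t + 2f̂)`, using the
  de-noised observed VAF and clipping to (0, 1] with a saturation flag.
* **Global estimate** — the per-sample `α` maximises a mixture likelihood
  over all usable present SNVs; at each `α` on a grid (0.02–1.00, step
  0.01, finer than the recovery tolerance) the per-SNV multiplicity
  weights are replaced by their responsibilities until the log-likelihood
  moves by less than 1e-6 or 100 rounds pass.  This update never
  decreases the likelihood.  SNVs at masked high-copy loci are excluded;
  at least five usable SNVs are required.
* **Clonal frequency** — `min(1, α̂_point/α)`; a value near 1 means the
  mutation is carried by essentially all cancer cells in the sample.
* **Detection power** — the probability that a binomial draw at the
  locus's depth and error-adjusted expected VAF clears the 3% presence
  cut-off; used to refuse reversion calls that could be coverage
  artefacts.

Joint Dirichlet-process clustering of clonal frequencies across samples
is out of scope; the ratio above is the package's clonal-frequency
definition, and an export in the TSV layout expected by external
clustering tools is provided for users who want that analysis.

## Array QC and profile hygiene (`arrayqc`)

MAPD is the genome-wide median of |adjacent probe log2 differences|
(pairs taken within chromosomes); MAC is the median across chromosomes
of the lag-1 Pearson autocorrelation of the log2 track — lag 1 is the
standard choice for detecting wavy FFPE profiles.  A sample fails QC iff
MAPD > 0.7 or MAC > 0.3 (boundary values pass).  Neighbouring segments
whose probe-level means differ by less than three pooled standard
deviations are merged left-to-right until a fixed point; merging only
coarsens the partition, never changes the genome span.  Because the
integer caller caps totals at 8, any segment reaching total 8 or major
allele > 4 in any sample is removed from all matched samples — except in
declared high-ploidy patients, whose genomes legitimately live near the
cap — and SNVs at such loci are excluded from CCF estimation.
Multi-track segmentation and integer calling are external upstream
steps: profiles enter this package pre-segmented with shared breakpoints.

## SNV phylogenies under Dollo parsimony (`dollo`)

Characters are the tier-3 binary calls; the outgroup is an all-absent
germline ancestor.  The score of a topology is the total number of
losses (each character gains exactly once, at the smallest clade
containing its present leaves; each maximal clade below it with absent
but no present leaves costs one loss; missing calls are uninformative —
they never force a loss and never anchor a gain).  The search is
stepwise leaf addition with branch-and-bound: the score of a partial
tree, computed on characters restricted to the inserted leaves, is a
lower bound on any completion, so pruning is exact.  *All* co-optimal
rooted topologies are returned; ties are broken by minimum unrooted
Robinson–Foulds distance to the patient's CNA tree, then by
lexicographic Newick order so the choice is deterministic.  Exhaustive
search is the default up to 9 leaves; beyond that the caller must opt
into a greedy flagged heuristic.

Ancestral states are reconstructed by accelerated transformation: the
gain is pushed rootward through purely-missing siblings, losses cut the
maximal all-absent clades, and branch lengths are the per-branch event
counts (gains + losses), so re-scoring the reconstruction reproduces the
search score exactly.

A predicted reversion is cross-examined in two steps.  First the
counterfactual is priced: the detection power in each affected sample is
computed for a single-copy mutation at the sample's CCF and the locus's
copy state *in the samples that do carry the mutation* — the question
being whether presence would have been seen, not whether the post-loss
state is visible.  Absences with power below 0.95 are reported as
possible false negatives, never as reversions.  Second, the affected
samples' profiles are compared with carriers at the SNV's locus: a total
or minor-allele decrease (or an allele at zero where carriers retain it)
annotates the reversion as supported; otherwise it is reported
unexplained.

## CNA phylogenies and WGD rooting (`cnaphylo`)

The directed distance between two allele vectors is the minimum number
of segmental ±1 events, with zero-copy loci acting as barriers; it is
computed in closed form from the run-length structure of the positive
and negative parts of the difference vector, and is validated against a
breadth-first-search oracle in the state graph.  Note that 2→0 at one
locus costs two events — every event moves one copy.  The symmetric
dissimilarity between two profiles minimises, over a common ancestor
profile, the events from the ancestor to each profile; because the
directed cost is a sum of terms local in consecutive loci, this
minimisation is an exact chain dynamic programme over ancestor states
0–8, per allele.

Trees are found by exhaustive search over rooted topologies (≤7 leaves;
beyond that a neighbour-joining topology is refitted and flagged),
scoring each by a per-locus, per-allele Sankoff dynamic programme with
edge cost |parent − child|, states 0–8, 0→positive forbidden, and the
root held at the outgroup profile — uniform 2/1 for near-diploid
patients.  The trunk is a real edge: the cancer MRCA's state is free.
Counting per locus treats an event spanning k adjacent segments as k
events; this is the package's documented approximation relative to a
full multi-locus transducer alignment, and the synthetic data plants
single-segment events so the approximation is exact on its own tests.

For tetraploid patients, the diploid-rooted tree supplies the topology
only, and the root is re-chosen among the four post-duplication
ancestral states 6/4, 4/2, 4/4 and 2/2 (total/major).  Each candidate
re-scores the tree with internal states restricted to the integer range
spanned by the observed copies and the root (the generalisation chosen
where "observed values" is ambiguous: intermediate integers are
allowed).  The minimum-score candidate wins; ties add the
pre-duplication event cost — the distance from diploid 2/1 to the halved
states 3/2, 2/1, 2/2, 1/1, i.e. 1, 0, 2 and 1 — and any residual tie
falls back to the fixed candidate order.  Loci infeasible under every
candidate are excluded with a warning.

Support values: the pairwise dissimilarity matrix is perturbed 100 times
with i.i.d. Gaussian noise (s.d. 1 event by default; the choice is a
free parameter), re-symmetrised and floored at zero; a neighbour-joining
tree is rebuilt from each perturbed matrix and support is the fraction
of rebuilds containing each original bipartition.  The zero-noise
guarantee (all supports 1) holds when the reference tree is itself the
NJ tree of the matrix; for the parsimony tree the support quantifies
agreement between the distance geometry and the parsimony topology.

## Progression metrics (`metrics`)

* **Normalized branch length** — per lesion, path(cancer-MRCA → leaf)
  divided by the trunk (root → cancer-MRCA).  The trunk is defined
  *excluding* nothing: it is the full path from the outgroup attachment
  to the first divergence; the outgroup's own pendant edge has length 0
  by construction, so the ambiguity of whether to include it is moot.
  Patient means are compared with overall survival by Spearman rank
  correlation (≥4 patients required).
* **Substitution spectra** — six pyrimidine-strand classes split by
  phase: *early* = gained on the trunk, *late* = gained below the cancer
  MRCA.  The fraction of C>T events at NpCpG trinucleotides (context
  normalised to the pyrimidine strand) is the APOBEC-style read-out; no
  96-context signature deconvolution is attempted.
* **Pairwise configurations** — per SNV and ordered sample pair, each
  sample's state is clonal (frequency ≥ 0.8), subclonal (≥ 0.1), or
  absent.  The 0.8 cut-off operationalises "fully clonal" (no number is
  canonical; it is configurable), and the 0.1 floor keeps error-level
  frequencies out of the subclonal class.  Configurations i–v are
  tree-compatible; vi/vii (clonal in one sample, subclonal in the other)
  are not.  A cross-seeding call (donor → recipient) requires at least
  k = 5 supporting SNVs clonal in the donor, subclonal in the recipient
  and absent elsewhere, *and* at least one private clonal SNV in the
  recipient (ruling out simple descent).  k = 5 separates a genuine
  seeded segment (~a dozen SNVs) from the one-to-three stray mutations
  that boundary noise produces.

## Synthetic data (`simulate`)

The generator draws a uniform random binary topology over the samples,
attaches a germline outgroup, and plants: a fixed number of truncal SNVs
(default 30) and Poisson numbers of private SNVs per branch (mean 8);
truncal and branch segmental CNA events (defaults 5 and Poisson 1.5,
70% gains) over 20 segments; optional WGD on the trunk; optional
cross-seeding (a fixed 0.3 fraction of the donor's private SNVs
appearing subclonally in the recipient); and, with probability
`loh_probability` per SNV, an LOH event on a descendant branch deleting
the mutated allele — a planted reversion.  Per-sample CCFs are uniform
on a configurable range (default 0.4–1.0, above the tier-4 floor).
Depth is Poisson around `depth_mean` (default 9,000×, the ultra-deep
targeted regime) floored at 100; variant reads are binomial at the
error-adjusted expected VAF; mutated-copy counts follow the planted
events (a gain duplicates the mutated copy with probability s/cn, a loss
removes it with the same probability), and mutation allele assignments
are resolved against the lineage so a mutation never arises on an allele
already lost.

Two deliberate departures from full realism, both in the direction of
testability: planted reversions are restricted to branches whose removal
keeps the surviving carriers straddling at least two children of the
gain node (otherwise parsimony would rightly prefer a later gain and the
reversion is unidentifiable in principle), and to SNVs that are alone on
their (segment, allele) slot, so each planted event creates exactly one
reversion character rather than a cluster.  Real FFPE data also carries
position-correlated noise, germline contamination and segmentation
error that the generator does not emulate; passing tests therefore
demonstrate correctness of the inference machinery under the stated
model, not robustness to every artefact of real arrays and amplicons.

## Problem sizes and numerics

The test and acceptance workloads run at desk scale by choice: 4–5
samples per patient, tens of SNVs, 20–40 segments, depths 2,000–5,000×,
15–150 simulated patients per property.  Exhaustive searches are exact
at these sizes (Dollo ≤ 9 leaves, CNA ≤ 7 leaves); both searches refuse
larger inputs unless a flagged heuristic is requested.  Ties everywhere
break deterministically (lexicographic Newick; fixed WGD candidate
order; DP backtrace prefers the child state closest to the parent).  All
randomness flows from explicit integer seeds.

## Known limitations

* Clonal frequencies are per-sample ratios, not joint multi-sample
  cluster assignments; borderline mutations near the 0.8 cut-off can
  flip configuration classes.
* The per-locus event counting undercounts multi-segment events relative
  to a transducer alignment (affects branch lengths, not topology, when
  events are segment-local).
* Reversion clusters (one LOH wiping many co-located SNVs), present in
  real tumours, weaken SNV-topology inference at desk scale; the
  generator avoids planting them, and on real data the CNA tree is the
  intended tie-breaker.
* MAPD is computed genome-wide (pooled across chromosomes), one of two
  defensible conventions.
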
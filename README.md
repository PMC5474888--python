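# metaphylo

Phylogenetic inference of metastatic dissemination patterns from
multi-sample tumour sequencing and copy-number data.

When several lesions of one cancer patient — primary tumour regions and
metastases — are profiled with ultra-deep targeted sequencing of somatic
SNVs and allele-specific copy-number arrays, their evolutionary history
can be reconstructed: which lesion seeded which, whether all metastases
descend from a single "metastatic precursor" clone or from several
independent seedings, and whether an established metastasis was
horizontally cross-seeded by another.  `metaphylo` implements that whole
computational chain as a tested, reusable library with a thin CLI, for
researchers analysing multi-region/multi-lesion cohorts and for
methodologists who need a transparent, oracle-checked reference
implementation.

## What it computes

1. **Tiered SNV filtering** (`metaphylo.tiers`) — background-noise
   estimation from flanking positions, presence calls at a 3% VAF
   cut-off, joint coverage/missingness filters (>1,500×, ≥75%
   non-missing per sample, ≤1 missing cell per SNV, >20% present per
   sample), and tier-4 promotion for samples with cancer cell fraction
   ≥ 30%.
2. **Array QC and masking** (`metaphylo.arrayqc`) — MAPD and MAC noise
   metrics (fail if MAPD > 0.7 or MAC > 0.3), 3-s.d. segment merging,
   and removal of capped loci (total copy 8 or major allele > 4).
3. **CCF estimation** (`metaphylo.ccf`) — for an SNV on `s_q` of `q_2`
   major copies at a locus with total copy `q_t` in a sample with cancer
   cell fraction `α`, the expected VAF is

       f(s_q, α) = s_q·α / (q_t·α + 2(1 − α)),

   observed through a binomial with error-adjusted success probability
   `f(1−e) + (1−f)e/3`.  A per-sample global `α` maximises a mixture
   likelihood over multiplicities on a grid; clonal frequency is
   `min(1, α̂_point/α)`; binomial tail powers certify absence calls.
4. **Dollo SNV phylogenies** (`metaphylo.dollo`) — exhaustive
   branch-and-bound over rooted topologies minimising the number of
   mutation losses (each SNV gained once, all-absent germline outgroup),
   all co-optimal trees returned, CNA-tree tie-breaking, ACCTRAN
   ancestral states, and reversion verification against LOH with
   detection-power guards.
5. **Minimum-event CNA phylogenies** (`metaphylo.cnaphylo`) — segmental
   ±1 event distances (no gain from zero), exact per-locus dynamic
   programming over internal states, diploid 2/1 rooting, tetraploid
   rooting over the four post-WGD ancestors 6/4, 4/2, 4/4, 2/2 with
   pre-duplication tie-break costs 1, 0, 2, 1, and Gaussian-resampling
   bipartition support.
6. **Progression metrics** (`metaphylo.metrics`) — normalized branch
   lengths (path from the cancer MRCA to each lesion over the trunk)
   and their Spearman correlation with survival, early/late substitution
   spectra with an NpCpG C>T read-out, and pairwise clonal-frequency
   configurations that flag horizontal cross-seeding.
7. **Synthetic cohorts** (`metaphylo.simulate`) — a seeded generator of
   ground-truth clone trees with truncal/branch SNVs and CNAs, planted
   LOH reversions, optional WGD and cross-seeding, binomial read counts
   at configurable depth and error — the substrate for every test in the
   suite.

## Worked example

```python
from metaphylo.simulate import (SimulationConfig, simulate_patient,
                                emit_read_counts, emit_cna_profiles)
from metaphylo.tiers import apply_tier3_filters
from metaphylo.dollo import dollo_search, acctran_reconstruct
from metaphylo.cnaphylo import build_cna_tree
from metaphylo.metrics import normalized_branch_lengths

cfg = SimulationConfig(n_samples=4, seed=3, depth_mean=3000,
                       error_rate=0.0, ccf_range=(0.9, 1.0))
truth = simulate_patient(cfg)
counts = emit_read_counts(truth, cfg)

matrix = apply_tier3_filters(counts)          # tier-3 presence calls
result = dollo_search(matrix)                 # all minimum-loss trees
rec = acctran_reconstruct(result.trees[0], matrix)
cna = build_cna_tree(emit_cna_profiles(truth))
summary = normalized_branch_lengths(rec.tree)

print("dollo score:", result.score, "co-optimal trees:", len(result.trees))
print("snv tree:", rec.tree.to_newick())
print("cna total events:", cna.total_events)
print("mean normalized branch length:", round(summary.mean, 3))
```

prints

```
dollo score: 0 co-optimal trees: 1
snv tree: (N:0,(((M1:7,M2:13)n3:3,P:10)n2:9,M3:9)n1:28)root;
cna total events: 17.0
mean normalized branch length: 0.643
```

The Dollo score of 0 says this patient's presence/absence matrix is
perfectly tree-like: a single topology explains every SNV with one gain
and no losses.  The Newick string is the rooted SNV tree: branch
lengths are event counts, `N` the germline outgroup, so 28 truncal SNVs
separate the germline from the cancer MRCA and the M1/M2 clade is the
most derived.  The mean normalized branch length of 0.643 says the
average lesion carries almost two-thirds of a trunk's worth of private
evolution — a late, diverged pattern rather than an early star-burst.

A shell version of the same chain:

```
metaphylo simulate --outdir out --seed 3
metaphylo tiers     --variants out/variants.tsv --out out/matrix.tsv
metaphylo phylo-cna --segments out/segments.tsv --out out/cna
metaphylo phylo-snv --matrix out/matrix.tsv --cna-tree out/cna/cna_tree.nwk --out out/snv
metaphylo ccf       --variants out/variants.tsv --segments out/segments.tsv --out out/ccf
metaphylo metrics   --tree out/snv/snv_tree.nwk --ccf-table out/ccf/clonal_frequencies.tsv --out out/metrics
```

## Layout

```
src/metaphylo/
  simulate.py    synthetic clone-tree cohorts (ground truth + read counts)
  tiers.py       tiered SNV filtering
  arrayqc.py     SNP-array QC, segment merging, high-copy masking
  ccf.py         CCF, clonal frequency, detection power
  dollo.py       Dollo parsimony search, ACCTRAN, reversion verification
  cnaphylo.py    event distances, CNA trees, WGD rooting, support values
  metrics.py     branch-length, spectrum and cross-seeding metrics
  trees.py       rooted trees, Newick, Robinson–Foulds, topology enumeration
  io.py, cli.py  tab-separated interchange formats and the CLI
docs/methods.md  model assumptions, parameter choices, limitations
```
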
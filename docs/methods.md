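# Methods

## Coordinate model

All internal coordinates are 0-based half-open; 1-based `m.####`
coordinates appear only at I/O boundaries (configuration files, VCF,
reports). The genome is a circle of length `l`; the custom reference for a
cut at 0-based position `x` is `R[l−d:] + R + R + R[:d]` (length
`2(l + d)`) with every base outside the inclusive window `[x, x + l + 2d]`
masked to `N`. The window keeps `d` bases of context on both copies of the
cut, so a read opened at the cut maps uniquely and in one piece whether it
is full or partial length; the masked base count is `l − 1` for every
cut-site. A custom-reference position collapses to the circle as
`x' = (x − d) mod l`, which is identical across cut-sites, so alignments
from different guides of one sample merge without coordinate translation.

A Cas9 break at 1-based position `c` opens the circle between `c − 1` and
`c`: plus-strand reads synthesise from `c` forward, minus-strand reads from
`c − 1` backward. A read start matches a cut-site if it lies at most
`tolerance_bp` (default 100) *after* the break in the direction of
synthesis, a read end if it lies at most `tolerance_bp` *before* it.

## Demultiplexing filters

A read is considered only if every PAF segment targets the mitochondrial
contig, at least one segment has mapping quality > 0, all segments share a
strand, the direction-adjusted genomic starts (rotated so the first
read-space segment is the origin) are non-decreasing, the traversed span is
at most one genome length, and segments cover at least `min_mapped_frac`
(default 0.90, operationalising "almost all of the read mapped") of the
read. Under `either`, a read whose start and end match *different*
cut-sites is rejected as ambiguous rather than assigned arbitrarily;
configurations with cut-sites closer than twice the tolerance produce a
warning. Secondary PAF records (`tp:A:S`) are ignored; all non-secondary
records of a read are treated as its segments, since PAF has no
supplementary flag.

## Error model and likelihood

Base quality `q` maps to error probability `e = min(10^(−q/10), e_cap)`
with `e_cap = 0.45`, and bases with `q < q_min = 5` are discarded. Both
bounds exist because the likelihood `p(f, e) = f(1−e) + (1−f)e` is
increasing in `f` only while `e < 1/2`; they matter only for pathological
inputs (q < 4). Deletion observations take the quality of the preceding
read base; an insertion is anchored at the preceding aligned base and forms
a combined `base+insertion` allele there whose quality is the minimum over
its component bases, so insertions never inflate site depth.

The per-site log likelihood over stratified counts `c_{i,j}` (allele `i`,
quality level `j`) is `L(f) = Σ c_{i,j} ln p(f_i, e_j)`, with
`f_0 = 1 − Σ_{i>0} f_i`. Score and expected information are

    S_i   = Σ_j (1 − 2e_j) (c_{i,j}/p(f_i,e_j) − c_{0,j}/p(f_0,e_j))
    I_ii  = Σ_j (1 − 2e_j)² c_j (1/p(f_i,e_j) + 1/p(f_0,e_j))
    I_ik  = Σ_j (1 − 2e_j)² c_j / p(f_0,e_j)        (k ≠ i)

with `c_j = Σ_i c_{i,j}` the per-level totals. Starting from raw allele
proportions, updates are `f' = f + a I⁻¹S` with `a ∈ {1, ½, ¼, …}`
backtracked until the likelihood does not decrease and all frequencies
(including `f_0`) stay non-negative; the step is additionally truncated at
the first boundary crossing. Iteration stops when no positive step
increases the likelihood or the relative log-likelihood change falls below
`tol = 1e−8` (at most `max_iter = 100` iterations; non-convergence flags
the estimate rather than raising).

Two boundary rules are needed for correctness at the constraint edges,
both verified against a brute-force grid maximiser on random sites:

* an allele at frequency 0 whose partial derivative is negative is fixed
  at 0 and removed from the maximisation;
* when the *baseline* frequency sits at 0 (reference allele essentially
  unobserved) and the unconstrained Newton step would push it negative,
  the equality-constrained (KKT) Newton step is taken instead, which moves
  mass only between the non-baseline alleles.

Standard errors are `sqrt(diag(I⁻¹))` at the optimum (the baseline SE is
`sqrt(1ᵀI⁻¹1)`); each retained allele gets a likelihood-ratio test with its
frequency fixed at 0, phred-scaled through the χ²₁ tail probability and
capped at 10⁴.

The reference base is always the baseline allele; when it is entirely
unobserved at a site the most-observed allele takes the baseline role (the
`baseline` field of the call records this).

## Candidate alleles and filters

An allele is a candidate if it has ≥ 2 observations on *each* strand.
Calls are flagged (never deleted) by: `strand_bias` — two-sided Fisher
exact test of minor vs baseline allele counts by strand, p < 1e−3;
`base_qual_bias` — one-sided Mann–Whitney test that minor-allele base
qualities are lower than the baseline's, p < 1e−3; `low_qual` — phred LRT
quality < 30; `low_freq` — estimated VAF < 0.005. These thresholds are
deliberately conservative given a ~1% per-base error regime and are all
configurable.

## Long deletions

Positions whose deletion allele is a candidate are scanned (circularly) for
maximal runs of at least `long_del_min = 64` bp; each run is a region.
Per-read CIGAR deletion intervals of at least `long_del_min` falling in a
region are clustered greedily: an interval joins a cluster when its start
and length are both within `merge_tol = 10` bp of the cluster medians.
Each cluster becomes a deletion allele with median breakpoints; its
frequency is estimated by the same Fisher-scoring fit, treating cluster
membership as the allele over the reads spanning the region (carrier reads
use the stored preceding-base quality, intact reads the base quality at the
region anchor). Inside a region, single-site estimates are recomputed with
all carrier reads excluded, so SNVs under a heteroplasmic deletion are
estimated from the intact molecules only. Deletions crossing the reference
origin are written as two VCF records sharing an `EVENT` id; `END` is the
last deleted base and `POS` the anchor base before the run.

## Short-indel haplotype merging

A run of deletion-candidate sites shorter than `long_del_min`, preceded by
an anchor site without one, is merged left to right (window capped at
`max_window = 50` bp): candidate merged alleles are the product of the
per-site retained alleles, counts come from the reads spanning the window
(window quality = minimum base quality inside it), the fit is re-run on the
merged counts, and alleles estimated at 0 are pruned after each extension.
The merged record reports haplotype strings (`-` marking deleted bases)
against the window's reference sequence.

## What the simulator emulates — and what it does not

The generator draws, per read: a source population from the configured
mixture (restricted, per cut-site, to populations whose deletions do not
remove that cut — which is why different guides can see different
population subsets), a strand (Bernoulli ½), start/end offsets from the
break (default 0, i.e. exact Cas9 ends; configurable up to the matching
tolerance), full-length vs fragment status, per-base Phred levels from a
discrete mix (default mass on q ∈ {10, 15, 20, 25, 30} centred on q20,
emulating a ~1% error regime), and substitution errors as Bernoulli(e(q))
flips to a uniformly random other base. Structural deletions are excised
exactly; an optional 1-bp indel error channel (default off) exercises the
indel plumbing. Ideal PAF (against the circle, split at the origin and at
long deletions) and SAM (against each cut-site's custom reference, one
linear segment) records are emitted from the known geometry.

Passing tests on this model therefore demonstrate the *statistical*
machinery — demultiplexing geometry, coordinate collapse, frequency
estimation, deletion disentangling — under quality-stratified substitution
noise. They do not demonstrate robustness to real nanopore artefacts:
homopolymer-length errors, context-dependent and correlated errors,
basecaller-miscalibrated qualities, chimeric reads, or NUMT contamination
(the demultiplexer's uniqueness filter is the only NUMT defence). Real
alignments may also left-shift or split indels differently from the ideal
CIGARs the simulator emits; no realignment is attempted.

For site-level statistics (`simulate_pileup_counts`) the observed allele is
flipped with probability `e(q)` to one of the other *listed* alleles, which
makes the generative model coincide with the caller's two-allele error
model; with more than two alleles the caller's per-allele error model is,
as in the source method, an approximation.

## Problem sizes and numerical checks

The default test and acceptance runs use a 2 kb toy circle for
demultiplexing/phasing checks and a full-size 16,569 bp circle with 1,000
full-length reads for the deletion scenario and the view-matrix geometry —
sizes chosen so the statistical targets (depth-2000 recovery, 3-SE
coverage, two-deletion disentangling) are meaningful while the whole suite
stays desk-scale. The Fisher-scoring fit is verified against an independent
brute-force grid maximiser (dense 1-D at step 1e−5 for two alleles;
coarse-to-fine 2-D for three) and against the two-allele single-quality
closed form `f̂ = clip((p̂ − e)/(1 − 2e), 0, 1)`. Deletion frequencies are
compared to the realised population fractions in the simulator's truth
table, the quantity the estimator is consistent for; the residual
difference reflects the error-model mismatch for noiseless deletion
carriage and stays within the asymptotic 3-SE band.

## Known limitations

* Per-site VCF records are emitted for every site with a retained
  non-reference allele, including sub-percent error-driven ones; they carry
  `low_freq`/`low_qual` flags rather than being suppressed, so downstream
  consumers should filter on FILTER = PASS.
* Symbolic site-level deletion alleles (`<DEL>` at a single site outside a
  merged window or long-deletion region) lose the preceding-base VCF
  normalisation.
* The view matrix anchors insertions (lower-case base) but does not expand
  them into extra columns.
* Thread-level parallelism is not implemented; the dense pileup holds two
  `reads × l` byte matrices in memory (~33 MB for 1,000 full-length
  mitochondrial reads).
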
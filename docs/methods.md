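# Methods

## The question and the study design

After a gene duplication, how long does the burst of accelerated protein
evolution last, and is it shared by both copies?  The design answers this with
six-taxon *sextuplet* sets: a gene duplicated in the common ancestor of two
sister species (mouse/rat, or human/orangutan) but present in single copy in
two outgroup species (dog, cow).  The unrooted topology is fixed:

```
(((M1, R1), (M2, R2)), C, D)
```

with internal nodes n1 = (M1,R1) ancestor, n2 = (M2,R2) ancestor, n3 = the
duplication node and n4 = the outgroup junction.  Five branch classes carry
independent dn/ds (ω) values:

| class   | branches          | meaning                              |
|---------|-------------------|--------------------------------------|
| preD    | C–n4, D–n4, n3–n4 | preduplication rate                  |
| ipostD1 | n1–n3             | initial post-duplication, copy 1     |
| ipostD2 | n2–n3             | initial post-duplication, copy 2     |
| rpostD1 | M1–n1, R1–n1      | recent post-duplication, copy 1      |
| rpostD2 | M2–n2, R2–n2      | recent post-duplication, copy 2      |

The statistics of interest are rate differences relative to the
preduplication rate:

```
δ_f  = max(ω_rpostD1, ω_rpostD2) − ω_preD      (fast copy)
δ_s  = min(ω_rpostD1, ω_rpostD2) − ω_preD      (slow copy)
δ_if = ω_ipost(fast copy)  − ω_preD
δ_is = ω_ipost(slow copy)  − ω_preD
```

δ_if/δ_is follow the *recent*-branch fast/slow assignment: the internal
branch "belonging" to the fast copy is the one leading up to its recent
branches (ipostD1 for copy 1).  Where descriptions of this assignment can be
read two ways, we follow the formulas, which are unambiguous.

A second, internal-branch-free route estimates the same contrast from five
pairwise comparisons only: O = dn/ds(C–D), P1 = dn/ds(M1–R1),
P2 = dn/ds(M2–R2), with δ_f = max(P1,P2) − O and δ_s = min(P1,P2) − O.
Duplication age is the synonymous divergence between the paralogs — for the
branch fit, the per-branch ds summed along the M1↔M2 and R1↔R2 paths,
averaged over the two species; for the pairwise route, the mean of
ds(M1–M2) and ds(R1–R2).  δ_if/δ_is are undefined on the pairwise route.

## Codon substitution model

A GY94-style model over the 61 sense codons of the standard code.  The
instantaneous rate from codon i to j is zero unless they differ at exactly
one nucleotide, otherwise

```
q_ij = π_j · κ^[transition] · ω^[nonsynonymous]
```

with stationary codon frequencies π, transition/transversion ratio κ shared
across branches, and the branch class's ω.  Each class generator is rescaled
to one expected substitution per codon per unit time at stationarity, so
branch lengths t are in substitutions per codon.  π is the empirical F3x4
estimate (position-specific nucleotide frequencies, product form restricted
to sense codons); a position with an unobserved nucleotide gets a flat 0.5
pseudocount so π stays strictly positive.  A uniform-π option exists for
tests.

The model is time-reversible; P(t) = exp(Qt) is computed through the
eigendecomposition of the symmetrized generator D^{1/2} Q D^{-1/2}
(D = diag π).  Likelihoods use Felsenstein pruning over unique column
patterns; gap codons (`---`) contribute an all-ones partial likelihood
(missing data) rather than triggering column deletion, preserving per-branch
information in partially gapped columns.  Reversibility makes the result
independent of the rooting used by the recursion (verified against rooting at
n3 versus n4, and against brute-force enumeration over internal states on
small trees).

### Branch dn/ds decomposition

With ρ_N, ρ_S the stationary fractions of substitutions that are
nonsynonymous/synonymous under the class ω, and ρ*_N, ρ*_S the same fractions
at ω = 1 (mutational opportunity):

```
dn = t · ρ_N / (3 ρ*_N),    ds = t · ρ_S / (3 ρ*_S)
```

so dn/ds = ω holds as an algebraic identity — the convention by which
branch-model codon fits report per-branch rates.  A pairwise comparison with
ds = 0 reports ω as undefined (not ∞); downstream consumers skip such
records.

### Fitting

Maximum likelihood over 9 branch lengths, κ and 5 class ω values (15
parameters; 11 for the tied single-ω null), by bounded L-BFGS-B on
log-transformed parameters.  Bounds: t ∈ [1e-8, 20], κ ∈ [0.05, 100],
ω ∈ [1e-6, 50]; ω estimates at a bound are flagged.  Starting point t = 0.1,
κ = 2, ω = 0.4, with deterministic seeded multiplicative jitter for restarts
(default 3).  Convergence is the optimizer's relative-change criterion
(ftol 1e-10); an unconverged best restart is flagged, not raised, and its
record is excluded from summaries.  Class generators are cached on exact
(κ, ω) keys, which removes nearly all redundant eigendecompositions during
finite-difference gradient evaluation.

### NG86 counting

The counting cross-check is Nei–Gojobori (1986): per-codon
synonymous/nonsynonymous site counts normalized to 3 and averaged over the
two sequences, pathway-averaged difference counting, Jukes–Cantor correction.
Mutations to stop codons count as nonsynonymous and multi-step pathways are
averaged with equal weight (the same conventions as Biopython's
implementation, against which ours is tested to 1e-10).  A difference
proportion ≥ 3/4 cannot be JC-corrected and is returned with a saturation
flag rather than an exception.

NG86's site counting assumes no transition/transversion bias.  Under κ > 1
it undercounts synonymous sites and therefore inflates ds relative to the ML
estimate, increasingly so as κ grows.  The cross-method consistency check
consequently simulates its pairs at κ = 1, where the comparison isolates the
counting and correction machinery from this documented estimator bias; under
the cohort default κ = 2.5 the two methods are *expected* to disagree on ds
by more than their κ = 1 gap, and NG86 is used in the pipeline only where a
fast, monotone divergence proxy suffices (family decomposition ordering, the
conversion diagnostic, age proxies).

## Synthetic data

The simulator draws root codons from π and evolves them along the rooted
topology (rooted at n4; immaterial for likelihoods by reversibility) with the
branch class's transition matrix.  Everything is deterministic in the seed,
and every generator returns machine-readable truth.

Default scenario (one choice, used everywhere):

* ω: preD 0.10, ipostD1 = ipostD2 0.40, rpostD1 0.25, rpostD2 0.10 — an
  initial burst in both copies, a persistent excess in one; true δ_f = 0.15,
  δ_s = 0.00, constant in age.
* κ = 2.5, mildly non-uniform position-specific nucleotide frequencies.
* Branch lengths: C = D = 0.20 (outgroup path 0.4), stem n3 = 0.10,
  n1 = n2 = 0.096, terminals 0.11 — giving a paralog synonymous depth
  (path ds between paralogs) of 0.30.  Age-stratified cohorts scale the six
  post-duplication branches.

Multi-duplication families are simulated as ultrametric nested duplications
(caterpillar topology) at given paralog-ds depths; gene conversion as a
single complete tract replacement (donor codons overwrite the acceptor's),
the strongest version of the signal screened for.  Homology- and
synteny-table generators plant valid/invalid orthology patterns and
original/novel neighborhoods with exact planted counts.

What the simulator does **not** emulate: indels and alignment error,
selection on synonymous sites, rate heterogeneity among sites, codon-usage
differences between lineages, tandem-array dynamics, or segmental
duplications spanning neighbors.  Passing recovery tests therefore show the
estimators are calibrated under the model's own assumptions — not that those
assumptions hold in real genomes.

## Set construction and filters

From a homology table, a candidate set is a dog gene with a one-to-one cow
ortholog and one-to-many orthology to mouse (human) paralogs, each with a
one-to-one rat (orangutan) ortholog.  Families with more than two paralogs
are decomposed recursively: take the paralog pair with smallest ds as the
most recent duplication, emit a set, remove one member (with its
sister-species ortholog) at random, recurse — k paralogs yield k − 1 sets.
The removal RNG is scoped per family (seed combined with a CRC of the family
id) so one family's stream never affects another's; ds ties are broken
lexicographically by gene-id pair and logged.

The divergence filter removes a set iff any of the five comparison ds values
(C–D, M1–R1, M2–R2, M1–M2, R1–R2) strictly exceeds the threshold (default
1.0; a value exactly at the threshold is retained); missing or non-finite
values reject the set as incomplete.  The threshold is configuration, not a
constant, because the same filter also purges outgroup gene losses and
misassignments.

## Diagnostics and tests

**Gene conversion.**  Conversion homogenizes paralogs within one species,
deflating that species' paralog ds only.  The screen correlates ds(M1–M2)
with ds(R1–R2) across sets (Pearson), and flags a set when either species'
paralog ds falls below 0.5× the standardized-major-axis prediction from the
other (both the ratio and the axis choice are configurable; SMA because both
variables carry comparable error).  The correlation needs n ≥ 3 and real
age spread to be meaningful.

**Original vs novel copy.**  The paralog whose flanking neighbors (window 3
per side, ≥ 2 matches — defaults, as no canonical values exist) share the dog
gene's neighborhood is labeled original; both-or-neither matching is
unresolved; paralogs occurring in each other's neighborhoods are tandem
duplicates and excluded.

**Fast-copy-is-novel test.**  Exact one-sided binomial against p = 1/2 (null:
the fast copy is equally likely to be the original or the novel copy).  For
21 of 26, p = 83,682/2^26 ≈ 1.25 × 10⁻³.  An exact binomial is used because
a 2×2 Fisher construction is underdetermined by counts of this form; the
implementation is verified against rational-arithmetic tail summation for
all n ≤ 30.

**Binning.**  Half-open age bins, default edges 0.0–0.6 in steps of 0.1.
SE = sample SD/√n, undefined for n < 2; flagged records are excluded and
out-of-range records counted.

## Problem sizes

Recovery and structural checks run at sizes chosen to make sampling error
small relative to the effects tested while keeping the suite quick: 20 sets
× 500 codons for δ recovery (both methods; the ML route fits 15 parameters
per set in a few seconds), 30 sets × 500 codons across three age bands for
the age-profile check, 30 sets × 1,000 codons for the conversion screen, 10
pairs × 2,000 codons for the cross-method check.  The neutral-recovery test
(all ω = 1) uses short terminal branches and moderate internal branches:
internal-branch ω classes are informative only when the internal nodes are
well reconstructed, which terminal-branch length, not substitution count,
limits.

## Known limitations

* ω is constant across sites within a class; no site- or branch-site
  variation, no synonymous rate variation.
* F3x4 is an assumption, not an estimate of the true codon distribution;
  with very short alignments its sampling error propagates into ω.
* Single-dataset ω estimates for the internal (ipost) classes are noisy even
  at 1,000 codons; cohort means, not per-set values, are the meaningful
  output.
* The pairwise route averages rates over whole paths, so it cannot separate
  the initial burst from the recent rate (δ_if/δ_is undefined there).
* NG86 ds is biased upward under transition bias (see above).
* The synteny classifier models neighborhoods as unordered id sets; it does
  not use gene order or orientation.
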
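# Methods

## The gamete-killing model

A toxin-antidote (TA) hybrid-sterility locus is a tightly linked gene pair:
a toxin gene and an antidote gene inherited as one haplotype (recombination
between them is neglected; the pair is treated as absolutely linked).  The
model's two action rules are:

* **Sporophytic toxin.**  The toxin is produced by the diploid plant and
  delivered to *every* developing pollen grain.  A plant is "exposed" at a
  locus if either haplotype carries a functional toxin there, or if a
  toxin-payload transgene targets the locus.
* **Gametophytic, cis-acting antidote.**  Only a pollen grain that itself
  carries a functional antidote copy — on its own haplotype or on a
  transgene segregating into it — is protected.  The antidote of the other
  parental haplotype never helps.

An exposed, unprotected grain is eliminated with probability `k`, the
locus's **killing efficiency** (default 1.0, i.e. complete killing;
`k < 1` models leak-through, the rare survival of unprotected grains).
Killing by a locus manifests at a locus-specific developmental stage drawn
from an ordered vocabulary (default `uninucleate < binucleate`; the first
locus of the default panel kills at the earlier stage, the second at the
later one).

For a diploid genotype over a panel of unlinked TA loci plus unlinked
single-insertion transgenes, the male gamete pool is enumerated exactly:
per-locus parental choice with probability 1/2, hemizygous transgenes
carried with probability 1/2.  Each gamete class survives with probability
`prod over loci (1 - k_locus)` restricted to loci at which it is exposed and
unprotected.  Pollen fertility is the summed viable fraction; the abortion
profile applies the kill terms of each class in stage order, so a grain
doomed at several loci is counted once, at the earliest stage at which it
dies (this reproduces the 50% + 25% staged decomposition of the stacked
double heterozygote).  All probabilities are exact floating-point
enumeration; nothing is sampled outside `tadote.simulate`.

Both loci of the default panel use the same two rules.  For the
second locus (qHMS7) the sporophytic/gametophytic assignment is a modeling
assumption rather than a directly demonstrated fact; it is adopted because
the stacked predictions (75% abortion, a single surviving pollen class,
four F2 classes at 1:1:1:1) follow from it.

## Crosses

A cross combines unselected female gametes (single TA loci do not affect
ovules) with the post-selection male pool.  Offspring transgene zygosity is
the number of copies inherited (0/1/2 → none/hemizygous/homozygous).
Genotype classes are canonical order-independent keys (per-locus sorted
allele tokens, e.g. `1D1M;7D7M`); classes below 1e-15 are pruned and the
distribution renormalized.

The stacked F2 exposes a **female transmission weight** vector `w` over
joint female gamete classes (`1M/7D` etc.).  Per-locus female viabilities
are deliberately *not* modeled: single loci demonstrably leave ovules
alone, and the observed female bias appears only in the stacked hybrid, so
it is expressed as a free weight vector over joint classes with uniform
default.

Pedigrees are scripted lists of cross/self/edit steps.  When a step
operates on a genotype *distribution*, pollen contributions are weighted by
class probability times viable pollen fraction, ovule contributions by
class probability alone, and selfing is restricted to classes with viable
pollen (a male-sterile plant sets no selfed seed).  A fully male-sterile
parent (or population) raises an error rather than returning an empty
distribution.

## Inference

`segregation_test` is a plain Pearson chi-square without continuity
correction (df = supported classes − 1), with an exact multinomial
probability-ordering test by enumeration when n ≤ 200.  A class with
expected probability 0 but positive observed count yields an infinite
statistic with the exact test as fallback.

`fit_killing_efficiency` maximizes the multinomial likelihood of the
observed class counts, with class probabilities computed *from the crossing
model* at each candidate `k` — the likelihood inherits the model's
assumptions exactly, and new designs need only a model recipe.  For the
heterozygote self the class probabilities are
`P = (1/(2(2-k)), 1/2, (1-k)/(2(2-k)))`, which the closed-form MLE
`k̂ = 1 − n(null/null)/n(func/func)` maximizes; the numerical optimizer
reproduces this and a grid-search oracle confirms it in the tests.  The
simpler moment inversion from the null-homozygote proportion,
`k = (1−4p)/(1−2p)`, is exposed separately as `invert_dd_proportion`; it is
the exact inverse of the forward model but not the full-likelihood
estimator (on large tables the two differ in the fourth decimal).
Confidence intervals are profile likelihood at the chi-square(1) 95% cutoff
(3.84/2 on the log-likelihood scale); boundary estimates (`k̂ = 1` whenever
the leak-through class is empty — the common case) are flagged and get
one-sided intervals.

`fit_female_weights` treats the stacked F2 as a saturated multinomial over
the four female gamete classes (the male gamete being fixed by complete
killing), so the MLE is the vector of sample proportions.  It reports a
likelihood-ratio test against the uniform null (df = 3) and nonparametric
bootstrap percentile CIs (1000 resamples; a seed is required, as
reproducibility demands).

## Drive dynamics

Single-locus haplotype classes: `FA` (intact element), `fA` (toxin dead,
antidote expressed), `Fa` (free-standing toxin), `fa` (double null).  The
deterministic recursion assumes an infinite population whose parental
genotypes form Hardy-Weinberg proportions from the current haplotype
frequencies each generation (an approximation under selfing, accepted for
simplicity); ovule pools are unselected, pollen pools pass through the
gamete-killing model with each genotype's pollen contribution proportional
to its frequency times its viable fraction (pollen quantity tracks
viability; no pollen-competition saturation).  A fraction `s` of each
plant's ovules is self-pollinated (default 0.95 — rice is predominantly
selfing; `s = 0` gives clean outcrossing drive properties); a male-sterile
plant loses its selfed seed share entirely rather than having it
redistributed, and total offspring mass is renormalized at the end.  The
Wright-Fisher variant samples N diploid offspring multinomially from the
same offspring genotype distribution each generation and is bit-reproducible
per seed.

The mutation-order experiment introduces a mutant haplotype at frequency
0.005 (deterministic) or one copy 1/(2N) (Wright-Fisher) and reports its
fate.  It embodies the ordering argument for the natural loss-of-function
alleles: `fa` is purged wherever `FA` segregates (its pollen is unprotected)
but is strictly neutral on an `fA` background, so promoter silencing of the
antidote can establish only after the toxin is dead; a free-standing toxin
`Fa` always transmits worse through pollen than through ovules and is
eliminated.  Two-locus population dynamics are out of scope — the stacked
system is exercised in the genotype-level modules — and drive strength is
not calibrated to the survey frequencies.

## Allele typing

Rule-based, desk-scale classification on engineered toy sequences (no
alignment to real genomes):

* **Toxin (HPT, 902-aa reference):** translate the CDS to the first stop;
  shorter product → `truncated` (the diagnostic G→T at CDS nt 2011 gives
  670 aa), equal length → `functional`, missing record → `absent`.  The
  nucleotide coordinate of the diagnostic stop is a configurable value,
  since only the protein lengths are anchored.  A stop-loss product longer
  than the reference has no class in the vocabulary and raises an input
  error (limitation).
* **Antidote (HPA, 361-aa F-box reference):** `te_silenced` iff an
  insertion of ≥ 50 bp (threshold configurable; chosen to separate the
  1391-bp transposon exemplar from small indels) lies inside the promoter
  window, by convention half-open [−200, −1] with the A of ATG = +1 and the
  insertion position defined as the base immediately 3′ of the insertion
  point (the transposon exemplar sits at −11).  Coding substitutions (the
  benign Asn→Thr) are reported but never change the class; a premature stop
  in the antidote CDS likewise has no class of its own and is only recorded
  (the coding region is invariant in all surveyed material).

Haplotype classes derive deterministically (F iff toxin functional, A iff
antidote expressed).  The coupling audit returns every `Fa` record — a
functional toxin uncoupled from an expressed antidote — as a violation; the
cross-compatibility predictor builds the F1 at the locus with k = 1 and
labels fertility 1.0 `compatible`, 0.5 `semi-sterile`, 0 `sterile`.

## Synthetic data

All generators are pure functions of (parameters, seed); substreams are
derived from the global seed plus a CRC32 hash of the generator name, so
adding a generator never perturbs another's output.  Cross count tables are
multinomial draws from model-predicted distributions; pollen tallies are
multinomial over (viable, aborted-per-stage) with default 200 grains per
plant (typical microscopy scoring depth); surveys sample haplotype classes
under the coupling constraint, defaulting to the wild-progenitor
composition 53:18:5 over FA:fA:fa out of 76, and can emit toy FASTA whose
reclassification round-trips exactly.  The toy reference (fixed default
seed) is regenerated deterministically: 902 + 361 sense codons with the
diagnostic codons engineered in, a 200-bp promoter and a 1391-bp insertion
element with unambiguous flanks.

What the generators do *not* emulate: genotyping error, sequencing reads,
real transposon sequence content, residual background heterozygosity
outside the panel, or environment effects.  Passing tests therefore show
internal consistency of model, estimators and classifiers under the model's
own assumptions, not robustness to those real-data complications.

## Numerical choices and problem sizes

Distribution normalization tolerance 1e-12; pruning threshold 1e-15; MLE by
bounded scalar minimization (xatol 1e-10) with explicit endpoint checks;
profile-CI edges by Brent root-finding; exact multinomial enumeration
capped at 2e6 compositions.  Simulation-based checks in the test suite use
200–500 replicates at n = 400–20000 (estimator consistency, CI coverage,
LRT power and size, GOF calibration) — sizes chosen so each property is
resolved well above its Monte-Carlo noise floor while the whole suite runs
in seconds.  The estimator-consistency check allows a small slack on the
bias ordering because beyond n ≈ 2000 the true bias is below the
200-replicate noise floor.

## Known limitations

* Within-locus recombination between toxin and antidote is ignored.
* Female-side killing by single loci is assumed absent; the stacked female
  bias is descriptive (a weight vector), not mechanistic.
* Hardy-Weinberg parental genotypes under partial selfing understate
  homozygote excess; inbreeding-aware genotype tracking would refine the
  selfing trajectories.
* The classifier vocabulary has no class for stop-loss toxin products or
  truncated antidote products.
* Drive dynamics are single-locus only and uncalibrated to natural allele
  frequencies.
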
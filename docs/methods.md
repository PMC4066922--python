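# Methods

This note documents the models and conventions behind `polykaryo`, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Data model and coordinates

All statistics operate on a `MultipleAlignment` (equal-length gapped
sequences over `{A,C,G,T,N,-}`) plus a `RegionMap` labelling every column
exon or intron. Columns are **1-based and inclusive** everywhere, so
reported positions line up with positions as conventionally printed for
annotated loci; BED input (0-based half-open) is converted on read. Input
is case-insensitive; `U` is mapped to `T` with a logged warning. 5′/3′
trimming is left to the user's region file: the package analyses exactly
the columns it is given.

## Polymorphism counting

A polymorphic site is a column with ≥2 distinct states among non-`N`
sequences. Conventions, chosen where the field's tables leave room:

* **`N` columns are skipped entirely** rather than per-sequence masked —
  the simplest rule, and ambiguity is rare in clone-resolved data.
* **Indels are merged**: a maximal run of consecutive gap-bearing columns
  with an identical gap pattern is one indel event of length = run length.
  Column-wise counting would turn one 4-bp deletion into four events;
  published indel counts (e.g. "12 indels of 1–4 bp") count events.
* **Multi-allelic sites** contribute `(distinct non-gap states − 1)`
  events by pairing each minor state with the majority state (ties broken
  alphabetically). This yields exactly one event at biallelic sites and a
  defensible minimum at tri-allelic ones; an `all_pairs` convention is
  available since published tables rarely state their rule.
* Spectrum-table integer percentages are rounded half away from zero;
  per-nucleotide frequency percentages are **truncated** to one decimal,
  which is how such frequencies are conventionally printed (97/207 →
  46.8%, 32/586 → 5.4%).

## Shared-error (birthday-paradox) model

Model: each of the *n* clones of a basidioma acquires at most one random
error, landing uniformly on one of the *L* polymorphic regions of the
clone alignment with relative class weights transition : transversion :
transversion = 2 : 1 : 1. The default (`variant="halved"`) probability
that one specific mutation recurs in ≥ *k* clones is the leading binomial
term for a transition,

    P(≥k) ≈ C(n, k) · (1/(2L))^k,

with the transversion value defined as exactly half the transition value
— the halving convention used when such numbers are reported. Two exact
alternatives are exposed: `weighted` uses q = w/(4L) with w ∈ {2, 1} and
equals the expected number of *k*-clone coincidences of that specific
mutation (this is what a coincidence-counting Monte-Carlo estimates, and
the tests verify the match for both classes); `binomial_tail` evaluates
the full tail Σ_{j≥k} C(n,j) q^j (1−q)^(n−j). The three variants agree to
within a factor of ~2 in the regimes of interest (n ≈ 16, L ≈ 15–17,
k ≤ 3); none can be pinned down further because the quantity is an
order-of-magnitude screen, not an inference target. Multiple independent
private mutations multiply. Defaults: *n* = all clones sequenced for the
basidioma (not only retained ones — errors arise in every clone), *L* =
polymorphic sites among the basidioma's collapsed haplotypes.

Indel private mutations are scored with the transversion (halved) weight:
proofreading polymerases make indel errors at most as often as
transversions, so this errs conservative (larger P, harder to call a
third parent).

## Parent-count decision

Per basidioma: collapse clones by exact match → exclude support <
`min_support` (default 2, the standard singleton-exclusion rule) → the two
best-supported retained haplotypes are dominant (ties broken by haplotype
id and logged; two parents is always the null) → each further retained
haplotype is a candidate parent, accepted iff

1. the joint shared-error probability of its unique polymorphisms (sites
   matching **no** dominant haplotype) is < `alpha` (default 0.05), and
2. it is not explainable as a recombinant of the dominant pair with ≤
   `max_crossovers_recent` switches (default 2 — "recent" recombination;
   more switches imply an inherited, older haplotype) and zero
   unexplained sites.

One retained haplotype → one parent, with a recorded caveat (homozygous
parents or an undetected second parent). Zero retained → uncallable, not
an error.

## Minimal template switches

Informative sites are the columns where the candidate parents differ from
each other; gaps count as a fifth state because indels are genuine
haplotype markers at an intron-rich locus. A dynamic program with one
state per parent and unit cost per parent change gives the minimum switch
count; among optimal paths the reported one switches as early as possible
(deterministic, lexicographically earliest breakpoints). Breakpoints are
open intervals between consecutive differently-assigned informative
sites. Sites where the child matches **no** parent — whether or not the
parents differ there — are reported as unexplained and never force a
switch; they are the minor haplotype's private polymorphisms.

## PHI

For each pair of parsimony-informative sites (≥2 states each carried by
≥2 sequences; gap a fifth state, `N` missing) the refined incompatibility
is the cycle rank E − V + C of the bipartite partition-intersection graph
over observed joint states — the minimum number of homoplasies any tree
needs, reducing to the four-gamete test for binary sites. The statistic
is the mean over site pairs ≤ `window` apart in informative-site rank
(default 100). The default p-value permutes the site order (seeded;
p = (1 + #{perm ≤ obs})/(B + 1)); under clonal evolution incompatibility
has no spatial structure, while recombination makes nearby pairs more
compatible than distant ones. The `normal` option uses exact Mantel-type
permutation moments of the statistic. Fewer than 4 sequences or 2
informative sites → flagged not computable. Note the window must be
smaller than the number of informative sites for the permutation test to
have any resolution; the simulation studies in this package use
window = 25 with alignments carrying ~60–150 informative sites.

## Gene diversity and Fst

Sampling units are haplotypes-within-basidiomata (haploid), each retained
haplotype counted once per basidioma regardless of clone support —
support reflects PCR sampling, not nuclear abundance. The default
estimator is the Weir–Cockerham variance-components θ adapted to haploid
data, computed per polymorphic site (site = locus), combined as the
multilocus ratio Σ(MSP − MSG) / Σ(MSP + (n_c − 1)·MSG), with a delete-one
jackknife over sites for the spread; it is unbiased and may be negative
under panmixia. Nei's G_ST = (H_T − H_S)/H_T on whole-haplotype
frequencies is the closed-form cross-check (bootstrap over individuals
for its spread). The two answer slightly different questions and both are
reported in the pipeline.

## Haplotype networks

Default: minimum-spanning network over Hamming distances on the site-state
matrix (a merged indel = one step). Distance classes are processed in
ascending order and every co-minimal edge joining two
previously-separate components is retained — deterministic with no tie
breaking. Edge labels are exactly the differing site positions. A
simplified median-joining variant (ε = 0, iterative majority-vector
augmentation while the spanning tree shortens) is available and flagged
experimental; topology only, no layout.

## Synthetic-data generator

The generator emulates the emitting process the analysis assumes, with
ground truth for every random choice:

* **Locus**: 586 exon columns in five segments interleaved with four
  introns of 50–58 nt (drawn per seed).
* **Latent site events**: every column (or, in introns, a run of 1–4
  columns designated an indel unit) gets one biallelic event — class
  drawn from the observed substitution spectrum of the emulated locus
  (exon 5:22:2:1:2:0 for A-G:C-T:A-C:A-T:C-G:G-T; intron
  7:44:9:12:6:7 plus a 12/97 indel share), ancestor base compatible with
  the class. Indels occur only in introns.
* **Parental pool**: 20 haplotypes from one ancestor (star genealogy —
  the statistics use polymorphism structure, never genealogy depth; a
  coalescent would add realism the pipeline cannot see). Each parent
  carries each derived allele independently with a probability calibrated
  so the expected polymorphic fraction is 0.054 per exon column and 0.468
  per intron column (ratio 8.67, the "about nine-fold" intron excess).
  Recurrent carriage of one derived allele by several parents produces
  genuine homoplasy, which is what gives clonal data a nonzero PHI
  statistic.
* **Basidiomata**: 2 parents, or 3 with probability 0.25 (three of eleven
  fruit bodies in the emulated study showed three haplotypes), drawn
  without replacement; 16 clones multinomially at proportions (0.5, 0.5)
  or (0.40, 0.35, 0.25). The three-parent split is a neutral
  moderately-uneven choice — no abundance model exists for nuclear
  ratios; the sharper {7,7,2}-style skew is available via
  `proportions=` and used in the worked example.
* **Noise**: PCR point errors at 5·10⁻⁵ per base per clone (order of
  magnitude of a proofreading polymerase over ~35 cycles) with 2:1:1
  transition:transversion weighting; chimeras at 0.02 per clone as a
  single uniform-breakpoint switch to another of the basidioma's parents.
  No published estimates exist for either rate; both are config knobs.
* **Population structure**: basidiomata allocated to demes at random;
  `divergence > 0` adds deme-private substitutions shared by all parents
  of a deme's pool copy — the simplest mechanism with a tunable realized
  Fst. The default 0 models panmixia.

What the generator does **not** emulate: genealogical correlation among
parents, sequencing-read noise and quality scores, alignment error,
multi-copy paralogy, and selection. Tests passing on simulated data show
the pipeline recovers the truth of *this* emitting process; on real data
the singleton filter and shared-error screen additionally absorb whatever
the generator idealises away.

## Problem sizes and determinism

The test suite and the acceptance script use 200 simulated basidiomata
for recovery rates, 200 clonal replicates (10-parent pools, duplicated
haplotypes, 199 permutations) for the PHI type-I rate, 100 replicates for
the panmictic Fst mean and 30 pools for generator calibration — sizes at
which the Monte-Carlo error of each quantity is well below its acceptance
band. All randomness flows through one seeded NumPy generator per run;
identical seed and config give byte-identical simulator output and
pipeline reports (manifest metadata aside).

## Known limitations

* The shared-error model treats "one error per clone" as the dominant
  regime; at much higher error rates the binomial-tail variant should be
  preferred.
* Equal-support ties for the dominant pair are broken by haplotype id —
  defensible but arbitrary; the log records when it happens.
* The PHI normal approximation relies on asymptotic normality of a
  permutation mean; with < ~20 informative sites use the permutation
  p-value.
* The accession-data checks require the user to download and align the
  deposited sequences; the package ships no sequence data beyond the
  four-site ITS variant table.
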
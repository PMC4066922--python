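# polykaryo

Detection of multi-parent ("polykaryotic" or chimeric) fungal fruit bodies
from cloned single-locus amplicon sequences, with the supporting
polymorphism-spectrum, recombination, gene-diversity and haplotype-network
statistics.

## The problem

A basidiomycete fruit body (basidioma) is expected to be a dikaryon: two
compatible haploid parents, hence at most two haplotypes at any nuclear
locus. Cloning a PCR amplicon of a polymorphic locus (here the intron-rich
5′ region of *tef1α*) and sequencing many clones per basidioma reveals the
parental haplotypes directly — but also PCR point errors, cloning
artefacts and PCR-mediated chimeras. The scientific question: when a third
distinct clone sequence shows up, is it a genuine third parental
monokaryon, a recurrent error, or a recombinant?

`polykaryo` answers this per basidioma with three ingredients:

1. **Support filtering.** Clones are collapsed by exact match into
   haplotypes with support counts; haplotypes seen fewer than
   `min_support` (default 2) times are excluded as possible cloning
   errors; the two best-supported retained haplotypes are the dominant
   (dikaryon-null) pair.
2. **Shared-error probability.** For a minor haplotype observed in
   *k* clones, the probability that its private mutations arose
   independently *k* times is approximated birthday-paradox style as

   P(≥k) ≈ C(n, k) · q^k,   q = 1/(2L)

   for a specific transition over *L* polymorphic regions and *n* clones,
   and half that for a transversion; independent private mutations
   multiply. Two exact variants (per-class coincidence expectation and the
   full binomial tail) are also exposed.
3. **Recombinant alternative.** A dynamic program over the sites where the
   dominant pair differ finds the minimum number of template switches
   deriving the minor from the dominants, with breakpoint intervals and
   the sites it cannot explain. A minor counts as a third parent only if
   its shared-error probability is below `alpha` (default 0.05) **and** it
   is not a ≤2-switch recombinant with zero unexplained sites.

Around this sit the standard population statistics: a
transition/transversion/indel spectrum by exon/intron region (with merged
gap-run indel counting), the pairwise homoplasy index (PHI) test for
recombination with permutation or Mantel-moment p-values, haploid
Weir–Cockerham θ / Nei G_ST gene diversity across localities, and
minimum-spanning (optionally median-joining) haplotype networks. A fully
truth-tracked synthetic-data generator emulates the locus so every stage
is testable without downloads.

## A worked example

```python
from polykaryo import (load_its_matrix, alignment_from_site_matrix,
                       find_polymorphic_sites, haplotype_matrix,
                       group_haplotypes)
from polykaryo.seqio import Region, RegionMap
from polykaryo.tables import ITS_ALIGNMENT_LENGTH

matrix = load_its_matrix(include_reference=False)
aln = alignment_from_site_matrix(matrix, ITS_ALIGNMENT_LENGTH)
regions = RegionMap((Region(1, ITS_ALIGNMENT_LENGTH, "intron"),))
sites = find_polymorphic_sites(aln, regions)
for s in sites:
    print(s.position, [f"{e.class_name} {e.kind}" for e in s.events])
print(len(group_haplotypes(haplotype_matrix(aln, sites))), "haplotypes")
```

prints

```
195 ['indel indel']
338 ['C-T transition']
538 ['indel indel']
669 ['A-G transition']
10 haplotypes
```

— the ITS1/ITS2 regions of the Vietnamese collections carry exactly four
polymorphisms (two single-adenosine indels, a C-T and an A-G transition)
defining ten distinct haplotypes. The `examples/` directory has one short
script per capability: variant tables and networks, the parent-count
decision, crossover analysis of a chimera, and PHI plus Fst on a simulated
multi-basidioma dataset. A thin CLI wraps the same functions
(`polykaryo simulate|variants|clones|recomb|phi|diversity|network|run`).

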
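"""Sample-wide statistics: PHI recombination test and Fst.

Simulates a full multi-basidioma dataset, then (a) tests the retained
haplotypes for recombination with the pairwise homoplasy index and
(b) estimates haploid gene diversity and Fst across the demes.
"""

from polykaryo import SimConfig, gene_diversity_fst, phi_test, simulate_dataset
from polykaryo.seqio import MultipleAlignment

dataset = simulate_dataset(SimConfig(seed=42, n_basidiomata=12))

haps, pops, records = [], [], []
for bid, parents in dataset.truth.parents_of.items():
    for pid in parents:
        uid = f"{bid}:{pid}"
        seq = dataset.pool.alignment[pid]
        records.append((uid, seq))
        haps.append(seq)
        pops.append(dataset.truth.population_of[bid])

phi = phi_test(MultipleAlignment(tuple(records)), window=25,
               n_permutations=999, seed=1)
print(f"PHI statistic {phi.statistic:.4f}, p = {phi.p_value:.3f} "
      f"({phi.n_informative} informative sites)")
# Clonal pool: homoplasy has no spatial pattern, so p is typically large.

div = gene_diversity_fst(haps, pops, seed=1)
print(f"Hs = {div.hs:.3f}, Ht = {div.ht:.3f}")
print(f"Fst ({div.estimator}) = {div.fst:.4f} +/- {div.sd_fst:.4f}")
# One shared parental pool across demes: Fst scatters around zero,
# the signature of panmixia.
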
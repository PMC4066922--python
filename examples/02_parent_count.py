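"""Calling the number of parental haplotypes behind one fruit body.

Simulates a basidioma whose 16 clones come from three parents at
supports ~{7, 7, 2}, then runs the full per-basidioma decision: collapse,
singleton exclusion, shared-error probability of the minor haplotype's
private mutations, and the recombinant (template-switch) alternative.
"""

import numpy as np

from polykaryo import SimConfig, analyze_basidioma
from polykaryo.seqio import MultipleAlignment, SampleSheet
from polykaryo.simulate import simulate_basidioma, simulate_parental_pool

config = SimConfig(seed=7, pcr_error_rate=0.0, chimera_rate=0.0)
rng = np.random.default_rng(config.seed)
pool = simulate_parental_pool(config, rng)

clones, rows, truth = simulate_basidioma(
    pool, config, "G25", rng,
    parent_ids=pool.alignment.ids[:3],
    proportions=(7 / 16, 7 / 16, 2 / 16),
)
aln = MultipleAlignment(tuple(clones))
sheet = SampleSheet(tuple(rows))

analysis = analyze_basidioma(aln, sheet, "G25")
print(f"true parents: {len(truth.parents_of['G25'])}")
print(f"called parents: {analysis.parent_call.n_parents}\n")
for entry in analysis.parent_call.evidence:
    print(" ", entry)

# A minor haplotype counts as a third parent only when its private
# mutations are too improbable to be shared PCR errors (shared_error_p
# below alpha) and it is not a simple recombinant of the dominant pair.
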
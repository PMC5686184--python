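"""Score structural disruption of SNVs on hairpin RNAs (riboSNitch calls).

Generates stem-loop RNAs carrying either stem-breaking or loop
(neutral) variants, computes the interval-maximised Euclidean distance
between wild-type and mutant base-pair probability matrices, assigns
empirical p-values against random same-window SNVs and calls
riboSNitches at p < 0.2.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from ernatlas import ribosnitch, simulate

cfg = simulate.SimConfig(seed=21, n_structure_cases=30)
seqs, snvs, truth = simulate.generate_structure_cases(cfg)

results = ribosnitch.score_snvs(seqs, snvs, n_null=100,
                                rng=np.random.default_rng(22))
d = np.array([r.d_max for r in results])
calls = np.array([r.is_ribosnitch for r in results])
flags = truth.true_disruptive_snvs

print(f"cases: {len(results)} ({int(flags.sum())} stem-breaking, "
      f"{int((~flags).sum())} loop variants)")
print(f"mean distance, stem-breaking: {d[flags].mean():.3f}")
print(f"mean distance, loop         : {d[~flags].mean():.3f}")
print(f"ranking AUC                 : {roc_auc_score(flags, d):.3f}")
print(f"riboSNitch calls (p < 0.2)  : {int(calls.sum())}")
print(f"  among stem-breaking       : {int(calls[flags].sum())} of {int(flags.sum())}")
print(f"  among loop variants       : {int(calls[~flags].sum())} of {int((~flags).sum())}")

# The distance measures how much the pairing ensemble moves when the
# variant is introduced; stem breaks unfold the hairpin and score far
# above loop substitutions.
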
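"""Is the number of similarly methylated positions more than chance?

Shuffling the subject labels of the blood samples breaks the matched
pairing; re-running the full SMP selection (correlation test, BH within
each iteration, the delta-beta filter) on each shuffle gives the null
distribution of the SMP count.  An observed count above every null count
yields the smallest attainable empirical p, 1/(iterations + 1).
"""

import methcord as mc

cfg = mc.SimulationConfig(n_sites=2000, frac_smp=0.2, frac_dmp=0.0,
                          batch_shift=0.0, seed=3)
data = mc.generate_dataset(cfg)

res = mc.permutation_null(data.mvalues, data.beta, data.sheet,
                          n_iterations=500, seed=4)
print(f"observed SMP-passing count: {res.observed_count}")
print(f"null counts over {res.n_iterations} shuffles: "
      f"mean {res.null_counts.mean():.1f}, max {res.null_counts.max()}")
print(f"empirical p = {res.empirical_p:.4g}")
print("-> the matched pairing carries far more cross-tissue concordance"
      " than label-shuffled data ever shows.")
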
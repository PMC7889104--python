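"""Generate a matched bone-blood methylation dataset with planted truth.

Twelve subjects, two tissues each, two chip batches, 2,000 CpG sites of
which 10% are planted as similarly methylated (shared subject effect in
both tissues) and 10% as differentially methylated (tissue offset of 0.4
on the beta scale).
"""

import methcord as mc

cfg = mc.SimulationConfig(n_subjects=12, n_sites=2000, seed=1)
data = mc.generate_dataset(cfg)

print("samples:", len(data.sheet.sample_ids),
      "(", data.sheet.n_subjects, "matched pairs )")
print("planted classes:", data.truth["class"].value_counts().to_dict())
print("beta range: %.3f .. %.3f" % (data.beta.values.values.min(),
                                    data.beta.values.values.max()))
failed = (data.detection_p > 0.01).any(axis=1).sum()
print("probes with >=1 detection failure:", int(failed))
print("SNP-overlapping probes:", int(data.annotation["snp_overlap"].sum()))
# The truth table is what downstream recovery tests score against: each
# site's class and the parameters that generated it.
print(data.truth.head(3).round(3))
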
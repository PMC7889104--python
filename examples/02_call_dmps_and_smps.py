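"""Full calling chain: QC filters, batch correction, DMPs, then SMPs.

DMPs (differentially methylated positions) are sites where bone and blood
differ: moderated-t q < 0.05 AND mean paired delta-beta > 0.2.  SMPs
(similarly methylated positions) are drawn from the remaining candidates:
within-subject Pearson r with q < 0.05, every pair within delta-beta < 0.2,
and r > 0.  The two call sets are disjoint by construction.
"""

import methcord as mc

data = mc.generate_dataset(mc.SimulationConfig(n_sites=2000, seed=1))

# probe-level QC: drop probes failing detection in any sample, then
# SNP-overlapping probes (order does not matter)
keep = mc.snp_filter(data.annotation, mc.detection_filter(data.detection_p))
m = mc.MethylationMatrix(data.mvalues.values.loc[keep], "mvalue")
b = mc.MethylationMatrix(data.beta.values.loc[keep], "beta")
print(f"{len(keep)} of {data.config.n_sites} probes pass QC")

# empirical-Bayes batch adjustment on M-values, tissue effect protected
m = mc.batch_correct(m, data.sheet)

dmp = mc.call_dmps(m, b, data.sheet)
n_dmp = int(dmp["is_dmp"].sum())
print(f"DMPs: {n_dmp} "
      f"({(dmp['direction'][dmp['is_dmp']] == 'hypo').mean():.0%} hypo in bone)")

cand = mc.candidate_sites(dmp["q"])
smp = mc.call_smps(m, b, data.sheet, cand)
n_smp = int(smp["is_smp"].sum())
called_r = smp.loc[smp["is_smp"], "r"]
print(f"SMP candidates (q >= 0.05 at the DMP stage): {len(cand)}")
print(f"SMPs: {n_smp}; correlation range of calls: "
      f"{called_r.min():.2f} .. {called_r.max():.2f}")

# score against the planted truth
for name, table, col in (("DMP", dmp, "is_dmp"), ("SMP", smp, "is_smp")):
    called = table[col].reindex(data.truth.index, fill_value=False)
    conf = mc.truth_confusion(called, data.truth, name.lower())
    print(f"{name} recovery: sensitivity {conf['sensitivity']:.2f}, "
          f"empirical FDR {conf['fdr']:.3f}")
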
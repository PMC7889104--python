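"""Where do the similarly methylated sites fall, and what do they cover?

Region enrichment normalizes hits by the probe count of each genomic
feature / CpG-island class; locus overlap counts how many genes from an
external disease-locus list contain a called site; the hypergeometric test
scores gene-set over-representation against the candidate gene universe.
"""

import methcord as mc

data = mc.generate_dataset(mc.SimulationConfig(n_sites=2000, seed=1))
m = mc.batch_correct(data.mvalues, data.sheet)
dmp = mc.call_dmps(m, data.beta, data.sheet)
cand = mc.candidate_sites(dmp["q"])
smp = mc.call_smps(m, data.beta, data.sheet, cand)
called = smp.index[smp["is_smp"]]

region = mc.region_enrichment(called, data.annotation, cand)
print("SMP fraction per CpG-island class (percent of class probes called):")
print(region[region["kind"] == "island"][["region", "n_hits", "n_array",
                                          "percent"]].round(1).to_string(index=False))

# overlap with an external locus list (here: three genes from the pool)
loci = sorted(mc.gene_universe(called, data.annotation))[:3]
report = mc.locus_overlap(called, data.annotation, loci, phenotype="demo")
print(f"\nlocus overlap: {report.n_loci_represented}/{report.n_catalog_loci} "
      f"loci represented ({report.percent_represented:.0f}%)")

# gene-set over-representation against the candidate gene universe
universe = mc.gene_universe(cand, data.annotation)
called_genes = mc.gene_universe(called, data.annotation) & universe
sets = {"DEMO_SET": frozenset(sorted(universe)[:40])}
table = mc.hypergeom_enrichment(called_genes, universe, sets)
print("\ngene-set over-representation (plain hypergeometric):")
print(table.to_string(index=False))
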
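"""Derive scVAF calling thresholds from WT-control cells and call genotypes.

Simulates one plate-style sample with spiked-in WT-control cells, derives
locus-specific WT/mutant/hom-mutant cutoffs from the control scVAF
distributions, validates the false-positive probability of each cutoff with
a bootstrap beta fit, and calls consensus genotypes per cell x mutation.
"""

import ampliclone as ac

cfg = ac.default_config(n_cells=1000)
sim = ac.simulate_cells(cfg, seed=7)
ds = ac.validate_dataset(sim.counts, sim.manifest, sim.meta)

thresholds = ac.derive_all_thresholds(ds)
controls = ac.control_scvaf_distributions(ds)

print("amplicon                 wt_thr   mut_thr  fp_prob")
for amp, t in thresholds.items():
    fp = ac.validate_fp_probability(controls[amp], t,
                                    ac.RunConfig(bootstrap_reps=200))
    print(f"{amp:24s} {t.wt_threshold:.5f}  {t.mutant_threshold:.5f}  "
          f"{fp.fp_probability:.2e}")

calls = ac.call_dataset(ds, thresholds)
print("\nconsensus genotype counts:")
print(calls["consensus"].value_counts().to_string())
# Each amplicon's mutant cutoff sits a fixed 0.01 scVAF above the control
# noise band (mean + 3 SD); the fp numbers say how often control-like noise
# would still exceed it -- effectively never at these error rates.
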
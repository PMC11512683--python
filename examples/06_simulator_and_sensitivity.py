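"""Exercise the simulator's knobs and the label-perturbation sensitivity check.

Shows the deterministic noise-free limit, the allelic-skew spread of
heterozygous scVAFs, and the effect of deliberately re-classifying 10% of
mutant cells as WT on cluster-level enrichment.
"""

import pandas as pd

import ampliclone as ac

# 1. noise-free limit: het cells at exactly 0.5, WT cells at exactly 0
locus = ac.LocusSim("M1", has_cdna=False, error_rate=0.0, ado_gdna=0.0,
                    deterministic=True)
cfg0 = ac.SimConfig(loci=(locus,), clone_tree={"C1": frozenset({"M1"})},
                    cluster_fractions={"HSC/MPP": 1.0},
                    clone_probs={"HSC/MPP": {"C1": 0.5}}, n_cells=200,
                    empty_well_fraction=0.0)
sim0 = ac.simulate_cells(cfg0, seed=1)
scvaf = sim0.counts["alt_reads"] / (sim0.counts["ref_reads"]
                                    + sim0.counts["alt_reads"])
print("noise-free scVAF values observed:", sorted(scvaf.unique()))

# 2. realistic skew: heterozygous scVAFs spread over ~0.01-0.99
cfg = ac.default_config(n_cells=2000)
sim = ac.simulate_cells(cfg, seed=2)
het = sim.counts.merge(sim.truth[["cell_id", "geno_TET2_pQ726X"]],
                       on="cell_id")
het = het[(het["amplicon_id"] == "TET2_pQ726X_gDNA")
          & (het["geno_TET2_pQ726X"] == "MUT")]
s = het["alt_reads"] / (het["ref_reads"] + het["alt_reads"])
print(f"het scVAF quantiles: 1% = {s.quantile(0.01):.3f}, "
      f"50% = {s.quantile(0.5):.3f}, 99% = {s.quantile(0.99):.3f}")

# 3. sensitivity: relabel 10% of mutant cells as WT and compare enrichment
assignments = sim.truth.loc[~sim.truth["is_wt_control"],
                            ["cell_id", "clone_id"]].reset_index(drop=True)
clone_muts = {"WT": frozenset(), "C1": frozenset({"TET2_pQ726X"}),
              "C2": frozenset({"TET2_pQ726X", "TET2_pR1261C"})}
base = ac.clone_fraction_by_cluster(assignments, sim.meta, clone_muts,
                                    "C1", "HSC/MPP")
labels = assignments["clone_id"].replace({"C1": "MUT", "C2": "MUT"})
perturbed, log = ac.perturb_labels(labels, fraction=0.10, seed=3)
a2 = assignments.copy()
a2.loc[log["index"], "clone_id"] = "WT"
pert = ac.clone_fraction_by_cluster(a2, sim.meta, clone_muts, "C1",
                                    "HSC/MPP")
cmp = pd.DataFrame({
    "original": base.set_index("cluster_label")["normalized_likelihood"],
    "perturbed": pert.set_index("cluster_label")["normalized_likelihood"],
})
print("\nnormalized likelihood before/after 10% MUT->WT relabeling:")
print(cmp.round(3).to_string())
print(f"({len(log)} cells relabeled)")
# Random mis-genotyping leaves the cluster ranking intact and at most
# mildly attenuates enrichment (the effect is within sampling noise at this
# size) -- it does not invert the clone-expansion signal.
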
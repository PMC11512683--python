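"""Synthetic single-cell amplicon datasets with known ground truth.

The generator emulates the observable structure of plate-based targeted
single-cell genotyping: a clone tree with cluster-dependent clone fractions;
per-amplicon coverage following a negative binomial; PCR allelic skew that
spreads heterozygous scVAFs over roughly 0.01-0.99 (a Beta-distributed
allele-sampling fraction feeding a binomial read draw); independent
per-allele allelic dropout (dropout of the mutant allele makes a het cell
look WT, dropout of the WT allele makes it look homozygous mutant);
locus-specific sequencing/PCR error in WT cells; empty wells with at most a
couple of stray reads; a germline heterozygous SNP sharing the gDNA
amplicon's skew and dropout so phase correlations arise naturally; and a
WT-control sample co-processed on every plate.

Everything downstream of the simulator is therefore testable against exact
per-cell truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

WT_CONTROL_SAMPLE = "WT_CTRL"


@dataclass(frozen=True)
class LocusSim:
    """Generative parameters for one target mutation."""

    mutation_id: str
    has_cdna: bool = True
    error_rate: float = 7.2e-4       # mean WT scVAF noise
    error_shape: float = 2.3         # beta shape a of the noise distribution
    ado_gdna: float = 0.05           # per-allele dropout, gDNA amplicon
    ado_cdna: float = 0.25           # per-allele dropout, cDNA amplicon
    skew_a: float = 1.2              # allele-sampling fraction ~ Beta(a, b)
    skew_b: float = 1.2
    cov_gdna_mean: float = 500.0
    cov_cdna_mean: float = 150.0
    cov_dispersion: float = 2.0
    snp_id: str | None = None        # linked germline het SNP on the gDNA amplicon
    snp_in_phase: bool = True        # SNP Alt allele on the mutant haplotype
    ploidy: str = "diploid"
    deterministic: bool = False      # noise-free limit: no skew (f = 0.5),
                                     # reads split exactly as round(cov * p)

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.ado_gdna, self.ado_cdna):
            if not 0 <= p < 1:
                raise ConfigurationError("probabilities must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Study design for one simulated sample.

    ``clone_tree`` maps clone_id to its mutation set (the WT clone is
    implicit); ``clone_probs`` gives, per cluster, the probability that a
    cell belongs to each clone (remainder = WT clone); ``cluster_fractions``
    sets the cell-state composition.
    """

    loci: tuple
    clone_tree: dict = field(default_factory=lambda: {})
    cluster_fractions: dict = field(
        default_factory=lambda: {"HSC/MPP": 1.0})
    clone_probs: dict = field(default_factory=lambda: {})
    n_cells: int = 1000
    wt_control_fraction: float = 0.10
    empty_well_fraction: float = 0.02
    empty_well_read_max: int = 2
    sample_id: str = "S1"
    n_plates: int = 1

    def __post_init__(self) -> None:
        for cluster, probs in self.clone_probs.items():
            total = sum(probs.values())
            if total > 1 + 1e-9 or any(p < 0 for p in probs.values()):
                raise ConfigurationError(
                    f"clone probabilities in cluster {cluster!r} must be "
                    f"non-negative and sum to <= 1 (got {total})")
        if not 0 <= self.wt_control_fraction < 1:
            raise ConfigurationError("wt_control_fraction must lie in [0, 1)")
        if not 0 <= self.empty_well_fraction < 1:
            raise ConfigurationError("empty_well_fraction must lie in [0, 1)")
        if abs(sum(self.cluster_fractions.values()) - 1) > 1e-9:
            raise ConfigurationError("cluster fractions must sum to 1")


@dataclass
class SimResult:
    counts: pd.DataFrame
    manifest: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame


def default_config(**overrides) -> SimConfig:
    """A two-mutation linear-clone sample with one SNP-linked locus."""
    loci = (
        LocusSim("TET2_pQ726X", snp_id="rsTET2a"),
        LocusSim("TET2_pR1261C"),
    )
    base = dict(
        loci=loci,
        clone_tree={"C1": frozenset({"TET2_pQ726X"}),
                    "C2": frozenset({"TET2_pQ726X", "TET2_pR1261C"})},
        cluster_fractions={"HSC/MPP": 0.4, "LMPP": 0.3, "GMP": 0.3},
        clone_probs={"HSC/MPP": {"C1": 0.10, "C2": 0.05},
                     "LMPP": {"C1": 0.15, "C2": 0.08},
                     "GMP": {"C1": 0.25, "C2": 0.15}},
    )
    base.update(overrides)
    return SimConfig(**base)


def build_manifest(config: SimConfig) -> pd.DataFrame:
    rows = []
    for locus in config.loci:
        rows.append({"amplicon_id": f"{locus.mutation_id}_gDNA",
                     "mutation_id": locus.mutation_id, "analyte": "gDNA",
                     "linked_snp_id": locus.snp_id or "",
                     "ploidy": locus.ploidy})
        if locus.has_cdna:
            rows.append({"amplicon_id": f"{locus.mutation_id}_cDNA",
                         "mutation_id": locus.mutation_id, "analyte": "cDNA",
                         "linked_snp_id": "", "ploidy": locus.ploidy})
        if locus.snp_id:
            # the SNP reads out through its own counts rows; genotyping code
            # recognizes it via the gDNA amplicon's linked_snp_id
            rows.append({"amplicon_id": locus.snp_id,
                         "mutation_id": locus.snp_id, "analyte": "gDNA",
                         "linked_snp_id": "", "ploidy": "diploid"})
    return pd.DataFrame(rows)


def _nb_coverage(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _noise_p(rng, locus: LocusSim) -> float:
    """Per-cell error-driven alt fraction for a WT-appearing allele pool.

    Beta-distributed around ``error_rate`` so control scVAFs have realistic
    spread (shape a fixed, b solved from the mean)."""
    if locus.error_rate == 0:
        return 0.0
    a = locus.error_shape
    b = a * (1 - locus.error_rate) / locus.error_rate
    return float(rng.beta(a, b))


def _draw_reads(rng, locus: LocusSim, coverage: int, p_alt: float) -> int:
    if coverage <= 0:
        return 0
    if locus.deterministic:
        return int(round(coverage * p_alt))
    return int(rng.binomial(coverage, p_alt))


def _amplicon_reads(rng, locus: LocusSim, coverage: int, mutant: bool,
                    ado_prob: float):
    """Simulate one amplicon for one cell.

    Returns (alt_reads, ref_reads, hap1_dropped, hap2_dropped, skew).
    Haplotype 1 carries the mutation in mutant cells.  Dropout of both
    haplotypes leaves the well empty for this amplicon.
    """
    drop1 = rng.random() < ado_prob
    drop2 = rng.random() < ado_prob
    if drop1 and drop2:
        return 0, 0, True, True, float("nan")
    skew = (0.5 if locus.deterministic
            else float(rng.beta(locus.skew_a, locus.skew_b)))
    if not mutant:
        p_alt = _noise_p(rng, locus)
    elif drop1:          # mutant haplotype lost: WT-appearing
        p_alt = _noise_p(rng, locus)
    elif drop2:          # WT haplotype lost: hom-mutant-appearing
        p_alt = 1 - _noise_p(rng, locus)
    else:
        p_alt = skew
    alt = _draw_reads(rng, locus, coverage, p_alt)
    return alt, coverage - alt, drop1, drop2, skew


def _snp_reads(rng, locus: LocusSim, coverage: int, het: bool,
               drop1: bool, drop2: bool, skew: float):
    """SNP reads sharing the gDNA amplicon's skew and dropout events.

    Haplotype 1 carries the SNP Alt allele when the SNP is in phase with the
    mutation, haplotype 2 otherwise.  WT-control cells are Hom Ref (het is
    False): only error-level Alt reads.
    """
    if drop1 and drop2:
        return 0, 0
    if not het:
        p_alt = _noise_p(rng, locus)
    else:
        alt_on_hap1 = locus.snp_in_phase
        if drop1:
            p_alt = (_noise_p(rng, locus) if alt_on_hap1
                     else 1 - _noise_p(rng, locus))
        elif drop2:
            p_alt = (1 - _noise_p(rng, locus) if alt_on_hap1
                     else _noise_p(rng, locus))
        else:
            p_alt = skew if alt_on_hap1 else 1 - skew
    alt = _draw_reads(rng, locus, coverage, p_alt)
    return alt, coverage - alt


def simulate_cells(config: SimConfig, seed: int = 0) -> SimResult:
    """Generate a full plate-style dataset plus per-cell ground truth.

    Sample cells are drawn over clusters and clones; WT-control cells
    (fraction ``wt_control_fraction`` of wells, spread over plates) are WT at
    every somatic locus and Hom Ref at every SNP.  The truth table records
    each cell's clone, cluster, per-locus genotype and per-allele dropout
    events, so estimator recovery can be checked exactly.
    """
    rng = np.random.default_rng(seed)
    manifest = build_manifest(config)
    clusters = list(config.cluster_fractions)
    cluster_p = np.array([config.cluster_fractions[c] for c in clusters])
    clones = list(config.clone_tree)
    clone_sets = {c: frozenset(config.clone_tree[c]) for c in clones}
    clone_sets["WT"] = frozenset()

    n_ctrl = int(round(config.n_cells * config.wt_control_fraction))
    n_sample = config.n_cells - n_ctrl

    counts_rows, meta_rows, truth_rows = [], [], []

    def emit_cell(cell_id: str, sample_id: str, is_ctrl: bool, plate: int,
                  cluster: str | None, clone: str | None, empty: bool) -> None:
        muts = clone_sets[clone] if clone else frozenset()
        truth = {"cell_id": cell_id, "sample_id": sample_id,
                 "is_wt_control": is_ctrl, "plate": plate,
                 "cluster_label": cluster or "", "clone_id": clone or "",
                 "is_empty_well": empty}
        for locus in config.loci:
            mutant = locus.mutation_id in muts
            truth[f"geno_{locus.mutation_id}"] = "MUT" if mutant else "WT"
            if empty:
                for suffix, present in (("_gDNA", True), ("_cDNA", locus.has_cdna)):
                    if not present:
                        continue
                    cov = int(rng.integers(0, config.empty_well_read_max + 1))
                    alt = int(rng.binomial(cov, 0.5)) if cov else 0
                    counts_rows.append((cell_id, locus.mutation_id + suffix,
                                        cov - alt, alt))
                if locus.snp_id:
                    cov = int(rng.integers(0, config.empty_well_read_max + 1))
                    counts_rows.append((cell_id, locus.snp_id, cov, 0))
                truth[f"ado_mut_{locus.mutation_id}"] = False
                truth[f"ado_wt_{locus.mutation_id}"] = False
                continue
            cov_g = int(_nb_coverage(rng, locus.cov_gdna_mean,
                                     locus.cov_dispersion, 1)[0])
            if locus.deterministic:
                cov_g += cov_g % 2  # even coverage so a het splits exactly
            alt, ref, d1, d2, skew = _amplicon_reads(
                rng, locus, cov_g, mutant, locus.ado_gdna)
            counts_rows.append((cell_id, f"{locus.mutation_id}_gDNA", ref, alt))
            truth[f"ado_mut_{locus.mutation_id}"] = bool(mutant and d1)
            truth[f"ado_wt_{locus.mutation_id}"] = bool(mutant and d2)
            if locus.snp_id:
                het = not is_ctrl  # germline het in the carrier sample
                s_alt, s_ref = _snp_reads(rng, locus, cov_g, het, d1, d2, skew)
                counts_rows.append((cell_id, locus.snp_id, s_ref, s_alt))
            if locus.has_cdna:
                cov_c = int(_nb_coverage(rng, locus.cov_cdna_mean,
                                         locus.cov_dispersion, 1)[0])
                if locus.deterministic:
                    cov_c += cov_c % 2
                alt, ref, d1c, d2c, _ = _amplicon_reads(
                    rng, locus, cov_c, mutant, locus.ado_cdna)
                counts_rows.append((cell_id, f"{locus.mutation_id}_cDNA",
                                    ref, alt))
                truth[f"ado_mut_cdna_{locus.mutation_id}"] = bool(mutant and d1c)
        meta_rows.append({"cell_id": cell_id, "sample_id": sample_id,
                          "is_wt_control": is_ctrl,
                          "cluster_label": cluster or "", "sort_gate": ""})
        truth_rows.append(truth)

    for i in range(n_sample):
        cell_id = f"{config.sample_id}_c{i:05d}"
        cluster = clusters[rng.choice(len(clusters), p=cluster_p)]
        probs = config.clone_probs.get(cluster, {})
        p = np.array([probs.get(c, 0.0) for c in clones] , dtype=float)
        p_wt = 1 - p.sum()
        pick = rng.choice(len(clones) + 1, p=np.append(p, p_wt))
        clone = clones[pick] if pick < len(clones) else "WT"
        empty = rng.random() < config.empty_well_fraction
        plate = i % config.n_plates
        emit_cell(cell_id, config.sample_id, False, plate, cluster, clone, empty)

    for i in range(n_ctrl):
        cell_id = f"CTRL_c{i:05d}"
        empty = rng.random() < config.empty_well_fraction
        plate = i % config.n_plates
        emit_cell(cell_id, WT_CONTROL_SAMPLE, True, plate, None, "WT", empty)

    counts = pd.DataFrame(counts_rows,
                          columns=["cell_id", "amplicon_id",
                                   "ref_reads", "alt_reads"])
    return SimResult(counts=counts, manifest=manifest,
                     meta=pd.DataFrame(meta_rows),
                     truth=pd.DataFrame(truth_rows))


def simulate_wt_controls(config: SimConfig, seed: int = 0,
                         n_cells: int | None = None) -> SimResult:
    """Control-sample cells only, in per-plate blocks, for threshold work."""
    n = n_cells if n_cells is not None else max(
        1, int(round(config.n_cells * config.wt_control_fraction)))
    ctrl_config = SimConfig(
        loci=config.loci, clone_tree=config.clone_tree,
        cluster_fractions=config.cluster_fractions, clone_probs={},
        n_cells=n, wt_control_fraction=1.0 - 1e-12,
        empty_well_fraction=config.empty_well_fraction,
        empty_well_read_max=config.empty_well_read_max,
        sample_id=config.sample_id, n_plates=config.n_plates)
    result = simulate_cells(ctrl_config, seed=seed)
    keep = result.meta["is_wt_control"]
    cells = set(result.meta.loc[keep, "cell_id"])
    return SimResult(
        counts=result.counts[result.counts["cell_id"].isin(cells)]
        .reset_index(drop=True),
        manifest=result.manifest,
        meta=result.meta[keep].reset_index(drop=True),
        truth=result.truth[result.truth["cell_id"].isin(cells)]
        .reset_index(drop=True))


def perturb_labels(labels: pd.Series, fraction: float = 0.10,
                   seed: int = 0, from_label: str = "MUT",
                   to_label: str = "WT") -> tuple[pd.Series, pd.DataFrame]:
    """Randomly re-classify a fraction of mutant labels as WT.

    Emulates the sensitivity analysis in which a random share of
    mutant-called cells is deliberately relabeled to probe the robustness of
    downstream comparisons.  Returns the perturbed labels and a log of the
    affected cells.
    """
    if not 0 <= fraction <= 1:
        raise ConfigurationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = labels.copy()
    idx = labels.index[labels == from_label]
    k = int(round(fraction * len(idx)))
    chosen = rng.choice(idx.to_numpy(), size=min(k, len(idx)), replace=False)
    labels.loc[chosen] = to_label
    log = pd.DataFrame({"index": chosen, "from": from_label, "to": to_label})
    return labels, log
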
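"""Clone abundance across cell states and normalized mutant-clone likelihood.

Clone size is tracked across transcriptional clusters (cell states) relative
to the most primitive compartment (HSC/MPP).  At cluster level the relative
likelihood of a cell being mutant is the mutant:WT odds (count ratio), the
discrete analogue of a density ratio, and

    normalized_likelihood(cluster) =
        odds(cluster) / odds(reference cluster)

so the reference cluster is 1 by construction and values > 1 mean the clone
expands with differentiation.  Computation is per sample first, then averaged
across samples; uncertainty comes from a cell-level bootstrap.  A companion
utility converts a bulk variant allele fraction into a clonal cell fraction
(2 x VAF for an autosomal heterozygous mutation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


def _mutant_mask(assignments: pd.DataFrame, clone_mutations: dict[str, frozenset],
                 clone_of_interest: str) -> pd.Series:
    """Cells whose assigned clone carries all mutations of the clone of
    interest (the clone itself and its descendants)."""
    target = clone_mutations[clone_of_interest]
    if not target:
        raise ConfigurationError("clone of interest must carry >= 1 mutation")
    carrier = {cid for cid, muts in clone_mutations.items() if target <= muts}
    return assignments["clone_id"].isin(carrier)


def clone_fraction_by_cluster(assignments: pd.DataFrame, meta: pd.DataFrame,
                              clone_mutations: dict[str, frozenset],
                              clone_of_interest: str,
                              reference_cluster: str,
                              per_sample: bool = True) -> pd.DataFrame:
    """Per-cluster clone fraction and normalized mutant likelihood.

    ``assignments`` has cell_id and clone_id (unassignable cells excluded
    beforehand or given clone_id NA); ``clone_mutations`` maps clone_id to
    its mutation set (the WT root has an empty set).  Cells carrying the
    clone of interest's mutations count as mutant; all other assigned cells
    count as WT for that clone.  With ``per_sample`` the odds are computed
    within each sample and averaged across samples.
    """
    df = assignments.dropna(subset=["clone_id"]).merge(
        meta[["cell_id", "sample_id", "cluster_label"]], on="cell_id")
    df = df.dropna(subset=["cluster_label"])
    df["is_mut"] = _mutant_mask(df, clone_mutations, clone_of_interest)

    def _per_frame(frame: pd.DataFrame) -> pd.DataFrame | None:
        tab = (frame.groupby("cluster_label", observed=True)["is_mut"]
               .agg(n_mut="sum", n_total="count").reset_index())
        tab["n_wt"] = tab["n_total"] - tab["n_mut"]
        ref = tab[tab["cluster_label"] == reference_cluster]
        if len(ref) == 0 or ref["n_mut"].iloc[0] == 0 or ref["n_wt"].iloc[0] == 0:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            tab["relative_likelihood"] = tab["n_mut"] / tab["n_wt"]
        ref_odds = float(ref["n_mut"].iloc[0] / ref["n_wt"].iloc[0])
        tab["normalized_likelihood"] = tab["relative_likelihood"] / ref_odds
        tab["clone_fraction"] = tab["n_mut"] / tab["n_total"]
        return tab

    if not per_sample:
        tab = _per_frame(df)
        if tab is None:
            raise ConfigurationError(
                f"reference cluster {reference_cluster!r} is empty or "
                "single-genotype")
        return tab.drop(columns="n_total")

    per_sample_tabs = []
    for sample, frame in df.groupby("sample_id"):
        tab = _per_frame(frame)
        if tab is None:
            log.warning("sample %s skipped: reference cluster %r empty or "
                        "single-genotype", sample, reference_cluster)
            continue
        tab["sample_id"] = sample
        per_sample_tabs.append(tab)
    if not per_sample_tabs:
        raise ConfigurationError(
            f"no sample has both genotypes in reference cluster "
            f"{reference_cluster!r}")
    allsamp = pd.concat(per_sample_tabs, ignore_index=True)
    out = (allsamp.groupby("cluster_label", observed=True)
           .agg(n_mut=("n_mut", "sum"), n_wt=("n_wt", "sum"),
                clone_fraction=("clone_fraction", "mean"),
                relative_likelihood=("relative_likelihood", "mean"),
                normalized_likelihood=("normalized_likelihood", "mean"),
                n_samples=("sample_id", "nunique"))
           .reset_index())
    return out


def mean_relative_density(density_a, density_b) -> float:
    """Mean relative density between two sample conditions:
    mean(density in condition A) / mean(density in condition B)."""
    a = float(np.mean(np.asarray(density_a, dtype=float)))
    b = float(np.mean(np.asarray(density_b, dtype=float)))
    if b <= 0:
        raise ConfigurationError("condition-B density must be positive")
    return a / b


def bootstrap_abundance_ci(assignments: pd.DataFrame, meta: pd.DataFrame,
                           clone_mutations: dict[str, frozenset],
                           clone_of_interest: str, reference_cluster: str,
                           reps: int = 1000, seed: int = 0,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Percentile bootstrap CIs for the per-cluster normalized likelihood.

    Cells are resampled with replacement within each sample; clusters whose
    CI excludes 1 are flagged as credibly shifted relative to the reference.
    """
    if reps < 100:
        raise ConfigurationError("bootstrap needs at least 100 replicates")
    rng = np.random.default_rng(seed)
    point = clone_fraction_by_cluster(assignments, meta, clone_mutations,
                                      clone_of_interest, reference_cluster)
    merged = assignments.dropna(subset=["clone_id"]).merge(
        meta[["cell_id", "sample_id", "cluster_label"]], on="cell_id")
    merged = merged.dropna(subset=["cluster_label"]).reset_index(drop=True)
    groups = {s: idx.to_numpy() for s, idx in merged.groupby("sample_id").groups.items()}
    stats: dict[str, list] = {c: [] for c in point["cluster_label"]}
    for _ in range(reps):
        take = np.concatenate([
            rng.choice(idx, size=idx.size, replace=True)
            for idx in groups.values()])
        boot = merged.iloc[take]
        try:
            tab = clone_fraction_by_cluster(
                boot[["cell_id", "clone_id"]].assign(
                    cell_id=np.arange(len(boot)).astype(str)),
                boot[["sample_id", "cluster_label"]].assign(
                    cell_id=np.arange(len(boot)).astype(str)),
                clone_mutations, clone_of_interest, reference_cluster)
        except ConfigurationError:
            continue
        got = dict(zip(tab["cluster_label"], tab["normalized_likelihood"]))
        for c in stats:
            if c in got and np.isfinite(got[c]):
                stats[c].append(got[c])
    lo, hi = [], []
    for c in point["cluster_label"]:
        vals = np.asarray(stats[c])
        if vals.size == 0:
            lo.append(np.nan)
            hi.append(np.nan)
        else:
            lo.append(float(np.quantile(vals, alpha / 2)))
            hi.append(float(np.quantile(vals, 1 - alpha / 2)))
    point = point.copy()
    point["ci_low"] = lo
    point["ci_high"] = hi
    point["ci_excludes_1"] = (point["ci_high"] < 1) | (point["ci_low"] > 1)
    return point


def bulk_clone_fraction(vaf: float, ploidy: str = "diploid") -> float:
    """Clonal cell fraction implied by a bulk VAF.

    For an autosomal heterozygous mutation the clone fraction is 2 x VAF;
    at a hemizygous locus the VAF is the clone fraction directly.  A diploid
    VAF above 0.5 (loss of heterozygosity or noise) is capped at a clone
    fraction of 1 with a warning.
    """
    if not 0 <= vaf <= 1:
        raise ConfigurationError("VAF must lie in [0, 1]")
    if ploidy == "hemizygous":
        return vaf
    if vaf > 0.5:
        log.warning("diploid VAF %.3f exceeds 0.5; clone fraction capped at 1",
                    vaf)
        return 1.0
    return 2 * vaf
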
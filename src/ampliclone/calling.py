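"""scVAF threshold derivation from WT-control cells and genotype calling.

The calling scheme exploits WT spike-in control cells co-processed on every
plate: because their genotype is known a priori, the distribution of their
single-cell variant allele fractions (scVAF = variant reads / coverage)
measures the locus-specific error ("noise") rate.  Thresholds:

    wt_threshold      = mean(scVAF_ctrl) + k * SD(scVAF_ctrl)      (k = 3)
    mutant_threshold  = wt_threshold + margin                      (margin = 0.01)
    hom_mutant_threshold = 1 - mutant_threshold

Cells with scVAF strictly below the WT threshold are called WT; cells at or
above the mutant threshold with enough mutant reads are called mutant;
anything in between is undetermined.  gDNA and cDNA amplicons are called
separately and combined into a consensus.  The threshold choice is validated
by bootstrap-resampling the control scVAFs, fitting a beta distribution to
each resample by the method of moments, and evaluating the upper-tail
probability beyond the mutant threshold (the per-locus false-positive rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ContractError, EstimationError, StructureError
from .io import Dataset, RunConfig

log = logging.getLogger(__name__)

# Amplicon-level call states
WT = "WT"
MUT = "MUT"
HOM_MUT = "HOM_MUT"
UNDETERMINED = "UNDETERMINED"
UNDETECTED = "UNDETECTED"

AMPLICON_STATES = (WT, MUT, HOM_MUT, UNDETERMINED, UNDETECTED)
MUTANT_STATES = (MUT, HOM_MUT)
NON_INFORMATIVE = (UNDETERMINED, UNDETECTED, None)


@dataclass(frozen=True)
class ThresholdSet:
    """Locus-specific scVAF cutoffs with the control moments they came from."""

    amplicon_id: str
    wt_threshold: float
    mutant_threshold: float
    hom_mutant_threshold: float
    control_mean: float = float("nan")
    control_sd: float = float("nan")
    n_control_cells: int = 0
    strategy: str = "control_thresholds"

    def __post_init__(self) -> None:
        if not (0 <= self.wt_threshold < self.mutant_threshold
                < self.hom_mutant_threshold <= 1):
            raise ConfigurationError(
                f"thresholds out of order for {self.amplicon_id}: "
                f"{self.wt_threshold} / {self.mutant_threshold} / "
                f"{self.hom_mutant_threshold}")


@dataclass(frozen=True)
class AmpliconCall:
    cell_id: str
    amplicon_id: str
    scvaf: float
    coverage: int
    mutant_reads: int
    call: str
    reason: str


@dataclass(frozen=True)
class ConsensusCall:
    cell_id: str
    mutation_id: str
    gdna_call: str | None
    cdna_call: str | None
    consensus: str
    ado_flag: str | None = None


@dataclass(frozen=True)
class FpValidation:
    """Beta-model false-positive probability for one amplicon's thresholds."""

    amplicon_id: str
    fp_probability: float
    fp_range: tuple
    beta_params: tuple  # (a, b) fitted on the full control sample, or None
    n_reps: int
    replicate_tails: tuple = ()


def compute_scvaf(variant_reads: int, coverage: int) -> float:
    """scVAF = variant reads / coverage, as an exact ratio."""
    if coverage <= 0:
        raise ContractError("scVAF is undefined at zero coverage; "
                            "the amplicon must be called UNDETECTED first")
    if not 0 <= variant_reads <= coverage:
        raise ContractError("variant reads must lie in [0, coverage]")
    return variant_reads / coverage


def mutant_threshold_from_wt(wt_threshold: float,
                             config: RunConfig | None = None) -> float:
    """Mutant-calling cutoff: the WT cutoff plus the fixed scVAF margin."""
    margin = (config or RunConfig()).mutant_margin
    return wt_threshold + margin


def thresholds_from_moments(mean: float, sd: float, amplicon_id: str = "",
                            config: RunConfig | None = None,
                            n_control_cells: int = 0) -> ThresholdSet:
    """Build a ThresholdSet from control-sample moments (mean, SD of scVAF)."""
    config = config or RunConfig()
    wt = mean + config.sd_multiplier * sd
    mut = mutant_threshold_from_wt(wt, config)
    return ThresholdSet(
        amplicon_id=amplicon_id,
        wt_threshold=wt,
        mutant_threshold=mut,
        hom_mutant_threshold=1 - mut,
        control_mean=mean,
        control_sd=sd,
        n_control_cells=n_control_cells,
    )


def derive_thresholds(control_scvafs: Sequence[float], amplicon_id: str = "",
                      config: RunConfig | None = None) -> ThresholdSet:
    """Derive WT/mutant/hom-mutant scVAF cutoffs from WT-control cells.

    ``control_scvafs`` must come only from control cells passing the coverage
    filter for this amplicon's analyte.  SD is the sample standard deviation
    (n-1 denominator).
    """
    config = config or RunConfig()
    x = np.asarray(control_scvafs, dtype=float)
    if x.size < config.min_control_cells:
        raise EstimationError(
            f"amplicon {amplicon_id!r}: only {x.size} WT-control cells pass "
            f"filters (minimum {config.min_control_cells})")
    if ((x < 0) | (x > 1)).any():
        raise ContractError("control scVAFs must lie in [0, 1]")
    return thresholds_from_moments(float(x.mean()), float(x.std(ddof=1)),
                                   amplicon_id, config, n_control_cells=x.size)


def control_scvaf_distributions(dataset: Dataset,
                                config: RunConfig | None = None
                                ) -> dict[str, np.ndarray]:
    """Per-amplicon scVAFs of WT-control cells passing the coverage filter."""
    config = config or RunConfig()
    ctrl = set(dataset.control_cells)
    counts = dataset.counts[dataset.counts["cell_id"].isin(ctrl)]
    merged = counts.merge(dataset.manifest[["amplicon_id", "analyte"]],
                          on="amplicon_id", how="inner")
    cov = merged["ref_reads"] + merged["alt_reads"]
    min_cov = merged["analyte"].map(
        {"gDNA": config.min_coverage_gdna, "cDNA": config.min_coverage_cdna})
    merged = merged[cov >= min_cov]
    out: dict[str, np.ndarray] = {}
    for amp, grp in merged.groupby("amplicon_id"):
        total = (grp["ref_reads"] + grp["alt_reads"]).to_numpy(float)
        out[str(amp)] = grp["alt_reads"].to_numpy(float) / total
    return out


def call_amplicon(cell_id: str, amplicon_id: str, ref_reads: int, alt_reads: int,
                  analyte: str, thresholds: ThresholdSet,
                  config: RunConfig | None = None,
                  ploidy: str = "diploid") -> AmpliconCall:
    """Call one cell x amplicon observation against locus-specific thresholds.

    Decision order: coverage below the analyte minimum -> UNDETECTED;
    scVAF < wt_threshold -> WT; scVAF >= mutant_threshold with at least
    ``min_mutant_reads`` mutant reads -> MUT (HOM_MUT when scVAF also reaches
    the hom-mutant cutoff at a diploid locus); otherwise UNDETERMINED.
    Hemizygous loci never receive the HOM_MUT distinction.
    """
    config = config or RunConfig()
    coverage = ref_reads + alt_reads
    if coverage < config.min_coverage(analyte):
        return AmpliconCall(cell_id, amplicon_id, float("nan"), coverage,
                            alt_reads, UNDETECTED, "low_coverage")
    scvaf = compute_scvaf(alt_reads, coverage)
    if scvaf < thresholds.wt_threshold:
        return AmpliconCall(cell_id, amplicon_id, scvaf, coverage, alt_reads,
                            WT, "below_wt_threshold")
    if scvaf >= thresholds.mutant_threshold:
        if alt_reads < config.min_mutant_reads:
            return AmpliconCall(cell_id, amplicon_id, scvaf, coverage, alt_reads,
                                UNDETERMINED, "insufficient_mutant_reads")
        if ploidy == "diploid" and scvaf >= thresholds.hom_mutant_threshold:
            return AmpliconCall(cell_id, amplicon_id, scvaf, coverage, alt_reads,
                                HOM_MUT, "above_hom_threshold")
        return AmpliconCall(cell_id, amplicon_id, scvaf, coverage, alt_reads,
                            MUT, "above_mutant_threshold")
    return AmpliconCall(cell_id, amplicon_id, scvaf, coverage, alt_reads,
                        UNDETERMINED, "borderline_scvaf")


def consensus_call(gdna: AmpliconCall | str | None,
                   cdna: AmpliconCall | str | None,
                   cell_id: str = "", mutation_id: str = "") -> ConsensusCall:
    """Combine gDNA and cDNA amplicon calls into a consensus genotype.

    1. mutant in either analyte -> MUT (HOM_MUT counts as mutant);
    2. both WT -> WT;
    3. gDNA WT, cDNA undetected/undetermined/absent -> WT;
    4. cDNA WT, gDNA undetected/undetermined -> UNDETERMINED
       (cDNA amplicons have a high allelic-dropout rate);
    both non-informative -> UNDETERMINED.
    """
    def _state(x):
        return x.call if isinstance(x, AmpliconCall) else x

    if (isinstance(gdna, AmpliconCall) and isinstance(cdna, AmpliconCall)
            and gdna.cell_id != cdna.cell_id):
        raise ContractError("gDNA and cDNA calls refer to different cells")
    g, c = _state(gdna), _state(cdna)
    for s in (g, c):
        if s is not None and s not in AMPLICON_STATES:
            raise ContractError(f"unknown amplicon call state {s!r}")

    if g in MUTANT_STATES or c in MUTANT_STATES:
        consensus = MUT
    elif g == WT and c == WT:
        consensus = WT
    elif g == WT and c in NON_INFORMATIVE:
        consensus = WT
    else:
        # cDNA WT with uninformative gDNA, or nothing informative at all
        consensus = UNDETERMINED
    if isinstance(gdna, AmpliconCall):
        cell_id = cell_id or gdna.cell_id
    return ConsensusCall(cell_id, mutation_id, g, c, consensus)


def _fit_beta_moments(x: np.ndarray) -> tuple | None:
    """Method-of-moments beta fit; zeros are nudged to half the smallest
    positive value (beta support is open). Returns None when degenerate."""
    x = x.astype(float).copy()
    pos = x[x > 0]
    if pos.size == 0:
        return None
    x[x == 0] = pos.min() / 2
    m, v = x.mean(), x.var(ddof=1)
    if v <= 0 or v >= m * (1 - m):
        return None
    t = m * (1 - m) / v - 1
    return (m * t, (1 - m) * t)


def beta_tail_probability(mean: float, sd: float, threshold: float) -> float:
    """Upper-tail probability beyond ``threshold`` of a beta distribution
    fitted by method of moments to (mean, sd). Degenerate moments give 0
    when the threshold exceeds the mean, else 1."""
    v = sd * sd
    if v <= 0 or v >= mean * (1 - mean):
        return 0.0 if threshold > mean else 1.0
    t = mean * (1 - mean) / v - 1
    a, b = mean * t, (1 - mean) * t
    return float(stats.beta.sf(threshold, a, b))


def validate_fp_probability(control_scvafs: Sequence[float],
                            thresholds: ThresholdSet,
                            config: RunConfig | None = None,
                            rng: np.random.Generator | None = None
                            ) -> FpValidation:
    """Bootstrap/beta false-positive validation of the mutant threshold.

    Each bootstrap replicate resamples the control scVAFs with replacement,
    fits a beta distribution by the method of moments, and records the
    upper-tail probability beyond the mutant threshold.  The point estimate
    is the tail probability of the fit to the full control sample.  An
    all-zero (noise-free) control distribution has false-positive
    probability 0 by construction and the beta fit is skipped.
    """
    config = config or RunConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    x = np.asarray(control_scvafs, dtype=float)
    full_fit = _fit_beta_moments(x)
    if full_fit is None:
        log.info("amplicon %s: degenerate control distribution; "
                 "beta fit skipped, fp_probability = 0", thresholds.amplicon_id)
        return FpValidation(thresholds.amplicon_id, 0.0, (0.0, 0.0), None, 0)
    point = float(stats.beta.sf(thresholds.mutant_threshold, *full_fit))
    tails = []
    for _ in range(config.bootstrap_reps):
        fit = _fit_beta_moments(rng.choice(x, size=x.size, replace=True))
        if fit is not None:
            tails.append(float(stats.beta.sf(thresholds.mutant_threshold, *fit)))
    fp_range = (min(tails), max(tails)) if tails else (point, point)
    return FpValidation(thresholds.amplicon_id, point, fp_range, full_fit,
                        len(tails), tuple(tails))


def minima_thresholds(scvafs: Sequence[float], amplicon_id: str = "",
                      grid_points: int = 1001,
                      wt_threshold: float | None = None) -> ThresholdSet:
    """Alternative calling cutoffs from the minima of the scVAF distribution.

    The all-cell scVAF histogram at a heterozygous locus is trimodal: a peak
    near 0 (reference-only), one near 0.5 (biallelic detection) and one near
    1 (variant-only).  A Gaussian KDE (Silverman bandwidth) is evaluated on a
    uniform grid over [0, 1]; the two interior local minima separating the
    three tallest peaks become the mutant-calling (lower) and hom-calling
    (upper) cutoffs.  When a control-derived WT cutoff is supplied it is
    retained, so that only the mutant cutoff moves: cells between the WT
    cutoff and the lower minimum become undetermined rather than WT.
    """
    x = np.asarray(scvafs, dtype=float)
    if x.size < 10:
        raise StructureError("too few scVAFs for a distribution-minima fit")
    grid = np.linspace(0.0, 1.0, grid_points)
    dens = stats.gaussian_kde(x, bw_method="silverman")(grid)
    d = np.diff(dens)
    rising, falling = d > 0, d < 0
    # interior extrema; a grid endpoint counts as a peak when the density
    # falls away from it (left end) or rises into it (right end)
    maxima = [i for i in range(1, grid_points - 1) if falling[i] and rising[i - 1]]
    if falling[0]:
        maxima.insert(0, 0)
    if rising[-1]:
        maxima.append(grid_points - 1)
    minima = [i for i in range(1, grid_points - 1) if rising[i] and falling[i - 1]]
    if len(maxima) < 3 or len(minima) < 2:
        raise StructureError(
            f"amplicon {amplicon_id!r}: scVAF distribution lacks a three-peak "
            "structure; fall back to the control_thresholds strategy")
    peaks = sorted(sorted(maxima, key=lambda i: -dens[i])[:3])
    cuts = []
    for lo, hi in zip(peaks[:-1], peaks[1:]):
        seg = np.arange(lo + 1, hi)
        cuts.append(grid[seg[np.argmin(dens[seg])]])
    return _minima_thresholdset(amplicon_id, float(cuts[0]), float(cuts[1]),
                                wt_threshold)


def _minima_thresholdset(amplicon_id: str, lower: float, upper: float,
                         wt_threshold: float | None = None) -> ThresholdSet:
    # Without a control-derived WT cutoff, WT and mutant cutoffs coincide at
    # the lower minimum; the WT cutoff is nudged down by one grid step to
    # preserve the ordering invariant.
    wt = lower - 1e-3 if wt_threshold is None else min(wt_threshold, lower - 1e-3)
    return ThresholdSet(
        amplicon_id=amplicon_id,
        wt_threshold=wt,
        mutant_threshold=lower,
        hom_mutant_threshold=upper,
        strategy="distribution_minima",
    )


def derive_all_thresholds(dataset: Dataset, config: RunConfig | None = None
                          ) -> dict[str, ThresholdSet]:
    """Control-based thresholds for every amplicon with enough control cells."""
    config = config or RunConfig()
    controls = control_scvaf_distributions(dataset, config)
    out = {}
    for amp in dataset.manifest["amplicon_id"]:
        if amp in controls and controls[amp].size >= config.min_control_cells:
            out[amp] = derive_thresholds(controls[amp], amp, config)
        else:
            n = controls.get(amp, np.empty(0)).size
            log.warning("amplicon %s: %d control cells pass filters "
                        "(minimum %d); no thresholds derived",
                        amp, n, config.min_control_cells)
    return out


def call_dataset(dataset: Dataset, thresholds: Mapping[str, ThresholdSet],
                 config: RunConfig | None = None,
                 include_controls: bool = False) -> pd.DataFrame:
    """Call every cell x mutation in a dataset and build consensus genotypes.

    Returns one row per cell x mutation with the per-analyte calls, scVAFs,
    coverages and the consensus genotype.  WT-control cells parameterize the
    thresholds and are excluded from the output unless requested.
    """
    config = config or RunConfig()
    manifest = dataset.manifest
    snp_ids = set(manifest.loc[manifest["linked_snp_id"].notna()
                               & (manifest["linked_snp_id"] != ""),
                               "linked_snp_id"])
    counts = dataset.counts
    if not include_controls:
        counts = counts[counts["cell_id"].isin(set(dataset.sample_cells))]
    amp_info = manifest.set_index("amplicon_id")
    per_amp: dict[tuple, AmpliconCall] = {}
    for row in counts.itertuples(index=False):
        if row.amplicon_id not in amp_info.index or row.amplicon_id in snp_ids:
            continue
        if row.amplicon_id not in thresholds:
            continue
        info = amp_info.loc[row.amplicon_id]
        per_amp[(row.cell_id, row.amplicon_id)] = call_amplicon(
            row.cell_id, row.amplicon_id, int(row.ref_reads), int(row.alt_reads),
            info["analyte"], thresholds[row.amplicon_id], config,
            ploidy=info["ploidy"])

    records = []
    mutations = [m for m in manifest["mutation_id"].unique()
                 if m not in {amp_info.loc[s, "mutation_id"]
                              for s in snp_ids if s in amp_info.index}]
    cells = sorted({c for c, _ in per_amp})
    for mutation in mutations:
        amps = manifest[manifest["mutation_id"] == mutation]
        gdna_amp = amps.loc[amps["analyte"] == "gDNA", "amplicon_id"]
        cdna_amp = amps.loc[amps["analyte"] == "cDNA", "amplicon_id"]
        gdna_amp = gdna_amp.iloc[0] if len(gdna_amp) else None
        cdna_amp = cdna_amp.iloc[0] if len(cdna_amp) else None
        for cell in cells:
            g = per_amp.get((cell, gdna_amp)) if gdna_amp else None
            c = per_amp.get((cell, cdna_amp)) if cdna_amp else None
            if g is None and c is None:
                continue
            # an amplicon with no counts row at all behaves as undetected
            cons = consensus_call(g if g else UNDETECTED, c,
                                  cell_id=cell, mutation_id=mutation)
            records.append({
                "cell_id": cell, "mutation_id": mutation,
                "gdna_call": g.call if g else None,
                "cdna_call": c.call if c else None,
                "consensus": cons.consensus,
                "gdna_scvaf": g.scvaf if g else float("nan"),
                "cdna_scvaf": c.scvaf if c else float("nan"),
                "gdna_coverage": g.coverage if g else 0,
                "cdna_coverage": c.coverage if c else 0,
                "ado_flag": None,
            })
    return pd.DataFrame.from_records(records)


def thresholds_table(thresholds: Mapping[str, ThresholdSet],
                     validations: Mapping[str, FpValidation] | None = None
                     ) -> pd.DataFrame:
    """Flatten threshold sets (and optional FP validations) into a table."""
    rows = []
    for amp, t in thresholds.items():
        row = {
            "amplicon_id": amp, "control_mean": t.control_mean,
            "control_sd": t.control_sd, "wt_threshold": t.wt_threshold,
            "mutant_threshold": t.mutant_threshold,
            "hom_mutant_threshold": t.hom_mutant_threshold,
            "n_control_cells": t.n_control_cells, "strategy": t.strategy,
        }
        if validations and amp in validations:
            row["fp_probability"] = validations[amp].fp_probability
        rows.append(row)
    return pd.DataFrame(rows)
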
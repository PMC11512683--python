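"""Allelic-dropout (ADO) detection and estimation.

Single-cell PCR can fail to amplify one of a cell's two alleles, making a
heterozygous mutant cell look WT (mutant-allele ADO) or homozygous mutant
(WT-allele ADO).  Two complementary estimators are implemented:

* **SNP method** — a germline heterozygous SNP covered by the same gDNA
  amplicon reports on both haplotypes in every cell.  The allele observed in
  the WT-control sample is the Ref allele; the allele private to the carrier
  sample is Alt.  Cells calling Hom Ref at the SNP lost the Alt haplotype,
  Hom Alt cells lost the Ref haplotype.  The sign of the correlation between
  mutation and SNP scVAFs phases the SNP against the mutation, which lets
  apparently-WT cells with dropout of the mutant haplotype be reassigned to
  "undetermined" instead of diluting the WT pool.

* **Homozygous-frequency method** — for loci without a linked SNP, assuming
  the mutation is heterozygous, homozygous-mutant calls can only arise from
  WT-allele dropout, so  WT ADO rate = n_hom / (n_het + 2 * n_hom).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .calling import MUT, UNDETERMINED, WT, ConsensusCall, ThresholdSet
from .errors import ConfigurationError, InsufficientDataError
from .io import RunConfig

HOM_REF = "HomRef"
HET = "Het"
HOM_ALT = "HomAlt"
SNP_UNDETECTED = "Undetected"
SNP_STATES = (HOM_REF, HET, HOM_ALT, SNP_UNDETECTED)

IN_PHASE = "in_phase"
OUT_OF_PHASE = "out_of_phase"
AMBIGUOUS = "ambiguous"

MUTANT_ALLELE_ADO = "mutant_allele_ADO"


@dataclass(frozen=True)
class SnpThresholds:
    """scVAF cutoffs for SNP genotype calling, from WT-control Hom-Ref cells.

    alt_detection_threshold = control mean + k*SD + margin (as for mutations);
    hom_alt_threshold is its mirror image, 1 - alt_detection_threshold.
    """

    snp_id: str
    alt_detection_threshold: float
    hom_alt_threshold: float

    def __post_init__(self) -> None:
        if not (0 < self.alt_detection_threshold
                < self.hom_alt_threshold < 1):
            raise ConfigurationError(
                f"SNP thresholds out of order for {self.snp_id}")


@dataclass(frozen=True)
class PhaseCall:
    snp_id: str
    mutation_id: str
    phase: str
    correlation: float
    p_value: float
    n_cells_used: int


@dataclass(frozen=True)
class AdoEstimate:
    locus_id: str
    method: str  # "snp" or "hom_frequency"
    ado_rate_ref_allele: float | None = None
    ado_rate_alt_allele: float | None = None
    wt_ado_rate: float | None = None
    n_cells: int = 0


def snp_thresholds_from_controls(control_scvafs, snp_id: str = "",
                                 config: RunConfig | None = None
                                 ) -> SnpThresholds:
    """Derive SNP-calling cutoffs from WT-control (Hom-Ref) cell scVAFs."""
    config = config or RunConfig()
    x = np.asarray(control_scvafs, dtype=float)
    if x.size < config.min_control_cells:
        raise InsufficientDataError(
            f"SNP {snp_id!r}: only {x.size} control cells "
            f"(minimum {config.min_control_cells})")
    alt_det = (float(x.mean()) + config.sd_multiplier * float(x.std(ddof=1))
               + config.mutant_margin)
    return SnpThresholds(snp_id, alt_det, 1 - alt_det)


def call_snp_genotype(snp_scvaf: float, thresholds: SnpThresholds,
                      coverage: int | None = None,
                      min_coverage: int = 50) -> str:
    """Hom Ref / Het / Hom Alt call for one cell's SNP observation.

    Hom Ref below the Alt-detection cutoff (Alt-allele dropout), Hom Alt
    above its mirror image (Ref-allele dropout), Het in between (biallelic
    detection).  A SNP amplicon failing the gDNA coverage filter is
    Undetected.
    """
    if coverage is not None and coverage < min_coverage:
        return SNP_UNDETECTED
    if snp_scvaf < thresholds.alt_detection_threshold:
        return HOM_REF
    if snp_scvaf > thresholds.hom_alt_threshold:
        return HOM_ALT
    return HET


def infer_phase(mutation_scvafs, snp_scvafs, snp_id: str = "",
                mutation_id: str = "", config: RunConfig | None = None
                ) -> PhaseCall:
    """Phase a germline SNP against a somatic mutation.

    Both scVAFs are driven by the same per-cell allelic amplification skew,
    so over cells with both amplicons detected their Pearson correlation is
    positive when the SNP Alt allele shares the mutant haplotype (in-phase)
    and negative otherwise.  Significance is a two-sided test at
    ``config.phase_alpha``; non-significant correlations are ambiguous and
    excluded from rescue rather than guessed.
    """
    config = config or RunConfig()
    x = np.asarray(mutation_scvafs, dtype=float)
    y = np.asarray(snp_scvafs, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("paired scVAF arrays differ in length")
    if x.size < config.min_phase_cells:
        raise InsufficientDataError(
            f"phase inference needs >= {config.min_phase_cells} paired cells; "
            f"got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        return PhaseCall(snp_id, mutation_id, AMBIGUOUS, float("nan"),
                         float("nan"), x.size)
    r, p = stats.pearsonr(x, y)
    if p < config.phase_alpha and r > 0:
        phase = IN_PHASE
    elif p < config.phase_alpha and r < 0:
        phase = OUT_OF_PHASE
    else:
        phase = AMBIGUOUS
    return PhaseCall(snp_id, mutation_id, phase, float(r), float(p), x.size)


def apply_snp_ado_rescue(consensus: ConsensusCall, snp_call: str,
                         phase: PhaseCall) -> ConsensusCall:
    """Reassign apparently-WT cells whose mutant haplotype dropped out.

    Mutant calls never change (the SNP analysis is not required).  A WT call
    becomes UNDETERMINED, flagged ``mutant_allele_ADO``, when the SNP shows
    loss of the haplotype that carries the mutation: Hom Ref under in-phase,
    Hom Alt under out-of-phase.  Any other SNP state confirms the WT call;
    an undetected SNP or ambiguous phase leaves the consensus unchanged.
    """
    if snp_call not in SNP_STATES:
        raise ConfigurationError(f"unknown SNP call {snp_call!r}")
    if consensus.consensus != WT or snp_call == SNP_UNDETECTED:
        return consensus
    if phase.phase == AMBIGUOUS:
        return consensus
    lost_mutant_hap = (HOM_REF if phase.phase == IN_PHASE else HOM_ALT)
    if snp_call == lost_mutant_hap:
        return replace(consensus, consensus=UNDETERMINED,
                       ado_flag=MUTANT_ALLELE_ADO)
    return consensus


def ado_rate_from_snp(snp_calls, locus_id: str = "") -> AdoEstimate:
    """Per-allele ADO rates from SNP genotypes of carrier-sample cells.

    Over cells passing genotyping QC (SNP detected), the fraction called
    Hom Ref estimates Alt-allele dropout and the fraction called Hom Alt
    estimates Ref-allele dropout.
    """
    calls = [c for c in snp_calls if c != SNP_UNDETECTED]
    n = len(calls)
    if n == 0:
        raise InsufficientDataError(f"SNP {locus_id!r}: no genotyped cells")
    return AdoEstimate(
        locus_id=locus_id, method="snp",
        ado_rate_alt_allele=calls.count(HOM_REF) / n,
        ado_rate_ref_allele=calls.count(HOM_ALT) / n,
        n_cells=n,
    )


def ado_rate_from_hom(n_het_mut: int, n_hom_mut: int,
                      locus_id: str = "") -> AdoEstimate:
    """WT-allele ADO rate from the homozygous-mutant frequency.

    Assuming the mutation is heterozygous, every homozygous-mutant call is a
    het cell that lost its WT allele, giving
    WT ADO rate = n_hom / (n_het + 2 * n_hom).
    """
    if n_het_mut < 0 or n_hom_mut < 0:
        raise ConfigurationError("counts must be non-negative")
    total = n_het_mut + n_hom_mut
    if total == 0:
        raise InsufficientDataError(
            f"locus {locus_id!r}: no mutant cells to estimate ADO from")
    rate = n_hom_mut / (n_het_mut + 2 * n_hom_mut)
    return AdoEstimate(locus_id=locus_id, method="hom_frequency",
                       wt_ado_rate=rate, n_cells=total)
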
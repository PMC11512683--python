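"""Bulk-variant post-processing: caller filters, germline/artefact flags,
pathogenic-driver annotation and sample-level CH classification.

Variants called by VarDict and Mutect2 in tumor-only mode are filtered
separately (read support, base/mapping quality, strand and position bias for
VarDict; default caller filters plus read support for Mutect2), flagged as
likely germline or artefact (population allele frequency, the ~0.5 / >0.9 VAF
bands, panel of normals, cohort recurrence — each with somatic-hotspot
rescues), and the survivors annotated as pathogenic drivers by an eight-rule
scheme (truncating mutations in known CH genes, hotspot residues, functional
domain windows, CALR exon 9, FLT3-ITD, COSMIC recurrence, InterPro domains).
A sample is CH-positive when it carries at least one pathogenic driver at or
above the VAF cutoff.  External annotations (COSMIC counts, population AF,
InterPro membership) are input columns, keeping the engine offline and
reproducible; every decision records the rule identifiers that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import pandas as pd

from .errors import FormatError

SNV = "SNV"
INDEL = "indel"
ITD = "ITD"

TRUNCATING = ("nonsense", "frameshift", "splice_site")
NON_SYNONYMOUS_EXCLUDED = ("synonymous",)

MAPQ_EXEMPT_GENES = ("U2AF1", "U2AF1L5")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated bulk variant from one caller."""

    gene: str
    chrom: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""
    variant_class: str = SNV  # SNV | indel | ITD
    consequence: str = "missense"
    protein_position: int | None = None
    protein_change: str = ""
    vaf: float = 0.0
    depth: int = 0
    alt_reads: int = 0
    alt_reads_forward: int = 0
    alt_reads_reverse: int = 0
    mean_base_quality: float = 0.0
    mean_mapping_quality: float = 0.0
    strand_bias_p: float = 1.0
    position_bias: bool = False
    caller: str = "vardict"  # vardict | mutect2
    caller_filters: frozenset = frozenset({"PASS"})
    population_af: float = 0.0  # max across gnomAD / 1000G / ESP6500
    cosmic_count: int = 0
    ch_list_member: bool = False
    ch_list_count: int = 0
    in_panel_of_normals: bool = False
    cohort_recurrence: int = 1
    in_interpro_domain: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise FormatError("vaf must lie in [0, 1]")
        if self.alt_reads_forward + self.alt_reads_reverse > self.alt_reads:
            raise FormatError("directional read counts exceed alt_reads")

    @property
    def key(self) -> tuple:
        return (self.gene, self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING

    @property
    def is_non_synonymous(self) -> bool:
        return self.consequence not in NON_SYNONYMOUS_EXCLUDED


@dataclass(frozen=True)
class ReferenceResources:
    truncating_driver_genes: frozenset
    hotspots: tuple  # (gene, residue, required_change or "")
    domain_windows: tuple  # (gene, start, end)
    special_truncating: tuple  # (gene, start, end)
    ch_variants: tuple = ()  # (gene, protein_change, n_reports)


def load_default_resources(override_dir: str | Path | None = None
                           ) -> ReferenceResources:
    """Load the packaged annotation tables (or user overrides from a
    directory containing the same file names)."""
    def _read(name: str) -> pd.DataFrame:
        if override_dir is not None:
            return pd.read_csv(Path(override_dir) / name, sep="\t")
        ref = importlib_resources.files("ampliclone.resources") / name
        with importlib_resources.as_file(ref) as path:
            return pd.read_csv(path, sep="\t")

    genes = _read("truncating_genes.tsv")
    hot = _read("hotspots.tsv").fillna({"required_change": ""})
    dom = _read("domain_windows.tsv")
    special = _read("special_truncating.tsv")
    ch = _read("ch_variants.tsv")
    return ReferenceResources(
        truncating_driver_genes=frozenset(genes["gene"]),
        hotspots=tuple((r.gene, int(r.residue), str(r.required_change or ""))
                       for r in hot.itertuples(index=False)),
        domain_windows=tuple((r.gene, int(r.start), int(r.end))
                             for r in dom.itertuples(index=False)),
        special_truncating=tuple((r.gene, int(r.start), int(r.end))
                                 for r in special.itertuples(index=False)),
        ch_variants=tuple((r.gene, str(r.protein_change), int(r.n_reports))
                          for r in ch.itertuples(index=False)),
    )


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    failed_rules: tuple


def _read_support_failures(v: VariantRecord) -> list[str]:
    if v.variant_class == SNV:
        min_alt, min_dir = 5, 2
    else:  # indels and ITDs
        min_alt, min_dir = 10, 4
    failed = []
    if v.alt_reads < min_alt:
        failed.append("min_variant_reads")
    if v.alt_reads_forward < min_dir or v.alt_reads_reverse < min_dir:
        failed.append("min_directional_reads")
    return failed


def apply_vardict_filters(v: VariantRecord) -> FilterResult:
    """VarDict post-filters: read support (5/2+2 for SNVs, 10/4+4 for
    indels), base quality >= 30, mapping quality >= 40 (waived for
    U2AF1/U2AF1L5, which are multi-mapped due to the hg38 gene duplication),
    strand-bias Fisher p >= 1e-4 and no read-position bias."""
    if v.caller != "vardict":
        raise FormatError("apply_vardict_filters requires a VarDict call")
    failed = _read_support_failures(v)
    if v.mean_base_quality < 30:
        failed.append("min_base_quality")
    if v.mean_mapping_quality < 40 and v.gene not in MAPQ_EXEMPT_GENES:
        failed.append("min_mapping_quality")
    if v.strand_bias_p < 0.0001:
        failed.append("strand_bias")
    if v.position_bias:
        failed.append("position_bias")
    return FilterResult(not failed, tuple(failed))


def apply_mutect2_filters(v: VariantRecord) -> FilterResult:
    """Mutect2 post-filters: all default caller filters passed (or only
    clustered_events failing), plus the same read-support rule as VarDict."""
    if v.caller != "mutect2":
        raise FormatError("apply_mutect2_filters requires a Mutect2 call")
    failed = _read_support_failures(v)
    extra = set(v.caller_filters) - {"PASS", "clustered_events"}
    if extra:
        failed.append("caller_filters:" + ",".join(sorted(extra)))
    return FilterResult(not failed, tuple(failed))


def apply_caller_filters(v: VariantRecord) -> FilterResult:
    return (apply_vardict_filters(v) if v.caller == "vardict"
            else apply_mutect2_filters(v))


def flag_germline_or_artefact(v: VariantRecord,
                              cohort_recurrence_min: int = 3) -> list[str]:
    """Likely-germline / artefact flags with somatic-hotspot rescues.

    * population AF > 1/1000 unless COSMIC count > 100 or on the CH list;
    * VAF in the germline bands (0.4-0.6 or > 0.9) unless COSMIC count > 5
      or on the CH list;
    * present in the panel of normals;
    * recurrent in the cohort (>= ``cohort_recurrence_min`` samples) unless
      COSMIC count >= 5 or reported >= 2 times in CH studies.
    """
    flags = []
    if (v.population_af > 0.001
            and not (v.cosmic_count > 100 or v.ch_list_member)):
        flags.append("population_af")
    in_germline_band = 0.4 <= v.vaf <= 0.6 or v.vaf > 0.9
    if in_germline_band and not (v.cosmic_count > 5 or v.ch_list_member):
        flags.append("germline_vaf_band")
    if v.in_panel_of_normals:
        flags.append("panel_of_normals")
    if (v.cohort_recurrence >= cohort_recurrence_min
            and not (v.cosmic_count >= 5 or v.ch_list_count >= 2)):
        flags.append("cohort_recurrent")
    return flags


@dataclass(frozen=True)
class RuleOutcome:
    variant_key: tuple
    passed_caller_filters: bool
    failed_filter_rules: tuple
    germline_artefact_flags: tuple
    classification: str  # pathogenic_driver | VUS | excluded
    driver_rule_ids: tuple


def _fires_driver_rules(v: VariantRecord, r: ReferenceResources) -> list[str]:
    fired = []
    if v.is_truncating and v.gene in r.truncating_driver_genes:
        fired.append("truncating_driver_gene")
    if v.is_non_synonymous and v.protein_position is not None:
        for gene, residue, required in r.hotspots:
            if v.gene == gene and v.protein_position == residue:
                if required and v.protein_change != required:
                    continue
                fired.append("hotspot_residue")
                break
        for gene, start, end in r.domain_windows:
            if v.gene == gene and start <= v.protein_position <= end:
                fired.append("listed_domain_window")
                break
    if v.is_truncating and v.protein_position is not None:
        for gene, start, end in r.special_truncating:
            if v.gene == gene and start <= v.protein_position <= end:
                fired.append("special_truncating_region")
                break
    if v.gene == "FLT3" and v.variant_class == ITD:
        fired.append("flt3_itd")
    if v.is_non_synonymous:
        if v.cosmic_count >= 10 and v.vaf < 0.4:
            fired.append("cosmic_recurrent_low_vaf")
        if v.in_interpro_domain and v.vaf < 0.4:
            fired.append("interpro_domain_low_vaf")
        if v.cosmic_count > 100:
            fired.append("cosmic_highly_recurrent")
    return fired


def classify_driver(v: VariantRecord, r: ReferenceResources,
                    cohort_recurrence_min: int = 3) -> RuleOutcome:
    """Full rule trace for one variant: caller filters, germline/artefact
    flags, then driver annotation.  A variant failing filters or carrying an
    exclusion flag is 'excluded'; otherwise it is 'pathogenic_driver' when
    any of the eight rules fires, else 'VUS'."""
    filt = apply_caller_filters(v)
    flags = (tuple(flag_germline_or_artefact(v, cohort_recurrence_min))
             if filt.passed else ())
    if not filt.passed or flags:
        return RuleOutcome(v.key, filt.passed, filt.failed_rules, flags,
                           "excluded", ())
    fired = tuple(_fires_driver_rules(v, r))
    return RuleOutcome(v.key, True, (), (),
                       "pathogenic_driver" if fired else "VUS", fired)


def consensus_keep(outcomes_by_caller: dict[str, RuleOutcome],
                   mode: str = "union") -> bool:
    """Whether a variant survives across callers.

    ``union`` keeps a variant when either caller's post-filter path retains
    it (the flag rules, not caller agreement, remove artefacts);
    ``intersect`` requires both callers.
    """
    kept = [o.classification != "excluded" for o in outcomes_by_caller.values()]
    if mode == "union":
        return any(kept)
    if mode == "intersect":
        return len(kept) >= 2 and all(kept)
    raise FormatError(f"unknown consensus mode {mode!r}")


def classify_sample_ch(variants_with_outcomes, vaf_cutoff: float = 0.02
                       ) -> dict:
    """Sample-level CH status from driver-classified variants.

    CH-positive iff at least one pathogenic driver at VAF >= ``vaf_cutoff``;
    driver counts are also reported for the 0.01 and 0.02 VAF bands.
    """
    driver_vafs = [v.vaf for v, o in variants_with_outcomes
                   if o.classification == "pathogenic_driver"]
    n_01 = sum(vaf >= 0.01 for vaf in driver_vafs)
    n_02 = sum(vaf >= 0.02 for vaf in driver_vafs)
    n_cut = sum(vaf >= vaf_cutoff for vaf in driver_vafs)
    return {
        "ch_status": n_cut >= 1,
        "vaf_cutoff": vaf_cutoff,
        "n_drivers_at_cutoff": n_cut,
        "n_drivers_vaf_ge_0.01": n_01,
        "n_drivers_vaf_ge_0.02": n_02,
    }


_BOOL_COLS = ("position_bias", "ch_list_member", "in_panel_of_normals",
              "in_interpro_domain")


def variants_from_table(df: pd.DataFrame) -> list[VariantRecord]:
    """Build VariantRecords from a TSV-derived DataFrame.

    Columns follow the VariantRecord field names; ``caller_filters`` is a
    comma-separated list.  Missing optional columns take their defaults.
    """
    if "gene" not in df.columns:
        raise FormatError("variants table is missing required column 'gene'")
    records = []
    valid = {f for f in VariantRecord.__dataclass_fields__}
    for row in df.to_dict(orient="records"):
        row = {k: v for k, v in row.items() if k in valid and pd.notna(v)}
        if "caller_filters" in row:
            row["caller_filters"] = frozenset(
                str(row["caller_filters"]).split(","))
        for col in _BOOL_COLS:
            if col in row and not isinstance(row[col], bool):
                row[col] = str(row[col]).strip().lower() in ("true", "1", "yes")
        if "protein_position" in row:
            row["protein_position"] = int(row["protein_position"])
        records.append(VariantRecord(**row))
    return records
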
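"""Data model, TSV readers/writers and run configuration.

All tables are plain tab-separated text with a header line, mirroring the
processed-data style of targeted single-cell genotyping studies:

* counts:   cell_id, amplicon_id, ref_reads, alt_reads
* manifest: amplicon_id, mutation_id, analyte, linked_snp_id, ploidy
* metadata: cell_id, sample_id, is_wt_control, cluster_label, sort_gate

Counts are stored as integers; single-cell variant allele fractions (scVAFs)
are always computed downstream and never stored as the source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

ANALYTES = ("gDNA", "cDNA")
PLOIDIES = ("diploid", "hemizygous")

COUNTS_COLUMNS = ["cell_id", "amplicon_id", "ref_reads", "alt_reads"]
MANIFEST_COLUMNS = ["amplicon_id", "mutation_id", "analyte", "linked_snp_id", "ploidy"]
META_COLUMNS = ["cell_id", "sample_id", "is_wt_control", "cluster_label", "sort_gate"]

GENOTYPE_COLUMNS = [
    "cell_id",
    "mutation_id",
    "gdna_call",
    "cdna_call",
    "consensus",
    "gdna_scvaf",
    "cdna_scvaf",
    "gdna_coverage",
    "cdna_coverage",
    "ado_flag",
    "clone_id",
]


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the genotyping pipeline.

    Defaults follow the targeted single-cell genotyping scheme this package
    implements: a minimum coverage of 50 reads for gDNA amplicons and 30 for
    cDNA amplicons, at least 10 mutant reads for a mutant call, a WT-calling
    threshold of control mean + 3 SD and a mutant-calling threshold a fixed
    margin of 0.01 scVAF above it.
    """

    min_coverage_gdna: int = 50
    min_coverage_cdna: int = 30
    min_mutant_reads: int = 10
    mutant_margin: float = 0.01
    sd_multiplier: float = 3.0
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    calling_strategy: str = "control_thresholds"
    min_control_cells: int = 30
    min_phase_cells: int = 20
    phase_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_coverage_gdna", "min_coverage_cdna", "min_mutant_reads",
                     "mutant_margin", "sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.calling_strategy not in ("control_thresholds", "distribution_minima"):
            raise ConfigurationError(
                f"unknown calling_strategy {self.calling_strategy!r}")

    def min_coverage(self, analyte: str) -> int:
        return self.min_coverage_gdna if analyte == "gDNA" else self.min_coverage_cdna

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML file; keyword overrides win over the file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **overrides) if overrides else self


@dataclass
class Dataset:
    """A cross-referenced trio of counts, amplicon manifest and cell metadata."""

    counts: pd.DataFrame
    manifest: pd.DataFrame
    meta: pd.DataFrame
    orphan_amplicons: list = field(default_factory=list)
    orphan_cells: list = field(default_factory=list)

    @property
    def control_cells(self) -> pd.Index:
        return pd.Index(self.meta.loc[self.meta["is_wt_control"], "cell_id"])

    @property
    def sample_cells(self) -> pd.Index:
        return pd.Index(self.meta.loc[~self.meta["is_wt_control"], "cell_id"])

    def amplicons_for(self, mutation_id: str) -> pd.DataFrame:
        return self.manifest[self.manifest["mutation_id"] == mutation_id]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing required column(s): {missing}")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "amplicon_id": str})


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(("true", "1", "yes"))


def validate_dataset(counts: pd.DataFrame, manifest: pd.DataFrame,
                     meta: pd.DataFrame, require_controls: bool = True) -> Dataset:
    """Cross-reference and validate the three core tables.

    Duplicate (cell, amplicon) rows and negative counts are rejected; amplicon
    or cell identifiers appearing in the counts but not in the manifest or
    metadata are reported as orphans (not fatal).  A run without any
    WT-control cells cannot derive thresholds and is rejected unless
    ``require_controls`` is disabled.
    """
    _require_columns(counts, COUNTS_COLUMNS, "counts")
    _require_columns(manifest, MANIFEST_COLUMNS, "manifest")
    _require_columns(meta, META_COLUMNS, "metadata")

    counts = counts.copy()
    for col in ("ref_reads", "alt_reads"):
        if (counts[col] < 0).any():
            raise ValidationError(f"negative values in counts column {col!r}")
        counts[col] = counts[col].astype(int)

    dup = counts.duplicated(subset=["cell_id", "amplicon_id"])
    if dup.any():
        first = counts.loc[dup, ["cell_id", "amplicon_id"]].iloc[0]
        raise ValidationError(
            f"duplicated (cell, amplicon) row: ({first.cell_id}, {first.amplicon_id})")

    if manifest["amplicon_id"].duplicated().any():
        raise ValidationError("duplicated amplicon_id in manifest")
    bad_analyte = ~manifest["analyte"].isin(ANALYTES)
    if bad_analyte.any():
        raise ValidationError(
            f"manifest analyte must be one of {ANALYTES}; got "
            f"{sorted(manifest.loc[bad_analyte, 'analyte'].unique())}")
    bad_ploidy = ~manifest["ploidy"].isin(PLOIDIES)
    if bad_ploidy.any():
        raise ValidationError(f"manifest ploidy must be one of {PLOIDIES}")
    linked = manifest["linked_snp_id"].notna() & (manifest["linked_snp_id"] != "")
    if (linked & (manifest["analyte"] != "gDNA")).any():
        raise ValidationError("a linked SNP may only be declared on a gDNA amplicon")

    meta = meta.copy()
    meta["is_wt_control"] = _as_bool(meta["is_wt_control"])
    if meta["cell_id"].duplicated().any():
        raise ValidationError("duplicated cell_id in metadata")
    if require_controls and not meta["is_wt_control"].any():
        raise ConfigurationError(
            "no WT-control cells in metadata; thresholds cannot be derived")

    orphan_amplicons = sorted(
        set(counts["amplicon_id"]) - set(manifest["amplicon_id"]))
    orphan_cells = sorted(set(counts["cell_id"]) - set(meta["cell_id"]))
    return Dataset(counts=counts, manifest=manifest, meta=meta,
                   orphan_amplicons=orphan_amplicons, orphan_cells=orphan_cells)


def load_dataset(counts_path: str | Path, manifest_path: str | Path,
                 meta_path: str | Path, require_controls: bool = True) -> Dataset:
    """Read and validate the counts/manifest/metadata trio from TSV files."""
    return validate_dataset(read_tsv(counts_path), read_tsv(manifest_path),
                            read_tsv(meta_path), require_controls=require_controls)


def write_genotype_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Write per cell x mutation consensus genotypes to a TSV, one row per call."""
    if len(calls) == 0:
        raise ValidationError("refusing to write an empty genotype table")
    out = calls.copy()
    for col in GENOTYPE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    write_tsv(out[GENOTYPE_COLUMNS
                  + [c for c in out.columns if c not in GENOTYPE_COLUMNS]], path)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "mutation_id": str})
    _require_columns(df, ["cell_id", "mutation_id", "consensus"], "genotype")
    return df


def qc_pass_rate(n_pass: int, n_total: int) -> float:
    """Fraction of sorted cells passing quality filters (0..1)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_pass <= n_total:
        raise ValidationError("n_pass must lie in [0, n_total]")
    return n_pass / n_total
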
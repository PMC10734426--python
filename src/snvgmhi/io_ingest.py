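"""Readers and writers for the external file formats of the pipeline.

All on-disk formats are plain text: tab-separated tables (metadata, SNV
tables, genome info, mapping info, feature tables), GFF3 gene annotations
and FASTA sequences.  Coordinates are converted exactly once at ingest:
GFF3 is 1-based inclusive on disk and 0-based half-open in memory; SNV
table positions are already 0-based (the convention of strain-resolved SNV
callers such as inStrain) and are kept as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("snvgmhi")

VALID_BASES = frozenset("ACGT")

#: SCFA-production gene families tracked by the codon-bias analysis.
SCFA_FAMILIES = (
    "ack", "buk", "ydiF", "atoD", "atoA", "ctfA", "ctfB", "BcAt", "scpC",
)

EFFECT_CLASSES = (
    "noncoding", "synonymous", "nonsynonymous",
    "stop_gain", "stop_loss", "start_loss",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Run-wide analysis parameters.

    min_cov
        Minimum read coverage at a site for a SNV call to be retained
        (default 5); also the coverage floor behind ``breadth_minCov``.
    depth_unit
        Unit for depth normalization: ``"Gb"`` (per gigabase, default) or
        ``"Mkb"`` (per million kilobases = per megabase-thousand).
    prevalence_thresholds
        ``(genome_level, detailed_strain)`` fractions; genomes must be
        mutated in at least this fraction of samples to enter feature
        tables (0.10) or the detailed per-strain analyses (0.30).
    alpha
        Significance level for marker selection and group tests.
    fdr_method
        Multiple-testing correction passed to statsmodels (``"fdr_bh"``).
    top_fraction
        Fraction of samples used for the GMHI population constants.
    epsilon
        Pseudo-value added to both collective terms in the GMHI log-ratio.
    """

    min_cov: int = 5
    depth_unit: str = "Gb"
    prevalence_thresholds: tuple[float, float] = (0.10, 0.30)
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    pseudocount_policy: str = "half_min"
    top_fraction: float = 0.01
    epsilon: float = 1e-5


class SchemaError(ValueError):
    """A required column is missing or an input violates its schema."""


#: Default column names for each TSV flavour; alternative caller versions
#: can be mapped onto these via the ``aliases`` argument of the readers.
SCHEMA_REGISTRY: dict[str, tuple[str, ...]] = {
    "metadata": ("sample_id", "cohort", "phenotype", "health_status", "depth_gb"),
    "snv": ("genome", "scaffold", "position", "ref_base", "alt_base",
            "ref_freq", "alt_freq", "position_coverage"),
    "genome_info": ("genome", "length", "coverage", "breadth_minCov",
                    "nucleotide_diversity"),
    "mapping_info": ("genome", "filtered_read_pairs"),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One metagenomic sample: identity, cohort, phenotype, label, depth."""

    sample_id: str
    cohort_id: str
    phenotype: str
    health_status: str          # "healthy" | "nonhealthy"
    depth: float                # sequencing throughput, gigabases
    extras: tuple = ()          # unknown metadata columns, (key, value) pairs

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError(f"sample {self.sample_id}: depth must be > 0")
        if self.health_status not in ("healthy", "nonhealthy"):
            raise ValueError(
                f"sample {self.sample_id}: health_status must be "
                f"'healthy' or 'nonhealthy', got {self.health_status!r}")


@dataclass(frozen=True)
class GenomeInfoRecord:
    """Per-(sample, genome) coverage summary from the SNV caller."""

    genome_id: str
    g_len: int
    coverage: float
    breadth_minCov: float
    nucleotide_diversity: float
    filtered_read_pairs: int = 0

    def __post_init__(self):
        if self.g_len <= 0:
            raise ValueError(f"{self.genome_id}: g_len must be > 0")
        if not 0.0 <= self.breadth_minCov <= 1.0:
            raise ValueError(f"{self.genome_id}: breadth_minCov outside [0,1]")
        if self.filtered_read_pairs < 0:
            raise ValueError(f"{self.genome_id}: negative read-pair count")


@dataclass(frozen=True)
class SnvRecord:
    """One called single-nucleotide variant (position is 0-based)."""

    genome_id: str
    scaffold_id: str
    position: int
    ref_base: str
    alt_base: str
    ref_freq: float
    alt_freq: float
    site_coverage: int
    gene_id: str | None = None
    effect: str | None = None

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.scaffold_id}:{self.position}: ref == alt")
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValueError(
                f"{self.scaffold_id}:{self.position}: non-ACGT allele")
        if self.ref_freq + self.alt_freq > 1.0 + 1e-9:
            raise ValueError(
                f"{self.scaffold_id}:{self.position}: allele freqs sum > 1")


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS interval; ``start``/``end`` are internal 0-based half-open."""

    gene_id: str
    genome_id: str
    scaffold_id: str
    start: int                  # 0-based inclusive
    end: int                    # 0-based exclusive
    strand: str                 # "+" | "-"
    scfa_family: str = "none"
    codon_eligible: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty or inverted interval")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def _rename(df: pd.DataFrame, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    """Map alternative column names onto the registry names."""
    if aliases:
        df = df.rename(columns=dict(aliases))
    return df


def _require(df: pd.DataFrame, schema: str, path) -> None:
    missing = [c for c in SCHEMA_REGISTRY[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for {schema} table")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_metadata(path, aliases: Mapping[str, str] | None = None
                  ) -> list[SampleMeta]:
    """Read the sample-metadata TSV into :class:`SampleMeta` records.

    Unknown columns are preserved on ``extras``; a duplicate ``sample_id``
    is a validation error.
    """
    df = _rename(pd.read_csv(path, sep="\t", comment="#", dtype=str), aliases)
    _require(df, "metadata", path)
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample_id(s): {dupes}")
    known = set(SCHEMA_REGISTRY["metadata"])
    extra_cols = [c for c in df.columns if c not in known]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(SampleMeta(
            sample_id=d["sample_id"],
            cohort_id=d["cohort"],
            phenotype=d["phenotype"],
            health_status=d["health_status"],
            depth=float(d["depth_gb"]),
            extras=tuple((c, d[c]) for c in extra_cols),
        ))
    return out


def read_snv_table(path, min_cov: int = 5,
                   aliases: Mapping[str, str] | None = None
                   ) -> list[SnvRecord]:
    """Read one sample's SNV table, dropping sites below ``min_cov``.

    Rows with non-ACGT alleles are rejected with a warning; the number of
    coverage-filtered rows is logged.
    """
    df = _rename(pd.read_csv(path, sep="\t", comment="#",
                            float_precision="round_trip"), aliases)
    _require(df, "snv", path)
    records: list[SnvRecord] = []
    n_lowcov = 0
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        if int(d["position_coverage"]) < min_cov:
            n_lowcov += 1
            continue
        ref, alt = str(d["ref_base"]).upper(), str(d["alt_base"]).upper()
        if ref not in VALID_BASES or alt not in VALID_BASES:
            logger.warning("%s row %d: non-ACGT allele %r>%r rejected",
                           path, i, ref, alt)
            continue
        try:
            records.append(SnvRecord(
                genome_id=str(d["genome"]),
                scaffold_id=str(d["scaffold"]),
                position=int(d["position"]),
                ref_base=ref,
                alt_base=alt,
                ref_freq=float(d["ref_freq"]),
                alt_freq=float(d["alt_freq"]),
                site_coverage=int(d["position_coverage"]),
                gene_id=(str(d["gene"]) if "gene" in d and pd.notna(d["gene"])
                         else None),
            ))
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
    if n_lowcov:
        logger.info("%s: dropped %d SNVs below min_cov=%d",
                    path, n_lowcov, min_cov)
    return records


def read_genome_info(path, aliases: Mapping[str, str] | None = None
                     ) -> list[GenomeInfoRecord]:
    """Read one sample's genome-info TSV (length, coverage, breadth, pi)."""
    df = _rename(pd.read_csv(path, sep="\t", comment="#",
                            float_precision="round_trip"), aliases)
    _require(df, "genome_info", path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(GenomeInfoRecord(
            genome_id=str(d["genome"]),
            g_len=int(d["length"]),
            coverage=float(d["coverage"]),
            breadth_minCov=float(d["breadth_minCov"]),
            nucleotide_diversity=float(d["nucleotide_diversity"]),
            filtered_read_pairs=int(d.get("filtered_read_pairs", 0)),
        ))
    return out


def read_mapping_info(path, aliases: Mapping[str, str] | None = None
                      ) -> dict[str, int]:
    """Read per-genome filtered read-pair counts for one sample."""
    df = _rename(pd.read_csv(path, sep="\t", comment="#",
                            float_precision="round_trip"), aliases)
    _require(df, "mapping_info", path)
    return {str(g): int(n) for g, n in
            zip(df["genome"], df["filtered_read_pairs"])}


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file.

    On-disk coordinates are 1-based inclusive and converted here, once, to
    0-based half-open.  A CDS whose length is not divisible by 3 is kept
    but flagged ineligible for codon analysis.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genome_id = feat.attributes.get("genome", [feat.seqid])[0]
        family = feat.attributes.get("scfa_family", ["none"])[0]
        start0, end0 = feat.start - 1, feat.end  # -> 0-based half-open
        eligible = (end0 - start0) % 3 == 0
        if not eligible:
            logger.warning("%s: CDS %s length %d not divisible by 3; "
                           "ineligible for codon analysis",
                           path, gene_id, end0 - start0)
        out.append(GeneAnnotation(
            gene_id=gene_id, genome_id=genome_id, scaffold_id=feat.seqid,
            start=start0, end=end0, strand=feat.strand,
            scfa_family=family, codon_eligible=eligible))
    return out


def load_cohort_dir(root, min_cov: int = 5):
    """Load a cohort directory laid out as the simulator writes it.

    Expects ``metadata.tsv`` plus ``snvs/``, ``genome_info/`` and
    ``mapping_info/`` subdirectories with one ``<sample_id>.tsv`` each.
    Returns ``(metadata, snvs_by_sample, genome_info_by_sample,
    mapping_by_sample)``.
    """
    root = Path(root)
    metadata = read_metadata(root / "metadata.tsv")
    snvs, ginfo, mapping = {}, {}, {}
    for m in metadata:
        snvs[m.sample_id] = read_snv_table(
            root / "snvs" / f"{m.sample_id}.tsv", min_cov=min_cov)
        ginfo[m.sample_id] = read_genome_info(
            root / "genome_info" / f"{m.sample_id}.tsv")
        mapping[m.sample_id] = read_mapping_info(
            root / "mapping_info" / f"{m.sample_id}.tsv")
    return metadata, snvs, ginfo, mapping


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{record_id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("abundance", "snv_rate", "scfa_snv_freq")


@dataclass
class FeatureTable:
    """Samples x features matrix tagged with the kind of feature it holds."""

    values: pd.DataFrame        # index = sample ids, columns = feature ids
    kind: str

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.values.values < 0).any():
            raise ValueError("feature table contains negative values")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV with the kind in a header comment."""
    if table.values.empty:
        raise ValueError("refusing to write an empty feature table")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind: {table.kind}\n")
        table.values.to_csv(fh, sep="\t", index_label="sample_id",
                            lineterminator="\n")


def read_feature_table(path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    kind = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# kind:"):
            kind = first.split(":", 1)[1].strip()
    if kind is None:
        raise SchemaError(f"{path}: missing '# kind:' header comment")
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id",
                     float_precision="round_trip")
    return FeatureTable(values=df, kind=kind)
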
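"""Per-(sample, genome) SNV metrics and feature-table assembly.

The central quantity is the SNV rate, a normalized per-genome variant
density that makes genomes with different sequencing breadth comparable::

    SNV rate = SNV number / (g_len * breadth_minCov)

i.e. variants per SNV-callable base, where callable bases are those with
at least ``min_cov`` coverage.  Raw per-sample counts (mutated genomes,
total SNVs) are separately normalized by sequencing depth because both
scale strongly with throughput.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import FeatureTable, SnvRecord, GeneAnnotation

logger = logging.getLogger("snvgmhi")

#: The six strand-complement-collapsed base-change classes, canonical order.
VARIANT_CLASSES = (
    "A>C|T>G", "A>G|T>C", "A>T|T>A", "C>A|G>T", "C>G|G>C", "C>T|G>A",
)

#: (ref, alt) -> collapsed class.  A change and its complement share a class.
_CLASS_OF: dict[tuple[str, str], str] = {}
for _cls in VARIANT_CLASSES:
    _a, _b = _cls.split("|")
    for _pair in (_a, _b):
        _r, _v = _pair.split(">")
        _CLASS_OF[(_r, _v)] = _cls


@dataclass(frozen=True)
class GenomeSnvProfile:
    """SNV summary of one genome in one sample."""

    sample_id: str
    genome_id: str
    snv_number: int
    g_len: int
    breadth_minCov: float
    snv_rate: float
    nucleotide_diversity: float
    sequence_abundance: float


def snv_rate(snv_number: int, g_len: int, breadth_minCov: float) -> float:
    """Variants per SNV-callable base: ``snv_number / (g_len * breadth)``."""
    if g_len <= 0:
        raise ValueError("g_len must be > 0")
    if not 0 < breadth_minCov <= 1:
        raise ValueError(
            f"breadth_minCov must be in (0, 1], got {breadth_minCov}; "
            "genomes with zero callable breadth have no defined rate")
    return snv_number / (g_len * breadth_minCov)


def normalize_by_depth(raw_count: float, depth: float,
                       unit: str = "Gb") -> float:
    """Normalize a raw per-sample count by sequencing depth.

    ``unit="Gb"`` returns counts per gigabase; ``unit="Mkb"`` counts per
    million kilobases (per 10^9 bases as well, but kept distinct so the
    unit travels with the number).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if unit not in ("Gb", "Mkb"):
        raise ValueError(f"unknown depth unit {unit!r}")
    return raw_count / depth


def nucleotide_diversity(allele_freqs: Iterable[Sequence[float]],
                         n_qualifying_sites: int) -> float:
    """Mean per-site pi over qualifying (>= min_cov) sites.

    ``allele_freqs`` holds the per-variant-site allele-frequency vectors;
    each contributes ``1 - sum(p_i^2)``; qualifying sites with no variant
    contribute 0.  Sites are qualifying when they meet the coverage floor.
    """
    if n_qualifying_sites <= 0:
        raise ValueError("no qualifying sites: diversity undefined")
    total = 0.0
    n_var = 0
    for freqs in allele_freqs:
        f = np.asarray(freqs, dtype=float)
        if f.sum() > 1.0 + 1e-9:
            raise ValueError("allele frequencies sum > 1 at a site")
        total += 1.0 - float((f ** 2).sum())
        n_var += 1
    if n_var > n_qualifying_sites:
        raise ValueError("more variant sites than qualifying sites")
    return total / n_qualifying_sites


def sequence_abundance(read_pairs: Mapping[str, int]) -> dict[str, float]:
    """Per-genome fraction of filtered read pairs within one sample."""
    total = sum(read_pairs.values())
    if total <= 0:
        raise ValueError("all-zero read-pair counts: abundance undefined")
    if any(v < 0 for v in read_pairs.values()):
        raise ValueError("negative read-pair count")
    return {g: n / total for g, n in read_pairs.items()}


def prevalence(carrier_samples: Iterable[str], subset: Sequence[str]) -> float:
    """Fraction of ``subset`` samples in which the genome is mutated."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    carriers = set(carrier_samples)
    return sum(1 for s in subset if s in carriers) / len(subset)


def pooled_prevalence(group_prevalences: Sequence[float],
                      group_sizes: Sequence[int]) -> float:
    """Pool printed per-group prevalences into an overall prevalence.

    Group carrier counts are recovered as ``round(prevalence * n)`` — the
    printed prevalences are two-decimal roundings of integer carrier
    counts — then summed and divided by the total sample count.
    """
    if len(group_prevalences) != len(group_sizes) or not group_sizes:
        raise ValueError("mismatched or empty group vectors")
    carriers = sum(round(p * n) for p, n in zip(group_prevalences, group_sizes))
    return carriers / sum(group_sizes)


@dataclass(frozen=True)
class VariantTypeProfile:
    """Proportions of the six collapsed variant classes."""

    owner_id: str
    proportions: tuple[float, ...]      # aligned with VARIANT_CLASSES
    total_snvs: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(VARIANT_CLASSES, self.proportions))


def collapse_variant_class(ref_base: str, alt_base: str) -> str:
    """Map a base change to its strand-complement-collapsed class."""
    try:
        return _CLASS_OF[(ref_base, alt_base)]
    except KeyError:
        raise ValueError(f"invalid base change {ref_base}>{alt_base}") from None


def variant_type_profile(snvs: Sequence[SnvRecord],
                         owner_id: str = "all") -> VariantTypeProfile:
    """Collapsed variant-class proportions over a set of SNVs.

    Empty input yields an all-zero profile with ``total_snvs == 0``.
    """
    counts = dict.fromkeys(VARIANT_CLASSES, 0)
    for snv in snvs:
        counts[collapse_variant_class(snv.ref_base, snv.alt_base)] += 1
    total = len(snvs)
    props = tuple((counts[c] / total if total else 0.0)
                  for c in VARIANT_CLASSES)
    return VariantTypeProfile(owner_id=owner_id, proportions=props,
                              total_snvs=total)


def coding_fraction(snvs: Sequence[SnvRecord],
                    annotations: Sequence[GeneAnnotation]) -> float:
    """Fraction of SNVs falling inside annotated CDS intervals."""
    if not snvs:
        return 0.0
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        by_scaffold.setdefault(ann.scaffold_id, []).append((ann.start, ann.end))
    inside = 0
    for snv in snvs:
        for start, end in by_scaffold.get(snv.scaffold_id, ()):
            if start <= snv.position < end:
                inside += 1
                break
    return inside / len(snvs)


def assemble_profiles(
        snvs_by_sample: Mapping[str, Sequence[SnvRecord]],
        genome_info_by_sample: Mapping[str, Sequence],
        mapping_by_sample: Mapping[str, Mapping[str, int]] | None = None,
) -> list[GenomeSnvProfile]:
    """Join SNV tables, genome info and mapping info into per-(sample,
    genome) :class:`GenomeSnvProfile` records.

    Genomes with zero callable breadth are excluded (their rate is
    undefined); sequence abundance comes from the sample's filtered
    read-pair counts when mapping info is given, else from the genome-info
    records.
    """
    profiles: list[GenomeSnvProfile] = []
    for sample_id, infos in genome_info_by_sample.items():
        counts: dict[str, int] = {}
        for snv in snvs_by_sample.get(sample_id, ()):
            counts[snv.genome_id] = counts.get(snv.genome_id, 0) + 1
        if mapping_by_sample is not None:
            pairs = dict(mapping_by_sample[sample_id])
        else:
            pairs = {g.genome_id: g.filtered_read_pairs for g in infos}
        abundances = sequence_abundance(pairs) if sum(pairs.values()) else {}
        for info in infos:
            if info.breadth_minCov <= 0:
                logger.info("%s/%s: zero callable breadth, excluded",
                            sample_id, info.genome_id)
                continue
            n = counts.get(info.genome_id, 0)
            profiles.append(GenomeSnvProfile(
                sample_id=sample_id, genome_id=info.genome_id,
                snv_number=n, g_len=info.g_len,
                breadth_minCov=info.breadth_minCov,
                snv_rate=snv_rate(n, info.g_len, info.breadth_minCov),
                nucleotide_diversity=info.nucleotide_diversity,
                sequence_abundance=abundances.get(info.genome_id, 0.0)))
    return profiles


def build_feature_table(profiles: Sequence[GenomeSnvProfile], kind: str,
                        sample_ids: Sequence[str] | None = None,
                        prevalence_threshold: float = 0.10) -> FeatureTable:
    """Assemble a samples x genomes :class:`FeatureTable`.

    Missing (sample, genome) pairs are filled with 0.  Genomes mutated in
    fewer than ``prevalence_threshold`` of the samples are dropped
    (default 10%, the genome-level analysis gate; the detailed per-strain
    analyses use 30%).
    """
    value_of = {
        "abundance": lambda p: p.sequence_abundance,
        "snv_rate": lambda p: p.snv_rate,
    }
    if kind not in value_of:
        raise ValueError(f"cannot build kind {kind!r} from SNV profiles")
    if not profiles and sample_ids is None:
        raise ValueError("no profiles and no sample list")
    records = [(p.sample_id, p.genome_id, value_of[kind](p)) for p in profiles]
    df = pd.DataFrame(records, columns=["sample_id", "genome_id", "value"])
    wide = df.pivot_table(index="sample_id", columns="genome_id",
                          values="value", aggfunc="sum", fill_value=0.0)
    if sample_ids is not None:
        wide = wide.reindex(list(sample_ids), fill_value=0.0)
    n = len(wide)
    if n and prevalence_threshold > 0:
        prev = (wide > 0).sum(axis=0) / n
        wide = wide.loc[:, prev >= prevalence_threshold]
    wide.columns.name = None
    wide.index.name = "sample_id"
    return FeatureTable(values=wide.astype(float), kind=kind)
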
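"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the *output* of strain-resolved SNV calling on a
two-group (healthy / nonhealthy) cohort, not the reads themselves: random
reference genomes carrying annotated SCFA-production genes, per-sample SNV
tables, genome-info tables (breadth, coverage, nucleotide diversity) and
mapping-info tables (filtered read pairs), plus a :class:`GroundTruth`
recording every planted effect so downstream recovery can be scored.

Planted structure, with directions matching the study system:

* healthy samples carry more mutated genomes per unit depth
  (``lambda_genomes_H > lambda_genomes_N``);
* a fraction of genomes are *markers* whose SNV rate and relative
  abundance are shifted in one group;
* base-change classes follow a per-group probability vector over the six
  strand-collapsed variant types (nonhealthy enriched for C>G|G>C);
* SNVs landing in SCFA genes create a stop-gain or start-loss with a
  group-dependent probability (nonhealthy higher).

All randomness flows from a single ``numpy.random.default_rng(seed)`` so
one integer reproduces a cohort byte-for-byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_ingest import (
    GeneAnnotation, GenomeInfoRecord, SampleMeta, SnvRecord, SCFA_FAMILIES,
)
from .selection_codon import (
    BASES, START_CODONS, STOP_CODONS, _codon_effect, complement,
)
from .snv_metrics import VARIANT_CLASSES

# class index -> compatible reference-base pair and, per ref base, the alt
_CLASS_ALT: dict[tuple[str, int], str] = {}
for _i, _cls in enumerate(VARIANT_CLASSES):
    for _pair in _cls.split("|"):
        _r, _v = _pair.split(">")
        _CLASS_ALT[(_r, _i)] = _v
_AT_CLASSES = (0, 1, 2)     # classes realisable at A/T reference bases
_CG_CLASSES = (3, 4, 5)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort (defaults are the
    scaled-down desk conditions; see the methods note for rationale)."""

    n_healthy: int = 100
    n_nonhealthy: int = 100
    n_genomes: int = 40
    genome_len: int = 12_000
    n_scfa_genes_per_genome: int = 3
    gene_len: int = 300                     # bases, divisible by 3
    depth_mu: float = float(np.log(5.0))    # log-normal, gigabases
    depth_sigma: float = 0.4
    lambda_genomes_H: float = 3.2           # mutated genomes per Gb
    lambda_genomes_N: float = 2.8
    snv_rate_H: float = 2e-3                # SNVs per callable base
    snv_rate_N: float = 2e-3
    marker_fraction: float = 0.25
    rate_effect: float = 2.0                # marker SNV-rate fold change
    abundance_effect: float = 2.0           # marker abundance fold change
    marker_weight: float = 3.0              # sampling weight of markers
    presence_effect: float = 1.3            # marker detection-odds fold change
    breadth_alpha: float = 8.0              # Beta prior on breadth_minCov
    breadth_beta: float = 4.0
    variant_type_bias_H: tuple[float, ...] = (
        0.12, 0.28, 0.14, 0.12, 0.08, 0.26)
    variant_type_bias_N: tuple[float, ...] = (
        0.12, 0.22, 0.12, 0.12, 0.16, 0.26)
    stopgain_prob_H: float = 0.05
    stopgain_prob_N: float = 0.35
    reads_per_gb: int = 50_000
    min_cov: int = 5
    seed: int = 0

    def __post_init__(self):
        for vec in (self.variant_type_bias_H, self.variant_type_bias_N):
            if len(vec) != 6 or abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError("variant_type_bias must be a 6-simplex vector")
        if self.gene_len % 3:
            raise ValueError("gene_len must be divisible by 3")
        for name in ("lambda_genomes_H", "lambda_genomes_N",
                     "snv_rate_H", "snv_rate_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stopgain_prob_N < self.stopgain_prob_H:
            raise ValueError(
                "stopgain_prob_N must be >= stopgain_prob_H to emulate the "
                "nonhealthy-enriched codon-bias direction")


@dataclass(frozen=True)
class PlantedLossEvent:
    """One planted stop-gain/start-loss SNV (recovery oracle)."""

    sample_id: str
    genome_id: str
    gene_id: str
    scaffold_id: str
    position: int
    ref_base: str
    alt_base: str
    effect: str


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    marker_direction: dict[str, str]                # genome -> enriched group
    planted_snv_counts: dict[tuple[str, str], int]  # (sample, genome) -> n
    planted_loss_events: list[PlantedLossEvent]


@dataclass
class SyntheticCohort:
    config: SimConfig
    genomes: dict[str, str]                         # genome -> scaffold seq
    annotations: list[GeneAnnotation]
    metadata: list[SampleMeta]
    snvs: dict[str, list[SnvRecord]]                # sample -> records
    genome_info: dict[str, list[GenomeInfoRecord]]
    mapping_info: dict[str, dict[str, int]]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# genomes and genes
# ---------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """A coding sequence: ATG start, sense codons only, one terminal stop."""
    n_codons = length // 3
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def generate_genomes(config: SimConfig, rng: np.random.Generator
                     ) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Random scaffolds with embedded, annotated SCFA genes.

    Genes are non-overlapping, length-divisible-by-3, start with ATG, end
    with a stop codon, carry no internal stop, sit on alternating strands
    and cycle through the nine SCFA families.
    """
    n_genes = config.n_scfa_genes_per_genome
    slot = config.genome_len // max(n_genes, 1)
    if slot < config.gene_len + 20:
        raise ValueError(
            "infeasible gene packing: reduce n_scfa_genes_per_genome or "
            "gene_len, or increase genome_len")
    genomes: dict[str, str] = {}
    annotations: list[GeneAnnotation] = []
    fam_cycle = 0
    for gi in range(config.n_genomes):
        genome_id = f"g{gi:03d}"
        seq = list(rng.choice(list(BASES), size=config.genome_len))
        for k in range(n_genes):
            start = slot * k + int(rng.integers(10, slot - config.gene_len - 9))
            end = start + config.gene_len
            strand = "+" if (gi + k) % 2 == 0 else "-"
            cds = _random_cds(rng, config.gene_len)
            placed = cds if strand == "+" else _revcomp(cds)
            seq[start:end] = list(placed)
            annotations.append(GeneAnnotation(
                gene_id=f"{genome_id}_scfa{k}", genome_id=genome_id,
                scaffold_id=genome_id, start=start, end=end, strand=strand,
                scfa_family=SCFA_FAMILIES[fam_cycle % len(SCFA_FAMILIES)]))
            fam_cycle += 1
        genomes[genome_id] = "".join(seq)
    return genomes, annotations


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _loss_candidates(gene: GeneAnnotation, cds: str
                     ) -> list[tuple[int, str, str, str]]:
    """All (genome position, genome ref, genome alt, effect) single-base
    changes in the gene that create a stop-gain or start-loss."""
    out = []
    for offset in range(len(cds)):
        ci, within = divmod(offset, 3)
        codon = cds[ci * 3: ci * 3 + 3]
        for b in BASES:
            if b == codon[within]:
                continue
            alt_codon = codon[:within] + b + codon[within + 1:]
            effect = _codon_effect(codon, alt_codon, ci)
            if effect not in ("stop_gain", "start_loss"):
                continue
            if gene.strand == "+":
                gpos, gref, galt = gene.start + offset, codon[within], b
            else:
                gpos = gene.end - 1 - offset
                gref, galt = complement(codon[within]), complement(b)
            out.append((gpos, gref, galt, effect))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (see module docstring)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genomes, annotations = generate_genomes(config, rng)
    genome_ids = sorted(genomes)

    # marker genomes: first block, alternating enriched direction
    n_markers = int(round(config.marker_fraction * config.n_genomes))
    marker_direction = {
        genome_ids[i]: ("healthy" if i % 2 == 0 else "nonhealthy")
        for i in range(n_markers)}
    # detection weights: markers are common overall, and more often
    # detected in their enriched group (presence_effect on the odds)
    group_weights = {}
    for grp in ("healthy", "nonhealthy"):
        w = []
        for g in genome_ids:
            direction = marker_direction.get(g)
            wi = config.marker_weight if direction else 1.0
            if direction == grp:
                wi *= config.presence_effect
            elif direction is not None:
                wi /= config.presence_effect
            w.append(wi)
        w = np.asarray(w)
        group_weights[grp] = w / w.sum()

    # per-genome precomputation
    genes_of: dict[str, list[GeneAnnotation]] = {g: [] for g in genome_ids}
    for ann in annotations:
        genes_of[ann.genome_id].append(ann)
    cds_of = {ann.gene_id: _extract_cds(genomes[ann.genome_id], ann)
              for ann in annotations}
    loss_of = {ann.gene_id: _loss_candidates(ann, cds_of[ann.gene_id])
               for ann in annotations}
    base_positions = {}
    for g in genome_ids:
        arr = np.frombuffer(genomes[g].encode(), dtype="S1")
        at = np.flatnonzero((arr == b"A") | (arr == b"T"))
        cg = np.flatnonzero((arr == b"C") | (arr == b"G"))
        base_positions[g] = (at, cg)

    group_of: list[tuple[str, str]] = (
        [(f"H{i:04d}", "healthy") for i in range(config.n_healthy)]
        + [(f"N{i:04d}", "nonhealthy") for i in range(config.n_nonhealthy)])

    metadata: list[SampleMeta] = []
    snvs: dict[str, list[SnvRecord]] = {}
    ginfo: dict[str, list[GenomeInfoRecord]] = {}
    mapping: dict[str, dict[str, int]] = {}
    planted_counts: dict[tuple[str, str], int] = {}
    loss_events: list[PlantedLossEvent] = []

    for sample_id, group in group_of:
        depth = float(rng.lognormal(config.depth_mu, config.depth_sigma))
        lam = (config.lambda_genomes_H if group == "healthy"
               else config.lambda_genomes_N)
        n_mut = int(min(rng.poisson(lam * depth), config.n_genomes))
        n_mut = max(n_mut, 1)
        mutated = sorted(rng.choice(genome_ids, size=n_mut, replace=False,
                                    p=group_weights[group]))
        bias = np.asarray(config.variant_type_bias_H if group == "healthy"
                          else config.variant_type_bias_N)
        stopgain_p = (config.stopgain_prob_H if group == "healthy"
                      else config.stopgain_prob_N)
        base_rate = (config.snv_rate_H if group == "healthy"
                     else config.snv_rate_N)

        sample_snvs: list[SnvRecord] = []
        sample_ginfo: list[GenomeInfoRecord] = []
        sample_pairs: dict[str, int] = {}
        cohort_tag = "cohortA" if int(sample_id[1:]) % 2 == 0 else "cohortB"

        for genome_id in mutated:
            g_len = config.genome_len
            breadth = float(rng.beta(config.breadth_alpha, config.breadth_beta))
            L = max(int(round(breadth * g_len)), 1)
            w0 = int(rng.integers(0, g_len - L + 1))
            w1 = w0 + L

            rate = base_rate
            direction = marker_direction.get(genome_id)
            if direction == group:
                rate *= config.rate_effect
            n_snv = int(rng.poisson(rate * L))

            abund_w = float(rng.lognormal(0.0, 0.6))
            if direction == group:
                abund_w *= config.abundance_effect
            sample_pairs[genome_id] = abund_w  # normalised below

            genome_genes = genes_of[genome_id]
            at_all, cg_all = base_positions[genome_id]
            at = at_all[np.searchsorted(at_all, w0):np.searchsorted(at_all, w1)]
            cg = cg_all[np.searchsorted(cg_all, w0):np.searchsorted(cg_all, w1)]
            used: set[int] = set()
            pi_sum = 0.0
            n_emitted = 0

            for _ in range(n_snv):
                record = _draw_snv(rng, genomes[genome_id], genome_id, bias,
                                   at, cg, used)
                if record is None:
                    continue
                position, ref, alt = record
                gene = next((gn for gn in genome_genes
                             if gn.contains(position)), None)
                effect_planted = None
                if gene is not None and rng.random() < stopgain_p:
                    cands = [c for c in loss_of[gene.gene_id]
                             if w0 <= c[0] < w1 and c[0] not in used]
                    if cands:
                        position, ref, alt, effect_planted = \
                            cands[int(rng.integers(len(cands)))]
                        gene = next(gn for gn in genome_genes
                                    if gn.contains(position))
                used.add(position)
                alt_freq = float(rng.uniform(0.05, 0.5))
                pi_sum += 2 * alt_freq * (1 - alt_freq)
                cov = int(config.min_cov + rng.poisson(depth * 3))
                sample_snvs.append(SnvRecord(
                    genome_id=genome_id, scaffold_id=genome_id,
                    position=int(position), ref_base=ref, alt_base=alt,
                    ref_freq=round(1 - alt_freq, 6),
                    alt_freq=round(alt_freq, 6),
                    site_coverage=cov,
                    gene_id=gene.gene_id if gene else None))
                n_emitted += 1
                if effect_planted is not None:
                    loss_events.append(PlantedLossEvent(
                        sample_id=sample_id, genome_id=genome_id,
                        gene_id=gene.gene_id, scaffold_id=genome_id,
                        position=int(position), ref_base=ref, alt_base=alt,
                        effect=effect_planted))

            planted_counts[(sample_id, genome_id)] = n_emitted
            sample_ginfo.append(GenomeInfoRecord(
                genome_id=genome_id, g_len=g_len,
                coverage=round(float(depth * 3 + config.min_cov), 3),
                breadth_minCov=round(breadth, 6),
                nucleotide_diversity=round(pi_sum / L, 8),
                filtered_read_pairs=0))

        total_w = sum(sample_pairs.values())
        total_pairs = config.reads_per_gb * depth
        sample_pairs = {g: max(int(round(total_pairs * w / total_w)), 1)
                        for g, w in sample_pairs.items()}
        for i, rec in enumerate(sample_ginfo):
            sample_ginfo[i] = replace(
                rec, filtered_read_pairs=sample_pairs[rec.genome_id])

        metadata.append(SampleMeta(
            sample_id=sample_id, cohort_id=cohort_tag,
            phenotype="CTRL" if group == "healthy" else "DIS",
            health_status=group, depth=round(depth, 4)))
        snvs[sample_id] = sample_snvs
        ginfo[sample_id] = sample_ginfo
        mapping[sample_id] = sample_pairs

    return SyntheticCohort(
        config=config, genomes=genomes, annotations=annotations,
        metadata=metadata, snvs=snvs, genome_info=ginfo,
        mapping_info=mapping,
        ground_truth=GroundTruth(
            marker_direction=marker_direction,
            planted_snv_counts=planted_counts,
            planted_loss_events=loss_events))


def _extract_cds(scaffold: str, gene: GeneAnnotation) -> str:
    seq = scaffold[gene.start:gene.end]
    return seq if gene.strand == "+" else _revcomp(seq)


def _draw_snv(rng, scaffold, genome_id, bias, at, cg, used,
              max_tries: int = 20):
    """Draw (position, ref, alt): class from the bias vector, then a
    callable position whose reference base can realise that class."""
    for _ in range(max_tries):
        cls = int(rng.choice(6, p=bias))
        pool = at if cls in _AT_CLASSES else cg
        if len(pool) == 0:
            continue
        position = int(pool[int(rng.integers(len(pool)))])
        if position in used:
            continue
        ref = scaffold[position]
        return position, ref, _CLASS_ALT[(ref, cls)]
    return None


# ---------------------------------------------------------------------------
# writing the file set the readers consume
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Emit the exact file set ``io_ingest`` reads, plus ground_truth.tsv."""
    out = Path(out_dir)
    (out / "snvs").mkdir(parents=True, exist_ok=True)
    (out / "genome_info").mkdir(exist_ok=True)
    (out / "mapping_info").mkdir(exist_ok=True)

    with open(out / "genomes.fasta", "w") as fh:
        for gid in sorted(cohort.genomes):
            fh.write(f">{gid}\n")
            seq = cohort.genomes[gid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in cohort.annotations:
            attrs = (f"ID={ann.gene_id};genome={ann.genome_id};"
                     f"scfa_family={ann.scfa_family}")
            fh.write("\t".join([
                ann.scaffold_id, "snvgmhi_sim", "CDS",
                str(ann.start + 1), str(ann.end),    # back to 1-based inclusive
                ".", ann.strand, "0", attrs]) + "\n")

    with open(out / "metadata.tsv", "w") as fh:
        fh.write("sample_id\tcohort\tphenotype\thealth_status\tdepth_gb\n")
        for m in cohort.metadata:
            fh.write(f"{m.sample_id}\t{m.cohort_id}\t{m.phenotype}\t"
                     f"{m.health_status}\t{m.depth}\n")

    for m in cohort.metadata:
        s = m.sample_id
        with open(out / "snvs" / f"{s}.tsv", "w") as fh:
            fh.write("genome\tscaffold\tposition\tref_base\talt_base\t"
                     "ref_freq\talt_freq\tposition_coverage\tgene\n")
            for r in cohort.snvs[s]:
                fh.write(f"{r.genome_id}\t{r.scaffold_id}\t{r.position}\t"
                         f"{r.ref_base}\t{r.alt_base}\t{r.ref_freq}\t"
                         f"{r.alt_freq}\t{r.site_coverage}\t"
                         f"{r.gene_id or ''}\n")
        with open(out / "genome_info" / f"{s}.tsv", "w") as fh:
            fh.write("genome\tlength\tcoverage\tbreadth_minCov\t"
                     "nucleotide_diversity\tfiltered_read_pairs\n")
            for g in cohort.genome_info[s]:
                fh.write(f"{g.genome_id}\t{g.g_len}\t{g.coverage}\t"
                         f"{g.breadth_minCov}\t{g.nucleotide_diversity}\t"
                         f"{g.filtered_read_pairs}\n")
        with open(out / "mapping_info" / f"{s}.tsv", "w") as fh:
            fh.write("genome\tfiltered_read_pairs\n")
            for g, n in sorted(cohort.mapping_info[s].items()):
                fh.write(f"{g}\t{n}\n")

    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("record_type\tsample_id\tgenome_id\tgene_id\tposition\t"
                 "ref\talt\teffect\tdirection\tn\n")
        for g, d in sorted(cohort.ground_truth.marker_direction.items()):
            fh.write(f"marker\t\t{g}\t\t\t\t\t\t{d}\t\n")
        for (s, g), n in sorted(cohort.ground_truth.planted_snv_counts.items()):
            fh.write(f"snv_count\t{s}\t{g}\t\t\t\t\t\t\t{n}\n")
        for ev in cohort.ground_truth.planted_loss_events:
            fh.write(f"loss_event\t{ev.sample_id}\t{ev.genome_id}\t"
                     f"{ev.gene_id}\t{ev.position}\t{ev.ref_base}\t"
                     f"{ev.alt_base}\t{ev.effect}\t\t\n")
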
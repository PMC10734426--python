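"""Coding-effect classification, pN/pS and codon variant bias.

Effects are classified under the bacterial/archaeal genetic code
(translation table 11) with start codons {ATG, GTG, TTG}.  "Codon variant
bias" is the event that a SNV converts a sense codon into a termination
codon (stop-gain) or inactivates the start codon (start-loss) — the
signature of loss-of-function variation in SCFA-production genes.

pN/pS is a per-gene polymorphism rate ratio: observed nonsynonymous and
synonymous SNV counts over the gene's expected nonsynonymous/synonymous
"siteness", obtained by enumerating all nine single-base changes of every
codon.  It is computed from observed polymorphic positions (at least two
alleles present), not from divergence to a reference, and uses no
substitution model.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import scipy.stats
from Bio.Data import CodonTable

from .io_ingest import GeneAnnotation, SnvRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid (stop codons map to "*")
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS = frozenset(_TABLE11.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: start codons actually used by the classifier (subset of table 11's list)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BASES = "ACGT"


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class ReferenceMismatchError(ValueError):
    """The SNV's reference allele disagrees with the gene sequence."""


@dataclass(frozen=True)
class CodonChange:
    """A single-base change expressed in coding orientation."""

    gene_id: str
    codon_index: int            # 0-based codon number
    within_codon_pos: int       # 0, 1 or 2
    ref_codon: str
    alt_codon: str
    effect: str                 # synonymous | nonsynonymous | stop_gain |
                                # stop_loss | start_loss


def _codon_effect(ref_codon: str, alt_codon: str, codon_index: int) -> str:
    """Effect of ref_codon -> alt_codon at the given codon position."""
    if codon_index == 0 and alt_codon not in START_CODONS:
        return "start_loss"
    ref_stop = ref_codon in STOP_CODONS
    alt_stop = alt_codon in STOP_CODONS
    if alt_stop and not ref_stop:
        return "stop_gain"
    if ref_stop and not alt_stop:
        return "stop_loss"
    if CODON_TO_AA[ref_codon] == CODON_TO_AA[alt_codon]:
        return "synonymous"
    return "nonsynonymous"


def classify_snv_effect(gene: GeneAnnotation, gene_seq: str,
                        snv: SnvRecord) -> CodonChange | str:
    """Classify a SNV's coding effect within ``gene``.

    ``gene_seq`` is the coding-strand sequence of the gene (starts with the
    start codon).  Returns ``"noncoding"`` when the SNV falls outside the
    gene span; otherwise a :class:`CodonChange`.  For minus-strand genes
    the genomic position and alleles are mapped into coding orientation
    before codon lookup.
    """
    if not gene.contains(snv.position):
        return "noncoding"
    if gene.length % 3 != 0 or not gene.codon_eligible:
        raise ValueError(f"{gene.gene_id}: not eligible for codon analysis")
    if gene.strand == "+":
        offset = snv.position - gene.start
        ref, alt = snv.ref_base, snv.alt_base
    else:
        offset = gene.end - 1 - snv.position
        ref, alt = complement(snv.ref_base), complement(snv.alt_base)
    if gene_seq[offset] != ref:
        raise ReferenceMismatchError(
            f"{gene.gene_id} offset {offset}: gene sequence has "
            f"{gene_seq[offset]!r}, SNV reference is {ref!r}")
    codon_index, within = divmod(offset, 3)
    ref_codon = gene_seq[codon_index * 3: codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    return CodonChange(
        gene_id=gene.gene_id, codon_index=codon_index,
        within_codon_pos=within, ref_codon=ref_codon, alt_codon=alt_codon,
        effect=_codon_effect(ref_codon, alt_codon, codon_index))


# ---------------------------------------------------------------------------
# pN/pS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSelectionStats:
    gene_id: str
    scfa_family: str
    pn: float
    ps: float
    pn_ps: float | None         # None when ps == 0
    n_sites_N: float
    n_sites_S: float
    n_obs_N: int
    n_obs_S: int


def expected_sites(gene_seq: str) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site counts for a gene.

    Every codon position contributes ``n_nonsyn/3 + n_syn/3 = 1`` site,
    where the nine single-base changes of the codon are classified under
    table 11; stop-affecting changes count as nonsynonymous.  Totals sum
    to the gene length.
    """
    n_sites = s_sites = 0.0
    for ci in range(len(gene_seq) // 3):
        codon = gene_seq[ci * 3: ci * 3 + 3]
        for pos in range(3):
            n_nonsyn = n_syn = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if (codon in STOP_CODONS) != (alt in STOP_CODONS):
                    n_nonsyn += 1       # stop gain/loss counted nonsynonymous
                elif CODON_TO_AA[codon] == CODON_TO_AA[alt]:
                    n_syn += 1
                else:
                    n_nonsyn += 1
            n_sites += n_nonsyn / 3.0
            s_sites += n_syn / 3.0
    return n_sites, s_sites


def pn_ps(gene: GeneAnnotation, gene_seq: str,
          snvs: Iterable[SnvRecord]) -> GeneSelectionStats:
    """Per-gene pN/pS from observed polymorphic positions.

    Only SNVs with both alleles observed (``ref_freq > 0`` and
    ``alt_freq > 0``) enter the counts.  ``pn = obs_N / sites_N``,
    ``ps = obs_S / sites_S``; the ratio is undefined (``None``) when
    ``ps == 0``.
    """
    sites_n, sites_s = expected_sites(gene_seq)
    obs_n = obs_s = 0
    for snv in snvs:
        if snv.ref_freq <= 0 or snv.alt_freq <= 0:
            continue            # only bi-allelic-or-more positions
        change = classify_snv_effect(gene, gene_seq, snv)
        if change == "noncoding":
            continue
        if change.effect == "synonymous":
            obs_s += 1
        else:                   # nonsyn, stop_gain/loss, start_loss
            obs_n += 1
    pn = obs_n / sites_n if sites_n > 0 else 0.0
    ps = obs_s / sites_s if sites_s > 0 else 0.0
    ratio = pn / ps if ps > 0 else None
    return GeneSelectionStats(
        gene_id=gene.gene_id, scfa_family=gene.scfa_family,
        pn=pn, ps=ps, pn_ps=ratio,
        n_sites_N=sites_n, n_sites_S=sites_s,
        n_obs_N=obs_n, n_obs_S=obs_s)


# ---------------------------------------------------------------------------
# codon variant bias
# ---------------------------------------------------------------------------

LOSS_EFFECTS = frozenset({"stop_gain", "start_loss"})


@dataclass(frozen=True)
class CodonBiasSummary:
    """Per-group frequency of codon variant bias on one gene (or genome)."""

    gene_id: str
    group: str                  # "healthy" | "nonhealthy"
    N: int                      # individuals with >=1 SNV on the gene
    carriers: int               # individuals with >=1 stop-gain/start-loss
    frequency: float


def codon_bias_frequency(gene_id: str,
                         carriers_by_group: Mapping[str, int],
                         n_by_group: Mapping[str, int],
                         ) -> tuple[list[CodonBiasSummary], float | None]:
    """Per-group codon-variant-bias frequencies and Fisher's exact p.

    ``n_by_group[g]`` is the number of individuals in group ``g`` with at
    least one SNV on the gene; ``carriers_by_group[g]`` the number of
    those with at least one stop-gain/start-loss.  The two-sided p-value
    comes from the 2x2 table (carriers, N-carriers) x group; it is ``None``
    when either group has N == 0.
    """
    summaries = []
    for group in ("healthy", "nonhealthy"):
        n = n_by_group.get(group, 0)
        carriers = carriers_by_group.get(group, 0)
        if carriers > n:
            raise ValueError(f"{gene_id} {group}: carriers > N")
        freq = carriers / n if n > 0 else float("nan")
        summaries.append(CodonBiasSummary(
            gene_id=gene_id, group=group, N=n, carriers=carriers,
            frequency=freq))
    h, n_ = summaries
    if h.N == 0 or n_.N == 0:
        return summaries, None
    table = [[h.carriers, h.N - h.carriers],
             [n_.carriers, n_.N - n_.carriers]]
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return summaries, float(p)


def carrier_counts(sample_changes: Mapping[str, Sequence[CodonChange]],
                   labels: Mapping[str, str],
                   ) -> tuple[dict[str, int], dict[str, int]]:
    """Collapse per-sample codon changes into (carriers, N) per group.

    ``sample_changes`` maps sample_id to the codon changes observed on the
    gene (or gene set) of interest; a sample counts toward N if it has any
    change at all, and toward carriers if any change is stop-gain or
    start-loss.
    """
    carriers: dict[str, int] = defaultdict(int)
    n: dict[str, int] = defaultdict(int)
    for sample_id, changes in sample_changes.items():
        if not changes:
            continue
        group = labels[sample_id]
        n[group] += 1
        if any(c.effect in LOSS_EFFECTS for c in changes):
            carriers[group] += 1
    return dict(carriers), dict(n)


# ---------------------------------------------------------------------------
# recurrent codon variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrentVariant:
    scaffold_id: str
    position: int
    ref_codon: str
    alt_codon: str
    effect: str
    n_individuals: int
    flanking_genes: tuple[str, ...]


def recurrent_codon_variants(
        per_sample: Mapping[str, Sequence[tuple[SnvRecord, CodonChange]]],
        annotations: Sequence[GeneAnnotation],
        min_individuals: int = 3) -> list[RecurrentVariant]:
    """Stop-gain/start-loss positions shared by >= ``min_individuals``.

    ``per_sample`` maps sample_id to (SNV, classified change) pairs.
    Results are sorted by the number of carrying individuals descending,
    ties broken by position ascending.  Flanking genes are the annotated
    genes immediately before and after the affected gene on the scaffold.
    """
    if min_individuals < 1:
        raise ValueError("min_individuals must be >= 1")
    by_scaffold: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_scaffold[ann.scaffold_id].append(ann)
    for genes in by_scaffold.values():
        genes.sort(key=lambda g: g.start)

    seen: dict[tuple, set[str]] = defaultdict(set)
    meta: dict[tuple, tuple] = {}
    for sample_id, pairs in per_sample.items():
        for snv, change in pairs:
            if change == "noncoding" or change.effect not in LOSS_EFFECTS:
                continue
            key = (snv.scaffold_id, snv.position,
                   change.ref_codon, change.alt_codon)
            seen[key].add(sample_id)
            meta[key] = (change.effect, change.gene_id)

    out = []
    for key, samples in seen.items():
        if len(samples) < min_individuals:
            continue
        scaffold, position, ref_codon, alt_codon = key
        effect, gene_id = meta[key]
        genes = by_scaffold.get(scaffold, [])
        idx = next((i for i, g in enumerate(genes) if g.gene_id == gene_id), None)
        flanks = []
        if idx is not None:
            if idx > 0:
                flanks.append(genes[idx - 1].gene_id)
            flanks.append(gene_id)
            if idx + 1 < len(genes):
                flanks.append(genes[idx + 1].gene_id)
        out.append(RecurrentVariant(
            scaffold_id=scaffold, position=position,
            ref_codon=ref_codon, alt_codon=alt_codon, effect=effect,
            n_individuals=len(samples), flanking_genes=tuple(flanks)))
    out.sort(key=lambda v: (-v.n_individuals, v.position))
    return out
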
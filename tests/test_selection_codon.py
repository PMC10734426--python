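"""Codon-effect classification, pN/pS siteness and codon-bias tests,
each checked against an independent oracle (full-gene translation,
exhaustive nine-change enumeration, hypergeometric enumeration)."""

from math import comb

import numpy as np
import pytest
from Bio.Seq import Seq

from snvgmhi.io_ingest import GeneAnnotation, SnvRecord
from snvgmhi.selection_codon import (
    START_CODONS, ReferenceMismatchError, carrier_counts,
    classify_snv_effect, codon_bias_frequency, expected_sites, pn_ps,
    recurrent_codon_variants,
)
from snvgmhi.synthetic_data import _random_cds, _revcomp

COMP = str.maketrans("ACGT", "TGCA")


def _gene(strand="+", start=0, length=300, gene_id="gX"):
    return GeneAnnotation(gene_id=gene_id, genome_id="g", scaffold_id="sc",
                          start=start, end=start + length, strand=strand)


def _snv(pos, ref, alt):
    return SnvRecord(genome_id="g", scaffold_id="sc", position=pos,
                     ref_base=ref, alt_base=alt, ref_freq=0.6, alt_freq=0.4,
                     site_coverage=10)


def _translation_oracle(cds, offset, alt):
    """Independent effect call: rebuild the mutated gene, translate both
    full sequences with table 11, and diff the proteins."""
    mutated = cds[:offset] + alt + cds[offset + 1:]
    if offset < 3 and mutated[:3] not in START_CODONS:
        return "start_loss"
    ref_p = str(Seq(cds).translate(table=11))
    alt_p = str(Seq(mutated).translate(table=11))
    if ref_p == alt_p:
        return "synonymous"
    i = next(k for k in range(len(ref_p)) if ref_p[k] != alt_p[k])
    if alt_p[i] == "*" and ref_p[i] != "*":
        return "stop_gain"
    if ref_p[i] == "*" and alt_p[i] != "*":
        return "stop_loss"
    return "nonsynonymous"


class TestClassifyEffect:
    def test_start_loss_forced_by_start_set(self):
        cds = "ATG" + "GGT" * 9 + "TAA"
        ann = _gene(length=33)
        change = classify_snv_effect(ann, cds, _snv(2, "G", "A"))
        assert change.effect == "start_loss"
        assert change.alt_codon == "ATA"

    def test_stop_gain_from_tgg(self):
        cds = "ATG" + "TGG" + "GGT" * 8 + "TAA"
        change = classify_snv_effect(_gene(length=36), cds, _snv(5, "G", "A"))
        assert change.effect == "stop_gain"
        assert change.alt_codon == "TGA"

    def test_reference_mismatch_raises(self):
        cds = "ATG" + "GGT" * 9 + "TAA"
        with pytest.raises(ReferenceMismatchError, match="gX"):
            classify_snv_effect(_gene(length=33), cds, _snv(4, "C", "A"))

    def test_outside_gene_is_noncoding(self):
        cds = "ATG" + "GGT" * 9 + "TAA"
        assert classify_snv_effect(_gene(length=33), cds,
                                   _snv(500, "A", "G")) == "noncoding"

    def test_agrees_with_translation_oracle_both_strands(self, rng):
        # 1,000 random (gene, SNV) fixtures, plus and minus strand
        for _ in range(1000):
            length = int(rng.choice([30, 60, 90]))
            cds = _random_cds(rng, length)
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 50))
            ann = _gene(strand=strand, start=start, length=length)
            offset = int(rng.integers(0, length))
            ref = cds[offset]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            if strand == "+":
                pos, gref, galt = start + offset, ref, alt
            else:
                pos = ann.end - 1 - offset
                gref, galt = ref.translate(COMP), alt.translate(COMP)
            change = classify_snv_effect(ann, cds, _snv(pos, gref, galt))
            assert change.effect == _translation_oracle(cds, offset, alt), \
                (cds, offset, alt, strand)


class TestPnPs:
    def test_ratio_arithmetic(self):
        # forced by the definition: pn/ps = (1/700)/(1/300)
        assert (1 / 700) / (1 / 300) == pytest.approx(0.42857, abs=1e-4)

    def test_siteness_sums_to_gene_length(self, rng):
        for _ in range(10):
            cds = _random_cds(rng, 90)
            n, s = expected_sites(cds)
            assert n + s == pytest.approx(len(cds), abs=1e-9)

    def test_siteness_matches_exhaustive_enumeration(self, rng):
        # independent oracle via whole-codon translation with biopython
        for _ in range(5):
            cds = _random_cds(rng, 900)     # 300 codons
            n_oracle = s_oracle = 0.0
            for ci in range(len(cds) // 3):
                codon = cds[ci * 3: ci * 3 + 3]
                aa = str(Seq(codon).translate(table=11))
                for pos in range(3):
                    for b in "ACGT":
                        if b == codon[pos]:
                            continue
                        alt = codon[:pos] + b + codon[pos + 1:]
                        if str(Seq(alt).translate(table=11)) == aa:
                            s_oracle += 1 / 3
                        else:
                            n_oracle += 1 / 3
            n, s = expected_sites(cds)
            assert n == pytest.approx(n_oracle, abs=1e-9)
            assert s == pytest.approx(s_oracle, abs=1e-9)

    def test_counts_and_undefined_ratio(self):
        cds = "ATG" + "CTT" * 8 + "TAA"      # CTT leucine block
        ann = _gene(length=30)
        stats = pn_ps(ann, cds, [])
        assert stats.pn == stats.ps == 0 and stats.pn_ps is None
        # CTT->CTC synonymous at third codon position (offset 5)
        syn = _snv(5, "T", "C")
        # CTT->ATT nonsynonymous at first position of codon 2 (offset 6)
        nonsyn = _snv(6, "C", "A")
        stats = pn_ps(ann, cds, [syn, nonsyn])
        assert stats.n_obs_S == 1 and stats.n_obs_N == 1
        assert stats.pn_ps == pytest.approx(
            (1 / stats.n_sites_N) / (1 / stats.n_sites_S))

    def test_monoallelic_positions_excluded(self):
        cds = "ATG" + "CTT" * 8 + "TAA"
        fixed = SnvRecord(genome_id="g", scaffold_id="sc", position=5,
                          ref_base="T", alt_base="C", ref_freq=0.0,
                          alt_freq=1.0, site_coverage=10)
        stats = pn_ps(_gene(length=30), cds, [fixed])
        assert stats.n_obs_S == 0 and stats.n_obs_N == 0


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n1, n2 = a + b, c + d
    k = a + c
    total = comb(n1 + n2, k)

    def pmf(x):
        if x < max(0, k - n2) or x > min(k, n1):
            return 0.0
        return comb(n1, x) * comb(n2, k - x) / total

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(min(k, n1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


class TestCodonBias:
    def test_no_events_p_one(self):
        summaries, p = codon_bias_frequency(
            "gA", {"healthy": 0, "nonhealthy": 0},
            {"healthy": 50, "nonhealthy": 60})
        assert all(s.frequency == 0 for s in summaries)
        assert p == pytest.approx(1.0)

    def test_equal_frequencies_p_one(self):
        _, p = codon_bias_frequency("gA", {"healthy": 5, "nonhealthy": 5},
                                    {"healthy": 50, "nonhealthy": 50})
        assert p == pytest.approx(1.0)

    def test_empty_group_skips_test(self):
        summaries, p = codon_bias_frequency(
            "gA", {"healthy": 1}, {"healthy": 10, "nonhealthy": 0})
        assert p is None
        assert np.isnan([s for s in summaries
                         if s.group == "nonhealthy"][0].frequency)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            _, p = codon_bias_frequency(
                "g", {"healthy": int(a), "nonhealthy": int(c)},
                {"healthy": int(a + b), "nonhealthy": int(c + d)})
            if p is None:
                continue
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-10)

    def test_invariant_under_group_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            _, p1 = codon_bias_frequency("g", {"healthy": a, "nonhealthy": c},
                                         {"healthy": a + b, "nonhealthy": c + d})
            _, p2 = codon_bias_frequency("g", {"healthy": c, "nonhealthy": a},
                                         {"healthy": c + d, "nonhealthy": a + b})
            if p1 is None or p2 is None:
                continue
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_carrier_counts_roll_up(self, small_cohort, small_cohort_cds):
        from collections import defaultdict
        labels = {m.sample_id: m.health_status
                  for m in small_cohort.metadata}
        anns = {a.gene_id: a for a in small_cohort.annotations}
        per_sample = defaultdict(list)
        for sample_id, records in small_cohort.snvs.items():
            for r in records:
                if r.gene_id:
                    per_sample[sample_id].append(classify_snv_effect(
                        anns[r.gene_id], small_cohort_cds[r.gene_id], r))
        carriers, n = carrier_counts(per_sample, labels)
        planted = {(ev.sample_id) for ev in
                   small_cohort.ground_truth.planted_loss_events}
        assert sum(carriers.values()) >= len(
            {labels[s] for s in planted}) and sum(n.values()) > 0


class TestRecurrentVariants:
    def _pairs(self, small_cohort, small_cohort_cds):
        anns = {a.gene_id: a for a in small_cohort.annotations}
        out = {}
        for sample_id, records in small_cohort.snvs.items():
            pairs = []
            for r in records:
                if r.gene_id:
                    pairs.append((r, classify_snv_effect(
                        anns[r.gene_id], small_cohort_cds[r.gene_id], r)))
            out[sample_id] = pairs
        return out

    def test_planted_recurrence_reported(self, small_cohort,
                                         small_cohort_cds):
        from collections import Counter
        per_sample = self._pairs(small_cohort, small_cohort_cds)
        shared = Counter((ev.scaffold_id, ev.position) for ev in
                         small_cohort.ground_truth.planted_loss_events)
        top, n_top = shared.most_common(1)[0]
        found = recurrent_codon_variants(per_sample,
                                         small_cohort.annotations,
                                         min_individuals=min(n_top, 2))
        assert any(v.scaffold_id == top[0] and v.position == top[1]
                   for v in found)

    def test_threshold_above_max_sharing_empty(self, small_cohort,
                                               small_cohort_cds):
        per_sample = self._pairs(small_cohort, small_cohort_cds)
        assert recurrent_codon_variants(per_sample,
                                        small_cohort.annotations,
                                        min_individuals=10 ** 6) == []

    def test_ties_ordered_by_position(self, small_cohort, small_cohort_cds):
        per_sample = self._pairs(small_cohort, small_cohort_cds)
        found = recurrent_codon_variants(per_sample,
                                         small_cohort.annotations,
                                         min_individuals=1)
        for a, b in zip(found, found[1:]):
            assert (a.n_individuals > b.n_individuals
                    or (a.n_individuals == b.n_individuals
                        and a.position <= b.position))
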
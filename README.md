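# snvgmhi

Strain-resolved single-nucleotide-variant (SNV) profiling of the gut
microbiome, and SNV-based Gut Microbiome Health Indices (GMHI).

Cross-cohort metagenomic studies show that host health status is reflected
not only in *which* gut microbes are present, but in the fine-scale genetic
variation *within* each microbial strain. `snvgmhi` implements the
downstream analysis of that signal for anyone who already has per-sample
strain-resolved SNV calls (inStrain-style TSV output plus GFF3/FASTA
references): per-genome variant-density metrics, base-variant-type bias,
loss-of-function (stop-gain / start-loss) bias in short-chain-fatty-acid
(SCFA) production genes, gene-level pN/pS, and health-index construction
with marker selection and ROC evaluation. A seeded synthetic-cohort
generator makes the whole pipeline testable without any sequence download.

## The core quantities

**SNV rate.** Raw per-genome SNV counts are incomparable across samples
because sequencing breadth and depth vary. The normalized variant density
of a mutated genome (a reference genome with ≥ 1 called SNV in a sample)
is

```
SNV rate = SNV number / (g_len × breadth_minCov)
```

i.e. SNVs per SNV-callable base, where `breadth_minCov` is the fraction of
the genome covered at ≥ `min_cov` (default 5) reads. Per-sample totals
(number of mutated genomes, total SNVs) are additionally normalized by
sequencing depth in gigabases.

**GMHI.** For a feature table (genome sequence abundance, genome SNV rate,
or SCFA-gene SNV frequency), health-enriched (MH) and nonhealthy-enriched
(MN) marker features are selected by two-sided Wilcoxon rank-sum tests
with Benjamini–Hochberg correction (q < 0.05), compositional tables being
CLR-transformed first. Each sample is then scored from its marker richness
(Hr, Nr), marker Shannon diversity (Hs, Ns) and cohort constants Hp, Np
(median richness of the top-ranked 1 % of samples):

```
psi_H = (Hr / Hp) · Hs        psi_N = (Nr / Np) · Ns
GMHI  = log10((psi_H + ε) / (psi_N + ε)),   ε = 1e-5
```

GMHI > 0 means the collective health-enriched signal dominates.

**Codon variant bias.** Each coding SNV is classified under the bacterial
genetic code (translation table 11; start codons ATG/GTG/TTG). A
stop-gain (sense codon → TAA/TAG/TGA) or start-loss (codon 0 leaves the
start set) in an SCFA-production gene (*ack*, *buk*, *ydiF*, *atoD/A*,
*ctfA/B*, *BcAt*, *scpC*) is a "codon variant bias" event; per-gene (or
per-genome) carrier frequencies are compared between host groups with
Fisher's exact test, and gene-level selection pressure with pN/pS
(observed nonsynonymous/synonymous SNVs over expected site counts from
exhaustive single-base codon enumeration).

## Worked example

```python
from snvgmhi import (SimConfig, generate_cohort, assemble_profiles,
                     build_feature_table, GmhiModel, evaluate_index)

cohort = generate_cohort(SimConfig(), seed=42)      # 100 + 100 samples
labels = {m.sample_id: m.health_status for m in cohort.metadata}
profiles = assemble_profiles(cohort.snvs, cohort.genome_info,
                             cohort.mapping_info)
table = build_feature_table(profiles, "snv_rate",
                            sample_ids=[m.sample_id for m in cohort.metadata],
                            prevalence_threshold=0.10)
model = GmhiModel().fit(table, labels)
scores = {r.sample_id: r.gmhi for r in model.score(table)}
report = evaluate_index(scores, labels)
print(f"features passing 10% prevalence: {table.values.shape[1]}")
print(f"markers: {len(model.markers.MH)} health-enriched, "
      f"{len(model.markers.MN)} nonhealthy-enriched")
print(f"SNV-rate GMHI AUROC: {100 * report.auroc:.2f}%  "
      f"(Wilcoxon p = {report.overall_p:.2e})")
```

prints

```
features passing 10% prevalence: 40
markers: 5 health-enriched, 5 nonhealthy-enriched
SNV-rate GMHI AUROC: 82.91%  (Wilcoxon p = 9.01e-16)
```

All ten genomes planted with a group-shifted SNV rate are recovered as
markers with the correct direction, and the resulting index separates the
two host groups cleanly at this cohort size. The same objects drive the
other stages (`scfa_snv_feature_table`, `classify_snv_effect`, `pn_ps`,
`codon_bias_frequency`, `permanova`, `match_pairs`, ...), and a thin CLI
wraps them:

```bash
snvgmhi simulate --seed 11 --out-dir fixtures/
snvgmhi profile  --cohort-dir fixtures/ --out-dir profiles/
snvgmhi markers  --table profiles/features_snv_rate.tsv \
                 --metadata fixtures/metadata.tsv --out markers.tsv
```

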
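# Methods

## Scope and data model

`snvgmhi` consumes the *output* of strain-resolved SNV calling on shotgun
metagenomes — per-sample SNV tables, genome-info tables (length, mean
coverage, `breadth_minCov`, nucleotide diversity), mapping-info tables
(filtered read-pair counts) — together with GFF3 gene annotations and
FASTA reference sequences. Read mapping and SNV calling themselves are out
of scope; the readers follow the inStrain TSV dialect, with a column-alias
mechanism for other caller versions. Coordinates are converted exactly
once at ingest: GFF3 1-based inclusive on disk, 0-based half-open in
memory; SNV positions are taken as 0-based, the convention of the caller
whose output we consume. SNVs below the coverage floor (`min_cov`,
default 5 reads) are dropped at ingest.

## Per-genome metrics

* **SNV rate** `= n_SNV / (g_len × breadth_minCov)` — variants per
  SNV-callable base. Undefined (genome excluded, logged) at zero breadth.
* **Depth normalization** of per-sample counts divides by sequencing
  throughput; the unit (per Gb by default, per Mkb optionally) is carried
  as metadata, never mixed silently.
* **Nucleotide diversity** is the mean over qualifying (≥ `min_cov`)
  sites of per-site `π = 1 − Σ p_i²`; non-variant qualifying sites
  contribute 0. Whether averaging should instead run over variant sites
  only is caller-dependent; the all-qualifying-sites reading is the
  default here and the alternative is a one-line change at the call site
  (pass the variant-site count as the denominator).
* **Sequence abundance** of a mutated genome is its share of the sample's
  filtered read pairs, so rows of an abundance table sum to 1.
* **Variant types** are collapsed into the six strand-complement classes
  (`A>C|T>G`, `A>G|T>C`, `A>T|T>A`, `C>A|G>T`, `C>G|G>C`, `C>T|G>A`);
  classification is invariant under simultaneous complementation of both
  alleles.
* **Prevalence** of a genome is the fraction of samples with ≥ 1 retained
  SNV on it; no abundance gate. Feature tables keep genomes above a
  prevalence threshold (0.10 for genome-level tables, 0.30 for the
  detailed strain analyses). Pooling printed per-group prevalences
  recovers integer carrier counts by rounding `prevalence × n` before
  summing — the printed two-decimal values are roundings of integers, and
  this is the only rule that reproduces the published pooled values
  exactly.

## Coding effects, pN/pS and codon variant bias

Effects use translation table 11 with start codons {ATG, GTG, TTG}.
Minus-strand SNVs are complemented and mapped into coding orientation
before codon lookup; a reference-allele mismatch with the gene sequence is
a hard error naming gene and offset. `start_loss` is defined as any
codon-0 change that leaves the start-codon set (checked before the stop
logic; a single base change cannot turn ATG into a stop codon, so the
precedence is only a definition, not a tie-break). `stop_loss` is
classified but reported separately: codon variant bias counts
stop-gain + start-loss only.

pN/pS is a polymorphism rate ratio, not dN/dS: expected
nonsynonymous/synonymous site counts come from enumerating all nine
single-base changes of every codon (stop-affecting changes count as
nonsynonymous; each codon position contributes siteness summing to 1, so
N + S sites equal the gene length), and observed counts include only
positions where both alleles are present (`ref_freq > 0` and
`alt_freq > 0`), i.e. polymorphism within the sample, not divergence from
the reference. The ratio is undefined and flagged when `ps = 0`.

Carrier frequencies (carriers / N, with N the individuals carrying ≥ 1
SNV on the gene or gene set) are compared between groups with two-sided
Fisher's exact tests. An individual is a carrier if *any* allele at any
position of the gene is stop-gain/start-loss; a majority-allele-only
definition would be stricter but the any-allele reading matches how the
events are called. Recurrent variants are loss positions shared by
≥ `min_individuals` (default 3) samples, sorted by carrier count
descending, position ascending.

## Diversity and matched comparison

Shannon (natural log) and Gini–Simpson indices operate on renormalized
proportions; Bray–Curtis and Euclidean distances feed classical PCoA
(eigendecomposition of the double-centred −½D² matrix; negative
eigenvalues are reported, never clipped) and one-factor PERMANOVA
(pseudo-F from the among/within sum-of-squares decomposition; p from
seeded label permutations with the add-one rule, 999 permutations by
default). Reported PERMANOVA effect sizes are R² in the vegan/adonis
sense.

The alpha-matched comparison pairs healthy with nonhealthy samples whose
alpha diversity differs by at most a tolerance (0.01 Shannon / 0.001
Simpson in the source analysis). The matching algorithm is greedy
nearest-difference without replacement — candidate pairs sorted by
|difference|, ties broken by sample ids for determinism — which the test
suite shows is within one pair of the exhaustive optimum on small inputs.
The tolerance is symmetric (|Δ| ≤ tol); a one-sided variant would be a
trivial filter on the pair list. Paired counts are then compared with the
Wilcoxon signed-rank test (exact for n ≤ 25 without ties, normal
approximation with continuity correction above).

## GMHI construction

Markers: per-feature two-sided Wilcoxon rank-sum between groups, BH
correction, q < 0.05; direction by the healthy-minus-nonhealthy median
difference (mean difference breaks exact median ties). Abundance-kind
tables are CLR-transformed before testing (zeros replaced by half the
sample's minimum positive value, rows renormalized); SNV-rate and
SCFA-frequency tables are tested raw, since they are densities, not
compositions — CLR remains available via a flag.

Per sample, richness Hr/Nr counts markers with value > 0 and Hs/Ns is
Shannon diversity over the marker sub-vector renormalized *among markers
only*, so the MH and MN summaries are independent. Population constants
Hp/Np are the median richness of the top ⌈1 %⌉ of samples ranked by that
same richness (ties broken by sample id); this literal richness-ranking
reading is the default, zero constants are floored at ε. The score is
`log10((psi_H + ε)/(psi_N + ε))` with ε = 1e-5, which keeps the score
finite when one side has no detected markers and makes the index exactly
antisymmetric under an MH/MN swap when Hp = Np. `GmhiModel` freezes
markers and constants fit on a discovery table and applies them unchanged
to validation tables, mirroring external validation. AUROC uses the rank
(Mann–Whitney) estimator with tie correction, healthy as the positive
class.

The SCFA-SNV feature is per (sample, genome): SNVs inside the genome's
SCFA-family genes divided by (total SCFA-gene length × breadth_minCov) —
a relative frequency on callable SCFA bases. The alternative denominator
(the genome's total SNV count) reads the same words differently; the
breadth-scaled gene length was chosen because it keeps the feature a
density commensurable with the genome-level SNV rate.

## Synthetic cohorts

The generator emulates the post-SNV-calling tables for a two-group cohort
and records every planted effect. Defaults (the desk-scale study
conditions; all configurable through `SimConfig`):

* 100 healthy + 100 nonhealthy samples; depth ~ log-normal(ln 5, 0.4) Gb,
  echoing the 1.6–11 Gb range of real cohorts.
* 40 reference genomes of 12 kb, each with three non-overlapping 300-bp
  SCFA genes (ATG start, clean table-11 ORF, terminal stop, alternating
  strands, families cycling through ack…scpC). Genome/gene sizes are
  scaled far below real bacterial genomes to keep the full pipeline
  seconds-fast; all metrics are densities, so the scaling changes counts,
  not structure.
* Mutated genomes per sample ~ Poisson(λ_group × depth) truncated to the
  genome panel, λ = 3.2 (healthy) vs 2.8 (nonhealthy) per Gb — the
  healthy excess (ratio ≈ 1.14) matches the direction and relative size
  of the real healthy/nonhealthy contrast in mutated-strain counts.
* Per mutated genome: breadth ~ Beta(8, 4) (mean ≈ 0.67, near the
  reported well-covered fraction), a contiguous callable window, SNV
  count ~ Poisson(rate × callable bases) with base rate 1e-3 per callable
  base.
* Ten marker genomes (25 %) alternate enriched direction; in their
  enriched group their SNV rate and abundance weight are multiplied by
  2.0 and their detection odds by 1.3. These effect sizes were calibrated
  once so that the SNV-rate GMHI reaches AUROC ≈ 0.75–0.80 at n = 200 —
  a qualitative stand-in for the discovery-scale separation — and then
  frozen.
* Alt alleles are drawn class-first from the per-group six-class bias
  vector (healthy enriched for A>G|T>C, nonhealthy for C>G|G>C), then a
  callable position with a compatible reference base is chosen, so the
  empirical collapsed-class frequencies converge to the configured vector
  exactly.
* An SNV landing in an SCFA gene is converted, with probability 0.05
  (healthy) vs 0.35 (nonhealthy), into a planted stop-gain/start-loss by
  drawing from the gene's precomputed single-base loss candidates; every
  planted event appears in exactly one emitted record and provably
  truncates the translated protein (or breaks the start codon).
* Nucleotide diversity is derived from the simulated allele frequencies
  (alt frequency ~ U(0.05, 0.5)); read-pair counts follow a per-genome
  log-normal abundance draw scaled by depth.

All draws flow from a single `numpy.random.default_rng(seed)`, so one
integer reproduces a cohort byte-for-byte.

What the generator does **not** emulate: real taxonomic structure and
phylogeny, linkage between nearby SNVs, strain replacement, 12 distinct
disease phenotypes (two groups plus cohort tags suffice), read-level error
or mapping artefacts, and compositional correlations beyond a shared
normalization. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure of the assumed form at realistic noise levels —
not that real cohorts carry that structure.

## Numerical choices and degenerate inputs

Zero callable breadth, all-zero abundance vectors, all-zero CLR rows,
empty matching sets, single-class cohorts and ps = 0 are all explicit
excluded/undefined cases with warnings, not silent zeros. Population
constants and GMHI use ε = 1e-5. The Fisher test is scipy's exact
implementation (validated in-suite against hypergeometric enumeration);
BH correction is statsmodels; AUROC is scikit-learn's rank estimator
(validated against exhaustive pair counting); PERMANOVA and PCoA are
implemented here (validated against scikit-bio) so that permutations are
seedable and negative eigenvalues visible.

## Problem sizes in tests

The acceptance checks run ten seeded cohorts at the default conditions
(n = 200 each, ≈ 25–30 k SNVs per cohort), 200 PERMANOVA null replicates
at 99 permutations, 1,000 random codon-effect fixtures, and exhaustive
enumeration oracles on ≤ 50-sample inputs — sizes chosen so the whole
suite completes in about a minute on one CPU while keeping every
Monte-Carlo margin wide.

## Known limitations

Greedy alpha-matching is not guaranteed optimal (only near-optimal);
pN/pS uses raw counts without substitution-model correction (by design —
it mirrors the polymorphism-based definition); the SCFA-SNV denominator
choice affects absolute feature values (not marker direction); and the
synthetic cohort's AUROC is a calibration target, not an estimate of real
discriminative power.
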
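"""Marker selection and the three Gut Microbiome Health Indices.

A GMHI summarises one feature table (sequence abundance, SNV rate, or
SCFA-gene SNV frequency) into a per-sample health score.  Markers are
features that differ between healthy and nonhealthy samples (two-sided
Wilcoxon rank-sum, Benjamini-Hochberg corrected, q < alpha), split into
health-enriched (MH) and nonhealthy-enriched (MN) sets by the direction of
the median difference.  For each sample:

    psi_H = (Hr / Hp) * Hs        psi_N = (Nr / Np) * Ns
    GMHI  = log10((psi_H + eps) / (psi_N + eps))

where Hr/Nr are marker richness (markers with a positive value), Hs/Ns
Shannon diversity over the marker sub-vector, and Hp/Np population
constants: the median richness of the top-ranked 1% of samples, ranked by
that same richness.  A positive GMHI indicates a sample whose collective
health-enriched signal dominates.

Abundance-kind tables are centred-log-ratio transformed before the marker
tests (compositional data); richness/diversity summaries always use the
raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .io_ingest import FeatureTable, GeneAnnotation, SnvRecord
from .diversity_stats import shannon, wilcoxon_rank_sum


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def clr_transform(table: pd.DataFrame,
                  pseudocount_policy: str = "half_min") -> pd.DataFrame:
    """Centred log-ratio transform, row-wise.

    Zeros are replaced per ``half_min`` policy (half the row's smallest
    positive value), rows renormalized, logged, and centred on the row's
    log geometric mean.  Output rows sum to 0.
    """
    if pseudocount_policy != "half_min":
        raise ValueError(f"unknown pseudocount policy {pseudocount_policy!r}")
    X = table.to_numpy(dtype=float).copy()
    if (X < 0).any():
        raise ValueError("CLR requires a nonnegative table")
    for i in range(X.shape[0]):
        row = X[i]
        pos = row[row > 0]
        if len(pos) == 0:
            raise ValueError(
                f"sample {table.index[i]!r} is all-zero: CLR undefined")
        row[row == 0] = pos.min() / 2.0
        row /= row.sum()
        X[i] = np.log(row) - np.log(row).mean()
    return pd.DataFrame(X, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    MH: list[str]                       # health-enriched feature ids
    MN: list[str]                       # nonhealthy-enriched feature ids
    q_values: dict[str, float]
    directions: dict[str, str]          # feature -> enriched group
    source_kind: str

    def __post_init__(self):
        if set(self.MH) & set(self.MN):
            raise ValueError("MH and MN overlap")


def select_markers(table: FeatureTable, labels: Mapping[str, str],
                   alpha: float = 0.05, fdr_method: str = "fdr_bh",
                   clr: bool | None = None) -> MarkerSet:
    """Select MH/MN markers from a feature table.

    Per feature: two-sided Wilcoxon rank-sum between groups on the
    (optionally CLR-transformed) values; BH correction across features;
    q < alpha retained; direction assigned by the sign of the healthy -
    nonhealthy median difference.  ``clr`` defaults to True for
    abundance-kind tables and False otherwise.
    """
    df = table.values
    lab = np.array([labels[s] for s in df.index])
    if (lab == "healthy").sum() < 2 or (lab == "nonhealthy").sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if clr is None:
        clr = table.kind == "abundance"
    test_df = clr_transform(df) if clr else df
    X = test_df.to_numpy(dtype=float)
    h_mask = lab == "healthy"

    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue                    # constant feature: p = 1
        pvals[j] = wilcoxon_rank_sum(col[h_mask], col[~h_mask])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method=fdr_method)

    MH, MN, qd, dirs = [], [], {}, {}
    med_diff = (np.median(X[h_mask], axis=0)
                - np.median(X[~h_mask], axis=0))
    # break zero-median ties by mean difference so every marker has a side
    tie = med_diff == 0
    if tie.any():
        med_diff = med_diff + tie * (X[h_mask].mean(axis=0)
                                     - X[~h_mask].mean(axis=0))
    for j, feat in enumerate(df.columns):
        qd[feat] = float(qvals[j])
        if not reject[j] or qvals[j] >= alpha or med_diff[j] == 0:
            continue
        if med_diff[j] > 0:
            MH.append(feat)
            dirs[feat] = "healthy"
        else:
            MN.append(feat)
            dirs[feat] = "nonhealthy"
    return MarkerSet(MH=MH, MN=MN, q_values=qd, directions=dirs,
                     source_kind=table.kind)


# ---------------------------------------------------------------------------
# per-sample summaries and population constants
# ---------------------------------------------------------------------------

def marker_summaries(sample_row: pd.Series, markers: MarkerSet,
                     detection_threshold: float = 0.0
                     ) -> tuple[float, int, float, int]:
    """Return ``(Hs, Hr, Ns, Nr)`` for one sample.

    Richness counts markers with value above the detection threshold
    (default: strictly positive); Shannon is over the marker sub-vector
    renormalized among markers only (natural log), 0 at zero richness.
    """
    def one(feature_ids):
        vals = sample_row.reindex(feature_ids, fill_value=0.0).to_numpy(float)
        present = vals > detection_threshold
        richness = int(present.sum())
        div = shannon(vals[present]) if richness else 0.0
        return div, richness

    hs, hr = one(markers.MH)
    ns, nr = one(markers.MN)
    return hs, hr, ns, nr


def population_constants(richness: Mapping[str, int] | pd.Series,
                         top_fraction: float = 0.01,
                         epsilon: float = 1e-5) -> float:
    """Median richness of the top-ranked ``top_fraction`` of samples.

    Samples are ranked by the richness value itself, descending, ties
    broken by sample id; at least one sample is always used.  A zero
    median is floored at ``epsilon``.
    """
    s = pd.Series(richness, dtype=float)
    if s.empty:
        raise ValueError("no samples")
    k = max(math.ceil(top_fraction * len(s)), 1)
    ranked = s.sort_index().sort_values(ascending=False, kind="stable")
    top = ranked.iloc[:k]
    med = float(top.median())
    return med if med > 0 else epsilon


@dataclass(frozen=True)
class GmhiResult:
    sample_id: str
    Hs: float
    Hr: int
    Ns: float
    Nr: int
    psi_H: float
    psi_N: float
    gmhi: float


def gmhi_score(sample_id: str, Hs: float, Hr: int, Ns: float, Nr: int,
               Hp: float, Np: float, epsilon: float = 1e-5) -> GmhiResult:
    """Score one sample: ``gmhi = log10((psi_H+eps)/(psi_N+eps))``."""
    if Hp <= 0 or Np <= 0:
        raise ValueError("population constants must be > 0")
    psi_h = (Hr / Hp) * Hs
    psi_n = (Nr / Np) * Ns
    return GmhiResult(
        sample_id=sample_id, Hs=Hs, Hr=Hr, Ns=Ns, Nr=Nr,
        psi_H=psi_h, psi_N=psi_n,
        gmhi=float(np.log10((psi_h + epsilon) / (psi_n + epsilon))))


class GmhiModel:
    """Markers + population constants fit on a discovery table, frozen for
    scoring validation tables (external-validation protocol)."""

    def __init__(self, alpha: float = 0.05, top_fraction: float = 0.01,
                 epsilon: float = 1e-5, clr: bool | None = None):
        self.alpha = alpha
        self.top_fraction = top_fraction
        self.epsilon = epsilon
        self.clr = clr
        self.markers: MarkerSet | None = None
        self.Hp: float | None = None
        self.Np: float | None = None

    def fit(self, table: FeatureTable, labels: Mapping[str, str]) -> "GmhiModel":
        self.markers = select_markers(table, labels, alpha=self.alpha,
                                      clr=self.clr)
        hr, nr = {}, {}
        for sample_id, row in table.values.iterrows():
            _, hr[sample_id], _, nr[sample_id] = \
                marker_summaries(row, self.markers)
        self.Hp = population_constants(hr, self.top_fraction, self.epsilon)
        self.Np = population_constants(nr, self.top_fraction, self.epsilon)
        return self

    def score(self, table: FeatureTable) -> list[GmhiResult]:
        if self.markers is None:
            raise RuntimeError("model not fitted")
        out = []
        for sample_id, row in table.values.iterrows():
            hs, hr, ns, nr = marker_summaries(row, self.markers)
            out.append(gmhi_score(sample_id, hs, hr, ns, nr,
                                  self.Hp, self.Np, self.epsilon))
        return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    auroc: float
    overall_p: float
    per_cohort_p: dict[str, float]
    per_cohort_pass: dict[str, bool]


def evaluate_index(scores: Mapping[str, float], labels: Mapping[str, str],
                   cohorts: Mapping[str, str] | None = None,
                   alpha: float = 0.05) -> EvaluationReport:
    """AUROC (healthy = positive class) and Wilcoxon group comparisons.

    AUROC uses the rank (Mann-Whitney) estimator with tie correction;
    single-class cohorts are skipped.
    """
    sample_ids = sorted(scores)
    y = np.array([1 if labels[s] == "healthy" else 0 for s in sample_ids])
    x = np.array([scores[s] for s in sample_ids])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    auroc = float(roc_auc_score(y, x))
    overall_p = wilcoxon_rank_sum(x[y == 1], x[y == 0])
    per_p, per_pass = {}, {}
    if cohorts is not None:
        for cohort in sorted(set(cohorts.values())):
            ids = [s for s in sample_ids if cohorts[s] == cohort]
            yc = y[[sample_ids.index(s) for s in ids]]
            xc = x[[sample_ids.index(s) for s in ids]]
            if len(np.unique(yc)) < 2:
                continue                # single-class cohort: skipped
            p = wilcoxon_rank_sum(xc[yc == 1], xc[yc == 0])
            per_p[cohort] = p
            per_pass[cohort] = p < alpha
    return EvaluationReport(auroc=auroc, overall_p=overall_p,
                            per_cohort_p=per_p, per_cohort_pass=per_pass)


# ---------------------------------------------------------------------------
# SCFA-gene SNV feature table
# ---------------------------------------------------------------------------

def scfa_snv_feature_table(
        snvs_by_sample: Mapping[str, Sequence[SnvRecord]],
        annotations: Sequence[GeneAnnotation],
        breadth_by_sample_genome: Mapping[tuple[str, str], float],
        prevalence_threshold: float = 0.0) -> FeatureTable:
    """Per-(sample, genome) relative SNV frequency in SCFA genes.

    Value = (SNVs inside the genome's SCFA-family genes) /
    (total SCFA-gene length x breadth_minCov).  Genomes with no SCFA
    genes contribute no feature; missing breadth means the genome was not
    detected in the sample, scored 0.
    """
    scfa_genes: dict[str, list[GeneAnnotation]] = {}
    scfa_len: dict[str, int] = {}
    for ann in annotations:
        if ann.scfa_family == "none":
            continue
        scfa_genes.setdefault(ann.genome_id, []).append(ann)
        scfa_len[ann.genome_id] = scfa_len.get(ann.genome_id, 0) + ann.length
    genome_ids = sorted(scfa_len)
    sample_ids = sorted(snvs_by_sample)
    data = np.zeros((len(sample_ids), len(genome_ids)))
    for i, s in enumerate(sample_ids):
        counts: dict[str, int] = {}
        for snv in snvs_by_sample[s]:
            for gene in scfa_genes.get(snv.genome_id, ()):
                if gene.scaffold_id == snv.scaffold_id and gene.contains(snv.position):
                    counts[snv.genome_id] = counts.get(snv.genome_id, 0) + 1
                    break
        for j, g in enumerate(genome_ids):
            n = counts.get(g, 0)
            if n == 0:
                continue
            breadth = breadth_by_sample_genome.get((s, g))
            if not breadth:
                continue
            data[i, j] = n / (scfa_len[g] * breadth)
    df = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"),
                      columns=genome_ids)
    if prevalence_threshold > 0 and len(df):
        prev = (df > 0).sum(axis=0) / len(df)
        df = df.loc[:, prev >= prevalence_threshold]
    return FeatureTable(values=df, kind="scfa_snv_freq")
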
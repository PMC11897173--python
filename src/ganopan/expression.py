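"""Expression normalization, differential-expression calling and the
SV-DEG association test.

The DE test is deliberately simple and fully specified: counts are
normalized to counts-per-million (CPM), log2-transformed with a 0.5
pseudo-count, and compared between two sample groups with Welch's t-test;
p-values are corrected with Benjamini-Hochberg step-up FDR across all
tested genes.  A gene is called differentially expressed when
|log2 fold change| > 1 and FDR < 0.05.  This is not a negative-binomial
GLM; see the methods note for the trade-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OrthogroupTable

__all__ = [
    "ExpressionStudy",
    "AssociationResult",
    "call_de",
    "category_expression_profile",
    "expression_breadth",
    "single_copy_homologs",
    "homolog_counts",
    "sv_deg_association",
    "sporulation_ratio",
]

logger = logging.getLogger("ganopan")

LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05


@dataclass
class ExpressionStudy:
    """Raw counts plus sample metadata, with lazy normalization."""

    counts: pd.DataFrame          # gene x sample, non-negative integers
    sheet: pd.DataFrame           # indexed by sample_id

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.sheet.index]
        if missing:
            raise ValueError(f"samples missing from sheet: {missing}")

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million; zero-total samples are dropped with a warning."""
        totals = self.counts.sum(axis=0)
        dead = totals.index[totals == 0].tolist()
        if dead:
            logger.warning("excluding zero-total samples from CPM: %s", dead)
        keep = totals.index[totals > 0]
        return self.counts[keep] * 1e6 / totals[keep]

    def tpm(self, lengths: Mapping[str, float]) -> pd.DataFrame:
        """Transcripts-per-million given per-gene lengths in bp."""
        lens = pd.Series({g: lengths[g] for g in self.counts.index}, dtype=float)
        rate = self.counts.div(lens, axis=0)
        totals = rate.sum(axis=0)
        keep = totals.index[totals > 0]
        return rate[keep] * 1e6 / totals[keep]

    def samples_for(self, genome: str | None = None,
                    tissue: str | None = None) -> list[str]:
        sel = self.sheet
        if genome is not None:
            sel = sel[sel["genome_id"] == genome]
        if tissue is not None:
            sel = sel[sel["tissue"] == tissue]
        return [s for s in sel["sample_id"] if s in self.counts.columns]


def _welch(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test on rows; identical rows give p = 1."""
    na, nb = log_a.shape[1], log_b.shape[1]
    ma, mb = log_a.mean(axis=1), log_b.mean(axis=1)
    va, vb = log_a.var(axis=1, ddof=1), log_b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance in both groups: p=1 when means agree, p=0 otherwise
    degenerate = se2 == 0
    p[degenerate] = np.where(ma[degenerate] == mb[degenerate], 1.0, 0.0)
    return p


def call_de(study: ExpressionStudy, group_a: Sequence[str], group_b: Sequence[str],
            pseudo_count: float = 0.5,
            lfc_threshold: float = LFC_THRESHOLD,
            fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Differential expression of group A versus group B.

    Returns a frame indexed by gene with columns log2_fold_change, p_value,
    fdr and is_deg.  Swapping the groups negates every fold change and
    leaves p-values unchanged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    cpm = study.cpm()
    missing = [s for s in group_a + group_b if s not in cpm.columns]
    if missing:
        raise ValueError(f"samples without usable counts: {missing}")
    a = cpm[group_a].to_numpy()
    b = cpm[group_b].to_numpy()
    lfc = np.log2((a.mean(axis=1) + pseudo_count) / (b.mean(axis=1) + pseudo_count))
    p = _welch(np.log2(a + pseudo_count), np.log2(b + pseudo_count))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2_fold_change": lfc,
        "p_value": p,
        "fdr": fdr,
        "is_deg": (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold),
    }, index=cpm.index)


def category_expression_profile(study: ExpressionStudy,
                                gene_category: Mapping[str, str],
                                tissue: str) -> tuple[pd.DataFrame, float, float]:
    """Per-category expression distributions within one tissue.

    Uses the per-gene mean CPM across the tissue's samples.  Returns the
    quartile summary per category plus the omnibus Kruskal-Wallis statistic
    and p-value across the (non-empty) categories.
    """
    samples = study.samples_for(tissue=tissue)
    if not samples:
        raise ValueError(f"no samples for tissue {tissue!r}")
    mean_cpm = study.cpm()[samples].mean(axis=1)
    mapped = mean_cpm.index.intersection(gene_category.keys())
    n_unmapped = len(mean_cpm) - len(mapped)
    if n_unmapped:
        logger.warning("%d genes without a pan-genome category excluded", n_unmapped)
    cats = pd.Series({g: gene_category[g] for g in mapped})
    groups, rows = [], []
    for cat in ("core", "softcore", "dispensable", "private"):
        vals = mean_cpm[cats.index[cats == cat]].to_numpy()
        if len(vals) == 0:
            logger.warning("category %s has no genes; omitted from test", cat)
            continue
        groups.append(vals)
        rows.append({"category": cat, "n_genes": len(vals),
                     "q1": float(np.quantile(vals, 0.25)),
                     "median": float(np.median(vals)),
                     "q3": float(np.quantile(vals, 0.75))})
    if len(groups) < 2:
        return pd.DataFrame(rows), 0.0, 1.0
    try:
        with np.errstate(invalid="ignore"):
            stat, p = stats.kruskal(*groups)
    except ValueError:
        stat, p = 0.0, 1.0
    if np.isnan(stat):  # all values identical across every group
        stat, p = 0.0, 1.0
    return pd.DataFrame(rows), float(stat), float(p)


def single_copy_homologs(tables: Iterable[OrthogroupTable],
                         genomes: Sequence[str]) -> dict[str, dict[str, str]]:
    """Families with exactly one member in every listed genome.

    Returns family_id -> {genome -> gene_id}; the pool of homolog groups
    used for cross-genome expression comparisons.
    """
    out: dict[str, dict[str, str]] = {}
    for t in tables:
        members = {g: t.members.get(g, []) for g in genomes}
        if all(len(v) == 1 for v in members.values()):
            out[t.family_id] = {g: v[0] for g, v in members.items()}
    return out


def homolog_counts(counts: pd.DataFrame,
                   homologs: Mapping[str, Mapping[str, str]],
                   sheet: pd.DataFrame) -> pd.DataFrame:
    """Collapse the gene x sample matrix to homolog-group x sample.

    Each sample column takes the counts of the group's member gene in that
    sample's genome, making expression comparable across genomes.
    """
    genome_of = dict(zip(sheet["sample_id"], sheet["genome_id"]))
    data = np.zeros((len(homologs), counts.shape[1]), dtype=int)
    groups = list(homologs)
    row_of_gene = {g: i for i, g in enumerate(counts.index)}
    for i, fam in enumerate(groups):
        for j, sample in enumerate(counts.columns):
            gene = homologs[fam].get(genome_of[sample])
            if gene is not None and gene in row_of_gene:
                data[i, j] = counts.iat[row_of_gene[gene], j]
    return pd.DataFrame(data, index=groups, columns=counts.columns)


def expression_breadth(study: ExpressionStudy,
                       homologs: Mapping[str, Mapping[str, str]],
                       tissue: str, threshold: float = 1.0) -> pd.Series:
    """Number of genomes (0..len) in which each homolog group is expressed.

    A group counts as expressed in a genome when its member gene's mean CPM
    across that genome's replicates of ``tissue`` is >= ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (CPM units)")
    cpm = study.cpm()
    genomes = sorted({g for fam in homologs.values() for g in fam})
    mean_by_genome = {}
    for genome in genomes:
        samples = study.samples_for(genome=genome, tissue=tissue)
        mean_by_genome[genome] = cpm[samples].mean(axis=1) if samples else None
    breadth = {}
    for fam, members in homologs.items():
        n = 0
        for genome, gene in members.items():
            m = mean_by_genome.get(genome)
            if m is not None and gene in m.index and m[gene] >= threshold:
                n += 1
        breadth[fam] = n
    return pd.Series(breadth, name="breadth")


@dataclass
class AssociationResult:
    """2x2 association between SV-affected status and DEG status."""

    table: np.ndarray             # [[sv&deg, sv&not], [nosv&deg, nosv&not]]
    statistic: float
    p_value: float
    method: str                   # "chi2" or "fisher"

    @property
    def n(self) -> int:
        return int(self.table.sum())

    @property
    def deg_proportion_sv(self) -> float:
        row = self.table[0]
        return float(row[0] / row.sum()) if row.sum() else float("nan")

    @property
    def deg_proportion_no_sv(self) -> float:
        row = self.table[1]
        return float(row[0] / row.sum()) if row.sum() else float("nan")


def sv_deg_association(deg_flags: Mapping[str, bool],
                       sv_flags: Mapping[str, bool]) -> AssociationResult:
    """Test whether SV-affected homolog groups are enriched for DEGs.

    Pearson chi-square with continuity correction on the 2x2 table; when a
    margin is zero, Fisher's exact test is substituted (noted in
    ``method``).
    """
    if set(deg_flags) != set(sv_flags):
        raise ValueError("deg_flags and sv_flags must cover the same groups")
    table = np.zeros((2, 2), dtype=int)
    for key, deg in deg_flags.items():
        sv = sv_flags[key]
        table[0 if sv else 1, 0 if deg else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(table, float(stat), float(p), "fisher")
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return AssociationResult(table, float(stat), float(p), "chi2")


def sporulation_ratio(spore_yield_g: float, fruiting_dry_weight_g: float) -> float:
    """Sporulation ratio (%) = 100 x spore yield / fruiting-body dry weight."""
    if not (spore_yield_g > 0 and fruiting_dry_weight_g > 0):
        raise ValueError("both weights must be positive (some strains yield "
                         "too little spore powder to collect)")
    return 100.0 * spore_yield_g / fruiting_dry_weight_g
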
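"""Set-based gene test: greedy LD-pruned SNP selection + label permutation.

For each gene interval the member SNPs are reduced to at most ``max_snps``
nominally significant, mutually near-independent representatives (greedy by
ascending p, pruning at pairwise dosage r-squared above a threshold, defaults
r2 = 0.5, p = 0.05, max 5 SNPs).  The gene score is the mean trend chi-square
of the selected SNPs (0 when none qualify) and its significance is the
empirical p-value over global case/control label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from segmeta.association import _prepare_genotypes, trend_statistics
from segmeta.genotype_io import Cohort


@dataclass(frozen=True)
class GeneSet:
    """Gene interval [start_bp, end_bp) with member SNP indices into a cohort map."""

    name: str
    chrom: int
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"{self.name}: start_bp must be < end_bp")


@dataclass
class SetTestResult:
    gene: GeneSet
    selected_snps: tuple[int, ...]
    set_statistic: float
    empirical_p: float
    n_permutations: int


def read_gene_intervals(path, cohort: Cohort) -> list[GeneSet]:
    """Read a 4-column TSV (name, chrom, start, end; 1-based inclusive start).

    Intervals are converted to half-open [start, end) internally and member
    SNPs resolved against the cohort map.
    """
    chroms, positions = cohort.chromosomes, cohort.positions
    genes: list[GeneSet] = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            name, chrom_s, start_s, end_s = ln.split()[:4]
            chrom, start, end = int(chrom_s), int(start_s), int(end_s)
            end = end + 1  # inclusive end -> half-open
            members = np.flatnonzero(
                (chroms == chrom) & (positions >= start) & (positions < end))
            genes.append(GeneSet(name=name, chrom=chrom, start_bp=start, end_bp=end,
                                 snp_indices=tuple(int(i) for i in members)))
    return genes


def _dosage_r2(G: np.ndarray, M: np.ndarray, a: int, b: int) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing individuals."""
    both = (M[:, a] > 0) & (M[:, b] > 0)
    if both.sum() < 2:
        return 0.0
    ga, gb = G[both, a], G[both, b]
    va, vb = ga.var(), gb.var()
    if va == 0 or vb == 0:
        return 0.0
    c = np.cov(ga, gb, bias=True)[0, 1]
    return float(c * c / (va * vb))


def select_independent(snp_pvalues: np.ndarray, snp_indices, genotypes_GM,
                       positions: np.ndarray,
                       r2_threshold: float = 0.5, p_threshold: float = 0.05,
                       max_snps: int = 5) -> list[int]:
    """Greedy selection of independent nominally significant member SNPs.

    Repeatedly takes the remaining member SNP with smallest p (< p_threshold;
    ties broken by lower genomic position), then prunes remaining members with
    dosage correlation-squared above ``r2_threshold`` against it; stops at
    ``max_snps`` or when no candidate qualifies.
    """
    G, M = genotypes_GM
    remaining = sorted(snp_indices, key=lambda i: (snp_pvalues[i], positions[i]))
    selected: list[int] = []
    while remaining and len(selected) < max_snps:
        best = remaining[0]
        if snp_pvalues[best] >= p_threshold:
            break
        selected.append(best)
        remaining = [i for i in remaining[1:]
                     if _dosage_r2(G, M, best, i) <= r2_threshold]
    return selected


def set_based_test(cohort: Cohort, gene_sets: list[GeneSet],
                   n_permutations: int = 1000, seed: int | None = None,
                   r2_threshold: float = 0.5, p_threshold: float = 0.05,
                   max_snps: int = 5,
                   phenotype_override: np.ndarray | None = None) -> list[SetTestResult]:
    """Permutation set-based test for a list of gene intervals.

    The observed score is the mean trend chi-square of the greedily selected
    SNPs (0 if none selected); each replicate shuffles the phenotype globally,
    repeats selection and scoring, and
    ``empirical_p = (1 + #{replicate score >= observed}) / (n_permutations + 1)``.
    Genes with no observed selection report empirical_p = 1.
    """
    if seed is None:
        raise ValueError("seed is required: permutation tests must be reproducible")
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    from scipy import stats as _st

    y = (cohort.phenotype.astype(np.float64) if phenotype_override is None
         else np.asarray(phenotype_override, dtype=np.float64))
    G, M = _prepare_genotypes(cohort)
    positions = cohort.positions

    def score_all(yv: np.ndarray):
        stat, _, mono = trend_statistics(G, M, yv)
        pval = np.where(mono, 1.0, _st.chi2.sf(stat, df=1))
        scores, selections = [], []
        for gene in gene_sets:
            sel = select_independent(pval, gene.snp_indices, (G, M), positions,
                                     r2_threshold, p_threshold, max_snps)
            selections.append(sel)
            scores.append(float(np.mean(stat[sel])) if sel else 0.0)
        return np.array(scores), selections

    observed, obs_sel = score_all(y)
    exceed = np.zeros(len(gene_sets), dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        null_scores, _ = score_all(y[perm])
        exceed += null_scores >= observed
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    return [SetTestResult(gene=g, selected_snps=tuple(obs_sel[i]),
                          set_statistic=float(observed[i]),
                          empirical_p=float(pvals[i]),
                          n_permutations=n_permutations)
            for i, g in enumerate(gene_sets)]


def geneset_table(results: list[SetTestResult]):
    """Set-test results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "gene": [r.gene.name for r in results],
        "chrom": [r.gene.chrom for r in results],
        "start": [r.gene.start_bp for r in results],
        "end": [r.gene.end_bp - 1 for r in results],  # back to inclusive
        "n_selected": [len(r.selected_snps) for r in results],
        "set_statistic": [r.set_statistic for r in results],
        "empirical_p": [r.empirical_p for r in results],
    })
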
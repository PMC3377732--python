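"""Per-SNP association and stratification adjustment.

The association statistic is the correlation form of the Armitage trend
test: ``N * r**2`` with ``r`` the Pearson correlation between allele dosage
and phenotype over individuals with a non-missing dosage, referred to the
upper tail of chi-square with one degree of freedom.  On an unadjusted 0/1
phenotype this equals the classical Cochran-Armitage trend chi-square with
scores (0, 1, 2); the same statistic applies unchanged to quantitative
residual phenotypes produced by :func:`eigenstrat_adjust`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from segmeta.genotype_io import MISSING, Cohort


@dataclass
class SnpAssoc:
    """Per-SNP trend statistics aligned to the cohort SNP map.

    ``monomorphic`` flags SNPs with zero dosage variance among tested
    individuals; those carry statistic 0 and p 1 by convention.
    """

    statistic: np.ndarray
    pvalue: np.ndarray
    n_used: np.ndarray
    monomorphic: np.ndarray

    def __len__(self) -> int:
        return len(self.statistic)


@dataclass
class AdjustedPhenotype:
    """Residual phenotype after regression on genotype principal components."""

    values: np.ndarray
    n_components: int


def _prepare_genotypes(cohort: Cohort):
    """Split the dosage matrix into values + missingness mask and cache sums."""
    G = cohort.genotypes.astype(np.float64)
    mask = cohort.genotypes != MISSING
    G[~mask] = 0.0
    return G, mask.astype(np.float64)


def trend_statistics(G: np.ndarray, M: np.ndarray, y: np.ndarray):
    """Vectorized ``N * r**2`` per column of ``G`` with missingness mask ``M``.

    Returns ``(statistic, n_used, monomorphic)``.  Pairwise deletion: for each
    SNP only individuals with a non-missing dosage enter the correlation.
    """
    y = np.asarray(y, dtype=np.float64)
    n = M.sum(axis=0)
    sg = G.sum(axis=0)
    sgg = (G * G).sum(axis=0)
    sy = y @ M
    syy = (y * y) @ M
    sgy = y @ G
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sgy - sg * sy
        var_g = n * sgg - sg * sg
        var_y = n * syy - sy * sy
        r2 = (cov * cov) / (var_g * var_y)
    mono = (var_g <= 0) | (var_y <= 0) | (n < 2)
    stat = np.where(mono, 0.0, n * r2)
    # guard fp noise: r^2 can exceed 1 by rounding at perfect correlation
    stat = np.minimum(stat, n)
    return stat, n.astype(np.int64), mono


def trend_test(cohort: Cohort, phenotype_override: np.ndarray | None = None) -> SnpAssoc:
    """Armitage trend test (``N * r**2`` form) for every SNP of a cohort.

    Parameters
    ----------
    cohort
        Cohort to test.
    phenotype_override
        Optional real-valued phenotype replacing the cohort's 0/1 vector
        (e.g. stratification-adjusted residuals, or a permuted copy).
    """
    y = cohort.phenotype if phenotype_override is None else np.asarray(phenotype_override, float)
    if len(y) != cohort.n_individuals:
        raise ValueError(f"phenotype length {len(y)} != individuals {cohort.n_individuals}")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; no association test possible")
    G, M = _prepare_genotypes(cohort)
    stat, n_used, mono = trend_statistics(G, M, y)
    pval = np.where(mono, 1.0, stats.chi2.sf(stat, df=1))
    return SnpAssoc(statistic=stat, pvalue=pval, n_used=n_used, monomorphic=mono)


def eigenstrat_adjust(cohort: Cohort, n_components: int = 10) -> AdjustedPhenotype:
    """Residualize case/control status on genotype principal components.

    The genotype matrix is standardized per SNP (centered, scaled by
    ``sqrt(p*(1-p))`` with ``p`` the sample allele frequency; missing entries
    set to 0 after centering), the top ``n_components`` left singular vectors
    over individuals are extracted, the 0/1 phenotype is fitted by logistic
    regression on those components, and the response residuals
    (observed - fitted probability) are returned.
    """
    if n_components < 0 or n_components >= cohort.n_individuals:
        raise ValueError(f"n_components must be in [0, n_individuals); got {n_components}")
    y = cohort.phenotype.astype(np.float64)
    if n_components == 0:
        return AdjustedPhenotype(values=y - y.mean(), n_components=0)

    G, M = _prepare_genotypes(cohort)
    n = M.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = G.sum(axis=0) / n
        p_hat = mean / 2.0
        scale = np.sqrt(p_hat * (1.0 - p_hat))
    poly = (scale > 0) & np.isfinite(scale)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs for component estimation")
    X = (G[:, poly] - mean[poly]) * M[:, poly] / scale[poly]

    # top left singular vectors over individuals
    k = min(n_components, min(X.shape) - 1)
    if k < n_components:
        raise ValueError(f"cannot extract {n_components} components from a "
                         f"{X.shape[0]}x{X.shape[1]} matrix")
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    comps = U[:, :n_components]

    fitted = _logistic_fit(comps, y)
    return AdjustedPhenotype(values=y - fitted, n_components=n_components)


def _logistic_fit(X: np.ndarray, y: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """IRLS logistic regression of y on [1, X]; returns fitted probabilities.

    Non-convergence (including quasi-separation driving weights to zero) is
    an error identifying the dominant component, never a silent fallback.
    """
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        if np.max(np.abs(beta[1:]), initial=0.0) > 1e3 or W.max() < 1e-10:
            break  # diverging -> report below
        XtWX = Z.T @ (Z * W[:, None])
        grad = Z.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return 1.0 / (1.0 + np.exp(-(Z @ beta)))
    worst = int(np.argmax(np.abs(beta[1:]))) + 1 if Z.shape[1] > 1 else 0
    raise RuntimeError(
        f"logistic regression did not converge (possible separation on component {worst})")


def association_table(cohort: Cohort, assoc: SnpAssoc):
    """Per-SNP association results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "snp": [s.id for s in cohort.snps],
        "chrom": [s.chrom for s in cohort.snps],
        "pos": [s.pos_bp for s in cohort.snps],
        "n_used": assoc.n_used,
        "statistic": assoc.statistic,
        "p": assoc.pvalue,
    })


def manhattan_table(cohort: Cohort, assoc: SnpAssoc):
    """Per-SNP (chrom, pos, -log10 p) export for Manhattan plotting."""
    import pandas as pd

    with np.errstate(divide="ignore"):
        neglog = -np.log10(assoc.pvalue)
    return pd.DataFrame({
        "chrom": [s.chrom for s in cohort.snps],
        "pos": [s.pos_bp for s in cohort.snps],
        "neglog10_p": neglog,
    })
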
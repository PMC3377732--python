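"""Overlapping-segment enrichment scan with a label-permutation null.

Each autosome is tiled by fixed-width segments anchored at position 0 and
starting at every multiple of half the width (50% overlap).  A segment's
score is the number of member SNPs with a nominally significant trend-test
p-value; its "metasignificance" is the one-sided permutation p-value of that
count under global case/control label shuffling, which preserves LD among
SNPs and correlation between overlapping segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from segmeta.association import _prepare_genotypes, trend_statistics
from segmeta.genotype_io import Cohort


@dataclass(frozen=True)
class Segment:
    """Half-open genomic interval [start_bp, end_bp) on one chromosome.

    ``snp_lo``/``snp_hi`` delimit the member SNPs as a contiguous slice of
    the cohort's sorted SNP map; ``testable`` is False for empty segments.
    """

    chrom: int
    start_bp: int
    end_bp: int
    snp_lo: int = 0
    snp_hi: int = 0

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return self.snp_hi - self.snp_lo

    @property
    def testable(self) -> bool:
        return self.n_snps > 0

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.snp_lo, self.snp_hi)

    def key(self) -> tuple[int, int, int]:
        return (self.chrom, self.start_bp, self.end_bp)


@dataclass
class SegmentResult:
    """Observed vs permutation-expected nominal-SNP count for one segment."""

    segment: Segment
    observed_count: int
    expected_count: float
    metasignificance_p: float
    n_permutations: int
    nominal_alpha: float


def make_segments(cohort_or_map, width_bp: int) -> list[Segment]:
    """Tile each chromosome with ``width_bp`` segments overlapping by 50%.

    Segments start at 0, width/2, width, ... per chromosome; tiling stops
    with the first segment whose interval covers the chromosome's largest
    SNP position.  Empty segments are retained (``testable`` False).
    """
    if width_bp <= 0 or width_bp % 2 != 0:
        raise ValueError(f"width_bp must be positive and even, got {width_bp}")
    chroms, positions = _chrom_pos(cohort_or_map)
    if len(positions) == 0:
        raise ValueError("SNP map is empty")
    step = width_bp // 2
    segments: list[Segment] = []
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        max_pos = int(pos[-1])
        start = 0
        while start <= max_pos:
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, start + width_bp, side="left"))
            segments.append(Segment(chrom=int(chrom), start_bp=start,
                                    end_bp=start + width_bp,
                                    snp_lo=int(idx[0]) + lo, snp_hi=int(idx[0]) + hi))
            start += step
    return segments


def _chrom_pos(cohort_or_map):
    if isinstance(cohort_or_map, Cohort):
        return cohort_or_map.chromosomes, cohort_or_map.positions
    snps = list(cohort_or_map)
    return (np.array([s.chrom for s in snps], dtype=np.int64),
            np.array([s.pos_bp for s in snps], dtype=np.int64))


def count_nominal(snp_pvalues: np.ndarray, segments: list[Segment],
                  nominal_alpha: float = 0.05) -> np.ndarray:
    """Per segment, the number of member SNPs with p strictly below alpha."""
    if not 0 < nominal_alpha < 1:
        raise ValueError(f"nominal_alpha must be in (0,1), got {nominal_alpha}")
    sig = np.asarray(snp_pvalues) < nominal_alpha
    cum = np.concatenate([[0], np.cumsum(sig)])
    return np.array([cum[s.snp_hi] - cum[s.snp_lo] for s in segments], dtype=np.int64)


def _permutation(seed: int, replicate: int, n: int) -> np.ndarray:
    """Replicate-indexed phenotype shuffle, independent of segment layout."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, replicate]))
    return rng.permutation(n)


def permutation_scan(cohort: Cohort, segments: list[Segment],
                     nominal_alpha: float = 0.05, n_permutations: int = 1000,
                     seed: int | None = None,
                     phenotype_override: np.ndarray | None = None) -> list[SegmentResult]:
    """Assign each segment a permutation metasignificance p-value.

    Observed counts come from trend tests on the true (or overridden)
    phenotype.  Each of ``n_permutations`` replicates applies one global
    shuffle of the phenotype vector, recomputes every SNP test, and recounts
    all segments, so LD and segment overlap are preserved under the null.
    ``metasignificance_p = (1 + #{null count >= observed}) / (n_permutations + 1)``
    (one-sided: only enrichment counts), and ``expected_count`` is the mean
    null count.
    """
    if seed is None:
        raise ValueError("seed is required: permutation scans must be reproducible")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = (cohort.phenotype.astype(np.float64) if phenotype_override is None
         else np.asarray(phenotype_override, dtype=np.float64))
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; no permutation test possible")

    G, M = _prepare_genotypes(cohort)
    crit = stats.chi2.isf(nominal_alpha, df=1)

    def counts_for(yv: np.ndarray) -> np.ndarray:
        stat, _, mono = trend_statistics(G, M, yv)
        sig = (stat > crit) & ~mono
        cum = np.concatenate([[0], np.cumsum(sig)])
        return np.array([cum[s.snp_hi] - cum[s.snp_lo] for s in segments], dtype=np.int64)

    observed = counts_for(y)
    exceed = np.zeros(len(segments), dtype=np.int64)
    total = np.zeros(len(segments), dtype=np.float64)
    for r in range(n_permutations):
        perm = _permutation(seed, r, len(y))
        null_counts = counts_for(y[perm])
        exceed += null_counts >= observed
        total += null_counts
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    expected = total / n_permutations
    return [SegmentResult(segment=s, observed_count=int(observed[i]),
                          expected_count=float(expected[i]),
                          metasignificance_p=float(pvals[i]),
                          n_permutations=n_permutations,
                          nominal_alpha=nominal_alpha)
            for i, s in enumerate(segments)]


def targeted_region_test(cohort: Cohort, chrom: int, start_bp: int, end_bp: int,
                         nominal_alpha: float = 0.05, n_permutations: int = 1000,
                         seed: int | None = None,
                         phenotype_override: np.ndarray | None = None) -> SegmentResult:
    """Metasignificance test of one ad-hoc interval (no lattice constraint).

    Uses the same replicate-indexed permutation stream as
    :func:`permutation_scan`, so a targeted interval that coincides with a
    lattice segment reproduces that segment's scan result under the same seed.
    """
    if end_bp <= start_bp:
        raise ValueError("interval must satisfy start_bp < end_bp")
    chroms, positions = cohort.chromosomes, cohort.positions
    idx = np.flatnonzero(chroms == chrom)
    if len(idx) == 0:
        raise ValueError(f"cohort has no SNPs on chromosome {chrom}")
    pos = positions[idx]
    lo = int(np.searchsorted(pos, start_bp, side="left"))
    hi = int(np.searchsorted(pos, end_bp, side="left"))
    seg = Segment(chrom=chrom, start_bp=start_bp, end_bp=end_bp,
                  snp_lo=int(idx[0]) + lo, snp_hi=int(idx[0]) + hi)
    if not seg.testable:
        raise ValueError(f"interval chr{chrom}:{start_bp}-{end_bp} contains no SNPs (untestable)")
    return permutation_scan(cohort, [seg], nominal_alpha=nominal_alpha,
                            n_permutations=n_permutations, seed=seed,
                            phenotype_override=phenotype_override)[0]


def results_table(cohort_id: str, results: list[SegmentResult]):
    """Segment results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "cohort_id": cohort_id,
        "chrom": [r.segment.chrom for r in results],
        "start": [r.segment.start_bp for r in results],
        "end": [r.segment.end_bp for r in results],
        "width": [r.segment.width_bp for r in results],
        "n_snps": [r.segment.n_snps for r in results],
        "observed": [r.observed_count for r in results],
        "expected": [r.expected_count for r in results],
        "p": [r.metasignificance_p for r in results],
    })
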
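"""Synthetic case/control cohorts with block LD and planted weak effects.

The generator draws genotypes from per-block haplotype pools (strong LD
within a block, essentially none between blocks), supports two-subpopulation
stratification via Balding-Nichols-style allele-frequency divergence plus a
subpopulation disease-risk offset, and can plant a genomic interval in which
a configurable fraction of SNPs are weak risk variants (per-SNP odds ratios
in the 1.05-1.1 band).  Disease status follows a logistic liability model
with the intercept solved for a configurable baseline prevalence; cases and
controls are collected by rejection sampling to exact target counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from segmeta.genotype_io import Cohort, SnpRecord, write_plink, write_text_cohort


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_cases: int = 728
    n_controls: int = 653
    chrom_lengths_bp: dict[int, int] = field(default_factory=lambda: {1: 40_000_000,
                                                                      2: 30_000_000})
    snp_spacing_bp: int = 20_000
    block_size_snps: int = 20
    haplotypes_per_block: int = 8
    planted_interval: tuple[int, int, int] | None = None  # (chrom, start_bp, end_bp)
    planted_fraction: float = 0.3
    planted_or: float = 1.08
    strat_fraction: float = 0.0
    strat_risk_offset: float = 0.0  # log-odds added for subpopulation 1
    baseline_prevalence: float = 0.01
    max_draws: int | None = None  # rejection-sampling budget; None = auto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.planted_or < 1.0:
            raise ValueError("planted_or must be >= 1")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.planted_interval is not None:
            chrom, start, end = self.planted_interval
            if chrom not in self.chrom_lengths_bp:
                raise ValueError(f"planted chromosome {chrom} not in chrom_lengths_bp")
            if not 0 <= start < end <= self.chrom_lengths_bp[chrom]:
                raise ValueError("planted_interval outside chromosome bounds")
        if self.snp_spacing_bp <= 0 or self.block_size_snps <= 0 or self.haplotypes_per_block < 2:
            raise ValueError("snp_spacing_bp/block_size_snps positive; >= 2 haplotypes per block")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0,1)")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated cohort."""

    causal_snp_ids: list[str]
    causal_indices: np.ndarray
    subpopulation: np.ndarray  # per retained individual, 0/1


def _build_map(config: SimConfig) -> list[SnpRecord]:
    snps = []
    for chrom in sorted(config.chrom_lengths_bp):
        length = config.chrom_lengths_bp[chrom]
        pos = config.snp_spacing_bp
        while pos <= length:
            snps.append(SnpRecord(f"rs{chrom}_{pos}", chrom, pos))
            pos += config.snp_spacing_bp
    return snps


def _block_slices(n_snps_per_chrom: list[int], block_size: int) -> list[slice]:
    """Blocks never span a chromosome boundary."""
    blocks, offset = [], 0
    for n in n_snps_per_chrom:
        for lo in range(0, n, block_size):
            blocks.append(slice(offset + lo, offset + min(lo + block_size, n)))
        offset += n
    return blocks


def simulate_cohort(config: SimConfig, cohort_id: str = "sim") -> tuple[Cohort, TruthRecord]:
    """Generate one cohort plus its ground-truth record.

    Returns ``(cohort, truth)``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    snps = _build_map(config)
    chroms = np.array([s.chrom for s in snps])
    positions = np.array([s.pos_bp for s in snps])
    n_snps = len(snps)
    per_chrom = [int((chroms == c).sum()) for c in sorted(config.chrom_lengths_bp)]
    blocks = _block_slices(per_chrom, config.block_size_snps)

    # haplotype pools: per block, H haplotypes drawn at per-SNP frequencies in
    # [0.05, 0.5]; a second, frequency-diverged pool for subpopulation 1
    H = config.haplotypes_per_block
    pools: list[np.ndarray] = []     # each (2, H, block_len): [subpop][hap][snp]
    for blk in blocks:
        m = blk.stop - blk.start
        freq = rng.uniform(0.05, 0.5, size=m)
        pool0 = (rng.random((H, m)) < freq).astype(np.int8)
        if config.strat_fraction > 0:
            f = config.strat_fraction
            # Balding-Nichols divergence around the ancestral frequency
            a, b = freq * (1 - f) / f, (1 - freq) * (1 - f) / f
            freq1 = np.clip(rng.beta(a, b), 0.01, 0.99)
            pool1 = (rng.random((H, m)) < freq1).astype(np.int8)
        else:
            pool1 = pool0
        pools.append(np.stack([pool0, pool1]))

    # causal SNPs within the planted interval
    causal = np.zeros(n_snps, dtype=bool)
    if config.planted_interval is not None and config.planted_or > 1.0:
        chrom, start, end = config.planted_interval
        members = np.flatnonzero((chroms == chrom) & (positions >= start) & (positions < end))
        n_causal = int(round(config.planted_fraction * len(members)))
        causal[rng.choice(members, size=n_causal, replace=False)] = True
    beta = np.log(config.planted_or)
    causal_blocks = [bi for bi, blk in enumerate(blocks) if causal[blk].any()]

    # intercept: solve logit(prevalence) = b0 + E[liability] at pool frequencies
    exp_dosage = 0.0
    for bi in causal_blocks:
        blk = blocks[bi]
        pool_freq = pools[bi].mean(axis=(0, 1))  # avg over subpops & haplotypes
        exp_dosage += float((2.0 * pool_freq * causal[blk]).sum())
    b0 = float(np.log(config.baseline_prevalence / (1 - config.baseline_prevalence))
               - beta * exp_dosage - 0.5 * config.strat_risk_offset)

    n_total = config.n_cases + config.n_controls
    kept_hap_idx: list[np.ndarray] = []   # per kept individual: (n_blocks, 2) pool rows
    kept_subpop: list[int] = []
    kept_status: list[int] = []
    n_case = n_ctrl = 0
    batch = max(4 * n_total, int(n_total / max(config.baseline_prevalence, 0.01)))
    budget = (config.max_draws if config.max_draws is not None
              else int(50 * n_total / min(config.baseline_prevalence,
                                          1 - config.baseline_prevalence)))
    draws = 0
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if draws >= budget:
            raise RuntimeError(
                "rejection sampling exhausted its draw budget before reaching the "
                "target case count; increase baseline_prevalence, planted_or, or max_draws")
        subpop = (rng.random(batch) < 0.5).astype(np.int8)
        hap_idx = rng.integers(0, H, size=(batch, len(blocks), 2), dtype=np.int16)
        # liability from causal blocks only
        liab = np.full(batch, b0)
        for bi in causal_blocks:
            blk = blocks[bi]
            w = (beta * causal[blk]).astype(np.float64)
            pool = pools[bi]  # (2, H, m)
            hap_scores = pool.astype(np.float64) @ w  # (2, H)
            liab += (hap_scores[subpop, hap_idx[:, bi, 0]]
                     + hap_scores[subpop, hap_idx[:, bi, 1]])
        liab += config.strat_risk_offset * subpop
        prob = 1.0 / (1.0 + np.exp(-liab))
        status = (rng.random(batch) < prob).astype(np.int8)
        draws += batch
        for i in range(batch):
            if status[i] == 1 and n_case < config.n_cases:
                n_case += 1
            elif status[i] == 0 and n_ctrl < config.n_controls:
                n_ctrl += 1
            else:
                continue
            kept_hap_idx.append(hap_idx[i])
            kept_subpop.append(int(subpop[i]))
            kept_status.append(int(status[i]))
            if n_case >= config.n_cases and n_ctrl >= config.n_controls:
                break

    # materialize genotypes for the retained individuals
    geno = np.empty((n_total, n_snps), dtype=np.int8)
    hap_arr = np.stack(kept_hap_idx)          # (n_total, n_blocks, 2)
    sub_arr = np.array(kept_subpop, dtype=np.int8)
    for bi, blk in enumerate(blocks):
        pool = pools[bi]
        geno[:, blk] = (pool[sub_arr, hap_arr[:, bi, 0]]
                        + pool[sub_arr, hap_arr[:, bi, 1]])

    cohort = Cohort(snps=snps, genotypes=geno,
                    phenotype=np.array(kept_status, dtype=np.int8),
                    cohort_id=cohort_id)
    truth = TruthRecord(
        causal_snp_ids=[snps[i].id for i in np.flatnonzero(causal)],
        causal_indices=np.flatnonzero(causal),
        subpopulation=sub_arr,
    )
    return cohort, truth


def write_fixture(cohort: Cohort, truth: TruthRecord, out_dir) -> dict[str, object]:
    """Emit PLINK trio + text fixture + truth TSV into ``out_dir``.

    Deterministic given the cohort (no randomness here).  Returns the paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed, bim, fam = write_plink(cohort, out_dir / cohort.cohort_id)
    text = write_text_cohort(cohort, out_dir / f"{cohort.cohort_id}.txt")
    truth_path = out_dir / f"{cohort.cohort_id}.truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("causal_snp\n")
        for sid in truth.causal_snp_ids:
            fh.write(f"{sid}\n")
    subpop_path = out_dir / f"{cohort.cohort_id}.subpop.tsv"
    with open(subpop_path, "w") as fh:
        fh.write("individual\tsubpopulation\n")
        for i, s in enumerate(truth.subpopulation):
            fh.write(f"I{i}\t{int(s)}\n")
    return {"bed": bed, "bim": bim, "fam": fam, "text": text,
            "truth": truth_path, "subpop": subpop_path}
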
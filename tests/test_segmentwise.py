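import numpy as np
import pytest

from segmeta.genotype_io import Cohort, SnpRecord
from segmeta.segmentwise import (
    Segment,
    count_nominal,
    make_segments,
    permutation_scan,
    targeted_region_test,
)
from segmeta.synthdata import SimConfig, simulate_cohort

from conftest import random_cohort

MBP = 1_000_000


def map_with_max(chrom_max: dict[int, int], spacing=500_000):
    snps = []
    for chrom, mx in sorted(chrom_max.items()):
        pos = spacing
        while pos <= mx:
            snps.append(SnpRecord(f"c{chrom}p{pos}", chrom, pos))
            pos += spacing
    return snps


class TestMakeSegments:
    def test_tiling_arithmetic(self):
        # largest SNP at 9.5 Mbp, width 4 -> starts 0, 2, 4, 6, 8
        snps = map_with_max({1: int(9.5 * MBP)})
        segs = make_segments(snps, 4 * MBP)
        assert [s.start_bp for s in segs] == [0, 2 * MBP, 4 * MBP, 6 * MBP, 8 * MBP]
        assert all(s.end_bp - s.start_bp == 4 * MBP for s in segs)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_segments(map_with_max({1: MBP}), 3)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_segments([], 2 * MBP)

    def test_member_indices_exact(self, rng):
        c = random_cohort(rng, n_individuals=4, n_snps=80)
        segs = make_segments(c, 2 * MBP)
        chroms, positions = c.chromosomes, c.positions
        for s in segs:
            want = set(np.flatnonzero((chroms == s.chrom)
                                      & (positions >= s.start_bp)
                                      & (positions < s.end_bp)))
            assert set(s.snp_indices) == want

    def test_lattice_anchoring(self, rng):
        c = random_cohort(rng, n_individuals=4, n_snps=40)
        for width in (2 * MBP, 4 * MBP):
            for s in make_segments(c, width):
                assert s.start_bp % (width // 2) == 0

    @pytest.mark.parametrize("width_mbp,start_mbp,end_mbp", [
        (4, 132, 136), (8, 128, 136), (16, 120, 136), (16, 128, 144), (32, 128, 160),
    ])
    def test_reference_regions_lie_on_lattice(self, width_mbp, start_mbp, end_mbp):
        """Known replicable regions of each width are lattice segments."""
        snps = map_with_max({5: 180 * MBP}, spacing=MBP)
        segs = make_segments(snps, width_mbp * MBP)
        keys = {(s.chrom, s.start_bp, s.end_bp) for s in segs}
        assert (5, start_mbp * MBP, end_mbp * MBP) in keys

    def test_genomewide_2mbp_segment_count_order(self):
        """hg18-like autosome lengths: 2 Mbp tiling is in the ~2.7-2.9k range."""
        hg18_mbp = [247, 243, 199, 191, 181, 171, 159, 146, 140, 135, 134, 132,
                    114, 106, 100, 89, 79, 76, 63, 62, 47, 50]
        snps = [SnpRecord(f"c{c}", c, int(l * MBP) - 1) for c, l in enumerate(hg18_mbp, 1)]
        # one terminal SNP per chromosome suffices to fix the tiling extent
        segs = make_segments(snps, 2 * MBP)
        assert 2500 <= len(segs) <= 3100

    def test_empty_segments_flagged_untestable(self):
        snps = [SnpRecord("a", 1, 100), SnpRecord("b", 1, 9 * MBP)]
        segs = make_segments(snps, 2 * MBP)
        assert any(not s.testable for s in segs)
        assert all(s.n_snps == 0 for s in segs if not s.testable)


class TestCountNominal:
    def test_literal_example(self):
        seg = Segment(chrom=1, start_bp=0, end_bp=8 * MBP, snp_lo=0, snp_hi=4)
        counts = count_nominal(np.array([0.01, 0.2, 0.04, 0.6]), [seg], 0.05)
        assert counts[0] == 2

    def test_empty_segment_zero(self):
        seg = Segment(chrom=1, start_bp=0, end_bp=2 * MBP, snp_lo=3, snp_hi=3)
        assert count_nominal(np.array([0.01] * 5), [seg])[0] == 0

    def test_strict_inequality(self):
        seg = Segment(chrom=1, start_bp=0, end_bp=2 * MBP, snp_lo=0, snp_hi=1)
        assert count_nominal(np.array([0.05]), [seg], 0.05)[0] == 0

    def test_alpha_domain(self):
        seg = Segment(chrom=1, start_bp=0, end_bp=2 * MBP, snp_lo=0, snp_hi=1)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                count_nominal(np.array([0.5]), [seg], bad)

    def test_brute_force_recount(self, rng):
        c = random_cohort(rng, n_individuals=4, n_snps=100)
        segs = make_segments(c, 2 * MBP)
        p = rng.random(100)
        counts = count_nominal(p, segs, 0.05)
        chroms, positions = c.chromosomes, c.positions
        for s, got in zip(segs, counts):
            members = (chroms == s.chrom) & (positions >= s.start_bp) & (positions < s.end_bp)
            assert got == int((p[members] < 0.05).sum())

    def test_disjoint_lattice_counts_sum_to_genomewide(self, rng):
        c = random_cohort(rng, n_individuals=4, n_snps=100)
        segs = make_segments(c, 2 * MBP)
        p = rng.random(100)
        even = [s for s in segs if s.start_bp % (2 * MBP) == 0]
        # drop even-lattice segments past each chromosome's own tiling end,
        # then totals must match the genome-wide count exactly
        total = count_nominal(p, even, 0.05).sum()
        assert total == (p < 0.05).sum()


@pytest.fixture(scope="module")
def scan_cohort():
    cfg = SimConfig(n_cases=80, n_controls=80, chrom_lengths_bp={1: 12 * MBP},
                    snp_spacing_bp=100_000, block_size_snps=5,
                    baseline_prevalence=0.2, seed=41)
    cohort, _ = simulate_cohort(cfg)
    return cohort


class TestPermutationScan:
    def test_seed_required(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        with pytest.raises(ValueError, match="seed"):
            permutation_scan(scan_cohort, segs, n_permutations=10)

    def test_p_floor_and_ceiling(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        res = permutation_scan(scan_cohort, segs, n_permutations=100, seed=5)
        for r in res:
            assert 1.0 / 101 <= r.metasignificance_p <= 1.0
            assert r.observed_count <= r.segment.n_snps

    def test_untestable_segment_p_one(self, scan_cohort):
        seg = Segment(chrom=1, start_bp=0, end_bp=2 * MBP, snp_lo=0, snp_hi=0)
        res = permutation_scan(scan_cohort, [seg], n_permutations=20, seed=1)
        assert res[0].observed_count == 0
        assert res[0].metasignificance_p == 1.0

    def test_identical_seed_identical_results(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        a = permutation_scan(scan_cohort, segs, n_permutations=50, seed=9)
        b = permutation_scan(scan_cohort, segs, n_permutations=50, seed=9)
        assert [(r.observed_count, r.expected_count, r.metasignificance_p) for r in a] \
            == [(r.observed_count, r.expected_count, r.metasignificance_p) for r in b]

    def test_different_seed_differs(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        a = permutation_scan(scan_cohort, segs, n_permutations=50, seed=9)
        b = permutation_scan(scan_cohort, segs, n_permutations=50, seed=10)
        assert any(x.metasignificance_p != y.metasignificance_p for x, y in zip(a, b))

    def test_null_type_one_error(self):
        """Fraction of testable segments with p < 0.05 is ~5% under the null."""
        cfg = SimConfig(n_cases=100, n_controls=100,
                        chrom_lengths_bp={1: 30 * MBP, 2: 30 * MBP},
                        snp_spacing_bp=60_000, block_size_snps=5,
                        baseline_prevalence=0.3, seed=77)
        cohort, _ = simulate_cohort(cfg)
        segs = [s for s in make_segments(cohort, 2 * MBP)]
        res = permutation_scan(cohort, segs, n_permutations=200, seed=3)
        testable = [r for r in res if r.segment.testable]
        frac = np.mean([r.metasignificance_p < 0.05 for r in testable])
        # overlapping segments are correlated; allow generous Monte-Carlo slack
        assert 0.0 <= frac <= 0.12

    def test_ld_widens_null_counts(self):
        """With block LD the permutation-null count variance exceeds binomial."""
        cfg = SimConfig(n_cases=120, n_controls=120, chrom_lengths_bp={1: 8 * MBP},
                        snp_spacing_bp=20_000, block_size_snps=20,
                        haplotypes_per_block=4, baseline_prevalence=0.3, seed=13)
        cohort, _ = simulate_cohort(cfg)
        seg = Segment(chrom=1, start_bp=0, end_bp=8 * MBP,
                      snp_lo=0, snp_hi=cohort.n_snps)
        from segmeta.association import _prepare_genotypes, trend_statistics
        from scipy import stats as st
        G, M = _prepare_genotypes(cohort)
        crit = st.chi2.isf(0.05, df=1)
        rng = np.random.default_rng(5)
        y = cohort.phenotype.astype(float)
        counts = []
        for _ in range(300):
            stat, _, mono = trend_statistics(G, M, y[rng.permutation(len(y))])
            counts.append(int(((stat > crit) & ~mono).sum()))
        m = cohort.n_snps
        assert np.var(counts) > m * 0.05 * 0.95

    def test_expected_count_is_null_mean(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        res = permutation_scan(scan_cohort, segs, n_permutations=50, seed=2)
        for r in res:
            assert 0.0 <= r.expected_count <= r.segment.n_snps


class TestTargetedRegion:
    def test_matches_lattice_segment_same_seed(self, scan_cohort):
        segs = make_segments(scan_cohort, 4 * MBP)
        scan = permutation_scan(scan_cohort, segs, n_permutations=100, seed=21)
        target = segs[1]
        solo = targeted_region_test(scan_cohort, target.chrom, target.start_bp,
                                    target.end_bp, n_permutations=100, seed=21)
        match = scan[1]
        assert solo.observed_count == match.observed_count
        assert solo.metasignificance_p == match.metasignificance_p
        assert solo.expected_count == match.expected_count

    def test_absent_chromosome_errors(self, scan_cohort):
        with pytest.raises(ValueError, match="chromosome 9"):
            targeted_region_test(scan_cohort, 9, 0, 2 * MBP, n_permutations=10, seed=1)

    def test_empty_interval_errors(self, scan_cohort):
        with pytest.raises(ValueError, match="no SNPs"):
            targeted_region_test(scan_cohort, 1, 10, 20, n_permutations=10, seed=1)

    def test_planted_interval_power(self):
        """A planted enriched 2 Mbp interval is detected with high power."""
        hits = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = SimConfig(n_cases=400, n_controls=400,
                            chrom_lengths_bp={1: 10 * MBP}, snp_spacing_bp=25_000,
                            block_size_snps=10, baseline_prevalence=0.1,
                            planted_interval=(1, 4 * MBP, 6 * MBP),
                            planted_fraction=0.3, planted_or=1.25, seed=100 + rep)
            cohort, _ = simulate_cohort(cfg)
            res = targeted_region_test(cohort, 1, 4 * MBP, 6 * MBP,
                                       n_permutations=200, seed=rep)
            hits += res.metasignificance_p < 0.05
        assert hits >= 5
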
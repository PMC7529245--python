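import math

import numpy as np
import pytest
from scipy import stats

from k9balance.genome import (
    ChromosomePartition,
    GeneRecord,
    GenomicInterval,
    TERecord,
)
from k9balance.simulate import SyntheticConfig, generate_annotation
from k9balance.teassoc import (
    TeAssocError,
    association_curve,
    nearest_distance_ttest,
    randomized_fisher_enrichment,
    resampled_anova,
    superfamily_size_proportions,
    te_bp_profile,
)

from conftest import make_tes


def gene(i, start, end, chrom="c"):
    return GeneRecord(id=f"g{i}", interval=GenomicInterval(chrom, start, end))


class TestResampledAnova:
    def test_null_average_p_near_half(self, rng):
        background = rng.normal(100, 20, size=2000)
        focal = rng.choice(background, size=165, replace=False)
        avg = resampled_anova(focal, background, n_resample=1000, seed=rng)
        assert 0.35 <= avg <= 0.65

    def test_shifted_focal_tiny_p(self, rng):
        background = rng.normal(100, 10, size=2000)
        focal = rng.normal(130, 10, size=165)  # 3 pooled SDs
        avg = resampled_anova(focal, background, n_resample=200, seed=1)
        assert avg < 1e-4

    def test_deterministic_under_seed(self, rng):
        background = rng.normal(0, 1, 500)
        focal = rng.normal(0.2, 1, 50)
        a = resampled_anova(focal, background, n_resample=100, seed=7)
        b = resampled_anova(focal, background, n_resample=100, seed=7)
        assert a == b

    def test_small_focal_error(self):
        with pytest.raises(TeAssocError):
            resampled_anova([1.0], [1.0, 2.0, 3.0], n_resample=10)

    def test_background_smaller_than_focal_error(self):
        with pytest.raises(TeAssocError):
            resampled_anova([1.0, 2.0, 3.0], [1.0, 2.0], n_resample=10)

    def test_anova_equals_pooled_ttest(self, rng):
        # the two-group one-way ANOVA p equals the equal-variance t-test p
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        p_f = stats.f_oneway(a, b).pvalue
        p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_monotone_in_effect_size(self, rng):
        background = rng.normal(100, 10, size=1000)
        avgs = []
        for shift in (0.0, 5.0, 10.0, 20.0):
            focal = rng.normal(100 + shift, 10, size=100)
            avgs.append(resampled_anova(focal, background, n_resample=200, seed=3))
        assert all(x >= y for x, y in zip(avgs, avgs[1:]))


class TestAssociationCurve:
    def test_no_tes_all_zero(self):
        focal = [gene(1, 100, 200), gene(2, 400, 500)]
        back = [gene(3, 700, 800), gene(4, 900, 1000)]
        curve = association_curve(focal, back, [], max_d=200, step=100, n_resample=10)
        assert (curve["mean_focal"] == 0).all()
        assert (curve["mean_background"] == 0).all()

    def test_monotone_in_distance(self, rng):
        cfg = SyntheticConfig(
            seed=5, n_genes=100, n_nlr=20, n_focal_nlr=5, n_te=300, chrom_length=500_000
        )
        ann, _ = generate_annotation(cfg)
        nlr = [g for g in ann.genes if g.is_nlr]
        rest = [g for g in ann.genes if not g.is_nlr]
        curve = association_curve(
            nlr, rest, ann.tes, chrom_lengths=ann.chrom_lengths, n_resample=5
        )
        assert (np.diff(curve["mean_focal"]) >= 0).all()
        assert (np.diff(curve["mean_background"]) >= 0).all()

    def test_overlapping_sets_rejected(self):
        g = gene(1, 0, 100)
        with pytest.raises(TeAssocError):
            association_curve([g], [g], [], n_resample=5)

    def test_step_must_divide(self):
        with pytest.raises(TeAssocError):
            association_curve(
                [gene(1, 0, 100)], [gene(2, 200, 300)], [], max_d=100, step=33
            )

    def test_recovers_planted_excess_over_seeds(self):
        # planted 236-bp NLR excess; sparse gene packing keeps the union
        # erosion from gene overlap small
        diffs = []
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=seed,
                n_chrom=1,
                n_genes=150,
                n_nlr=30,
                n_focal_nlr=10,
                n_te=300,
                chrom_length=2_000_000,
            )
            ann, _ = generate_annotation(cfg)
            by = ann.tes_by_chrom()
            nlr = [g for g in ann.genes if g.is_nlr]
            rest = [g for g in ann.genes if not g.is_nlr]
            f = te_bp_profile(nlr, by, [0], ann.chrom_lengths).mean()
            b = te_bp_profile(rest, by, [0], ann.chrom_lengths).mean()
            diffs.append(f - b)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean() - 236.0) <= 2 * se


class TestNearestDistanceTtest:
    def test_identical_groups(self):
        tes = make_tes([GenomicInterval("c", 500, 600)])
        a = [gene(1, 100, 200)]
        b = [gene(2, 100, 200)]
        mean_a, mean_b, p = nearest_distance_ttest(a, b, tes)
        assert mean_a == mean_b == 300
        assert p == 1.0

    def test_undefined_distances_excluded(self):
        tes = make_tes([GenomicInterval("c", 500, 600)])
        a = [gene(1, 100, 200), gene(2, 0, 10, chrom="other")]
        b = [gene(3, 650, 700), gene(4, 700, 750)]
        mean_a, mean_b, p = nearest_distance_ttest(a, b, tes)
        assert mean_a == 300  # the off-chromosome gene is dropped

    def test_all_excluded_errors(self):
        tes = make_tes([GenomicInterval("c", 500, 600)])
        a = [gene(1, 0, 10, chrom="other")]
        b = [gene(2, 650, 700)]
        with pytest.raises(TeAssocError):
            nearest_distance_ttest(a, b, tes)

    def test_null_pvalues_uniform(self):
        # two groups from one distribution, n=59 vs 106; KS over 500 reps
        master = np.random.default_rng(42)
        ps = []
        for _ in range(500):
            d = master.exponential(2000, size=165).astype(int) + 1
            order = master.permutation(165)
            a_d, b_d = d[order[:59]], d[order[59:]]
            genes_a = [gene(i, 10_000_000 + i * 30_000, 10_000_000 + i * 30_000 + 100) for i in range(59)]
            genes_b = [gene(100 + i, 20_000_000 + i * 30_000, 20_000_000 + i * 30_000 + 100) for i in range(106)]
            tes = make_tes(
                [
                    GenomicInterval("c", g.interval.end + int(dd), g.interval.end + int(dd) + 50)
                    for g, dd in zip(genes_a + genes_b, np.concatenate([a_d, b_d]))
                ]
            )
            _, _, p = nearest_distance_ttest(genes_a, genes_b, tes)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_inflation_detected(self):
        master = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            a_d = (master.exponential(2000, size=59) * 2).astype(int) + 1
            b_d = master.exponential(2000, size=106).astype(int) + 1
            genes_a = [gene(i, 10_000_000 + i * 30_000, 10_000_000 + i * 30_000 + 100) for i in range(59)]
            genes_b = [gene(100 + i, 20_000_000 + i * 30_000, 20_000_000 + i * 30_000 + 100) for i in range(106)]
            tes = make_tes(
                [
                    GenomicInterval("c", g.interval.end + int(dd), g.interval.end + int(dd) + 50)
                    for g, dd in zip(genes_a + genes_b, np.concatenate([a_d, b_d]))
                ]
            )
            _, _, p = nearest_distance_ttest(genes_a, genes_b, tes)
            hits += p < 0.01
        assert hits >= 15


class TestSuperfamilyProportions:
    def test_single_te(self):
        tes = [TERecord("t", GenomicInterval("c", 0, 100), "Gypsy")]
        assert superfamily_size_proportions(tes) == {"Gypsy": 1.0}

    def test_equal_split(self):
        tes = [
            TERecord("t1", GenomicInterval("c", 0, 100), "Gypsy"),
            TERecord("t2", GenomicInterval("c", 200, 250), "Copia"),
            TERecord("t3", GenomicInterval("c", 300, 350), "Copia"),
        ]
        props = superfamily_size_proportions(tes)
        assert props == {"Copia": 0.5, "Gypsy": 0.5}

    def test_matches_accumulation_oracle(self, rng):
        fams = ["Gypsy", "Copia", "LINE", "DNA", "other"]
        tes = []
        totals = {}
        for i in range(200):
            ln = int(rng.integers(50, 500))
            fam = fams[int(rng.integers(0, 5))]
            tes.append(TERecord(f"t{i}", GenomicInterval("c", 1000 * i, 1000 * i + ln), fam))
            totals[fam] = totals.get(fam, 0) + ln
        props = superfamily_size_proportions(tes)
        grand = sum(totals.values())
        for fam, bp in totals.items():
            assert props[fam] == pytest.approx(bp / grand)

    def test_sums_to_one(self, rng):
        cfg = SyntheticConfig(seed=2, n_genes=50, n_nlr=10, n_focal_nlr=5, n_te=200, chrom_length=500_000)
        ann, _ = generate_annotation(cfg)
        assert sum(superfamily_size_proportions(ann.tes).values()) == pytest.approx(1.0)

    def test_empty_error(self):
        with pytest.raises(TeAssocError):
            superfamily_size_proportions([])


def single_arm_partition(length=1_000_000):
    return ChromosomePartition(
        {"c": ((GenomicInterval("c", 0, length), "arm"),)}
    )


def make_pool(rng, n, frac_gypsy):
    tes = []
    for i in range(n):
        start = 1000 * i
        fam = "Gypsy" if rng.random() < frac_gypsy else "DNA"
        tes.append(TERecord(f"t{i}", GenomicInterval("c", start, start + 200), fam))
    return tes


class TestRandomizedFisher:
    def test_extreme_enrichment(self, rng):
        pool = make_pool(rng, 1000, 0.10)
        gypsy = [t for t in pool if t.superfamily == "Gypsy"][:50]
        row = randomized_fisher_enrichment(
            gypsy, pool, single_arm_partition(), "Gypsy", "arm", n_random=1000, seed=0
        )
        assert row.p_observed < 1e-10
        assert row.rank_observed <= 1 / 1000

    def test_proportional_table_p_one(self):
        # 5/5 focal vs 50/50 background in one compartment
        tes = []
        for i in range(110):
            fam = "Gypsy" if i % 2 == 0 else "DNA"
            tes.append(TERecord(f"t{i}", GenomicInterval("c", 1000 * i, 1000 * i + 100), fam))
        focal = tes[:10]  # 5 Gypsy, 5 DNA
        row = randomized_fisher_enrichment(
            focal, tes, single_arm_partition(), "Gypsy", "arm", n_random=10, seed=0
        )
        assert row.p_observed == 1.0

    def test_null_rank_uniform_over_seeds(self, rng):
        pool = make_pool(rng, 300, 0.3)
        ranks = []
        for seed in range(60):
            r = np.random.default_rng(1000 + seed)
            focal = [pool[i] for i in r.choice(300, 40, replace=False)]
            row = randomized_fisher_enrichment(
                focal, pool, single_arm_partition(), "Gypsy", "arm",
                n_random=100, seed=seed,
            )
            ranks.append(row.rank_observed)
        # ranks of a null focal set should spread over (0, 1]; Fisher p is
        # discrete so test coarse uniformity: not concentrated in either tail
        ranks = np.asarray(ranks)
        assert 0.25 <= ranks.mean() <= 0.85
        assert (ranks <= 0.05).mean() <= 0.15

    def test_focal_not_subset_error(self, rng):
        pool = make_pool(rng, 20, 0.5)
        outsider = TERecord("x", GenomicInterval("c", 999_000, 999_100), "Gypsy")
        with pytest.raises(TeAssocError):
            randomized_fisher_enrichment(
                [outsider], pool, single_arm_partition(), "Gypsy", "arm", n_random=5
            )

    def test_empty_compartment_undefined(self, rng):
        pool = make_pool(rng, 20, 0.5)
        row = randomized_fisher_enrichment(
            pool[:5], pool, single_arm_partition(), "Gypsy", "pericentromere", n_random=5
        )
        assert row.p_observed is None and row.n_focal == 0

    def test_deterministic(self, rng):
        pool = make_pool(rng, 100, 0.4)
        focal = pool[:20]
        part = single_arm_partition()
        a = randomized_fisher_enrichment(focal, pool, part, "Gypsy", "arm", n_random=50, seed=3)
        b = randomized_fisher_enrichment(focal, pool, part, "Gypsy", "arm", n_random=50, seed=3)
        assert a == b


class TestFisherOracle:
    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        # all 2x2 tables with n <= 40: two-sided Fisher p equals the sum of
        # hypergeometric probabilities <= the observed one
        for _ in range(60):
            n = int(rng.integers(4, 41))
            a_plus_b = int(rng.integers(1, n))
            a_plus_c = int(rng.integers(1, n))
            a_lo = max(0, a_plus_b + a_plus_c - n)
            a_hi = min(a_plus_b, a_plus_c)
            a = int(rng.integers(a_lo, a_hi + 1))
            table = [[a, a_plus_b - a], [a_plus_c - a, n - a_plus_b - a_plus_c + a]]
            p_fisher = stats.fisher_exact(table, alternative="two-sided")[1]
            rv = stats.hypergeom(n, a_plus_c, a_plus_b)
            p_obs = rv.pmf(a)
            total = sum(
                rv.pmf(k)
                for k in range(a_lo, a_hi + 1)
                if rv.pmf(k) <= p_obs * (1 + 1e-7)
            )
            assert p_fisher == pytest.approx(min(1.0, total), rel=1e-6)
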
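"""Population phases: drift, selection, assortative mating, crosses."""

import numpy as np
import pytest
from scipy import stats

from f2qtl.forward_sim import (BreedingError, BreedingPhase, HistoricalPhase,
                               Population, advance_generation, censor_pedigree,
                               cross_populations, founder_population,
                               historical_size_schedule,
                               sample_reference_population, select_founders,
                               simulate_historical)
from f2qtl.genome import NO_MUTATION, MutationModel, build_genome_map
from f2qtl.quantgen import sample_qtl_effects, compute_tbv


def _genome(n_markers=200, n_qtl=5, seed=0, lengths=(120.0, 80.0)):
    return build_genome_map(len(lengths), list(lengths), n_markers, n_qtl,
                            np.random.default_rng(seed))


def _with_tbv(pop, genome, seed=0):
    trait = sample_qtl_effects(genome.n_qtl, genome.n_alleles[genome.qtl_idx],
                               0.4, np.random.default_rng(seed))
    pop.tbv = compute_tbv(pop, trait, genome)
    return pop, trait


class TestHistorical:
    def test_size_schedule_linear_ramp(self):
        sizes = historical_size_schedule(
            [HistoricalPhase(3, 100), HistoricalPhase(4, 60, ramp=True)])
        assert list(sizes) == [100, 100, 100, 90, 80, 70, 60]

    def test_drift_reduces_heterozygosity_and_keeps_segregation(self):
        g = _genome(500, 2, seed=1)
        mut = MutationModel(1e-5, 1e-5)
        rng = np.random.default_rng(11)
        pop0 = founder_population(g, 200, rng)
        pop = simulate_historical(g, mut, [HistoricalPhase(50, 200),
                                           HistoricalPhase(50, 200)], rng)
        def exp_het(p):
            f = p.marker_genotypes(g).mean(axis=0) / 2
            return np.mean(2 * f * (1 - f))
        maf = np.minimum(pop.marker_genotypes(g).mean(axis=0) / 2,
                         1 - pop.marker_genotypes(g).mean(axis=0) / 2)
        seg = np.mean(maf >= 0.1)
        assert 0.0 < seg < 1.0
        assert exp_het(pop) < exp_het(pop0)

    def test_one_generation_gene_dropping(self):
        g = _genome(100, 2, seed=2)
        rng = np.random.default_rng(3)
        pop = simulate_historical(g, NO_MUTATION, [HistoricalPhase(1, 60)], rng)
        # founders started Bernoulli(1/2); one generation of gene dropping
        # keeps every allele within each locus's founder allele set
        assert np.all(pop.haplotypes < g.n_alleles[None, None, :])

    def test_bottleneck_increases_adjacent_marker_ld(self):
        g = _genome(300, 2, seed=4, lengths=(100.0,))
        mut = NO_MUTATION
        def mean_r2(pop):
            x = pop.marker_genotypes(g).astype(float)
            x = x[:, x.std(axis=0) > 0]
            a, b = x[:, :-1], x[:, 1:]
            r = np.array([np.corrcoef(a[:, j], b[:, j])[0, 1]
                          for j in range(a.shape[1])])
            return np.nanmean(r ** 2)
        wins = 0
        n_rep = 12
        for rep in range(n_rep):
            rng1 = np.random.default_rng(100 + rep)
            const = simulate_historical(g, mut, [HistoricalPhase(60, 200)], rng1)
            rng2 = np.random.default_rng(100 + rep)
            bott = simulate_historical(g, mut, [HistoricalPhase(30, 200),
                                                HistoricalPhase(30, 40, ramp=True)],
                                       rng2)
            wins += mean_r2(bott) > mean_r2(const)
        # paired sign test at alpha = 0.05 against p = 1/2
        assert stats.binomtest(wins, n_rep, 0.5, alternative="greater").pvalue < 0.05


class TestSelection:
    def test_high_tbv_raises_mean(self):
        g = _genome(50, 6, seed=5)
        pop = founder_population(g, 200, np.random.default_rng(6))
        pop, _ = _with_tbv(pop, g)
        sel = select_founders(pop, 10, 20, "high_tbv")
        assert sel.tbv.mean() >= pop.tbv.mean()
        assert sel.n == 30

    def test_high_and_low_tails_disjoint(self):
        g = _genome(50, 6, seed=5)
        pop = founder_population(g, 400, np.random.default_rng(7))
        pop, _ = _with_tbv(pop, g)
        hi = select_founders(pop, 20, 40, "high_tbv")
        lo = select_founders(pop, 20, 40, "low_tbv")
        assert not set(hi.ids) & set(lo.ids)

    def test_full_scale_founder_count(self):
        g = _genome(50, 6, seed=5)
        pop = founder_population(g, 2000, np.random.default_rng(8))
        pop, _ = _with_tbv(pop, g)
        sel = select_founders(pop, 60, 600, "high_tbv")
        assert sel.n == 660

    def test_insufficient_candidates(self):
        g = _genome(50, 2, seed=5)
        pop = founder_population(g, 10, np.random.default_rng(9))
        pop, _ = _with_tbv(pop, g)
        with pytest.raises(BreedingError):
            select_founders(pop, 50, 0, "high_tbv")


class TestAdvanceGeneration:
    def _parents(self, n_m, n_f, genome, seed=0):
        rng = np.random.default_rng(seed)
        pop = founder_population(genome, 4 * (n_m + n_f), rng)
        pop, trait = _with_tbv(pop, genome)
        return select_founders(pop, n_m, n_f, "high_tbv"), trait

    def test_cohort_size_is_dams_times_offspring(self):
        g = _genome(60, 4, seed=10)
        parents, trait = self._parents(15, 150, g)
        phase = BreedingPhase(15, 150, 1, "high_tbv", "positive_assortative", 10)
        out = advance_generation(parents, phase, g, NO_MUTATION, trait,
                                 np.random.default_rng(1))
        assert out.n == 1500
        assert out.tbv is not None
        # every sire is male and dam female in the parent cohort
        sires = {str(s) for s in out.sire}
        male_ids = {str(i) for i in parents.ids[parents.males()]}
        assert sires <= male_ids

    def test_rank_matching_when_equal_counts(self):
        g = _genome(60, 4, seed=11)
        parents, trait = self._parents(12, 12, g)
        phase = BreedingPhase(12, 12, 1, "high_tbv", "positive_assortative", 1)
        out = advance_generation(parents, phase, g, NO_MUTATION, trait,
                                 np.random.default_rng(2))
        def ranked(idx):
            order = np.lexsort((parents.ids[idx], -parents.tbv[idx]))
            return list(parents.ids[idx][order])
        expected = dict(zip(ranked(parents.males()), ranked(parents.females())))
        for s, d in zip(out.sire, out.dam):
            assert expected[s] == d

    def test_assortative_mating_inflates_offspring_tbv_variance(self):
        g = _genome(40, 8, seed=12)
        parents, trait = self._parents(10, 50, g, seed=3)
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            va = np.var(advance_generation(
                parents, BreedingPhase(10, 50, 1, mating="positive_assortative",
                                       offspring_per_dam=4),
                g, NO_MUTATION, trait, np.random.default_rng(rep)).tbv)
            vr = np.var(advance_generation(
                parents, BreedingPhase(10, 50, 1, mating="random",
                                       offspring_per_dam=4),
                g, NO_MUTATION, trait, np.random.default_rng(rep)).tbv)
            wins += va >= vr
        assert stats.binomtest(wins, n_rep, 0.5, alternative="greater").pvalue < 0.05


class TestCrossesAndSampling:
    def _fixed_line(self, genome, allele, n, label, seed):
        rng = np.random.default_rng(seed)
        pop = founder_population(genome, n, rng, label)
        pop.haplotypes[:, :, genome.marker_idx] = allele
        pop, _ = _with_tbv(pop, genome)
        return pop

    def test_f1_heterozygous_and_f2_segregates_1_2_1(self):
        g = _genome(30, 2, seed=13)
        l1 = self._fixed_line(g, 0, 80, "L1", 1)
        l2 = self._fixed_line(g, 1, 80, "L2", 2)
        trait = sample_qtl_effects(g.n_qtl, g.n_alleles[g.qtl_idx], 0.4,
                                   np.random.default_rng(0))
        rng = np.random.default_rng(14)
        phase = BreedingPhase(10, 40, 1, "random", "random", 10)
        f1 = cross_populations(l1, l2, 10, 40, phase, g, NO_MUTATION, trait,
                               rng, "F1")
        geno1 = f1.marker_genotypes(g)
        assert np.all(geno1 == 1)
        f2_parents = select_founders(f1, 10, 40, "random", rng)
        phase2 = BreedingPhase(10, 40, 1, "random", "random", 50)
        f2 = advance_generation(f2_parents, phase2, g, NO_MUTATION, trait, rng)
        assert f2.n == 2000
        counts = np.bincount(f2.marker_genotypes(g)[:, 0], minlength=3)
        p = stats.chisquare(counts, f2.n * np.array([0.25, 0.5, 0.25])).pvalue
        assert p > 0.001

    def test_founder_count_for_f2(self, toy_lineage):
        founders = toy_lineage.f2_founders
        assert founders.n == 2 * (5 + 50)

    def test_reference_population_sampling(self):
        g = _genome(30, 2, seed=15)
        rng = np.random.default_rng(16)
        a = founder_population(g, 300, rng, "F2a")
        b = founder_population(g, 300, rng, "F2b")
        rp = sample_reference_population([a, b], 100, np.random.default_rng(1))
        assert rp.n == 100
        assert len(set(rp.ids)) == 100
        everyone = sample_reference_population([a, b], 600, np.random.default_rng(2))
        assert everyone.n == 600
        with pytest.raises(BreedingError):
            sample_reference_population([a, b], 601, np.random.default_rng(3))
        draws = {tuple(sample_reference_population([a, b], 50,
                                                   np.random.default_rng(s)).ids)
                 for s in range(10)}
        assert len(draws) == 10

    def test_censor_pedigree(self):
        g = _genome(20, 2, seed=17)
        rng = np.random.default_rng(18)
        pop = founder_population(g, 100, rng)
        kids = advance_generation(
            pop, BreedingPhase(10, 50, 1, offspring_per_dam=10), g,
            NO_MUTATION, None, rng)
        same = censor_pedigree(kids, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(same.sire, kids.sire)
        gone = censor_pedigree(kids, 1.0, np.random.default_rng(0))
        assert np.all(gone.sire == "0") and np.all(gone.dam == "0")
        big = Population.concat([kids] * 10)
        cens = censor_pedigree(big, 0.05, np.random.default_rng(1))
        n_missing = int(np.sum(cens.sire == "0") + np.sum(cens.dam == "0"))
        assert 440 <= n_missing <= 560          # 3-sigma binomial on 10,000 slots
        np.testing.assert_array_equal(cens.haplotypes, big.haplotypes)


class TestLineageProperties:
    def test_divergent_selection_separates_line_means(self, toy_lineage):
        assert toy_lineage.line1.tbv.mean() > toy_lineage.line2.tbv.mean()

    def test_f2_restores_heterozygosity_at_divergent_loci(self, toy_lineage):
        g = toy_lineage.genome
        f1 = (toy_lineage.line1.marker_genotypes(g).mean(axis=0) / 2)
        f2 = (toy_lineage.line2.marker_genotypes(g).mean(axis=0) / 2)
        divergent = np.abs(f1 - f2) > 0.8
        assert divergent.any()
        def het(pop):
            return (pop.marker_genotypes(g)[:, divergent] == 1).mean()
        pool = Population.concat(list(toy_lineage.f2_cohorts.values()))
        assert het(pool) > max(het(toy_lineage.line1), het(toy_lineage.line2))

    def test_lineage_reproducible(self):
        from f2qtl.experiment import simulate_lineage
        from conftest import toy_config
        a = simulate_lineage(toy_config(seed=5), 0)
        b = simulate_lineage(toy_config(seed=5), 0)
        pa = Population.concat(list(a.f2_cohorts.values()))
        pb = Population.concat(list(b.f2_cohorts.values()))
        np.testing.assert_array_equal(pa.haplotypes, pb.haplotypes)
        np.testing.assert_array_equal(pa.ids, pb.ids)
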
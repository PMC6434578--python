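import numpy as np
import pytest

from hybridassign import (
    AncestryGenome,
    Haplotype,
    SchemeSpec,
    ancestry_heterozygosity,
    artificial_genotype,
    expected_stats,
    make_gamete,
    origin_fraction,
    simulate_backcross,
    simulate_swarm,
    true_junctions,
    windowed_true_junctions,
)
from hybridassign.pedigree import dosage_profile, meiosis
from hybridassign.synthetic import AllelePanel

from conftest import manual_map


def _mean_and_se(values):
    v = np.asarray(values, dtype=float)
    return v.mean(), v.std(ddof=1) / np.sqrt(v.size)


class TestMeiosis:
    def test_homozygous_parent_always_transmits_its_ancestry(self):
        rng = np.random.default_rng(0)
        parent = AncestryGenome.pure("A", {"c": 2.0})
        for _ in range(50):
            g = make_gamete(parent, "c", rng)
            assert g.n_junctions == 0 and g.origins[0] == 0

    def test_f1_gamete_without_crossover_is_pure_either_way(self):
        # on a very short chromosome crossovers essentially never happen
        rng = np.random.default_rng(1)
        parent = AncestryGenome.f1({"c": 1e-9})
        origins = {int(make_gamete(parent, "c", rng).origins[0]) for _ in range(200)}
        assert origins == {0, 1}

    def test_f1_gamete_mean_junction_count_is_chromosome_length(self):
        # every crossover in an F1 falls at an ancestry-heterogenic site, so
        # the expected gamete junction count equals Poisson mean L
        rng = np.random.default_rng(2)
        parent = AncestryGenome.f1({"c": 1.0})
        counts = [make_gamete(parent, "c", rng).n_junctions for _ in range(20_000)]
        mean, se = _mean_and_se(counts)
        assert abs(mean - 1.0) < 3 * se

    def test_gamete_tracts_tile_and_are_maximal(self):
        rng = np.random.default_rng(3)
        parent = AncestryGenome.f1({"c": 3.0})
        for _ in range(200):
            g = meiosis(*parent.haplotypes["c"], rng)
            assert g.breaks[0] == 0.0
            assert np.all(np.diff(g.breaks) > 0)
            assert np.all(g.origins[1:] != g.origins[:-1])
            parent = AncestryGenome({"c": (g, make_gamete(parent, "c", rng))})


class TestBackcross:
    def test_f1_is_fully_heterozygous_with_no_junctions(self):
        reps = simulate_backcross(SchemeSpec(generations=1, replicates=5, seed=0),
                                  {"c1": 1.0, "c2": 0.5})
        for lineage in reps:
            per, total = ancestry_heterozygosity(lineage[0])
            assert total == 1.0 and all(v == 1.0 for v in per.values())
            assert all(j.diploid == 0 for j in true_junctions(lineage[0]).values())

    def test_heterozygosity_halves_per_generation(self):
        reps = simulate_backcross(SchemeSpec(generations=4, replicates=1000, seed=1),
                                  {"c": 1.0})
        hets = [ancestry_heterozygosity(lin[3])[1] for lin in reps]
        mean, se = _mean_and_se(hets)
        assert abs(mean - 0.125) < 3 * se

    def test_recurrent_parent_fraction_follows_one_minus_half_power(self):
        reps = simulate_backcross(
            SchemeSpec(generations=5, replicates=600, seed=2, recurrent_parent="A"),
            {"c": 1.0})
        for t in (2, 3, 5):
            fr = [origin_fraction(lin[t - 1], "A") for lin in reps]
            mean, se = _mean_and_se(fr)
            assert abs(mean - (1 - 2.0 ** -t)) < 3 * se

    def test_mean_junction_count_reproducible_across_seeds(self):
        # the saturating junction curve is self-consistent between reruns
        counts = {}
        for seed in (11, 12):
            reps = simulate_backcross(
                SchemeSpec(generations=6, replicates=1000, seed=seed), {"c": 1.0})
            counts[seed] = np.array(
                [[true_junctions(lin[t])["c"].diploid for lin in reps]
                 for t in range(6)])
        assert np.all(counts[11][0] == 0) and np.all(counts[12][0] == 0)  # F1
        for t in range(1, 6):
            m1, s1 = _mean_and_se(counts[11][t])
            m2, s2 = _mean_and_se(counts[12][t])
            assert abs(m1 - m2) < 3 * np.hypot(s1, s2)

    def test_junctions_increase_with_chromosome_length(self):
        means = []
        for L in (0.5, 2.0):
            reps = simulate_backcross(SchemeSpec(generations=3, replicates=400, seed=4),
                                      {"c": L})
            means.append(np.mean([true_junctions(lin[2])["c"].diploid for lin in reps]))
        assert means[1] > means[0]


class TestSwarm:
    def test_founder_cohort_heterozygosity_near_half(self):
        reps = simulate_swarm(
            SchemeSpec(scheme="hybrid_swarm", swarm_size=400, generations=1,
                       replicates=1, seed=5), {"c": 1.0})
        hets = [ancestry_heterozygosity(g)[1] for g in reps[0][0]]
        mean, se = _mean_and_se(hets)
        assert abs(mean - 0.5) < 3 * max(se, 1e-6)

    def test_small_swarm_heterozygosity_decays_by_drift(self):
        # exact non-selfing Wright-Fisher recursion as the oracle:
        # h[t+1] = x[t];  x[t+1] = (1/N) * h[t]/2 + (1 - 1/N) * x[t]
        N = 10
        n_gen = 5
        h, x = [0.5], [0.5]
        for _ in range(n_gen):
            h.append(x[-1])
            x.append((1 / N) * h[-2] / 2 + (1 - 1 / N) * x[-1])
        reps = simulate_swarm(
            SchemeSpec(scheme="hybrid_swarm", swarm_size=N, generations=n_gen,
                       replicates=300, seed=6), {"c": 1.0})
        for g in (2, 5):  # cohorts with hybrid age t = g + 1
            # individuals within a population share drift: use the SE of
            # per-population means
            pop_means = [np.mean([ancestry_heterozygosity(ind)[1] for ind in pop[g]])
                         for pop in reps]
            mean, se = _mean_and_se(pop_means)
            assert abs(mean - h[g]) < 3 * se
        # and the closed-form approximation tracks the same declining curve
        approx = [expected_stats("hybrid_swarm", t, N=N)[0] for t in range(1, n_gen + 2)]
        assert np.all(np.diff(approx) < 0) and abs(approx[-1] - h[-1]) < 0.05

    def test_monomorphic_founders_stay_homozygous(self):
        lengths = {"c": 1.0}
        rng = np.random.default_rng(7)
        pop = [AncestryGenome.pure("A", lengths) for _ in range(6)]
        from hybridassign.pedigree import _offspring

        for _ in range(3):
            pop = [_offspring(pop[i % 6], pop[(i + 1) % 6], rng, 1) for i in range(6)]
        assert all(ancestry_heterozygosity(g)[1] == 0.0 for g in pop)

    def test_swarm_requires_two_individuals(self):
        with pytest.raises(ValueError):
            SchemeSpec(scheme="hybrid_swarm", swarm_size=1)


class TestJunctionTruth:
    def test_alternating_tracts_count_two_junctions(self):
        hap = Haplotype([0.0, 0.3, 0.7], [0, 1, 0], 1.0)
        genome = AncestryGenome({"c": (hap, Haplotype.pure("A", 1.0))})
        assert true_junctions(genome)["c"].hap0 == 2
        assert true_junctions(genome)["c"].diploid == 2

    def test_dosage_profile_merges_equal_dosage_segments(self):
        # A|B on one haplotype against B|A on the other: dosage is 1 throughout
        h0 = Haplotype([0.0, 0.5], [0, 1], 1.0)
        h1 = Haplotype([0.0, 0.5], [1, 0], 1.0)
        breaks, dosage = dosage_profile(AncestryGenome({"c": (h0, h1)}), "c")
        assert list(dosage) == [1]
        assert true_junctions(AncestryGenome({"c": (h0, h1)}))["c"].diploid == 0

    def test_windowed_counts_match_plain_counts_for_wide_tracts(self):
        hap = Haplotype([0.0, 0.55], [0, 1], 1.0)
        genome = AncestryGenome({"c": (hap, Haplotype.pure("A", 1.0))})
        assert windowed_true_junctions(genome, 20)["c"] == 1


class TestExpectedStats:
    def test_backcross_f1_values(self):
        h, fr = expected_stats("backcross", 1)
        assert h == 1.0 and fr == 0.5

    def test_backcross_t5_heterozygosity(self):
        assert expected_stats("backcross", 5)[0] == pytest.approx(0.0625)

    def test_backcross_independent_of_population_size(self):
        assert expected_stats("backcross", 4, N=10) == expected_stats("backcross", 4, N=10_000)

    def test_large_swarm_keeps_half_heterozygosity(self):
        h, _ = expected_stats("hybrid_swarm", 7, N=10**9)
        assert h == pytest.approx(0.5, abs=1e-6)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            expected_stats("selfing", 2)


class TestArtificialGenotype:
    def test_alt_probability_follows_panel_counts(self):
        # reference worked example: counts [40, 10] vs [10, 40]
        m = manual_map(np.arange(1, 201), length_bp=400)
        panel = AllelePanel(m, ref_a=np.full(200, 40), alt_a=np.full(200, 10),
                            ref_b=np.full(200, 10), alt_b=np.full(200, 40))
        genome = AncestryGenome.pure("A", {"c": 1.0})
        rng = np.random.default_rng(8)
        draws = np.concatenate(
            [artificial_genotype(genome, m, panel, rng) for _ in range(50)])
        p_alt = draws.mean() / 2  # two independent draws per SNP
        assert abs(p_alt - 0.2) < 3 * np.sqrt(0.2 * 0.8 / draws.size / 2)

    def test_perfect_markers_give_deterministic_dosages(self):
        m = manual_map(np.arange(1, 51))
        panel = AllelePanel(m, ref_a=np.full(50, 20), alt_a=np.zeros(50, int),
                            ref_b=np.zeros(50, int), alt_b=np.full(50, 20))
        rng = np.random.default_rng(9)
        pure = artificial_genotype(AncestryGenome.pure("A", {"c": 1.0}), m, panel, rng)
        f1 = artificial_genotype(AncestryGenome.f1({"c": 1.0}), m, panel, rng)
        assert np.all(pure == 0) and np.all(f1 == 1)

    def test_missing_chromosome_rejected(self):
        m = manual_map(np.arange(1, 11))
        panel = AllelePanel(m, *(np.full(10, 5),) * 4)
        genome = AncestryGenome.pure("A", {"other": 1.0})
        with pytest.raises(ValueError, match="chromosome"):
            artificial_genotype(genome, m, panel, np.random.default_rng(0))
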
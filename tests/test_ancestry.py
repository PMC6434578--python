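import itertools

import numpy as np
import pytest

from hybridassign import (
    AncestryGenome,
    LocalAncestryHMM,
    PanelSpec,
    SchemeSpec,
    artificial_genotype,
    build_reference_panels,
    call_junctions,
    infer_local_ancestry,
    simulate_backcross,
    simulate_panels,
)
from hybridassign.ancestry import (
    _diploid_transition,
    _emission_matrix,
    _forward_backward,
)
from hybridassign.synthetic import AllelePanel

from conftest import manual_map, single_chrom_map


def brute_force_posteriors(emissions, gaps, pi_b, lam):
    """Exhaustive enumeration over all 3**n state paths (oracle)."""
    n = emissions.shape[0]
    pi_a = 1 - pi_b
    init = np.array([pi_a**2, 2 * pi_a * pi_b, pi_b**2])
    Ts = [_diploid_transition(pi_b, np.exp(-lam * d)) for d in gaps]
    marg = np.zeros((n, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=n):
        p = init[path[0]] * emissions[0, path[0]]
        for i in range(1, n):
            p *= Ts[i - 1][path[i - 1], path[i]] * emissions[i, path[i]]
        total += p
        for i, s in enumerate(path):
            marg[i, s] += p
    return marg / total, np.log(total)


class TestForwardBackward:
    @pytest.mark.parametrize("n,t,seed", [(3, 1.0, 0), (5, 2.5, 1), (8, 4.0, 2)])
    def test_matches_exhaustive_enumeration(self, n, t, seed):
        rng = np.random.default_rng(seed)
        emissions = rng.random((n, 3)) + 0.05
        gaps = rng.uniform(0.01, 0.3, size=n - 1)
        pi_b = 2.0 ** (-t)
        lam = t - 1.0
        gamma, ll = _forward_backward(emissions, gaps, pi_b, lam)
        ref_gamma, ref_ll = brute_force_posteriors(emissions, gaps, pi_b, lam)
        assert np.max(np.abs(gamma - ref_gamma)) < 1e-8
        assert ll == pytest.approx(ref_ll, abs=1e-8)

    def test_transition_rows_are_stochastic(self):
        for pi_b in (0.01, 0.3, 0.5):
            for r in (0.0, 0.4, 1.0):
                T = _diploid_transition(pi_b, r)
                np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(T >= 0)


class TestEmissions:
    def test_heterozygous_state_mixes_one_allele_from_each_pool(self):
        e = _emission_matrix(np.array([0, 1, 2]), np.array([0.2, 0.2, 0.2]),
                            np.array([0.9, 0.9, 0.9]))
        assert e[0, 1] == pytest.approx(0.8 * 0.1)
        assert e[1, 1] == pytest.approx(0.2 * 0.1 + 0.9 * 0.8)
        assert e[2, 1] == pytest.approx(0.2 * 0.9)

    def test_missing_genotypes_are_uninformative(self):
        e = _emission_matrix(np.array([-1, 1]), np.array([0.1, 0.1]),
                            np.array([0.9, 0.9]))
        np.testing.assert_array_equal(e[0], 1.0)


class TestInference:
    def test_perfect_marker_f1_recovers_heterozygosity(self, small_map, perfect_panel,
                                                       perfect_hmm):
        rng = np.random.default_rng(0)
        f1 = AncestryGenome.f1({c.name: c.length_morgan for c in small_map.chromosomes})
        geno = artificial_genotype(f1, small_map, perfect_panel[0], rng)
        post = perfect_hmm.infer(geno)
        assert post.t_hat == 1.0
        assert np.all(post.table["p_AB"] > 0.99)

    def test_pure_individual_recovers_homozygosity_and_no_junctions(
            self, small_map, perfect_panel, perfect_hmm):
        rng = np.random.default_rng(1)
        lengths = {c.name: c.length_morgan for c in small_map.chromosomes}
        geno = artificial_genotype(AncestryGenome.pure("A", lengths), small_map,
                                   perfect_panel[0], rng)
        post = perfect_hmm.infer(geno)
        assert np.all(post.table["p_AA"] > 0.99)
        assert sum(call_junctions(post, marker_map=small_map).values()) == 0

    def test_posteriors_sum_to_one_and_age_is_at_least_one(self, small_map,
                                                           lowfst_panel):
        rng = np.random.default_rng(2)
        lin = simulate_backcross(SchemeSpec(generations=3, replicates=1, seed=3),
                                 small_map)
        geno = artificial_genotype(lin[0][2], small_map, lowfst_panel[0], rng)
        post = infer_local_ancestry(geno, small_map, lowfst_panel[0])
        sums = post.table[["p_AA", "p_AB", "p_BB"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert post.t_hat >= 1.0

    def test_low_differentiation_markers_hide_f1_heterozygosity(self, small_map,
                                                                lowfst_panel):
        rng = np.random.default_rng(3)
        lengths = {c.name: c.length_morgan for c in small_map.chromosomes}
        geno = artificial_genotype(AncestryGenome.f1(lengths), small_map,
                                   lowfst_panel[0], rng)
        post = infer_local_ancestry(geno, small_map, lowfst_panel[0])
        assert post.table["p_AB"].mean() < 0.9

    def test_selected_age_maximizes_the_penalized_objective(self, small_map,
                                                            perfect_panel, perfect_hmm):
        rng = np.random.default_rng(4)
        lin = simulate_backcross(SchemeSpec(generations=4, replicates=1, seed=5),
                                 small_map)
        geno = artificial_genotype(lin[0][3], small_map, perfect_panel[0], rng)
        prof = perfect_hmm.profile(geno)
        best = prof["best"][0]
        assert np.all(prof["objective"][:, 0] <= prof["objective"][best, 0] + 1e-12)

    def test_stronger_prior_never_increases_inferred_age(self, small_map, perfect_panel):
        rng = np.random.default_rng(5)
        lin = simulate_backcross(SchemeSpec(generations=6, replicates=3, seed=6),
                                 small_map)
        for rep in lin:
            geno = artificial_genotype(rep[5], small_map, perfect_panel[0], rng)
            ages = [
                LocalAncestryHMM(prior_mean=m).fit(perfect_panel[0]).infer(geno).t_hat
                for m in (2.0, 10.0, 40.0)
            ]
            assert ages[0] <= ages[1] <= ages[2]

    def test_dense_perfect_markers_give_high_state_accuracy(self):
        # simulated F2-F4, one 1-Morgan chromosome at 300 SNPs
        m = single_chrom_map(n_snps=300, seed=7)
        panel, *_ = simulate_panels(m, PanelSpec(n_pop_a=20, n_pop_b=20,
                                                 diag_fraction=1.0, seed=8))
        hmm = LocalAncestryHMM().fit(panel)
        rng = np.random.default_rng(9)
        lin = simulate_backcross(SchemeSpec(generations=4, replicates=6, seed=10), m)
        correct = total = 0
        for rep in lin:
            for t in (2, 3, 4):
                g = rep[t - 1]
                geno = artificial_genotype(g, m, panel, rng)
                calls = hmm.predict(geno)
                pos = m.positions_morgan("chr1")
                h0, h1 = g.haplotypes["chr1"]
                dos = (h0.origin_at(pos) == 0).astype(int) + (h1.origin_at(pos) == 0).astype(int)
                truth = np.array(["BB", "AB", "AA"])[dos]
                correct += (calls == truth).sum()
                total += truth.size
        assert correct / total >= 0.99

    def test_zero_count_snps_are_skipped_with_warning(self):
        m = manual_map([10, 20, 30, 40, 50])
        panel = AllelePanel(m, ref_a=[4, 4, 0, 4, 4], alt_a=[0, 0, 0, 0, 0],
                            ref_b=[0, 0, 0, 0, 0], alt_b=[4, 4, 0, 4, 4])
        with pytest.warns(UserWarning, match="zero panel counts"):
            model = LocalAncestryHMM().fit(panel)
        assert model.usable_.sum() == 4
        post = model.infer(np.array([0, 0, 2, 0, 0]))
        assert len(post.table) == 4 and post.n_skipped == 1

    def test_chromosome_with_single_usable_snp_rejected(self):
        m = manual_map([10])
        panel = AllelePanel(m, ref_a=[4], alt_a=[0], ref_b=[0], alt_b=[4])
        with pytest.raises(ValueError, match="usable SNPs"):
            LocalAncestryHMM().fit(panel)


class TestReferencePanels:
    def test_equalization_enforced_in_panel_set(self, small_map, perfect_panel):
        panel, ga, gb = perfect_panel
        ps = build_reference_panels(ga, gb, small_map, variant="default", seed=0)
        ta, tb = ps.panel.totals()
        np.testing.assert_array_equal(ta, tb)

    def test_perfect_parentals_all_pass_pure_filter(self):
        m = single_chrom_map(n_snps=80, seed=12)
        panel, ga, gb, _ = simulate_panels(
            m, PanelSpec(n_pop_a=8, n_pop_b=8, diag_fraction=1.0, seed=13))
        ps = build_reference_panels(ga, gb, m, variant="pure", seed=1)
        assert ps.members_a.size == 8 and ps.members_b.size == 8

    def test_pure_panel_smaller_than_default_under_weak_divergence(self):
        # noisy low-FST markers make some vetted parentals look recombined
        smaller = 0
        n_seeds = 10
        for seed in range(n_seeds):
            m = single_chrom_map(n_snps=120, seed=100 + seed)
            panel, ga, gb, _ = simulate_panels(
                m, PanelSpec(n_pop_a=10, n_pop_b=10, target_fst=0.01,
                             diag_fraction=0.0, seed=200 + seed))
            default = build_reference_panels(ga, gb, m, variant="default",
                                             assign_threshold=0.5, seed=seed)
            pure = build_reference_panels(ga, gb, m, variant="pure",
                                          assign_threshold=0.5, seed=seed)
            n_def = default.members_a.size + default.members_b.size
            n_pure = pure.members_a.size + pure.members_b.size
            assert n_pure <= n_def
            smaller += n_pure < n_def
        assert smaller >= 0.9 * n_seeds

    def test_empty_panel_raises_with_filter_name(self, small_map, perfect_panel):
        panel, ga, gb = perfect_panel
        with pytest.raises(ValueError, match="assignment"):
            build_reference_panels(ga, gb, small_map, q_a=np.zeros(ga.shape[1]),
                                   q_b=np.ones(gb.shape[1]), variant="default")
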
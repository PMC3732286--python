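import itertools

import numpy as np
import pytest

from conftest import (EPISTATIC, HETEROGENEITY, null_two_locus_tables,
                      planted_pair_tables, random_consistent_trio)
from triogwas.interaction import (MODELS, TwoLocusTables, classify_pair,
                                  cross_region_pairs, expected_null_pairs,
                                  fit_model, hwe_probs, loglik, lrt,
                                  penetrance_matrix, pseudo_control_genotype,
                                  tabulate_two_locus, evaluate_pair)
from triogwas.trio_data import AA, AB, BB, mendelian_consistent


class TestPseudoControl:
    @pytest.mark.parametrize("trio,expected", [
        ((AB, AB, AA), BB), ((AB, AB, AB), AB), ((AA, AA, AA), AA),
        ((AB, AA, AA), AB), ((AB, BB, BB), AB),
    ])
    def test_untransmitted_alleles(self, trio, expected):
        assert pseudo_control_genotype(*trio) == expected

    def test_case_plus_pseudo_equals_parents(self):
        """Allele conservation: child + pseudo-control = father + mother."""
        for trio in itertools.product((0, 1, 2), repeat=3):
            if not mendelian_consistent(*trio):
                continue
            f, m, c = trio
            assert pseudo_control_genotype(f, m, c) == f + m - c

    def test_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            pseudo_control_genotype(AA, AA, AB)


class TestTabulate:
    def test_single_family(self):
        tab = tabulate_two_locus([AB], [AA], [AB], [BB], [BB], [BB])
        assert tab.n[1, 0] == 1          # case: AB at locus A, BB at locus B
        assert tab.m[2, 0] == 1          # pseudo-control: AA at A, BB at B
        assert tab.n_families == 1

    def test_missing_genotype_skips_family(self):
        tab = tabulate_two_locus([AB, -1], [AA, AA], [AB, AA],
                                 [BB, BB], [BB, BB], [BB, BB])
        assert tab.n_families == 1

    def test_conservation_on_simulated_families(self):
        tab = null_two_locus_tables(seed=11, n_families=95)
        assert tab.n.sum() == tab.m.sum() == tab.n_families == 95

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TwoLocusTables(np.eye(3, dtype=int), np.zeros((3, 3), dtype=int))


class TestLoglik:
    def test_certain_single_cell_probability_one(self):
        n = np.zeros((3, 3), dtype=int)
        n[2, 2] = 1
        tab = TwoLocusTables(n, n.copy())
        # p near 1 puts all genotype mass on the (2,2) cell
        assert loglik(0.999, 0.999, np.full((3, 3), 0.3), tab) == pytest.approx(
            2 * np.log(0.999 ** 4), abs=1e-9)

    def test_saturated_multinomial_value(self):
        """HWE(0.5)-proportional tables at p=q=0.5: l hits the saturated value
        and the general model cannot improve on it."""
        g = np.outer(hwe_probs(0.5), hwe_probs(0.5))
        n = (16 * g).astype(int)         # [[1,2,1],[2,4,2],[1,2,1]]
        tab = TwoLocusTables(n, n.copy())
        expected = 2 * float((n * np.log(g)).sum())
        assert loglik(0.5, 0.5, np.full((3, 3), 0.2), tab) == pytest.approx(expected)
        assert fit_model("MG", tab).loglik == pytest.approx(expected, abs=1e-6)

    def test_hand_computed_two_family_example(self):
        # families: case cells (1,1) and (2,0); pseudo-controls (0,1), (1,1)
        n = np.zeros((3, 3), dtype=int); n[1, 1] = 1; n[2, 0] = 1
        m = np.zeros((3, 3), dtype=int); m[0, 1] = 1; m[1, 1] = 1
        pA, pB = 0.4, 0.3
        f = np.array([[0.1, 0.1, 0.1], [0.1, 0.2, 0.1], [0.3, 0.1, 0.1]])
        gA, gB = hwe_probs(pA), hwe_probs(pB)
        g = np.outer(gA, gB)
        s = float((g * f).sum())
        manual = (np.log(g[1, 1] * f[1, 1] / s) + np.log(g[2, 0] * f[2, 0] / s)
                  + np.log(g[0, 1]) + np.log(g[1, 1]))
        assert loglik(pA, pB, f, TwoLocusTables(n, m)) == pytest.approx(manual)

    def test_scale_invariance_of_general_model(self):
        tab = null_two_locus_tables(seed=2, n_families=60)
        f = np.random.default_rng(0).uniform(0.05, 0.9, size=(3, 3))
        base = loglik(0.4, 0.5, f, tab)
        for c in (0.1, 0.5, 1.0):
            assert loglik(0.4, 0.5, c * f, tab) == pytest.approx(base)

    def test_penetrance_matrix_shapes(self):
        assert penetrance_matrix("M0", [0.3]).shape == (3, 3)
        mm = penetrance_matrix("MM", [0.1, 0.2, 0.3, 0.2, 0.4, 0.8])
        assert mm[1, 2] == pytest.approx(0.2 * 0.8)
        mr = penetrance_matrix("MR", [0.1, 0.2, 0.3, 0.2, 0.4, 0.8])
        assert mr[1, 2] == pytest.approx(1 - 0.8 * 0.2)


class TestFitModel:
    def test_m0_matches_margin_mle(self):
        """Analytic oracle: under M0 the allele-frequency MLEs are the pooled
        margin estimates of the combined case + pseudo-control table."""
        tab = null_two_locus_tables(seed=21, n_families=200)
        total = tab.n + tab.m
        pa = (total.sum(axis=1) @ np.arange(3)) / (2 * total.sum())
        pb = (total.sum(axis=0) @ np.arange(3)) / (2 * total.sum())
        fit = fit_model("M0", tab)
        assert fit.allele_freqs[0] == pytest.approx(pa, abs=1e-9)
        assert fit.allele_freqs[1] == pytest.approx(pb, abs=1e-9)

    def test_numeric_agrees_with_analytic(self):
        tab = null_two_locus_tables(seed=22, n_families=80)
        for model in ("M0", "MM", "MG"):
            ana = fit_model(model, tab, method="analytic")
            num = fit_model(model, tab, method="numeric", seed=5)
            assert num.loglik == pytest.approx(ana.loglik, abs=1e-4)
            assert num.loglik <= ana.loglik + 1e-6

    def test_optimizer_beats_coarse_grid(self):
        """Grid-search oracle: the MR optimizer is at least as good as an
        exhaustive 3-level grid over all parameters."""
        tab = null_two_locus_tables(seed=23, n_families=20)
        grid_best = -np.inf
        levels_p = (0.3, 0.5, 0.7)
        levels_f = (0.05, 0.3, 0.7)
        for pA in levels_p:
            for pB in levels_p:
                for alpha in itertools.product(levels_f, repeat=3):
                    for beta in itertools.product(levels_f, repeat=3):
                        f = 1.0 - np.outer(1.0 - np.array(alpha), 1.0 - np.array(beta))
                        grid_best = max(grid_best, loglik(pA, pB, f, tab))
        fit = fit_model("MR", tab, seed=1)
        assert fit.loglik >= grid_best - 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_loglik_ordering(self, seed):
        tab = null_two_locus_tables(seed=100 + seed, n_families=60)
        fits = {m: fit_model(m, tab, seed=seed) for m in MODELS}
        assert fits["M0"].loglik <= fits["MR"].loglik + 1e-6
        assert fits["M0"].loglik <= fits["MM"].loglik + 1e-6
        assert fits["MR"].loglik <= fits["MG"].loglik + 1e-6
        assert fits["MM"].loglik <= fits["MG"].loglik + 1e-6


class TestLrtAndClassification:
    def test_equal_fits_give_p_one(self):
        tab = null_two_locus_tables(seed=31, n_families=50)
        fit = fit_model("MG", tab)
        assert lrt(fit, fit, df=4) == 1.0

    def test_shared_chisquare_routine(self):
        # Lambda = 30.27 on 1 df reproduces the published tail probability
        from scipy import stats
        assert stats.chi2.sf(30.27, 1) == pytest.approx(3.76e-8, rel=0.01)

    def test_default_df_from_parameter_counts(self):
        tab = null_two_locus_tables(seed=32, n_families=80)
        f0, fg = fit_model("M0", tab), fit_model("MG", tab)
        from scipy import stats
        lam = 2 * (fg.loglik - f0.loglik)
        assert lrt(f0, fg) == pytest.approx(stats.chi2.sf(lam, 8))

    @pytest.mark.parametrize("ps,expected", [
        ((2e-5, 3e-6, 0.01), "epistasis"),
        ((2e-5, 0.6, 0.01), "heterogeneity"),
        ((2e-3, 0.6, 0.01), "not-reported"),
        ((2e-5, 0.6, 0.2), "multiplicative-consistent"),
        ((2e-5, 0.01, 0.01), "reported-unlabeled"),
        ((np.nan, 0.1, 0.1), "not-reported"),
    ])
    def test_classification_rules(self, ps, expected):
        assert classify_pair(*ps) == expected

    @pytest.mark.parametrize("n,alpha,expected", [
        (582, 0.05, 29), (0, 0.05, 0), (1000, 0.01, 10),
    ])
    def test_expected_null_pairs(self, n, alpha, expected):
        assert expected_null_pairs(n, alpha) == expected


class TestDiscrimination:
    def test_epistatic_pair_recovered(self):
        labels = [evaluate_pair(planted_pair_tables(EPISTATIC, seed=s), seed=s)[3]
                  for s in range(6)]
        assert labels.count("epistasis") >= 4

    def test_heterogeneity_pair_recovered(self):
        res = [evaluate_pair(planted_pair_tables(HETEROGENEITY, seed=s), seed=s)
               for s in range(6)]
        assert [r[3] for r in res].count("heterogeneity") >= 4
        assert np.median([r[1] for r in res]) > 0.05      # P_12 large
        assert np.median([r[2] for r in res]) < 0.05      # P_M2 rejects


class TestPairEnumeration:
    def test_cross_region_only(self):
        region_of = {"a": 0, "b": 0, "c": 1, "d": 2}
        pairs = cross_region_pairs(["a", "b", "c", "d", "zzz"], region_of)
        assert ("a", "b") not in pairs
        assert set(pairs) == {("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")}

    def test_min_families_skips_pair(self, caplog):
        from triogwas.interaction import analyze_pairs
        from triogwas.simulate import SimulationConfig, simulate_families
        from conftest import NULL_MODEL
        cfg = SimulationConfig(n_families=10, freqs=np.array([0.5, 0.5]),
                               disease_model=NULL_MODEL, seed=3)
        data = simulate_families(cfg)
        with caplog.at_level("WARNING"):
            out = analyze_pairs(data, [("snp0", "snp1")], min_families=20)
        assert len(out) == 0
        assert "skipped" in caplog.text
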
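import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_consistent_trio
from triogwas.tdt import (TransmissionCounts, assign_stratum,
                          count_transmissions, exp_tdt_test,
                          expected_transmissions, stratified_tdt, tdt_test,
                          transmission_scan, weighted_chisq)
from triogwas.trio_data import AA, AB, BB, mendelian_consistent


class TestCountTransmissions:
    @pytest.mark.parametrize("trio,expected", [
        ((AB, AA, AA), (1, 0)),
        ((AB, AB, AB), (1, 1)),
        ((AB, AB, AA), (2, 0)),
        ((AB, AB, BB), (0, 2)),
        ((AA, BB, AB), (0, 0)),    # no heterozygous parent: uninformative
        ((AB, BB, BB), (0, 1)),
    ])
    def test_classical_counting(self, trio, expected):
        c = count_transmissions(*trio)
        assert (c.t, c.u) == expected

    def test_inconsistent_trio_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            count_transmissions(AA, AA, AB)

    def test_each_het_parent_contributes_exactly_one(self):
        for trio in itertools.product((0, 1, 2), repeat=3):
            if not mendelian_consistent(*trio):
                continue
            c = count_transmissions(*trio)
            hets = (trio[0] == 1) + (trio[1] == 1)
            assert c.t + c.u == hets

    def test_scan_matches_scalar_sum(self):
        rng = np.random.default_rng(3)
        trios = [random_consistent_trio(rng) for _ in range(200)]
        F, M, C = (np.array(x).reshape(-1, 1) for x in zip(*trios))
        T, U = transmission_scan(F, M, C)
        t = sum(count_transmissions(*trio).t for trio in trios)
        u = sum(count_transmissions(*trio).u for trio in trios)
        assert (T[0], U[0]) == (t, u)


class TestTdtTest:
    def test_symmetric_counts_give_null(self):
        r = tdt_test(TransmissionCounts(10, 10))
        assert r.chisq == 0 and r.p == pytest.approx(1.0)

    def test_non_informative_flagged(self):
        r = tdt_test(TransmissionCounts(0, 0))
        assert np.isnan(r.p) and np.isnan(r.odds)

    def test_odds_undefined_when_u_zero(self):
        assert np.isnan(tdt_test(TransmissionCounts(5, 0)).odds)

    def test_agrees_with_mcnemar(self):
        """The TDT statistic is a McNemar test on discordant transmissions."""
        from statsmodels.stats.contingency_tables import mcnemar
        for t, u in [(39, 90), (87, 28), (7, 3), (116, 64)]:
            table = [[0, t], [u, 0]]
            ref = mcnemar(table, exact=False, correction=False)
            r = tdt_test(TransmissionCounts(t, u))
            assert r.chisq == pytest.approx(ref.statistic, rel=1e-12)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(deadline=None)
    def test_allele_swap_symmetry(self, t, u):
        if t + u == 0:
            return
        a = tdt_test(TransmissionCounts(t, u))
        b = tdt_test(TransmissionCounts(u, t))
        assert a.chisq == pytest.approx(b.chisq)
        assert a.p == pytest.approx(b.p)
        if t > 0 and u > 0:
            assert a.odds == pytest.approx(1.0 / b.odds)


class TestExpectedTransmissions:
    def test_certain_posteriors_reduce_to_hard_counts(self):
        rng = np.random.default_rng(4)
        eye = np.eye(3)
        for _ in range(300):
            f, m, c = random_consistent_trio(rng)
            hard = count_transmissions(f, m, c)
            soft = expected_transmissions(eye[f], eye[m], eye[c])
            assert (soft.t, soft.u) == (hard.t, hard.u)

    def test_against_brute_force_enumeration(self):
        """Independent oracle: renormalized weighted sum over all 27 configs."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            pf, pm, pc = rng.dirichlet([1, 1, 1], size=3)
            num_t = num_u = mass = 0.0
            for f in range(3):
                for m in range(3):
                    for c in range(3):
                        if not mendelian_consistent(f, m, c):
                            continue
                        w = pf[f] * pm[m] * pc[c]
                        cnt = count_transmissions(f, m, c)
                        mass += w
                        num_t += w * cnt.t
                        num_u += w * cnt.u
            got = expected_transmissions(pf, pm, pc)
            assert got.t == pytest.approx(num_t / mass)
            assert got.u == pytest.approx(num_u / mass)

    def test_half_het_father(self):
        # father half AB / half AA, certain AA mother and child: only the
        # AB-father configuration transmits, with renormalized weight 0.5
        got = expected_transmissions([0, 0.5, 0.5], [0, 0, 1], [0, 0, 1])
        assert (got.t, got.u) == (0.5, 0.0)

    def test_double_het_parents_uncertain_child(self):
        got = expected_transmissions([0, 1, 0], [0, 1, 0], [0.25, 0.5, 0.25])
        assert (got.t, got.u) == (1.0, 1.0)

    def test_zero_mass_trio_rejected(self):
        # certain AA x AA parents with a certain BB child: no consistent config
        with pytest.raises(ValueError, match="mass"):
            expected_transmissions([0, 0, 1], [0, 0, 1], [1, 0, 0])


class TestStratified:
    @pytest.mark.parametrize("high,low,expected", [
        ((26, 35), (87, 28), 20.24),
        ((41, 35), (22, 69), 13.44),
        ((20, 25), (53, 15), 13.00),
    ])
    def test_published_weighted_chisq_rows(self, high, low, expected):
        w = weighted_chisq([TransmissionCounts(*high), TransmissionCounts(*low)])
        assert w == pytest.approx(expected, abs=0.005)

    def test_single_stratum_reduces_to_plain_chisq(self):
        r = stratified_tdt({"low": TransmissionCounts(39, 90)})
        assert r.weighted_chisq == pytest.approx(r.per_stratum["low"].chisq)

    def test_empty_stratum_contributes_nothing(self):
        full = stratified_tdt({"high": TransmissionCounts(0, 0),
                               "low": TransmissionCounts(10, 30)})
        only = stratified_tdt({"low": TransmissionCounts(10, 30)})
        assert full.weighted_chisq == only.weighted_chisq

    @given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)),
                    min_size=1, max_size=4))
    @settings(deadline=None)
    def test_weighted_chisq_nonnegative(self, counts):
        w = weighted_chisq([TransmissionCounts(t, u) for t, u in counts])
        assert w >= 0


class TestAssignStratum:
    @pytest.mark.parametrize("carrier,copies,expected", [
        (True, 2, "high"), (True, 1, "low"), (True, 0, "low"),
        (False, 2, "low"), (False, 0, "low"),
    ])
    def test_rule(self, carrier, copies, expected):
        assert assign_stratum(carrier, copies) == expected

    def test_invalid_copy_number(self):
        with pytest.raises(ValueError):
            assign_stratum(True, 3)


def test_null_calibration_hard_and_expected():
    """Null rejection at alpha=0.05 stays within 3 MC errors for both modes."""
    from triogwas.simulate import (PenetranceSpec, SimulationConfig,
                                   blur_posteriors, simulate_families)
    from triogwas.trio_data import hard_call
    from triogwas.tdt import tdt_scan
    n_markers = 500
    cfg = SimulationConfig(n_families=200, freqs=np.full(n_markers, 0.3),
                           disease_model=[PenetranceSpec("constant", params={"value": 0.5})],
                           seed=7)
    data = simulate_families(cfg)
    data.posteriors = blur_posteriors(data.genotypes, 0.053, rng=8)
    data.genotypes = hard_call(data.posteriors)
    band = 3 * np.sqrt(0.05 * 0.95 / n_markers)
    for mode in ("hard", "expected"):
        rej = (tdt_scan(data, mode=mode)["p"] < 0.05).mean()
        assert abs(rej - 0.05) < band, f"{mode} mode miscalibrated: {rej:.3f}"
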
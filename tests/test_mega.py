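"""Pooling, heterogeneity, DerSimonian–Laird τ² and the model-selection rule.

The oracle functions here re-derive the weighted-mean formulas with plain
Python loops, independent of the package's vectorized implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megapool.mega import (
    MegaResult,
    ScreenCriteria,
    dl_tau2,
    fixed_effect,
    heterogeneity,
    mega_analyze,
    percent_change,
    pool_gene,
    random_effects,
    screen,
)

from conftest import make_effect


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_weighted_mean(ys, vs, tau2=0.0):
    num = den = 0.0
    for y, v in zip(ys, vs):
        w = 1.0 / (v + tau2)
        num += w * y
        den += w
    return num / den, math.sqrt(1.0 / den)


def oracle_Q(ys, vs):
    est, _ = oracle_weighted_mean(ys, vs)
    return sum((y - est) ** 2 / v for y, v in zip(ys, vs))


def effects_from(ys, vs):
    return [make_effect(f"s{i}", y, v) for i, (y, v) in enumerate(zip(ys, vs))]


# ---------------------------------------------------------------------------


class TestFixedEffect:
    def test_single_study_is_identity(self):
        est, se = fixed_effect(effects_from([1.2], [0.04]))
        assert est == pytest.approx(1.2)
        assert se == pytest.approx(0.2)

    def test_equal_weights_give_plain_mean(self):
        est, _ = fixed_effect(effects_from([1.0, 2.0], [0.25, 0.25]))
        assert est == pytest.approx(1.5)

    def test_zero_effects_pool_to_zero(self):
        est, _ = fixed_effect(effects_from([0.0, 0.0], [0.1, 0.5]))
        assert est == pytest.approx(0.0)

    def test_empty_list_signals_absence(self):
        assert fixed_effect([]) is None


class TestHeterogeneity:
    def test_no_dispersion_gives_zero_Q(self):
        effs = effects_from([0.7, 0.7, 0.7], [0.1, 0.2, 0.3])
        est, _ = fixed_effect(effs)
        Q, df, ISq, q_p = heterogeneity(effs, est)
        assert Q == pytest.approx(0.0)
        assert ISq == 0.0
        assert q_p == pytest.approx(1.0)

    def test_isq_formula(self):
        # construct k=9 effects whose Q is exactly 50: ISq = 100*(50-8)/50 = 84
        ys = np.zeros(9)
        ys[0], ys[1] = 5.0, -5.0
        effs = effects_from(ys, [1.0] * 9)
        est, _ = fixed_effect(effs)
        Q, df, ISq, _ = heterogeneity(effs, est)
        assert Q == pytest.approx(50.0)
        assert df == 8
        assert ISq == pytest.approx(84.0)

    def test_Q_at_or_below_df_floors_isq_at_zero(self):
        # tiny dispersion: Q < df = 8
        ys = [0.01 * i for i in range(9)]
        effs = effects_from(ys, [1.0] * 9)
        est, _ = fixed_effect(effs)
        Q, df, ISq, _ = heterogeneity(effs, est)
        assert Q < df
        assert ISq == 0.0

    def test_k1_degenerates_cleanly(self):
        effs = effects_from([1.0], [0.1])
        assert heterogeneity(effs, 1.0) == (0.0, 0, 0.0, 1.0)


class TestDLTau2:
    def test_truncation_at_zero(self):
        effs = effects_from([0.5, 0.5, 0.5], [0.25, 0.25, 0.25])
        assert dl_tau2(effs, Q=1.0, df=2) == 0.0

    def test_hand_evaluated_equal_weight_case(self):
        # k=3, v=0.25 (w=4): tau2 = (4-2) / (12 - 48/12) = 0.25
        effs = effects_from([0.0, 0.0, 0.0], [0.25, 0.25, 0.25])
        assert dl_tau2(effs, Q=4.0, df=2) == pytest.approx(0.25)

    @given(
        v=st.floats(0.01, 2.0),
        k=st.integers(2, 8),
        excess=st.floats(0.0, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_weight_closed_form(self, v, k, excess):
        # equal variances: tau2 = v * (Q - df) / (k - 1)
        effs = effects_from([0.0] * k, [v] * k)
        df = k - 1
        Q = df + excess
        expected = v * (Q - df) / (k - 1)
        assert dl_tau2(effs, Q, df) == pytest.approx(expected, rel=1e-9)


class TestRandomEffects:
    def test_tau2_zero_reduces_to_fixed(self):
        effs = effects_from([0.3, 1.1, -0.4], [0.1, 0.3, 0.2])
        assert random_effects(effs, 0.0) == pytest.approx(fixed_effect(effs))

    def test_large_tau2_approaches_unweighted_mean(self):
        ys = [0.0, 2.0, 5.0]
        effs = effects_from(ys, [0.01, 1.0, 0.3])
        est, _ = random_effects(effs, 1e9)
        assert est == pytest.approx(np.mean(ys), abs=1e-5)

    def test_estimate_pulled_toward_unweighted_mean(self):
        effs = effects_from([0.0, 2.0], [0.01, 1.0])
        fixed_est, _ = fixed_effect(effs)
        rand_est, _ = random_effects(effs, 1.0)
        assert fixed_est < rand_est < 1.0  # unweighted mean is 1.0


class TestOracleEquivalence:
    """Pooled estimates match loop-coded oracles for all k <= 4 instances."""

    @given(
        data=st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.01, 2.0)), min_size=1, max_size=4
        ),
        tau2=st.floats(0.0, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_pooling_matches_oracle(self, data, tau2):
        ys = [d[0] for d in data]
        vs = [d[1] for d in data]
        effs = effects_from(ys, vs)
        est, se = fixed_effect(effs)
        oest, ose = oracle_weighted_mean(ys, vs)
        assert est == pytest.approx(oest, rel=1e-9, abs=1e-12)
        assert se == pytest.approx(ose, rel=1e-9)
        rest, rse = random_effects(effs, tau2)
        orest, orse = oracle_weighted_mean(ys, vs, tau2)
        assert rest == pytest.approx(orest, rel=1e-9, abs=1e-12)
        assert rse == pytest.approx(orse, rel=1e-9)
        if len(ys) >= 2:
            Q, _, _, _ = heterogeneity(effs, est)
            assert Q == pytest.approx(oracle_Q(ys, vs), rel=1e-9, abs=1e-9)


class TestModelSelection:
    @given(
        data=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)), min_size=1, max_size=6
        )
    )
    @settings(max_examples=1000, deadline=None)
    def test_isq_zero_iff_fixed_model(self, data):
        """The binary rule: Q <= df forces ISq = 0 and the fixed model."""
        effs = effects_from([d[0] for d in data], [d[1] for d in data])
        res = pool_gene("G0", effs)
        assert 0.0 <= res.ISq <= 100.0
        assert res.df == res.k - 1
        assert (res.model == "fixed") == (res.ISq == 0.0)
        if res.Q <= res.df:
            assert res.ISq == 0.0 and res.model == "fixed"

    def test_identical_effects_select_fixed_model(self):
        effs = effects_from([0.9] * 5, [0.2] * 5)
        res = pool_gene("G0", effs)
        assert res.model == "fixed"
        assert res.tau2 == 0.0
        est, se = fixed_effect(effs)
        assert res.se_pooled == pytest.approx(se)

    def test_heterogeneous_effects_select_random_model(self):
        effs = effects_from([0.0, 1.0, 2.0, 3.0], [0.01] * 4)
        res = pool_gene("G0", effs)
        assert res.model == "random"
        assert res.tau2 > 0
        assert res.se_pooled > fixed_effect(effs)[1]

    def test_adding_study_at_pooled_estimate_never_inflates_se(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(2, 6)
            ys = rng.normal(0, 1, k)
            vs = rng.uniform(0.05, 1.0, k)
            effs = effects_from(ys, vs)
            before = pool_gene("G0", effs)
            extra = make_effect("extra", before.lfc_pooled, rng.uniform(0.05, 1.0))
            after = pool_gene("G0", effs + [extra])
            assert after.se_pooled <= before.se_pooled + 1e-12


class TestMegaAnalyze:
    def test_low_k_genes_flagged_not_dropped(self, effects_factory):
        by_gene = {
            "A": effects_factory([1.0, 1.2], [0.1, 0.1], gene="A"),
            "B": effects_factory([0.5], [0.1], gene="B"),
        }
        results = {r.gene: r for r in mega_analyze(by_gene, min_k=2)}
        assert not results["A"].low_k
        assert results["B"].low_k and results["B"].model == "fixed"

    def test_results_sorted_by_p(self, effects_factory):
        by_gene = {
            "A": effects_factory([0.1, 0.05], [0.5, 0.5], gene="A"),
            "B": effects_factory([2.0, 2.1], [0.01, 0.01], gene="B"),
        }
        results = mega_analyze(by_gene)
        assert [r.gene for r in results] == ["B", "A"]


class TestScreen:
    def _result(self, lfc, p):
        return MegaResult(
            gene="G",
            k=2,
            lfc_pooled=lfc,
            se_pooled=0.1,
            sd_between=0.0,
            p_value=p,
            Q=0.0,
            df=1,
            ISq=0.0,
            q_p=1.0,
            tau2=0.0,
            model="fixed",
        )

    def test_strong_up_effect_passes(self):
        assert screen([self._result(1.34, 0.0045)]) != []

    def test_sub_threshold_lfc_fails_despite_tiny_p(self):
        assert screen([self._result(0.79, 0.0009)]) == []

    def test_down_regulation_branch(self):
        assert screen([self._result(-1.2, 0.004)]) != []

    def test_boundary_is_strict(self):
        crit = ScreenCriteria()
        assert screen([self._result(1.0, 0.001)], crit) == []
        assert screen([self._result(1.5, 0.005)], crit) == []


def test_percent_change_of_lfc():
    assert percent_change(1.0) == pytest.approx(100.0)
    assert percent_change(0.0) == pytest.approx(0.0)
    assert percent_change(-1.0) == pytest.approx(-50.0)
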
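"""Unit and property tests for the effect-size and combining machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from megex import (
    InsufficientStudiesError,
    LfcUndefinedError,
    StudyDataset,
    cochran_q,
    combine_fixed,
    combine_random,
    gene_lfc,
    i_squared,
    mega_analyze,
    mega_analyze_collection,
    meta_combine,
    select_significant,
    study_gene_effects,
)
from megex.mega import GeneEffect, MetaResult

from _oracles import loop_fixed, loop_q, loop_random

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


class TestGeneLfc:
    def test_noise_free_doubling(self, tiny_study):
        eff = gene_lfc(tiny_study, "DOUBLE")
        assert eff.lfc == pytest.approx(1.0, abs=1e-12)

    def test_identity_is_zero(self, tiny_study):
        assert gene_lfc(tiny_study, "FLAT").lfc == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_control_mean_hand_example(self, tiny_study):
        # controls (2,4) -> arithmetic mean 3; per-case log2 ratios of
        # (3,6,12) to 3 are (0,1,2): lfc 1, case variance component 1/3
        eff = gene_lfc(tiny_study, "MIXED", control_mean="arithmetic")
        assert eff.lfc == pytest.approx(1.0, abs=1e-12)
        case_component = 1.0 / 3.0
        ctrl_component = np.var([2.0, 4.0], ddof=1) / (2 * 9 * math.log(2) ** 2)
        assert eff.var == pytest.approx(case_component + ctrl_component, rel=1e-12)

    def test_geometric_control_mean_hand_example(self, tiny_study):
        # geometric control mean sqrt(8): lfc = mean(log2 cases) - 1.5
        eff = gene_lfc(tiny_study, "MIXED")
        expected = np.mean(np.log2([3.0, 6.0, 12.0])) - 1.5
        assert eff.lfc == pytest.approx(expected, rel=1e-12)
        assert eff.var == pytest.approx(1.0 / 3.0 + 0.5 / 2.0, rel=1e-12)

    def test_absent_gene_returns_none(self, tiny_study):
        assert gene_lfc(tiny_study, "MISSING") is None

    def test_nonpositive_control_mean_raises(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 0.0, 0.0]], index=["G"], columns=list("abcd")
        )
        study = StudyDataset("S", mat, ["case", "case", "control", "control"])
        with pytest.raises(LfcUndefinedError):
            gene_lfc(study, "G")

    @pytest.mark.parametrize("control_mean", ["geometric", "arithmetic"])
    def test_vectorized_matches_scalar(self, small_collection, control_mean):
        _, studies, _ = small_collection
        study = studies[3]
        table = study_gene_effects(study, control_mean=control_mean)
        for gene in list(table.index)[:10]:
            eff = gene_lfc(study, gene, control_mean=control_mean)
            assert table.at[gene, "lfc"] == pytest.approx(eff.lfc, rel=1e-12)
            assert table.at[gene, "var"] == pytest.approx(eff.var, rel=1e-12)


class TestHeterogeneity:
    def test_q_hand_example(self):
        q, df, q_p = cochran_q([0.0, 2.0], [1.0, 1.0])
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1

    def test_q_zero_for_identical_effects(self):
        q, df, q_p = cochran_q([0.7] * 4, [0.3, 1.0, 2.0, 0.5])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert q_p == pytest.approx(1.0)

    def test_q_requires_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([1.0], [1.0])

    @pytest.mark.parametrize(
        "q, df, expected",
        [(0.5, 2, 0.0), (20.0, 10, 50.0), (3.0, 3, 0.0), (0.0, 2, 0.0)],
    )
    def test_i_squared_clamp_and_formula(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)

    @given(q=st.floats(0, 1e6), df=st.integers(1, 100))
    @settings(max_examples=200, derandomize=True)
    def test_i_squared_range(self, q, df):
        isq = i_squared(q, df)
        assert 0.0 <= isq < 100.0
        assert (isq == 0.0) == (q <= df)


class TestCombining:
    def test_fixed_equal_weights(self):
        effect, se, p = combine_fixed([1.0, 3.0], [1.0, 1.0])
        assert effect == pytest.approx(2.0)
        assert se == pytest.approx(math.sqrt(0.5))

    def test_fixed_single_study_passthrough(self):
        effect, se, _ = combine_fixed([0.4], [0.09])
        assert effect == pytest.approx(0.4)
        assert se == pytest.approx(0.3)

    def test_fixed_unequal_weights_hand_example(self):
        effect, se, _ = combine_fixed([0.0, 2.0], [1.0, 3.0])
        assert effect == pytest.approx(0.5)
        assert se == pytest.approx(math.sqrt(3.0) / 2.0)

    def test_random_dl_hand_example(self):
        effect, se, p, tau2 = combine_random([0.0, 2.0], [1.0, 1.0])
        assert tau2 == pytest.approx(1.0)
        assert effect == pytest.approx(1.0)
        assert se == pytest.approx(1.0)

    def test_random_degenerates_to_fixed_when_tau2_zero(self):
        effects, variances = [0.5, 0.5, 0.5], [0.2, 0.4, 0.9]
        r = combine_random(effects, variances)
        f = combine_fixed(effects, variances)
        assert r[3] == 0.0
        assert r[:3] == pytest.approx(f)

    def test_random_equal_vars_closed_form(self):
        v, k = 0.7, 5
        _, se, _, tau2 = combine_random([1.1] * k, [v] * k)
        assert tau2 == 0.0
        assert se == pytest.approx(math.sqrt(v / k))

    def test_loop_oracle_equivalence_small_batch(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 12))
            y = rng.normal(0, 2, k).tolist()
            v = rng.uniform(0.05, 3.0, k).tolist()
            q, df, _ = cochran_q(y, v)
            assert q == pytest.approx(loop_q(y, v), abs=1e-10)
            assert combine_fixed(y, v)[:2] == pytest.approx(loop_fixed(y, v), abs=1e-10)
            re_, rse, _, rtau2 = combine_random(y, v)
            oe, ose, otau2 = loop_random(y, v)
            assert (re_, rse, rtau2) == pytest.approx((oe, ose, otau2), abs=1e-10)


class TestMegaAnalyze:
    def test_k_counts_only_studies_containing_gene(self, small_collection):
        cfg, studies, truth = small_collection
        # drop one gene from one study's matrix to force k = 15
        gene = "G00010"
        trimmed = []
        for i, s in enumerate(studies):
            if i == 0:
                mat = s.matrix.drop(index=gene)
                s = StudyDataset(s.study_id, mat, list(s.groups), s.country, s.study_age)
            trimmed.append(s)
        res = mega_analyze(gene, trimmed)
        assert res.k == len(studies) - 1

    def test_identical_effects_select_fixed_model(self):
        effects = [GeneEffect(f"S{i}", "G", 0.8, 0.5, 10, 10) for i in range(6)]
        res = meta_combine("G", effects)
        assert res.model == "fixed"
        assert res.isq == 0.0
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_model_selection_consistency(self, small_collection):
        _, studies, _ = small_collection
        for res in mega_analyze_collection(studies):
            assert res.df == res.k - 1
            assert (res.model == "fixed") == (res.q <= res.df)
            assert (res.isq == 0.0) == (res.q <= res.df)
            assert res.tau2 >= 0.0
            assert 0.0 <= res.isq < 100.0

    def test_min_studies_skip_marker(self, small_collection):
        _, studies, _ = small_collection
        assert mega_analyze("G00001", studies[:3], min_studies=4) is None

    def test_study_order_permutation_invariance(self, small_collection):
        _, studies, _ = small_collection
        a = mega_analyze("G00020", studies)
        b = mega_analyze("G00020", list(reversed(studies)))
        for field in ("k", "effect", "se", "p", "q", "isq", "q_p", "tau2", "model"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)

    def test_audit_retains_both_models(self, small_collection):
        _, studies, _ = small_collection
        res = mega_analyze("G00001", studies)
        chosen = res.fixed if res.model == "fixed" else res.random
        assert (res.effect, res.se, res.p) == chosen
        assert np.isfinite(res.fixed).all() and np.isfinite(res.random).all()


class TestSelectSignificant:
    def _mk(self, gene, p, effect):
        return MetaResult(
            gene=gene, k=15, effect=effect, se=0.1, p=p, q=10.0, df=14,
            isq=0.0, q_p=0.5, tau2=0.0, model="fixed",
        )

    def test_threshold_semantics(self):
        results = [
            self._mk("KEEP", 1e-8, -1.5),
            self._mk("SMALL_LFC", 1e-8, -0.5),
            self._mk("WEAK_P", 1e-6, -2.0),
            self._mk("BOUNDARY_P", 1e-7, -1.5),
            self._mk("BOUNDARY_LFC", 1e-8, 1.0),
        ]
        kept = select_significant(results)
        assert [r.gene for r in kept] == ["KEEP"]

    def test_empty_input(self):
        assert select_significant([]) == []

    def test_sorted_by_abs_effect_descending(self):
        results = [self._mk("A", 1e-9, -1.2), self._mk("B", 1e-9, 2.5),
                   self._mk("C", 1e-9, -1.9)]
        assert [r.gene for r in select_significant(results)] == ["B", "C", "A"]
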
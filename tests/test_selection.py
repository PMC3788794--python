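"""Candidate sets, AICc, Akaike weights and variable importance."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metaoccu as mo
from metaoccu.selection import FOCAL_COVARIATES


class TestCandidateSet:
    def test_psi_and_gamma_sets_have_31_models(self):
        assert len(mo.candidate_set("psi")) == 31
        assert len(mo.candidate_set("gamma")) == 31

    def test_epsilon_and_p_sets_have_15_models(self):
        assert len(mo.candidate_set("epsilon")) == 15
        assert len(mo.candidate_set("p")) == 15

    def test_single_covariate_universe(self):
        assert len(mo.candidate_set("psi", covariates=("size",))) == 1

    def test_null_model_excluded_by_default_but_recoverable(self):
        assert len(mo.candidate_set("p", include_null=True)) == 16

    def test_other_parameters_are_intercept_only(self):
        for spec in mo.candidate_set("gamma"):
            assert spec.psi == spec.epsilon == spec.p == ()
            assert spec.gamma

    def test_isolation_absent_from_epsilon_universe(self):
        assert "isolation" not in FOCAL_COVARIATES["epsilon"]


class TestAicc:
    @pytest.mark.parametrize(
        "neg2, K, n, expected",
        [
            (2907.01, 18, 289, 2945.54),
            (2940.15, 15, 289, 2971.91),
            (100.0, 3, 20, 107.5),
        ],
    )
    def test_values(self, neg2, K, n, expected):
        assert mo.aicc(neg2, K, n) == pytest.approx(expected, abs=0.01)

    def test_small_sample_domain_error(self):
        with pytest.raises(mo.DomainError):
            mo.aicc(100.0, 19, 20)


class TestAkaikeWeights:
    def test_equal_values_share_weight(self):
        np.testing.assert_allclose(mo.akaike_weights([10.0, 10.0]), [0.5, 0.5])
        np.testing.assert_allclose(mo.akaike_weights([5.0] * 3), [1 / 3] * 3)

    def test_two_point_hand_arithmetic(self):
        w = mo.akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)))
        assert w[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)))

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=8), st.floats(-1e4, 1e4))
    def test_shift_invariance_and_normalisation(self, values, shift):
        w1 = mo.akaike_weights(values)
        w2 = mo.akaike_weights([v + shift for v in values])
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w1, w2, atol=1e-9)


def fake_fit(spec, neg2, n=289, converged=True):
    K = 4 + sum(len(spec.covariates(p)) for p in ("psi", "gamma", "epsilon", "p"))
    return SimpleNamespace(
        spec=spec, K=K, neg2loglik=neg2, aicc=mo.aicc(neg2, K, n), converged=converged
    )


class TestRankModels:
    def test_single_model(self):
        table = mo.rank_models([fake_fit(mo.ModelSpec(psi=("size",)), 100.0)])
        assert table["delta_aicc"].iloc[0] == 0.0
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_order_invariance(self):
        fits = [
            fake_fit(mo.ModelSpec(psi=("size",)), 100.0),
            fake_fit(mo.ModelSpec(psi=("matrix",)), 104.0),
            fake_fit(mo.ModelSpec(psi=("size", "matrix")), 99.0),
        ]
        a = mo.rank_models(fits).drop(columns="spec")
        b = mo.rank_models(fits[::-1]).drop(columns="spec")
        pd.testing.assert_frame_equal(a, b)

    def test_nonconverged_excluded_with_warning(self):
        fits = [
            fake_fit(mo.ModelSpec(psi=("size",)), 100.0),
            fake_fit(mo.ModelSpec(psi=("matrix",)), 90.0, converged=False),
        ]
        with pytest.warns(UserWarning, match="non-converged"):
            table = mo.rank_models(fits)
        assert len(table) == 1

    def test_all_nonconverged_is_an_error(self):
        with pytest.raises(ValueError):
            mo.rank_models([fake_fit(mo.ModelSpec(), 1.0, converged=False)])

    def test_delta_against_table_arithmetic(self):
        """Two models at (-2logL, K) = (2906.96, 19) and (2907.01, 18) with
        n=289: the second-ranked model sits 2.24 AICc above the first."""
        fits = [
            SimpleNamespace(spec=mo.ModelSpec(psi=("size",)), K=19, neg2loglik=2906.96,
                            aicc=mo.aicc(2906.96, 19, 289), converged=True),
            SimpleNamespace(spec=mo.ModelSpec(psi=("matrix",)), K=18, neg2loglik=2907.01,
                            aicc=mo.aicc(2907.01, 18, 289), converged=True),
        ]
        table = mo.rank_models(fits)
        assert table["K"].iloc[0] == 18  # the 18-parameter model ranks first
        assert table["delta_aicc"].iloc[1] == pytest.approx(2.24, abs=0.01)


class TestSummedImportance:
    def make_ranking(self, weights_and_specs):
        return pd.DataFrame(
            {
                "spec": [s for _, s in weights_and_specs],
                "weight": [w for w, _ in weights_and_specs],
            }
        )

    def test_in_every_model(self):
        ranking = self.make_ranking(
            [(0.7, mo.ModelSpec(psi=("size",))), (0.3, mo.ModelSpec(psi=("size", "matrix")))]
        )
        value, retained = mo.summed_importance(ranking, "psi", "size")
        assert value == pytest.approx(1.0)
        assert retained

    def test_in_no_model(self):
        ranking = self.make_ranking([(1.0, mo.ModelSpec(psi=("size",)))])
        value, retained = mo.summed_importance(ranking, "psi", "vegetation")
        assert value == 0.0
        assert not retained

    def test_direct_sum_and_retention(self):
        ranking = self.make_ranking(
            [(0.6, mo.ModelSpec(gamma=("matrix",))), (0.4, mo.ModelSpec(gamma=("size",)))]
        )
        value, retained = mo.summed_importance(ranking, "gamma", "matrix")
        assert value == pytest.approx(0.6)
        assert retained

    def test_unknown_covariate_rejected(self):
        ranking = self.make_ranking([(1.0, mo.ModelSpec(psi=("size",)))])
        with pytest.raises(ValueError):
            mo.summed_importance(ranking, "psi", "altitude")


class TestTemporalCandidateSet:
    RETAINED = {
        "psi": ["size", "matrix"],
        "gamma": ["size", "matrix"],
        "epsilon": ["size", "composition", "vegetation", "matrix"],
        "p": ["size", "composition", "matrix"],
    }

    def test_exactly_five_structures(self):
        specs = mo.temporal_candidate_set(self.RETAINED)
        assert len(specs) == 5
        flags = [(s.gamma_time, s.epsilon_time, s.p_time) for s in specs]
        assert flags == [
            (False, True, True), (True, True, True), (False, False, True),
            (True, False, True), (False, False, False),
        ]

    def test_psi_uses_retained_covariates_everywhere(self):
        for spec in mo.temporal_candidate_set(self.RETAINED):
            assert spec.psi == ("size", "matrix")

    def test_parameter_counts_in_printed_order(self, study_patches):
        Ks = [
            mo.build_design_matrices(study_patches, s, 3).K
            for s in mo.temporal_candidate_set(self.RETAINED)
        ]
        assert Ks == [18, 19, 17, 18, 15]

    def test_empty_retained_list_rejected(self):
        retained = dict(self.RETAINED, gamma=[])
        with pytest.raises(ValueError):
            mo.temporal_candidate_set(retained)
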
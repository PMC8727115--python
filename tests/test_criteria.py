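import copy

import numpy as np
import pandas as pd
import pytest

from ndcrfs import Dataset
from ndcrfs.criteria import (
    CRITERION_NAMES,
    SelectionState,
    c_ratio,
    dwfs_update,
    dwur_update,
    make_criterion,
    score_cife,
    score_cmim,
    score_drjmim,
    score_jmi,
    score_mim,
    score_ndcrfs,
)
from ndcrfs.errors import DegenerateInputError, InputError, UnknownFeatureError
from conftest import random_dataset

MI_F1_C = 0.18872187554086706
H_F1_GIVEN_C = 0.8112781244591328
CMI_F3_F1_GIVEN_C = 0.31127812445913294


@pytest.fixture
def toy_state(toy_a):
    """Toy-A with f1 already selected."""
    state = SelectionState(toy_a)
    state.select("f1")
    return state


class TestMIM:
    def test_toy_values(self, toy_a):
        state = SelectionState(toy_a)
        assert score_mim(state, "f3").score == 0.0
        assert score_mim(state, "f1").score == pytest.approx(MI_F1_C, abs=1e-9)

    def test_independent_of_selected_set(self, toy_state, toy_a):
        fresh = SelectionState(toy_a)
        assert score_mim(toy_state, "f2").score == score_mim(fresh, "f2").score

    def test_unknown_feature_rejected(self, toy_state):
        with pytest.raises(UnknownFeatureError):
            score_mim(toy_state, "nope")
        with pytest.raises(UnknownFeatureError):
            score_mim(toy_state, "f1")  # already selected


class TestCIFEJMICMIM:
    def test_empty_s_reduces_to_mim(self, toy_a):
        state = SelectionState(toy_a)
        for scorer in (score_cife, score_jmi, score_cmim, score_ndcrfs, score_drjmim):
            assert scorer(state, "f1").score == pytest.approx(MI_F1_C, abs=0.0)

    def test_toy_duplicate_and_balanced_candidates(self, toy_state):
        # duplicate: 0.1887 - (1.0 - 0.8113) ~ 0
        assert score_cife(toy_state, "f2").score == pytest.approx(
            MI_F1_C - (1.0 - H_F1_GIVEN_C), abs=1e-9
        )
        # class-balanced: 0 - (0.1887 - 0.3113) = +0.1226
        expected_f3 = -(MI_F1_C - CMI_F3_F1_GIVEN_C)
        assert score_cife(toy_state, "f3").score == pytest.approx(expected_f3, abs=1e-9)
        # |S| = 1: JMI and CMIM coincide with CIFE
        for f in ("f2", "f3"):
            assert score_jmi(toy_state, f).score == pytest.approx(
                score_cife(toy_state, f).score, abs=1e-12
            )
            assert score_cmim(toy_state, f).score == pytest.approx(
                score_cife(toy_state, f).score, abs=1e-12
            )

    def test_jmi_averages_and_cmim_maxes_brute_force(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, n_samples=30, n_features=4)
        state = SelectionState(ds)
        state.select("f0")
        state.select("f1")
        state.select("f2")
        fresh = SelectionState(ds)  # no-cache style recomputation path
        terms = [fresh.interaction("f3", s) for s in ("f0", "f1", "f2")]
        assert score_jmi(state, "f3").score == pytest.approx(
            fresh.mi_class("f3") - float(np.mean(terms)), abs=1e-9
        )
        assert score_cmim(state, "f3").score == pytest.approx(
            fresh.mi_class("f3") - max(terms), abs=1e-9
        )
        assert score_cife(state, "f3").score == pytest.approx(
            fresh.mi_class("f3") - sum(terms), abs=1e-9
        )


class TestCRatioAndWeights:
    def test_c_ratio_zero_when_relevance_unchanged(self, toy_a):
        # conditioning on a constant leaves relevance unchanged exactly
        frame = toy_a.frame.assign(const=0)
        state = SelectionState(Dataset(frame, kinds={"const": "discrete"}))
        state.select("const")
        assert c_ratio(state, "f1", "const") == pytest.approx(0.0, abs=1e-12)

    def test_c_ratio_xor_is_plus_one(self, xor_dataset):
        state = SelectionState(xor_dataset)
        state.select("y")
        # 2*(1-0)/(1+1)
        assert c_ratio(state, "x", "y") == pytest.approx(1.0, abs=1e-12)

    def test_dwfs_multiplier_examples(self, xor_dataset, toy_a):
        state = SelectionState(xor_dataset)
        state.select("y")
        assert dwfs_update(state, "x", "y") == pytest.approx(2.0, abs=1e-12)
        # unchanged relevance -> multiplier 1 (weight stays 1): noise bit z
        assert dwfs_update(state, "z", "y") == pytest.approx(1.0, abs=1e-12)
        # Toy-A duplicate: conditional relevance collapses -> multiplier < 1
        tstate = SelectionState(toy_a)
        tstate.select("f1")
        assert dwfs_update(tstate, "f2", "f1") < 1.0
        assert c_ratio(tstate, "f2", "f1") < 0.0

    def test_dwur_update_reductions(self, xor_dataset):
        # beta = 0 and C_Ratio = 0 -> multiplier = I(f_k;C)
        state = SelectionState(xor_dataset, beta=0.0)
        state.select("y")
        w = dwur_update(state, "z", "y")
        assert w == pytest.approx(state.mi_class("z"), abs=1e-12)

    def test_dwur_redundancy_factor(self):
        # beta = 1 and f_new a duplicate of f_k (balanced binary): 1 - H(f_k) = 0
        frame = pd.DataFrame({
            "a": [0, 1, 0, 1, 0, 1, 0, 1],
            "b": [0, 1, 0, 1, 0, 1, 0, 1],
            "class": [0, 0, 1, 1, 0, 1, 1, 0],
        })
        state = SelectionState(Dataset(frame), beta=1.0)
        state.select("b")
        assert dwur_update(state, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_denominator_raises(self):
        frame = pd.DataFrame({"a": [0, 0, 0, 0], "b": [0, 1, 0, 1], "class": [0, 0, 0, 0]})
        state = SelectionState(Dataset(frame, kinds={"class": "discrete"}))
        state.select("b")
        with pytest.raises(DegenerateInputError):
            c_ratio(state, "a", "b")


class TestDRJMIM:
    def test_single_selected_matches_direct_formula(self, toy_state):
        for f in ("f2", "f3"):
            s = "f1"
            expected = toy_state.interaction(f, s) * (
                toy_state.mi_class(f) + c_ratio(toy_state, f, s) * toy_state.mi_class(s)
            )
            assert score_drjmim(toy_state, f).score == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_min_over_selected(self):
        rng = np.random.default_rng(23)
        ds = random_dataset(rng, n_samples=25, n_features=5)
        state = SelectionState(ds)
        for s in ("f0", "f2", "f4"):
            state.select(s)
        for f in ("f1", "f3"):
            brute = min(
                state.interaction(f, s)
                * (state.mi_class(f) + c_ratio(state, f, s) * state.mi_class(s))
                for s in ("f0", "f2", "f4")
            )
            assert score_drjmim(state, f).score == pytest.approx(brute, abs=1e-12)


class TestNDCRFS:
    def test_toy_duplicate_rejected(self, toy_state):
        # composed from the estimator oracles:
        # 0.1887 - 1.2326*(0.8113 - 0.1887) and 0 - 2/(0.8113+1)*(0.3113-0.1887)
        cu_dup = 2.0 / (2 * H_F1_GIVEN_C)
        expected_f2 = MI_F1_C - cu_dup * (H_F1_GIVEN_C - MI_F1_C)
        cu_f3 = 2.0 / (H_F1_GIVEN_C + 1.0)
        expected_f3 = -cu_f3 * (CMI_F3_F1_GIVEN_C - MI_F1_C)
        assert score_ndcrfs(toy_state, "f2").score == pytest.approx(expected_f2, abs=1e-9)
        assert score_ndcrfs(toy_state, "f3").score == pytest.approx(expected_f3, abs=1e-9)
        assert expected_f2 == pytest.approx(-0.579, abs=1e-3)
        assert expected_f3 == pytest.approx(-0.135, abs=1e-3)
        # the duplicate never outranks the class-balanced feature
        assert score_ndcrfs(toy_state, "f3").score > score_ndcrfs(toy_state, "f2").score

    def test_conditionally_coupled_partner_is_penalized(self, xor_dataset):
        """Eq-faithful behavior: the criterion charges I(f_k;f_select|C), which is
        maximal for an XOR partner, so the partner scores *below* independent
        noise once its trigger is selected (the conditional coupling term does
        not distinguish synergy from redundancy)."""
        state = SelectionState(xor_dataset)
        state.select("y")
        assert score_ndcrfs(state, "x").score < score_ndcrfs(state, "z").score
        assert score_ndcrfs(state, "x").score == pytest.approx(-1.0, abs=1e-9)


class TestSynergyProperty:
    def test_pairwise_synergy_criteria_reward_xor_partner(self, xor_dataset):
        """With the trigger selected, CMIM/CIFE/JMI score the partner strictly
        above an independent noise bit; MIM scores them equally."""
        state = SelectionState(xor_dataset)
        state.select("y")
        for scorer in (score_cmim, score_cife, score_jmi):
            assert scorer(state, "x").score > scorer(state, "z").score
        assert score_mim(state, "x").score == pytest.approx(
            score_mim(state, "z").score, abs=1e-12
        )


class TestStateContract:
    def test_scoring_never_mutates_state(self, toy_state):
        before = (
            list(toy_state.selected),
            list(toy_state.candidates),
            dict(toy_state.weights),
        )
        for name in CRITERION_NAMES:
            make_criterion(name).score(toy_state, "f2")
        assert before == (
            list(toy_state.selected),
            list(toy_state.candidates),
            dict(toy_state.weights),
        )

    def test_cache_matches_fresh_recomputation(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng)
        cached = SelectionState(ds)
        uncached = SelectionState(ds, use_cache=False)
        feats = ds.feature_names
        for f in feats:
            for g in feats:
                if f == g:
                    continue
                assert cached.mi(f, g) == uncached.mi(f, g)
                assert cached.cmi_given_class(f, g) == uncached.cmi_given_class(f, g)
                assert cached.cmi_class_given(f, g) == uncached.cmi_class_given(f, g)
        # cache actually caches; the no-cache path recomputes every call
        assert cached.pair_evals < uncached.pair_evals

    def test_unknown_criterion_name(self):
        with pytest.raises(InputError):
            make_criterion("igrfe")
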
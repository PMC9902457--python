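"""Choice-model values, softmax probabilities and likelihoods."""

import math

import numpy as np
import pandas as pd
import pytest

from hedoseek.choice_models import (
    ChoiceParams,
    center_covariates,
    choice_loglik,
    choice_probability,
    simulate_choices,
    source_value,
)


def make_frame(nAccA, nPosA, nAccB, nPosB, chose_A=None, participant=0):
    df = pd.DataFrame(
        dict(
            participant_id=participant,
            nAccA=nAccA, nPosA=nPosA, nAccB=nAccB, nPosB=nPosB,
        )
    )
    if chose_A is not None:
        df["chose_A"] = chose_A
    return df


class TestCenterCovariates:
    def test_constant_goes_to_zero(self):
        df = make_frame([4, 4], [1, 2], [4, 4], [3, 2], [1, 0])
        out, offsets = center_covariates(df)
        assert np.allclose(out["nAccA_c"], 0.0)
        assert offsets["nAcc"] == 4.0

    def test_symmetric_values(self):
        df = make_frame([3, 5], [0, 0], [5, 3], [0, 0])
        out, _ = center_covariates(df)
        assert sorted(out["nAccA_c"]) == [-1.0, 1.0]

    def test_idempotent(self):
        df = make_frame([3, 5, 4], [0, 2, 4], [5, 3, 4], [2, 4, 0], [1, 0, 1])
        once, off1 = center_covariates(df)
        renamed = once.copy()
        renamed[["nAccA", "nPosA", "nAccB", "nPosB"]] = once[
            ["nAccA_c", "nPosA_c", "nAccB_c", "nPosB_c"]]
        twice, off2 = center_covariates(renamed)
        assert np.allclose(twice["nAccA_c"], once["nAccA_c"])
        assert off2["nAcc"] == pytest.approx(0.0)

    def test_offsets_recoverable(self):
        df = make_frame([3, 5, 4], [0, 2, 4], [5, 3, 4], [2, 4, 0])
        out, offsets = center_covariates(df)
        assert np.allclose(out["nAccA_c"] + offsets["nAcc"], df["nAccA"])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            center_covariates(make_frame([], [], [], []))

    def test_mean_pools_both_sources(self):
        df = make_frame([3, 3], [0, 0], [5, 5], [0, 0])
        _, offsets = center_covariates(df)
        assert offsets["nAcc"] == 4.0


class TestSourceValue:
    def test_accpos_arithmetic(self):
        p = ChoiceParams(k_Acc=1.0, k_Pos=0.5, beta=1.0)
        assert source_value("accpos", p, 1.0, 2.0) == pytest.approx(2.0)

    def test_pos_only_zero_weight(self):
        p = ChoiceParams(k_Pos=0.0, beta=1.0)
        assert source_value("pos", p, 3.0, -2.0) == 0.0

    def test_tiebreak_reduces_to_acc_when_unequal(self):
        p = ChoiceParams(k_Acc=1.3, k_Pos=0.7, beta=1.0)
        v_tb = source_value("tiebreak", p, 0.5, 1.5, EQ=0.0)
        v_acc = source_value("acc", p, 0.5, 1.5)
        assert v_tb == pytest.approx(v_acc)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            source_value("bogus", ChoiceParams(), 0, 0)


class TestChoiceProbability:
    def test_equal_values(self):
        assert choice_probability(1.7, 1.7, 3.0) == pytest.approx(0.5)

    def test_beta_zero(self):
        assert choice_probability(10.0, -10.0, 0.0) == pytest.approx(0.5)

    def test_unit_difference(self):
        assert choice_probability(1.0, 0.0, 1.0) == pytest.approx(0.7311, abs=1e-4)

    def test_bounds_error(self):
        with pytest.raises(ValueError):
            choice_probability(1.0, 0.0, 5.5)
        with pytest.raises(ValueError):
            choice_probability(1.0, 0.0, -0.1)

    def test_sums_to_one_and_monotone(self, rng):
        vx = rng.normal(size=50)
        vy = rng.normal(size=50)
        p = choice_probability(vx, vy, 2.0)
        q = choice_probability(vy, vx, 2.0)
        assert np.allclose(p + q, 1.0)
        diffs = np.linspace(-3, 3, 20)
        probs = choice_probability(diffs, 0.0, 2.0)
        assert np.all(np.diff(probs) > 0)

    def test_numerically_stable_extremes(self):
        assert choice_probability(1000.0, -1000.0, 5.0) == pytest.approx(1.0)
        assert choice_probability(-1000.0, 1000.0, 5.0) == pytest.approx(0.0)


def centered(df):
    out, _ = center_covariates(df)
    return out


class TestChoiceLoglik:
    def test_beta_zero(self):
        df = centered(make_frame([3, 4, 5], [0, 1, 2], [4, 5, 3], [1, 2, 0],
                                 [1, 0, 1]))
        p = ChoiceParams(k_Acc=2.0, k_Pos=1.0, beta=0.0)
        total, per = choice_loglik("accpos", p, df)
        assert total == pytest.approx(3 * math.log(0.5))
        assert np.allclose(per, math.log(0.5))

    def test_single_trial_value(self):
        # value difference of exactly 1 at beta=1 -> P = expit(1)
        df = make_frame([4], [0], [3], [0], [1])
        df, _ = center_covariates(df)
        p = ChoiceParams(k_Acc=1.0, k_Pos=0.0, beta=1.0)
        total, _ = choice_loglik("accpos", p, df)
        assert total == pytest.approx(math.log(1 / (1 + math.exp(-1))), abs=1e-6)
        assert total == pytest.approx(-0.3133, abs=1e-4)

    def test_label_swap_symmetry(self, rng):
        df = make_frame(rng.integers(3, 6, 20), rng.integers(0, 6, 20),
                        rng.integers(3, 6, 20), rng.integers(0, 6, 20),
                        rng.integers(0, 2, 20))
        dfc = centered(df)
        p = ChoiceParams(k_Acc=1.2, k_Pos=0.4, beta=2.0)
        t1, _ = choice_loglik("accpos", p, dfc)
        swapped = df.rename(columns={"nAccA": "nAccB", "nAccB": "nAccA",
                                     "nPosA": "nPosB", "nPosB": "nPosA"})
        swapped["chose_A"] = 1 - swapped["chose_A"]
        t2, _ = choice_loglik("accpos", p, centered(swapped))
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_brute_force_oracle(self, rng):
        """Per-trial recomputation with plain math.exp, to 1e-10."""
        df = make_frame(rng.integers(3, 6, 30), rng.integers(0, 6, 30),
                        rng.integers(3, 6, 30), rng.integers(0, 6, 30),
                        rng.integers(0, 2, 30))
        dfc = centered(df)
        for model in ("accpos", "acc", "pos", "tiebreak"):
            p = ChoiceParams(k_Acc=rng.normal(), k_Pos=rng.normal(),
                             beta=float(rng.uniform(0, 5)))
            total, per = choice_loglik(model, p, dfc)
            expected = []
            for _, row in dfc.iterrows():
                eq = float(row["nAccA"] == row["nAccB"])
                va = dict(
                    accpos=p.k_Acc * row["nAccA_c"] + p.k_Pos * row["nPosA_c"],
                    acc=p.k_Acc * row["nAccA_c"],
                    pos=p.k_Pos * row["nPosA_c"],
                    tiebreak=p.k_Acc * row["nAccA_c"] + p.k_Pos * row["nPosA_c"] * eq,
                )[model]
                vb = dict(
                    accpos=p.k_Acc * row["nAccB_c"] + p.k_Pos * row["nPosB_c"],
                    acc=p.k_Acc * row["nAccB_c"],
                    pos=p.k_Pos * row["nPosB_c"],
                    tiebreak=p.k_Acc * row["nAccB_c"] + p.k_Pos * row["nPosB_c"] * eq,
                )[model]
                # log softmax via explicit max-shift (independent of the
                # log1p-based implementation)
                chosen = va if row["chose_A"] == 1 else vb
                m = max(p.beta * va, p.beta * vb)
                log_denom = m + math.log(
                    math.exp(p.beta * va - m) + math.exp(p.beta * vb - m))
                expected.append(p.beta * chosen - log_denom)
            assert np.allclose(per, expected, atol=1e-10)
            assert total == pytest.approx(sum(expected), abs=1e-8)

    def test_nesting_accpos_equals_acc(self, rng):
        df = centered(make_frame(rng.integers(3, 6, 25), rng.integers(0, 6, 25),
                                 rng.integers(3, 6, 25), rng.integers(0, 6, 25),
                                 rng.integers(0, 2, 25)))
        p = ChoiceParams(k_Acc=1.5, k_Pos=0.0, beta=3.0)
        t1, _ = choice_loglik("accpos", p, df)
        t2, _ = choice_loglik("acc", p, df)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_missing_choice_errors(self):
        df = centered(make_frame([3], [0], [4], [1]))
        with pytest.raises(ValueError, match="chose_A"):
            choice_loglik("accpos", ChoiceParams(), df)


class TestSimulateChoices:
    def test_deterministic(self):
        df = centered(make_frame([3, 4] * 10, [0, 1] * 10, [4, 5] * 10,
                                 [1, 2] * 10))
        p = ChoiceParams(k_Acc=1.0, k_Pos=0.5, beta=2.0)
        a = simulate_choices("accpos", p, df, np.random.default_rng(3))
        b = simulate_choices("accpos", p, df, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_beta_zero_near_half(self):
        df = centered(make_frame([3] * 10_000, [0] * 10_000, [5] * 10_000,
                                 [2] * 10_000))
        p = ChoiceParams(k_Acc=3.0, k_Pos=1.0, beta=0.0)
        sim = simulate_choices("accpos", p, df, np.random.default_rng(4))
        assert abs(sim["chose_A"].mean() - 0.5) < 0.02

    def test_softmax_saturation(self):
        df = centered(make_frame([5] * 10_000, [2] * 10_000, [3] * 10_000,
                                 [2] * 10_000))
        p = ChoiceParams(k_Acc=10.0, k_Pos=0.0, beta=5.0)
        sim = simulate_choices("accpos", p, df, np.random.default_rng(5))
        assert sim["chose_A"].mean() > 0.99
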
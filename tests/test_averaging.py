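"""Model lattice, BIC weights, averaging algebra and fitting paths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suspicion.averaging import (
    ModelFitResult,
    average_estimates,
    bic_weights,
    ci_overlap,
    enumerate_models,
    fit_participant_profiles,
    fit_suspicion_model,
    model_average,
    significance_by_ci,
)
from suspicion.cues import CUE_NAMES, add_cues
from suspicion.simulate import simulate_study


class TestModelLattice:
    @pytest.mark.parametrize("k, expected", [(1, 1), (2, 3), (3, 7), (4, 15)])
    def test_lattice_size(self, k, expected):
        assert len(enumerate_models(CUE_NAMES[:k])) == expected

    def test_order_is_by_size_then_lexicographic(self):
        subsets = enumerate_models(("b", "a"))
        assert subsets == [("a",), ("b",), ("a", "b")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models(("own_lie", "own_lie"))


class TestBicWeights:
    def test_equal_evidence_splits_evenly(self):
        np.testing.assert_allclose(bic_weights([100.0, 100.0]), [0.5, 0.5])
        np.testing.assert_allclose(bic_weights([100.0]), [1.0])

    def test_two_point_bic_gap(self):
        # delta BIC of 2 -> weight ratio e
        w = bic_weights([100.0, 102.0])
        e = np.exp(1.0)
        np.testing.assert_allclose(w, [e / (1 + e), 1 / (1 + e)], atol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=15),
           st.floats(-1000, 1000))
    @settings(max_examples=50, deadline=None)
    def test_sum_one_and_shift_invariance(self, bics, shift):
        w = bic_weights(bics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, bic_weights(np.asarray(bics) + shift), atol=1e-9)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bic_weights([])
        with pytest.raises(ValueError):
            bic_weights([1.0, np.inf])


def _fit(subset, betas, ses, bic, converged=True):
    return ModelFitResult(tuple(subset), dict(betas), dict(ses), bic, converged, 100)


class TestAveraging:
    def test_two_equal_models_average_their_betas(self):
        fits = [
            _fit(("signed_ev",), {"signed_ev": 0.2}, {"signed_ev": 0.01}, 50.0),
            _fit(("lost", "signed_ev"), {"signed_ev": 0.4, "lost": 0.1},
                 {"signed_ev": 0.01, "lost": 0.01}, 50.0),
        ]
        estimates, weights = average_estimates(fits, cue_names=("signed_ev", "lost"))
        assert estimates["signed_ev"].weighted_beta == pytest.approx(0.3)
        # the model omitting 'lost' contributes beta 0 at half weight
        assert estimates["lost"].weighted_beta == pytest.approx(0.05)
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_dominating_model_takes_all_weight(self):
        fits = [
            _fit(("signed_ev",), {"signed_ev": 0.7}, {"signed_ev": 0.02}, 10.0),
            _fit(("unsigned_ev",), {"unsigned_ev": 0.3}, {"unsigned_ev": 0.02}, 80.0),
        ]
        estimates, _ = average_estimates(fits, cue_names=("signed_ev", "unsigned_ev"))
        assert estimates["signed_ev"].weighted_beta == pytest.approx(0.7, abs=1e-8)
        assert estimates["unsigned_ev"].weighted_beta == pytest.approx(0.0, abs=1e-8)

    def test_nonconverged_fits_are_excluded_from_weights(self):
        fits = [
            _fit(("signed_ev",), {"signed_ev": 0.5}, {"signed_ev": 0.02}, 20.0),
            _fit(("unsigned_ev",), {"unsigned_ev": 9.9}, {"unsigned_ev": 0.02},
                 5.0, converged=False),
        ]
        estimates, weights = average_estimates(fits, cue_names=("signed_ev", "unsigned_ev"))
        assert list(weights) == [("signed_ev",)]
        assert estimates["signed_ev"].weighted_beta == pytest.approx(0.5)


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "lo, hi, sig",
        [
            (0.033, 0.054, True),        # reported-style interval clear of zero
            (-0.0004, 0.0004, False),    # rounds to [0.000, 0.000]
            (0.0, 0.0, False),
            (0.0006, 0.01, True),        # lower bound rounds to 0.001
            (-0.01, 0.2, False),
        ],
    )
    def test_three_decimal_rounding_rule(self, lo, hi, sig):
        assert significance_by_ci(lo, hi) is sig

    @pytest.mark.parametrize(
        "a, b, overlap",
        [((0.1, 0.3), (0.4, 0.5), False),
         ((0.0, 0.2), (0.1, 0.3), True),
         ((0.1, 0.2), (0.2, 0.3), True)],  # shared endpoint counts as overlap
    )
    def test_ci_overlap(self, a, b, overlap):
        assert ci_overlap(a, b) is overlap


class TestSingleUnitFits:
    def test_perfect_linear_relation_gives_unit_beta(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"participant_id": 1, "signed_ev": x, "suspicion": 0.5 * x})
        fit = fit_suspicion_model(df, ("signed_ev",), level="single-unit")
        assert fit.betas["signed_ev"] == pytest.approx(1.0, abs=1e-8)

    def test_beta_matches_hand_computed_ols_slope(self):
        # five hand-picked rows; slope of z(y) on z(x) = pearson r
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        y = np.array([0.2, 0.8, 0.4, 0.6, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        df = pd.DataFrame({"participant_id": 1, "lost": x, "suspicion": y})
        fit = fit_suspicion_model(df, ("lost",), level="single-unit")
        assert fit.betas["lost"] == pytest.approx(r, abs=1e-10)

    def test_constant_cue_gets_zero_beta_by_convention(self, rng):
        df = pd.DataFrame({
            "participant_id": 1,
            "own_lie": np.zeros(50),
            "signed_ev": rng.normal(size=50),
        })
        df["suspicion"] = 0.3 * df["signed_ev"] + rng.normal(0, 0.1, 50)
        fit = fit_suspicion_model(df, ("own_lie", "signed_ev"), level="single-unit")
        assert fit.betas["own_lie"] == 0.0
        assert fit.ses["own_lie"] == 0.0
        assert "own_lie" in fit.degenerate
        assert fit.betas["signed_ev"] > 0.5


class TestGroupFits:
    def test_group_mixed_needs_multiple_participants(self, rng):
        df = pd.DataFrame({"participant_id": 1, "signed_ev": rng.normal(size=30)})
        df["suspicion"] = df["signed_ev"]
        with pytest.raises(ValueError, match="two participants"):
            fit_suspicion_model(df, ("signed_ev",), level="group-mixed")

    def test_group_and_pooled_fits_agree_on_small_cohort(self, exp1_cohort):
        sub = exp1_cohort[exp1_cohort["participant_id"] <= 10]
        mixed = fit_suspicion_model(sub, ("signed_ev", "unsigned_ev"),
                                    level="group-mixed")
        pooled = fit_suspicion_model(sub, ("signed_ev", "unsigned_ev"),
                                     level="single-unit")
        assert mixed.converged
        # fixed effects track the pooled slopes up to shrinkage
        for cue in ("signed_ev", "unsigned_ev"):
            assert mixed.betas[cue] == pytest.approx(pooled.betas[cue], abs=0.1)

    def test_noise_cue_is_shrunk_by_the_lattice(self, rng):
        # a pure-noise cue: averaging downweights models containing it
        n = 600
        df = pd.DataFrame({
            "participant_id": np.repeat(np.arange(6), 100),
            "signed_ev": rng.normal(size=n),
            "lost": rng.integers(0, 2, size=n).astype(float),
        })
        df["suspicion"] = 0.4 * df["signed_ev"] + rng.normal(0, 0.3, n)
        single = fit_suspicion_model(df, ("lost",), level="single-unit")
        result = model_average(df, level="single-unit", cue_names=("lost", "signed_ev"))
        averaged = abs(result.estimates["lost"].weighted_beta)
        assert averaged <= abs(single.betas["lost"]) + 1e-12
        assert not result.estimates["lost"].significant
        assert result.estimates["signed_ev"].significant


class TestParticipantProfiles:
    def test_zero_convention_for_never_lied_and_never_lost(self, rng):
        trials = add_cues(simulate_study(1, seed=77, n_participants=8))
        pid = trials["participant_id"].unique()[0]
        mask = trials["participant_id"] == pid
        trials.loc[mask, "own_lie"] = 0
        trials.loc[mask, "lost"] = 0
        profiles = fit_participant_profiles(trials)
        row = profiles.set_index("participant_id").loc[pid]
        assert row["beta_own_lie"] == 0.0
        assert row["beta_lost"] == 0.0
        assert row["reliable"]

    def test_single_cue_driver_dominates_profile(self, rng):
        n = 90
        sev = rng.normal(size=n)
        df = pd.DataFrame({
            "participant_id": 1,
            "own_lie": rng.integers(0, 2, n).astype(float),
            "signed_ev": rng.normal(size=n),
            "unsigned_ev": sev,
            "lost": rng.integers(0, 2, n).astype(float),
            "suspicion": 0.6 * sev,
        })
        profiles = fit_participant_profiles(df)
        row = profiles.iloc[0]
        assert row["beta_unsigned_ev"] > 0.9
        for other in ("beta_own_lie", "beta_signed_ev", "beta_lost"):
            assert abs(row[other]) < 0.1
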
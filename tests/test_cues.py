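"""Cue computation, suspicion coding, outcomes and exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from suspicion.cues import (
    add_cues,
    apply_exclusions,
    compute_cues,
    dichotomize_rating,
    rating_to_suspicion,
    signed_expectation_violation,
    suspicion_to_rating,
    unsigned_expectation_violation,
)
from suspicion.task import BLUE, RED, CardSet, CardTrial, trial_outcome


def make_trial(n_blue=3, partner_report=RED, own_pick=BLUE, own_report=BLUE,
               rating=4, pid=1):
    return CardTrial(
        participant_id=pid, trial_index=1, block=1, stakes="none",
        card_set=CardSet(n_blue, 7 - n_blue), own_pick_colour=own_pick,
        own_report_colour=own_report, own_lied=int(own_pick != own_report),
        partner_report_colour=partner_report,
        partner_lied=0, outcome=trial_outcome(own_report, partner_report),
        honesty_rating=rating,
    )


class TestExpectationViolation:
    @pytest.mark.parametrize(
        "n_blue, report, signed, unsigned",
        [
            (3, RED, -0.429, 0.429),     # worked example: improbable-but-unfavourable red
            (3, BLUE, 4 / 7, 4 / 7),     # blue report against 3 blue cards
            (6, BLUE, 1 / 7, 1 / 7),     # likely blue: little surprise
            (1, BLUE, 6 / 7, 6 / 7),     # improbable self-favourable report
            (6, RED, -6 / 7, 6 / 7),     # improbable but self-damaging
        ],
    )
    def test_worked_examples(self, n_blue, report, signed, unsigned):
        cs = CardSet(n_blue, 7 - n_blue)
        assert signed_expectation_violation(cs, report) == pytest.approx(signed, abs=5e-4)
        assert unsigned_expectation_violation(cs, report) == pytest.approx(unsigned, abs=5e-4)

    @given(n_blue=st.integers(1, 6), report_blue=st.booleans())
    def test_unsigned_is_magnitude_of_signed(self, n_blue, report_blue):
        cs = CardSet(n_blue, 7 - n_blue)
        report = BLUE if report_blue else RED
        s = signed_expectation_violation(cs, report)
        u = unsigned_expectation_violation(cs, report)
        assert u == pytest.approx(abs(s))
        # sign tracks the reported colour's value; magnitude is 1 - p
        assert np.sign(s) == (1 if report_blue else -1)
        assert u == pytest.approx(1 - cs.colour_fraction(report))

    def test_compute_cues_mirrors_trial_fields(self):
        trial = make_trial(own_pick=RED, own_report=BLUE, partner_report=BLUE)
        cv = compute_cues(trial)
        assert cv.own_lie == 1
        assert cv.lost == 0  # both reported blue -> tie
        lost_trial = make_trial(own_pick=RED, own_report=RED, partner_report=BLUE)
        assert compute_cues(lost_trial).lost == 1


class TestSuspicionCoding:
    @pytest.mark.parametrize("rating, suspicion", [(1, 1.0), (6, 0.0), (4, 0.4)])
    def test_reverse_coding(self, rating, suspicion):
        assert rating_to_suspicion(rating) == pytest.approx(suspicion)

    @pytest.mark.parametrize("rating, flag", [(1, 1), (3, 1), (4, 0), (6, 0)])
    def test_dichotomisation(self, rating, flag):
        assert dichotomize_rating(rating) == flag

    @pytest.mark.parametrize("rating", range(1, 7))
    def test_round_trip_and_threshold_consistency(self, rating):
        s = rating_to_suspicion(rating)
        assert suspicion_to_rating(s) == rating
        assert dichotomize_rating(rating) == int(s > 0.5)

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            rating_to_suspicion(bad)
        with pytest.raises(ValueError):
            dichotomize_rating(bad)


class TestTrialOutcome:
    @pytest.mark.parametrize(
        "own, partner, expected",
        [(BLUE, RED, "win"), (RED, BLUE, "lose"), (RED, RED, "tie"), (BLUE, BLUE, "tie")],
    )
    def test_outcomes(self, own, partner, expected):
        assert trial_outcome(own, partner) == expected

    @given(a=st.sampled_from([RED, BLUE]), b=st.sampled_from([RED, BLUE]))
    def test_antisymmetry(self, a, b):
        mine, theirs = trial_outcome(a, b), trial_outcome(b, a)
        if mine == "tie":
            assert theirs == "tie"
        else:
            assert {mine, theirs} == {"win", "lose"}


class TestVectorisedCues:
    def test_add_cues_matches_scalar_path(self, exp1_cohort):
        sample = exp1_cohort.sample(40, random_state=0)
        for _, row in sample.iterrows():
            trial = CardTrial(
                participant_id=row.participant_id, trial_index=row.trial,
                block=row.block, stakes=row.stakes,
                card_set=CardSet(int(row.n_blue), int(row.n_red)),
                own_pick_colour=row.pick, own_report_colour=row.report,
                own_lied=int(row.own_lied), partner_report_colour=row.partner_report,
                partner_lied=int(row.partner_lied), outcome=row.outcome,
                honesty_rating=int(row.rating),
            )
            cv = compute_cues(trial)
            assert row.signed_ev == pytest.approx(cv.signed_ev)
            assert row.unsigned_ev == pytest.approx(cv.unsigned_ev)
            assert row.own_lie == cv.own_lie
            assert row.lost == cv.lost
            assert row.suspicion == pytest.approx(rating_to_suspicion(int(row.rating)))

    def test_malformed_card_sets_rejected(self, exp1_cohort):
        broken = exp1_cohort.copy()
        broken.loc[broken.index[0], "n_blue"] = 0
        with pytest.raises(ValueError, match="malformed"):
            add_cues(broken)


class TestExclusions:
    def _table(self, ratings_by_pid, attn=None):
        rows = []
        for pid, ratings in ratings_by_pid.items():
            for i, r in enumerate(ratings):
                row = {"participant_id": pid, "trial": i + 1, "rating": r}
                if attn:
                    row["attn_failed"], row["attn_total"] = attn[pid]
                rows.append(row)
        return pd.DataFrame(rows)

    def test_flat_rater_excluded(self):
        table = self._table({1: [5] * 10, 2: [1, 2, 3, 4, 5, 6, 1, 2, 3, 4]})
        kept, log = apply_exclusions(table)
        assert set(kept["participant_id"]) == {2}
        assert log[0]["reason"] == "near-zero rating variance"

    @pytest.mark.parametrize("failed, excluded", [(3, True), (2, False), (9, True)])
    def test_attention_threshold(self, failed, excluded):
        table = self._table({1: [1, 2, 3, 4, 5, 6] * 2}, attn={1: (failed, 9)})
        kept, log = apply_exclusions(table)
        assert kept.empty == excluded
        if excluded:
            assert log[0]["reason"] == "failed attention checks"

    def test_attention_threshold_scales_to_six_checks(self):
        # two of six failed meets the one-third rule
        table = self._table({1: [1, 2, 3, 4, 5, 6] * 2}, attn={1: (2, 6)})
        kept, _ = apply_exclusions(table)
        assert kept.empty
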
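"""Trial-level suspicion values, cue regressors, and participant exclusions.

Four cues are hypothesised to drive suspicion of the partner's report:

* ``own_lie`` — self-projection: did the assessor lie on this trial?
* ``signed_ev`` — signed expectation violation: the reported colour's
  value (red = -1, blue = +1) minus its expected value, i.e.
  ``v * (1 - p)`` with ``p`` the reported colour's card fraction.
  Positive when the report is improbable *and* self-favourable.
* ``unsigned_ev`` — unsigned expectation violation: ``1 - p``, surprise
  irrespective of benefit.
* ``lost`` — motivation: did the assessor lose the trial?

Honesty ratings (1..6, 1 = completely dishonest) are reverse-coded to a
suspicion value on [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import BLUE, COLOUR_VALUE, CardSet, trial_outcome  # noqa: F401

#: Canonical cue order used by every downstream stage.
CUE_NAMES = ("own_lie", "signed_ev", "unsigned_ev", "lost")


@dataclass(frozen=True)
class CueVector:
    """The four suspicion cues for a single trial."""

    own_lie: int
    signed_ev: float
    unsigned_ev: float
    lost: int

    def as_dict(self) -> dict[str, float]:
        return {
            "own_lie": float(self.own_lie),
            "signed_ev": self.signed_ev,
            "unsigned_ev": self.unsigned_ev,
            "lost": float(self.lost),
        }


def signed_expectation_violation(card_set: CardSet, reported_colour: str) -> float:
    """``v - v*p = v*(1 - p)`` for reported-colour value ``v`` and card fraction ``p``."""
    v = COLOUR_VALUE[reported_colour]
    p = card_set.colour_fraction(reported_colour)
    return v - v * p


def unsigned_expectation_violation(card_set: CardSet, reported_colour: str) -> float:
    """``1 - p``: the surprise of seeing the reported colour, sign-free."""
    return 1.0 - card_set.colour_fraction(reported_colour)


def compute_cues(trial) -> CueVector:
    """Cue vector for one trial (any object with CardTrial's fields)."""
    card_set = trial.card_set
    report = trial.partner_report_colour
    return CueVector(
        own_lie=int(trial.own_lied),
        signed_ev=signed_expectation_violation(card_set, report),
        unsigned_ev=unsigned_expectation_violation(card_set, report),
        lost=int(trial.outcome == "lose"),
    )


def add_cues(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised cue computation over a canonical trial table.

    Adds ``own_lie``, ``signed_ev``, ``unsigned_ev``, ``lost`` and
    ``suspicion`` columns; input is not modified.
    """
    out = trials.copy()
    n_blue = out["n_blue"].to_numpy(dtype=float)
    n_red = out["n_red"].to_numpy(dtype=float)
    if np.any(n_blue + n_red != 7) or np.any(n_blue < 1) or np.any(n_red < 1):
        bad = np.nonzero((n_blue + n_red != 7) | (n_blue < 1) | (n_red < 1))[0]
        raise ValueError(f"malformed card sets at rows {bad.tolist()[:10]}")
    report_blue = out["partner_report"].to_numpy() == BLUE
    v = np.where(report_blue, 1.0, -1.0)
    p = np.where(report_blue, n_blue, n_red) / 7.0
    out["own_lie"] = out["own_lied"].astype(int)
    out["signed_ev"] = v * (1.0 - p)
    out["unsigned_ev"] = 1.0 - p
    out["lost"] = (out["outcome"] == "lose").astype(int)
    out["suspicion"] = (6 - out["rating"].astype(int)) / 5.0
    return out


def rating_to_suspicion(rating: int) -> float:
    """Reverse-code a 1..6 honesty rating to suspicion on [0, 1]."""
    if rating not in range(1, 7):
        raise ValueError(f"rating must be an integer in 1..6, got {rating!r}")
    return (6 - rating) / 5.0


def suspicion_to_rating(suspicion: float) -> int:
    """Inverse of :func:`rating_to_suspicion` on the six attainable values."""
    rating = 6 - 5 * suspicion
    if not math.isclose(rating, round(rating), abs_tol=1e-9) or not 1 <= round(rating) <= 6:
        raise ValueError(f"suspicion {suspicion!r} does not map to a 1..6 rating")
    return int(round(rating))


def dichotomize_rating(rating: int) -> int:
    """1 if the rating falls in the dishonest half of the scale (1..3), else 0."""
    if rating not in range(1, 7):
        raise ValueError(f"rating must be an integer in 1..6, got {rating!r}")
    return int(rating <= 3)


def apply_exclusions(
    trials: pd.DataFrame,
    variance_epsilon: float = 1e-6,
    attention_fail_fraction: float = 1 / 3,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop participants with flat ratings or too many failed attention checks.

    A participant is excluded when the variance of their raw 1..6 ratings is
    below ``variance_epsilon`` (no meaningful model can be fitted to constant
    ratings), or when they failed at least ``ceil(attention_fail_fraction *
    n_checks)`` attention checks (three of nine in the 90-trial design).
    Attention columns (``attn_failed``, ``attn_total``) are optional; the
    check is skipped when absent.

    Returns the filtered table and an exclusion log, one record per removed
    participant with the reason.
    """
    log: list[dict] = []
    excluded: set = set()
    grouped = trials.groupby("participant_id")
    rating_var = grouped["rating"].var(ddof=1).fillna(0.0)
    for pid, var in rating_var.items():
        if var < variance_epsilon:
            excluded.add(pid)
            log.append(
                {"participant_id": pid, "reason": "near-zero rating variance",
                 "value": float(var)}
            )
    if {"attn_failed", "attn_total"} <= set(trials.columns):
        per = grouped[["attn_failed", "attn_total"]].first()
        for pid, row in per.iterrows():
            if pid in excluded:
                continue
            threshold = math.ceil(attention_fail_fraction * row["attn_total"])
            if row["attn_failed"] >= threshold:
                excluded.add(pid)
                log.append(
                    {"participant_id": pid, "reason": "failed attention checks",
                     "value": f"{int(row['attn_failed'])}/{int(row['attn_total'])}"}
                )
    kept = trials[~trials["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, log
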
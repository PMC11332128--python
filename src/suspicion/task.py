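"""Primitives of the two-player cards game.

Each trial both players see the same set of seven red/blue cards, the
computer picks one card independently for each player, and each player
reports a colour. Reporting blue against a red report wins a point, so
misreporting a red pick as blue is the profitable lie. The assessor then
rates the partner's honesty on a 6-point scale (1 = completely dishonest,
6 = completely honest).
"""

from __future__ import annotations

from dataclasses import dataclass

RED = "red"
BLUE = "blue"
COLOURS = (RED, BLUE)

#: Fixed value convention used throughout: red = -1, blue = +1.
COLOUR_VALUE = {RED: -1.0, BLUE: 1.0}

#: Every trial uses exactly seven cards.
N_CARDS = 7


@dataclass(frozen=True)
class CardSet:
    """A seven-card set with at least one card of each colour."""

    n_blue: int
    n_red: int

    def __post_init__(self) -> None:
        if self.n_blue + self.n_red != N_CARDS:
            raise ValueError(
                f"card set must have {N_CARDS} cards, got {self.n_blue + self.n_red}"
            )
        if self.n_blue < 1 or self.n_red < 1:
            raise ValueError("card set needs at least one card of each colour")

    def colour_fraction(self, colour: str) -> float:
        """Fraction of cards showing ``colour`` (the pick probability of that colour)."""
        if colour == BLUE:
            return self.n_blue / N_CARDS
        if colour == RED:
            return self.n_red / N_CARDS
        raise ValueError(f"unknown colour {colour!r}")


def other_colour(colour: str) -> str:
    if colour == RED:
        return BLUE
    if colour == BLUE:
        return RED
    raise ValueError(f"unknown colour {colour!r}")


def trial_outcome(own_report: str, partner_report: str) -> str:
    """Outcome from the assessor's perspective.

    Reports alone determine the outcome: the player reporting blue against
    a red report wins one point; equal reports tie.
    """
    for report in (own_report, partner_report):
        if report not in COLOURS:
            raise ValueError(f"report must be one of {COLOURS}, got {report!r}")
    if own_report == partner_report:
        return "tie"
    return "win" if own_report == BLUE else "lose"


@dataclass(frozen=True)
class CardTrial:
    """One task trial as experienced by the assessor."""

    participant_id: int
    trial_index: int
    block: int
    stakes: str
    card_set: CardSet
    own_pick_colour: str
    own_report_colour: str
    own_lied: int
    partner_report_colour: str
    partner_lied: int
    outcome: str
    honesty_rating: int

    def __post_init__(self) -> None:
        expected_lie = int(self.own_report_colour != self.own_pick_colour)
        if self.own_lied != expected_lie:
            raise ValueError("own_lied must flag own_report != own_pick")
        if self.outcome != trial_outcome(self.own_report_colour, self.partner_report_colour):
            raise ValueError("outcome inconsistent with the two reports")
        if self.honesty_rating not in range(1, 7):
            raise ValueError("honesty_rating must be an integer in 1..6")
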
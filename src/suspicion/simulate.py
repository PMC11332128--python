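"""Synthetic cards-task experiments with known ground truth.

The generator emulates the sender-receiver deception study end to end:

* seven-card sets with at least one card of each colour and varying
  colour ratios;
* uniform random computer picks (pick-colour probability equals that
  colour's card fraction, picks independent between players);
* a pool of past sender responses from which each live trial's partner
  response is sampled, so the partner lie base rate is ecological
  (~23.5% under the default policy) or can be fixed at exactly 50% by
  stratified sampling of lie and honest responses;
* assessors whose latent suspicion is a noisy linear function of the
  four cues, thresholded onto the 6-point honesty scale.

Three study styles are bundled: style 1 (3 blocks x 30 trials,
ecological lie rate), style 2 (3 x 30, lie rate fixed at 50%) and
style 3 (2 x 30 with high/low monetary stakes, partner responses shared
across the two stake blocks so only the assessor's own incentive
varies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import BLUE, RED, CardSet, N_CARDS, other_colour
from .cues import CUE_NAMES, CueVector

#: Canonical column order of the trial table written/read by this package.
TRIAL_COLUMNS = [
    "participant_id", "trial", "block", "stakes", "n_blue", "n_red",
    "pick", "report", "own_lied", "partner_report", "partner_lied",
    "outcome", "rating",
]

#: Optional per-participant attention-check columns (constant within participant).
ATTENTION_COLUMNS = ["attn_failed", "attn_total"]


@dataclass(frozen=True)
class SenderPolicy:
    """Probability of misreporting, by picked colour.

    Only lying on a red pick (reporting blue) is ever profitable; the
    default ``p_lie_when_red = 0.47`` yields an overall lie rate of
    ~23.5% under uniform card ratios, matching the ecological regime.
    """

    p_lie_when_red: float = 0.47
    p_lie_when_blue: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_lie_when_red, self.p_lie_when_blue):
            if not 0.0 <= p <= 1.0:
                raise ValueError("lie probabilities must lie in [0, 1]")

    def p_lie(self, picked_colour: str) -> float:
        return self.p_lie_when_red if picked_colour == RED else self.p_lie_when_blue


HONEST_POLICY = SenderPolicy(0.0, 0.0)


@dataclass(frozen=True)
class AssessorParams:
    """Generative model of an assessor's honesty ratings.

    Latent suspicion for a trial is

    ``intercept + b_own_lie*own_lie + b_signed*signed_ev
    + b_unsigned*unsigned_ev + b_lost*lost + stakes_effect*[high stakes]
    + participant offsets + N(0, noise_sd)``

    on the 0-1 suspicion scale, then mapped to the 6-point honesty scale
    through five strictly increasing thresholds (latent below the first
    threshold -> rating 6 "completely honest"; above the last -> rating 1).
    ``intercept_sd`` and ``slope_sd`` add Gaussian between-participant
    heterogeneity in the intercept and each cue weight, mirroring the
    individual differences the group mixed model is meant to absorb.
    """

    intercept: float = 0.45
    beta_own_lie: float = 0.05
    beta_signed_ev: float = 0.35
    beta_unsigned_ev: float = 0.20
    beta_lost: float = 0.05
    noise_sd: float = 0.15
    thresholds: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    intercept_sd: float = 0.05
    slope_sd: float = 0.03
    stakes_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.thresholds) != 5 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be 5 strictly increasing cut points")
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("heterogeneity SDs must be nonnegative")

    @property
    def betas(self) -> dict[str, float]:
        return {
            "own_lie": self.beta_own_lie,
            "signed_ev": self.beta_signed_ev,
            "unsigned_ev": self.beta_unsigned_ev,
            "lost": self.beta_lost,
        }


@dataclass(frozen=True)
class ExperimentConfig:
    """Shape and sampling mode of one simulated study."""

    n_participants: int = 100
    n_blocks: int = 3
    trials_per_block: int = 30
    lie_base_rate_mode: str = "ecological-pool"
    stakes_schedule: tuple[str, ...] | None = None
    seed: int = 0
    pool_senders: int = 50
    pool_trials_per_sender: int = 84
    n_attention_checks: int = 9
    attention_fail_rate: float = 0.02
    counterbalance_stakes: bool = True

    def __post_init__(self) -> None:
        if self.lie_base_rate_mode not in ("ecological-pool", "fixed-50"):
            raise ValueError(f"unknown lie_base_rate_mode {self.lie_base_rate_mode!r}")
        if self.stakes_schedule is not None and len(self.stakes_schedule) != self.n_blocks:
            raise ValueError("stakes_schedule must name one label per block")
        total = self.n_blocks * self.trials_per_block
        if self.lie_base_rate_mode == "fixed-50" and total % 2:
            raise ValueError("fixed-50 mode needs an even number of trials per participant")
        if min(self.n_participants, self.n_blocks, self.trials_per_block) < 1:
            raise ValueError("counts must be positive")

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def schedule(self) -> tuple[str, ...]:
        return self.stakes_schedule or ("none",) * self.n_blocks


def generate_card_set(rng: np.random.Generator, ratio_weights=None) -> CardSet:
    """Draw a card set; ``ratio_weights`` is a probability vector over blue counts 1..6."""
    if ratio_weights is None:
        n_blue = int(rng.integers(1, N_CARDS))
    else:
        w = np.asarray(ratio_weights, dtype=float)
        if w.shape != (6,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("ratio_weights must be a probability vector over blue counts 1..6")
        n_blue = int(rng.choice(np.arange(1, N_CARDS), p=w))
    return CardSet(n_blue=n_blue, n_red=N_CARDS - n_blue)


def pick_card_colour(card_set: CardSet, rng: np.random.Generator) -> str:
    """Uniform pick over the seven cards; returns the picked card's colour."""
    return BLUE if rng.random() < card_set.colour_fraction(BLUE) else RED


def simulate_sender(card_set: CardSet, picked_colour: str, policy: SenderPolicy,
                    rng: np.random.Generator) -> tuple[str, int]:
    """Report a colour for a picked card under a lying policy.

    Returns ``(report_colour, lied)`` with ``lied = 1`` iff the report
    differs from the pick.
    """
    if picked_colour not in (RED, BLUE):
        raise ValueError(f"unknown colour {picked_colour!r}")
    if card_set.colour_fraction(picked_colour) <= 0:
        raise ValueError(f"picked colour {picked_colour!r} absent from the card set")
    lied = int(rng.random() < policy.p_lie(picked_colour))
    report = other_colour(picked_colour) if lied else picked_colour
    return report, lied


def _latent_to_rating(latent: np.ndarray, thresholds) -> np.ndarray:
    """Map latent suspicion to honesty ratings: rating = 6 - #(thresholds exceeded)."""
    t = np.asarray(thresholds, dtype=float)
    return (6 - np.searchsorted(t, np.atleast_1d(latent), side="right")).astype(int)


def simulate_assessor_rating(cues: CueVector, params: AssessorParams,
                             rng: np.random.Generator, stakes: str = "none") -> int:
    """One honesty rating from the latent linear suspicion model.

    Deterministic when ``noise_sd = 0`` (participant heterogeneity is a
    cohort-level property and does not enter the single-trial path).
    """
    latent = params.intercept + sum(
        params.betas[name] * value for name, value in cues.as_dict().items()
    )
    if stakes == "high":
        latent += params.stakes_effect
    if params.noise_sd > 0:
        latent += rng.normal(0.0, params.noise_sd)
    return int(_latent_to_rating(np.array([latent]), params.thresholds)[0])


def _simulate_pool(policy: SenderPolicy, n_entries: int, rng: np.random.Generator,
                   ratio_weights=None) -> pd.DataFrame:
    """Simulate a seed cohort of sender responses (card set, pick, report)."""
    if ratio_weights is None:
        n_blue = rng.integers(1, N_CARDS, size=n_entries)
    else:
        w = np.asarray(ratio_weights, dtype=float)
        if w.shape != (6,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("ratio_weights must be a probability vector over blue counts 1..6")
        n_blue = rng.choice(np.arange(1, N_CARDS), size=n_entries, p=w)
    pick_blue = rng.random(n_entries) < n_blue / N_CARDS
    p_lie = np.where(pick_blue, policy.p_lie_when_blue, policy.p_lie_when_red)
    lied = rng.random(n_entries) < p_lie
    report_blue = pick_blue ^ lied
    return pd.DataFrame({
        "n_blue": n_blue.astype(int),
        "partner_pick": np.where(pick_blue, BLUE, RED),
        "partner_report": np.where(report_blue, BLUE, RED),
        "partner_lied": lied.astype(int),
    })


def _policy_for(sender_policies, stakes: str) -> SenderPolicy:
    if isinstance(sender_policies, SenderPolicy):
        return sender_policies
    try:
        return sender_policies[stakes]
    except KeyError:
        raise ValueError(f"no sender policy for stakes label {stakes!r}") from None


def simulate_experiment(config: ExperimentConfig,
                        sender_policies: SenderPolicy | dict = SenderPolicy(),
                        assessor_params: AssessorParams = AssessorParams(),
                        pool_policy: SenderPolicy | None = None,
                        ratio_weights=None) -> pd.DataFrame:
    """Simulate a full cohort; returns the canonical trial table.

    ``sender_policies`` is a single policy or a mapping from stakes label
    to policy (the assessor's own lying behaviour per block). The partner
    pool is generated once from ``pool_policy`` (defaults to the single
    sender policy, or the ecological default when policies vary by
    stakes). When the schedule contains more than one distinct stakes
    label, each participant's partner responses are drawn once and reused
    across stake blocks, so partner behaviour is constant across stakes
    by construction.
    """
    master = np.random.SeedSequence(config.seed)
    rng_pool, rng_trials, rng_assessor, rng_attn = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    if pool_policy is None:
        pool_policy = (sender_policies if isinstance(sender_policies, SenderPolicy)
                       else SenderPolicy())
    pool = _simulate_pool(pool_policy, config.pool_senders * config.pool_trials_per_sender,
                          rng_pool, ratio_weights)

    n_p = config.n_participants
    total = config.trials_per_participant
    schedule = config.schedule
    share_partners = len(set(schedule)) > 1

    # --- partner side: sample pool entries per participant -------------
    if config.lie_base_rate_mode == "fixed-50":
        lie_idx = np.flatnonzero(pool["partner_lied"].to_numpy() == 1)
        honest_idx = np.flatnonzero(pool["partner_lied"].to_numpy() == 0)
        if len(lie_idx) == 0 or len(honest_idx) == 0:
            raise ValueError("fixed-50 mode needs both lie and honest responses in the pool")
        half = total // 2
        rows = np.empty((n_p, total), dtype=int)
        for i in range(n_p):
            chosen = np.concatenate([
                rng_trials.choice(lie_idx, size=half, replace=True),
                rng_trials.choice(honest_idx, size=half, replace=True),
            ])
            rows[i] = rng_trials.permutation(chosen)
    elif share_partners:
        base = rng_trials.choice(len(pool), size=(n_p, config.trials_per_block), replace=True)
        rows = np.tile(base, (1, config.n_blocks))
    else:
        rows = rng_trials.choice(len(pool), size=(n_p, total), replace=True)

    flat = rows.reshape(-1)
    n_blue = pool["n_blue"].to_numpy()[flat]
    partner_report = pool["partner_report"].to_numpy()[flat]
    partner_lied = pool["partner_lied"].to_numpy()[flat]

    # --- assessor side: own pick and report ----------------------------
    stakes = np.tile(np.repeat(np.array(schedule, dtype=object), config.trials_per_block), n_p)
    if share_partners and config.counterbalance_stakes:
        # half the cohort sees the block order reversed
        per = np.repeat(np.array(schedule, dtype=object), config.trials_per_block)
        rev = np.repeat(np.array(schedule[::-1], dtype=object), config.trials_per_block)
        stakes = np.concatenate([per if i % 2 == 0 else rev for i in range(n_p)])

    pick_blue = rng_trials.random(n_p * total) < n_blue / N_CARDS
    p_lie = np.empty(n_p * total)
    for label in set(schedule):
        policy = _policy_for(sender_policies, label)
        mask = stakes == label
        p_lie[mask] = np.where(pick_blue[mask], policy.p_lie_when_blue,
                               policy.p_lie_when_red)
    own_lied = (rng_trials.random(n_p * total) < p_lie).astype(int)
    report_blue = pick_blue ^ own_lied.astype(bool)

    partner_blue = partner_report == BLUE
    outcome = np.where(report_blue == partner_blue, "tie",
                       np.where(report_blue, "win", "lose"))

    # --- cues and latent suspicion -------------------------------------
    v = np.where(partner_blue, 1.0, -1.0)
    p_report = np.where(partner_blue, n_blue, N_CARDS - n_blue) / N_CARDS
    cue_matrix = np.column_stack([
        own_lied.astype(float),
        v * (1.0 - p_report),
        1.0 - p_report,
        (outcome == "lose").astype(float),
    ])
    base_betas = np.array([assessor_params.betas[c] for c in CUE_NAMES])
    person_betas = base_betas + rng_assessor.normal(
        0.0, assessor_params.slope_sd, size=(n_p, 4))
    person_intercepts = assessor_params.intercept + rng_assessor.normal(
        0.0, assessor_params.intercept_sd, size=n_p)
    pid_per_row = np.repeat(np.arange(n_p), total)
    latent = (person_intercepts[pid_per_row]
              + np.einsum("ij,ij->i", cue_matrix, person_betas[pid_per_row])
              + assessor_params.stakes_effect * (stakes == "high"))
    if assessor_params.noise_sd > 0:
        latent = latent + rng_assessor.normal(0.0, assessor_params.noise_sd,
                                              size=n_p * total)
    rating = _latent_to_rating(latent, assessor_params.thresholds)

    attn_failed = rng_attn.binomial(config.n_attention_checks,
                                    config.attention_fail_rate, size=n_p)

    table = pd.DataFrame({
        "participant_id": pid_per_row + 1,
        "trial": np.tile(np.arange(1, total + 1), n_p),
        "block": np.tile(np.repeat(np.arange(1, config.n_blocks + 1),
                                   config.trials_per_block), n_p),
        "stakes": stakes,
        "n_blue": n_blue.astype(int),
        "n_red": (N_CARDS - n_blue).astype(int),
        "pick": np.where(pick_blue, BLUE, RED),
        "report": np.where(report_blue, BLUE, RED),
        "own_lied": own_lied,
        "partner_report": partner_report,
        "partner_lied": partner_lied.astype(int),
        "outcome": outcome,
        "rating": rating,
        "attn_failed": attn_failed[pid_per_row],
        "attn_total": config.n_attention_checks,
    })
    return table


# ----------------------------------------------------------------------
# Bundled study styles


def implied_standardized_betas(style: int = 1, n_participants: int = 3000,
                               seed: int = 0) -> dict[str, float]:
    """Large-sample standardized cue weights implied by a study style.

    The generative cue weights live on the raw 0-1 suspicion scale while
    the fitted models report standardized betas, so parameter recovery
    needs the generating values expressed in standardized units. This
    simulates one large cohort under the style's defaults and returns the
    pooled least-squares standardized coefficients — the population
    target a fitted cohort estimates. Solved directly via ``lstsq`` so
    the oracle shares no code with the model-fitting path.
    """
    trials = simulate_study(style, seed, n_participants)
    n_blue = trials["n_blue"].to_numpy(dtype=float)
    report_blue = trials["partner_report"].to_numpy() == BLUE
    v = np.where(report_blue, 1.0, -1.0)
    p = np.where(report_blue, n_blue, N_CARDS - n_blue) / N_CARDS
    X = np.column_stack([
        trials["own_lied"].to_numpy(dtype=float),
        v * (1.0 - p),
        1.0 - p,
        (trials["outcome"].to_numpy() == "lose").astype(float),
    ])
    y = (6 - trials["rating"].to_numpy(dtype=float)) / 5.0
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    design = np.column_stack([np.ones(len(yz)), Xz])
    coef = np.linalg.lstsq(design, yz, rcond=None)[0][1:]
    return dict(zip(CUE_NAMES, coef.astype(float)))


def make_config(style: int, seed: int, n_participants: int | None = None,
                **overrides) -> ExperimentConfig:
    """Experiment shape for study style 1, 2 or 3."""
    if style == 1:
        cfg = ExperimentConfig(n_participants=n_participants or 100, seed=seed)
    elif style == 2:
        cfg = ExperimentConfig(n_participants=n_participants or 100,
                               lie_base_rate_mode="fixed-50", seed=seed)
    elif style == 3:
        cfg = ExperimentConfig(n_participants=n_participants or 100, n_blocks=2,
                               stakes_schedule=("low", "high"),
                               n_attention_checks=6, seed=seed)
    else:
        raise ValueError(f"unknown study style {style!r}")
    return replace(cfg, **overrides) if overrides else cfg


def default_sender_policies(style: int) -> SenderPolicy | dict:
    """Assessors' own lying behaviour per study style.

    Style 3 raises the red-pick lie probability from 0.40 (low stakes) to
    0.488 (high stakes); with red picked half the time this yields a lie
    rate difference of 0.044 between blocks.
    """
    if style in (1, 2):
        return SenderPolicy()
    if style == 3:
        return {"low": SenderPolicy(0.40, 0.0), "high": SenderPolicy(0.488, 0.0)}
    raise ValueError(f"unknown study style {style!r}")


def default_assessor_params(style: int) -> AssessorParams:
    """Rating-model parameters per study style.

    Style 3 strengthens the self-projection weight to 0.083 and adds a
    direct stakes effect of 0.022 on latent suspicion, so own lying
    partially mediates the stakes-suspicion link by construction.
    """
    if style in (1, 2):
        return AssessorParams()
    if style == 3:
        return replace(AssessorParams(), beta_own_lie=0.083, stakes_effect=0.022)
    raise ValueError(f"unknown study style {style!r}")


def simulate_study(style: int, seed: int, n_participants: int | None = None,
                   **config_overrides) -> pd.DataFrame:
    """Simulate one of the three bundled study styles with its defaults."""
    config = make_config(style, seed, n_participants, **config_overrides)
    return simulate_experiment(
        config,
        sender_policies=default_sender_policies(style),
        assessor_params=default_assessor_params(style),
        pool_policy=SenderPolicy(),
    )
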
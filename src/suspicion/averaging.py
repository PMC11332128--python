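"""BIC-weighted Bayesian model averaging of cue-subset suspicion models.

All 2^k - 1 nonempty subsets of the cue set (15 for the four standard
cues) are fitted to the suspicion values, either as linear mixed-effects
models with fixed and random intercepts and fixed and random (mutually
uncorrelated) slopes grouped by participant, or as plain least squares
for a single unit / pooled data. Each model's BIC is converted to a
normalised model probability

    w_i = exp(-(BIC_i - min BIC)/2) / sum_j exp(-(BIC_j - min BIC)/2)

and each cue's standardized coefficient is averaged over the lattice,
models that omit the cue contributing beta = 0 (shrinkage-style
averaging). The confidence interval uses the unconditional
model-averaged standard error

    SE(cue) = sum_i w_i * sqrt(SE_i^2 + (beta_i - beta_bar)^2)

with absent models entering at beta = 0, SE = 0, and CI = beta_bar +/-
1.96 SE. A cue is deemed non-significant when its CI, rounded to three
decimals, contains zero.

Predictors and outcome are z-scored on the fitted dataset (binary cues
included) before fitting, so coefficients are standardized betas. Cues
that are constant in the data (a participant who never lied or never
lost) are flagged degenerate and carry beta = 0, SE = 0 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cues import CUE_NAMES

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% standard-normal quantile


@dataclass(frozen=True)
class ModelFitResult:
    """One fitted cue-subset model (standardized scale)."""

    cue_subset: tuple[str, ...]
    betas: dict[str, float]
    ses: dict[str, float]
    bic: float
    converged: bool
    n_obs: int
    degenerate: frozenset = frozenset()


@dataclass(frozen=True)
class AveragedEstimate:
    """A cue's BIC-weighted beta with its 95% CI and significance flag."""

    cue: str
    weighted_beta: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass(frozen=True)
class ModelAverageResult:
    fits: tuple[ModelFitResult, ...]
    weights: dict[tuple[str, ...], float]
    estimates: dict[str, AveragedEstimate]

    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            {"cue": e.cue, "weighted_beta": e.weighted_beta, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "significant": e.significant}
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"cue_subset": "+".join(f.cue_subset), "bic": f.bic,
                   "weight": self.weights.get(f.cue_subset, 0.0),
                   "converged": f.converged, "n_obs": f.n_obs}
            for cue in CUE_NAMES:
                row[f"beta_{cue}"] = f.betas.get(cue, np.nan)
                row[f"se_{cue}"] = f.ses.get(cue, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_models(cue_names=CUE_NAMES) -> list[tuple[str, ...]]:
    """All nonempty cue subsets, ordered by size then lexicographically."""
    names = list(cue_names)
    if not 1 <= len(names) <= 4:
        raise ValueError("expected between 1 and 4 cue names")
    if len(set(names)) != len(names):
        raise ValueError("duplicate cue names")
    subsets = []
    for k in range(1, len(names) + 1):
        subsets.extend(sorted(combinations(sorted(names), k)))
    return subsets


def _zscore_frame(trials: pd.DataFrame, columns, outcome: str) -> tuple[pd.DataFrame, list[str]]:
    """Standardize outcome and predictors; constant predictors are dropped."""
    z = pd.DataFrame(index=trials.index)
    y = trials[outcome].astype(float)
    sd_y = y.std(ddof=1)
    if not np.isfinite(sd_y) or sd_y == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    z["_y"] = (y - y.mean()) / sd_y
    degenerate = []
    for col in columns:
        x = trials[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            degenerate.append(col)
        else:
            z[col] = (x - x.mean()) / sd
    return z, degenerate


def fit_suspicion_model(trials: pd.DataFrame, cue_subset, level: str = "group-mixed",
                        outcome: str = "suspicion") -> ModelFitResult:
    """Fit one cue-subset model and return standardized betas, SEs and BIC.

    ``level='group-mixed'`` fits a linear mixed-effects model (random
    intercept plus uncorrelated random slopes by participant, ML so BICs
    are comparable across fixed-effect structures); ``level='single-unit'``
    fits OLS with an intercept. Cues constant in the data are recorded as
    degenerate with beta = 0, SE = 0. Non-convergence triggers a refit
    with random intercept only; if that also fails the fit is flagged.
    """
    cue_subset = tuple(cue_subset)
    z, degenerate = _zscore_frame(trials, cue_subset, outcome)
    active = [c for c in cue_subset if c not in degenerate]
    n = len(z)
    betas = {c: 0.0 for c in degenerate}
    ses = {c: 0.0 for c in degenerate}

    if level == "single-unit":
        X = sm.add_constant(z[active]) if active else pd.DataFrame(
            {"const": np.ones(n)}, index=z.index)
        res = sm.OLS(z["_y"], X).fit()
        for c in active:
            betas[c] = float(res.params[c])
            ses[c] = float(res.bse[c])
        return ModelFitResult(cue_subset, betas, ses, float(res.bic), True, n,
                              frozenset(degenerate))

    if level != "group-mixed":
        raise ValueError(f"unknown level {level!r}")
    if trials["participant_id"].nunique() < 2:
        raise ValueError("group-mixed fitting needs at least two participants")

    data = z.copy()
    data["participant_id"] = trials["participant_id"].to_numpy()
    rhs = " + ".join(active) if active else "1"
    formula = f"_y ~ {rhs}"
    vc = {c: f"0 + {c}" for c in active}

    def _fit(vc_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups="participant_id",
                                re_formula="1", vc_formula=vc_formula or None)
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
            # boundary fits can yield a non-PD Hessian and NaN SEs for the
            # cue coefficients (the intercept SE is allowed to degenerate)
            bse = dict(zip(res.fe_params.index, np.asarray(res.bse_fe)))
            ok = (res.converged
                  and np.all(np.isfinite(res.fe_params))
                  and all(np.isfinite(bse[c]) for c in active))
            return res, ok

    res, n_vc = None, len(vc)
    try:
        res, ok = _fit(vc)
        if not ok:
            raise RuntimeError("mixed model did not converge")
    except Exception:
        logger.warning("random-slope fit failed for %s; retrying intercept-only",
                       cue_subset)
        try:
            res, ok = _fit({})
            n_vc = 0
        except Exception:
            res, ok = None, False
    if res is None or not ok:
        return ModelFitResult(cue_subset, betas, ses, np.inf, False, n,
                              frozenset(degenerate))

    for c in active:
        betas[c] = float(res.fe_params[c])
        ses[c] = float(res.bse_fe[c])
    # BIC by hand: statsmodels MixedLM does not expose one. Parameters =
    # fixed effects (incl. intercept) + random-intercept variance +
    # slope variance components + residual variance.
    k = len(res.fe_params) + 1 + n_vc + 1
    bic = -2.0 * float(res.llf) + k * np.log(n)
    return ModelFitResult(cue_subset, betas, ses, bic, True, n, frozenset(degenerate))


def bic_weights(bics) -> np.ndarray:
    """Normalised model probabilities from BIC values (shift-invariant)."""
    b = np.asarray(list(bics), dtype=float)
    if b.size == 0:
        raise ValueError("empty BIC list")
    if not np.all(np.isfinite(b)):
        raise ValueError("BIC values must be finite")
    rel = np.exp(-0.5 * (b - b.min()))
    return rel / rel.sum()


def significance_by_ci(ci_low: float, ci_high: float) -> bool:
    """Significant iff the CI rounded to three decimals excludes zero."""
    lo, hi = round(ci_low, 3), round(ci_high, 3)
    return not (lo <= 0.0 <= hi)


def ci_overlap(ci_a, ci_b) -> bool:
    """True when two intervals share at least one point (closed intervals)."""
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    return max(lo_a, lo_b) <= min(hi_a, hi_b)


def average_estimates(fits, cue_names=CUE_NAMES):
    """BIC-weighted estimates over a fitted model lattice.

    Non-converged fits are excluded and the weights renormalised over
    the remainder (logged). Returns ``(estimates, weights)`` with
    weights keyed by cue subset.
    """
    fits = list(fits)
    usable = [f for f in fits if f.converged and np.isfinite(f.bic)]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("excluding %d non-converged fits from the averaging", dropped)
    if not usable:
        raise ValueError("no converged fits to average")
    w = bic_weights([f.bic for f in usable])
    weights = {f.cue_subset: float(wi) for f, wi in zip(usable, w)}
    estimates = {}
    for cue in cue_names:
        beta_bar = sum(wi * f.betas.get(cue, 0.0) for f, wi in zip(usable, w))
        se = sum(
            wi * np.sqrt(f.ses.get(cue, 0.0) ** 2 + (f.betas.get(cue, 0.0) - beta_bar) ** 2)
            for f, wi in zip(usable, w)
        )
        lo, hi = beta_bar - Z_95 * se, beta_bar + Z_95 * se
        estimates[cue] = AveragedEstimate(cue, float(beta_bar), float(lo), float(hi),
                                          significance_by_ci(lo, hi))
    return estimates, weights


def model_average(trials: pd.DataFrame, level: str = "group-mixed",
                  outcome: str = "suspicion", cue_names=CUE_NAMES) -> ModelAverageResult:
    """Fit the full cue-subset lattice and average it."""
    fits = tuple(
        fit_suspicion_model(trials, subset, level=level, outcome=outcome)
        for subset in enumerate_models(cue_names)
    )
    estimates, weights = average_estimates(fits, cue_names)
    return ModelAverageResult(fits, weights, estimates)


def fit_participant_profiles(trials: pd.DataFrame, cue_names=CUE_NAMES,
                             outcome: str = "suspicion") -> pd.DataFrame:
    """Per-participant weighted betas from single-unit model averaging.

    Cues constant within a participant (never lied, never lost) get
    beta 0 by the degeneracy convention. Participants with fewer than
    ``2 * len(cue_names)`` trials are emitted with ``reliable = False``.
    """
    rows = []
    for pid, sub in trials.groupby("participant_id"):
        result = model_average(sub, level="single-unit", outcome=outcome,
                               cue_names=cue_names)
        row = {"participant_id": pid, "n_trials": len(sub),
               "reliable": len(sub) >= 2 * len(cue_names)}
        for cue in cue_names:
            row[f"beta_{cue}"] = result.estimates[cue].weighted_beta
        rows.append(row)
    return pd.DataFrame(rows)
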
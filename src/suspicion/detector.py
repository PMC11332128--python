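"""The accurate lie detector: ground-truth-trained oracle benchmark.

The detector applies the identical BIC-weighted model-averaging lattice
used for human suspicion, except that the outcome is the ground-truth
lie indicator (0 = partner honest, 1 = partner lied) and the fits are
single pooled least squares over all participants' trials (no random
effects). Its weighted cue betas show which cues an agent with perfect
hindsight would weight; its d'-scores on each participant's trial set
upper-bound what cue-based discernment can achieve with a linear rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import AveragedEstimate, ModelAverageResult, model_average
from .cues import CUE_NAMES
from .sdt import detection_summary


@dataclass(frozen=True)
class DetectorModel:
    """Averaged linear model of the ground-truth lie indicator.

    Prediction maps the weighted standardized betas back to the outcome
    scale: ``score = y_mean + y_sd * sum_c beta_c * z(cue_c)``, which for
    a 0/1 outcome reads as a (unclipped) lie probability.
    """

    estimates: dict[str, AveragedEstimate]
    averaging: ModelAverageResult
    y_mean: float
    y_sd: float
    cue_means: dict[str, float]
    cue_sds: dict[str, float]
    n_obs: int

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        score = np.zeros(len(trials))
        for cue, est in self.estimates.items():
            sd = self.cue_sds[cue]
            if sd == 0:
                continue
            z = (trials[cue].to_numpy(dtype=float) - self.cue_means[cue]) / sd
            score += est.weighted_beta * z
        return self.y_mean + self.y_sd * score


def fit_detector(trials: pd.DataFrame, cue_names=CUE_NAMES) -> DetectorModel:
    """Fit the accurate detector on all pooled trials.

    Requires ``partner_lied`` ground truth with both classes present.
    """
    y = trials["partner_lied"].astype(float)
    if y.nunique() < 2:
        raise ValueError(
            "ground truth is constant (all honest or all lies); detector undefined")
    result = model_average(trials, level="single-unit", outcome="partner_lied",
                           cue_names=cue_names)
    return DetectorModel(
        estimates=result.estimates,
        averaging=result,
        y_mean=float(y.mean()),
        y_sd=float(y.std(ddof=1)),
        cue_means={c: float(trials[c].mean()) for c in cue_names},
        cue_sds={c: float(trials[c].std(ddof=1)) for c in cue_names},
        n_obs=len(trials),
    )


def detector_dprime(model: DetectorModel, trials: pd.DataFrame,
                    threshold: float = 0.5,
                    correction: str = "half_count") -> pd.DataFrame:
    """Detector d' on each participant's set of trials.

    Predictions are dichotomised at ``threshold`` (on the outcome scale,
    i.e. predicted lie probability) and scored against ``partner_lied``.
    A trial set missing one ground-truth class is scored with the
    log-linear correction (which remains defined there) and flagged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rows = []
    for pid, sub in trials.groupby("participant_id"):
        judged = (model.predict(sub) >= threshold).astype(int)
        truth = sub["partner_lied"].to_numpy(dtype=int)
        empty_class = truth.sum() in (0, len(truth))
        if empty_class:
            j = np.asarray(judged)
            n_lie = int(truth.sum())
            n_honest = len(truth) - n_lie
            from .sdt import _corrected_rate, dprime_from_rates
            h = _corrected_rate(int((j & truth).sum()), max(n_lie, 1), "loglinear") \
                if n_lie else 0.5
            fa = _corrected_rate(int((j & (1 - truth)).sum()), max(n_honest, 1),
                                 "loglinear") if n_honest else 0.5
            d = dprime_from_rates(h, fa)
            rows.append({"participant_id": pid, "dprime": d, "hits": int((j & truth).sum()),
                         "false_alarms": int((j & (1 - truth)).sum()),
                         "n_lie": n_lie, "n_honest": n_honest, "empty_class": True})
            continue
        score = detection_summary(judged, truth, correction)
        rows.append({"participant_id": pid, "dprime": score.dprime, "hits": score.hits,
                     "false_alarms": score.false_alarms, "n_lie": score.n_lie_trials,
                     "n_honest": score.n_honest_trials, "empty_class": False})
    return pd.DataFrame(rows)


def threshold_sweep(model: DetectorModel, trials: pd.DataFrame,
                    thresholds=(0.3, 0.4, 0.5, 0.6, 0.7),
                    correction: str = "half_count") -> pd.DataFrame:
    """Mean detector d' across a grid of dichotomisation thresholds."""
    rows = []
    for t in thresholds:
        scores = detector_dprime(model, trials, threshold=t, correction=correction)
        rows.append({"threshold": t, "mean_dprime": float(scores["dprime"].mean())})
    return pd.DataFrame(rows)
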
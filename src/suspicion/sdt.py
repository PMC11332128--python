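"""Signal-detection scoring of lie discernment.

Discernment is measured as d' = z(H) - z(FA), where H is the hit rate
(detected lies / lie trials), FA the false-alarm rate (lies suspected on
honest trials / honest trials) and z the standard-normal quantile.
Extreme rates (0 or 1) are corrected before the quantile transform,
since z is unbounded there. Overall accuracy is provided as the naive
alternative; at a 25% lie base rate an always-"honest" judge already
scores 0.75 on it, which is why d' is the primary metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class DetectionScore:
    n_lie_trials: int
    n_honest_trials: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    dprime: float


def _corrected_rate(count: int, n: int, correction: str) -> float:
    if correction == "loglinear":
        return (count + 0.5) / (n + 1)
    if correction == "half_count":
        # replace only offending rates by 1/(2N) resp. 1 - 1/(2N)
        rate = count / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate
    raise ValueError(f"unknown correction {correction!r}")


def dprime(hits: int, n_lie: int, false_alarms: int, n_honest: int,
           correction: str = "half_count") -> float:
    """d' from raw counts, with edge correction of extreme rates.

    ``correction='half_count'`` (default) replaces a rate of 0 with
    1/(2N) and a rate of 1 with 1 - 1/(2N), leaving interior rates
    untouched; ``'loglinear'`` adds 0.5 to both counts and 1 to both
    denominators unconditionally.
    """
    if n_lie < 1 or n_honest < 1:
        raise ValueError("d' undefined without both lie and honest trials")
    if not 0 <= hits <= n_lie or not 0 <= false_alarms <= n_honest:
        raise ValueError("counts out of range")
    h = _corrected_rate(hits, n_lie, correction)
    fa = _corrected_rate(false_alarms, n_honest, correction)
    return float(norm.ppf(h) - norm.ppf(fa))


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' straight from rates; rates must lie strictly inside (0, 1)."""
    for r in (hit_rate, fa_rate):
        if not 0.0 < r < 1.0:
            raise ValueError("rates must lie strictly in (0, 1); correct counts first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def detection_summary(judgements, ground_truth,
                      correction: str = "half_count") -> DetectionScore:
    """Tally hits and false alarms for one rater and score d'.

    ``judgements`` and ``ground_truth`` are equal-length binary arrays
    (1 = lie suspected / lie told).
    """
    j = np.asarray(judgements, dtype=int)
    t = np.asarray(ground_truth, dtype=int)
    if j.shape != t.shape or j.ndim != 1:
        raise ValueError("judgements and ground truth must be equal-length 1-d arrays")
    if not (np.isin(j, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("judgements and ground truth must be binary")
    n_lie = int(t.sum())
    n_honest = int(len(t) - n_lie)
    hits = int(((j == 1) & (t == 1)).sum())
    fas = int(((j == 1) & (t == 0)).sum())
    d = dprime(hits, n_lie, fas, n_honest, correction)
    return DetectionScore(
        n_lie_trials=n_lie, n_honest_trials=n_honest, hits=hits, false_alarms=fas,
        hit_rate=_corrected_rate(hits, n_lie, correction),
        fa_rate=_corrected_rate(fas, n_honest, correction),
        dprime=d,
    )


def overall_accuracy(judgements, ground_truth) -> float:
    """Proportion of correct binary judgements (true positives + true negatives)."""
    j = np.asarray(judgements, dtype=int)
    t = np.asarray(ground_truth, dtype=int)
    if j.shape != t.shape or j.ndim != 1:
        raise ValueError("judgements and ground truth must be equal-length 1-d arrays")
    if len(j) == 0:
        raise ValueError("empty input")
    return float((j == t).mean())
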
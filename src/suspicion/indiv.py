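"""Cross-participant analyses: discernment regressions, the
stakes -> own lying -> suspicion mediation, and nonparametric group
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .averaging import fit_participant_profiles
from .cues import add_cues, dichotomize_rating
from .sdt import detection_summary


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediation of the stakes effect on suspicion.

    ``path_a``: stakes (0 = low, 1 = high) -> own lying;
    ``path_b``: own lying -> suspicion, stakes-adjusted;
    ``indirect = a * b``; ``direct``: stakes coefficient in the adjusted
    model; ``total = direct + indirect`` (an exact identity for nested
    least squares). Inference is by participant-level cluster bootstrap.
    """

    path_a: float
    path_b: float
    indirect: float
    direct: float
    total: float
    ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n_boot: int


def build_profiles(trials: pd.DataFrame, covariates: pd.DataFrame | None = None,
                   correction: str = "half_count") -> pd.DataFrame:
    """One row per participant: weighted cue betas, d', mean suspicion, lie tendency.

    ``trials`` is a canonical trial table (cues are added if absent).
    ``covariates``, if given, is merged on ``participant_id``.
    """
    if "suspicion" not in trials.columns:
        trials = add_cues(trials)
    profiles = fit_participant_profiles(trials)
    extras = []
    for pid, sub in trials.groupby("participant_id"):
        judged = sub["rating"].map(dichotomize_rating).to_numpy()
        truth = sub["partner_lied"].to_numpy(dtype=int)
        if 0 < truth.sum() < len(truth):
            d = detection_summary(judged, truth, correction).dprime
        else:
            d = np.nan
        extras.append({
            "participant_id": pid,
            "dprime": d,
            "mean_suspicion": float(sub["suspicion"].mean()),
            "lie_tendency": float(sub["own_lied"].mean()),
        })
    out = profiles.merge(pd.DataFrame(extras), on="participant_id")
    if covariates is not None:
        out = out.merge(covariates, on="participant_id", how="left")
    return out


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns that are (numerically) linear combinations of the others."""
    offenders = []
    cols = list(X.columns)
    for col in cols:
        others = [c for c in cols if c != col]
        if not others:
            continue
        resid = sm.OLS(X[col], sm.add_constant(X[others])).fit().resid
        if np.allclose(resid, 0, atol=1e-8):
            offenders.append(col)
    return offenders


def regress_outcome_on_profiles(profiles: pd.DataFrame, outcome: str,
                                predictors) -> pd.DataFrame:
    """OLS of a participant-level outcome on standardized predictors.

    Complete-case analysis; outcome and predictors are z-scored, so the
    coefficients are standardized betas with two-tailed p-values and 95%
    CIs. A rank-deficient design raises, naming the collinear columns.
    """
    predictors = list(predictors)
    data = profiles[[outcome, *predictors]].dropna().astype(float)
    if len(data) < len(predictors) + 2:
        raise ValueError("not enough complete-case rows for the requested design")
    z = (data - data.mean()) / data.std(ddof=1)
    if z.isna().any().any():
        flat = z.columns[z.isna().any()].tolist()
        raise ValueError(f"constant columns in the design: {flat}")
    X = z[predictors]
    if np.linalg.matrix_rank(X.to_numpy()) < len(predictors):
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{_collinear_columns(X)}")
    res = sm.OLS(z[outcome], sm.add_constant(X)).fit()
    ci = res.conf_int(alpha=0.05)
    rows = [
        {"predictor": name, "beta": float(res.params[name]), "se": float(res.bse[name]),
         "t": float(res.tvalues[name]), "p": float(res.pvalues[name]),
         "ci_low": float(ci.loc[name, 0]), "ci_high": float(ci.loc[name, 1])}
        for name in predictors
    ]
    table = pd.DataFrame(rows)
    table.attrs["df_resid"] = int(res.df_resid)
    table.attrs["n"] = int(len(data))
    return table


def _mediation_paths(df: pd.DataFrame):
    """a, b, direct, total from three least-squares fits on the same rows."""
    x = sm.add_constant(df["stakes01"])
    a = float(sm.OLS(df["own_lied"], x).fit().params["stakes01"])
    xb = sm.add_constant(df[["own_lied", "stakes01"]])
    fit_b = sm.OLS(df["suspicion"], xb).fit()
    b = float(fit_b.params["own_lied"])
    direct = float(fit_b.params["stakes01"])
    total = float(sm.OLS(df["suspicion"], x).fit().params["stakes01"])
    return a, b, direct, total


def mediation(trials: pd.DataFrame, n_boot: int = 5000,
              seed: int | np.random.Generator = 0,
              level: str = "trial") -> MediationResult:
    """Does own lying mediate the stakes effect on suspicion?

    ``trials`` must carry ``stakes`` in {low, high}, ``own_lied`` and
    ``suspicion`` (cues are added if absent). ``level='trial'`` fits the
    paths on trial rows; ``level='participant'`` first collapses to
    participant-by-stakes means. Confidence intervals and p-values come
    from a cluster bootstrap resampling participants with replacement
    (percentile CIs; p = 2 * min tail fraction with add-one smoothing).
    """
    if "suspicion" not in trials.columns:
        trials = add_cues(trials)
    levels = set(trials["stakes"].unique())
    if not {"low", "high"} <= levels:
        raise ValueError(f"need both 'low' and 'high' stakes levels, got {sorted(levels)}")
    df = trials[trials["stakes"].isin(["low", "high"])].copy()
    df["stakes01"] = (df["stakes"] == "high").astype(float)
    df["own_lied"] = df["own_lied"].astype(float)
    if level == "participant":
        df = (df.groupby(["participant_id", "stakes01"], as_index=False)
                [["own_lied", "suspicion"]].mean())
    elif level != "trial":
        raise ValueError(f"unknown level {level!r}")

    degenerate_mediator = df["own_lied"].nunique() < 2
    if degenerate_mediator:
        warnings.warn("mediator has zero variance; indirect effect forced to 0")
        x = sm.add_constant(df["stakes01"])
        total = float(sm.OLS(df["suspicion"], x).fit().params["stakes01"])
        a, b, direct = 0.0, 0.0, total
    else:
        a, b, direct, total = _mediation_paths(df)
    indirect = a * b

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pids = df["participant_id"].unique()
    by_pid = {pid: sub for pid, sub in df.groupby("participant_id")}
    draws = {k: np.empty(n_boot) for k in ("a", "b", "indirect", "direct", "total")}
    for i in range(n_boot):
        sample = rng.choice(pids, size=len(pids), replace=True)
        boot = pd.concat([by_pid[pid] for pid in sample], ignore_index=True)
        if boot["stakes01"].nunique() < 2 or boot["own_lied"].nunique() < 2:
            ba = bb = bd = bt = np.nan
        else:
            ba, bb, bd, bt = _mediation_paths(boot)
        draws["a"][i], draws["b"][i] = ba, bb
        draws["indirect"][i] = ba * bb if np.isfinite(ba) else np.nan
        draws["direct"][i], draws["total"][i] = bd, bt

    ci, pvals = {}, {}
    for key, arr in draws.items():
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            ci[key], pvals[key] = (np.nan, np.nan), np.nan
            continue
        ci[key] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
        lower = (np.sum(arr <= 0) + 1) / (len(arr) + 1)
        upper = (np.sum(arr >= 0) + 1) / (len(arr) + 1)
        pvals[key] = float(min(1.0, 2 * min(lower, upper)))

    return MediationResult(path_a=a, path_b=b, indirect=indirect, direct=direct,
                           total=total, ci=ci, p_values=pvals, n_boot=n_boot)


def group_compare(sample_a, sample_b, design: str = "independent"):
    """Nonparametric two-sample comparison; returns ``(statistic, p)``.

    Independent design: Mann-Whitney U (exact when both n <= 25 and no
    ties, otherwise normal approximation with continuity correction).
    Paired design: Wilcoxon signed-rank with zero differences dropped
    (exact under the same smallness condition).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if design == "independent":
        combined = np.concatenate([a, b])
        has_ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    if design == "paired":
        if a.shape != b.shape:
            raise ValueError("paired design needs equal-length samples")
        diffs = a - b
        nonzero = diffs[diffs != 0]
        if len(nonzero) == 0:
            raise ValueError("all paired differences are zero; test degenerate")
        has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
        method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown design {design!r}")
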
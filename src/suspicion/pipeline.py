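"""End-to-end analysis pipeline on simulated or deposited-format data.

Stage order: exclusions -> cue computation -> group-level model
averaging -> per-participant profiles -> accurate detector -> d'
comparison -> individual-difference regressions (-> mediation for the
stakes design). Every output table is written as CSV next to a JSON run
manifest recording the seed and the gap-filling defaults in force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .averaging import ci_overlap, model_average
from .cues import CUE_NAMES, add_cues, apply_exclusions
from .detector import detector_dprime, fit_detector, threshold_sweep
from .indiv import build_profiles, group_compare, mediation, regress_outcome_on_profiles
from .io import read_trials, write_trials
from .simulate import simulate_study

logger = logging.getLogger(__name__)


_CONFIG_FIELDS = (
    "style", "seed", "out_dir", "input_path", "alias_map", "n_participants",
    "variance_epsilon", "detector_threshold", "sdt_correction", "n_boot",
    "mediation_level",
)


@dataclass
class PipelineConfig:
    style: int = 1
    seed: int = 0
    out_dir: str = "suspicion_results"
    input_path: str | None = None          # read this table instead of simulating
    alias_map: str | None = None
    n_participants: int | None = None
    variance_epsilon: float = 1e-6
    detector_threshold: float = 0.5
    sdt_correction: str = "half_count"
    n_boot: int = 5000
    mediation_level: str = "trial"

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Build a config from a flat key-value YAML file; kwargs win."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def replay_manifest(path) -> dict:
    """Re-run the pipeline exactly as recorded in a run manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return run_pipeline(PipelineConfig(**manifest["config"]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the results bundle and writes all tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/read"
    results: dict = {}
    try:
        if config.input_path:
            trials = read_trials(config.input_path, alias_map=config.alias_map)
        else:
            trials = simulate_study(config.style, config.seed, config.n_participants)
            write_trials(trials, out / "trials.csv", seed=config.seed)

        stage = "exclusions"
        trials, exclusion_log = apply_exclusions(
            trials, variance_epsilon=config.variance_epsilon)
        with open(out / "exclusions.log", "w") as fh:
            for rec in exclusion_log:
                fh.write(f"participant {rec['participant_id']}: {rec['reason']}"
                         f" ({rec['value']})\n")

        stage = "cues"
        trials = add_cues(trials)

        stage = "group averaging"
        group = model_average(trials, level="group-mixed")
        group.estimates_frame().to_csv(out / "group_estimates.csv", index=False)
        group.fits_frame().to_csv(out / "group_fits.csv", index=False)
        results["group"] = group

        stage = "participant profiles"
        profiles = build_profiles(trials, correction=config.sdt_correction)
        profiles.to_csv(out / "profiles.csv", index=False)
        results["profiles"] = profiles

        stage = "detector"
        det = fit_detector(trials)
        det.averaging.estimates_frame().to_csv(out / "detector_estimates.csv",
                                               index=False)
        det_scores = detector_dprime(det, trials, threshold=config.detector_threshold,
                                     correction=config.sdt_correction)
        sweep = threshold_sweep(det, trials, correction=config.sdt_correction)
        sweep.to_csv(out / "detector_threshold_sweep.csv", index=False)
        # cue-by-cue human vs detector: non-overlapping CIs flag a reliable
        # difference in how much weight each judge puts on the cue
        cue_rows = []
        for cue in CUE_NAMES:
            human, oracle = group.estimates[cue], det.estimates[cue]
            cue_rows.append({
                "cue": cue,
                "human_beta": human.weighted_beta,
                "human_ci_low": human.ci_low, "human_ci_high": human.ci_high,
                "detector_beta": oracle.weighted_beta,
                "detector_ci_low": oracle.ci_low, "detector_ci_high": oracle.ci_high,
                "cis_overlap": ci_overlap((human.ci_low, human.ci_high),
                                          (oracle.ci_low, oracle.ci_high)),
            })
        pd.DataFrame(cue_rows).to_csv(out / "cue_comparison.csv", index=False)
        comparison = det_scores.merge(
            profiles[["participant_id", "dprime"]], on="participant_id",
            suffixes=("_detector", "_human"))
        comparison.to_csv(out / "dprime_comparison.csv", index=False)
        results["detector"] = det
        results["dprime_comparison"] = comparison

        stage = "detector vs human test"
        paired = comparison.dropna(subset=["dprime_detector", "dprime_human"])
        stat, p = group_compare(paired["dprime_detector"], paired["dprime_human"],
                                design="paired")
        results["detector_vs_human"] = {"wilcoxon": stat, "p": p}

        stage = "individual differences"
        predictors = [f"beta_{c}" for c in CUE_NAMES] + ["lie_tendency"]
        dprime_reg = regress_outcome_on_profiles(profiles, "dprime", predictors)
        dprime_reg.to_csv(out / "dprime_regression.csv", index=False)
        suspicion_reg = regress_outcome_on_profiles(
            profiles, "mean_suspicion", ["lie_tendency"])
        suspicion_reg.to_csv(out / "suspicion_regression.csv", index=False)
        results["dprime_regression"] = dprime_reg
        results["suspicion_regression"] = suspicion_reg

        if config.style == 3 or (config.input_path
                                 and {"low", "high"} <= set(trials["stakes"])):
            stage = "mediation"
            med = mediation(trials, n_boot=config.n_boot, seed=config.seed,
                            level=config.mediation_level)
            med_rows = [
                {"effect": k, "estimate": getattr(med, attr),
                 "ci_low": med.ci[k][0], "ci_high": med.ci[k][1], "p": med.p_values[k]}
                for k, attr in [("a", "path_a"), ("b", "path_b"),
                                ("indirect", "indirect"), ("direct", "direct"),
                                ("total", "total")]
            ]
            pd.DataFrame(med_rows).to_csv(out / "mediation.csv", index=False)
            results["mediation"] = med
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_trials": int(len(trials)),
        "n_participants": int(trials["participant_id"].nunique()),
        "defaults": {
            "variance_epsilon": config.variance_epsilon,
            "sdt_correction": config.sdt_correction,
            "detector_threshold": config.detector_threshold,
            "ci_formula": "unconditional model-averaged SE, beta +/- 1.96*SE",
            "standardization": "pooled z-scoring of outcome and predictors",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
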
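"""Canonical trial-table CSV schema, readers and writers.

One row per participant x trial, columns::

    participant_id, trial, block, stakes, n_blue, n_red, pick, report,
    own_lied, partner_report, partner_lied, outcome, rating

plus optional ``attn_failed`` / ``attn_total`` attention-check columns.
Files may start with ``#``-comment lines (the writer records the
simulation seed that way). Deposited files with different column names
are handled through a user-supplied alias map (YAML: alias -> canonical
name). Ratings coded 0..5 are auto-detected and shifted to the 1..6
convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ATTENTION_COLUMNS, TRIAL_COLUMNS
from .task import COLOURS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """The file does not match the canonical trial schema."""


def write_trials(trials: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS + ATTENTION_COLUMNS if c in trials.columns]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        trials[cols].to_csv(fh, index=False)


def load_alias_map(path) -> dict[str, str]:
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not all(isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()):
        raise SchemaError("alias map must be a flat mapping of column aliases")
    return mapping


def _validate(trials: pd.DataFrame) -> None:
    bad = {}
    n_blue, n_red = trials["n_blue"], trials["n_red"]
    bad["card set"] = trials.index[
        (n_blue + n_red != 7) | (n_blue < 1) | (n_red < 1)].tolist()
    bad["colour"] = trials.index[
        ~trials["pick"].isin(COLOURS) | ~trials["report"].isin(COLOURS)
        | ~trials["partner_report"].isin(COLOURS)].tolist()
    bad["own_lied"] = trials.index[
        trials["own_lied"].astype(int) != (trials["pick"] != trials["report"]).astype(int)
    ].tolist()
    expected = np.where(trials["report"] == trials["partner_report"], "tie",
                        np.where(trials["report"] == "blue", "win", "lose"))
    bad["outcome"] = trials.index[trials["outcome"] != expected].tolist()
    bad["rating"] = trials.index[~trials["rating"].isin(range(1, 7))].tolist()
    messages = [f"{what}: rows {rows[:10]}" for what, rows in bad.items() if rows]
    if messages:
        raise SchemaError("invariant violations — " + "; ".join(messages))


def read_trials(path, alias_map: dict[str, str] | str | None = None,
                validate: bool = True) -> pd.DataFrame:
    """Read and validate a canonical trial table.

    ``alias_map`` maps foreign column names to canonical ones (a dict or
    a YAML file path). Unknown columns after aliasing raise a
    :class:`SchemaError` naming them; attention columns are optional.
    """
    if isinstance(alias_map, (str, Path)):
        alias_map = load_alias_map(alias_map)
    trials = pd.read_csv(path, comment="#")
    if alias_map:
        trials = trials.rename(columns=alias_map)
    known = set(TRIAL_COLUMNS) | set(ATTENTION_COLUMNS)
    unknown = [c for c in trials.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown columns after aliasing: {unknown}")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    ratings = trials["rating"].astype(int)
    if ratings.min() >= 0 and ratings.max() <= 5 and ratings.min() == 0:
        logger.info("ratings look 0-coded (range %d..%d); shifting to 1..6",
                    ratings.min(), ratings.max())
        trials["rating"] = ratings + 1
    if validate:
        _validate(trials)
    logger.info("read %d trials from %d participants", len(trials),
                trials["participant_id"].nunique())
    return trials
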
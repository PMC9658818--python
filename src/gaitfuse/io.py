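"""CSV/JSON persistence for trials, feature matrices and selection results.

All tabular artifacts are plain CSV (tiny volumes, diffable); every
dataset CSV gets a JSON sidecar carrying the generator config so a run
can be reproduced bit-for-bit from its files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import CHANNEL_ABBRS, N_CHANNELS
from .selection import SelectionResult
from .synthetic import SynthConfig, TrialRecording

_TRIAL_COLUMNS = ["trial_id", "label", "channel_abbr", "t_index", "value"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_trials(trials: Sequence[TrialRecording], path, config: SynthConfig | None = None) -> None:
    """Write one long-format CSV per dataset plus a JSON config sidecar."""
    path = Path(path)
    frames = []
    for tid, trial in enumerate(trials):
        n = trial.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": np.repeat(tid, N_CHANNELS * n),
                    "label": np.repeat(trial.label, N_CHANNELS * n),
                    "channel_abbr": np.repeat(CHANNEL_ABBRS, n),
                    "t_index": np.tile(np.arange(n), N_CHANNELS),
                    "value": trial.channels.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta: dict = {"sample_rate": trials[0].sample_rate if trials else 100.0}
    if config is not None:
        meta["synth_config"] = dataclasses.asdict(config)
        if not isinstance(config.n_per_class, int):
            meta["synth_config"]["n_per_class"] = list(config.n_per_class)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_trials(path) -> list[TrialRecording]:
    """Reconstruct a trial list from a dataset CSV (lossless round trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"dataset file is empty: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed dataset CSV {path}: {err}") from err
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"dataset CSV has no rows: {path}")
    bad = set(df["channel_abbr"].unique()) - set(CHANNEL_ABBRS)
    if bad:
        raise ValueError(f"unknown channel abbreviations: {sorted(bad)}")

    sample_rate = 100.0
    side = sidecar_path(path)
    if side.exists():
        sample_rate = float(json.loads(side.read_text())["sample_rate"])

    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        present = set(g["channel_abbr"].unique())
        absent = [c for c in CHANNEL_ABBRS if c not in present]
        if absent:
            raise ValueError(f"trial {tid}: missing channel(s) {absent}")
        n = g["t_index"].max() + 1
        mat = np.full((N_CHANNELS, n), np.nan)
        ci = {c: i for i, c in enumerate(CHANNEL_ABBRS)}
        mat[
            g["channel_abbr"].map(ci).to_numpy(),
            g["t_index"].to_numpy(),
        ] = g["value"].to_numpy()
        if np.isnan(mat).any():
            ch = CHANNEL_ABBRS[int(np.argwhere(np.isnan(mat))[0, 0])]
            raise ValueError(f"trial {tid}: incomplete samples for channel {ch!r}")
        trials.append(
            TrialRecording(channels=mat, sample_rate=sample_rate, label=int(g["label"].iloc[0]))
        )
    return trials


def write_feature_matrix(X, y, names: Sequence[str], path) -> None:
    """Feature CSV: one named column per feature, final column ``label``."""
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(names))
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature file not found: {path}")
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must end with a 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), y, list(df.columns)


def write_selection(result: SelectionResult, names: Sequence[str], path, extra: dict | None = None) -> None:
    payload = {
        "mrmr_ranking": list(result.mrmr_ranking),
        "final_subset": list(result.final_subset),
        "final_subset_names": [names[i] for i in result.final_subset],
        "objective_trace": list(result.objective_trace),
        "converged": result.converged,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_selection(path) -> dict:
    return json.loads(Path(path).read_text())
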
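"""Trial-table and config I/O.

The canonical trial format is tab-delimited text, one row per trial, with
gambles serialized compactly as ``"m1:p1;m2:p2;..."``.  Required columns:
``session, trial, gamble_left, gamble_right, chosen_side,
reward_delivered``; the simulator's extra columns (``pa``, ``test_side``,
``cond``) round-trip when present.  History columns (``prev_choice``,
``prev_reward``) are derived from session ordering on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gambles import Gamble, GambleError

__all__ = [
    "format_gamble",
    "parse_gamble",
    "write_trials",
    "read_trials",
    "read_config",
    "write_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

REQUIRED_COLUMNS = ("session", "trial", "gamble_left", "gamble_right",
                    "chosen_side", "reward_delivered")
OPTIONAL_COLUMNS = ("pa", "test_side", "cond")


def format_gamble(g: Gamble) -> str:
    """Serialize a gamble as ``"m1:p1;m2:p2;..."`` (repr-exact floats)."""
    return ";".join(f"{m!r}:{p!r}" for m, p in g.outcomes)


def parse_gamble(s: str) -> Gamble:
    """Inverse of :func:`format_gamble`."""
    try:
        pairs = [tuple(float(x) for x in part.split(":"))
                 for part in s.strip().split(";")]
        if any(len(p) != 2 for p in pairs):
            raise ValueError("each outcome must be 'magnitude:probability'")
        return Gamble(pairs)
    except (ValueError, GambleError) as err:
        raise GambleError(f"malformed gamble string {s!r}: {err}") from err


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as tab-delimited text."""
    out = trials.copy()
    for col in ("gamble_left", "gamble_right"):
        out[col] = out[col].map(format_gamble)
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table; derive history columns.

    Raises a parse error naming the offending row for malformed gamble
    strings or unknown side codes.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: empty trial table")
        df["prev_choice"] = pd.Series(dtype=int)
        df["prev_reward"] = pd.Series(dtype=float)
        return df
    for col in ("gamble_left", "gamble_right"):
        parsed = []
        for i, s in enumerate(df[col]):
            try:
                parsed.append(parse_gamble(s))
            except GambleError as err:
                raise GambleError(f"row {i + 2} ({col}): {err}") from err
        df[col] = parsed
    bad = ~df["chosen_side"].isin(["L", "R"])
    if bad.any():
        raise ValueError(f"row {int(np.flatnonzero(bad)[0]) + 2}: chosen_side "
                         f"must be 'L' or 'R'")
    df = df.sort_values(["session", "trial"], kind="stable").reset_index(drop=True)
    prev_choice = np.zeros(len(df), int)
    prev_reward = np.zeros(len(df), float)
    for _, idx in df.groupby("session").indices.items():
        idx = np.sort(idx)
        ch = np.where(df.loc[idx, "chosen_side"].to_numpy() == "R", 1, -1)
        prev_choice[idx[1:]] = ch[:-1]
        prev_reward[idx[1:]] = df.loc[idx, "reward_delivered"].to_numpy()[:-1]
    df["prev_choice"] = prev_choice
    df["prev_reward"] = prev_reward
    return df


def read_config(path: str | Path) -> dict:
    """Load a YAML pipeline config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write stage results as delimited tables plus a JSON summary.

    ``results`` maps stage names to DataFrames (written as ``<name>.tsv``)
    or to JSON-serializable objects (collected into ``summary.json``).
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=bool(obj.index.name))
            written.append(p)
        else:
            summary[name] = obj
    if summary:
        p = out_dir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, default=_json_default))
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Gamble):
        return format_gamble(obj)
    return str(obj)
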
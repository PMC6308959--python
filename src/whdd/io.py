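"""File formats: sample-stream CSV, baseline JSON, YAML configs, logs.

Sample stream CSV columns (one row per 0.5 s epoch at the nominal 2 Hz):
``t_s, hr_bpm, skin_temp_c, gsr_us, amb_temp_c, rh_pct``.  A reading of 0
encodes a failed sensor read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from whdd.baseline import BaselineProfile
from whdd.filters import FilterConfig
from whdd.risk import FuzzyConfig
from whdd.simulate import SessionResult

__all__ = [
    "STREAM_COLUMNS",
    "read_stream",
    "write_stream",
    "read_baseline",
    "write_baseline",
    "read_filter_config",
    "write_filter_config",
    "read_fuzzy_config",
    "write_fuzzy_config",
    "write_session",
]

STREAM_COLUMNS = ["t_s", "hr_bpm", "skin_temp_c", "gsr_us",
                  "amb_temp_c", "rh_pct"]


def read_stream(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stream CSV missing columns {sorted(missing)}")
    return df[STREAM_COLUMNS]


def write_stream(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=STREAM_COLUMNS)


def read_baseline(path: str | Path) -> BaselineProfile:
    return BaselineProfile.from_json(Path(path).read_text())


def write_baseline(profile: BaselineProfile, path: str | Path) -> None:
    Path(path).write_text(profile.to_json() + "\n")


def read_filter_config(path: str | Path) -> FilterConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return FilterConfig.from_mapping(data)


def write_filter_config(config: FilterConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_fuzzy_config(path: str | Path) -> FuzzyConfig:
    return FuzzyConfig.from_mapping(yaml.safe_load(Path(path).read_text()))


def write_fuzzy_config(config: FuzzyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_session(session: SessionResult, out_dir: str | Path,
                  prefix: str | None = None) -> dict[str, Path]:
    """Write a simulated session's three files into ``out_dir``.

    Emits the observed sample CSV, the parallel latent-truth CSV, and the
    feedback-event log; returns the written paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = prefix or session.runner.name
    paths = {
        "observed": out / f"{stem}_stream.csv",
        "latent": out / f"{stem}_latent.csv",
        "events": out / f"{stem}_events.csv",
    }
    write_stream(session.observed, paths["observed"])
    session.latent.to_csv(paths["latent"], index=False)
    session.events.to_csv(paths["events"], index=False)
    return paths
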
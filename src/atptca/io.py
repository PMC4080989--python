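"""Delimited-text input/output for plate tables and layout configuration."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .plate import PLATE_COLUMNS, validate_plate_frame


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a comma-separated plate table.

    Columns: plate_id, well, condition, dilution_step (empty for controls),
    replicate, counts.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "condition": str})
    df["dilution_step"] = pd.to_numeric(df["dilution_step"], errors="coerce").astype("Int64")
    df["replicate"] = df["replicate"].astype(int)
    df["counts"] = df["counts"].astype(float)
    return validate_plate_frame(df)


def write_plate_csv(df: pd.DataFrame, path: str | Path) -> None:
    df = df.loc[:, list(PLATE_COLUMNS)]
    df.to_csv(path, index=False)


def read_layout(path: str | Path) -> dict:
    """Read the layout/config file (YAML).

    Expected keys: ``drugs`` (drug -> {tdc}), optional ``combinations``
    (list of {drug_a, drug_b}), optional ``groups`` (group -> [plate ids],
    tying single-agent and combination plates of one cell line together),
    optional ``cv_limit``, ``alpha``, ``seed``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "drugs" not in cfg:
        raise ValueError(f"{path}: layout file must define a 'drugs' mapping")
    for drug, spec in cfg["drugs"].items():
        if "tdc" not in spec:
            raise ValueError(f"{path}: drug {drug!r} needs a 'tdc' entry (uM)")
    return cfg


def write_layout(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
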
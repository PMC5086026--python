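"""CSV/JSON interchange with provenance headers.

All tabular artifacts are plain CSV with ISO-8601 dates.  Files written by
the pipeline carry a leading ``#``-comment line recording the config hash,
seed, and row count, and are read back with ``comment='#'``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ENCOUNTER_COLUMNS = [
    "patient_id", "category", "date", "specialty", "med_count", "msg_direction",
]
PATIENT_COLUMNS = ["patient_id", "age", "sex", "payer", "clinic", "provider"]


class InputError(ValueError):
    """Input file does not meet the header contract."""


def _require_columns(df: pd.DataFrame, required: list[str], label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{label} is missing required columns: {missing}")


def read_encounters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"specialty": str, "msg_direction": str})
    _require_columns(df, ENCOUNTER_COLUMNS, "encounters file")
    df["specialty"] = df["specialty"].fillna("")
    df["msg_direction"] = df["msg_direction"].fillna("")
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"sex": str})
    _require_columns(df, PATIENT_COLUMNS, "patients file")
    df["sex"] = df["sex"].fillna("")
    return df


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash} seed={seed} rows={len(df)}\n")
        df.to_csv(fh, index=index)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
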
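"""Plain-text formats: record CSVs, flat key-value configs, checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .lifetable import RECORD_COLS, records_frame


def write_records_csv(records, path) -> None:
    """Write records with header fly_id,isoline,sex,treatment,observed_age,event."""
    records_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} missing columns: {missing}")
    return df[RECORD_COLS]


def read_config(path) -> dict:
    """Flat key-value configuration ("key: value" per line; YAML-compatible)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
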
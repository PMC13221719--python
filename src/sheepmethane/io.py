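"""Plain-CSV dataset bundles, YAML configuration, and structured logs.

One CSV per entity (animals, emissions, dmi, weights, carcass, ct, maternal,
truth), ISO-8601 dates, floats at 10 significant digits so a read/write
round trip is byte-stable.  Logs are emitted both human-readable and as one
JSON object per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

BUNDLE_TABLES = ("animals", "emissions", "dmi", "weights", "carcass", "ct",
                 "maternal", "truth")
_DATE_COLS = ("measurement_date", "birth_date", "date", "slaughter_date", "scan_date")

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    df = df.copy()
    for c in df.columns:
        if c in _DATE_COLS:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in df.columns:
        if c in _DATE_COLS:
            df[c] = pd.to_datetime(df[c])
    return df


def write_bundle(bundle: dict, outdir, config: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        write_table(df, outdir / f"{name}.csv")
    if config is not None:
        (outdir / "simulation_config.yaml").write_text(
            yaml.safe_dump(config, sort_keys=False)
        )


def read_bundle(indir) -> dict:
    indir = Path(indir)
    bundle = {}
    for name in BUNDLE_TABLES:
        path = indir / f"{name}.csv"
        if path.exists():
            bundle[name] = read_table(path)
    return bundle


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


class RunLog:
    """Append-only structured log: plain text plus one JSON object per line."""

    def __init__(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self._jsonl = outdir / "log.jsonl"
        self._text = outdir / "log.txt"
        self._jsonl.write_text("")
        self._text.write_text("")

    def event(self, stage: str, message: str, **fields) -> None:
        rec = {"stage": stage, "message": message, **fields}
        with self._jsonl.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
        with self._text.open("a") as fh:
            extra = " ".join(f"{k}={v}" for k, v in fields.items())
            fh.write(f"[{stage}] {message} {extra}".rstrip() + "\n")
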
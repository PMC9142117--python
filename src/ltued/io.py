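"""Reading and writing the pipeline's plain-text tables.

All tables are delimiter-separated text with a header row; comma is the
default and tab is accepted.  Outputs optionally carry a ``# seed=N``
comment line so every artifact records the run seed; readers skip ``#``
comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_table(
    df: pd.DataFrame, path, delimiter: str = ",", seed: int | None = None
) -> Path:
    """Write a DataFrame as delimited text, with an optional seed header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep=delimiter, index=False)
    return path


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited table, sniffing comma vs tab unless told."""
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            line = fh.readline()
            while line.startswith("#"):
                line = fh.readline()
        delimiter = "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","
    return pd.read_csv(path, sep=delimiter, comment="#")


def write_json(obj, path, seed: int | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if seed is not None and isinstance(obj, dict):
        obj = {"seed": seed, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
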
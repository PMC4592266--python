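"""CSV reading/writing with a seed comment header."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a table as CSV, preceded by a ``# seed=...`` comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")
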
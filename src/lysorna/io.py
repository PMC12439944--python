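"""TSV reading and writing with the package's fixed dialect.

All tables are tab-separated, UTF-8, LF newlines, '.' decimal, header row,
gene_id (or the table's key column) first. Re-reading any written table
round-trips losslessly at double precision.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

PathLike = Union[str, Path]


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so round-trips are exact
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=None)
    return path
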
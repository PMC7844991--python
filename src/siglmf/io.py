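"""TSV dialects shared by every pipeline stage.

All matrices travel as tab-separated text: a header row of feature/column
ids, a first column of entity/row ids, missing values spelled ``NA``.
Keeping a single reader/writer pair here guarantees that whatever the
synthetic generator writes, the pipeline reads back bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

NA_REP = "NA"


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as the pipeline's TSV dialect (index = entity ids)."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=True)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP],
                       keep_default_na=False, float_precision="round_trip")


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plain table (no meaningful index), e.g. the mutation table."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=False)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP],
                       keep_default_na=False, float_precision="round_trip")


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path: str | Path, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
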
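"""Tabular input helpers: CSV/TSV reading and categorical encoding."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_tabular", "encode_categoricals"]

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_tabular(path, target: str, sep: str | None = None):
    """Read a CSV/TSV with a header row into (X, y, feature_names).

    Missing cells may be empty or "NA".  Categorical (non-numeric) feature
    columns are ordinal-encoded by target mean; the target column must be
    numeric.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=True)
    if target not in df.columns:
        raise ValueError(f"target column {target!r} not found in {path}")
    y = pd.to_numeric(df[target]).to_numpy(dtype=float)
    feats = df.drop(columns=[target])
    X = encode_categoricals(feats, y)
    return X, y, list(feats.columns)


def encode_categoricals(features: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Numeric matrix with non-numeric columns replaced by target means.

    Each category maps to the mean target of its rows (unseen/missing stays
    NaN), which gives categorical features a split-friendly ordering.
    """
    cols = []
    for name in features.columns:
        col = features[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            means = pd.Series(y, index=features.index).groupby(col, observed=True).mean()
            cols.append(col.map(means).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(features), 0))
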
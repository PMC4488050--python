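"""Child-level rectangular dataset container.

The analysis operates on a plain :class:`pandas.DataFrame` with ``NaN`` as
the missing marker; :class:`Dataset` is a light wrapper that carries
per-column metadata (units, whether a column is already on the log2 scale)
so that fitted models and reports can state the scale they worked on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "as_frame", "prepare_model_frame"]


@dataclass
class Dataset:
    """A rectangular child-level table with an explicit missing marker.

    Parameters
    ----------
    df : pandas.DataFrame
        Numeric table; missing cells are ``NaN``.
    units : dict
        Optional per-column unit strings (e.g. ``{"pfos_7": "ng/mL"}``).
    log2_columns : tuple
        Names of columns already on the log2 scale.
    """

    df: pd.DataFrame
    units: dict = field(default_factory=dict)
    log2_columns: tuple = ()

    @property
    def columns(self):
        return list(self.df.columns)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)


def as_frame(data) -> pd.DataFrame:
    """Return the underlying DataFrame of a Dataset or pass a frame through."""
    if isinstance(data, Dataset):
        return data.df
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError(f"expected Dataset or DataFrame, got {type(data).__name__}")


def prepare_model_frame(data, concentration_cols, covariate_cols=()):
    """Log2-transform concentration columns for modeling.

    Nonpositive concentrations cannot be log-transformed; those cells are set
    to missing and counted.

    Returns
    -------
    frame : pandas.DataFrame
        Copy with ``concentration_cols`` replaced by their log2 values.
    n_nonpositive : int
        Number of cells flagged as nonpositive and set to missing.
    """
    df = as_frame(data).copy()
    n_bad = 0
    for col in concentration_cols:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in data")
        x = df[col].to_numpy(dtype=float)
        bad = np.isfinite(x) & (x <= 0)
        n_bad += int(bad.sum())
        x = np.where(bad, np.nan, x)
        with np.errstate(invalid="ignore"):
            df[col] = np.log2(x)
    for col in covariate_cols:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in data")
    return df, n_bad
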
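"""Dataset and report I/O: CSV tables, column dictionaries, config files."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import ANTIBODY_COLUMNS, PFAS_COLUMNS, PRE_COLUMNS, CohortConfig
from .data import Dataset, as_frame

__all__ = ["ColumnDictionary", "LoadReport", "load_dataset", "write_dataset",
           "read_cohort_config", "write_cohort_config", "write_report_bundle"]

STANDARD_UNITS = {
    **{c: "ng/mL" for c in PFAS_COLUMNS},
    **{c: "IU/mL" for c in (*ANTIBODY_COLUMNS, *PRE_COLUMNS)},
    "albumin_5": "g/L", "albumin_7": "g/L", "age": "years", "bmi": "kg/m^2",
    "sex": "indicator (girl = 1)", "booster_type": "indicator (type 1 = 1)",
}

CONCENTRATION_COLUMNS = (*PFAS_COLUMNS, *ANTIBODY_COLUMNS, *PRE_COLUMNS)


@dataclass
class ColumnDictionary:
    """Mapping from logical variable names to file column names.

    By default the file uses the logical names directly.  ``missing_token``
    is the string marking a missing cell (default: empty cell).
    """

    mapping: dict = field(default_factory=dict)
    missing_token: str = ""

    def file_name(self, logical: str) -> str:
        return self.mapping.get(logical, logical)


@dataclass
class LoadReport:
    n_rows: int
    n_cols: int
    nonpositive_rows: dict      # logical concentration column -> row indices
    missing_frac: dict


def load_dataset(path, dictionary: ColumnDictionary | None = None,
                 required=()):
    """Read a child-level CSV into a Dataset.

    Nonpositive concentration cells are flagged in the report (they cannot
    be log2-transformed and will be excluded by the analyses).

    Returns (dataset, report).
    """
    dictionary = dictionary or ColumnDictionary()
    na = [dictionary.missing_token, "NA", "NaN", "nan"]
    raw = pd.read_csv(path, na_values=na, keep_default_na=True)
    rename = {dictionary.file_name(k): k for k in
              set(list(dictionary.mapping) + list(STANDARD_UNITS))
              if dictionary.file_name(k) in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"required column(s) absent from {path}: {missing}")
    for c in df.columns:
        if c == "child_id":
            continue
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable cell in column {c!r}: {exc}") from exc
    nonpos = {}
    for c in CONCENTRATION_COLUMNS:
        if c in df.columns:
            bad = df.index[df[c].notna() & (df[c] <= 0)].tolist()
            if bad:
                nonpos[c] = bad
    report = LoadReport(
        n_rows=len(df), n_cols=df.shape[1], nonpositive_rows=nonpos,
        missing_frac={c: float(df[c].isna().mean()) for c in df.columns})
    units = {c: STANDARD_UNITS[c] for c in df.columns if c in STANDARD_UNITS}
    return Dataset(df=df, units=units), report


def write_dataset(data, path):
    df = as_frame(data)
    df.to_csv(path, index=False, na_rep="")


def read_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


def write_cohort_config(config: CohortConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_report_bundle(report, out_dir):
    """Write an AnalysisReport as CSV tables plus a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.regression_table is not None:
        report.regression_table.to_csv(out / "per_chemical_effects.csv",
                                       index=False)
    if report.joint_table is not None:
        report.joint_table.to_csv(out / "joint_pfas_effects.csv", index=False)
    if report.fit_indices:
        rows = []
        for name, fi in report.fit_indices.items():
            rows.append({"model": name, "chi2": fi.chi2, "df": fi.df,
                         "p": fi.p, "rmsea": fi.rmsea, "cfi": fi.cfi,
                         "srmr": fi.srmr, "n": fi.n})
        pd.DataFrame(rows).to_csv(out / "fit_indices.csv", index=False)
    for key, chk in report.spline_checks.items():
        safe = key.replace(":", "_").replace("/", "_")
        chk.curve.to_csv(out / f"spline_curve_{safe}.csv", index=False)
    (out / "summary.txt").write_text(report.summary() + "\n")
    return out
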
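"""CSV/YAML/JSON readers and writers for the documented file schemas.

Schemas (all plain text):

* rate tables — CSV with ``age_start, age_end, rate`` (inclusive integer
  ages, probability per person-year);
* SNP tables — CSV with ``snp.name, snp.odds.ratio, snp.freq``;
* model spec — YAML or JSON with ``covariates`` (name/type/levels),
  ``interactions``, ``log_relative_risks`` and optional
  ``family_history_name``;
* profiles / reference / study data — CSV, one row per subject; the markers
  ``""`` and ``NA`` denote missing values.

Round trips are lossless for finite values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ModelSpec
from .rates import RateTable
from .snps import SnpInfo
from .validation import ValidationReport

__all__ = [
    "read_rate_table",
    "read_snp_table",
    "read_model_spec",
    "read_profiles",
    "read_study",
    "write_predictions",
    "write_report",
]

_NA_VALUES = ["", "NA"]


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=True, **kw)


def _require_columns(df: pd.DataFrame, expected: list[str], path, what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} file {path}: expected columns {expected}, "
            f"found {list(df.columns)} (missing {missing})"
        )


def read_rate_table(path: str | Path) -> RateTable:
    df = _read_csv(path)
    _require_columns(df, ["age_start", "age_end", "rate"], path, "rate table")
    try:
        return RateTable.from_dataframe(df)
    except ValueError as err:
        raise ValueError(f"rate table file {path}: {err}") from err


def read_snp_table(path: str | Path) -> SnpInfo:
    df = _read_csv(path)
    _require_columns(df, ["snp.name", "snp.odds.ratio", "snp.freq"], path, "SNP table")
    try:
        return SnpInfo.from_dataframe(df)
    except ValueError as err:
        raise ValueError(f"SNP table file {path}: {err}") from err


def read_model_spec(path: str | Path) -> ModelSpec:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    return ModelSpec.from_dict(payload)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Covariate or genotype profiles; missing markers map to NaN."""
    return _read_csv(path)


def read_study(path: str | Path) -> pd.DataFrame:
    """Validation study data with the standard follow-up columns."""
    df = _read_csv(path)
    _require_columns(
        df, ["observed.outcome", "study.entry.age", "study.exit.age"], path, "study"
    )
    return df


def write_predictions(results, path: str | Path, reference_path: str | Path | None = None) -> None:
    """Write per-profile predictions (and optionally reference risks) as CSV."""
    results.predictions.to_csv(path, index=False)
    if reference_path is not None and results.reference_risks is not None:
        pd.DataFrame(
            {
                "reference_row": np.arange(1, results.reference_risks.size + 1),
                "risk": results.reference_risks,
                "linear_predictor": results.reference_linear_predictors,
            }
        ).to_csv(reference_path, index=False)


def write_report(report: ValidationReport, text_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    """Plain-text validation report plus its machine-readable JSON twin."""
    Path(text_path).write_text(str(report) + "\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
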
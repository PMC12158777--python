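"""Cohort CSV input/output and the external-cohort column-mapping layer.

A cohort table is a plain pandas DataFrame carrying the canonical columns of
:mod:`compositebias.names` — heights in centimetres, weights in kilograms,
binary variables in the study encodings (malaise inverted: 1 = Normal).
``read_cohort`` maps a user CSV onto that canonical layout via a
:class:`ColumnMapping`, recodes and unit-converts, drops incomplete rows
(complete-case, with a warning above 10% missingness), and attaches the six
composite columns.

The external mode for the real birth-cohort extract is a documented recipe:
a mapping file ships with the package (``examples/ncds_mapping.yaml``), but
the data themselves are access-gated and never bundled or fetched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import names as N
from .composites import add_composite_columns

logger = logging.getLogger(__name__)

#: canonical variables a mapping must cover before any analysis can run
REQUIRED_VARIABLES = (
    N.ETHNICITY,
    N.SEX,
    N.HEIGHT_SELF,
    N.HEIGHT_MEASURED,
    N.WEIGHT_BASE,
    N.WEIGHT_FOLLOW,
)

#: optional exposure variables (needed only when analysed)
OPTIONAL_VARIABLES = (N.ECONOMIC_STATUS, N.MALAISE)

BINARY_VARIABLES = (N.ETHNICITY, N.SEX, N.ECONOMIC_STATUS, N.MALAISE)
HEIGHT_VARIABLES = (N.HEIGHT_SELF, N.HEIGHT_MEASURED)
WEIGHT_VARIABLES = (N.WEIGHT_BASE, N.WEIGHT_FOLLOW)


@dataclass
class ColumnMapping:
    """Map canonical variable names onto the columns of a user CSV.

    ``columns``: canonical name -> CSV column name; ``encodings``: canonical
    binary name -> {observed level: 0/1}; ``height_unit``: the unit heights
    are recorded in ('cm' or 'm'; canonical storage is cm).
    """

    columns: dict[str, str]
    encodings: dict[str, dict] = field(default_factory=dict)
    height_unit: str = "cm"

    def __post_init__(self) -> None:
        if self.height_unit not in ("cm", "m"):
            raise ValueError("height_unit must be 'cm' or 'm'")
        unknown = set(self.columns) - set(REQUIRED_VARIABLES) - set(OPTIONAL_VARIABLES)
        if unknown:
            raise ValueError(f"mapping names unknown canonical variables: {sorted(unknown)}")
        missing = [v for v in REQUIRED_VARIABLES if v not in self.columns]
        if missing:
            raise ValueError(f"mapping must cover required variables; missing: {missing}")

    def to_dict(self) -> dict:
        return {"columns": dict(self.columns),
                "encodings": {k: dict(v) for k, v in self.encodings.items()},
                "height_unit": self.height_unit}

    @classmethod
    def from_dict(cls, data: dict) -> "ColumnMapping":
        return cls(columns=dict(data["columns"]),
                   encodings={k: dict(v) for k, v in data.get("encodings", {}).items()},
                   height_unit=data.get("height_unit", "cm"))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ColumnMapping":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(data)


def identity_mapping() -> ColumnMapping:
    """Mapping for a CSV already in canonical columns/units/encodings."""
    cols = {v: v for v in (*REQUIRED_VARIABLES, *OPTIONAL_VARIABLES)}
    return ColumnMapping(columns=cols)


def _decode_binary(series: pd.Series, variable: str, encoding: dict) -> pd.Series:
    """Recode observed levels to canonical 0/1; unknown levels are an error."""
    decoded = pd.Series(np.nan, index=series.index, dtype=float)
    mask_missing = series.isna()
    str_keys = {str(k): v for k, v in encoding.items()}
    observed = series[~mask_missing]
    unknown = sorted(set(str(v) for v in observed) - set(str_keys))
    if unknown:
        raise ValueError(
            f"column for {variable!r} has levels {unknown} not covered by the "
            f"encoding {sorted(str_keys)}")
    decoded.loc[~mask_missing] = [float(str_keys[str(v)]) for v in observed]
    return decoded


def read_cohort(path: str | Path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Read a cohort CSV into canonical form and attach composite columns.

    Complete-case over the mapped variables: rows missing any mapped value are
    dropped with a log line reporting the counts; a missingness fraction above
    10% triggers a warning (analyses grow unreliable beyond that).
    Non-positive heights or weights are rejected with their row indices.
    """
    mapping = mapping or identity_mapping()
    raw = pd.read_csv(path)
    missing_cols = [c for c in mapping.columns.values() if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"CSV lacks mapped columns: {missing_cols}")

    out = pd.DataFrame(index=raw.index)
    for canonical, source in mapping.columns.items():
        col = raw[source]
        if canonical in BINARY_VARIABLES and canonical in mapping.encodings:
            out[canonical] = _decode_binary(col, canonical, mapping.encodings[canonical])
        else:
            out[canonical] = pd.to_numeric(col, errors="coerce")
        if canonical in BINARY_VARIABLES and canonical not in mapping.encodings:
            levels = set(out[canonical].dropna().unique())
            if not levels <= {0.0, 1.0}:
                raise ValueError(
                    f"column for {canonical!r} has levels {sorted(levels)}; "
                    f"provide an encoding mapping them to 0/1")

    if mapping.height_unit == "m":
        for h in HEIGHT_VARIABLES:
            if h in out.columns:
                out[h] = out[h] * 100.0

    for col in (*HEIGHT_VARIABLES, *WEIGHT_VARIABLES):
        if col in out.columns:
            bad = out.index[out[col].notna() & (out[col] <= 0)].tolist()
            if bad:
                raise ValueError(
                    f"non-positive values in {col!r} (kg/cm) at rows {bad}")

    n_read = len(out)
    complete = out.dropna()
    n_dropped = n_read - len(complete)
    frac = n_dropped / n_read if n_read else 0.0
    logger.info("read_cohort(%s): %d records read, %d dropped as incomplete "
                "(missingness %.1f%%)", path, n_read, n_dropped, 100 * frac)
    if frac > 0.10:
        logger.warning("missingness %.1f%% exceeds 10%%; complete-case "
                       "analyses are likely biased", 100 * frac)
    return add_composite_columns(complete.reset_index(drop=True))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical cohort table as comma-separated UTF-8 with header."""
    cohort.to_csv(path, index=False)
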
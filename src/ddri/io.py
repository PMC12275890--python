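"""Reading, validation, preprocessing and stratification of laboratory result tables.

The pipeline consumes a flat delimited table with one laboratory test result
per row: a numeric analyte value, patient age in whole years, sex, an
administrative case identifier, and up to five three-character ICD-10
category codes (e.g. ``N18``).  This module turns such a table into
sex × age-band strata, each holding its Global Distribution (GD) of values.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ddri")

#: three-character ICD-10 category code: one uppercase letter + two digits
CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}$")

SEXES = ("female", "male")

#: adult age span covered by the stratification
AGE_MIN = 20
AGE_MAX = 89


@dataclass(frozen=True, slots=True)
class TestResult:
    """One laboratory measurement with demographics and associated ICD-10 codes."""

    value: float
    age: int
    sex: str
    case_id: str
    codes: tuple[str, ...] = ()
    time: str | None = None


@dataclass(frozen=True)
class Dialect:
    """Column mapping and parsing configuration for the input table."""

    value_col: str = "value"
    age_col: str = "age"
    sex_col: str = "sex"
    case_col: str = "case_id"
    code_cols: tuple[str, ...] = ("code1", "code2", "code3", "code4", "code5")
    time_col: str | None = None
    delimiter: str = ","
    # raw label -> canonical sex; labels not mapped are kept verbatim and
    # removed during preprocessing with audit reason "unknown_sex"
    sex_map: dict[str, str] = field(
        default_factory=lambda: {
            "female": "female", "f": "female", "w": "female",
            "male": "male", "m": "male",
        }
    )


@dataclass
class Audit:
    """Record-removal bookkeeping for :func:`preprocess`.

    ``removed`` counts whole-record removals by reason and satisfies
    ``len(input) == len(output) + sum(removed.values())``.  ``codes_dropped``
    counts malformed codes stripped from otherwise-kept records.
    """

    removed: Counter = field(default_factory=Counter)
    codes_dropped: int = 0

    def total_removed(self) -> int:
        return sum(self.removed.values())


@dataclass
class Stratum:
    """One sex × age-band slice with its Global Distribution of values."""

    sex: str
    age_lo: int
    age_hi: int
    results: list[TestResult] = field(default_factory=list)

    @property
    def gd_values(self) -> np.ndarray:
        """All analyte values in the slice, before any DD removal."""
        return np.array([r.value for r in self.results], dtype=float)

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_lo}-{self.age_hi}"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.results)


class ConfigurationError(ValueError):
    """Raised for invalid column mappings or impossible parameter combinations."""


def read_results(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[TestResult], list[dict]]:
    """Read a delimited result table into :class:`TestResult` records.

    No filtering is applied; empty code cells are compacted out of the code
    list.  Rows whose value or age cell is present but unparseable are not
    converted; they are returned in the rejects report instead.

    Returns
    -------
    (results, rejects)
        ``rejects`` is a list of ``{"row": index, "reason": str}`` entries.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)

    required = [dialect.value_col, dialect.age_col, dialect.sex_col, dialect.case_col]
    required += list(dialect.code_cols)
    if dialect.time_col:
        required.append(dialect.time_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing input column(s): {', '.join(missing)}")

    results: list[TestResult] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        raw_value = rec[dialect.value_col].strip()
        if raw_value == "":
            value = float("nan")  # removed later as missing_value
        else:
            try:
                value = float(raw_value)
            except ValueError:
                rejects.append({"row": i, "reason": f"unparseable value {raw_value!r}"})
                continue
        raw_age = rec[dialect.age_col].strip()
        try:
            age = int(float(raw_age)) if raw_age else -1
        except ValueError:
            rejects.append({"row": i, "reason": f"unparseable age {raw_age!r}"})
            continue
        sex_raw = rec[dialect.sex_col].strip()
        sex = dialect.sex_map.get(sex_raw.lower(), sex_raw)
        codes = tuple(
            rec[c].strip() for c in dialect.code_cols if rec[c].strip() != ""
        )
        time = rec[dialect.time_col].strip() if dialect.time_col else None
        results.append(
            TestResult(
                value=value, age=age, sex=sex,
                case_id=rec[dialect.case_col].strip(), codes=codes, time=time,
            )
        )
    return results, rejects


def _dedupe_first_per_case(results: Sequence[TestResult], audit: Audit) -> list[TestResult]:
    """Keep the first result per administrative case.

    "First" is file order, or time order (stable tie-break on file order)
    when records carry a timestamp.
    """
    ordered = list(results)
    if ordered and all(r.time is not None for r in ordered):
        ordered = sorted(ordered, key=lambda r: r.time)  # stable sort
    seen: set[str] = set()
    kept = []
    for r in ordered:
        if r.case_id in seen:
            audit.removed["duplicate_case"] += 1
        else:
            seen.add(r.case_id)
            kept.append(r)
    return kept


def preprocess(
    results: Sequence[TestResult],
    value_min: float = 0.5,
    value_max: float = 12.0,
    *,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
    strict_code_filter: bool = False,
) -> tuple[list[TestResult], Audit]:
    """Apply the study-population filters and return kept records plus an audit.

    Steps, in order: keep the first result per case; remove records with an
    unknown sex label, age outside ``[age_min, age_max]``, a missing value, or
    a non-positive / implausible value (outside ``[value_min, value_max]``).
    Malformed ICD-10 codes are dropped from the code list (the measurement
    itself remains valid); with ``strict_code_filter`` the whole record is
    removed instead.
    """
    if not value_min < value_max:
        raise ConfigurationError("value_min must be < value_max")
    audit = Audit()
    kept: list[TestResult] = []
    for r in _dedupe_first_per_case(results, audit):
        if r.sex not in SEXES:
            audit.removed["unknown_sex"] += 1
            continue
        if not (age_min <= r.age <= age_max):
            audit.removed["invalid_age"] += 1
            continue
        if r.value is None or np.isnan(r.value):
            audit.removed["missing_value"] += 1
            continue
        if not np.isfinite(r.value) or r.value <= 0 or not (value_min <= r.value <= value_max):
            audit.removed["implausible_value"] += 1
            continue
        bad = [c for c in r.codes if not CODE_PATTERN.match(c)]
        if bad and strict_code_filter:
            audit.removed["erroneous_code"] += 1
            continue
        if bad:
            audit.codes_dropped += len(bad)
            r = replace(r, codes=tuple(c for c in r.codes if CODE_PATTERN.match(c)))
        # de-duplicate codes within a record, preserving order
        if len(set(r.codes)) != len(r.codes):
            seen: set[str] = set()
            uniq = tuple(c for c in r.codes if not (c in seen or seen.add(c)))
            r = replace(r, codes=uniq)
        kept.append(r)
    return kept, audit


def age_bands(band_width: int = 10, age_min: int = AGE_MIN, age_max: int = AGE_MAX) -> list[tuple[int, int]]:
    """Inclusive age bands covering ``[age_min, age_max]``."""
    span = age_max - age_min + 1
    if band_width < 1 or span % band_width != 0:
        raise ConfigurationError(
            f"band_width {band_width} does not evenly divide the {age_min}-{age_max} span"
        )
    return [(lo, lo + band_width - 1) for lo in range(age_min, age_max + 1, band_width)]


def stratify(
    results: Sequence[TestResult],
    band_width: int = 10,
    *,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> list[Stratum]:
    """Partition preprocessed results into sex × age-band strata.

    Every result falls in exactly one stratum; all (sex, band) combinations
    are returned even if empty (2 × span/band_width strata).
    """
    bands = age_bands(band_width, age_min, age_max)
    strata = {
        (sex, lo): Stratum(sex=sex, age_lo=lo, age_hi=hi)
        for sex in SEXES
        for lo, hi in bands
    }
    for r in results:
        lo = age_min + ((r.age - age_min) // band_width) * band_width
        key = (r.sex, lo)
        if r.sex not in SEXES or not (age_min <= r.age <= age_max):
            raise RuntimeError(
                f"unpreprocessed result reached stratify: sex={r.sex} age={r.age}"
            )
        strata[key].results.append(r)
    return list(strata.values())


def results_to_frame(results: Iterable[TestResult], n_code_cols: int = 5) -> pd.DataFrame:
    """Flatten records back to the tabular input dialect."""
    rows = []
    for r in results:
        row = {"value": r.value, "age": r.age, "sex": r.sex, "case_id": r.case_id}
        for j in range(n_code_cols):
            row[f"code{j + 1}"] = r.codes[j] if j < len(r.codes) else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: Iterable[TestResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def write_audit(audit: Audit, path: str | Path) -> None:
    """Audit report CSV: one (reason, count) row per removal reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reason", "count"])
        for reason, count in sorted(audit.removed.items()):
            w.writerow([reason, count])
        w.writerow(["codes_dropped (informational, records kept)", audit.codes_dropped])
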
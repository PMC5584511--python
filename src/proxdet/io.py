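"""Reading, validating and writing flat CSV survey microdata.

Two tables are used throughout the package:

``women`` — one row per respondent with her interview-time state
(dates in century-month code, union status, current contraceptive
method, postpartum amenorrhea/abstinence flags, stratifiers, sampling
weight).

``births`` — one row per live birth, keyed by ``woman_id`` with the
child's date of birth in century-month code (CMC: integer months since
January 1900, the DHS date encoding).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .config import EDUCATION_LEVELS, METHODS, NO_METHOD, RESIDENCE_LEVELS
from .errors import MicrodataValidationError, ReferentialError, SchemaError

logger = logging.getLogger(__name__)

WOMEN_COLUMNS = [
    "woman_id",
    "dob_cmc",
    "interview_cmc",
    "currently_married",
    "age_at_first_marriage_years",
    "current_method",
    "amenorrheic",
    "abstaining",
    "residence",
    "education",
    "weight",
]
BIRTHS_COLUMNS = ["woman_id", "birth_cmc"]

_VALID_METHODS = set(METHODS) | {NO_METHOD}


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    got = list(df.columns)
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        if not parts:
            parts.append(f"columns out of order: got {got}")
        raise SchemaError(f"{path}: " + "; ".join(parts))


def _parse_int(s: pd.Series, name, errors, allow_missing=False):
    out = pd.to_numeric(s.replace("", np.nan), errors="coerce")
    bad = out.isna() & (s != "" if allow_missing else True)
    nonint = ~out.isna() & (out != out.round())
    for idx in s.index[bad | nonint]:
        errors.append((idx + 1, f"{name} is not an integer: {s[idx]!r}"))
    return out


def _parse_bool(s: pd.Series, name, errors, missing_to=None):
    out = pd.Series(np.nan, index=s.index, dtype=float)
    out[s == "0"] = 0.0
    out[s == "1"] = 1.0
    bad = out.isna() & (s != "")
    for idx in s.index[bad]:
        errors.append((idx + 1, f"{name} must be 0 or 1, got {s[idx]!r}"))
    n_missing = int(((s == "") & ~bad).sum())
    if missing_to is not None:
        out = out.fillna(float(missing_to))
    return out, n_missing


def _parse_enum(s: pd.Series, name, valid, errors, missing_to=None):
    out = s.copy()
    if missing_to is not None:
        out = out.replace("", missing_to)
    bad = ~out.isin(valid)
    for idx in s.index[bad]:
        errors.append((idx + 1, f"unknown {name} code {s[idx]!r}"))
    return out


def read_women(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(raw, WOMEN_COLUMNS, path)
    errors: list[tuple[int, str]] = []
    out = pd.DataFrame(index=raw.index)
    out["woman_id"] = raw["woman_id"]
    dup = raw["woman_id"].duplicated(keep=False) & (raw["woman_id"] != "")
    for idx in raw.index[raw["woman_id"] == ""]:
        errors.append((idx + 1, "empty woman_id"))
    for idx in raw.index[dup]:
        errors.append((idx + 1, f"duplicate woman_id {raw['woman_id'][idx]!r}"))
    out["dob_cmc"] = _parse_int(raw["dob_cmc"], "dob_cmc", errors)
    out["interview_cmc"] = _parse_int(raw["interview_cmc"], "interview_cmc", errors)
    married, _ = _parse_bool(raw["currently_married"], "currently_married", errors)
    for idx in raw.index[married.isna()]:
        errors.append((idx + 1, "currently_married is missing"))
    out["currently_married"] = married.fillna(0.0).astype(bool)
    out["age_at_first_marriage_years"] = pd.to_numeric(
        raw["age_at_first_marriage_years"].replace("", np.nan), errors="coerce"
    )
    bad_afm = (
        out["age_at_first_marriage_years"].isna()
        & (raw["age_at_first_marriage_years"] != "")
    ) | (out["age_at_first_marriage_years"] < 0)
    for idx in raw.index[bad_afm]:
        errors.append(
            (idx + 1, "age_at_first_marriage_years is not a nonnegative number")
        )
    out["current_method"] = _parse_enum(
        raw["current_method"], "current_method", _VALID_METHODS, errors,
        missing_to=NO_METHOD,
    )
    amen, n_miss_a = _parse_bool(raw["amenorrheic"], "amenorrheic", errors, missing_to=0)
    abst, n_miss_b = _parse_bool(raw["abstaining"], "abstaining", errors, missing_to=0)
    if n_miss_a or n_miss_b:
        # conservative: missing postpartum flags count as not insusceptible
        logger.warning(
            "missing postpartum flags treated as not insusceptible "
            "(amenorrheic: %d, abstaining: %d rows)", n_miss_a, n_miss_b,
        )
    out["amenorrheic"] = amen.astype(bool)
    out["abstaining"] = abst.astype(bool)
    out["residence"] = _parse_enum(
        raw["residence"], "residence", set(RESIDENCE_LEVELS), errors
    )
    out["education"] = _parse_enum(
        raw["education"], "education", set(EDUCATION_LEVELS), errors
    )
    out["weight"] = pd.to_numeric(raw["weight"].replace("", np.nan), errors="coerce")
    bad_w = out["weight"].isna() | (out["weight"] < 0)
    for idx in raw.index[bad_w]:
        errors.append((idx + 1, f"weight must be a nonnegative number, got {raw['weight'][idx]!r}"))

    # age-at-interview invariant: completed months in [180, 600)
    with np.errstate(invalid="ignore"):
        age_m = out["interview_cmc"] - out["dob_cmc"]
        bad_age = age_m.notna() & ((age_m < 180) | (age_m >= 600))
    for idx in out.index[bad_age]:
        errors.append(
            (idx + 1, f"age at interview {age_m[idx] / 12:.1f}y outside [15, 50)")
        )
    if errors:
        raise MicrodataValidationError(sorted(set(errors)))
    out["dob_cmc"] = out["dob_cmc"].astype(int)
    out["interview_cmc"] = out["interview_cmc"].astype(int)
    return out


def read_births(path, women: pd.DataFrame) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(raw, BIRTHS_COLUMNS, path)
    errors: list[tuple[int, str]] = []
    out = pd.DataFrame(index=raw.index)
    out["woman_id"] = raw["woman_id"]
    out["birth_cmc"] = _parse_int(raw["birth_cmc"], "birth_cmc", errors)
    if errors:
        raise MicrodataValidationError(sorted(set(errors)))

    known = set(women["woman_id"])
    orphans = sorted(set(out["woman_id"]) - known)
    if orphans:
        raise ReferentialError(
            f"birth record(s) reference unknown woman_id(s): {orphans}"
        )
    mothers = women.set_index("woman_id")
    dob = out["woman_id"].map(mothers["dob_cmc"])
    itv = out["woman_id"].map(mothers["interview_cmc"])
    # no births before maternal age 10, none after the interview
    bad_lo = out["birth_cmc"] <= dob + 120
    bad_hi = out["birth_cmc"] > itv
    for idx in out.index[bad_lo]:
        errors.append((idx + 1, "birth before maternal age 10"))
    for idx in out.index[bad_hi]:
        errors.append((idx + 1, "birth after mother's interview"))
    if errors:
        raise MicrodataValidationError(sorted(set(errors)))
    out["birth_cmc"] = out["birth_cmc"].astype(int)
    return out


def read_microdata(women_path, births_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the women and births CSV tables.

    Returns typed DataFrames. Raises :class:`SchemaError` on header
    mismatch, :class:`MicrodataValidationError` with row-addressed
    messages on bad values, and :class:`ReferentialError` if a birth
    references an unknown woman.
    """
    women = read_women(women_path)
    births = read_births(births_path, women)
    return women, births


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, (bool, np.bool_)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return repr(float(x)) if x != int(x) else str(int(x)) + ".0"
    return str(x)


def write_microdata(women: pd.DataFrame, births: pd.DataFrame, out_dir) -> tuple[str, str]:
    """Write the two tables with deterministic formatting.

    Booleans are serialised as 0/1 and missing values as empty fields,
    so identical frames always produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    wpath = os.path.join(out_dir, "women.csv")
    bpath = os.path.join(out_dir, "births.csv")
    w = women.copy()
    for col in ("currently_married", "amenorrheic", "abstaining"):
        w[col] = w[col].astype(int)
    w["age_at_first_marriage_years"] = w["age_at_first_marriage_years"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}"
    )
    w["weight"] = w["weight"].map(lambda v: f"{v:.6g}")
    w[WOMEN_COLUMNS].to_csv(wpath, index=False, lineterminator="\n")
    births[BIRTHS_COLUMNS].to_csv(bpath, index=False, lineterminator="\n")
    return wpath, bpath
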
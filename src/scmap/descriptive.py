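"""Variable categorization and gender-stratified prevalence tabulation.

Individual-level records are held as a pandas DataFrame with one row per
subject and the columns of :data:`SUBJECT_COLUMNS` (missing values as NaN /
empty fields in the delimited-text form).  Categorizers implement the study
cut points: age bands 45-59 / 60-74 / 75+, Chinese-adult BMI classes with the
obese boundary at 28.0 kg/m^2 inclusive, and the waist-to-height ratio
(WHtR) 0.5 cut with 0.5 itself counted as "pear" (apple is strictly > 0.5).
"""

from __future__ import annotations

import decimal
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECT_COLUMNS",
    "categorize_age",
    "categorize_bmi",
    "categorize_whtr",
    "stratified_prevalence",
    "prevalence_from_counts",
    "overall_prevalence",
    "covariate_aggregates",
    "read_subject_table",
    "write_subject_table",
    "validate_subjects",
    "summed_totals",
    "round_half_up",
]

SUBJECT_COLUMNS = [
    "region", "gender", "age", "bmi", "waist", "height",
    "smoking", "alcohol", "sleep_night", "nap", "hypertension",
]

AGE_BANDS = ("45-59", "60-74", "75+")
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")
WHTR_CLASSES = ("pear", "apple")

_STRATIFIERS = ("age", "bmi", "whtr", "smoking", "alcohol")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (printed-table convention, not banker's)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def categorize_age(age) -> pd.Series | str:
    """Age band: middle-aged 45-59, young elderly 60-74, older 75+.

    Ages below the 45-year study entry criterion map to NaN and are reported
    through :func:`validate_subjects` as exclusions, never silently dropped.
    """
    scalar = np.isscalar(age)
    a = pd.Series(np.atleast_1d(np.asarray(age, dtype=float)))
    out = pd.Series(pd.NA, index=a.index, dtype="object")
    out[(a >= 45) & (a <= 59)] = "45-59"
    out[(a >= 60) & (a <= 74)] = "60-74"
    out[a >= 75] = "75+"
    return out.iloc[0] if scalar else out


def categorize_bmi(bmi) -> pd.Series | str:
    """BMI class at cut points 18.5 / 24.0 / 28.0 kg/m^2, obese = >= 28.0."""
    scalar = np.isscalar(bmi)
    b = pd.Series(np.atleast_1d(np.asarray(bmi, dtype=float)))
    out = pd.Series(pd.NA, index=b.index, dtype="object")
    valid = b > 0
    out[valid & (b < 18.5)] = "underweight"
    out[valid & (b >= 18.5) & (b < 24.0)] = "normal"
    out[valid & (b >= 24.0) & (b < 28.0)] = "overweight"
    out[valid & (b >= 28.0)] = "obese"
    return out.iloc[0] if scalar else out


def categorize_whtr(waist, height) -> pd.Series | str:
    """Body shape from waist/height: ratio <= 0.5 "pear", > 0.5 "apple"."""
    scalar = np.isscalar(waist) and np.isscalar(height)
    w = pd.Series(np.atleast_1d(np.asarray(waist, dtype=float)))
    h = pd.Series(np.atleast_1d(np.asarray(height, dtype=float)))
    out = pd.Series(pd.NA, index=w.index, dtype="object")
    valid = (w > 0) & (h > 0)
    ratio = w / h
    out[valid & (ratio <= 0.5)] = "pear"
    out[valid & (ratio > 0.5)] = "apple"
    return out.iloc[0] if scalar else out


def _stratum_series(records: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "age":
        return categorize_age(records["age"].to_numpy())
    if stratifier == "bmi":
        return categorize_bmi(records["bmi"].to_numpy())
    if stratifier == "whtr":
        return categorize_whtr(records["waist"].to_numpy(), records["height"].to_numpy())
    if stratifier in ("smoking", "alcohol"):
        s = records[stratifier].astype("object")
        return s.where(s.isin(["never", "current"]), pd.NA).reset_index(drop=True)
    raise ValueError(
        f"unknown stratifier {stratifier!r}; one of {_STRATIFIERS}"
    )


def _stratum_order(stratifier: str) -> tuple[str, ...]:
    return {
        "age": AGE_BANDS,
        "bmi": BMI_CLASSES,
        "whtr": WHTR_CLASSES,
        "smoking": ("never", "current"),
        "alcohol": ("never", "current"),
    }[stratifier]


def stratified_prevalence(records: pd.DataFrame, stratifier: str) -> pd.DataFrame:
    """Cases, denominators and percentages per (stratum, gender).

    Subjects with a missing stratum value drop out of that stratifier's
    denominators (published-table convention); strata with zero denominator
    are omitted with a warning.  Percentages are half-up rounded to two
    decimals and always recomputable from the returned counts.
    """
    if records.empty:
        raise ValueError("no subject records supplied")
    strata = _stratum_series(records.reset_index(drop=True), stratifier)
    df = records.reset_index(drop=True).assign(stratum=strata.to_numpy())
    rows = []
    for stratum in _stratum_order(stratifier):
        for gender in ("male", "female"):
            sub = df[(df["stratum"] == stratum) & (df["gender"] == gender)]
            denom = len(sub)
            if denom == 0:
                warnings.warn(
                    f"empty stratum ({stratifier}={stratum}, {gender}); omitted",
                    stacklevel=2,
                )
                continue
            cases = int(sub["hypertension"].sum())
            rows.append(
                {
                    "stratifier": stratifier,
                    "stratum": stratum,
                    "gender": gender,
                    "cases": cases,
                    "denominator": denom,
                    "percent": round_half_up(100.0 * cases / denom, 2),
                }
            )
    return pd.DataFrame(rows)


def prevalence_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach half-up two-decimal percentages to a (cases, denominator) table."""
    out = counts.copy()
    out["percent"] = [
        round_half_up(100.0 * c / d, 2)
        for c, d in zip(out["cases"], out["denominator"])
    ]
    return out


def overall_prevalence(
    counts: pd.DataFrame, stratifier: str = "age", by_gender: bool = False
) -> float | dict[str, float]:
    """Headline prevalence (one-decimal %) from summed stratum counts.

    Summing one stratifier's rows over strata (and genders unless
    ``by_gender``) recovers the cohort totals that stratifier covers; because
    subjects missing a stratum value are excluded from its denominators, the
    total can fall slightly short of full enrolment.
    """
    sub = counts[counts["stratifier"] == stratifier]
    if sub.empty:
        raise ValueError(f"no rows for stratifier {stratifier!r}")
    if by_gender:
        return {
            g: round_half_up(
                100.0 * grp["cases"].sum() / grp["denominator"].sum(), 1
            )
            for g, grp in sub.groupby("gender")
        }
    return round_half_up(100.0 * sub["cases"].sum() / sub["denominator"].sum(), 1)


def covariate_aggregates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(region, gender) covariate proportions for the regional model.

    Returns proportions in [0, 1] of subjects aged 60+, obese
    (BMI >= 28.0), WHtR > 0.5, current smokers and current drinkers, each
    computed among subjects non-missing on that variable.  A cell with zero
    non-missing subjects for a covariate gets NaN there and a raised
    ``missing`` flag (consumed by the model-side imputation step).
    """
    if records.empty:
        raise ValueError("no subject records supplied")
    df = records.reset_index(drop=True).copy()
    df["_elderly"] = (df["age"].astype(float) >= 60).where(df["age"].notna())
    df["_obese"] = (categorize_bmi(df["bmi"].to_numpy()) == "obese").where(
        df["bmi"].notna()
    )
    whtr = categorize_whtr(df["waist"].to_numpy(), df["height"].to_numpy())
    df["_apple"] = (whtr == "apple").where(whtr.notna().to_numpy())
    df["_smoke"] = (df["smoking"] == "current").where(df["smoking"].notna())
    df["_drink"] = (df["alcohol"] == "current").where(df["alcohol"].notna())
    rows = []
    for (region, gender), grp in df.groupby(["region", "gender"], sort=False):
        row: dict = {
            "region": region,
            "gender": gender,
            "cases": int(grp["hypertension"].sum()),
            "n": len(grp),
        }
        missing = []
        for name, col in [
            ("prop_elderly", "_elderly"),
            ("prop_obese", "_obese"),
            ("prop_apple", "_apple"),
            ("prop_smoking", "_smoke"),
            ("prop_alcohol", "_drink"),
        ]:
            vals = grp[col].dropna()
            if len(vals) == 0:
                row[name] = np.nan
                missing.append(name)
            else:
                row[name] = float(vals.astype(float).mean())
        row["missing"] = ",".join(missing)
        rows.append(row)
    return pd.DataFrame(rows)


def validate_subjects(records: pd.DataFrame) -> pd.DataFrame:
    """Schema check plus exclusion flags; returns records with an ``excluded`` column."""
    missing_cols = set(SUBJECT_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"subject table missing column(s): {sorted(missing_cols)}")
    bad_gender = ~records["gender"].isin(["male", "female"])
    if bad_gender.any():
        raise ValueError(
            f"invalid gender values at rows {list(records.index[bad_gender])[:5]}"
        )
    out = records.copy()
    out["excluded"] = (records["age"].astype(float) < 45).fillna(False)
    n_young = int(out["excluded"].sum())
    if n_young:
        warnings.warn(
            f"{n_young} record(s) below the 45-year entry criterion flagged",
            stacklevel=2,
        )
    return out


def read_subject_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    return validate_subjects(df)


def write_subject_table(records: pd.DataFrame, path, sep: str = "\t") -> None:
    records.loc[:, [c for c in SUBJECT_COLUMNS if c in records.columns]].to_csv(
        path, sep=sep, index=False
    )


def summed_totals(counts: pd.DataFrame, stratifier: str = "age") -> tuple[int, int]:
    """(cases, denominator) summed over one stratifier's rows, both genders."""
    sub = counts[counts["stratifier"] == stratifier]
    return int(sub["cases"].sum()), int(sub["denominator"].sum())
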
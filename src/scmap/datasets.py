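"""Bundled reference inputs.

The package ships two small reference objects used in worked examples and in
the reproduction scripts:

* the Zhejiang 11-prefecture contiguity graph (``zhejiang_map``), and
* the published gender-stratified prevalence table for the 2012
  middle-aged-and-elderly Zhejiang study population
  (``reference_prevalence_counts``), as printed counts
  ``cases/denominator`` per stratum and gender.

Also defined here are two study constants: the log shared-weight prior
variance (chosen so that the squared weight ratio lies in [1/5, 5] with 95 %
prior probability) and the self-report/measured concordance counts quoted for
hypertension ascertainment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .regions import RegionMap, read_adjacency

__all__ = [
    "zhejiang_map",
    "reference_prevalence_counts",
    "LOG_DELTA_PRIOR_VARIANCE",
    "BIOHP_CONCORDANT",
    "BIOHP_TOTAL",
]

#: Variance of the zero-mean normal prior on log(delta); sd ~= 0.411, which
#: places delta^2 in [1/5, 5] with ~95 % prior probability.
LOG_DELTA_PRIOR_VARIANCE = 0.169

#: Subjects positive on both self-reported and measured/medication-defined
#: hypertension, out of all self-reported cases (concordance worked example).
BIOHP_CONCORDANT = 387
BIOHP_TOTAL = 419


def zhejiang_map() -> RegionMap:
    """The 11-prefecture Zhejiang contiguity graph bundled with the package."""
    ref = resources.files("scmap.data").joinpath("zhejiang11.adj")
    with resources.as_file(ref) as path:
        return read_adjacency(path)


# (stratifier, stratum, gender) -> (cases, denominator); the published
# study's stratified self-reported hypertension table.
_REFERENCE_COUNTS = [
    ("age", "45-59", "male", 48, 235),
    ("age", "45-59", "female", 78, 307),
    ("age", "60-74", "male", 94, 273),
    ("age", "60-74", "female", 114, 253),
    ("age", "75+", "male", 44, 100),
    ("age", "75+", "female", 41, 96),
    ("smoking", "never", "male", 60, 179),
    ("smoking", "never", "female", 227, 642),
    ("smoking", "current", "male", 126, 428),
    ("smoking", "current", "female", 6, 14),
    ("alcohol", "never", "male", 59, 201),
    ("alcohol", "never", "female", 182, 520),
    ("alcohol", "current", "male", 38, 93),
    ("alcohol", "current", "female", 23, 55),
    ("bmi", "underweight", "male", 6, 30),
    ("bmi", "underweight", "female", 9, 31),
    ("bmi", "normal", "male", 64, 248),
    ("bmi", "normal", "female", 60, 242),
    ("bmi", "overweight", "male", 47, 119),
    ("bmi", "overweight", "female", 77, 158),
    ("bmi", "obese", "male", 13, 29),
    ("bmi", "obese", "female", 30, 55),
    ("whtr", "pear", "male", 29, 156),
    ("whtr", "pear", "female", 15, 85),
    ("whtr", "apple", "male", 103, 272),
    ("whtr", "apple", "female", 163, 408),
]


def reference_prevalence_counts() -> pd.DataFrame:
    """Published stratified counts as a tidy frame.

    Columns: stratifier, stratum, gender, cases, denominator.  Percentages
    are deliberately not stored; they are recomputed by
    :func:`scmap.descriptive.prevalence_from_counts`.
    """
    return pd.DataFrame(
        _REFERENCE_COUNTS,
        columns=["stratifier", "stratum", "gender", "cases", "denominator"],
    )
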
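"""Traditional comparison arm: univariate screen and stepwise logistic models.

Implements the individual-level analysis the spatial model is compared
against: a univariate logistic screen at p < 0.06 (likelihood-ratio test per
variable, all dummy levels jointly), forward-stepwise multivariable logistic
regression fitted separately per gender, Wald 95 % confidence intervals on
the log-odds scale, and variance-inflation-factor multicollinearity checks.
Fitting is delegated to statsmodels maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .descriptive import categorize_age, categorize_bmi, categorize_whtr

__all__ = [
    "CovariateSpec",
    "STUDY_COVARIATES",
    "build_design",
    "univariate_screen",
    "forward_stepwise",
    "fit_multivariable",
    "multicollinearity_check",
]

P_SCREEN = 0.06        # univariate entry threshold
P_ENTER = 0.05         # forward-stepwise entry threshold (LRT)


@dataclass(frozen=True)
class CovariateSpec:
    """A model variable: how to derive it from subject records and its reference level."""

    name: str
    levels: tuple[str, ...] = ()          # empty -> continuous
    reference: str | None = None

    @property
    def categorical(self) -> bool:
        return bool(self.levels)


#: The lifestyle/adiposity variables offered to the multivariable models.
STUDY_COVARIATES = (
    CovariateSpec("age_band", ("45-59", "60-74", "75+"), "45-59"),
    CovariateSpec("bmi_class", ("underweight", "normal", "overweight", "obese"), "normal"),
    CovariateSpec("whtr_class", ("pear", "apple"), "pear"),
    CovariateSpec("smoking", ("never", "current"), "never"),
    CovariateSpec("alcohol", ("never", "current"), "never"),
    CovariateSpec("sleep_night"),
)


def derive_variables(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the categorized analysis variables to a subject table."""
    df = records.reset_index(drop=True).copy()
    df["age_band"] = categorize_age(df["age"].to_numpy()).to_numpy()
    df["bmi_class"] = categorize_bmi(df["bmi"].to_numpy()).to_numpy()
    df["whtr_class"] = categorize_whtr(
        df["waist"].to_numpy(), df["height"].to_numpy()
    ).to_numpy()
    return df


def build_design(
    df: pd.DataFrame, covariates: list[CovariateSpec]
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (intercept + dummies vs. reference / continuous columns).

    Rows with a missing value on any requested covariate or the outcome are
    dropped listwise; the outcome is returned aligned.
    """
    cols: dict[str, np.ndarray] = {}
    keep = df["hypertension"].notna()
    for spec in covariates:
        keep &= df[spec.name].notna()
    sub = df.loc[keep]
    cols["const"] = np.ones(len(sub))
    for spec in covariates:
        if spec.categorical:
            for lvl in spec.levels:
                if lvl == spec.reference:
                    continue
                cols[f"{spec.name}[{lvl}]"] = (
                    (sub[spec.name] == lvl).astype(float).to_numpy()
                )
        else:
            cols[spec.name] = sub[spec.name].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=sub.index)
    y = sub["hypertension"].astype(float)
    return X, y


def _fit_logit(X: pd.DataFrame, y: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def _lrt_pvalue(df_full: pd.DataFrame, y: pd.Series, df_null: pd.DataFrame) -> float:
    full = _fit_logit(df_full, y)
    null = _fit_logit(df_null, y)
    lr = 2.0 * (full.llf - null.llf)
    dof = df_full.shape[1] - df_null.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), dof))


def univariate_screen(
    records: pd.DataFrame,
    candidates: tuple[CovariateSpec, ...] = STUDY_COVARIATES,
    p_threshold: float = P_SCREEN,
) -> tuple[list[CovariateSpec], pd.DataFrame]:
    """Select variables whose single-variable logistic LRT has p < threshold.

    The test is the likelihood-ratio test of the whole variable (all dummy
    levels jointly) against the intercept-only model.  Degenerate variables
    (constant after listwise deletion) are never selected; variables showing
    complete separation are flagged but retained in the report.
    """
    df = derive_variables(records)
    rows, selected = [], []
    for spec in candidates:
        X, y = build_design(df, [spec])
        flag = ""
        if X.shape[1] == 1 or any(X[c].std() == 0 for c in X.columns[1:]):
            warnings.warn(f"degenerate covariate {spec.name!r}", stacklevel=2)
            rows.append({"variable": spec.name, "p_value": np.nan,
                         "selected": False, "flag": "degenerate"})
            continue
        try:
            p = _lrt_pvalue(X, y, X[["const"]])
        except Exception:  # perfect separation can break Newton iterations
            p, flag = 0.0, "separation"
        if flag == "" and _is_separated(X, y):
            flag = "separation"
        sel = bool(p < p_threshold)
        rows.append({"variable": spec.name, "p_value": p, "selected": sel,
                     "flag": flag})
        if sel:
            selected.append(spec)
    return selected, pd.DataFrame(rows)


def _is_separated(X: pd.DataFrame, y: pd.Series) -> bool:
    try:
        res = _fit_logit(X, y)
    except Exception:
        return True
    return bool(np.any(np.abs(res.params.to_numpy()) > 15))


def forward_stepwise(
    df: pd.DataFrame,
    candidates: list[CovariateSpec],
    p_enter: float = P_ENTER,
) -> list[CovariateSpec]:
    """Forward selection by per-step LRT; stop when no candidate has p < p_enter."""
    chosen: list[CovariateSpec] = []
    remaining = list(candidates)
    while remaining:
        best, best_p = None, 1.0
        for spec in remaining:
            trial = chosen + [spec]
            X, y = build_design(df, trial)
            null_cols = ["const"] + [
                c for c in X.columns
                if c != "const" and not c.startswith(spec.name)
            ]
            try:
                p = _lrt_pvalue(X, y, X[null_cols])
            except Exception:
                continue
            if p < best_p:
                best, best_p = spec, p
        if best is None or best_p >= p_enter:
            break
        chosen.append(best)
        remaining.remove(best)
    return chosen


@dataclass
class ORTable:
    """Odds ratios with Wald 95 % intervals; reference levels carry OR 1."""

    gender: str
    table: pd.DataFrame = field(repr=False)
    converged: bool = True

    def to_text(self, path=None, sep: str = "\t") -> str | None:
        df = self.table.copy()
        df["sig"] = np.where(
            df["reference"].astype(bool) | df["p_value"].isna(), "",
            np.where(df["p_value"] < 0.05, "*", ""),
        )
        if path is None:
            return df.to_csv(sep=sep, index=False)
        df.to_csv(path, sep=sep, index=False)
        return None


def fit_multivariable(
    records: pd.DataFrame,
    gender: str,
    candidates: tuple[CovariateSpec, ...] = STUDY_COVARIATES,
    stepwise: bool = True,
    p_enter: float = P_ENTER,
) -> ORTable:
    """Gender-stratified multivariable logistic model as an OR table.

    ``candidates`` are the screened variables plus the forced lifestyle set;
    with ``stepwise`` they enter by forward LRT selection, otherwise all are
    fitted jointly.  Confidence intervals are Wald intervals built on the
    log-odds scale and exponentiated.
    """
    df = derive_variables(records)
    df = df[df["gender"] == gender]
    if df.empty:
        raise ValueError(f"no records for gender {gender!r}")
    chosen = (
        forward_stepwise(df, list(candidates), p_enter) if stepwise
        else list(candidates)
    )
    if not chosen:
        warnings.warn(f"stepwise retained no variables for {gender}", stacklevel=2)
        return ORTable(gender, pd.DataFrame(
            columns=["variable", "level", "reference", "odds_ratio",
                     "ci_low", "ci_high", "p_value"]))
    X, y = build_design(df, chosen)
    res = _fit_logit(X, y)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"logistic fit did not converge for {gender}: {res.mle_retvals}"
        )
    rows = []
    for spec in chosen:
        if spec.categorical:
            rows.append({"variable": spec.name, "level": spec.reference,
                         "reference": True, "odds_ratio": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "p_value": np.nan})
            names = [(lvl, f"{spec.name}[{lvl}]") for lvl in spec.levels
                     if lvl != spec.reference]
        else:
            names = [("", spec.name)]
        for lvl, col in names:
            beta = float(res.params[col])
            se = float(res.bse[col])
            rows.append({
                "variable": spec.name, "level": lvl, "reference": False,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p_value": float(res.pvalues[col]),
            })
    return ORTable(gender, pd.DataFrame(rows))


def multicollinearity_check(
    records: pd.DataFrame, covariates: tuple[CovariateSpec, ...]
) -> pd.DataFrame:
    """Variance inflation factors per design column (flag above 10).

    VIF_k = 1/(1 - R^2_k) from regressing column k on the remaining columns;
    exact linear dependence yields an infinite-VIF flag.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two covariates for a collinearity check")
    df = derive_variables(records)
    X, _ = build_design(df, list(covariates))
    cols = [c for c in X.columns if c != "const"]
    rows = []
    for col in cols:
        others = X[["const"] + [c for c in cols if c != col]].to_numpy()
        target = X[col].to_numpy()
        beta, res_ss, rank, _ = np.linalg.lstsq(others, target, rcond=None)
        tss = float(np.sum((target - target.mean()) ** 2))
        rss = float(np.sum((target - others @ beta) ** 2))
        if tss == 0 or rss / max(tss, 1e-300) < 1e-12:
            vif, flag = np.inf, "exact dependence"
        else:
            r2 = 1.0 - rss / tss
            vif = 1.0 / (1.0 - r2)
            flag = "high" if vif > 10 else ""
        rows.append({"column": col, "vif": vif, "flag": flag})
    return pd.DataFrame(rows)
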
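"""Log-linear geometric-mean-ratio age models and sensitivity analyses.

The analysis variable is person-level mean daily minutes of vigorous
(or moderate) activity.  Vigorous minutes are winsorized at the sample
99th percentile and, like moderate minutes, natural-log transformed;
ordinary least squares of the log outcome on age, monitor wear time and
study indicators then yields a per-year geometric-mean ratio
``exp(beta_age)`` with a normal-approximation 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import REFERENCE_LEVELS

#: Normal 95% critical value used for all interval back-transforms.
Z95 = 1.96

AGE_RANGE = (5.0, 18.0)


@dataclass(frozen=True)
class FitResult:
    """Age coefficient of one model, on the log and ratio scales."""

    beta_age: float
    se_beta: float
    ratio: float
    ratio_ci: tuple[float, float]
    pct_change: float
    p_value: float
    n: int
    covariates_used: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "beta_age": self.beta_age,
            "se_beta": self.se_beta,
            "ratio": self.ratio,
            "ci_low": self.ratio_ci[0],
            "ci_high": self.ratio_ci[1],
            "pct_change": self.pct_change,
            "p_value": self.p_value,
            "n": self.n,
            "covariates": "+".join(self.covariates_used),
        }


@dataclass(frozen=True)
class InteractionResult:
    moderator: str
    reference_level: str
    interaction_p: Mapping[str, float]  # per non-reference level
    joint_p: float
    joint_df: int
    stratified: Mapping[str, FitResult]


@dataclass(frozen=True)
class LeaveOneStudyOutResult:
    full: FitResult
    fits: Mapping[str, FitResult]
    sign_changes: Mapping[str, bool]


@dataclass
class BuildReport:
    """Row bookkeeping for dataset construction; never silently drops."""

    n_input_summaries: int = 0
    n_missing_metadata: int = 0
    missing_metadata_ids: list[str] = field(default_factory=list)
    n_after_first_measurement: int = 0
    n_excluded_age: int = 0
    n_final: int = 0


ANALYSIS_COLUMNS = [
    "participant_id", "age", "vpa_min", "mpa_min", "wear_min", "study_id",
    "sex", "ethnicity", "maternal_education", "weight_status", "region",
]


def build_analysis_dataset(
    person_summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    age_range: tuple[float, float] = AGE_RANGE,
) -> tuple[pd.DataFrame, BuildReport]:
    """Merge processed summaries with metadata under the inclusion rules.

    Keeps the earliest measurement per participant, then drops ages
    outside ``age_range`` (inclusive bounds).  Returns the analysis
    frame (one row per participant) plus a :class:`BuildReport`;
    summaries without metadata are listed there rather than silently
    discarded.
    """
    report = BuildReport(n_input_summaries=len(person_summaries))
    if person_summaries.empty:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS), report

    summaries = person_summaries.rename(
        columns={
            "mean_vpa_minutes": "vpa_min",
            "mean_mpa_minutes": "mpa_min",
            "mean_wear_minutes": "wear_min",
        }
    )
    meta_keys = ["participant_id"]
    if "measurement_date" in summaries.columns and "measurement_date" in metadata.columns:
        summaries = summaries.copy()
        metadata = metadata.copy()
        summaries["measurement_date"] = pd.to_datetime(summaries["measurement_date"])
        metadata["measurement_date"] = pd.to_datetime(metadata["measurement_date"])
        meta_keys.append("measurement_date")
    merged = summaries.merge(metadata, on=meta_keys, how="left", indicator=True)

    missing = merged["_merge"] == "left_only"
    report.n_missing_metadata = int(missing.sum())
    report.missing_metadata_ids = sorted(
        merged.loc[missing, "participant_id"].astype(str)
    )
    merged = merged.loc[~missing].drop(columns="_merge")

    if "measurement_date" in merged.columns:
        merged = merged.sort_values(["participant_id", "measurement_date"])
    first = merged.drop_duplicates("participant_id", keep="first")
    report.n_after_first_measurement = len(first)

    lo, hi = age_range
    in_age = (first["age"] >= lo) & (first["age"] <= hi)
    report.n_excluded_age = int((~in_age).sum())
    out = first.loc[in_age, [c for c in ANALYSIS_COLUMNS if c in first.columns]]
    out = out.reset_index(drop=True)
    report.n_final = len(out)
    return out, report


def winsorize_p99(values, percentile: float = 99.0) -> np.ndarray:
    """Cap values above the sample percentile at that percentile.

    The percentile is computed by linear interpolation of order
    statistics (numpy's default).  Values at or below the cap are
    returned unchanged.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("winsorization requires at least 2 finite values")
    cap = np.percentile(finite, percentile)
    return np.minimum(arr, cap)


def log_transform(values, zero_offset: float = 0.0) -> np.ndarray:
    """Natural log of ``values + zero_offset``.

    Zeros require a positive offset; negatives are always an error.
    """
    arr = np.asarray(values, dtype=float)
    if zero_offset < 0:
        raise ValueError("zero_offset must be >= 0")
    if np.any(arr < 0):
        raise ValueError("negative values cannot be log-transformed")
    if zero_offset == 0 and np.any(arr == 0):
        raise ValueError(
            "zero values present: set a positive zero_offset to log-transform"
        )
    return np.log(arr + zero_offset)


def ratio_and_pct(
    beta: float, se: float
) -> tuple[float, tuple[float, float], float]:
    """Back-transform a log-scale slope to (ratio, 95% CI, percent change).

    ``pct_change`` is signed: negative values are relative decreases per
    year of age.
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    ratio = float(np.exp(beta))
    ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
    return ratio, ci, (ratio - 1.0) * 100.0


def _prepare_outcome(
    df: pd.DataFrame,
    outcome: str,
    winsorize: bool,
    zero_offset: float,
) -> np.ndarray:
    col = {"vpa": "vpa_min", "mpa": "mpa_min"}[outcome]
    values = df[col].to_numpy(float)
    if winsorize:
        values = winsorize_p99(values)
    return log_transform(values, zero_offset)


def _study_dummies(df: pd.DataFrame) -> pd.DataFrame:
    dummies = pd.get_dummies(df["study_id"], prefix="study", dtype=float)
    return dummies.iloc[:, 1:]  # first (sorted) study is the reference


def _ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, X.astype(float))
    return model.fit()


def _fit_result(res, n: int, covariates: Sequence[str]) -> FitResult:
    beta = float(res.params["age"])
    se = float(res.bse["age"])
    ratio, ci, pct = ratio_and_pct(beta, se)
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else (1.0 if beta == 0 else 0.0)
    return FitResult(
        beta_age=beta,
        se_beta=se,
        ratio=ratio,
        ratio_ci=ci,
        pct_change=pct,
        p_value=p,
        n=n,
        covariates_used=tuple(covariates),
    )


def fit_age_model(
    df: pd.DataFrame,
    outcome: str = "vpa",
    adjust_for_mpa: bool = False,
    winsorize: bool | None = None,
    zero_offset: float = 0.5,
) -> FitResult:
    """OLS of log(outcome) on age, wear time and study indicators.

    ``winsorize`` defaults to True for the vigorous outcome only.  When
    ``adjust_for_mpa`` is set the log of moderate minutes enters as an
    additional covariate (used to ask whether the vigorous age trend is
    independent of moderate activity).
    """
    if outcome not in ("vpa", "mpa"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if df["age"].nunique() < 2:
        raise ValueError("age has fewer than 2 distinct values; model is collinear")
    if winsorize is None:
        winsorize = outcome == "vpa"

    y = _prepare_outcome(df, outcome, winsorize, zero_offset)
    X = pd.DataFrame(
        {"const": 1.0, "age": df["age"].to_numpy(float),
         "wear_min": df["wear_min"].to_numpy(float)},
        index=df.index,
    )
    covariates = ["age", "wear_min", "study"]
    X = pd.concat([X, _study_dummies(df)], axis=1)
    if adjust_for_mpa:
        X["log_mpa"] = log_transform(df["mpa_min"].to_numpy(float), zero_offset)
        covariates.append("log_mpa")
    res = _ols(y, X)
    return _fit_result(res, len(df), covariates)


def test_interaction(
    df: pd.DataFrame,
    moderator: str,
    reference: str | None = None,
    alpha: float = 0.05,
    outcome: str = "vpa",
    zero_offset: float = 0.5,
    force_stratified: bool = False,
) -> InteractionResult:
    """Add age-by-moderator terms and test them; stratify when significant.

    Per-level Wald p-values are reported for every non-reference level,
    plus a joint chi-square test across all interaction terms.
    Stratified fits (one :func:`fit_age_model` per level) are computed
    when any of those p-values falls below ``alpha``.  Winsorization is
    applied once on the full sample, before stratification.
    """
    levels = [str(v) for v in pd.unique(df[moderator].dropna())]
    if len(levels) < 2:
        raise ValueError(f"moderator {moderator!r} has fewer than 2 levels")
    reference = reference or REFERENCE_LEVELS.get(moderator, sorted(levels)[0])
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from {moderator!r}")
    others = [lv for lv in sorted(levels) if lv != reference]

    data = df.dropna(subset=[moderator]).copy()
    if outcome == "vpa":
        data["vpa_min"] = winsorize_p99(data["vpa_min"].to_numpy(float))
    y = _prepare_outcome(data, outcome, winsorize=False, zero_offset=zero_offset)

    X = pd.DataFrame(
        {"const": 1.0, "age": data["age"].to_numpy(float),
         "wear_min": data["wear_min"].to_numpy(float)},
        index=data.index,
    )
    X = pd.concat([X, _study_dummies(data)], axis=1)
    inter_cols = []
    mod_values = data[moderator].astype(str)
    for lv in others:
        ind = (mod_values == lv).to_numpy(float)
        X[f"{moderator}={lv}"] = ind
        col = f"age:{moderator}={lv}"
        X[col] = ind * data["age"].to_numpy(float)
        inter_cols.append(col)

    res = _ols(y, X)
    per_level = {}
    for lv, col in zip(others, inter_cols):
        z = res.params[col] / res.bse[col]
        per_level[lv] = float(2 * stats.norm.sf(abs(z)))
    R = np.zeros((len(inter_cols), X.shape[1]))
    for i, col in enumerate(inter_cols):
        R[i, X.columns.get_loc(col)] = 1.0
    joint = res.wald_test(R, use_f=False, scalar=True)
    joint_p = float(joint.pvalue)

    stratified: dict[str, FitResult] = {}
    significant = min(list(per_level.values()) + [joint_p]) < alpha
    if significant or force_stratified:
        for lv in sorted(levels):
            sub = data[mod_values == lv]
            if sub["age"].nunique() < 2:
                continue
            stratified[lv] = fit_age_model(
                sub, outcome=outcome, winsorize=False, zero_offset=zero_offset
            )
    return InteractionResult(
        moderator=moderator,
        reference_level=reference,
        interaction_p=per_level,
        joint_p=joint_p,
        joint_df=len(inter_cols),
        stratified=stratified,
    )


def age_band_check(
    df: pd.DataFrame,
    outcome: str = "vpa",
    zero_offset: float = 0.5,
    band_edges: Sequence[float] = (5, 7, 9, 11, 13, 15, 17, 18),
) -> pd.DataFrame:
    """Linearity check: refit with 2-year age-band indicators.

    Returns a frame of band labels, fitted band coefficients (reference
    band fixed at 0) and the difference from the previous band; under a
    log-linear age trend the differences between adjacent full-width
    bands are all close to ``width * beta_age``.  Empty bands yield NaN
    coefficients and flagged (NaN) differences.
    """
    edges = np.asarray(band_edges, dtype=float)
    top = np.nextafter(edges[-1], np.inf)  # make the last band right-inclusive
    bins = np.concatenate([edges[:-1], [top]])
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    band = pd.cut(df["age"], bins=bins, right=False, labels=labels)
    populated = [lab for lab in labels if (band == lab).sum() > 0]
    if len(populated) < 2:
        raise ValueError("need at least 2 populated age bands")

    y = _prepare_outcome(df, outcome, winsorize=(outcome == "vpa"), zero_offset=zero_offset)
    X = pd.DataFrame(
        {"const": 1.0, "wear_min": df["wear_min"].to_numpy(float)}, index=df.index
    )
    X = pd.concat([X, _study_dummies(df)], axis=1)
    for lab in populated[1:]:
        X[f"band={lab}"] = (band == lab).to_numpy(float)
    res = _ols(y, X)

    coefs = []
    for lab in labels:
        if lab == populated[0]:
            coefs.append(0.0)
        elif lab in populated:
            coefs.append(float(res.params[f"band={lab}"]))
        else:
            coefs.append(np.nan)
    coefs = np.asarray(coefs)
    diffs = np.concatenate([[np.nan], np.diff(coefs)])
    return pd.DataFrame({"band": labels, "coef": coefs, "diff_from_previous": diffs})


def leave_one_study_out(
    df: pd.DataFrame, outcome: str = "vpa", **fit_kwargs
) -> LeaveOneStudyOutResult:
    """Refit the age model once per omitted study; flag slope sign changes."""
    studies = sorted(df["study_id"].astype(str).unique())
    if len(studies) < 2:
        raise ValueError("leave-one-study-out requires at least 2 studies")
    full = fit_age_model(df, outcome=outcome, **fit_kwargs)
    fits = {}
    sign_changes = {}
    for study in studies:
        sub = df[df["study_id"].astype(str) != study]
        fit = fit_age_model(sub, outcome=outcome, **fit_kwargs)
        fits[study] = fit
        sign_changes[study] = bool(np.sign(fit.beta_age) != np.sign(full.beta_age))
    return LeaveOneStudyOutResult(full=full, fits=fits, sign_changes=sign_changes)
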
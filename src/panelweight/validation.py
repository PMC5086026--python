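"""Predictive validation of the utilization phenotypes.

The phenotypes are validated as a risk-adjustment predictor: log-linear
models predict each patient's year-2 primary care encounters (office visits
plus telephone encounters, or office visits only) from age-sex bins, payer,
and either the seven utilization phenotypes or a "naive phenotype" — the
septile rank of the patient's total year-1 in-person encounters.  Models are
fit on the training split, scored out-of-sample on the test split, and
compared by adjusted R-squared and AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.genmod.families import Poisson

from .features import IN_PERSON_COLUMNS

AGE_GROUPS = [(18, 34), (35, 49), (50, 64), (65, 69), (70, 84), (85, 115)]
AGE_LABELS = [f"{lo}-{hi}" for lo, hi in AGE_GROUPS]
SEX_LABELS = ["F", "M"]
AGE_SEX_CATEGORIES = [f"{s}:{g}" for s in SEX_LABELS for g in AGE_LABELS]

PAYER_THREE = ["commercial", "medicare_medicaid", "other"]
PAYER_FOUR = ["commercial", "medicare", "medicaid", "other"]

PHENOTYPE_LEVELS = ["A", "B", "C", "D", "E", "F", "G"]
SEPTILE_LEVELS = [str(i) for i in range(1, 8)]

#: The seven predictor combinations of the model-comparison design.
MODEL_SPECS = {
    "age_sex": ["age_sex_bin"],
    "payer": ["payer"],
    "naive_phenotype": ["naive_phenotype"],
    "utilization_phenotype": ["phenotype"],
    "age_sex_payer": ["age_sex_bin", "payer"],
    "age_sex_payer_naive": ["age_sex_bin", "payer", "naive_phenotype"],
    "age_sex_payer_utilization": ["age_sex_bin", "payer", "phenotype"],
}


def age_sex_bin(age: float, sex: str | None) -> str:
    """One of 12 sex-by-age-group categories; missing sex counts as female."""
    if not 18 <= age <= 115:
        raise ValueError(f"age {age} outside the empaneled adult range [18, 115]")
    sex = sex if sex in ("M", "F") else "F"
    for (lo, hi), label in zip(AGE_GROUPS, AGE_LABELS):
        if lo <= age <= hi:
            return f"{sex}:{label}"
    raise AssertionError("unreachable")


def age_sex_bins(ages: pd.Series, sexes: pd.Series) -> pd.Series:
    """Vectorised :func:`age_sex_bin`."""
    ages = pd.Series(ages)
    if ((ages < 18) | (ages > 115)).any():
        bad = ages[(ages < 18) | (ages > 115)]
        raise ValueError(f"ages outside [18, 115]: {bad.tolist()[:5]}")
    edges = [lo for lo, _ in AGE_GROUPS] + [116]
    group = pd.cut(ages, bins=edges, labels=AGE_LABELS, right=False)
    sex = pd.Series(sexes).where(pd.Series(sexes).isin(["M", "F"]), "F")
    return (sex.astype(str) + ":" + group.astype(str)).rename("age_sex_bin")


def naive_phenotype(vectors: pd.DataFrame, n_bins: int = 7) -> pd.Series:
    """Septile rank (1..7) of total year-1 in-person encounters.

    Sums attended in-person categories only (no telephone, no messages, no
    missed appointments); ties share the lower septile via minimum ranks.
    """
    totals = vectors[IN_PERSON_COLUMNS].sum(axis=1)
    n = len(totals)
    ranks = totals.rank(method="min")
    septile = np.ceil(ranks * n_bins / n).astype(int).clip(1, n_bins)
    return septile.rename("naive_phenotype")


def train_test_split_ids(
    ids, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Random split with nearest-integer training size (round(f * n))."""
    ids = pd.Index(ids)
    n_train = int(math.floor(train_fraction * len(ids) + 0.5))
    perm = np.random.default_rng(seed).permutation(len(ids))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def build_feature_table(
    patients: pd.DataFrame,
    phenotypes: pd.Series,
    vectors_y1: pd.DataFrame,
    vectors_y2: pd.DataFrame,
    payer_scheme: str = "three_level",
    outcome: str = "pcp_telephone",
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Assemble the regression table for the phenotyped (active, non-inactive)
    patients: demographics, phenotype, naive septile, and year-2 outcome."""
    pats = patients.set_index("patient_id") if "patient_id" in patients else patients
    keep = phenotypes[phenotypes != "inactive"].index

    bins = age_sex_bins(pats.loc[keep, "age"], pats.loc[keep, "sex"])
    payer_raw = pats.loc[keep, "payer"].astype(str)
    if payer_scheme == "three_level":
        payer = payer_raw.replace({"medicare": "medicare_medicaid",
                                   "medicaid": "medicare_medicaid"})
        payer = payer.where(payer.isin(PAYER_THREE), "other")
        payer_levels = PAYER_THREE
    elif payer_scheme == "four_level":
        payer = payer_raw.where(payer_raw.isin(PAYER_FOUR), "other")
        payer_levels = PAYER_FOUR
    else:
        raise ValueError(f"unknown payer scheme {payer_scheme!r}")

    septiles = naive_phenotype(vectors_y1.loc[keep])

    y2 = vectors_y2.loc[keep]
    if outcome == "pcp_telephone":
        y = y2["raw_pcp"] + y2["telephone"]
    elif outcome == "pcp_only":
        y = y2["raw_pcp"]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    df = pd.DataFrame(
        {
            "age_sex_bin": pd.Categorical(bins, categories=AGE_SEX_CATEGORIES),
            "payer": pd.Categorical(payer, categories=payer_levels),
            "phenotype": pd.Categorical(
                phenotypes.loc[keep], categories=PHENOTYPE_LEVELS
            ),
            "naive_phenotype": pd.Categorical(
                septiles.astype(str), categories=SEPTILE_LEVELS
            ),
            "outcome_y2": y.astype(float),
        },
        index=keep,
    )
    df["log_y"] = np.log(df["outcome_y2"] + log_offset)
    return df


@dataclass
class ModelReport:
    name: str
    predictors: list
    result: object                  # fitted statsmodels results
    n: int
    p: int                          # model df, excluding intercept
    adjusted_r2: float
    r2: float
    aic: float

    @property
    def coefficients(self) -> dict:
        return dict(self.result.params)


def _formula(response: str, predictors: list[str]) -> str:
    terms = " + ".join(f"C({p})" for p in predictors)
    return f"{response} ~ {terms}"


def fit_log_linear(
    features: pd.DataFrame, predictors: list[str], name: str = "model"
) -> ModelReport:
    """OLS on log(year-2 encounters + offset) with categorical predictors.

    Adjusted R-squared and AIC are reported under the Gaussian likelihood on
    the log scale.
    """
    res = smf.ols(_formula("log_y", predictors), data=features).fit()
    return ModelReport(
        name=name,
        predictors=list(predictors),
        result=res,
        n=int(res.nobs),
        p=int(res.df_model),
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        aic=float(res.aic),
    )


def evaluate_on_test(report: ModelReport, test: pd.DataFrame) -> dict:
    """Score frozen training coefficients on the test split.

    R-squared is 1 - SSE/SST on the test log outcomes; the adjustment uses
    the test n with the training model's parameter count.
    """
    pred = np.asarray(report.result.predict(test))
    y = test["log_y"].to_numpy()
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    n, p = len(y), report.p
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return {"r2": r2, "adjusted_r2": adj, "n": n, "rmse": float(np.sqrt(sse / n))}


def fit_poisson(
    features: pd.DataFrame, predictors: list[str], name: str = "poisson"
) -> ModelReport:
    """Poisson regression with canonical log link on the raw year-2 counts."""
    y = features["outcome_y2"]
    if not np.allclose(y, np.round(y)):
        raise ValueError("Poisson outcome must be integer counts")
    res = smf.glm(
        _formula("outcome_y2", predictors), data=features, family=Poisson()
    ).fit()
    return ModelReport(
        name=name,
        predictors=list(predictors),
        result=res,
        n=int(res.nobs),
        p=int(res.df_model),
        adjusted_r2=float("nan"),
        r2=float("nan"),
        aic=float(res.aic),
    )


def model_comparison_table(
    train: pd.DataFrame, test: pd.DataFrame
) -> pd.DataFrame:
    """Fit the seven predictor combinations on the training split and score
    each out-of-sample; lower AIC is better."""
    rows = []
    for name, predictors in MODEL_SPECS.items():
        report = fit_log_linear(train, predictors, name=name)
        oos = evaluate_on_test(report, test)
        rows.append(
            {
                "model": name,
                "n_train": report.n,
                "p": report.p,
                "adjusted_r2_train": report.adjusted_r2,
                "aic": report.aic,
                "r2_test": oos["r2"],
                "adjusted_r2_test": oos["adjusted_r2"],
            }
        )
    table = pd.DataFrame(rows)
    table["best_aic"] = table["aic"] == table["aic"].min()
    return table
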
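"""Per-gene moderator regression of study-level effect sizes.

For each gene, the per-study log2 fold changes are regressed (ordinary
least squares) on three study-level moderators: total sample size
(n_case + n_control, continuous), study age in years (continuous) and
country (categorical, reference-coded).  Continuous moderators are reported
with their coefficient, two-sided t-test p and 95% CI; the multi-level
country factor is summarized by a single partial F-test p comparing the
model with and without the country block.  An optional inverse-variance
weighting (weights 1/var of the study LFC) is available via `weighted=True`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError
from .mega import GeneEffect

__all__ = ["FactorReport", "ModeratorResult", "moderator_mlr", "moderators_table"]

_ZERO_TOL = 1e-12


@dataclass
class FactorReport:
    """One moderator's summary: a t-based report for continuous factors, an
    F-based one (single p across all levels) for the categorical factor."""

    factor: str
    estimate: float | None  # None for the multi-level categorical block
    p: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    f_stat: float = float("nan")
    df_num: int = 0
    df_den: int = 0


@dataclass
class ModeratorResult:
    gene: str
    factors: dict[str, FactorReport]
    n_obs: int
    r2: float
    coefficients: dict[str, float] = field(default_factory=dict)


def _design(
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Intercept + continuous moderators + reference-coded country dummies.

    A continuous moderator that is constant across the contributing studies
    carries no information and is dropped (reported as a no-effect factor);
    a single-level country likewise contributes no dummy columns.
    """
    X = pd.DataFrame({"const": 1.0}, index=covariates.index)
    dropped: list[str] = []
    for name in ("n_sample", "study_age"):
        col = covariates[name].astype(float)
        if float(np.var(col)) < _ZERO_TOL:
            dropped.append(name)
        else:
            X[name] = col
    country_cols: list[str] = []
    levels = sorted(covariates["country"].astype(str).unique())
    for lv in levels[1:]:  # first level is the reference
        col = f"country[{lv}]"
        X[col] = (covariates["country"].astype(str) == lv).astype(float)
        country_cols.append(col)
    return X, country_cols, dropped


def moderator_mlr(
    effects: Sequence[GeneEffect],
    covariates: pd.DataFrame,
    weighted: bool = False,
) -> ModeratorResult:
    """OLS of per-study LFC on n_sample, study_age and country.

    `covariates` is indexed by study_id with columns n_sample, country,
    study_age; every contributing study must have a complete row.

    Raises
    ------
    DegenerateDesignError
        If the design matrix is rank deficient (e.g. a country level pattern
        collinear with the other columns), naming the offending factor.
    """
    if not effects:
        raise ValueError("no study effects supplied")
    gene = effects[0].gene
    ids = [e.study_id for e in effects]
    missing = [s for s in ids if s not in covariates.index]
    if missing:
        raise ValueError(f"missing covariates for studies {missing}")
    cov = covariates.loc[ids]
    if cov[["n_sample", "study_age", "country"]].isna().any().any():
        raise ValueError("missing covariate values")
    y = np.array([e.lfc for e in effects], dtype=float)
    X, country_cols, dropped = _design(cov)
    k = X.shape[1]
    if len(y) < k + 1:
        raise DegenerateDesignError(
            f"gene {gene!r}: {len(y)} studies cannot support {k} parameters"
        )
    continuous_cols = [c for c in ("n_sample", "study_age") if c in X.columns]
    base = X[["const", *continuous_cols]].to_numpy()
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise DegenerateDesignError(
            f"gene {gene!r}: rank-deficient design (factor: n_sample/study_age)"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise DegenerateDesignError(
            f"gene {gene!r}: rank-deficient design (factor: country)"
        )

    if float(np.var(y)) < _ZERO_TOL:
        # constant response: no moderator can explain anything; report
        # zero effects with p = 1 instead of a 0/0 pathology
        factors = {
            "n_sample": FactorReport("n_sample", 0.0, 1.0, 0.0, 0.0),
            "study_age": FactorReport("study_age", 0.0, 1.0, 0.0, 0.0),
            "country": FactorReport(
                "country", None, 1.0,
                f_stat=0.0, df_num=len(country_cols), df_den=len(y) - k,
            ),
        }
        return ModeratorResult(
            gene=gene, factors=factors, n_obs=len(y), r2=0.0,
            coefficients={c: (float(np.mean(y)) if c == "const" else 0.0) for c in X.columns},
        )

    if weighted:
        w = 1.0 / np.array([e.var for e in effects], dtype=float)
        fit = sm.WLS(y, X, weights=w).fit()
    else:
        fit = sm.OLS(y, X).fit()

    ci = fit.conf_int(alpha=0.05)
    factors: dict[str, FactorReport] = {}
    for name in ("n_sample", "study_age"):
        if name in dropped:  # constant across studies: nothing to estimate
            factors[name] = FactorReport(name, 0.0, 1.0, 0.0, 0.0)
            continue
        factors[name] = FactorReport(
            factor=name,
            estimate=float(fit.params[name]),
            p=float(fit.pvalues[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
        )
    if country_cols:
        constraint = " = 0, ".join(country_cols) + " = 0"
        ftest = fit.f_test(constraint)
        factors["country"] = FactorReport(
            factor="country",
            estimate=None,
            p=float(ftest.pvalue),
            f_stat=float(ftest.fvalue),
            df_num=int(ftest.df_num),
            df_den=int(ftest.df_denom),
        )
    else:  # single country: no contrast to test
        factors["country"] = FactorReport("country", None, 1.0)
    return ModeratorResult(
        gene=gene,
        factors=factors,
        n_obs=len(y),
        r2=float(fit.rsquared),
        coefficients={c: float(fit.params[c]) for c in X.columns},
    )


def moderators_table(results: Sequence[ModeratorResult]) -> pd.DataFrame:
    """One row per gene x factor, for the report TSV."""
    rows = []
    for res in results:
        for rep in res.factors.values():
            rows.append(
                {
                    "gene": res.gene,
                    "factor": rep.factor,
                    "estimate": np.nan if rep.estimate is None else rep.estimate,
                    "p": rep.p,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "n_obs": res.n_obs,
                    "r2": res.r2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "factor", "estimate", "p", "ci_low", "ci_high", "n_obs", "r2"],
    )
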
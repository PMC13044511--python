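"""Multiple Imputation by Chained Equations for HER2 status and age.

Missingness in the cohort is confined (by assumption, checked) to columns
with a configured imputation method: a logistic draw for the binary HER2
status and predictive mean matching (PMM, k donors) for continuous age.
Each of the m imputations runs an independently seeded chain — initial fill
by random draws from the observed values, then a fixed number of
full-conditional sweeps in which each incomplete column is regressed on all
other clinical covariates plus the subtype label. Downstream estimates from
the m completed cohorts are combined with Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import ClinicalCohort, SUBTYPE_LABELS

__all__ = [
    "MiceConfig",
    "PooledEstimate",
    "UnimputableError",
    "mice",
    "pool_rubin",
    "pool_model_coefficients",
]


class UnimputableError(ValueError):
    """A column cannot be imputed (e.g. no observed values)."""


@dataclass
class MiceConfig:
    """Chained-equations settings; defaults follow common MI practice
    (m=5 imputations, 10 sweeps, PMM with 5 donors)."""

    m: int = 5
    n_iterations: int = 10
    method_by_column: dict[str, str] = field(
        default_factory=lambda: {"her2": "logistic", "age": "pmm"}
    )
    donor_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2 (got {self.m}); single imputation is not MI")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.donor_k < 1:
            raise ValueError("donor_k must be >= 1")
        for col, method in self.method_by_column.items():
            if method not in ("logistic", "pmm"):
                raise ValueError(f"unknown method {method!r} for column {col!r}")


def _numeric_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric working copy: receptors as 0/1, subtype as dummies."""
    out = pd.DataFrame(index=df.index)
    out["age"] = pd.to_numeric(df["age"], errors="coerce")
    for col in ("er", "pr", "her2"):
        out[col] = df[col].map({"positive": 1.0, "negative": 0.0})
    out["stage"] = pd.to_numeric(df["stage"], errors="coerce")
    for lab in SUBTYPE_LABELS[1:]:
        out[f"subtype_{lab}"] = (df["subtype"] == lab).astype(float)
    return out


def _fit_logistic_draw(work, target, predictors, miss, rng, sweep):
    obs = ~miss
    yobs = work.loc[obs, target].to_numpy()
    if len(np.unique(yobs)) < 2:
        # degenerate conditional: draw from the (single-valued) observed margin
        work.loc[miss, target] = yobs[0]
        return
    # C=inf: plain maximum likelihood, no shrinkage of the imputation model
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(work.loc[obs, predictors].to_numpy(), yobs)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"logistic imputation model for {target!r} failed to converge "
                f"at sweep {sweep}"
            ) from exc
    p = clf.predict_proba(work.loc[miss, predictors].to_numpy())[:, 1]
    work.loc[miss, target] = (rng.random(miss.sum()) < p).astype(float)


def _fit_pmm(work, target, predictors, miss, rng, donor_k, sweep):
    obs = ~miss
    Xo = np.column_stack([np.ones(obs.sum()), work.loc[obs, predictors].to_numpy()])
    Xm = np.column_stack([np.ones(miss.sum()), work.loc[miss, predictors].to_numpy()])
    yo = work.loc[obs, target].to_numpy()
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    if not np.isfinite(beta).all():
        raise RuntimeError(f"PMM regression for {target!r} failed at sweep {sweep}")
    pred_obs = Xo @ beta
    pred_miss = Xm @ beta
    k = min(donor_k, len(yo))
    # k nearest observed predictions; one donor drawn per missing cell
    dist = np.abs(pred_miss[:, None] - pred_obs[None, :])
    donor_pool = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=miss.sum())
    work.loc[miss, target] = yo[donor_pool[np.arange(miss.sum()), choice]]


def mice(cohort: ClinicalCohort, config: MiceConfig | None = None) -> list[ClinicalCohort]:
    """Produce m completed copies of the cohort by chained-equations imputation.

    Raises
    ------
    UnimputableError
        If a modeled column has no observed values, or missingness occurs in
        a column without a configured method.
    """
    config = config or MiceConfig()
    config.validate()
    df = cohort.data
    mask = cohort.missing_mask
    targets = [c for c in config.method_by_column if mask[c].any()]
    stray = [c for c in mask.columns if mask[c].any() and c not in config.method_by_column]
    if stray:
        raise UnimputableError(
            f"missing cells in columns without an imputation method: {stray}"
        )
    if not targets:
        return [cohort.copy() for _ in range(config.m)]
    for col in targets:
        if mask[col].all():
            raise UnimputableError(f"column {col!r} is 100% missing")

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    completed: list[ClinicalCohort] = []
    base = _numeric_frame(df)
    all_cols = list(base.columns)
    for chain_seq in seeds:
        rng = np.random.default_rng(chain_seq)
        work = base.copy()
        # initial fill: random draws from the observed values of each column
        for col in targets:
            miss = mask[col].to_numpy()
            observed = work.loc[~miss, col].to_numpy()
            work.loc[miss, col] = rng.choice(observed, size=miss.sum(), replace=True)
        for sweep in range(1, config.n_iterations + 1):
            for col in targets:
                miss = mask[col].to_numpy()
                predictors = [c for c in all_cols if c != col]
                if config.method_by_column[col] == "logistic":
                    _fit_logistic_draw(work, col, predictors, miss, rng, sweep)
                else:
                    _fit_pmm(work, col, predictors, miss, rng, config.donor_k, sweep)
        out = df.copy()
        for col in targets:
            miss = mask[col].to_numpy()
            if config.method_by_column[col] == "logistic":
                out.loc[miss, col] = np.where(
                    work.loc[miss, col].to_numpy() > 0.5, "positive", "negative"
                )
            else:
                out.loc[miss, col] = work.loc[miss, col].to_numpy()
        completed.append(ClinicalCohort(out, seed=cohort.seed))
    return completed


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one scalar estimate across m imputations."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Pool point estimates and their squared SEs across imputations.

    Qbar = mean(estimates); W = mean(variances); B = sample variance of the
    estimates (divisor m-1); T = W + (1 + 1/m) B; small-sample df
    (m-1)(1 + W/((1+1/m)B))^2, with B = 0 reported as infinite df.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape or estimates.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D sequences")
    m = len(estimates)
    if m < 2:
        raise ValueError(f"Rubin pooling requires m >= 2 imputations, got {m}")
    if (variances < 0).any():
        raise ValueError("variances must be nonnegative")
    qbar = float(estimates.mean())
    w = float(variances.mean())
    b = float(estimates.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = float("inf")
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    return PooledEstimate(qbar, w, b, t, df, m)


def pool_model_coefficients(models) -> pd.DataFrame:
    """Rubin-pool every coefficient of a list of fitted subtype models.

    All models must share column names and class labels (fits of the same
    specification on m completed cohorts). Returns one row per
    (class, column) with the pooled estimate, total-variance SE and df.
    """
    first = models[0]
    for mod in models[1:]:
        if (list(mod.column_names) != list(first.column_names)
                or list(mod.class_labels) != list(first.class_labels)):
            raise ValueError("models disagree on columns or class labels")
    rows = []
    ses = [mod.standard_errors() for mod in models]
    coefs = [mod.coefficient_frame() for mod in models]
    for lab in first.class_labels[1:]:
        for col in first.column_names:
            est = [c.loc[lab, col] for c in coefs]
            var = [s.loc[lab, col] ** 2 for s in ses]
            pooled = pool_rubin(est, var)
            rows.append({
                "class": lab, "column": col, "estimate": pooled.point,
                "se": pooled.se, "df": pooled.df,
                "within_var": pooled.within_var, "between_var": pooled.between_var,
            })
    return pd.DataFrame(rows)
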
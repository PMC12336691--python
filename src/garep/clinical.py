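"""Clinical association layer: carrier-level linkage disequilibrium,
exact matching, linear interaction models, Cox and Andersen-Gill
recurrent-event regression, Schoenfeld diagnostics, and Kaplan-Meier
curves.

The quantity of interest throughout is the treatment-by-HLA
interaction: whether carriers of an allele draw extra benefit from one
treatment relative to another. Survival models are proportional-hazards
fits by maximum partial likelihood with Efron tie handling (delegated
to lifelines); the Andersen-Gill recurrent-event model uses
counting-process (start, stop] intervals with robust sandwich standard
errors clustered by subject. Linear models are ordinary least squares
(statsmodels) with age and disease duration min-max scaled within the
analysis dataset.

Linkage disequilibrium is computed on *carrier* (phenotype)
frequencies, not haplotypes: with carrier fractions fA, fB and joint
carrier fraction fAB, D = fAB - fA*fB is scaled by its maximum
attainable magnitude given the margins, giving a normalized D' in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "CarrierTable",
    "ModelFit",
    "carrier_dprime",
    "exact_match",
    "minmax_scale_columns",
    "fit_linear_interaction",
    "fit_cox",
    "fit_cox_ag",
    "schoenfeld_residuals",
    "kaplan_meier",
]


@dataclass(frozen=True)
class CarrierTable:
    """Carrier counts for two alleles in one cohort."""

    n: int
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self) -> None:
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValueError("n_ab cannot exceed either single-carrier count")
        if self.n_a + self.n_b - self.n_ab > self.n:
            raise ValueError("carrier counts exceed cohort size")
        if min(self.n, self.n_a, self.n_b, self.n_ab) < 0:
            raise ValueError("counts must be nonnegative")


def carrier_dprime(t: CarrierTable) -> float:
    """Normalized D' from carrier counts.

    D = fAB - fA*fB; Dmax = min(fA(1-fB), (1-fA)fB) for D >= 0, else
    min(fA*fB, (1-fA)(1-fB)); returns |D|/Dmax (0 when D = 0).
    Undefined when either margin is degenerate (fA or fB in {0, 1}).
    """
    fa, fb, fab = t.n_a / t.n, t.n_b / t.n, t.n_ab / t.n
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        raise ValueError("D' undefined for degenerate carrier margins")
    d = fab - fa * fb
    if d == 0:
        return 0.0
    if d > 0:
        dmax = min(fa * (1 - fb), (1 - fa) * fb)
    else:
        dmax = min(fa * fb, (1 - fa) * (1 - fb))
    return abs(d) / dmax


# ---------------------------------------------------------------------------
# matching


def exact_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    variables: Sequence[str] = ("age", "sex", "a03", "dr15"),
    age_col: str = "age",
    n_age_bins: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact matching on categorical variables with quantile-binned age.

    Retains subjects in strata containing both groups. Returns the
    matched table (with a ``group`` column) and a per-stratum report
    (cases/controls retained per stratum plus discarded counts).
    """
    for v in variables:
        for df, name in ((cases, "cases"), (controls, "controls")):
            if v not in df.columns:
                raise ValueError(f"matching variable {v!r} missing from {name}")
    both = pd.concat(
        [cases.assign(group="case"), controls.assign(group="control")], ignore_index=True
    )
    strata_vars = list(variables)
    if age_col in strata_vars:
        bins = pd.qcut(both[age_col], q=n_age_bins, duplicates="drop")
        both = both.assign(_age_bin=bins)
        strata_vars = [v if v != age_col else "_age_bin" for v in strata_vars]
    key = both[strata_vars].astype(str).agg("|".join, axis=1)
    both = both.assign(_stratum=key)
    counts = both.groupby(["_stratum", "group"], observed=True).size().unstack(fill_value=0)
    if "case" not in counts.columns or "control" not in counts.columns:
        keep_strata: set[str] = set()
    else:
        keep_strata = set(counts.index[(counts["case"] > 0) & (counts["control"] > 0)])
    matched = both[both["_stratum"].isin(keep_strata)].drop(columns=["_age_bin"], errors="ignore")
    report = counts.reindex(columns=["case", "control"], fill_value=0)
    report["retained"] = report.index.isin(keep_strata)
    if matched.empty:
        import warnings

        warnings.warn("no overlapping strata; matched set is empty", stacklevel=2)
    return matched.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# model fits


@dataclass
class ModelFit:
    """Coefficients, hazard ratios, and inference for one fitted model.

    ``summary`` has one row per covariate with columns coef, se, p,
    hr, hr_lo, hr_hi (HR columns only for hazard models).
    """

    model: str
    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int | None = None
    fitter: object = field(default=None, repr=False)
    train_df: pd.DataFrame | None = field(default=None, repr=False)
    #: covariates whose partial likelihood is monotone (separation);
    #: their coefficients are not identified
    separated_terms: tuple[str, ...] = ()

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])

    def hr(self, term: str) -> float:
        return float(np.exp(self.summary.loc[term, "coef"]))

    def hr_ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["hr_lo"]), float(row["hr_hi"])


def minmax_scale_columns(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Min-max scale the named columns to [0, 1] within the dataset."""
    df = df.copy()
    for c in columns:
        lo, hi = df[c].min(), df[c].max()
        if hi > lo:
            df[c] = (df[c] - lo) / (hi - lo)
        else:
            df[c] = 0.0
    return df


def _check_design(X: pd.DataFrame) -> None:
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(float)]))
    if rank < X.shape[1] + 1:
        # name the offending columns by greedy elimination
        cols, bad = [], []
        base = np.ones((len(X), 1))
        for c in X.columns:
            cand = np.column_stack([base] + [X[k].to_numpy(float)[:, None] for k in cols + [c]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                cols.append(c)
            else:
                bad.append(c)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_linear_interaction(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    scale_columns: Sequence[str] = ("age", "disease_duration"),
) -> ModelFit:
    """OLS of ``outcome`` on covariates (treatment, HLA, and their
    interaction indicators included by the caller), with min-max
    scaling of the named continuous columns first."""
    import statsmodels.api as sm

    data = minmax_scale_columns(df, [c for c in scale_columns if c in df.columns])
    X = data[list(covariates)].astype(float)
    _check_design(X)
    y = data[outcome].astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    summary = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "p": res.pvalues,
        }
    )
    return ModelFit(
        model=f"ols:{outcome}",
        summary=summary,
        log_likelihood=float(res.llf),
        n=int(res.nobs),
        fitter=res,
    )


_SEPARATION_COEF = 5.0  # |log HR| beyond this flags a monotone likelihood


def _separated(summary: pd.DataFrame) -> tuple[str, ...]:
    big = summary.index[summary["coef"].abs() > _SEPARATION_COEF]
    return tuple(big)


def _cox_summary(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "p": s["p"],
            "hr": s["exp(coef)"],
            "hr_lo": s["exp(coef) lower 95%"],
            "hr_hi": s["exp(coef) upper 95%"],
        }
    )


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    scale_columns: Sequence[str] = (),
) -> ModelFit:
    """Cox proportional-hazards fit (time-to-first-event form).

    Maximum partial likelihood with Efron tie handling; Wald CIs on
    the hazard-ratio scale.
    """
    if df[event_col].sum() < 1:
        raise ValueError("no events in the data")
    data = minmax_scale_columns(df, [c for c in scale_columns if c in df.columns])
    X = data[list(covariates)].astype(float)
    _check_design(X)
    model_df = pd.concat([data[[duration_col, event_col]], X], axis=1)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col=duration_col, event_col=event_col)
    summary = _cox_summary(cph)
    return ModelFit(
        model="cox",
        summary=summary,
        separated_terms=_separated(summary),
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[event_col].sum()),
        fitter=cph,
        train_df=model_df,
    )


def fit_cox_ag(
    df: pd.DataFrame,
    start_col: str,
    stop_col: str,
    event_col: str,
    covariates: Sequence[str],
    cluster_col: str = "subject_id",
    scale_columns: Sequence[str] = (),
) -> ModelFit:
    """Andersen-Gill recurrent-event Cox fit on (start, stop] intervals.

    The same partial likelihood with risk sets defined by the
    counting-process intervals (left truncation at ``start``), with
    robust sandwich standard errors clustered by subject.
    """
    g = df.sort_values([cluster_col, start_col])
    if (g[start_col] >= g[stop_col]).any():
        raise ValueError("intervals must satisfy start < stop")
    overlap = (
        g.groupby(cluster_col, sort=False)
        .apply(lambda s: bool((s[start_col].values[1:] < s[stop_col].values[:-1]).any()),
               include_groups=False)
    )
    if overlap.any():
        bad = overlap.index[overlap].tolist()
        raise ValueError(f"overlapping intervals within subject(s): {bad}")
    data = minmax_scale_columns(df, [c for c in scale_columns if c in df.columns])
    X = data[list(covariates)].astype(float)
    _check_design(X)
    model_df = pd.concat(
        [data[[start_col, stop_col, event_col, cluster_col]], X], axis=1
    )
    cph = CoxPHFitter()
    cph.fit(
        model_df,
        duration_col=stop_col,
        event_col=event_col,
        entry_col=start_col,
        cluster_col=cluster_col,
    )
    summary = _cox_summary(cph)
    return ModelFit(
        model="cox-andersen-gill",
        summary=summary,
        separated_terms=_separated(summary),
        log_likelihood=float(cph.log_likelihood_),
        n=int(df[cluster_col].nunique()),
        n_events=int(df[event_col].sum()),
        fitter=cph,
        train_df=model_df,
    )


def schoenfeld_residuals(fit: ModelFit) -> pd.DataFrame:
    """Per-event Schoenfeld residuals (observed minus risk-set-weighted
    expected covariate) of a fitted Cox model; columns sum to ~0 at the
    maximum partial-likelihood estimate."""
    cph = fit.fitter
    if not isinstance(cph, CoxPHFitter):
        raise ValueError("schoenfeld_residuals requires a Cox model fit")
    if fit.n_events is None or fit.n_events < 1:
        raise ValueError("no events")
    if fit.train_df is None:
        raise ValueError("model fit carries no training data")
    return cph.compute_residuals(fit.train_df, kind="schoenfeld")


def kaplan_meier(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    group_col: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates (Greenwood variance) per group."""
    groups = {"all": df} if group_col is None else dict(tuple(df.groupby(group_col)))
    out = {}
    for name, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        tab = kmf.survival_function_.join(kmf.confidence_interval_)
        tab.columns = ["survival", "ci_lo", "ci_hi"]
        out[str(name)] = tab
    return out
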
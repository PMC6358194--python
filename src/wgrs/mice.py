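"""Multiple imputation by chained equations and Rubin's-rules pooling.

The engine fills missing values in a mixed binary/continuous table by
iterated conditional draws:

* initialise each missing cell with a random draw from the variable's
  observed values;
* sweep the variables in ascending order of missingness rate (ties broken
  by plan order); for each, regress the variable on all other variables
  over the full current table, draw coefficients from their asymptotic
  posterior, and redraw the missing cells from the resulting predictive
  distribution (Bernoulli for binary variables, normal with drawn residual
  variance for continuous ones);
* repeat for a fixed number of cycles, independently in m chains, giving m
  completed datasets.

Observed cells are never altered.  A logistic conditional that separates is
refitted with a small ridge penalty (1e-6) and logged; this only stabilises
the coefficient draw, observed data are untouched.

Estimates computed on each completed dataset are combined with
:func:`pool_rubin`: the pooled point estimate is the mean, the total
variance adds the within-imputation mean and the (1 + 1/m)-inflated
between-imputation variance, and intervals use the Barnard-Rubin
degrees-of-freedom adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SeparationError
from .rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "MiceVariable",
    "MicePlan",
    "ImputedStack",
    "PooledEstimate",
    "mice_impute",
    "pool_rubin",
    "default_plan",
]


@dataclass(frozen=True)
class MiceVariable:
    name: str
    kind: str  # "binary" | "continuous"
    imputed: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ConfigError(f"unknown variable kind {self.kind!r}")


@dataclass(frozen=True)
class MicePlan:
    """Which variables enter the chain, and how many datasets/cycles."""

    variables: tuple[MiceVariable, ...]
    m: int = 75
    cycles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate variable names in plan")
        if not any(v.imputed for v in self.variables):
            raise ConfigError("at least one variable must be flagged for imputation")
        if self.m < 2:
            raise ConfigError("m must be >= 2 for pooling")
        if self.cycles < 1:
            raise ConfigError("cycles must be >= 1")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]


def default_plan(m: int = 75, cycles: int = 100, seed: int = 0, impute_ectopic: bool = False) -> MicePlan:
    """The study's chain: recurrence, score, diathesis features and sex.

    Ectopic disease enters as a predictor but is only imputed on request
    (one cohort had it complete, the other carried missing values).
    """
    variables = (
        MiceVariable("recurrence", "binary"),
        MiceVariable("wgrs", "continuous"),
        MiceVariable("family_history", "binary"),
        MiceVariable("early_onset", "binary"),
        MiceVariable("ectopic", "binary", imputed=impute_ectopic),
        MiceVariable("bilateral", "binary"),
        MiceVariable("sex", "binary"),
    )
    return MicePlan(variables=variables, m=m, cycles=cycles, seed=seed)


@dataclass(frozen=True)
class ImputedStack:
    """m completed datasets plus provenance and chain diagnostics.

    ``diagnostics[name]`` is an (m x cycles) array of the mean imputed value
    of that variable after each cycle of each chain, for convergence checks.
    """

    datasets: tuple[pd.DataFrame, ...]
    plan: MicePlan
    chain_seeds: tuple[int, ...]
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for idx, df in enumerate(self.datasets, start=1):
            out = df.copy()
            out.insert(0, "dataset_index", idx)
            out.insert(1, "sample_id", df.index)
            frames.append(out.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True)


def _draw_coef(fit, rng: np.random.Generator) -> np.ndarray:
    """Draw coefficients from the asymptotic normal around the MLE."""
    L = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(len(fit.coef)))
    return fit.coef + L @ rng.standard_normal(len(fit.coef))


def _impute_binary(
    X: np.ndarray, y: np.ndarray, miss: np.ndarray, rng: np.random.Generator, terms: list[str]
) -> np.ndarray:
    from .association import fit_logistic

    design = pd.DataFrame(X, columns=terms)
    try:
        fit = fit_logistic(design, y)
    except SeparationError:
        logger.warning("separation in conditional model; ridge-stabilised refit")
        fit = fit_logistic(design, y, ridge=1e-6)
    beta = _draw_coef(fit, rng)
    p = 1.0 / (1.0 + np.exp(-(X[miss] @ beta)))
    return (rng.random(miss.sum()) < p).astype(float)


def _impute_continuous(
    X: np.ndarray, y: np.ndarray, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n, k = X.shape
    XtX = X.T @ X
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    rss = float(resid @ resid)
    sigma2 = rss / rng.chisquare(df)
    XtX_inv = np.linalg.pinv(XtX)
    L = np.linalg.cholesky(sigma2 * XtX_inv + 1e-12 * np.eye(k))
    beta = beta_hat + L @ rng.standard_normal(k)
    return X[miss] @ beta + rng.normal(0.0, np.sqrt(sigma2), size=int(miss.sum()))


def mice_impute(data: pd.DataFrame, plan: MicePlan) -> ImputedStack:
    """Run chained-equations imputation and return the completed stack.

    ``data`` must contain every plan variable; missingness is allowed only
    in variables flagged ``imputed``.  Returns m completed datasets; cells
    observed in the input are bit-identical across all of them.
    """
    for v in plan.variables:
        if v.name not in data.columns:
            raise ConfigError(f"plan variable {v.name!r} absent from data")
        col = data[v.name]
        if col.notna().sum() == 0:
            raise ConfigError(f"variable {v.name!r} has zero observed values")
        if not v.imputed and col.isna().any():
            raise ConfigError(f"variable {v.name!r} has missing values but is not imputed")
        if v.kind == "binary":
            vals = col.dropna().unique()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ConfigError(f"binary variable {v.name!r} has non-0/1 values")

    work0 = data[plan.names].astype(float)
    miss_mask = work0.isna()
    to_impute = [v for v in plan.variables if v.imputed and miss_mask[v.name].any()]
    # visit order: ascending missingness rate, ties by plan order
    rates = {v.name: float(miss_mask[v.name].mean()) for v in to_impute}
    order = sorted(to_impute, key=lambda v: (rates[v.name], plan.names.index(v.name)))

    chain_seeds = tuple(
        int(substream(plan.seed, "mice", f"chain{j}").integers(2**31)) for j in range(plan.m)
    )
    datasets: list[pd.DataFrame] = []
    diagnostics = {v.name: np.full((plan.m, plan.cycles), np.nan) for v in order}

    if not order:  # nothing to impute: m copies of the input
        return ImputedStack(
            datasets=tuple(work0.copy() for _ in range(plan.m)),
            plan=plan,
            chain_seeds=chain_seeds,
            diagnostics=diagnostics,
        )

    predictors = {v.name: [n for n in plan.names if n != v.name] for v in order}
    for j in range(plan.m):
        rng = np.random.default_rng(chain_seeds[j])
        work = work0.copy()
        for v in order:  # initialise from observed marginals
            obs = work0[v.name].dropna().to_numpy()
            idx = miss_mask[v.name]
            work.loc[idx, v.name] = rng.choice(obs, size=int(idx.sum()), replace=True)
        for cycle in range(plan.cycles):
            for v in order:
                miss = miss_mask[v.name].to_numpy()
                X = np.column_stack(
                    [np.ones(len(work))] + [work[p].to_numpy() for p in predictors[v.name]]
                )
                yv = work[v.name].to_numpy()
                terms = ["intercept"] + predictors[v.name]
                if v.kind == "binary":
                    drawn = _impute_binary(X, yv, miss, rng, terms)
                else:
                    drawn = _impute_continuous(X, yv, miss, rng)
                work.loc[miss, v.name] = drawn
                diagnostics[v.name][j, cycle] = float(np.mean(drawn))
        datasets.append(work)

    return ImputedStack(
        datasets=tuple(datasets), plan=plan, chain_seeds=chain_seeds, diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass(frozen=True)
class PooledEstimate:
    """One coefficient pooled across m imputed-data fits."""

    term: str
    q_bar: float
    w_bar: float
    b: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def pool_rubin(fits: Sequence, dfcom: float | None = None) -> list[PooledEstimate]:
    """Pool per-dataset regression fits by Rubin's rules.

    ``fits`` are :class:`~wgrs.association.RegressionFit` objects (or any
    objects with ``terms``, ``coef`` and ``cov``) sharing one coefficient
    layout.  ``dfcom`` is the complete-data residual degrees of freedom used
    by the Barnard-Rubin adjustment; by default it is taken as
    ``n_obs - k`` from the first fit.
    """
    fits = list(fits)
    m = len(fits)
    if m < 2:
        raise ConfigError("pooling requires m >= 2 fits")
    terms = tuple(fits[0].terms)
    for f in fits[1:]:
        if tuple(f.terms) != terms:
            raise ConfigError("fits have inconsistent coefficient layouts")
    est = np.array([f.coef for f in fits], dtype=float)  # m x k
    wvar = np.array([np.diag(f.cov) for f in fits], dtype=float)
    if dfcom is None:
        n_obs = getattr(fits[0], "n_obs", None)
        dfcom = float(n_obs - len(terms)) if n_obs else np.inf

    q_bar = est.mean(axis=0)
    w_bar = wvar.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    total = w_bar + (1.0 + 1.0 / m) * b

    out = []
    for i, term in enumerate(terms):
        if b[i] <= 0.0 or total[i] == 0.0:
            df = np.inf
        else:
            lam = (1.0 + 1.0 / m) * b[i] / total[i]
            df_old = (m - 1) / lam**2
            if np.isfinite(dfcom):
                df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
                df = df_old * df_obs / (df_old + df_obs)
            else:
                df = df_old
        se = np.sqrt(total[i])
        if np.isinf(df):
            tcrit = stats.norm.ppf(0.975)
            p = 2.0 * stats.norm.sf(abs(q_bar[i]) / se) if se > 0 else (0.0 if q_bar[i] else 1.0)
        else:
            tcrit = stats.t.ppf(0.975, df)
            p = 2.0 * stats.t.sf(abs(q_bar[i]) / se, df) if se > 0 else (0.0 if q_bar[i] else 1.0)
        out.append(
            PooledEstimate(
                term=term,
                q_bar=float(q_bar[i]),
                w_bar=float(w_bar[i]),
                b=float(b[i]),
                total_var=float(total[i]),
                df=float(df),
                ci_low=float(q_bar[i] - tcrit * se),
                ci_high=float(q_bar[i] + tcrit * se),
                p=float(p),
                m=m,
            )
        )
    return out
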
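"""Binary and multinomial logistic regression with Wald odds ratios.

Fits maximise the exact likelihood by Newton-Raphson with a step-halving
guard (the log-likelihood never decreases across iterations), converging on
a gradient max-norm below 1e-8 within 50 iterations.  The coefficient
covariance is the inverse observed information at the optimum; odds ratios
and 95% confidence intervals are Wald, ``exp(b -/+ 1.959964 * se)``.

Complete or quasi-complete separation is an explicit error rather than a
silent huge odds ratio: with low-prevalence clinical covariates separation
is a real possibility at small n, and a divergent coefficient is not an
estimate.

The table-level helpers (:func:`recurrence_by_category`,
:func:`per_unit_association`, :func:`diathesis_count_analysis`) accept
either a single completed dataset or a stack of multiply-imputed datasets;
in the latter case each dataset is fitted separately and the coefficients
are pooled by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ConfigError, ConvergenceError, SeparationError

__all__ = [
    "Z_95",
    "RegressionFit",
    "fit_logistic",
    "fit_multinomial",
    "recurrence_by_category",
    "per_unit_association",
    "diathesis_count_analysis",
    "DIATHESIS_FEATURES",
]

Z_95 = 1.959964
_GRAD_TOL = 1e-8
_MAX_ITER = 50
_SEPARATION_COEF = 15.0

DIATHESIS_FEATURES = ["family_history", "early_onset", "bilateral", "ectopic"]


@dataclass(frozen=True)
class RegressionFit:
    """A fitted model block: coefficients with Wald inference."""

    terms: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    n_obs: int
    n_iterations: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + Z_95 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "estimate": float(self.coef[i]),
            "se": float(self.se[i]),
            "or": float(self.odds_ratio[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p_values[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": self.coef,
                "se": self.se,
                "or": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
                "n": self.n_obs,
                "converged": self.converged,
            }
        )


def _validate_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ConfigError("design matrix contains missing values")
    const = [c for c in X.columns if c != "intercept" and np.ptp(arr[:, X.columns.get_loc(c)]) == 0]
    if const:
        raise CollinearityError(f"constant non-intercept columns in design: {const}")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise CollinearityError("design matrix is rank deficient")


def fit_logistic(
    X: pd.DataFrame,
    y: Sequence[float],
    ridge: float = 0.0,
    max_iter: int = _MAX_ITER,
    tol: float = _GRAD_TOL,
) -> RegressionFit:
    """Maximum-likelihood logistic regression of a 0/1 outcome on ``X``.

    ``X`` must include its intercept column.  ``ridge`` adds a small penalty
    to the Hessian diagonal (used by the imputation engine to stabilise
    separated conditional fits); 0 means plain maximum likelihood.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ConfigError("outcome must be binary 0/1")
    if len(yv) != len(X):
        raise ConfigError("outcome length does not match design")
    _validate_design(X)
    A = X.to_numpy(dtype=float)
    n, k = A.shape

    def loglik(beta: np.ndarray) -> float:
        eta = A @ beta
        # log(1 + e^eta) computed stably
        return float(yv @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * ridge * beta @ beta)

    beta = np.zeros(k)
    ll = loglik(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(A @ beta)))
        grad = A.T @ (yv - p) - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            n_iter -= 1
            break
        w = p * (1.0 - p)
        H = (A * w[:, None]).T @ A + ridge * np.eye(k)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular information matrix: {exc}") from exc
        # the gradient's achievable floor scales with n; once the Newton step
        # is at machine precision the optimum is reached even if the absolute
        # gradient norm sits marginally above tol
        if np.max(np.abs(delta)) < 1e-10 * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
        step = 1.0
        # acceptance slack scales with |ll|: near the optimum the true
        # improvement drops below the evaluation noise of the likelihood
        slack = 1e-9 * (1.0 + abs(ll))
        for _ in range(30):  # step-halving: never decrease the likelihood
            cand = beta + step * delta
            if loglik(cand) >= ll - slack:
                break
            step *= 0.5
        beta = beta + step * delta
        ll = loglik(beta)
    else:
        p = 1.0 / (1.0 + np.exp(-(A @ beta)))
        grad = A.T @ (yv - p) - ridge * beta
        converged = bool(np.max(np.abs(grad)) < tol)

    # divergent coefficients mean separation whether or not the gradient
    # has numerically underflowed to "converged" at saturated probabilities
    if ridge == 0.0 and np.max(np.abs(beta)) > _SEPARATION_COEF:
        raise SeparationError(
            "complete or quasi-complete separation detected "
            f"(|coef| > {_SEPARATION_COEF})"
        )
    if not converged:
        raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations")

    p = 1.0 / (1.0 + np.exp(-(A @ beta)))
    w = p * (1.0 - p)
    H = (A * w[:, None]).T @ A + ridge * np.eye(k)
    cov = np.linalg.inv(H)
    return RegressionFit(
        terms=tuple(X.columns),
        coef=beta,
        cov=cov,
        log_likelihood=ll,
        n_obs=n,
        n_iterations=n_iter,
        converged=converged,
    )


def fit_multinomial(
    X: pd.DataFrame,
    y: Sequence,
    reference=None,
    max_iter: int = _MAX_ITER,
    tol: float = _GRAD_TOL,
) -> dict[object, RegressionFit]:
    """Multinomial (softmax) logistic regression vs a reference category.

    Returns one :class:`RegressionFit` per non-reference category, each
    holding that category's coefficient block against the reference
    (default: the smallest category label).  With K = 2 this reduces exactly
    to :func:`fit_logistic`.
    """
    X = pd.DataFrame(X)
    _validate_design(X)
    yv = pd.Series(list(y))
    levels = sorted(yv.unique().tolist())
    if len(levels) < 2:
        raise ConfigError("outcome must have at least 2 observed categories")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ConfigError(f"reference category {reference!r} not observed")
    others = [l for l in levels if l != reference]
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    K1 = len(others)
    Y = np.column_stack([(yv == lvl).to_numpy(dtype=float) for lvl in others])

    def probs(B: np.ndarray) -> np.ndarray:
        eta = A @ B  # n x K1
        stack = np.column_stack([np.zeros(n), eta])
        stack -= stack.max(axis=1, keepdims=True)
        e = np.exp(stack)
        return (e / e.sum(axis=1, keepdims=True))[:, 1:]

    def loglik(B: np.ndarray) -> float:
        eta = A @ B
        lse = np.logaddexp.reduce(np.column_stack([np.zeros(n), eta]), axis=1)
        return float((Y * eta).sum() - lse.sum())

    B = np.zeros((k, K1))
    ll = loglik(B)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = probs(B)
        grad = (A.T @ (Y - P)).ravel(order="F")  # stacked per category
        if np.max(np.abs(grad)) < tol:
            converged = True
            n_iter -= 1
            break
        H = np.zeros((k * K1, k * K1))
        for a in range(K1):
            for b in range(K1):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                H[a * k:(a + 1) * k, b * k:(b + 1) * k] = (A * w[:, None]).T @ A
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular multinomial information: {exc}") from exc
        delta = delta.reshape((k, K1), order="F")
        if np.max(np.abs(delta)) < 1e-10 * (1.0 + np.max(np.abs(B))):
            converged = True
            break
        step = 1.0
        slack = 1e-9 * (1.0 + abs(ll))
        for _ in range(30):
            if loglik(B + step * delta) >= ll - slack:
                break
            step *= 0.5
        B = B + step * delta
        ll = loglik(B)
    else:
        P = probs(B)
        grad = (A.T @ (Y - P)).ravel(order="F")
        converged = bool(np.max(np.abs(grad)) < tol)

    if np.max(np.abs(B)) > _SEPARATION_COEF:
        raise SeparationError("separation detected in multinomial fit")
    if not converged:
        raise ConvergenceError(f"multinomial fit did not converge in {max_iter} iterations")

    P = probs(B)
    H = np.zeros((k * K1, k * K1))
    for a in range(K1):
        for b in range(K1):
            w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
            H[a * k:(a + 1) * k, b * k:(b + 1) * k] = (A * w[:, None]).T @ A
    cov = np.linalg.inv(H)
    fits: dict[object, RegressionFit] = {}
    for a, lvl in enumerate(others):
        block = cov[a * k:(a + 1) * k, a * k:(a + 1) * k]
        fits[lvl] = RegressionFit(
            terms=tuple(X.columns),
            coef=B[:, a].copy(),
            cov=block,
            log_likelihood=ll,
            n_obs=n,
            n_iterations=n_iter,
            converged=converged,
        )
    return fits


# ---------------------------------------------------------------------------
# table-level analyses (single dataset or multiply-imputed stack)


def _as_datasets(data) -> list[pd.DataFrame]:
    from .mice import ImputedStack

    if isinstance(data, ImputedStack):
        return list(data.datasets)
    if isinstance(data, pd.DataFrame):
        return [data]
    return list(data)


def _pool_term(fits: list[RegressionFit], term: str) -> dict[str, float]:
    """One term's estimate across datasets: single fit as-is, else Rubin."""
    from .mice import pool_rubin

    if len(fits) == 1:
        return fits[0][term]
    pooled = pool_rubin(fits)
    est = next(e for e in pooled if e.term == term)
    return {
        "estimate": est.q_bar,
        "se": float(np.sqrt(est.total_var)),
        "or": float(np.exp(est.q_bar)),
        "ci_low": float(np.exp(est.ci_low)),
        "ci_high": float(np.exp(est.ci_high)),
        "p": est.p,
    }


def _category_design(df: pd.DataFrame, adjust: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    if "wgrs_category" not in df.columns:
        raise ConfigError("dataset lacks a wgrs_category column")
    cat = df["wgrs_category"].astype(int)
    present = sorted(cat.unique().tolist())
    if present[0] != 1 or any(c not in present for c in (2, 3, 4)):
        raise ConfigError(f"all four score categories required, observed {present}")
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for c in (2, 3, 4):
        X[f"category_{c}"] = (cat == c).astype(float)
    for f in adjust:
        X[f] = df[f].astype(float)
    return X, df["recurrence"].astype(float)


def recurrence_by_category(
    data, adjust: Sequence[str] = tuple(DIATHESIS_FEATURES)
) -> pd.DataFrame:
    """Odds of recurrence by score category vs the lowest category.

    Returns one row per (category 2-4, model in {unadjusted, adjusted});
    the adjusted model controls for the supplied diathesis features.  On a
    multiply-imputed stack the fits are pooled by Rubin's rules.
    """
    datasets = _as_datasets(data)
    rows = []
    for model, feats in (("unadjusted", ()), ("adjusted", tuple(adjust))):
        fits = []
        for df in datasets:
            X, yv = _category_design(df, feats)
            fits.append(fit_logistic(X, yv))
        for c in (2, 3, 4):
            cell = _pool_term(fits, f"category_{c}")
            rows.append({"category": c, "model": model, **cell, "n": fits[0].n_obs})
    return pd.DataFrame(rows)


def per_unit_association(
    data,
    outcome: str = "recurrence",
    adjust: Sequence[str] = (),
    predictor: str = "wgrs",
) -> pd.DataFrame:
    """Odds of ``outcome`` per unit increase of the (continuous) score."""
    datasets = _as_datasets(data)
    fits = []
    for df in datasets:
        X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
        X[predictor] = df[predictor].astype(float)
        for f in adjust:
            X[f] = df[f].astype(float)
        fits.append(fit_logistic(X, df[outcome].astype(float)))
    cell = _pool_term(fits, predictor)
    return pd.DataFrame([{"term": predictor, **cell, "n": fits[0].n_obs}])


def diathesis_by_category(
    data, features: Sequence[str] = tuple(DIATHESIS_FEATURES)
) -> pd.DataFrame:
    """Multinomial association between each diathesis feature and score category.

    For every feature separately (univariable), fits a multinomial logistic
    model of the four score categories (reference: lowest) on the binary
    feature and reports the per-category odds ratios.  Stacks of imputed
    datasets are pooled by Rubin's rules.
    """
    datasets = _as_datasets(data)
    rows = []
    for feature in features:
        fits_by_cat: dict[int, list[RegressionFit]] = {2: [], 3: [], 4: []}
        for df in datasets:
            if "wgrs_category" not in df.columns:
                raise ConfigError("dataset lacks a wgrs_category column")
            X = pd.DataFrame(
                {"intercept": np.ones(len(df)), feature: df[feature].astype(float)},
                index=df.index,
            )
            fits = fit_multinomial(X, df["wgrs_category"].astype(int), reference=1)
            for c in (2, 3, 4):
                fits_by_cat[c].append(fits[c])
        for c in (2, 3, 4):
            cell = _pool_term(fits_by_cat[c], feature)
            rows.append(
                {"feature": feature, "category": c, **cell, "n": fits_by_cat[c][0].n_obs}
            )
    return pd.DataFrame(rows)


def diathesis_count_analysis(data) -> pd.DataFrame:
    """Odds of recurrence by number of diathesis features (vs zero).

    The count is the sum of the four binary features; each level k is an
    indicator regression of recurrence on count = k vs count = 0, restricted
    to those two groups.  Levels that are absent, or too sparse to estimate
    (separated), are flagged ``available = False`` rather than raised — a
    small cohort legitimately has few individuals with all four features.
    """
    datasets = _as_datasets(data)
    counts = [df[DIATHESIS_FEATURES].astype(float).sum(axis=1).astype(int) for df in datasets]
    if not all((c == 0).any() for c in counts):
        raise ConfigError("no samples with zero diathesis features: reference level empty")
    rows = []
    for k in (1, 2, 3, 4):
        if not all((c == k).any() for c in counts):
            rows.append({"count": k, "available": False, "reason": "level absent"})
            continue
        try:
            fits = []
            for df, cnt in zip(datasets, counts):
                sub = cnt.isin([0, k])
                X = pd.DataFrame(
                    {
                        "intercept": np.ones(int(sub.sum())),
                        f"count_{k}": (cnt[sub] == k).astype(float),
                    },
                    index=df.index[sub],
                )
                fits.append(fit_logistic(X, df.loc[sub, "recurrence"].astype(float)))
        except SeparationError:
            rows.append({"count": k, "available": False, "reason": "separated (too sparse)"})
            continue
        cell = _pool_term(fits, f"count_{k}")
        rows.append({"count": k, "available": True, "reason": "", **cell, "n": fits[0].n_obs})
    return pd.DataFrame(rows)
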
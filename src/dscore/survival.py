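"""Median-split Kaplan-Meier comparison, log-rank test, and Cox regression.

The Cox model maximizes the Breslow partial likelihood by Newton iteration;
ties in event times are handled with the Breslow approximation throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dscore.scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalFit",
    "CoxResult",
    "LogrankResult",
    "median_split",
    "logrank_test",
    "cox_fit",
    "km_analysis",
    "read_clinical_tsv",
    "ConvergenceError",
    "SeparationError",
]


class ConvergenceError(RuntimeError):
    """Newton iteration did not converge."""


class SeparationError(RuntimeError):
    """A coefficient diverged (quasi-complete separation)."""


class LogrankResult(NamedTuple):
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    """Fit summary for one Cox model; `coef` etc. refer to the score covariate."""

    coef: float
    se: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    p_value: float
    score_test_chi_square: float
    n_used: int
    n_events: int
    n_dropped: int
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if not (self.hr_ci_low <= self.hazard_ratio <= self.hr_ci_high):
            raise ValueError("CI must bracket the hazard ratio")


@dataclass(frozen=True)
class SurvivalFit:
    """Median-split group comparison: log-rank statistic plus high-vs-low HR."""

    chi_square: float
    p_value: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    n_high: int
    n_low: int

    def __post_init__(self) -> None:
        if not (self.hr_ci_low <= self.hazard_ratio <= self.hr_ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (sample, time, event, optional covariate columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.set_index("sample")


def median_split(scores: ScoreTable) -> pd.Series:
    """Label samples "high" (score strictly above the median) or "low"."""
    if len(scores.samples) < 2:
        raise ValueError("need >= 2 samples to split")
    s = scores.as_series()
    med = s.median()
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    if (labels == "low").all():
        warnings.warn("all scores at or below the median: every sample labelled 'low'")
    return labels


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence[str]
) -> LogrankResult:
    """Two-group log-rank test (hypergeometric observed-vs-expected tabulation)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if e.sum() == 0:
        raise ValueError("no events in the data")
    in1 = g == levels[0]
    observed = expected = variance = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n_j = at_risk.sum()
        n1_j = (at_risk & in1).sum()
        d_j = ((t == tj) & (e == 1)).sum()
        d1_j = ((t == tj) & (e == 1) & in1).sum()
        observed += d1_j
        expected += d_j * n1_j / n_j
        if n_j > 1:
            variance += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if variance == 0:
        return LogrankResult(chi_square=0.0, p_value=1.0)
    chi2 = (observed - expected) ** 2 / variance
    return LogrankResult(chi_square=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)))


def _breslow_loglik(beta, X, t, e):
    """Breslow partial log-likelihood with gradient and Hessian.

    Rows must be sorted by descending time so risk sets are prefixes.
    """
    eta = X @ beta
    # stabilize exp
    c = eta.max()
    with np.errstate(over="ignore", under="ignore"):
        w = np.exp(eta - c)
    S0 = np.cumsum(w)  # S0[i] = sum over risk set at time t[i] (desc order)
    S1 = np.cumsum(w[:, None] * X, axis=0)
    p = X.shape[1]
    S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)

    # Breslow: all events at a tied time share the risk set including all ties.
    # With descending sort, the risk set for time t is the prefix up to the
    # LAST index having that time.
    order_last = np.searchsorted(-t, -t, side="right") - 1
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev = np.flatnonzero(e == 1)
    if not np.all(np.isfinite(S0[ev])) or np.any(S0[ev] <= 0):
        raise SeparationError("partial likelihood degenerated; data are separated")
    with np.errstate(over="ignore", invalid="ignore"):
        for i in ev:
            j = order_last[i]
            s0 = S0[j]
            s1 = S1[j]
            s2 = S2[j]
            ll += (eta[i] - c) - np.log(s0)
            grad += X[i] - s1 / s0
            hess -= s2 / s0 - np.outer(s1, s1) / s0**2
    if not np.all(np.isfinite(grad)) or not np.all(np.isfinite(hess)):
        raise SeparationError("partial likelihood degenerated; data are separated")
    return ll, grad, hess


def _design_matrix(
    covariates: pd.DataFrame | None, index: pd.Index
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """One-hot encode categoricals (first level reference); returns kept-row mask."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((len(index), 0)), [], np.ones(len(index), dtype=bool)
    cov = covariates.loc[index]
    keep = cov.notna().all(axis=1).to_numpy()
    cov = cov[keep]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in cov.columns:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((keep.sum(), 0))
    return X, names, keep


def cox_fit(
    clinical: pd.DataFrame,
    score: pd.Series | Sequence[float],
    extra_covariates: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit of survival on a continuous score.

    ``clinical`` must have columns ``time`` and ``event`` indexed by sample;
    ``score`` is aligned on that index. Rows with missing covariates are
    dropped with a logged count. Requires >= 10 events and no constant
    covariates. Reports the Wald HR and 95% CI for the score covariate and
    the score test statistic at the null (which equals the log-rank
    chi-square for a single binary covariate without ties).
    """
    if not isinstance(score, pd.Series):
        score = pd.Series(np.asarray(score, dtype=float), index=clinical.index)
    df = clinical[["time", "event"]].copy()
    df["__score__"] = score.loc[df.index]
    X_extra, extra_names, keep = _design_matrix(extra_covariates, df.index)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d record(s) with missing covariates", n_dropped)
    df = df.loc[df.index[keep]]
    X = np.column_stack([df["__score__"].to_numpy(), X_extra])
    names = ["score"] + extra_names

    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event must be binary")
    if e.sum() < 10:
        raise ValueError(f"need >= 10 events, found {int(e.sum())}")
    const = [names[j] for j in range(X.shape[1]) if np.all(X[:, j] == X[0, j])]
    if const:
        raise ValueError(f"constant covariate(s): {const}")

    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    sd = Xs.std(axis=0)
    Xn = Xs / sd  # standardized for conditioning; coefficients rescaled back

    p = Xn.shape[1]
    beta = np.zeros(p)
    _, grad0, hess0 = _breslow_loglik(beta, Xn, ts, es)
    score_chi2 = float(grad0 @ np.linalg.solve(-hess0, grad0))

    ll_old = -np.inf
    for it in range(max_iter):
        ll, grad, hess = _breslow_loglik(beta, Xn, ts, es)
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(-hess, grad)
        new_beta = beta + step
        new_ll, _, _ = _breslow_loglik(new_beta, Xn, ts, es)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, _, _ = _breslow_loglik(new_beta, Xn, ts, es)
            halvings += 1
        beta = new_beta
        if np.any(np.abs(beta / sd) > 50):
            raise SeparationError(
                "coefficient diverged (|coef| > 50); data are separated - "
                "penalized regression is out of scope"
            )
        if abs(new_ll - ll_old) < 1e-12 and np.linalg.norm(grad) < 1e-4:
            break
        ll_old = new_ll
    else:
        raise ConvergenceError(f"Newton iteration did not converge in {max_iter} steps")

    _, _, hess = _breslow_loglik(beta, Xn, ts, es)
    cov = np.linalg.inv(-hess)
    beta_raw = beta / sd
    se_raw = np.sqrt(np.diag(cov)) / sd
    z = 1.959963984540054
    coef, se = float(beta_raw[0]), float(se_raw[0])
    wald_p = float(2 * stats.norm.sf(abs(coef) / se))
    with np.errstate(over="ignore"):
        hr = float(np.exp(coef))
        ci_low = float(np.exp(coef - z * se))
        ci_high = float(np.exp(coef + z * se))
    return CoxResult(
        coef=coef,
        se=se,
        hazard_ratio=hr,
        hr_ci_low=ci_low,
        hr_ci_high=ci_high,
        p_value=wald_p,
        score_test_chi_square=score_chi2,
        n_used=int(len(ts)),
        n_events=int(es.sum()),
        n_dropped=n_dropped,
        coefficients=dict(zip(names, beta_raw.tolist())),
    )


def km_analysis(scores: ScoreTable, clinical: pd.DataFrame) -> SurvivalFit:
    """Median-split the score, log-rank the two groups, and report the high-vs-low HR."""
    groups = median_split(scores)
    common = [s for s in scores.samples if s in clinical.index]
    g = groups.loc[common]
    t = clinical.loc[common, "time"]
    e = clinical.loc[common, "event"]
    lr = logrank_test(t.to_numpy(), e.to_numpy(), g.to_numpy())
    indicator = pd.Series((g == "high").astype(float), index=g.index)
    cox = cox_fit(clinical.loc[common], indicator)
    return SurvivalFit(
        chi_square=lr.chi_square,
        p_value=lr.p_value,
        hazard_ratio=cox.hazard_ratio,
        hr_ci_low=cox.hr_ci_low,
        hr_ci_high=cox.hr_ci_high,
        n_high=int((g == "high").sum()),
        n_low=int((g == "low").sum()),
    )
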
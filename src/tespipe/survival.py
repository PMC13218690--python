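"""Survival statistics: Kaplan-Meier, log-rank, univariate Cox.

Kaplan-Meier curves and the log-rank test are delegated to lifelines.  The
univariate Cox proportional-hazards fit is implemented here directly —
Newton-Raphson on the partial likelihood with Breslow tie handling,
step-halving, convergence at |delta beta| < 1e-8 within 50 iterations, and
a Wald p-value — because the prognostic gene-set filter depends on its
exact tie and convergence behavior.  A multivariate fit with the same
solver is exposed for completeness but is not part of the core pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

from .errors import ConvergenceError, DegenerateCovariateError, FormatError


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up: positive time and a binary event indicator.

    Time units are whatever the cohort uses (months for MSK-IMPACT-style
    data); all statistics here are unit-agnostic.
    """

    data: pd.DataFrame  # index: sample_id; columns: time, event

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise FormatError("duplicate sample IDs in survival table")
        if (d["time"] <= 0).any():
            raise FormatError("survival times must be positive")
        if not d["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


def read_survival_tsv(path: str | Path) -> SurvivalTable:
    d = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"time", "event"} - set(d.columns)
    if missing:
        raise FormatError(f"survival table missing column(s) {sorted(missing)}")
    d.index = d.index.astype(str)
    return SurvivalTable(d[["time", "event"]].astype({"time": float, "event": int}))


@dataclass(frozen=True)
class CoxResult:
    covariate: str
    beta: float
    hazard_ratio: float
    se: float
    z: float
    p_value: float
    n_iterations: int

    @property
    def direction(self) -> str:
        return "risk" if self.beta > 0 else "protective"


def km_estimate(table: SurvivalTable, groups: pd.Series | None = None
                ) -> dict[object, pd.DataFrame]:
    """Product-limit survival estimate, optionally per group.

    Returns, per group (single key ``"all"`` when groups is None), a frame
    with the step-function timeline and S(t).  With zero events the
    estimator is flat at 1 (lifelines handles this; we do not raise).
    """
    out: dict[object, pd.DataFrame] = {}
    if groups is None:
        member = {"all": table.data.index}
    else:
        groups = groups.loc[table.data.index]
        member = {g: groups.index[groups == g] for g in sorted(groups.unique())}
    for g, ids in member.items():
        sub = table.data.loc[ids]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                               "survival": sf.iloc[:, 0].to_numpy()})
    return out


def logrank_test(table: SurvivalTable, groups: pd.Series) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >=2 groups."""
    groups = groups.loc[table.data.index]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(table.time, groups, table.event)
    return float(res.test_statistic), float(res.p_value)


def restricted_mean_survival(table: SurvivalTable, horizon: float | None = None) -> float:
    """Area under the KM curve up to ``horizon`` (default: largest observed time)."""
    if horizon is None:
        horizon = float(table.time.max())
    kmf = KaplanMeierFitter().fit(table.time, table.event)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def _cox_negloglik_parts(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                         event: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, gradient and Hessian at beta.

    x is n x p with rows sorted by decreasing time so that the risk set at
    each event time is a prefix (cumulative sums over the sorted order).
    """
    eta = x @ beta
    eta -= eta.max()  # overflow guard; shifts cancel in the partial likelihood
    w = np.exp(eta)
    # prefix sums over the risk sets (decreasing-time order)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    # ties (Breslow): tied events share one risk set = prefix up to the tie's last index
    last = len(time) - 1 - np.searchsorted(time[::-1], time, side="left")
    ev = event.astype(bool)
    idx = last[ev]
    ll = float(np.sum(eta[ev]) - np.sum(np.log(s0[idx])))
    xbar = s1[idx] / s0[idx, None]
    grad = x[ev].sum(axis=0) - xbar.sum(axis=0)
    vbar = s2[idx] / s0[idx, None, None] - xbar[:, :, None] * xbar[:, None, :]
    hess = -vbar.sum(axis=0)
    return ll, grad, hess


def cox_fit(
    table: SurvivalTable,
    covariates: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> list[CoxResult]:
    """Cox proportional-hazards fit (one or more covariates).

    Newton-Raphson with step-halving; Breslow handling of tied event times;
    Wald z and p per coefficient.
    """
    covariates = covariates.loc[table.data.index]
    x = covariates.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DegenerateCovariateError("covariates contain non-finite values")
    if np.any(x.std(axis=0) == 0):
        bad = covariates.columns[x.std(axis=0) == 0].tolist()
        raise DegenerateCovariateError(f"zero-variance covariate(s): {bad}")
    if table.event.sum() == 0:
        raise DegenerateCovariateError("no events: Cox model is unidentifiable")

    order = np.argsort(-table.time.to_numpy(), kind="mergesort")
    xs = x[order]
    ts = table.time.to_numpy()[order]
    es = table.event.to_numpy()[order]

    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_negloglik_parts(beta, xs, ts, es)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {n_iter}") from exc
        step = 1.0
        for _ in range(30):  # step-halving on the partial likelihood
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _cox_negloglik_parts(cand, xs, ts, es)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter} (log-likelihood {ll:.6g})"
            )
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(step * delta).max() < tol:
            break
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations "
            f"(|grad| = {np.abs(grad).max():.3e})"
        )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    results = []
    for j, name in enumerate(covariates.columns):
        z = beta[j] / se[j]
        pval = 2.0 * stats.norm.sf(abs(z))
        results.append(CoxResult(covariate=str(name), beta=float(beta[j]),
                                 hazard_ratio=float(np.exp(beta[j])), se=float(se[j]),
                                 z=float(z), p_value=float(pval), n_iterations=n_iter))
    return results


def cox_univariate(table: SurvivalTable, covariate: pd.Series) -> CoxResult:
    """Single-covariate Cox fit (the prognostic gene-set filter's statistic)."""
    name = covariate.name if covariate.name is not None else "covariate"
    return cox_fit(table, covariate.to_frame(name))[0]
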
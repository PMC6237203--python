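"""Cox proportional-hazards recurrence analysis.

Implements the Cox partial likelihood (Efron tie handling by default,
Breslow optional) with a Newton-Raphson solver, Wald statistics from the
inverse observed information, the Breslow baseline cumulative hazard,
Harrell's concordance index, univariate Wald-test feature screening, and
the biomarker-plus-clinical-factors evaluation protocol: each screened
biomarker feature is fit jointly with the clinical covariates and reported
with per-covariate hazard ratios and the model's held-out C-index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood optimization cannot converge."""


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    converged: bool
    n_iter: int
    ties: str = "efron"

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta,
            "HR": self.hazard_ratios,
            "se": self.se,
            "z": self.wald_z,
            "p": self.wald_p,
        }, index=self.names)

    def risk_score(self, X) -> np.ndarray:
        """Linear predictor X @ beta (log relative hazard)."""
        return np.asarray(X, dtype=float) @ self.beta


def _partial_loglik(beta, X, time, event, ties):
    """Efron/Breslow partial log-likelihood, gradient and information.

    Arrays must be pre-sorted by time ascending.  Returns (ll, grad, info).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums over the risk set {i : t_i >= t_k}
    S = np.cumsum(w[::-1])[::-1]
    Z = np.cumsum(wx[::-1], axis=0)[::-1]
    Q = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dead = [k for k in range(i, j) if event[k] == 1]
        d = len(dead)
        if d > 0:
            S_R, Z_R, Q_R = S[i], Z[i], Q[i]
            ll += eta[dead].sum()
            grad += X[dead].sum(axis=0)
            if ties == "breslow" or d == 1:
                fracs = np.zeros(d)
            else:
                fracs = np.arange(d) / d
            S_D = w[dead].sum()
            Z_D = wx[dead].sum(axis=0)
            Q_D = wxx[dead].sum(axis=0)
            for frac in fracs:
                phi = S_R - frac * S_D
                mu = (Z_R - frac * Z_D) / phi
                ll -= np.log(phi)
                grad -= mu
                info += (Q_R - frac * Q_D) / phi - np.outer(mu, mu)
        i = j
    return ll, grad, info


def fit_cox(X, time, event, names: list[str] | None = None,
            ties: str = "efron", tol: float = 1e-8,
            max_iter: int = 100) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``X`` is the n x p covariate matrix (DataFrame or array), ``time`` the
    positive follow-up times and ``event`` the 1/0 event indicators.  The
    coefficient vector maximizes the partial log-likelihood with Efron (or
    Breslow) handling of tied event times; iteration stops when the
    gradient's max norm falls below ``tol`` or the relative log-likelihood
    change falls below 1e-9.  Hazard ratios are exp(beta);
    standard errors come from the inverse observed information.  The
    baseline cumulative hazard is the Breslow step-function estimate.

    Raises ``ValueError`` for rank-deficient covariates and
    ``ConvergenceError`` for monotone likelihood (perfect separation).
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(time)) != 1:
            X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < p:
        raise ValueError("covariate matrix is rank deficient")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")

    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    beta = np.zeros(p)
    ll, grad, info = _partial_loglik(beta, Xs, ts, es, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving line search on the partial likelihood
        alpha = 1.0
        for _ in range(20):
            new_beta = beta + alpha * step
            new_ll, new_grad, new_info = _partial_loglik(
                new_beta, Xs, ts, es, ties)
            if new_ll >= ll - 1e-12:
                break
            alpha /= 2
        delta_ll = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "diverging coefficients: monotone likelihood "
                "(perfect separation) suspected")
        # relative likelihood-change stop: near the optimum the gradient is
        # a difference of large sums and can sit at the float noise floor
        if abs(delta_ll) < 1e-9 * (abs(ll) + 0.1):
            converged = True
            break
    if not converged and np.max(np.abs(grad)) >= 1e-4:
        raise ConvergenceError(
            f"Newton iteration did not converge in {max_iter} steps")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    bt, bh = _breslow_baseline(beta, Xs, ts, es)
    return CoxFit(names=names, beta=beta, se=se, loglik=ll,
                  baseline_times=bt, baseline_cumhaz=bh,
                  converged=converged, n_iter=it, ties=ties)


def _breslow_baseline(beta, X, time, event):
    """Breslow estimate of the baseline cumulative hazard (sorted input)."""
    w = np.exp(np.clip(X @ beta, -500, 500))
    S = np.cumsum(w[::-1])[::-1]
    times, cumhaz = [], []
    h = 0.0
    i, n = 0, len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = int(event[i:j].sum())
        if d > 0:
            h += d / S[i]
            times.append(time[i])
            cumhaz.append(h)
        i = j
    return np.asarray(times), np.asarray(cumhaz)


def concordance_index(risk, time, event) -> float:
    """Harrell's C over admissible pairs.

    A pair is admissible when the member with the strictly earlier observed
    time had an event.  A pair scores 1 if the earlier-failing member has
    the higher risk, 0.5 on tied risks, 0 otherwise.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.all(np.isfinite(risk)):
        raise ValueError("non-finite risk scores")
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = earlier.sum()
    if n_pairs == 0:
        raise ValueError("no admissible pairs")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    score = (earlier & higher).sum() + 0.5 * (earlier & tied).sum()
    return float(score / n_pairs)


def wald_select(features, time, event, alpha: float = 0.05,
                min_events: int = 10) -> list[int]:
    """Univariate Cox screen: keep features with Wald p < alpha (strict).

    Each feature is fit in its own single-covariate model; features whose
    fit fails to converge are skipped with a warning.
    """
    F = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < min_events:
        raise ValueError(
            f"need at least {min_events} events for a stable screen, "
            f"got {event.sum()}")
    selected = []
    for j in range(F.shape[1]):
        col = F[:, j:j + 1]
        if col.std() == 0:
            continue
        try:
            fit = fit_cox(col, time, event)
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"feature {j}: univariate fit failed ({exc}); "
                          "skipped", stacklevel=2)
            continue
        if fit.wald_p[0] < alpha:
            selected.append(j)
    return selected


@dataclass
class EvaluationReport:
    """Per-feature Cox evaluation mirroring the HR + C-index table layout."""

    table: pd.DataFrame
    selected: list[int] = field(default_factory=list)

    @property
    def best(self) -> pd.Series:
        """Row with the maximum biomarker hazard ratio."""
        return self.table.loc[self.table["biomarker_HR"].idxmax()]


def evaluate_biomarkers(biomarkers: pd.DataFrame, clinical: pd.DataFrame,
                        time, event, alpha: float = 0.05,
                        train_mask=None, test_mask=None,
                        min_events: int = 10) -> EvaluationReport:
    """Screen biomarker features and evaluate each with clinical factors.

    The univariate Wald screen runs on the training portion; each selected
    feature then enters a multivariate Cox model alongside the clinical
    covariates (fit on the training portion), and the model's risk scores
    are scored by C-index on the held-out portion.  The report has one row
    per feature with the per-covariate hazard ratios and that C-index; the
    row with the maximum biomarker HR is exposed as ``.best``.

    With no split masks, fitting and evaluation both use the full cohort.
    If no feature survives the screen, the smallest-p convergent feature is
    carried forward with a warning so the report is never empty.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    train = np.ones(n, bool) if train_mask is None else np.asarray(train_mask)
    test = train if test_mask is None else np.asarray(test_mask)

    B = biomarkers.to_numpy(dtype=float)
    C = clinical.to_numpy(dtype=float)
    selected = wald_select(B[train], time[train], event[train], alpha=alpha,
                           min_events=min_events)
    if not selected:
        warnings.warn("no biomarker feature passed the Wald screen; "
                      "falling back to the smallest-p feature", stacklevel=2)
        pvals = []
        for j in range(B.shape[1]):
            col = B[train][:, j:j + 1]
            if col.std() == 0:
                pvals.append(np.inf)
                continue
            try:
                pvals.append(fit_cox(col, time[train], event[train]).wald_p[0])
            except (ConvergenceError, ValueError):
                pvals.append(np.inf)
        if not np.isfinite(min(pvals)):
            raise ConvergenceError("no biomarker feature could be fit")
        selected = [int(np.argmin(pvals))]

    clin_names = list(clinical.columns)
    # prune clinical columns that are collinear (after centering) with the
    # ones already kept — e.g. secondary pattern on a Gleason-7-only cohort,
    # where secondary = 7 - primary is unidentifiable in a Cox model
    kept_cols: list[int] = []
    Ctr = C[train] - C[train].mean(axis=0)
    for k in range(C.shape[1]):
        trial = kept_cols + [k]
        if np.linalg.matrix_rank(Ctr[:, trial]) == len(trial):
            kept_cols.append(k)
    dropped = [clin_names[k] for k in range(C.shape[1]) if k not in kept_cols]
    if dropped:
        warnings.warn(f"clinical factors {dropped} collinear with the rest; "
                      "dropped from the multivariate fits (HR reported as "
                      "NaN)", stacklevel=2)
    rows = []
    for j in selected:
        Xj = np.column_stack([B[:, j], C[:, kept_cols]])
        names = [f"biomarker_{biomarkers.columns[j]}",
                 *[clin_names[k] for k in kept_cols]]
        try:
            fit = fit_cox(Xj[train], time[train], event[train], names=names)
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"feature {j}: multivariate fit failed ({exc}); "
                          "skipped", stacklevel=2)
            continue
        risk = fit.risk_score(Xj[test])
        cindex = concordance_index(risk, time[test], event[test])
        row = {"feature": biomarkers.columns[j],
               "biomarker_HR": fit.hazard_ratios[0],
               "biomarker_p": fit.wald_p[0]}
        hr_by_name = dict(zip(names[1:], fit.hazard_ratios[1:]))
        for cn in clin_names:
            row[f"HR_{cn}"] = hr_by_name.get(cn, np.nan)
        row["cindex"] = cindex
        rows.append(row)
    if not rows:
        raise ConvergenceError("no multivariate model could be fit")
    return EvaluationReport(table=pd.DataFrame(rows).set_index("feature"),
                            selected=selected)
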
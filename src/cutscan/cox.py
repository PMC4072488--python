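"""Cox proportional-hazards regression by maximum partial likelihood.

Implements the Breslow and Efron tie corrections, Newton-Raphson with
step-halving, Wald inference, the score test at beta = 0 (which for a
binary covariate with Breslow ties equals the log-rank chi-square), and
the Breslow estimator of the cumulative baseline hazard.

The model object / results object split follows the statsmodels idiom::

    model = CoxPH(time, event, X, names=["treated", "apache2"])
    res = model.fit()
    res.summary()
    hr, lo, hi = res.wald_interval("treated", alpha=0.05)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, DegenerateDesignError, SchemaError

__all__ = ["SurvivalData", "CoxPH", "CoxPHResults", "score_test", "breslow_baseline"]

#: |beta| beyond which the partial likelihood is treated as monotone
#: (complete separation of a dichotomized group, HR > e^15).
MONOTONE_BETA_BOUND = 15.0


@dataclass
class SurvivalData:
    """Right-censored survival data with a covariate matrix.

    ``time`` must be strictly positive, ``event`` is 1 for an observed
    death and 0 for censoring (discharge alive), and ``X`` is an
    (n, p) matrix with one column per covariate.
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.X.shape[0] != n:
            raise SchemaError("time, event and X must have equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise SchemaError("column 'time': all follow-up times must be finite and > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise SchemaError("column 'event': indicator must be 0/1")
        if not np.all(np.isfinite(self.X)):
            raise SchemaError("covariate matrix contains missing/non-finite values")
        if self.event.sum() < 1:
            raise SchemaError("column 'event': at least one event is required")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: list[str],
        time_col: str = "time",
        event_col: str = "event",
    ) -> "SurvivalData":
        for col in [time_col, event_col, *covariates]:
            if col not in df.columns:
                raise SchemaError(f"column '{col}' missing from input table")
        sub = df[[time_col, event_col, *covariates]]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise SchemaError(f"missing values in column(s) {bad}")
        return cls(
            time=sub[time_col].to_numpy(float),
            event=sub[event_col].to_numpy(int),
            X=sub[covariates].to_numpy(float),
            names=list(covariates),
        )

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


class _PartialLik:
    """Pre-sorted sufficient structure for the partial likelihood.

    Subjects are sorted by descending time so each risk set is a prefix;
    tied times form blocks whose last index gives the risk-set boundary.
    Efron's correction downweights tied events within a block; with
    ``frac = 0`` the same arithmetic yields Breslow.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray, ties: str):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.ties = ties
        order = np.argsort(-time, kind="stable")
        self.t = time[order]
        self.e = event[order].astype(bool)
        # centering keeps exp(eta) in range without changing beta
        self.center = X.mean(axis=0)
        self.Xs = X[order] - self.center
        self.p = X.shape[1]
        # last index of the tie block containing position i
        self.block_end = np.searchsorted(-self.t, -self.t, side="right") - 1
        # tie groups among events only
        ev_idx = np.nonzero(self.e)[0]
        self.ev_idx = ev_idx
        grp_key = self.block_end[ev_idx]
        _, grp_ids, grp_counts = np.unique(grp_key, return_inverse=True, return_counts=True)
        self.grp_ids = grp_ids
        d = grp_counts[grp_ids].astype(float)
        # rank l = 0..d-1 of each event within its tie group
        first_of_grp = np.r_[True, grp_ids[1:] != grp_ids[:-1]]
        l = np.arange(ev_idx.size) - np.maximum.accumulate(
            np.where(first_of_grp, np.arange(ev_idx.size), 0)
        )
        self.frac = l / d if ties == "efron" else np.zeros(ev_idx.size)
        self.n_groups = grp_counts.size
        self.order = order

    def loglik_derivs(self, beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Partial log-likelihood, score vector, observed information."""
        if not np.all(np.isfinite(beta)):
            raise ValueError("non-finite beta")
        Xs, e = self.Xs, self.e
        eta = Xs @ beta
        w = np.exp(np.clip(eta, -500, 500))
        wX = w[:, None] * Xs
        wXX = wX[:, :, None] * Xs[:, None, :]

        ends = self.block_end[self.ev_idx]
        R0 = np.cumsum(w)[ends]
        R1 = np.cumsum(wX, axis=0)[ends]
        R2 = np.cumsum(wXX, axis=0)[ends]

        # tied-event aggregates, broadcast back to each event
        gi = self.grp_ids
        T0 = np.bincount(gi, weights=w[self.ev_idx])[gi]
        T1 = np.stack(
            [np.bincount(gi, weights=wX[self.ev_idx, j])[gi] for j in range(self.p)], axis=1
        )
        T2 = np.stack(
            [
                np.stack(
                    [np.bincount(gi, weights=wXX[self.ev_idx, j, k])[gi] for k in range(self.p)],
                    axis=1,
                )
                for j in range(self.p)
            ],
            axis=1,
        )

        f = self.frac
        D0 = R0 - f * T0
        D1 = R1 - f[:, None] * T1
        D2 = R2 - f[:, None, None] * T2

        ll = float(eta[self.ev_idx].sum() - np.log(D0).sum())
        mu = D1 / D0[:, None]
        grad = Xs[self.ev_idx].sum(axis=0) - mu.sum(axis=0)
        info = (D2 / D0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mu, mu)
        return ll, grad, info


def partial_loglik(data: SurvivalData, beta: np.ndarray, ties: str = "efron") -> float:
    """Breslow- or Efron-corrected partial log-likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.shape[0] != data.X.shape[1]:
        raise ValueError("beta dimension does not match covariate matrix")
    pl = _PartialLik(data.time, data.event, data.X, ties)
    return pl.loglik_derivs(beta)[0]


class CoxPH:
    """Cox proportional-hazards model.

    Parameters
    ----------
    time, event, X
        Follow-up times (> 0), event indicators (1 = death) and the
        covariate matrix.
    names
        Covariate names, used in summaries and for indexing results.
    ties
        Tie correction, ``"efron"`` (default) or ``"breslow"``.
    """

    def __init__(self, time, event, X, names=None, ties: str = "efron"):
        self.data = SurvivalData(time, event, X, names=list(names) if names else [])
        self.ties = ties
        sd = self.data.X.std(axis=0)
        if np.any(sd == 0):
            j = int(np.argmin(sd))
            raise DegenerateDesignError(
                f"covariate '{self.data.names[j]}' is constant across subjects"
            )
        self._pl = _PartialLik(self.data.time, self.data.event, self.data.X, ties)

    @classmethod
    def from_dataframe(cls, df, covariates, time_col="time", event_col="event", ties="efron"):
        sd = SurvivalData.from_dataframe(df, covariates, time_col, event_col)
        return cls(sd.time, sd.event, sd.X, names=sd.names, ties=ties)

    def loglik(self, beta) -> float:
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        return self._pl.loglik_derivs(beta)[0]

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> "CoxPHResults":
        """Newton-Raphson from beta = 0 with step-halving.

        Convergence when the score sup-norm or the relative change in the
        partial log-likelihood drops below ``tol``.  Monotone likelihoods
        (|beta_j| > 15, e.g. a separated dichotomized group) are reported
        as non-converged rather than raised.
        """
        p = self.data.X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._pl.loglik_derivs(beta)
        ll0 = ll
        ll_path = [ll]
        converged = False
        message = "maximum iterations reached"
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise DegenerateDesignError(f"singular information matrix: {exc}") from exc
            # step-halving to guarantee likelihood ascent
            new_beta, new = beta + step, None
            for _ in range(11):
                cand = self._pl.loglik_derivs(new_beta)
                if cand[0] >= ll - 1e-12:
                    new = cand
                    break
                new_beta = beta + (new_beta - beta) / 2.0
            if new is None:
                message = "step-halving failed to increase the likelihood"
                break
            rel_change = abs(new[0] - ll) / max(1.0, abs(ll))
            beta, (ll, grad, info) = new_beta, new
            ll_path.append(ll)
            if np.any(np.abs(beta) > MONOTONE_BETA_BOUND):
                message = (
                    "monotone partial likelihood: |beta| exceeded "
                    f"{MONOTONE_BETA_BOUND:g} (likely separation)"
                )
                break
            if np.max(np.abs(grad)) < tol or rel_change < tol:
                converged = True
                message = "converged"
                break
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        cov = (cov + cov.T) / 2.0
        return CoxPHResults(
            model=self,
            params=beta,
            cov=cov,
            llf=ll,
            llnull=ll0,
            converged=converged,
            n_iter=n_iter,
            message=message,
            ll_path=np.array(ll_path),
        )


@dataclass
class CoxPHResults:
    """Fitted Cox model: estimates, observed-information covariance, diagnostics."""

    model: CoxPH
    params: np.ndarray
    cov: np.ndarray
    llf: float
    llnull: float
    converged: bool
    n_iter: int
    message: str
    #: partial log-likelihood after each accepted Newton step (ascending)
    ll_path: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def names(self) -> list[str]:
        return self.model.data.names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def n(self) -> int:
        return self.model.data.n

    @property
    def n_events(self) -> int:
        return self.model.data.n_events

    def _index(self, j) -> int:
        return self.names.index(j) if isinstance(j, str) else int(j)

    def wald_interval(self, j, alpha: float = 0.05) -> tuple[float, float, float]:
        """Hazard ratio exp(beta_j) with a two-sided (1 - alpha) Wald interval."""
        if not self.converged:
            raise ConvergenceError(f"fit did not converge: {self.message}")
        j = self._index(j)
        z = stats.norm.ppf(1 - alpha / 2.0)
        b, se = self.params[j], self.bse[j]
        return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            zsq = (self.params / self.bse) ** 2
        return stats.chi2.sf(zsq, df=1)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "HR lower 95%": np.exp(ci[:, 0]),
                "HR upper 95%": np.exp(ci[:, 1]),
                "p": self.pvalues,
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        """JSON-ready fit summary."""
        ci = self.conf_int()
        return {
            "covariates": self.names,
            "beta": self.params.tolist(),
            "se": self.bse.tolist(),
            "hr": self.hazard_ratios.tolist(),
            "ci_lower": np.exp(ci[:, 0]).tolist(),
            "ci_upper": np.exp(ci[:, 1]).tolist(),
            "p": self.pvalues.tolist(),
            "loglik_null": self.llnull,
            "loglik_final": self.llf,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.model.ties,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
        }

    def score_residuals(self) -> np.ndarray:
        """Per-subject score residuals U_i at the fitted beta (n x p).

        U_i = delta_i (x_i - xbar(t_i)) - w_i (x_i L0(t_i) - M(t_i)) with
        xbar the risk-set mean, L0 the Breslow cumulative baseline and
        M(t) = sum_{t_k <= t} d_k xbar_k / S0_k; they sum to the total
        score (zero at the MLE) and their outer products give the robust
        (infinitesimal-jackknife) covariance.  Breslow risk-set weights
        are used regardless of the fitting ties method.
        """
        pl = self.model._pl
        t, e, Xs = pl.t, pl.e, pl.Xs
        w = np.exp(np.clip(Xs @ self.params, -500, 500))
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * Xs, axis=0)
        ev_pos = np.nonzero(e)[0]
        ends = pl.block_end[ev_pos]
        # distinct event times ascending with risk-set aggregates
        ev_t = t[ev_pos]
        uniq, inv, d = np.unique(ev_t, return_inverse=True, return_counts=True)
        S0_k = np.zeros(uniq.size)
        S0_k[inv] = S0[ends]
        xbar_k = np.zeros((uniq.size, Xs.shape[1]))
        xbar_k[inv] = S1[ends] / S0[ends][:, None]
        H = np.cumsum(d / S0_k)
        M = np.cumsum(d[:, None] * xbar_k / S0_k[:, None], axis=0)
        idx = np.searchsorted(uniq, t, side="right") - 1
        L0_i = np.where(idx >= 0, H[np.clip(idx, 0, None)], 0.0)
        M_i = np.where(idx[:, None] >= 0, M[np.clip(idx, 0, None)], 0.0)
        U = -w[:, None] * (Xs * L0_i[:, None] - M_i)
        U[ev_pos] += Xs[ev_pos] - xbar_k[inv]
        out = np.empty_like(U)
        out[pl.order] = U
        return out

    def dfbeta(self) -> np.ndarray:
        """Per-subject influence on beta: score residuals times I^{-1} (n x p)."""
        return self.score_residuals() @ self.cov

    def robust_cov(self) -> np.ndarray:
        """Lin-Wei sandwich covariance from the dfbeta outer products."""
        D = self.dfbeta()
        return D.T @ D

    def baseline_cumhazard(self) -> pd.DataFrame:
        """Breslow cumulative baseline hazard at covariates = 0 (see module fn)."""
        return breslow_baseline(self, self.model.data)

    def predict_survival(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject predicted survival curves S_i(t) = exp(-L0(t) e^{x_i beta}).

        Returns (event_times, matrix of shape (n_subjects, n_times)).
        """
        base = self.baseline_cumhazard()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X @ self.params
        L0 = base["cumhazard"].to_numpy()
        S = np.exp(-np.outer(np.exp(eta), L0))
        return base["time"].to_numpy(), S


def breslow_baseline(fit: CoxPHResults, data: SurvivalData | None = None) -> pd.DataFrame:
    """Breslow estimate of the cumulative baseline hazard.

    A nondecreasing step function with jumps d_k / sum_{risk set} exp(x beta)
    at each distinct event time; with beta = 0 this is the Nelson-Aalen
    estimator.  Returned as a tidy frame (time, hazard jump, cumhazard).
    """
    if not fit.converged:
        raise ConvergenceError(f"fit did not converge: {fit.message}")
    data = data or fit.model.data
    w = np.exp(np.clip(data.X @ fit.params, -500, 500))
    order = np.argsort(-data.time, kind="stable")
    t, e, ws = data.time[order], data.event[order].astype(bool), w[order]
    block_end = np.searchsorted(-t, -t, side="right") - 1
    S0 = np.cumsum(ws)
    ev_times = t[e]
    uniq, inv, counts = np.unique(ev_times, return_inverse=True, return_counts=True)
    # risk-set total for each distinct event time
    risk_tot = np.zeros(uniq.size)
    risk_tot[inv] = S0[block_end[e.nonzero()[0]]]
    jumps = counts / risk_tot
    return pd.DataFrame(
        {"time": uniq, "jump": jumps, "cumhazard": np.cumsum(jumps)}
    )


def score_test(data: SurvivalData, j: int | str = 0, ties: str = "breslow") -> float:
    """Chi-square score test of beta_j = 0 in a univariate Cox model.

    For a binary group indicator with Breslow ties this is exactly the
    two-sample log-rank chi-square.
    """
    jdx = data.names.index(j) if isinstance(j, str) else int(j)
    x = data.X[:, [jdx]]
    pl = _PartialLik(data.time, data.event, x, ties)
    _, grad, info = pl.loglik_derivs(np.zeros(1))
    if info[0, 0] <= 0:
        return 0.0
    return float(grad[0] ** 2 / info[0, 0])
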
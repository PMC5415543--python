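"""Probit estimation of critical thermal limits (UL50 / LL50).

A critical thermal limit is the temperature at which half the animals in an
acute exposure lose their righting response. Given a table of per-temperature
binomial outcomes (n exposed, n dead), the limit is the 50% point of a probit
dose-response curve: probit(p_i) = a + b * T_i, limit = -a / b.

Two estimators are provided:

``empirical_probit``
    Finney's classical approach: observed mortality proportions are mapped to
    probits (normal quantiles), with the 1/(2n) correction for 0% and 100%
    tables, then regressed on temperature by ordinary least squares.

``ml_probit``
    Binomial maximum likelihood with a probit link, fitted by Fisher-scoring
    iteratively reweighted least squares; the limit's standard error comes
    from the delta method applied to -a/b.

``direction`` records whether mortality rises with temperature (upper limit,
heat death, positive slope) or falls (lower limit, cold death, negative
slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoDoseResponseError, UnidentifiableError, ValidationError

__all__ = ["MortalityTable", "ProbitLimitModel", "ProbitFit", "fit_probit", "check_design"]

MAX_IRLS_ITER = 50
IRLS_RTOL = 1e-10
SLOPE_FLOOR = 1e-8


@dataclass(frozen=True)
class MortalityTable:
    """Per-temperature binomial mortality outcomes for one species and direction."""

    temperature: np.ndarray
    n_exposed: np.ndarray
    n_dead: np.ndarray
    direction: Literal["upper", "lower"] = "upper"

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        n = np.asarray(self.n_exposed, dtype=int)
        k = np.asarray(self.n_dead, dtype=int)
        if not (t.shape == n.shape == k.shape) or t.ndim != 1:
            raise ValidationError("temperature, n_exposed, n_dead must be 1-d and aligned")
        if not np.all(np.isfinite(t)):
            raise ValidationError("temperatures must be finite")
        if len(np.unique(t)) < 2:
            raise ValidationError("need at least 2 distinct temperatures")
        if np.any(n <= 0):
            raise ValidationError("n_exposed must be positive")
        if np.any((k < 0) | (k > n)):
            raise ValidationError("n_dead must lie in 0..n_exposed")
        if self.direction not in ("upper", "lower"):
            raise ValidationError("direction must be 'upper' or 'lower'")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "n_exposed", n)
        object.__setattr__(self, "n_dead", k)

    @classmethod
    def from_records(cls, records: Sequence[tuple], direction="upper") -> "MortalityTable":
        t, n, k = zip(*records)
        return cls(np.array(t), np.array(n), np.array(k), direction)

    @classmethod
    def from_csv(cls, path, direction="upper") -> "MortalityTable":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            return cls(
                df[cols["temperature"]].to_numpy(),
                df[cols["n_exposed"]].to_numpy(),
                df[cols["n_dead"]].to_numpy(),
                direction,
            )
        except KeyError as exc:
            raise ValidationError(
                "mortality table needs columns temperature, n_exposed, n_dead"
            ) from exc

    @property
    def proportions(self) -> np.ndarray:
        return self.n_dead / self.n_exposed

    @property
    def design_valid(self) -> bool:
        """True iff mortality strictly exceeds 50% somewhere and is strictly below elsewhere."""
        p = self.proportions
        return bool(np.any(p > 0.5) and np.any(p < 0.5))


def check_design(data: MortalityTable) -> dict:
    """Report whether the temperature series brackets the 50% mortality point."""
    p = data.proportions
    return {
        "bracketing": data.design_valid,
        "n_temperatures": int(len(np.unique(data.temperature))),
        "proportions": {float(t): float(pi) for t, pi in zip(data.temperature, p)},
        "direction": data.direction,
    }


@dataclass(frozen=True)
class ProbitFit:
    """Fitted probit dose-response line and the implied 50% limit."""

    intercept: float
    slope: float
    l50: float
    se_l50: float
    method: str
    direction: str
    converged: bool
    loglik: float
    n_obs: int
    cov_params: np.ndarray
    design_valid: bool

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation (delta method) confidence interval for the limit."""
        z = stats.norm.ppf(0.5 + level / 2)
        return self.l50 - z * self.se_l50, self.l50 + z * self.se_l50

    def summary(self) -> str:
        lo, hi = self.conf_int()
        label = "UL50" if self.direction == "upper" else "LL50"
        lines = [
            f"Probit critical-limit fit ({self.method})",
            "-" * 44,
            f"{label:>10s}: {self.l50:9.3f} deg C  (SE {self.se_l50:.3f})",
            f"{'95% CI':>10s}: [{lo:.3f}, {hi:.3f}]",
            f"{'intercept':>10s}: {self.intercept:9.4f}",
            f"{'slope':>10s}: {self.slope:9.4f} per deg C",
            f"{'loglik':>10s}: {self.loglik:9.4f}   n temps: {self.n_obs}",
            f"{'converged':>10s}: {self.converged}   design bracketed: {self.design_valid}",
        ]
        return "\n".join(lines)


def _binom_loglik(table: MortalityTable, intercept: float, slope: float) -> float:
    eta = intercept + slope * table.temperature
    mu = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(stats.binom.logpmf(table.n_dead, table.n_exposed, mu)))


class ProbitLimitModel:
    """Dose-response model for a single critical thermal limit.

    Parameters
    ----------
    data : MortalityTable
        Temperatures with binomial death counts; ``data.direction`` decides
        the expected slope sign.
    """

    def __init__(self, data: MortalityTable):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, direction="upper") -> "ProbitLimitModel":
        return cls(
            MortalityTable(
                df["temperature"].to_numpy(),
                df["n_exposed"].to_numpy(),
                df["n_dead"].to_numpy(),
                direction,
            )
        )

    def _check_identifiable(self):
        p = self.data.proportions
        if np.all(p == 0) or np.all(p == 1):
            raise UnidentifiableError(
                "mortality is all-or-none at every temperature; the 50% point "
                "is not identifiable"
            )

    def fit(self, method: Literal["empirical_probit", "ml_probit"] = "empirical_probit") -> ProbitFit:
        self._check_identifiable()
        if method == "empirical_probit":
            return self._fit_empirical()
        if method == "ml_probit":
            return self._fit_ml()
        raise ValidationError(f"unknown method {method!r}")

    # -- Finney's empirical probit regression ------------------------------
    def _fit_empirical(self) -> ProbitFit:
        d = self.data
        p = d.proportions.copy()
        zero, one = p == 0, p == 1
        p[zero] = 1.0 / (2 * d.n_exposed[zero])
        p[one] = 1.0 - 1.0 / (2 * d.n_exposed[one])
        probits = stats.norm.ppf(p)
        X = np.column_stack([np.ones_like(d.temperature), d.temperature])
        beta, res, rank, _ = np.linalg.lstsq(X, probits, rcond=None)
        a, b = beta
        if abs(b) < SLOPE_FLOOR:
            raise NoDoseResponseError("probit slope is numerically zero")
        n = len(d.temperature)
        dof = n - 2
        if dof > 0 and res.size:
            s2 = float(res[0]) / dof
        else:
            s2 = 0.0
        cov = s2 * np.linalg.inv(X.T @ X)
        return self._package(a, b, cov, "empirical_probit", converged=True)

    # -- binomial ML with probit link, Fisher-scoring IRLS -----------------
    def _irls_pieces(self, beta: np.ndarray, X: np.ndarray):
        d = self.data
        eta = X @ beta
        mu = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
        phi = np.maximum(stats.norm.pdf(eta), 1e-10)  # floor keeps X'WX full rank
        w = d.n_exposed * phi**2 / (mu * (1 - mu))
        z = eta + (d.n_dead / d.n_exposed - mu) / phi
        return w, z

    def _fit_ml(self) -> ProbitFit:
        d = self.data
        t = d.temperature
        X = np.column_stack([np.ones_like(t), t])
        beta = self._fit_empirical_start()
        ll = _binom_loglik(d, *beta)
        converged = False
        for _ in range(MAX_IRLS_ITER):
            w, z = self._irls_pieces(beta, X)
            WX = X * w[:, None]
            try:
                new = np.linalg.solve(X.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError as exc:
                raise UnidentifiableError("IRLS normal equations singular") from exc
            # step-halving: never accept a likelihood decrease
            step = new - beta
            for _ in range(30):
                cand = beta + step
                ll_cand = _binom_loglik(d, *cand)
                if ll_cand >= ll - 1e-12:
                    break
                step = step / 2
            rel = np.max(np.abs(cand - beta)) / max(1.0, np.max(np.abs(beta)))
            beta, ll_prev, ll = cand, ll, ll_cand
            if rel < IRLS_RTOL or abs(ll - ll_prev) < IRLS_RTOL * (abs(ll) + 1):
                converged = True
                break
        a, b = beta
        if abs(b) < SLOPE_FLOOR:
            raise NoDoseResponseError("probit slope is numerically zero")
        w, _ = self._irls_pieces(beta, X)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        return self._package(a, b, cov, "ml_probit", converged=converged)

    def _fit_empirical_start(self) -> np.ndarray:
        try:
            fit = self._fit_empirical()
            return np.array([fit.intercept, fit.slope])
        except NoDoseResponseError:
            return np.array([0.0, 1e-3 if self.data.direction == "upper" else -1e-3])

    def _package(self, a: float, b: float, cov: np.ndarray, method: str, converged: bool) -> ProbitFit:
        l50 = -a / b
        grad = np.array([-1.0 / b, a / b**2])  # d(l50)/d(a,b)
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        return ProbitFit(
            intercept=float(a),
            slope=float(b),
            l50=float(l50),
            se_l50=se,
            method=method,
            direction=self.data.direction,
            converged=converged,
            loglik=_binom_loglik(self.data, a, b),
            n_obs=len(self.data.temperature),
            cov_params=cov,
            design_valid=self.data.design_valid,
        )


def fit_probit(
    data: MortalityTable,
    method: Literal["empirical_probit", "ml_probit"] = "empirical_probit",
) -> ProbitFit:
    """Functional wrapper: fit the probit limit model in one call."""
    return ProbitLimitModel(data).fit(method=method)
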
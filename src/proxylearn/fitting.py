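"""Least-squares estimation of learning-curve models.

Three model classes, each following the Model -> fit() -> Results pattern:

* :class:`ProxyProcessModel` — fits a proxy-process drift structure to the
  no-vision observations of one learning curve. By default the
  deterministic recursion is simulated over *all* consecutive trials from
  the first-trial error e0 (the proxy bridges the vision-trial gaps) and
  the objective sums squared deviations at the observed trials; an
  alternative "anchored" objective re-anchors the forward prediction at
  each observed error, mirroring the two-rate learner's proxy estimate.
* :class:`MultiRateModel` — fits the two-rate learner's retention/learning
  rates (Af, As, Bf, Bs) with the embedded second-order proxy coefficients
  held fixed at previously fitted values.
* :class:`WashoutDecayModel` — fits A*exp(-n/tau) to washout error
  magnitudes; tau indexes skill retention.

All fits are deterministic (the Wiener term is switched off; sigma enters
only simulation and reporting) and use seeded multi-start bounded
least-squares — best of ``n_starts`` local solves from uniform draws within
the bounds — standing in for a global-search optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import least_squares

from ._kernels import (
    multirate_path,
    proxy_forced_path,
    proxy_forced_path_sens,
    proxy_path,
    proxy_path_sens,
)
from .multirate import DPxMRMLParams
from .structures import ProxyModelParams, ProxyModelSpec, get_spec

__all__ = [
    "FitConfig",
    "GoodnessOfFit",
    "goodness_of_fit",
    "estimate_sigma",
    "ProxyProcessModel",
    "ProxyProcessResults",
    "MultiRateModel",
    "MultiRateResults",
    "WashoutDecayModel",
    "WashoutFit",
    "fit_proxy",
    "fit_dpxmrml",
    "fit_washout_exponential",
]

_BIG_RESIDUAL = 1e6

#: default box bounds per coefficient name
DEFAULT_BOUNDS = {
    "a": (-5.0, 5.0),     # cm/trial
    "b": (-2.0, 2.0),     # per-trial, also all b1..b8
    "c": (-1.0, 1.0),
    "d": (-0.5, 0.5),
}


@dataclass
class FitConfig:
    """Multi-start optimizer settings.

    ``n_starts`` local solves are launched from seeded uniform draws inside
    the bounds (the first start is the no-drift/no-learning baseline); the
    best final objective wins. ``sigma_divisor`` selects how the residual spread is
    normalized into the Wiener scale sigma ("n" divides by the number of
    learning-curve trials, "sqrt_n" by its square root).
    """

    n_starts: int = 1000
    seed: int = 0
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: Optional[int] = None
    sigma_divisor: str = "n"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.sigma_divisor not in ("n", "sqrt_n"):
            raise ValueError("sigma_divisor must be 'n' or 'sqrt_n'")


class GoodnessOfFit(NamedTuple):
    rsquared: float
    rsquared_adj: float
    rmse: float


def goodness_of_fit(observed, predicted, n_free_params: int) -> GoodnessOfFit:
    """R^2, adjusted R^2 and RMSE of predictions against observations.

    Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1); NaN when observations
    have zero variance (R^2 undefined) or when n <= p + 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2 or obs.shape != pred.shape:
        raise ValueError("need >= 2 paired observations")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(np.mean(resid**2)))
    if ss_tot == 0.0:
        return GoodnessOfFit(np.nan, np.nan, rmse)
    r2 = 1.0 - ss_res / ss_tot
    n, p = obs.size, n_free_params
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return GoodnessOfFit(r2, r2_adj, rmse)


def estimate_sigma(residuals, n_curve_trials: int, divisor: str = "n") -> float:
    """Wiener noise scale from fit residuals.

    The (population) standard deviation of the residuals normalized by the
    number of learning-curve trials — or by its square root when
    ``divisor="sqrt_n"``.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        return 0.0
    sd = float(np.std(r))
    den = float(n_curve_trials) if divisor == "n" else float(np.sqrt(n_curve_trials))
    return sd / den


def _spec_bounds(spec: ProxyModelSpec):
    lo, hi = [], []
    for name in spec.param_names:
        key = name if name in DEFAULT_BOUNDS else "b"
        b = DEFAULT_BOUNDS[key]
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def _multistart_least_squares(resid, jac, lo, hi, config: FitConfig):
    """Best-of-N bounded local least squares; returns (x, cost, n_run)."""
    rng = np.random.default_rng(config.seed)
    p = lo.size
    # deterministic first start: the no-drift / no-learning baseline (zeros
    # clipped into the box), which also breaks flat-objective ties sensibly
    starts = [np.clip(np.zeros(p), lo, hi)]
    if config.n_starts > 1:
        starts.extend(rng.uniform(lo, hi, size=(config.n_starts - 1, p)))
    best_x, best_cost = None, np.inf
    for x0 in starts:
        try:
            # probing divergent parameter regions triggers benign overflow
            # warnings inside the trust-region solver
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(
                    resid, x0, jac=jac if jac is not None else "2-point",
                    bounds=(lo, hi), method="trf",
                    xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
                    max_nfev=config.max_nfev,
                )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best_x = sol.x
    if best_x is None:
        raise RuntimeError("all local solves failed")
    return best_x, 2.0 * best_cost, len(starts)  # least_squares cost = SSE/2


# ---------------------------------------------------------------------------
# proxy-process model


class ProxyProcessModel:
    """One learning curve's no-vision observations + a drift structure.

    Parameters
    ----------
    observed : array of signed errors at the observed (no-vision) trials
    trial_index : matching consecutive trial indices (0-based; the
        deterministic simulation runs over 0..n_trials-1 from e0)
    e0 : first-trial error of the curve (initial condition)
    spec : ProxyModelSpec or structure id string
    n_trials : total learning-curve length; defaults to max(trial_index)+1
    objective : "simulation" (default) scores the free deterministic path
        simulated from e0 at the observed trials; "anchored" scores
        forward predictions that are re-anchored at each observed error
        (the gap-bridging semantics of the two-rate learner's proxy
        estimate).
    """

    def __init__(self, observed, trial_index, e0: float, spec,
                 n_trials: Optional[int] = None, objective: str = "simulation"):
        self.spec = get_spec(spec) if isinstance(spec, str) else spec
        if objective not in ("simulation", "anchored"):
            raise ValueError("objective must be 'simulation' or 'anchored'")
        self.objective = objective
        self.observed = np.asarray(observed, dtype=float)
        self.trial_index = np.asarray(trial_index, dtype=np.int64)
        if self.observed.shape != self.trial_index.shape or self.observed.ndim != 1:
            raise ValueError("observed and trial_index must be 1-d and equally long")
        if self.observed.size < self.spec.n_free_params + 1:
            raise ValueError(
                f"need >= {self.spec.n_free_params + 1} observations to fit "
                f"{self.spec.structure_id}, got {self.observed.size}"
            )
        if not np.isfinite(e0):
            raise ValueError("e0 must be finite")
        self.e0 = float(e0)
        self.n_trials = int(n_trials) if n_trials is not None else int(self.trial_index.max()) + 1
        if self.trial_index.min() < 0 or self.trial_index.max() >= self.n_trials:
            raise ValueError("trial indices out of range")
        self.constant_observations = bool(np.ptp(self.observed) == 0.0)
        self.full_obs = np.zeros(self.n_trials)
        self.avail = np.zeros(self.n_trials, dtype=bool)
        self.full_obs[self.trial_index] = self.observed
        self.avail[self.trial_index] = True
        if not self.avail[0]:
            self.full_obs[0] = self.e0
            self.avail[0] = True
        # trial 0 carries the initial condition, not a prediction
        self.resid_index = self.trial_index[self.trial_index > 0]

    @classmethod
    def from_curve(cls, curve, spec) -> "ProxyProcessModel":
        """Build from a long-format trial-table slice of one learning curve.

        Uses the ``error`` at trial 0 as e0 and the no-vision rows as
        observations; ``curve`` must hold a single subject/task/direction
        learning phase.
        """
        curve = curve[curve["phase"] == "learning"] if "phase" in curve else curve
        curve = curve.sort_values("trial")
        first = curve[curve["trial"] == 0]
        if first.empty:
            raise ValueError("curve lacks a trial-0 row to define e0")
        e0 = float(first["error"].iloc[0])
        obs = curve[curve["no_vision"].astype(bool)]
        return cls(obs["error"].to_numpy(), obs["trial"].to_numpy(), e0, spec,
                   n_trials=int(curve["trial"].max()) + 1)

    def predict(self, theta) -> np.ndarray:
        """Model path over all trials for coefficients theta.

        Under the "simulation" objective this is the free deterministic
        path from e0; under "anchored" it is the forward prediction that
        re-anchors at every observed no-vision error.
        """
        theta = np.asarray(theta, float)
        if self.objective == "anchored":
            pred, _, _ = proxy_forced_path(self.spec.code, self.spec.order, theta,
                                           self.e0, self.full_obs, self.avail)
            return pred
        e, _ = proxy_path(self.spec.code, self.spec.order, theta, self.e0,
                          self.n_trials - 1, np.zeros(self.n_trials - 1))
        return e

    def prediction_rmse(self, params) -> float:
        """RMSE of the model path at this curve's observed trials.

        Uses the same semantics as the fit objective, so cross-validation
        scores test curves exactly the way training curves were fitted.
        """
        theta = params.theta if hasattr(params, "theta") else np.asarray(params, float)
        idx = self.resid_index if self.objective == "anchored" else self.trial_index
        path = self.predict(theta)
        r = path[idx] - self.full_obs[idx]
        return float(np.sqrt(np.mean(r**2)))

    def _residuals(self, theta):
        if self.objective == "anchored":
            path, _, diverged = proxy_forced_path(self.spec.code, self.spec.order,
                                                  theta, self.e0, self.full_obs,
                                                  self.avail)
            idx = self.resid_index
        else:
            path, diverged = proxy_path(self.spec.code, self.spec.order, theta,
                                        self.e0, self.n_trials - 1,
                                        np.zeros(self.n_trials - 1))
            idx = self.trial_index
        r = path[idx] - self.full_obs[idx]
        if diverged or not np.all(np.isfinite(r)):
            return np.full(r.size, _BIG_RESIDUAL)
        return r

    def _jacobian(self, theta):
        if self.objective == "anchored":
            _, S, diverged = proxy_forced_path_sens(self.spec.code, self.spec.order,
                                                    theta, self.e0, self.full_obs,
                                                    self.avail)
            idx = self.resid_index
        else:
            _, S, diverged = proxy_path_sens(self.spec.code, self.spec.order, theta,
                                             self.e0, self.n_trials - 1)
            idx = self.trial_index
        if diverged:
            return np.zeros((idx.size, theta.size))
        return S[idx]

    def fit(self, config: Optional[FitConfig] = None) -> "ProxyProcessResults":
        config = config or FitConfig()
        lo, hi = _spec_bounds(self.spec)
        theta, sse, n_run = _multistart_least_squares(
            self._residuals, self._jacobian, lo, hi, config
        )
        idx = self.resid_index if self.objective == "anchored" else self.trial_index
        path = self.predict(theta)
        diverged = bool(np.any(np.abs(path) >= 1e8))
        fitted = path[idx]
        obs = self.full_obs[idx]
        resid = obs - fitted
        gof = goodness_of_fit(obs, fitted, self.spec.n_free_params)
        sigma = estimate_sigma(resid, self.n_trials, config.sigma_divisor)
        params = ProxyModelParams(self.spec, theta, sigma)
        return ProxyProcessResults(
            model=self, params=params, sse=float(np.sum(resid**2)),
            rmse=gof.rmse, rsquared=gof.rsquared, rsquared_adj=gof.rsquared_adj,
            resid=resid, fittedvalues=fitted, sigma=sigma, diverged=bool(diverged),
            n_starts_run=n_run, best_objective=float(sse),
        )


@dataclass
class ProxyProcessResults:
    """Fitted proxy-process coefficients and fit diagnostics."""

    model: ProxyProcessModel
    params: ProxyModelParams
    sse: float
    rmse: float
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray
    fittedvalues: np.ndarray
    sigma: float
    diverged: bool
    n_starts_run: int
    best_objective: float

    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def nobs(self) -> int:
        return self.model.observed.size

    def predict(self) -> np.ndarray:
        return self.model.predict(self.theta)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Proxy-process fit: structure {spec.structure_id} "
            f"(order {spec.order}, {spec.n_free_params} drift coefficients)",
            f"  observations: {self.nobs} no-vision trials of "
            f"{self.model.n_trials}; e0 = {self.model.e0:.4g}",
        ]
        for name, v in zip(spec.param_names, self.theta):
            lines.append(f"  {name:>4s} = {v: .6g}")
        lines.append(f"  sigma = {self.sigma:.6g}")
        lines.append(
            f"  SSE = {self.sse:.6g}  RMSE = {self.rmse:.6g}  "
            f"R2 = {self.rsquared:.4f}  R2adj = {self.rsquared_adj:.4f}"
        )
        if self.diverged:
            lines.append("  WARNING: simulated path hit the divergence cap")
        if self.model.constant_observations:
            lines.append("  NOTE: observations are constant (R2 undefined)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed no-vision errors with the fitted deterministic path."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        path = self.predict()
        ax.plot(np.arange(path.size), path, "-", lw=1, label="model path")
        ax.plot(self.model.trial_index, self.model.observed, "o", ms=3, label="no-vision errors")
        ax.set_xlabel("trial")
        ax.set_ylabel("signed error (cm)")
        ax.legend()
        return ax


def fit_proxy(observed, trial_index, e0, spec, n_trials=None,
              config: Optional[FitConfig] = None) -> ProxyProcessResults:
    """Functional wrapper around :class:`ProxyProcessModel`."""
    return ProxyProcessModel(observed, trial_index, e0, spec, n_trials).fit(config)


# ---------------------------------------------------------------------------
# two-rate state-space model


class MultiRateModel:
    """Two-rate learner over one curve with fixed proxy coefficients.

    ``observed``/``trial_index`` are the measured no-vision errors; the
    availability mask marks those trials (plus trial 0, whose error is e0)
    for the state recursion, and the objective sums squared deviations of
    the learner's prediction from the measured errors. Constraints As > Af
    and Bf > Bs are enforced by fitting (Af, dA, Bs, dB) with dA, dB > 0.
    """

    _LO = np.array([-1.0, 1e-6, -2.0, 1e-6])  # Af, dA, Bs, dB
    _HI = np.array([1.0, 2.0, 2.0, 4.0])
    _PENALTY = 1e3

    def __init__(self, observed, trial_index, e0: float, proxy_params: ProxyModelParams,
                 n_trials: Optional[int] = None):
        if proxy_params.spec.structure_id != "2.1":
            raise ValueError("proxy support must use structure 2.1")
        self.observed = np.asarray(observed, dtype=float)
        self.trial_index = np.asarray(trial_index, dtype=np.int64)
        if self.observed.shape != self.trial_index.shape or self.observed.ndim != 1:
            raise ValueError("observed and trial_index must be 1-d and equally long")
        self.e0 = float(e0)
        self.proxy_params = proxy_params
        self.n_trials = int(n_trials) if n_trials is not None else int(self.trial_index.max()) + 1
        self.full_obs = np.zeros(self.n_trials)
        self.avail = np.zeros(self.n_trials, dtype=bool)
        self.full_obs[self.trial_index] = self.observed
        self.avail[self.trial_index] = True
        if not self.avail[0]:
            self.full_obs[0] = self.e0
            self.avail[0] = True
        # trial 0 only seeds the error estimate: the prediction there is
        # identically zero (states start at rest), so its residual is a
        # constant and is excluded from the objective
        self.resid_index = self.trial_index[self.trial_index > 0]

    @classmethod
    def from_curve(cls, curve, proxy_params: ProxyModelParams) -> "MultiRateModel":
        curve = curve[curve["phase"] == "learning"] if "phase" in curve else curve
        curve = curve.sort_values("trial")
        first = curve[curve["trial"] == 0]
        if first.empty:
            raise ValueError("curve lacks a trial-0 row to define e0")
        obs = curve[curve["no_vision"].astype(bool)]
        return cls(obs["error"].to_numpy(), obs["trial"].to_numpy(),
                   float(first["error"].iloc[0]), proxy_params,
                   n_trials=int(curve["trial"].max()) + 1)

    def _run(self, x):
        Af, dA, Bs, dB = x
        a, b1, b2 = self.proxy_params.theta
        yhat, ehat, diverged = multirate_path(
            Af, Af + dA, Bs + dB, Bs, a, b1, b2, 0.0,
            self.full_obs, self.avail, np.zeros(self.n_trials),
        )
        return yhat, ehat, diverged

    def _residuals(self, x):
        yhat, _, diverged = self._run(x)
        r = self.full_obs[self.resid_index] - yhat[self.resid_index]
        if diverged or not np.all(np.isfinite(r)):
            r = np.full(r.size, _BIG_RESIDUAL)
        As = x[0] + x[1]
        pen = self._PENALTY * max(0.0, As - 1.0)
        return np.append(r, pen)

    def fit(self, config: Optional[FitConfig] = None) -> "MultiRateResults":
        config = config or FitConfig()
        x, sse, n_run = _multistart_least_squares(
            self._residuals, None, self._LO, self._HI, config
        )
        Af, dA, Bs, dB = x
        params = DPxMRMLParams(Af=float(Af), As=float(Af + dA), Bf=float(Bs + dB),
                               Bs=float(Bs), proxy=self.proxy_params)
        yhat, ehat, diverged = self._run(x)
        fitted = yhat[self.resid_index]
        obs = self.full_obs[self.resid_index]
        resid = obs - fitted
        gof = goodness_of_fit(obs, fitted, 4)
        return MultiRateResults(
            model=self, params=params, sse=float(np.sum(resid**2)), rmse=gof.rmse,
            rsquared=gof.rsquared, rsquared_adj=gof.rsquared_adj, resid=resid,
            fittedvalues=fitted, yhat=yhat, ehat=ehat, diverged=bool(diverged),
            n_starts_run=n_run, best_objective=float(sse),
        )


@dataclass
class MultiRateResults:
    """Fitted retention/learning rates of the two-rate learner."""

    model: MultiRateModel
    params: DPxMRMLParams
    sse: float
    rmse: float
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray
    fittedvalues: np.ndarray
    yhat: np.ndarray
    ehat: np.ndarray
    diverged: bool
    n_starts_run: int
    best_objective: float

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-rate learner fit (proxy-supported)",
            f"  Af = {p.Af: .6g}  As = {p.As: .6g}  (As > Af)",
            f"  Bf = {p.Bf: .6g}  Bs = {p.Bs: .6g}  (Bf > Bs)",
            f"  SSE = {self.sse:.6g}  RMSE = {self.rmse:.6g}  R2 = {self.rsquared:.4f}",
        ]
        if self.diverged:
            lines.append("  WARNING: state recursion hit the divergence cap")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(self.yhat.size), self.yhat, "-", lw=1, label="prediction")
        ax.plot(self.model.trial_index, self.model.observed, "o", ms=3, label="no-vision errors")
        ax.set_xlabel("trial")
        ax.set_ylabel("signed error (cm)")
        ax.legend()
        return ax


def fit_dpxmrml(observed, trial_index, e0, proxy_params, n_trials=None,
                config: Optional[FitConfig] = None) -> MultiRateResults:
    """Functional wrapper around :class:`MultiRateModel`."""
    return MultiRateModel(observed, trial_index, e0, proxy_params, n_trials).fit(config)


# ---------------------------------------------------------------------------
# washout exponential decay


class WashoutDecayModel:
    """Exponential decay A*exp(-n/tau) of washout error magnitudes."""

    TAU_BOUNDS = (0.1, 300.0)

    def __init__(self, magnitudes, offset: bool = False):
        self.magnitudes = np.asarray(magnitudes, dtype=float)
        if self.magnitudes.size < 3:
            raise ValueError("need >= 3 washout points")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be >= 0")
        self.offset = bool(offset)
        self.n = np.arange(self.magnitudes.size, dtype=float)

    def _predict(self, x):
        if self.offset:
            A, tau, c = x
            return A * np.exp(-self.n / tau) + c
        A, tau = x
        return A * np.exp(-self.n / tau)

    def fit(self, config: Optional[FitConfig] = None) -> "WashoutFit":
        config = config or FitConfig(n_starts=50)
        y = self.magnitudes
        ymax = float(y.max())
        if ymax == 0.0:
            return WashoutFit(amplitude=0.0, tau=np.nan, sse=0.0, offset=0.0,
                              flagged=True, flag_reason="all-zero series (tau unidentifiable)")
        lo = np.array([0.0, self.TAU_BOUNDS[0]] + ([0.0] if self.offset else []))
        hi = np.array([10.0 * ymax, self.TAU_BOUNDS[1]] + ([ymax] if self.offset else []))

        def resid(x):
            return self._predict(x) - y

        rng = np.random.default_rng(config.seed)
        taus = np.geomspace(self.TAU_BOUNDS[0], self.TAU_BOUNDS[1],
                            max(2, min(config.n_starts, 25)))
        starts = [np.array([ymax, t] + ([0.0] if self.offset else [])) for t in taus]
        n_extra = max(0, config.n_starts - len(starts))
        if n_extra:
            starts.extend(rng.uniform(lo, hi, size=(n_extra, lo.size)))
        best_x, best_cost = None, np.inf
        for x0 in starts:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=config.xtol, ftol=config.ftol, gtol=config.gtol)
            if sol.cost < best_cost:
                best_cost, best_x = sol.cost, sol.x
        A, tau = best_x[0], best_x[1]
        c = best_x[2] if self.offset else 0.0
        flagged = tau >= 0.999 * self.TAU_BOUNDS[1]
        return WashoutFit(
            amplitude=float(A), tau=float(tau), sse=float(2.0 * best_cost),
            offset=float(c), flagged=bool(flagged),
            flag_reason="tau at upper bound (non-decaying data)" if flagged else "",
        )


@dataclass
class WashoutFit:
    """Fitted washout decay: amplitude (cm) and time constant tau (trials)."""

    amplitude: float
    tau: float
    sse: float
    offset: float = 0.0
    flagged: bool = False
    flag_reason: str = ""

    def summary(self) -> str:
        s = (f"Washout decay fit: A = {self.amplitude:.4g} cm, "
             f"tau = {self.tau:.4g} trials, SSE = {self.sse:.4g}")
        if self.flagged:
            s += f" [flag: {self.flag_reason}]"
        return s


def fit_washout_exponential(magnitudes, config: Optional[FitConfig] = None,
                            offset: bool = False) -> WashoutFit:
    """Functional wrapper around :class:`WashoutDecayModel`."""
    return WashoutDecayModel(magnitudes, offset=offset).fit(config)
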
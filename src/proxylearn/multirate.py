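"""Two-rate state-space learner with proxy-bridged observation gaps.

The dynamic-proxy multi-rate model maintains a fast and a slow internal state
whose sum predicts the signed error on each trial:

    xf_{n+1} = Af * xf_n + Bf * ehat_n
    xs_{n+1} = As * xs_n + Bs * ehat_n
    yhat_n   = xf_n + xs_n
    ehat_n   = e_n                       if an observation is available,
               ehat_{n-1} + a + b1*ehat_{n-1} + b2*ehat_{n-2} + sigma*dz
                                         otherwise,

with Af, As (dimensionless) the fast/slow retention rates, Bf, Bs the
learning rates, constrained As > Af and Bf > Bs, and a second-order
proxy-process (coefficients a, b1, b2, sigma) bridging trials without
feedback. Both states start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import multirate_path
from .structures import ProxyModelParams, get_spec

__all__ = ["DPxMRMLParams", "DPxMRMLState", "dpxmrml_step", "run_dpxmrml", "simulate_dpxmrml_curve"]


@dataclass
class DPxMRMLParams:
    """Retention/learning rates plus the embedded ``2.1`` proxy process."""

    Af: float
    As: float
    Bf: float
    Bs: float
    proxy: ProxyModelParams = None

    def __post_init__(self) -> None:
        if self.proxy is None:
            self.proxy = ProxyModelParams.from_dict("2.1", a=0.0, b1=0.0, b2=0.0, sigma=0.0)
        if self.proxy.spec.structure_id != "2.1":
            raise ValueError("embedded proxy process must use structure 2.1")
        if not (self.As > self.Af):
            raise ValueError(f"slow retention must exceed fast retention (As={self.As} <= Af={self.Af})")
        if not (self.Bf > self.Bs):
            raise ValueError(f"fast learning must exceed slow learning (Bf={self.Bf} <= Bs={self.Bs})")

    def as_dict(self) -> dict:
        return {"Af": self.Af, "As": self.As, "Bf": self.Bf, "Bs": self.Bs}


@dataclass
class DPxMRMLState:
    """Fast/slow states and the (up to) two most recent proxy errors."""

    xf: float = 0.0
    xs: float = 0.0
    e_hat_history: tuple = ()

    @property
    def yhat(self) -> float:
        return self.xf + self.xs


def dpxmrml_step(params: DPxMRMLParams, state: DPxMRMLState, e_hat: float):
    """Advance the learner one trial on error estimate ``e_hat``.

    Returns ``(next_state, yhat_next)`` where yhat_next is the prediction
    emitted by the updated states.
    """
    if not (np.isfinite(state.xf) and np.isfinite(state.xs) and np.isfinite(e_hat)):
        raise ValueError("state and e_hat must be finite")
    xf = params.Af * state.xf + params.Bf * e_hat
    xs = params.As * state.xs + params.Bs * e_hat
    hist = (state.e_hat_history + (float(e_hat),))[-2:]
    nxt = DPxMRMLState(xf=xf, xs=xs, e_hat_history=hist)
    return nxt, nxt.yhat


def run_dpxmrml(
    params: DPxMRMLParams,
    observed_errors,
    available,
    rng: Optional[np.random.Generator] = None,
):
    """Run the learner over a full curve of trials.

    Parameters
    ----------
    observed_errors : array of length n
        Signed errors; entries where ``available`` is False are ignored.
    available : boolean array of length n
        True on trials with a measured error (the first trial must be
        available — there is no proxy history to seed from otherwise).
    rng : numpy Generator, optional
        When given, proxy-bridged trials receive sigma-scaled Wiener noise;
        deterministic (dz = 0) otherwise.

    Returns
    -------
    (yhat, ehat, diverged) : predictions, error estimates, overflow flag.
    """
    obs = np.asarray(observed_errors, dtype=float)
    avail = np.asarray(available, dtype=bool)
    if obs.shape != avail.shape or obs.ndim != 1:
        raise ValueError("observed_errors and available must be 1-d and equally long")
    if obs.size == 0:
        return np.empty(0), np.empty(0), False
    if not avail[0]:
        raise ValueError("first trial must carry an observation (no proxy history to seed)")
    if not np.all(np.isfinite(obs[avail])):
        raise ValueError("available observations must be finite")
    sigma = params.proxy.sigma
    if rng is None or sigma == 0.0:
        noise = np.zeros(obs.size)
    else:
        noise = rng.standard_normal(obs.size)
    a, b1, b2 = params.proxy.theta
    yhat, ehat, diverged = multirate_path(
        params.Af, params.As, params.Bf, params.Bs, a, b1, b2,
        sigma if rng is not None else 0.0, obs, avail, noise,
    )
    return yhat, ehat, bool(diverged)


def simulate_dpxmrml_curve(
    params: DPxMRMLParams,
    e0: float,
    n_trials: int,
    rng: Optional[np.random.Generator] = None,
    obs_noise: float = 0.0,
    available=None,
):
    """Generate a self-consistent learning curve from the two-rate learner.

    The first-trial error is pinned at ``e0``; on every other *available*
    trial the realized error is the learner's own prediction xf + xs plus
    optional observation noise, and the states update on it. Trials marked
    unavailable in ``available`` are bridged by the embedded proxy process
    exactly as during fitting (their stored error is the proxy estimate),
    so a fit with the same proxy coefficients and availability recovers the
    rates on noiseless data. Used by the synthetic-data generator as a
    ground-truth process.
    """
    n = int(n_trials)
    avail = np.ones(n, dtype=bool) if available is None else np.asarray(available, dtype=bool)
    if avail.shape != (n,):
        raise ValueError("available mask must have length n_trials")
    avail = avail.copy()
    avail[0] = True  # e0 is the first-trial observation
    a, b1, b2 = params.proxy.theta
    sig = params.proxy.sigma
    if rng is None:
        dz_obs = np.zeros(n)
        dz_proxy = np.zeros(n)
    else:
        dz_obs = rng.standard_normal(n)
        dz_proxy = rng.standard_normal(n)
    e = np.empty(n)
    ehat = np.empty(n)
    xf = 0.0
    xs = 0.0
    for t in range(n):
        if avail[t]:
            et = e0 if t == 0 else xf + xs + obs_noise * dz_obs[t]
            eh = et
        else:
            e1 = ehat[t - 1]
            e2 = ehat[t - 2] if t >= 2 else ehat[0]
            eh = e1 + a + b1 * e1 + b2 * e2 + sig * dz_proxy[t]
            et = eh
        e[t] = et
        ehat[t] = eh
        xf = params.Af * xf + params.Bf * eh
        xs = params.As * xs + params.Bs * eh
    return e
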
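"""Low-level trial-recursion kernels.

The proxy-process and multi-rate recursions are inherently sequential, so the
inner loops live here and are JIT-compiled with numba when it is importable;
plain-Python fallbacks keep the package usable (slowly) without a compiler.

Structure codes (``code`` argument):

====  ============  ==================================================
code  structure     drift f over the error history
====  ============  ==================================================
0     linear        b*e
1     affine        a + b*e
2     quadratic     a + (b + c*e)*e
3     cubic         a + (b + c*e + d*e^2)*e
4     k-th order    a + b1*e_n + ... + bk*e_{n-k+1}
====  ============  ==================================================

Trajectories are capped at ``CAP`` in magnitude; once the cap is hit the path
is flagged divergent and its parameter sensitivities are zeroed, so optimizers
see a large, flat objective instead of overflow.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


CAP = 1e8


@njit
def proxy_path(code, order, theta, e0, n, noise):
    """Iterate e_{t+1} = e_t + f(history) + noise_t for n steps.

    ``noise`` has length n and already includes the sigma scale (pass zeros
    for a deterministic path). History shorter than ``order`` is padded by
    repeating e0. Returns (errors[0..n], diverged).
    """
    e = np.empty(n + 1)
    e[0] = e0
    diverged = False
    for t in range(n):
        if code == 4:
            f = theta[0]
            for i in range(1, order + 1):
                m = t - i + 1
                h = e0 if m < 0 else e[m]
                f += theta[i] * h
        else:
            x = e[t]
            if code == 0:
                f = theta[0] * x
            elif code == 1:
                f = theta[0] + theta[1] * x
            elif code == 2:
                f = theta[0] + (theta[1] + theta[2] * x) * x
            else:
                f = theta[0] + (theta[1] + theta[2] * x + theta[3] * x * x) * x
        v = e[t] + f + noise[t]
        if not np.isfinite(v):
            v = CAP
            diverged = True
        elif v > CAP:
            v = CAP
            diverged = True
        elif v < -CAP:
            v = -CAP
            diverged = True
        e[t + 1] = v
    return e, diverged


@njit
def proxy_path_sens(code, order, theta, e0, n):
    """Deterministic path plus sensitivities d e_t / d theta_j.

    Forward sensitivity recursion for the same update as :func:`proxy_path`
    with zero noise; S[0] = 0 because e0 is data, not a parameter. Returns
    (errors, S, diverged) with S of shape (n+1, len(theta)).
    """
    p = theta.shape[0]
    e = np.empty(n + 1)
    S = np.zeros((n + 1, p))
    e[0] = e0
    diverged = False
    for t in range(n):
        if diverged:
            e[t + 1] = e[t]
            continue
        if code == 4:
            f = theta[0]
            for i in range(1, order + 1):
                m = t - i + 1
                f += theta[i] * (e0 if m < 0 else e[m])
            for j in range(p):
                ds = S[t, j]
                for i in range(1, order + 1):
                    m = t - i + 1
                    if m >= 0:
                        ds += theta[i] * S[m, j]
                S[t + 1, j] = ds
            S[t + 1, 0] += 1.0
            for i in range(1, order + 1):
                m = t - i + 1
                S[t + 1, i] += e0 if m < 0 else e[m]
        else:
            x = e[t]
            if code == 0:
                f = theta[0] * x
                fe = theta[0]
            elif code == 1:
                f = theta[0] + theta[1] * x
                fe = theta[1]
            elif code == 2:
                f = theta[0] + (theta[1] + theta[2] * x) * x
                fe = theta[1] + 2.0 * theta[2] * x
            else:
                f = theta[0] + (theta[1] + theta[2] * x + theta[3] * x * x) * x
                fe = theta[1] + 2.0 * theta[2] * x + 3.0 * theta[3] * x * x
            for j in range(p):
                S[t + 1, j] = S[t, j] * (1.0 + fe)
            if code == 0:
                S[t + 1, 0] += x
            else:
                S[t + 1, 0] += 1.0
                S[t + 1, 1] += x
                if code >= 2:
                    S[t + 1, 2] += x * x
                if code >= 3:
                    S[t + 1, 3] += x * x * x
        v = e[t] + f
        if not np.isfinite(v) or v > CAP or v < -CAP:
            v = CAP if v > 0 else -CAP
            diverged = True
            for j in range(p):
                S[t + 1, j] = 0.0
        e[t + 1] = v
    return e, S, diverged


@njit
def proxy_forced_path(code, order, theta, e0, obs, avail):
    """Teacher-forced forward prediction over one learning curve.

    The proxy process runs over all consecutive trials; wherever an
    observation is available the history is re-anchored to it (``h``),
    so between observations the proxy forward-predicts across the gap.
    ``pred[t]`` is the model's prediction of trial t made before seeing
    its observation. Histories before trial 0 are padded with e0.
    Returns (pred, h, diverged).
    """
    n = obs.shape[0]
    pred = np.empty(n)
    h = np.empty(n)
    h[0] = obs[0] if avail[0] else e0
    pred[0] = e0
    diverged = False
    for t in range(n - 1):
        if code == 4:
            f = theta[0]
            for i in range(1, order + 1):
                m = t - i + 1
                f += theta[i] * (e0 if m < 0 else h[m])
        else:
            x = h[t]
            if code == 0:
                f = theta[0] * x
            elif code == 1:
                f = theta[0] + theta[1] * x
            elif code == 2:
                f = theta[0] + (theta[1] + theta[2] * x) * x
            else:
                f = theta[0] + (theta[1] + theta[2] * x + theta[3] * x * x) * x
        v = h[t] + f
        if not np.isfinite(v) or v > CAP or v < -CAP:
            v = CAP if v > 0 else -CAP
            diverged = True
        pred[t + 1] = v
        h[t + 1] = obs[t + 1] if avail[t + 1] else v
    return pred, h, diverged


@njit
def proxy_forced_path_sens(code, order, theta, e0, obs, avail):
    """Teacher-forced predictions plus sensitivities d pred_t / d theta_j.

    Observed (re-anchored) history entries are data, so their sensitivity
    is zero; sensitivities only accumulate across unobserved gaps. Returns
    (pred, S, diverged) with S of shape (n, p).
    """
    n = obs.shape[0]
    p = theta.shape[0]
    pred = np.empty(n)
    S = np.zeros((n, p))       # sensitivity of pred
    Sh = np.zeros((n, p))      # sensitivity of the anchored history
    h = np.empty(n)
    h[0] = obs[0] if avail[0] else e0
    pred[0] = e0
    diverged = False
    for t in range(n - 1):
        if code == 4:
            f = theta[0]
            for i in range(1, order + 1):
                m = t - i + 1
                f += theta[i] * (e0 if m < 0 else h[m])
            for j in range(p):
                ds = Sh[t, j]
                for i in range(1, order + 1):
                    m = t - i + 1
                    if m >= 0:
                        ds += theta[i] * Sh[m, j]
                S[t + 1, j] = ds
            S[t + 1, 0] += 1.0
            for i in range(1, order + 1):
                m = t - i + 1
                S[t + 1, i] += e0 if m < 0 else h[m]
        else:
            x = h[t]
            if code == 0:
                f = theta[0] * x
                fe = theta[0]
            elif code == 1:
                f = theta[0] + theta[1] * x
                fe = theta[1]
            elif code == 2:
                f = theta[0] + (theta[1] + theta[2] * x) * x
                fe = theta[1] + 2.0 * theta[2] * x
            else:
                f = theta[0] + (theta[1] + theta[2] * x + theta[3] * x * x) * x
                fe = theta[1] + 2.0 * theta[2] * x + 3.0 * theta[3] * x * x
            for j in range(p):
                S[t + 1, j] = Sh[t, j] * (1.0 + fe)
            if code == 0:
                S[t + 1, 0] += x
            else:
                S[t + 1, 0] += 1.0
                S[t + 1, 1] += x
                if code >= 2:
                    S[t + 1, 2] += x * x
                if code >= 3:
                    S[t + 1, 3] += x * x * x
        v = h[t] + f
        if not np.isfinite(v) or v > CAP or v < -CAP:
            v = CAP if v > 0 else -CAP
            diverged = True
            for j in range(p):
                S[t + 1, j] = 0.0
        pred[t + 1] = v
        if avail[t + 1]:
            h[t + 1] = obs[t + 1]
            # anchored to data: no parameter dependence
        else:
            h[t + 1] = v
            for j in range(p):
                Sh[t + 1, j] = S[t + 1, j]
    return pred, S, diverged


@njit
def multirate_path(Af, As, Bf, Bs, a, b1, b2, sigma, obs, avail, noise):
    """Run the two-rate learner with proxy-bridged gaps over n trials.

    At each trial t the prediction yhat_t = xf_t + xs_t is emitted first; the
    error estimate ehat_t is the observation when ``avail[t]`` else the
    embedded second-order proxy forward-prediction from the two most recent
    estimates (history padded with ehat_0); both states then update on
    ehat_t. The caller must guarantee avail[0]. Returns (yhat, ehat,
    diverged).
    """
    n = obs.shape[0]
    yhat = np.empty(n)
    ehat = np.empty(n)
    xf = 0.0
    xs = 0.0
    diverged = False
    for t in range(n):
        yhat[t] = xf + xs
        if avail[t]:
            eh = obs[t]
        else:
            e1 = ehat[t - 1]
            e2 = ehat[t - 2] if t >= 2 else ehat[0]
            eh = e1 + a + b1 * e1 + b2 * e2 + sigma * noise[t]
        if not np.isfinite(eh) or eh > CAP or eh < -CAP:
            eh = CAP if eh > 0 else -CAP
            diverged = True
        ehat[t] = eh
        xf = Af * xf + Bf * eh
        xs = As * xs + Bs * eh
        if xf > CAP or xf < -CAP or xs > CAP or xs < -CAP:
            xf = min(max(xf, -CAP), CAP)
            xs = min(max(xs, -CAP), CAP)
            diverged = True
    return yhat, ehat, diverged
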
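"""Proxy-process model structures and their forward simulation.

A proxy process is a scalar autoregressive update for the signed reach error

    e_{n+1} = e_n + f(e_n, ..., e_{n-k+1}) + sigma * dz_n,      dz ~ N(0, 1)

used to forward-predict error across trials on which no measurement exists.
Eleven drift structures f are supported: four first-order polynomials in the
current error (linear ``1.1L``, affine ``1.1``, quadratic ``1.2``, cubic
``1.3``) and the k-th order linear-history family ``k.1`` for k = 2..8.
History shorter than k is padded by repeating the initial condition e0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._kernels import proxy_path, proxy_path_sens

__all__ = [
    "ProxyModelSpec",
    "ProxyModelParams",
    "SteadyState",
    "registry",
    "get_spec",
    "drift",
    "proxy_step",
    "simulate_proxy",
    "steady_state_error",
]

#: factor relative to |e0| beyond which a trial-250 value is flagged divergent
DIVERGENCE_FACTOR = 10.0

_FIRST_ORDER_NAMES = {
    "1.1L": ("b",),
    "1.1": ("a", "b"),
    "1.2": ("a", "b", "c"),
    "1.3": ("a", "b", "c", "d"),
}
_CODES = {"1.1L": 0, "1.1": 1, "1.2": 2, "1.3": 3}


@dataclass(frozen=True)
class ProxyModelSpec:
    """One of the eleven proxy-process drift structures.

    Attributes
    ----------
    structure_id : str
        ``"1.1L"``, ``"1.1"``, ``"1.2"``, ``"1.3"`` or ``"k.1"`` for k=2..8.
    order : int
        History depth k (1 for the four first-order structures).
    param_names : tuple of str
        Drift coefficient names in the order they appear in a parameter
        vector (sigma is carried separately and never counted here).
    """

    structure_id: str
    order: int
    param_names: tuple

    @property
    def n_free_params(self) -> int:
        return len(self.param_names)

    @property
    def code(self) -> int:
        return _CODES.get(self.structure_id, 4)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.structure_id


def _make_spec(structure_id: str) -> ProxyModelSpec:
    if structure_id in _FIRST_ORDER_NAMES:
        return ProxyModelSpec(structure_id, 1, _FIRST_ORDER_NAMES[structure_id])
    k = int(structure_id.split(".")[0])
    if not (2 <= k <= 8) or not structure_id.endswith(".1"):
        raise ValueError(f"unknown structure id {structure_id!r}")
    names = ("a",) + tuple(f"b{i}" for i in range(1, k + 1))
    return ProxyModelSpec(structure_id, k, names)


_REGISTRY = tuple(
    _make_spec(s)
    for s in ("1.1L", "1.1", "1.2", "1.3", "2.1", "3.1", "4.1", "5.1", "6.1", "7.1", "8.1")
)


def registry() -> list:
    """All eleven candidate structures in a stable order."""
    return list(_REGISTRY)


def get_spec(structure_id: str) -> ProxyModelSpec:
    for s in _REGISTRY:
        if s.structure_id == structure_id:
            return s
    raise KeyError(structure_id)


@dataclass
class ProxyModelParams:
    """Drift coefficients plus the inter-trial noise scale sigma.

    Only the coefficients used by the owning spec are meaningful; the vector
    layout follows ``spec.param_names``. Units: ``a`` in error-units/trial,
    the b/b_i coefficients are dimensionless per-trial rates, ``c`` is
    1/(error-units*trial), ``d`` 1/(error-units^2*trial), ``sigma`` in
    error-units (>= 0).
    """

    spec: ProxyModelSpec
    theta: np.ndarray
    sigma: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.spec.n_free_params,):
            raise ValueError(
                f"{self.spec.structure_id} expects {self.spec.n_free_params} "
                f"coefficients {self.spec.param_names}, got {self.theta.shape}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def from_dict(cls, structure_id: str, sigma: float = 0.0, **coeffs) -> "ProxyModelParams":
        spec = get_spec(structure_id)
        missing = set(spec.param_names) - set(coeffs)
        extra = set(coeffs) - set(spec.param_names)
        if missing or extra:
            raise ValueError(f"coefficients for {structure_id}: missing {missing}, extra {extra}")
        theta = np.array([coeffs[name] for name in spec.param_names], dtype=float)
        return cls(spec, theta, sigma)

    def as_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(self.spec.param_names, self.theta)}
        d["sigma"] = float(self.sigma)
        return d


@dataclass
class SteadyState:
    """Deterministic model-implied error at the final learning trial."""

    value: float
    diverged: bool


def _check_history(spec: ProxyModelSpec, history: Sequence[float]) -> np.ndarray:
    h = np.asarray(history, dtype=float)
    if h.ndim != 1 or h.size < spec.order:
        raise ValueError(
            f"history of length >= {spec.order} required for {spec.structure_id}, got {h.size}"
        )
    if not np.all(np.isfinite(h)):
        raise ValueError("history must be finite")
    return h


def drift(spec: ProxyModelSpec, params: ProxyModelParams, history: Sequence[float]) -> float:
    """Evaluate the drift f on the most recent ``spec.order`` errors.

    ``history`` is ordered most-recent-last; a pure function of its inputs.
    """
    h = _check_history(spec, history)
    th = params.theta
    e = h[-1]
    if spec.structure_id == "1.1L":
        return float(th[0] * e)
    if spec.structure_id == "1.1":
        return float(th[0] + th[1] * e)
    if spec.structure_id == "1.2":
        return float(th[0] + (th[1] + th[2] * e) * e)
    if spec.structure_id == "1.3":
        return float(th[0] + (th[1] + th[2] * e + th[3] * e * e) * e)
    # k-th order: b1 multiplies e_n, bk multiplies e_{n-k+1}
    recent = h[::-1][: spec.order]  # e_n, e_{n-1}, ...
    return float(th[0] + np.dot(th[1:], recent))


def proxy_step(
    spec: ProxyModelSpec,
    params: ProxyModelParams,
    history: Sequence[float],
    noise_draw: float = 0.0,
) -> float:
    """One stochastic update e_{n+1} = e_n + f(history) + sigma*noise_draw."""
    h = _check_history(spec, history)
    return float(h[-1] + drift(spec, params, h) + params.sigma * noise_draw)


def simulate_proxy(
    spec: ProxyModelSpec,
    params: ProxyModelParams,
    e0: float,
    n_trials: int,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate ``n_trials`` updates from e0; returns array of length n+1.

    Element 0 equals e0; history deeper than available is padded with e0.
    Deterministic (dz = 0) when ``rng`` is None. Returns (errors, diverged).
    """
    if not np.isfinite(e0):
        raise ValueError("e0 must be finite")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        noise = np.zeros(n_trials)
    else:
        noise = params.sigma * rng.standard_normal(n_trials)
    e, diverged = proxy_path(spec.code, spec.order, params.theta, float(e0), int(n_trials), noise)
    return e, bool(diverged)


def simulate_proxy_with_sensitivities(spec: ProxyModelSpec, theta: np.ndarray, e0: float, n_trials: int):
    """Deterministic path and Jacobian d e_t / d theta (used by the fitter)."""
    e, S, diverged = proxy_path_sens(spec.code, spec.order, np.asarray(theta, float), float(e0), int(n_trials))
    return e, S, bool(diverged)


def steady_state_error(
    spec: ProxyModelSpec,
    params: ProxyModelParams,
    e0: float,
    n: int = 250,
) -> SteadyState:
    """Deterministic simulated error at trial ``n`` (sigma treated as 0).

    Divergent dynamics are not clipped below the numeric cap; values with
    magnitude beyond ``DIVERGENCE_FACTOR * |e0|`` are flagged instead so the
    caller can exclude them.
    """
    e, capped = simulate_proxy(spec, ProxyModelParams(spec, params.theta, 0.0), e0, n, rng=None)
    value = float(e[n])
    flag = capped or (abs(value) > DIVERGENCE_FACTOR * max(abs(e0), 1e-12))
    return SteadyState(value=value, diverged=flag)
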
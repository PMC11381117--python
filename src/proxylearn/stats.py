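"""Weighted-bootstrap nonparametric inference.

Group-level questions about fitted parameters (is a coefficient's sign
consistent across curves? does an EA coordinate differ from veridical
feedback?) are answered with sign tests and rank-sum tests realized through
weighted bootstrap resampling: each curve's contribution is resampled with
probability proportional to its weight (by default the inverse of its
regression RMSE, so noisy fits count less), the test statistic is computed
on every replicate, and the consensus (median-over-replicates) statistic is
referred to its classical null distribution — the exact binomial for the
sign test, the continuity-corrected normal approximation for the rank-sum.
Under equal weights this reduces to the classical tests, which preserves
type-I calibration. Medians and 95% confidence intervals of the median come
from percentiles of the replicate medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import CONTROL_EA
from .structures import steady_state_error

__all__ = [
    "WeightedSample",
    "TestOutcome",
    "default_weights",
    "boot_median_ci",
    "sign_test",
    "ranksum_test",
    "parameter_table",
    "steady_state_table",
    "washout_table",
]

DEFAULT_B = 100_000
_CHUNK_ELEMS = 2_000_000


@dataclass
class WeightedSample:
    """Values with resampling weights (default 1/RMSE) and a group label."""

    values: np.ndarray
    weights: Optional[np.ndarray] = None
    label: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.values.shape:
            raise ValueError("weights must match values in length")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 with at least one positive")

    @property
    def probabilities(self) -> np.ndarray:
        return self.weights / self.weights.sum()


@dataclass
class TestOutcome:
    """A single nonparametric test result with its bootstrap median/CI."""

    pvalue: float
    pvalue_corrected: float
    reject: bool
    median: float
    ci95: Tuple[float, float]
    n: int
    statistic: float = np.nan

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.median <= hi + 1e-12):
            raise ValueError("CI95 must contain the median point estimate")


def default_weights(rmses, floor_percentile: float = 1.0) -> np.ndarray:
    """Inverse-RMSE weights with the RMSE floored at a low percentile.

    The floor prevents near-perfect fits from dominating the resampling.
    """
    r = np.asarray(rmses, dtype=float)
    floor = max(float(np.percentile(r, floor_percentile)), 1e-12)
    return 1.0 / np.maximum(r, floor)


def _resample_chunks(rng, n, prob, B):
    chunk = max(1, _CHUNK_ELEMS // max(n, 1))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        yield rng.choice(n, size=(m, n), replace=True, p=prob)
        done += m


def _replicate_medians(rng, values, prob, B):
    meds = np.empty(B)
    pos = 0
    for idx in _resample_chunks(rng, values.size, prob, B):
        meds[pos:pos + idx.shape[0]] = np.median(values[idx], axis=1)
        pos += idx.shape[0]
    return meds


def boot_median_ci(sample: WeightedSample, B: int = DEFAULT_B, seed: int = 0):
    """Weighted-bootstrap median and 95% CI of the median.

    Returns ``(median, (lo, hi))``; the point estimate is the median of the
    replicate medians, so it always lies inside its own interval.
    """
    rng = np.random.default_rng(seed)
    meds = _replicate_medians(rng, sample.values, sample.probabilities, int(B))
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(np.median(meds)), (float(lo), float(hi))


def _binom_two_sided(k: int, n: int) -> float:
    if n == 0:
        return 1.0
    lo = sps.binom.cdf(k, n, 0.5)
    hi = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def sign_test(
    sample: WeightedSample,
    null_value: float = 0.0,
    alpha: float = 0.05,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> TestOutcome:
    """Weighted-bootstrap sign test against ``null_value`` (two-sided).

    Each replicate resamples the values with the sample weights and counts
    how many exceed the null; the consensus count over replicates is
    referred to the exact Binomial(n, 1/2) null. With a single value the
    test can never reject at conventional levels.
    """
    rng = np.random.default_rng(seed)
    v = sample.values
    prob = sample.probabilities
    if np.all(v == null_value):
        med, ci = boot_median_ci(sample, B=min(B, 1000), seed=seed)
        return TestOutcome(1.0, 1.0, False, med, ci, v.size, statistic=0.0)
    B = int(B)
    ks = np.empty(B)
    ms = np.empty(B)
    meds = np.empty(B)
    pos = 0
    for idx in _resample_chunks(rng, v.size, prob, B):
        res = v[idx]
        ks[pos:pos + idx.shape[0]] = np.sum(res > null_value, axis=1)
        ms[pos:pos + idx.shape[0]] = np.sum(res != null_value, axis=1)
        meds[pos:pos + idx.shape[0]] = np.median(res, axis=1)
        pos += idx.shape[0]
    k_star = int(round(float(np.median(ks))))
    n_star = int(round(float(np.median(ms))))
    k_star = min(k_star, n_star)
    p = _binom_two_sided(k_star, n_star)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return TestOutcome(p, p, p < alpha, float(np.median(meds)),
                       (float(lo), float(hi)), v.size, statistic=float(k_star))


def ranksum_test(
    sample_a: WeightedSample,
    sample_b: WeightedSample,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> TestOutcome:
    """Weighted-bootstrap Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Each group is resampled with its own weights; the Mann-Whitney U of each
    replicate is computed and the consensus U over replicates is referred to
    the continuity-corrected normal null. ``pvalue_corrected`` applies the
    Bonferroni factor ``n_comparisons``. The reported median/CI describe the
    difference of group medians (A - B).
    """
    rng = np.random.default_rng(seed)
    a, b = sample_a.values, sample_b.values
    pa, pb = sample_a.probabilities, sample_b.probabilities
    na, nb = a.size, b.size
    B = int(B)
    chunk = max(1, _CHUNK_ELEMS // max(na * nb, 1))
    us = np.empty(B)
    dmeds = np.empty(B)
    pos = 0
    while pos < B:
        m = min(chunk, B - pos)
        ia = rng.choice(na, size=(m, na), replace=True, p=pa)
        ib = rng.choice(nb, size=(m, nb), replace=True, p=pb)
        ra = a[ia]
        rb = b[ib]
        gt = (ra[:, :, None] > rb[:, None, :]).sum(axis=(1, 2))
        eq = (ra[:, :, None] == rb[:, None, :]).sum(axis=(1, 2))
        us[pos:pos + m] = gt + 0.5 * eq
        dmeds[pos:pos + m] = np.median(ra, axis=1) - np.median(rb, axis=1)
        pos += m
    u_star = float(np.median(us))
    mu = na * nb / 2.0
    sd = math.sqrt(na * nb * (na + nb + 1) / 12.0)
    if sd == 0:
        p = 1.0
    else:
        z = (abs(u_star - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    p_corr = min(1.0, p * max(1, int(n_comparisons)))
    lo, hi = np.percentile(dmeds, [2.5, 97.5])
    return TestOutcome(p, p_corr, p_corr < alpha, float(np.median(dmeds)),
                       (float(lo), float(hi)), na + nb, statistic=u_star)


# ---------------------------------------------------------------------------
# figure-style tables


def _spawn_seeds(seed: int, labels: Sequence) -> Dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % (2**31)) for lab, c in zip(labels, children)}


def _coordinate_table(
    samples: Mapping[tuple, WeightedSample],
    null_value: Optional[float],
    control: tuple,
    alpha: float,
    B: int,
    seed: int,
) -> pd.DataFrame:
    coords = sorted(samples)
    seeds = _spawn_seeds(seed, coords)
    non_control = [c for c in coords if tuple(c) != tuple(control)]
    divisor = max(1, len(non_control))
    have_control = tuple(control) in {tuple(c) for c in coords}
    rows = []
    for coord in coords:
        s = samples[coord]
        med, ci = boot_median_ci(s, B=B, seed=seeds[coord])
        row = {
            "ea_gain": coord[0], "ea_offset": coord[1], "n": s.values.size,
            "median": med, "ci_lo": ci[0], "ci_hi": ci[1],
        }
        if null_value is not None:
            st = sign_test(s, null_value=null_value, alpha=alpha, B=B, seed=seeds[coord])
            row["p_sign"] = st.pvalue
            row["reject_sign"] = st.reject
            row["direction"] = (
                "ns" if not st.reject else ("positive" if med > null_value else "negative")
            )
        if have_control and tuple(coord) != tuple(control):
            rt = ranksum_test(s, samples[tuple(control)], alpha=alpha,
                              n_comparisons=divisor, B=B, seed=seeds[coord] + 1)
            row["p_vs_control"] = rt.pvalue
            row["p_vs_control_corrected"] = rt.pvalue_corrected
            row["reject_vs_control"] = rt.reject
        elif tuple(coord) == tuple(control):
            row["p_vs_control"] = np.nan
            row["p_vs_control_corrected"] = np.nan
            row["reject_vs_control"] = False
        else:
            row["p_vs_control"] = np.nan
            row["p_vs_control_corrected"] = np.nan
            row["reject_vs_control"] = None  # control group unavailable
        rows.append(row)
    return pd.DataFrame(rows).set_index(["ea_gain", "ea_offset"])


def parameter_table(
    samples: Mapping[tuple, WeightedSample],
    null_value: float = 0.0,
    control: tuple = CONTROL_EA,
    alpha: float = 0.05,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-EA-coordinate sign tests plus rank-sum comparisons vs control.

    ``samples`` maps EA coordinates to weighted per-curve values of one
    fitted parameter. The Bonferroni divisor for the control comparisons is
    the number of non-control coordinates present.
    """
    if not samples:
        raise ValueError("need samples for >= 1 coordinate")
    return _coordinate_table(samples, null_value, control, alpha, B, seed)


def steady_state_table(
    fits_by_coord: Mapping[tuple, Sequence],
    n_trial: int = 250,
    control: tuple = CONTROL_EA,
    alpha: float = 0.05,
    B: int = DEFAULT_B,
    seed: int = 0,
):
    """Sign tests on model-implied steady-state errors at the final trial.

    ``fits_by_coord`` maps EA coordinates to second-order proxy fit results
    (each carries its own e0 and RMSE). Divergent curves are excluded and
    reported in the returned log. Returns ``(table, excluded_log)``.
    """
    samples: Dict[tuple, WeightedSample] = {}
    log: List[str] = []
    for coord, fits in fits_by_coord.items():
        vals, rmses = [], []
        for f in fits:
            ss = steady_state_error(f.params.spec, f.params, f.model.e0, n=n_trial)
            if ss.diverged:
                log.append(f"EA{coord}: curve excluded (divergent steady state)")
                continue
            vals.append(ss.value)
            rmses.append(max(f.rmse, 1e-12))
        if vals:
            samples[coord] = WeightedSample(np.array(vals), default_weights(rmses), coord)
    if not samples:
        raise ValueError("no non-divergent curves to analyse")
    table = _coordinate_table(samples, 0.0, control, alpha, B, seed)
    return table, log


def washout_table(
    tau_by_coord: Mapping[tuple, WeightedSample],
    control: tuple = CONTROL_EA,
    alpha: float = 0.05,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Washout time-constant medians/CIs and rank-sum comparisons vs control."""
    if len(tau_by_coord) < 2:
        raise ValueError("need >= 2 coordinates to compare washout decay")
    return _coordinate_table(tau_by_coord, None, control, alpha, B, seed)
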
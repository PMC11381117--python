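"""Self-validation experiments at the study's conditions.

Each function runs one end-to-end property check of the package on
synthetic data whose ground truth is known — parameter recovery, model
structure recovery through cross-validation, type-I calibration of the
bootstrap tests, washout time-constant recovery — and returns plain
numbers. The test suite asserts on them; ``scripts/acceptance.py`` reports
them.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .fitting import FitConfig, MultiRateModel, ProxyProcessModel, WashoutDecayModel
from .multirate import DPxMRMLParams, simulate_dpxmrml_curve
from .selection import cross_validate
from .simulate import DesignConfig, default_ground_truth, generate_dataset, make_schedule
from .stats import WeightedSample, ranksum_test, sign_test
from .structures import ProxyModelParams, get_spec, simulate_proxy

__all__ = [
    "proxy_recovery",
    "multirate_recovery",
    "selection_replicate",
    "selection_recovery",
    "test_calibration",
    "washout_recovery",
]

#: noise condition for the recovery studies: sigma = 0.02 * |e0|
RECOVERY_SIGMA_FRACTION = 0.02


def proxy_recovery(n_curves: int = 100, seed: int = 0, n_starts: int = 8,
                   coord=(1, 1)) -> Dict:
    """Fit the second-order structure to curves simulated from known truth.

    Uses the generator's default coefficients for the given EA coordinate
    (all three drift coefficients are non-zero at offset-1 coordinates) and
    per-curve noise sigma = 0.02*|e0|. Returns the coefficient medians and
    their relative errors, plus a bootstrap CI cover flag per coefficient.
    """
    spec = get_spec("2.1")
    truth = default_ground_truth()[tuple(coord)]
    rng = np.random.default_rng(seed)
    thetas = []
    for i in range(n_curves):
        mask = make_schedule(250, 74, rng)
        e0 = rng.uniform(2, 6) * (1 if rng.random() < 0.5 else -1)
        params = ProxyModelParams(spec, truth.theta, RECOVERY_SIGMA_FRACTION * abs(e0))
        e, _ = simulate_proxy(spec, params, e0, 249, rng=rng)
        idx = np.flatnonzero(mask)
        res = ProxyProcessModel(e[idx], idx, e0, spec, n_trials=250).fit(
            FitConfig(n_starts=n_starts, seed=i))
        thetas.append(res.params.theta)
    th = np.array(thetas)
    medians = np.median(th, axis=0)
    rel_err = np.abs((medians - truth.theta) / truth.theta)
    # percentile bootstrap CI of each coefficient median
    boot = np.median(th[rng.integers(0, n_curves, (2000, n_curves))], axis=1)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    covered = (lo <= truth.theta) & (truth.theta <= hi)
    return {
        "truth": dict(zip(spec.param_names, truth.theta)),
        "medians": dict(zip(spec.param_names, medians)),
        "rel_err": dict(zip(spec.param_names, rel_err)),
        "max_rel_err": float(rel_err.max()),
        "ci_covers": dict(zip(spec.param_names, covered.tolist())),
    }


def multirate_recovery(seed: int = 0, n_noisy: int = 10) -> Dict:
    """Two-rate learner rate recovery: exact on noiseless data, ordered under noise."""
    proxy = ProxyModelParams.from_dict("2.1", a=-0.05, b1=0.1, b2=-0.3)
    truth = DPxMRMLParams(Af=-0.5, As=0.95, Bf=0.4, Bs=-0.05, proxy=proxy)
    rng = np.random.default_rng(seed)

    def one(obs_noise, fit_seed):
        mask = make_schedule(250, 74, rng)
        avail = mask.copy()
        avail[0] = True
        e0 = rng.uniform(2, 6)
        e = simulate_dpxmrml_curve(truth, e0, 250, available=avail,
                                   rng=rng if obs_noise > 0 else None,
                                   obs_noise=obs_noise)
        idx = np.flatnonzero(avail)
        return MultiRateModel(e[idx], idx, e0, proxy, n_trials=250).fit(
            FitConfig(n_starts=20, seed=fit_seed)).params

    clean = one(0.0, 0)
    rel = {name: abs(getattr(clean, name) - target) / abs(target)
           for name, target in truth.as_dict().items()}
    orderings = 0
    noisy = []
    for i in range(n_noisy):
        p = one(0.1, 100 + i)
        orderings += (p.As > p.Af) and (p.Bf > p.Bs)
        noisy.append([p.Af, p.As, p.Bf, p.Bs])
    med = np.median(np.array(noisy), axis=0)
    truth_vec = np.array([truth.Af, truth.As, truth.Bf, truth.Bs])
    # group-level sign consistency: the median noisy estimate carries the
    # true sign of each rate (individual fits of the small Bs may flip)
    median_signs_correct = bool(np.all(np.sign(med) == np.sign(truth_vec)))
    return {
        "noiseless_rel_err": rel,
        "noiseless_max_rel_err": float(max(rel.values())),
        "ordering_rate": orderings / n_noisy,
        "median_signs_correct": median_signs_correct,
        "noisy_medians": dict(zip(("Af", "As", "Bf", "Bs"), med)),
        "truth": truth.as_dict(),
        "noiseless_fit": clean.as_dict(),
    }


def selection_replicate(seed: int, n_starts: int = 4) -> Dict:
    """One seeded model-selection replicate at the stated design.

    10 subjects x 2 tasks x 6 directions, second-order ground truth with
    sigma = 0.02*|e0|; every subject gets the same EA coordinate per task so
    the across-subject cross-validation has two full 10-subject groups.
    """
    rng = np.random.default_rng(seed)
    design = DesignConfig(n_subjects=10, n_control=0, n_tasks=2, n_directions=6,
                          sigma_e0_fraction=RECOVERY_SIGMA_FRACTION)
    assignment = {(s, 1): (1, 0) for s in range(1, 11)}
    assignment.update({(s, 2): (2, 0) for s in range(1, 11)})
    data = generate_dataset(design, rng=rng, ea_assignment=assignment)
    report = cross_validate(data, grouping="subjects",
                            config=FitConfig(n_starts=n_starts, seed=seed))
    first_order = ("1.1L", "1.1", "1.2", "1.3")
    return {
        "winner_includes_truth": "2.1" in report.winners,
        "first_order_beats_truth": any(
            int(report.matrix.loc[m, "2.1"]) == 1 for m in first_order),
        "scores": report.scores.to_dict(),
    }


def selection_recovery(n_replicates: int = 20, seed: int = 0,
                       n_starts: int = 4) -> Dict:
    """Model-structure recovery rate over seeded replicates."""
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    reps = [selection_replicate(int(c.generate_state(1)[0] % (2**31)),
                                n_starts=n_starts) for c in ss]
    return {
        "top_rate": float(np.mean([r["winner_includes_truth"] for r in reps])),
        "first_order_beat_rate": float(
            np.mean([r["first_order_beats_truth"] for r in reps])),
        "n_replicates": n_replicates,
    }


def test_calibration(n_replicates: int = 500, n: int = 20, B: int = 10_000,
                     alpha: float = 0.05, seed: int = 0) -> Dict:
    """Empirical type-I error of the bootstrap sign and rank-sum tests."""
    rng = np.random.default_rng(seed)
    sign_rej = rank_rej = 0
    for i in range(n_replicates):
        v = rng.standard_normal(n)
        sign_rej += sign_test(WeightedSample(v), 0.0, alpha=alpha, B=B,
                              seed=seed + i).reject
        a = WeightedSample(rng.standard_normal(n))
        b = WeightedSample(rng.standard_normal(n))
        rank_rej += ranksum_test(a, b, alpha=alpha, B=B, seed=seed + i).reject
    return {
        "sign_type1": sign_rej / n_replicates,
        "ranksum_type1": rank_rej / n_replicates,
        "alpha": alpha,
        "band": (alpha / 2, 2 * alpha),
    }


def washout_recovery(n_curves: int = 20, tau: float = 5.0, amplitude: float = 3.0,
                     noise: float = 0.2, n_trials: int = 30, seed: int = 0) -> Dict:
    """Recover the washout decay time constant under half-normal noise.

    The offset variant of the exponential fit is used because the
    half-normal noise has a non-zero mean that would otherwise bias tau.
    """
    errs = []
    for i in range(n_curves):
        rng = np.random.default_rng(seed + i)
        y = (amplitude * np.exp(-np.arange(n_trials) / tau)
             + noise * np.abs(rng.standard_normal(n_trials)))
        fit = WashoutDecayModel(y, offset=True).fit(FitConfig(n_starts=25, seed=i))
        errs.append(abs(fit.tau - tau) / tau)
    return {"tau": tau, "median_rel_err": float(np.median(errs)),
            "n_curves": n_curves}
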
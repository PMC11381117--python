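"""Synthetic error-augmentation reaching experiment.

Emulates the structure of a target-to-target visuomotor learning study:
targets at the vertices of a 15 cm equilateral triangle (six directed
reaches at least 60 degrees apart), eight learning tasks of 250 trials each
followed by a 30-trial washout, 74 non-consecutive no-vision catch trials
per learning phase, and per-task error-augmentation (EA) settings drawn from
the gain {0..3} x offset {0..2} grid (control = gain 1, offset 0).

Signed errors on each curve follow a configurable ground-truth process —
either a proxy-process autoregression or the two-rate learner — from a
per-curve initial error e0, with Wiener-type inter-trial noise. The signed
maximum-deviation error metric itself is computed on *unaugmented* cursor
trajectories; error augmentation only distorts what the learner sees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .multirate import DPxMRMLParams, simulate_dpxmrml_curve
from .structures import ProxyModelParams, simulate_proxy

__all__ = [
    "EA_GRID",
    "CONTROL_EA",
    "TargetGeometry",
    "DesignConfig",
    "make_geometry",
    "make_schedule",
    "assign_ea",
    "augment_cursor",
    "synth_trajectory",
    "signed_error",
    "default_ground_truth",
    "default_washout_tau",
    "generate_dataset",
]

#: the 12 EA coordinates: gain in {0,1,2,3} x offset in {0,1,2} restricted to
#: the combinations used in the study design (4 gains x 3 offsets = 12)
EA_GRID = tuple((g, o) for g in range(4) for o in range(3))
CONTROL_EA = (1, 0)

TRIAL_COLUMNS = [
    "subject", "task", "direction", "phase", "trial", "presentation",
    "no_vision", "ea_gain", "ea_offset", "error",
]


@dataclass(frozen=True)
class TargetGeometry:
    """Three triangle vertices and the six directed reaches between them."""

    vertices: np.ndarray          # (3, 2) cm
    reaches: tuple                # 6 ordered (start_idx, target_idx) pairs

    @property
    def n_directions(self) -> int:
        return len(self.reaches)

    def reach_endpoints(self, direction: int) -> Tuple[np.ndarray, np.ndarray]:
        i, j = self.reaches[direction]
        return self.vertices[i], self.vertices[j]

    def unit_direction(self, direction: int) -> np.ndarray:
        p0, p1 = self.reach_endpoints(direction)
        v = p1 - p0
        return v / np.linalg.norm(v)

    def reach_lengths(self) -> np.ndarray:
        return np.array([
            np.linalg.norm(self.vertices[j] - self.vertices[i]) for i, j in self.reaches
        ])

    def min_pairwise_angle_deg(self) -> float:
        dirs = [self.unit_direction(d) for d in range(self.n_directions)]
        best = 180.0
        for u, v in itertools.combinations(dirs, 2):
            ang = math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))
            best = min(best, ang)
        return best


def make_geometry(side: float = 15.0) -> TargetGeometry:
    """Equilateral-triangle target layout with the given side length (cm)."""
    if side <= 0:
        raise ValueError("side must be positive")
    h = side * math.sqrt(3.0) / 2.0
    vertices = np.array([[0.0, 0.0], [side, 0.0], [side / 2.0, h]])
    reaches = tuple((i, j) for i in range(3) for j in range(3) if i != j)
    return TargetGeometry(vertices=vertices, reaches=reaches)


def make_schedule(n_trials: int, n_novision: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform no-vision catch-trial mask: exact count, never two in a row.

    Sampled constructively: choosing k of n-k+1 slots and spreading them
    (stars-and-bars) is a bijection onto the valid masks, so the draw is
    exactly uniform without rejection.
    """
    n_trials = int(n_trials)
    n_novision = int(n_novision)
    if n_novision < 0 or n_trials < 1:
        raise ValueError("counts must be positive")
    if n_novision > math.ceil(n_trials / 2):
        raise ValueError(
            f"{n_novision} non-adjacent no-vision trials do not fit in {n_trials} trials"
        )
    mask = np.zeros(n_trials, dtype=bool)
    if n_novision == 0:
        return mask
    slots = rng.choice(n_trials - n_novision + 1, size=n_novision, replace=False)
    slots.sort()
    mask[slots + np.arange(n_novision)] = True
    return mask


def assign_ea(
    n_subjects: int,
    n_control: int,
    n_tasks: int,
    rng: np.random.Generator,
) -> Dict[Tuple[int, int], Tuple[int, int]]:
    """Per subject x task EA coordinate assignment.

    The first ``n_control`` subjects receive the control coordinate for all
    tasks; every other subject draws, independently per task, uniformly from
    the 11 non-control coordinates.
    """
    if n_control > n_subjects:
        raise ValueError("n_control cannot exceed n_subjects")
    non_control = [ea for ea in EA_GRID if ea != CONTROL_EA]
    out: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for s in range(1, n_subjects + 1):
        for t in range(1, n_tasks + 1):
            if s <= n_control:
                out[(s, t)] = CONTROL_EA
            else:
                out[(s, t)] = non_control[rng.integers(len(non_control))]
    return out


def augment_cursor(c, c_d, c_0, ea: Tuple[int, int]) -> np.ndarray:
    """Error-augmented cursor position.

    chat = c_d + gain * (c - c_d) + offset * (c_0 - c_d), where c is the true
    cursor sample, c_d the matching point on the ideal straight path and c_0
    the first-exposure cursor sample. Gain 1 / offset 0 is the identity.
    """
    c = np.asarray(c, dtype=float)
    c_d = np.asarray(c_d, dtype=float)
    c_0 = np.asarray(c_0, dtype=float)
    gain, offset = ea
    return c_d + gain * (c - c_d) + offset * (c_0 - c_d)


def synth_trajectory(
    geometry: TargetGeometry,
    direction: int,
    lateral_amplitude: float,
    n_samples: int = 51,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.0,
):
    """Straight reach plus a smooth lateral bump of given signed peak (cm).

    The bump is a half-sine normalized on the sample grid, so the maximum
    perpendicular deviation over the returned samples equals
    ``lateral_amplitude`` exactly (before jitter). Positive amplitude lies on
    the left of the movement direction. Returns (samples, ideal_endpoints).
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    p0, p1 = geometry.reach_endpoints(direction)
    u = geometry.unit_direction(direction)
    normal = np.array([-u[1], u[0]])
    t = np.linspace(0.0, 1.0, n_samples)
    bump = np.sin(math.pi * t)
    peak = bump.max()
    if peak > 0:
        bump = bump / peak
    pts = p0[None, :] + np.outer(t, p1 - p0) + lateral_amplitude * np.outer(bump, normal)
    if jitter > 0 and rng is not None:
        pts = pts + jitter * rng.standard_normal(pts.shape)
        pts[0] = p0
    return pts, (p0, p1)


def signed_error(trajectory, ideal_endpoints, reference_sign_direction: int) -> float:
    """Signed maximum-deviation error of a reach (cm).

    Magnitude is the largest perpendicular distance between the trajectory
    samples and the ideal straight path; the sign is positive when that
    maximal-deviation sample lies on the same side as on the first exposure
    to the task/direction (``reference_sign_direction`` = +1 for the left of
    the movement direction, -1 for the right).
    """
    pts = np.asarray(trajectory, dtype=float)
    p0, p1 = (np.asarray(p, dtype=float) for p in ideal_endpoints)
    v = p1 - p0
    length = np.linalg.norm(v)
    if length == 0:
        raise ValueError("degenerate ideal path (zero length)")
    if reference_sign_direction not in (-1, 1):
        raise ValueError("reference_sign_direction must be +1 or -1")
    u = v / length
    rel = pts - p0
    perp = u[0] * rel[:, 1] - u[1] * rel[:, 0]  # signed cross product u x rel
    idx = int(np.argmax(np.abs(perp)))
    mag = abs(perp[idx])
    if mag == 0:
        return 0.0
    side = 1 if perp[idx] > 0 else -1
    return float(mag if side == reference_sign_direction else -mag)


# ---------------------------------------------------------------------------
# full-dataset generation


@dataclass
class DesignConfig:
    """Experiment design; defaults reproduce the study's structure."""

    n_subjects: int = 15
    n_control: int = 5
    n_tasks: int = 8
    n_directions: int = 6
    n_trials: int = 250
    n_novision: int = 74
    n_washout: int = 30
    side_cm: float = 15.0
    e0_low: float = 2.0
    e0_high: float = 6.0
    washout_noise: float = 0.2
    #: when set, the ground-truth process noise is sigma = fraction * |e0|
    #: per curve instead of the per-coordinate sigma in the parameter map
    sigma_e0_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_control", "n_tasks", "n_directions",
                     "n_trials", "n_novision", "n_washout"):
            if getattr(self, name) < 0 or (name not in ("n_control", "n_novision", "n_washout")
                                           and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")


def default_ground_truth() -> Dict[Tuple[int, int], ProxyModelParams]:
    """Second-order proxy-process truths per EA coordinate.

    Chosen to mirror the qualitative pattern of fitted coefficients in this
    paradigm: the history coefficient b2 is negative everywhere and more
    negative at higher gains (faster error reduction with veridical or
    amplified feedback); b1 is small and positive, clearly so only for
    gain 0 / offset 1; the constant drift a is negative for the offset
    conditions and gain 0 (continued drift past the target skill level); the
    inter-trial noise sigma is larger when the feedback carries no knowledge
    of results (gain 0).
    """
    a_negative = {(0, 0), (0, 1), (1, 1), (2, 1), (3, 1), (1, 2)}
    out: Dict[Tuple[int, int], ProxyModelParams] = {}
    for gain, offset in EA_GRID:
        out[(gain, offset)] = ProxyModelParams.from_dict(
            "2.1",
            a=-0.08 if (gain, offset) in a_negative else 0.0,
            b1=0.35 if (gain, offset) == (0, 1) else 0.2,
            # complex characteristic roots: damped oscillatory error decay
            # (the second-order signature), faster at higher gains
            b2=-(0.42 + 0.06 * gain),
            sigma=0.2 if gain == 0 else 0.12,
        )
    return out


def default_washout_tau() -> Dict[Tuple[int, int], float]:
    """Washout decay time constants (trials) per EA coordinate."""
    tau = {ea: 5.0 for ea in EA_GRID}
    tau[(1, 0)] = 4.34
    tau[(2, 0)] = 2.90
    tau[(3, 0)] = 21.1
    return tau


GroundTruth = Mapping[Tuple[int, int], Union[ProxyModelParams, DPxMRMLParams]]


def _simulate_curve_errors(truth, e0: float, n_trials: int,
                           novision_mask: np.ndarray,
                           rng: np.random.Generator,
                           sigma_override: Optional[float] = None) -> np.ndarray:
    if sigma_override is not None:
        if isinstance(truth, DPxMRMLParams):
            proxy = ProxyModelParams(truth.proxy.spec, truth.proxy.theta, sigma_override)
            truth = DPxMRMLParams(truth.Af, truth.As, truth.Bf, truth.Bs, proxy)
        else:
            truth = ProxyModelParams(truth.spec, truth.theta, sigma_override)
    if isinstance(truth, DPxMRMLParams):
        avail = novision_mask.copy()
        avail[0] = True
        return simulate_dpxmrml_curve(truth, e0, n_trials, rng=rng,
                                      obs_noise=truth.proxy.sigma,
                                      available=avail)
    e, _ = simulate_proxy(truth.spec, truth, e0, n_trials - 1, rng=rng)
    return e


def generate_dataset(
    design: DesignConfig = None,
    ground_truth: GroundTruth = None,
    rng: np.random.Generator = None,
    washout_tau: Mapping[Tuple[int, int], float] = None,
    ea_assignment: Mapping[Tuple[int, int], Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Long-format trial table for the whole synthetic experiment.

    Every subject x task x direction yields one learning curve (``n_trials``
    rows, with a fresh no-vision schedule) plus ``n_washout`` washout rows;
    48 curves per subject under the default design. No-vision rows carry the
    measurable signed error of the ground-truth process; vision rows carry
    the same generated error but are flagged, since downstream fitting uses
    no-vision rows only. Washout magnitudes decay exponentially with the
    per-coordinate time constant plus half-normal noise. The ``presentation``
    column is the randomized per-trial direction interleaving within each
    subject x task phase.
    """
    design = design or DesignConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    ground_truth = ground_truth if ground_truth is not None else default_ground_truth()
    washout_tau = washout_tau if washout_tau is not None else default_washout_tau()
    if ea_assignment is None:
        ea_assignment = assign_ea(design.n_subjects, design.n_control, design.n_tasks, rng)

    rows = []
    for s in range(1, design.n_subjects + 1):
        for t in range(1, design.n_tasks + 1):
            ea = tuple(ea_assignment[(s, t)])
            if ea not in ground_truth:
                raise KeyError(f"no ground truth for EA coordinate {ea}")
            truth = ground_truth[ea]
            # randomized direction interleave, one slot per trial per direction
            for phase, n_phase in (("learning", design.n_trials), ("washout", design.n_washout)):
                order = np.repeat(np.arange(1, design.n_directions + 1), n_phase)
                rng.shuffle(order)
                pres = {d: np.flatnonzero(order == d) for d in range(1, design.n_directions + 1)}
                if phase == "learning":
                    phase_cache = {}
                for d in range(1, design.n_directions + 1):
                    if phase == "learning":
                        mask = make_schedule(design.n_trials, design.n_novision, rng)
                        sign = -1.0 if rng.random() < 0.5 else 1.0
                        e0 = sign * rng.uniform(design.e0_low, design.e0_high)
                        sig = (design.sigma_e0_fraction * abs(e0)
                               if design.sigma_e0_fraction is not None else None)
                        errors = _simulate_curve_errors(truth, e0, design.n_trials,
                                                        mask, rng, sigma_override=sig)
                        phase_cache[d] = errors
                    else:
                        learn = phase_cache[d]
                        amp = abs(learn[-1])
                        sgn = 1.0 if learn[-1] >= 0 else -1.0
                        tau = float(washout_tau.get(ea, 5.0))
                        nmag = design.washout_noise * np.abs(rng.standard_normal(n_phase))
                        mags = amp * np.exp(-np.arange(n_phase) / tau) + nmag
                        errors = sgn * mags
                        mask = np.zeros(n_phase, dtype=bool)
                    for n in range(n_phase):
                        rows.append((
                            s, t, d, phase, n, int(pres[d][n]),
                            bool(mask[n]), ea[0], ea[1], float(errors[n]),
                        ))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df
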
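"""Exhaustive cross-validation model selection.

Candidate drift structures compete on their ability to predict held-out
learning curves. Units (subjects within an EA coordinate, or learning tasks
within a control subject) are exhaustively partitioned into 4/5 train and
1/5 test sets; the *average model* (coefficient-wise mean of the training
fits) is simulated on each test curve from that curve's own e0 and scored by
RMSE at its no-vision trials. Because RMSE distributions are non-normal,
each partition is summarized by the mode of a Gaussian kernel density
estimate over its test-curve RMSEs; models are then compared pairwise with
left-tailed Wilcoxon signed-rank tests (Bonferroni over all ordered pairs)
and ranked by model score = wins - losses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitConfig, ProxyProcessModel, ProxyProcessResults
from .simulate import CONTROL_EA
from .structures import ProxyModelParams, ProxyModelSpec, get_spec, registry

__all__ = [
    "Partition",
    "CVReport",
    "enumerate_partitions",
    "average_model",
    "kde_mode",
    "cross_validate",
    "pairwise_compare",
    "model_scores",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint train/test split of unit ids; test size = max(1, round(n/5))."""

    train: tuple
    test: tuple


def enumerate_partitions(ids: Sequence) -> List[Partition]:
    """All C(n, test_size) splits at the 4/5 : 1/5 ratio."""
    ids = tuple(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 ids to partition")
    test_size = max(1, round(n / 5))
    out = []
    for test in itertools.combinations(ids, test_size):
        train = tuple(i for i in ids if i not in test)
        out.append(Partition(train=train, test=test))
    return out


def average_model(fits: Sequence, spec: Optional[ProxyModelSpec] = None,
                  method: str = "median") -> ProxyModelParams:
    """Coefficient-wise average of fitted parameter sets.

    Accepts :class:`ProxyProcessResults` or :class:`ProxyModelParams`; all
    entries must share one structure. Sigma is averaged alongside. The
    default location estimator is the coefficient-wise median: single-curve
    least-squares estimates of these recursions are heavy-tailed (a noisy
    curve occasionally pins a coefficient near a bound), and one such fit
    can drag an arithmetic mean into a different dynamical regime entirely;
    the median is the robust reading of "the average model". ``method="mean"``
    gives the plain arithmetic mean. Both are permutation-invariant and
    coincide for one or two fits.
    """
    if len(fits) == 0:
        raise ValueError("need >= 1 fit to average")
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    params = [f.params if isinstance(f, ProxyProcessResults) else f for f in fits]
    specs = {p.spec.structure_id for p in params}
    if len(specs) != 1:
        raise ValueError(f"cannot average across structures {sorted(specs)}")
    if spec is not None and spec.structure_id not in specs:
        raise ValueError("fits do not match the requested structure")
    reduce = np.median if method == "median" else np.mean
    theta = reduce(np.array([p.theta for p in params]), axis=0)
    sigma = float(reduce(np.array([p.sigma for p in params])))
    return ProxyModelParams(params[0].spec, theta, sigma)


def kde_mode(values) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) over a dense grid.

    The grid spans the data range widened by three bandwidths, with 512
    points; degenerate inputs (single or all-equal values) return the value
    itself.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("need >= 1 value")
    if v.size == 1 or np.ptp(v) == 0.0:
        return float(v[0])
    kde = sps.gaussian_kde(v, bw_method="silverman")
    bw = kde.factor * np.std(v, ddof=1)
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, 512)
    return float(grid[np.argmax(kde(grid))])


def _rmse_on_curve(params: ProxyModelParams, model: ProxyProcessModel) -> float:
    return model.prediction_rmse(params)


def pairwise_compare(values: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Left-tailed signed-rank tests over every ordered model pair.

    ``values`` holds one column of partition-level KDE-mode RMSEs per model.
    The Bonferroni divisor is the number of ordered pairs m(m-1); entry
    (i, j) of the returned matrix is +1 when model i's RMSEs are
    significantly lower than model j's at the corrected level, -1 for the
    converse, 0 otherwise. All-tied pairs are not significant.
    """
    models = list(values.columns)
    m = len(models)
    mat = pd.DataFrame(0, index=models, columns=models, dtype=int)
    if m < 2:
        return mat
    n_tests = m * (m - 1)
    for i, j in itertools.permutations(models, 2):
        x = values[i].to_numpy(dtype=float)
        y = values[j].to_numpy(dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired value sequences must have equal length")
        d = x - y
        if np.all(d == 0):
            continue
        try:
            p = sps.wilcoxon(x, y, alternative="less", zero_method="wilcox").pvalue
        except ValueError:
            continue
        if p * n_tests < alpha:
            mat.loc[i, j] = 1
            mat.loc[j, i] = -1
    return mat


def model_scores(matrix: pd.DataFrame) -> pd.Series:
    """Wins minus losses per model from the significance matrix."""
    wins = (matrix == 1).sum(axis=1)
    losses = (matrix == -1).sum(axis=1)
    return (wins - losses).astype(int)


@dataclass
class CVReport:
    """Cross-validation outcome for a set of candidate structures."""

    partition_values: pd.DataFrame      # partitions x models: KDE-mode RMSE
    matrix: pd.DataFrame                # m x m win/loss/ns (+1/-1/0)
    scores: pd.Series
    grouping: str
    alpha: float
    skipped: List[str] = field(default_factory=list)

    @property
    def winners(self) -> List[str]:
        """Top-scoring structures; ties reported as co-winners."""
        if self.scores.empty:
            return []
        top = self.scores.max()
        return list(self.scores[self.scores == top].index)

    @property
    def n_pairs_tested(self) -> int:
        m = len(self.scores)
        return m * (m - 1)

    def summary(self) -> str:
        codes = {1: "W", -1: "L", 0: "."}
        lines = [
            f"Cross-validation ({self.grouping}): "
            f"{self.partition_values.shape[0]} partitions, "
            f"{len(self.scores)} models, {self.n_pairs_tested} ordered pairs, "
            f"alpha = {self.alpha} (Bonferroni)",
            "",
            "model    " + " ".join(f"{m:>5s}" for m in self.matrix.columns) + "  score",
        ]
        for mdl in self.matrix.index:
            row = " ".join(f"{codes[int(self.matrix.loc[mdl, c])]:>5s}" for c in self.matrix.columns)
            lines.append(f"{mdl:<8s} {row}  {int(self.scores[mdl]):+d}")
        lines.append("")
        lines.append(f"winner(s): {', '.join(self.winners) or 'none'}")
        for msg in self.skipped:
            lines.append(f"note: {msg}")
        return "\n".join(lines)


def _curve_groups(dataset: pd.DataFrame):
    learning = dataset[dataset["phase"] == "learning"]
    return learning.groupby(["subject", "task", "direction"], sort=True)


def cross_validate(
    dataset: pd.DataFrame,
    grouping: str = "subjects",
    specs: Optional[Sequence] = None,
    config: Optional[FitConfig] = None,
    alpha: float = 0.01,
) -> CVReport:
    """Exhaustive CV of candidate structures over a trial table.

    grouping="subjects": within each EA coordinate, subjects are the
    partitioned units (coordinates with < 2 subjects are skipped and
    logged). grouping="tasks": learning tasks are partitioned within each
    control subject (all-control task assignment). Partition-level values
    are pooled across coordinates/subjects before the pairwise comparison.
    """
    if grouping not in ("subjects", "tasks"):
        raise ValueError("grouping must be 'subjects' or 'tasks'")
    specs = [get_spec(s) if isinstance(s, str) else s for s in (specs or registry())]
    config = config or FitConfig()
    skipped: List[str] = []

    # fit every curve once per structure; partitions reuse these fits
    curve_models: Dict[tuple, ProxyProcessModel] = {}
    curve_meta: Dict[tuple, tuple] = {}
    for key, curve in _curve_groups(dataset):
        first = curve.loc[curve["trial"] == 0]
        ea = (int(first["ea_gain"].iloc[0]), int(first["ea_offset"].iloc[0]))
        curve_meta[key] = ea
        curve_models[key] = curve

    fits: Dict[tuple, ProxyProcessResults] = {}
    built: Dict[tuple, Dict[str, ProxyProcessModel]] = {}

    def model_for(key, spec):
        d = built.setdefault(key, {})
        if spec.structure_id not in d:
            d[spec.structure_id] = ProxyProcessModel.from_curve(curve_models[key], spec)
        return d[spec.structure_id]

    def fit_for(key, spec):
        fk = (key, spec.structure_id)
        if fk not in fits:
            fits[fk] = model_for(key, spec).fit(config)
        return fits[fk]

    # build the unit layout
    blocks = []  # list of (label, unit_ids, curves_by_unit)
    if grouping == "subjects":
        by_ea: Dict[tuple, Dict[int, list]] = {}
        for key, ea in curve_meta.items():
            by_ea.setdefault(ea, {}).setdefault(key[0], []).append(key)
        for ea in sorted(by_ea):
            units = by_ea[ea]
            if len(units) < 2:
                skipped.append(f"EA{{gain {ea[0]}, offset {ea[1]}}}: "
                               f"{len(units)} subject(s), skipped")
                continue
            blocks.append((f"EA{ea[0]}{ea[1]}", sorted(units), units))
    else:
        by_subject: Dict[int, Dict[int, list]] = {}
        for key, ea in curve_meta.items():
            if ea == CONTROL_EA:
                by_subject.setdefault(key[0], {}).setdefault(key[1], []).append(key)
        for s in sorted(by_subject):
            tasks = by_subject[s]
            # only subjects with the control coordinate on every task qualify
            n_tasks_total = dataset[dataset["subject"] == s]["task"].nunique()
            if len(tasks) < 2 or len(tasks) != n_tasks_total:
                skipped.append(f"subject {s}: not a full control subject, skipped")
                continue
            blocks.append((f"S{s}", sorted(tasks), tasks))

    rows = []
    index = []
    for label, unit_ids, curves_by_unit in blocks:
        for pi, part in enumerate(enumerate_partitions(unit_ids)):
            row = {}
            for spec in specs:
                train_fits = [
                    fit_for(key, spec)
                    for u in part.train
                    for key in curves_by_unit[u]
                ]
                avg = average_model(train_fits)
                test_rmses = [
                    _rmse_on_curve(avg, model_for(key, spec))
                    for u in part.test
                    for key in curves_by_unit[u]
                ]
                row[spec.structure_id] = kde_mode(test_rmses)
            rows.append(row)
            index.append(f"{label}:p{pi}")

    values = pd.DataFrame(rows, index=index,
                          columns=[s.structure_id for s in specs])
    if values.empty:
        matrix = pd.DataFrame(0, index=values.columns, columns=values.columns, dtype=int)
    else:
        matrix = pairwise_compare(values, alpha=alpha)
    scores = model_scores(matrix)
    return CVReport(partition_values=values, matrix=matrix, scores=scores,
                    grouping=grouping, alpha=alpha, skipped=skipped)
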
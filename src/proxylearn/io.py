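"""Trial-table and configuration I/O.

The interchange format is comma-delimited text with a versioned comment
header; no binary formats. Configurations are YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .simulate import EA_GRID, DesignConfig, TRIAL_COLUMNS

__all__ = [
    "TRIAL_TABLE_HEADER",
    "TrialTableError",
    "write_trial_table",
    "read_trial_table",
    "PipelineConfig",
]

TRIAL_TABLE_HEADER = "# proxylearn trial table v1"

_VALID_PHASES = {"learning", "washout"}


class TrialTableError(ValueError):
    """Schema violation in a trial table, with file line numbers."""


def write_trial_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"cannot write table, missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(TRIAL_TABLE_HEADER + "\n")
        df.to_csv(fh, index=False, columns=TRIAL_COLUMNS, lineterminator="\n")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table; row order is preserved.

    Raises :class:`TrialTableError` naming the offending file line for
    missing columns, non-numeric errors, off-grid EA values or unknown
    phases. An empty table with a valid header is fine.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(path, skiprows=skip)
    line0 = skip + 2  # 1-based line number of the first data row
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    if df.empty:
        return df[TRIAL_COLUMNS]

    err = pd.to_numeric(df["error"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(err.to_numpy(dtype=float)))
    if bad.size:
        raise TrialTableError(
            f"{path}: non-numeric or non-finite error value at line {bad[0] + line0}"
        )
    df["error"] = err
    grid = set(EA_GRID)
    pairs = list(zip(df["ea_gain"].astype(int), df["ea_offset"].astype(int)))
    for i, pair in enumerate(pairs):
        if pair not in grid:
            raise TrialTableError(
                f"{path}: EA coordinate {pair} off the grid at line {i + line0}"
            )
    bad_phase = ~df["phase"].isin(_VALID_PHASES)
    if bad_phase.any():
        i = int(np.flatnonzero(bad_phase.to_numpy())[0])
        raise TrialTableError(
            f"{path}: unknown phase {df['phase'].iloc[i]!r} at line {i + line0}"
        )
    df["no_vision"] = df["no_vision"].astype(bool)
    for c in ("subject", "task", "direction", "trial", "presentation",
              "ea_gain", "ea_offset"):
        df[c] = df[c].astype(int)
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# pipeline configuration


def _coord_key(coord) -> str:
    return f"{int(coord[0])},{int(coord[1])}"


def _parse_coord(key: str) -> Tuple[int, int]:
    g, o = key.split(",")
    return int(g), int(o)


@dataclass
class PipelineConfig:
    """All knobs for a full pipeline run.

    ``ground_truth`` and ``washout_tau`` optionally override the built-in
    generator defaults, keyed by "gain,offset" strings; fit/CV/stats
    settings are scaled down in the ``test_scale`` profile used by the test
    suite.
    """

    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int = 0
    outdir: str = "runs/default"
    n_starts: int = 50
    cv_specs: Optional[list] = None          # None = all 11 structures
    cv_alpha: float = 0.01
    stats_alpha: float = 0.05
    bootstrap_B: int = 100_000
    sigma_null: float = 1.0
    ground_truth: Optional[Dict[str, dict]] = None
    washout_tau: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed must be set")
        if self.n_starts < 1 or self.bootstrap_B < 1:
            raise ValueError("n_starts and bootstrap_B must be positive")
        grid = set(EA_GRID)
        for mapping in (self.ground_truth, self.washout_tau):
            if mapping:
                for key in mapping:
                    if _parse_coord(key) not in grid:
                        raise ValueError(f"EA coordinate {key!r} outside the grid")

    @classmethod
    def test_scale(cls, outdir: str = "runs/test", seed: int = 0) -> "PipelineConfig":
        """Small profile: short curves, few units, reduced optimizer effort."""
        design = DesignConfig(n_subjects=4, n_control=2, n_tasks=2,
                              n_directions=3, n_trials=60, n_novision=18,
                              n_washout=15)
        return cls(design=design, seed=seed, outdir=outdir, n_starts=6,
                   cv_specs=["1.1L", "1.1", "2.1", "3.1"], bootstrap_B=2000)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = DesignConfig(**d["design"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def resolved_ground_truth(self):
        from .simulate import default_ground_truth
        from .structures import ProxyModelParams

        gt = default_ground_truth()
        if self.ground_truth:
            for key, coeffs in self.ground_truth.items():
                coeffs = dict(coeffs)
                structure = coeffs.pop("structure", "2.1")
                gt[_parse_coord(key)] = ProxyModelParams.from_dict(structure, **coeffs)
        return gt

    def resolved_washout_tau(self):
        from .simulate import default_washout_tau

        tau = default_washout_tau()
        if self.washout_tau:
            for key, value in self.washout_tau.items():
                tau[_parse_coord(key)] = float(value)
        return tau
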
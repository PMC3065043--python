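"""Synthetic tumor-volume datasets with known ground truth.

Generates per-arm (day, volume) measurements the way a caliper study would
record them: daily sampling from treatment start (day 8) to the horizon
(day 17), one tumor per replicate (its own vessel-mosaic seed), and
multiplicative lognormal observation noise (volumes are positive and their
errors grow with size).  The generating parameters are stored with the
data, so calibration can be validated end-to-end by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ModelParameters
from .simulator import Grid, run_arm

__all__ = [
    "SyntheticDataset",
    "generate",
    "write_dataset_csv",
    "read_dataset_csv",
    "DEFAULT_DAYS",
]

DEFAULT_DAYS = tuple(range(8, 18))
_COLUMNS = ("arm", "day", "volume_mm3", "replicate")

#: Seeds handed to numpy must stay below 2**31.
_SEED_MOD = 2**31 - 1


@dataclass
class SyntheticDataset:
    """Observations plus the truth that generated them."""

    data: pd.DataFrame  # columns: arm, day, volume_mm3, replicate
    truth: ModelParameters
    noise_rel: float
    seed: int
    arms: tuple[str, ...]

    def for_arm(self, arm: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == arm].reset_index(drop=True)


def generate(truth: ModelParameters, arms=("V", "L_C", "NC_D"), *,
             noise_rel: float = 0.05, n_replicates: int = 5, seed: int = 0,
             days=DEFAULT_DAYS, grid_kwargs: dict | None = None,
             run_kwargs: dict | None = None,
             vary_initial_condition: bool = True) -> SyntheticDataset:
    """Simulate each arm and sample noisy volumes at the listed days.

    Observations are ``model_volume(day) * exp(eps)`` with
    ``eps ~ Normal(0, noise_rel^2)`` i.i.d.  Replicates differ by the
    initial vessel-mosaic seed and the noise draw; with
    ``vary_initial_condition=False`` all replicates share one tumor and
    differ by observation noise only (useful to isolate the noise model).
    Fully reproducible from ``seed``.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    grid_kwargs = grid_kwargs or {}
    run_kwargs = run_kwargs or {}
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    rows = []
    for arm in arms:
        base_curve = None
        for rep in range(n_replicates):
            ic_seed = int(rng.integers(_SEED_MOD))
            noise = rng.normal(0.0, noise_rel, size=days.size) if noise_rel > 0 else np.zeros(days.size)
            if vary_initial_condition or base_curve is None:
                grid = Grid.for_params(truth, **grid_kwargs)
                base_curve = run_arm(arm, truth, grid, seed=ic_seed, **run_kwargs)
            vols = np.asarray(base_curve.at_day(days)) * np.exp(noise)
            rows.append(pd.DataFrame({
                "arm": arm, "day": days, "volume_mm3": vols, "replicate": rep,
            }))
    data = pd.concat(rows, ignore_index=True)
    return SyntheticDataset(data=data, truth=truth, noise_rel=noise_rel,
                            seed=seed, arms=tuple(arms))


def write_dataset_csv(data: pd.DataFrame | SyntheticDataset, path: str | Path) -> None:
    """Write observations in the calibration input schema."""
    df = data.data if isinstance(data, SyntheticDataset) else data
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    df.loc[:, list(_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV, validating schema and numeric values.

    Raises a ValueError naming any missing column, or citing the 1-based
    file line of the first malformed (non-numeric) row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("day", "volume_mm3", "replicate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    df["replicate"] = df["replicate"].astype(int)
    return df.loc[:, list(_COLUMNS)]
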
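"""Parameter fitting to volume curves and the single-parameter sensitivity scan.

The fitting strategy mirrors the study design: free parameters are adjusted
against the control and the two single-agent arms only (V, L[C], NC[D]);
the combined arms are then pure model predictions.  The loss is a sum of
squared volume residuals, averaged over a fixed set of initial-condition
seeds (common random numbers) so the objective is deterministic, and the
optimizer is derivative-free (Nelder--Mead with box bounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import ModelParameters
from .pharmacokinetics import AdministrationSchedule
from .simulator import Grid, VolumeCurve, run_arm

__all__ = [
    "FitSpec",
    "FitResult",
    "curve_loss",
    "fit",
    "sensitivity_scan",
    "TABLE_PARAMETERS",
]

logger = logging.getLogger("nanocell.calibration")

#: Parameters of the default sensitivity scan: the dimensionless table of
#: model coefficients plus the therapy strengths and the tumor diffusivity.
TABLE_PARAMETERS = (
    "alpha1_t", "D2_t", "alpha_t", "beta_t", "gamma_t", "alpha2_t",
    "delta_t", "m_lim", "D3_t", "lambdaC_t", "nuC_t", "nuD_t", "mu_t",
    "AC_t", "AD_t", "D1",
)

_FIT_ARMS = ("V", "L_C", "NC_D")


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters with bounds, arms, loss, seeds."""

    free_params: dict[str, tuple[float, float]]
    arms_used: tuple[str, ...] = _FIT_ARMS
    loss: str = "sse"  # or "sse_log"
    seeds: tuple[int, ...] = (0, 1, 2)
    start: dict[str, float] | None = None
    optimizer_options: dict = field(default_factory=dict)
    allow_combined_arms: bool = False
    #: for single-parameter fits: number of coarse pre-scan points across the
    #: bounds used to seed the simplex (guards against plateau slides when
    #: the volume response saturates in the parameter)
    prescan: int = 0

    def __post_init__(self) -> None:
        if not self.free_params:
            raise ValueError("free_params must be non-empty")
        if self.loss not in ("sse", "sse_log"):
            raise ValueError("loss must be 'sse' or 'sse_log'")
        if not self.allow_combined_arms:
            bad = set(self.arms_used) - set(_FIT_ARMS)
            if bad:
                raise ValueError(
                    f"arms {sorted(bad)} are combined-therapy arms; the study-faithful "
                    "fit uses V, L_C, NC_D only (set allow_combined_arms=True to override)")


@dataclass
class FitResult:
    """Point estimates plus everything needed to reproduce the fit."""

    estimates: dict[str, float]
    loss_value: float
    residuals: dict[str, np.ndarray]
    converged: bool
    seeds: tuple[int, ...]
    n_evaluations: int
    message: str = ""


def _simulate_arm_volumes(arm: str, params: ModelParameters, days: np.ndarray,
                          seed: int, grid_kwargs: dict, run_kwargs: dict) -> np.ndarray:
    grid = Grid.for_params(params, **grid_kwargs)
    curve = run_arm(arm, params, grid, seed=seed, **run_kwargs)
    return np.asarray(curve.at_day(days), dtype=float)


def curve_loss(params: ModelParameters, datasets: pd.DataFrame,
               seeds: Sequence[int] = (0,), *, loss: str = "sse",
               grid_kwargs: dict | None = None,
               run_kwargs: dict | None = None) -> float:
    """Mean over seeds of the summed squared volume residuals.

    ``datasets`` is tidy observed data with columns (arm, day, volume_mm3);
    model volumes are linearly interpolated at the observed days.  A failed
    simulation yields an infinite loss (with a log diagnostic) rather than
    an exception, so an optimizer can route around a bad parameter vector.
    """
    if datasets.empty:
        raise ValueError("datasets must be non-empty")
    grid_kwargs = grid_kwargs or {}
    run_kwargs = run_kwargs or {}
    total = 0.0
    for seed in seeds:
        for arm, obs in datasets.groupby("arm", sort=True):
            days = obs["day"].to_numpy(dtype=float)
            vols = obs["volume_mm3"].to_numpy(dtype=float)
            try:
                model = _simulate_arm_volumes(str(arm), params, days, int(seed),
                                              grid_kwargs, run_kwargs)
            except (RuntimeError, ValueError) as exc:
                logger.warning("simulation failed for arm %s (seed %d): %s", arm, seed, exc)
                return float("inf")
            if loss == "sse_log":
                r = np.log(np.maximum(model, 1e-9)) - np.log(np.maximum(vols, 1e-9))
            else:
                r = model - vols
            total += float(np.sum(r * r))
    return total / len(seeds)


def fit(spec: FitSpec, datasets: pd.DataFrame, base_params: ModelParameters,
        *, grid_kwargs: dict | None = None,
        run_kwargs: dict | None = None) -> FitResult:
    """Derivative-free minimization of the curve loss over the free parameters.

    Starts from ``spec.start`` (default: the values in ``base_params``) and
    is deterministic given the seed set.  Non-convergence is flagged on the
    result, not raised.
    """
    names = list(spec.free_params)
    bounds = [spec.free_params[k] for k in names]
    start = spec.start or {}
    x0 = np.array([start.get(k, getattr(base_params, k)) for k in names])
    arms = set(datasets["arm"].unique())
    missing = set(spec.arms_used) - arms
    if missing:
        raise ValueError(f"datasets lack observations for arms {sorted(missing)}")
    data = datasets[datasets["arm"].isin(spec.arms_used)]
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = base_params.replace(**{k: float(v) for k, v in zip(names, x)})
        return curve_loss(p, data, spec.seeds, loss=spec.loss,
                          grid_kwargs=grid_kwargs, run_kwargs=run_kwargs)

    if spec.prescan > 1 and len(names) == 1:
        lo, hi = bounds[0]
        grid = np.linspace(lo, hi, spec.prescan)
        losses = [objective(np.array([g])) for g in grid]
        x0 = np.array([grid[int(np.argmin(losses))]])
    options = {"xatol": 1e-3, "fatol": 1e-6, "maxfev": 400}
    options.update(spec.optimizer_options)
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            bounds=bounds, options=options)
    estimates = {k: float(v) for k, v in zip(names, res.x)}
    fitted = base_params.replace(**estimates)
    residuals: dict[str, np.ndarray] = {}
    for arm, obs in data.groupby("arm", sort=True):
        days = obs["day"].to_numpy(dtype=float)
        vols = obs["volume_mm3"].to_numpy(dtype=float)
        model = _simulate_arm_volumes(str(arm), fitted, days, int(spec.seeds[0]),
                                      grid_kwargs or {}, run_kwargs or {})
        residuals[str(arm)] = model - vols
    return FitResult(
        estimates=estimates,
        loss_value=float(res.fun),
        residuals=residuals,
        converged=bool(res.success),
        seeds=tuple(spec.seeds),
        n_evaluations=n_eval,
        message=str(res.message),
    )


def fit_sequential(stages: Sequence[FitSpec], datasets: pd.DataFrame,
                   base_params: ModelParameters, *,
                   grid_kwargs: dict | None = None,
                   run_kwargs: dict | None = None) -> FitResult:
    """Staged fitting, mirroring the study's strategy: growth parameters are
    estimated from the control arm first, then each agent strength from its
    single-agent arm, each stage conditioning on the previous estimates.

    Returns a combined result with the merged estimates; convergence is the
    conjunction of the stages.
    """
    params = base_params
    estimates: dict[str, float] = {}
    residuals: dict[str, np.ndarray] = {}
    n_eval = 0
    converged = True
    messages = []
    last = None
    for stage in stages:
        last = fit(stage, datasets, params, grid_kwargs=grid_kwargs, run_kwargs=run_kwargs)
        estimates.update(last.estimates)
        residuals.update(last.residuals)
        n_eval += last.n_evaluations
        converged = converged and last.converged
        messages.append(last.message)
        params = params.replace(**last.estimates)
    if last is None:
        raise ValueError("stages must be non-empty")
    return FitResult(
        estimates=estimates,
        loss_value=last.loss_value,
        residuals=residuals,
        converged=converged,
        seeds=last.seeds,
        n_evaluations=n_eval,
        message=" | ".join(messages),
    )


def sensitivity_scan(params: ModelParameters, arms: Sequence[str] = ("L_CD", "NC_CD"),
                     *, rel_change: float = 0.05, seed: int = 0,
                     param_names: Sequence[str] = TABLE_PARAMETERS,
                     grid_kwargs: dict | None = None,
                     run_kwargs: dict | None = None,
                     read_day: float = 17.0) -> pd.DataFrame:
    """Single-parameter perturbation scan: each parameter x (1 + rel_change).

    Reruns every arm at a matched seed with one parameter perturbed at a
    time and reports the relative change of the day-``read_day`` volume.
    The two free-drug diffusivities are tied (the model sets D3 = D4), so
    perturbing ``D3_t`` perturbs both.  A failed run is recorded in the
    ``status`` column and the scan continues.  The baseline row (parameter
    "baseline", factor 1) is included.
    """
    grid_kwargs = grid_kwargs or {}
    run_kwargs = dict(run_kwargs or {})
    run_kwargs.setdefault("t_end_day", read_day)

    def day_volume(p: ModelParameters, arm: str) -> float:
        grid = Grid.for_params(p, **grid_kwargs)
        curve = run_arm(arm, p, grid, seed=seed, **run_kwargs)
        return float(curve.at_day(read_day))

    rows = []
    baseline: dict[str, float] = {}
    for arm in arms:
        v = day_volume(params, arm)
        baseline[arm] = v
        rows.append({"parameter": "baseline", "arm": arm, "factor": 1.0,
                     "volume_mm3": v, "rel_change": 0.0, "status": "ok"})
    factor = 1.0 + rel_change
    for name in param_names:
        changes = {name: getattr(params, name) * factor}
        if name == "D3_t":
            changes["D4_t"] = params.D4_t * factor
        perturbed = params.replace(**changes)
        for arm in arms:
            try:
                v = day_volume(perturbed, arm)
                rel = (v - baseline[arm]) / baseline[arm] if baseline[arm] > 0 else np.nan
                rows.append({"parameter": name, "arm": arm, "factor": factor,
                             "volume_mm3": v, "rel_change": rel, "status": "ok"})
            except (RuntimeError, ValueError) as exc:
                logger.warning("sensitivity run failed (%s, %s): %s", name, arm, exc)
                rows.append({"parameter": name, "arm": arm, "factor": factor,
                             "volume_mm3": np.nan, "rel_change": np.nan,
                             "status": f"failed: {exc}"})
    return pd.DataFrame(rows)
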
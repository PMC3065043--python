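"""Carrier uptake, release profiles, and free-drug dynamics.

Liposomes/nanocells administered at times ``t_i`` build up tissue carrier
fields ``C_i(x,t)`` through vessel-efficiency-limited extravasation, while
their blood concentration ``Gamma_i(t)`` decays exponentially.  Each carrier
then releases free agent according to a truncated gamma-family kernel

    RP_i(t) = (1/N) * theta(t - t_i) (t - t_i)^p exp(-(t - t_i)/tau),

with a single normalization constant ``N`` per treatment chosen so that the
total release over all administrations up to the horizon ``t_f`` integrates
to one.  All kernels are defined and normalized on the day axis; the
simulator samples them at (converted) simulation times.  Free agents obey

    dc/dt = D3 lap(c) + lambda_C R_C - nu_C c
    dd/dt = D4 lap(d) + lambda_D R_D - mu m d - nu_D d

where the ``mu m d`` term is the reabsorption of free chemotherapy into the
blood vessels -- the term whose suppression by antiangiogenic vascular
collapse ("trapping") drives the synergy of the sequential-release design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .model_core import DeliveryForm, ModelParameters, delivery_efficiency

__all__ = [
    "AdministrationSchedule",
    "ReleaseProfile",
    "DrugFields",
    "gamma_kernel",
    "normalization_constant",
    "single_window_normalization",
    "vessel_concentration",
    "uptake_rate",
    "release_rate",
    "rhs_c",
    "rhs_d",
    "profile_table",
]


@dataclass(frozen=True)
class AdministrationSchedule:
    """Dose times and horizon, in days."""

    dose_times: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 16.0)
    horizon: float = 17.0

    def __post_init__(self) -> None:
        if len(self.dose_times) == 0:
            raise ValueError("schedule must contain at least one dose")
        object.__setattr__(self, "dose_times", tuple(float(t) for t in self.dose_times))
        if any(b <= a for a, b in zip(self.dose_times, self.dose_times[1:])):
            raise ValueError("dose_times must be strictly increasing")
        if self.dose_times[-1] >= self.horizon:
            raise ValueError("all dose_times must precede the horizon")

    def to_dict(self) -> dict:
        return {"dose_times": list(self.dose_times), "horizon": self.horizon}

    @classmethod
    def from_dict(cls, d: dict) -> "AdministrationSchedule":
        return cls(tuple(d["dose_times"]), float(d["horizon"]))


def gamma_kernel(t, t_i: float, p: float, tau: float):
    """Un-normalized release kernel ``theta(s) s^p exp(-s/tau)``, s = t - t_i.

    Right-continuous step: the kernel is zero for t < t_i and switches on at
    t = t_i (where it vanishes anyway for p > 0).  Its maximum sits at
    ``t_i + p tau``.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    s = t - t_i
    with np.errstate(invalid="ignore"):
        out = np.where(s >= 0, np.power(np.maximum(s, 0.0), p) * np.exp(-np.maximum(s, 0.0) / tau), 0.0)
    return out if out.ndim else float(out)


def single_window_normalization(p: float, tau: float, window: float | None = None) -> float:
    """Closed-form integral of one kernel window.

    ``integral_0^L s^p exp(-s/tau) ds = tau^(p+1) Gamma(p+1) P(p+1, L/tau)``
    with P the regularized lower incomplete gamma function; the untruncated
    limit (window=None) is ``tau^(p+1) Gamma(p+1)``.
    """
    full = tau ** (p + 1.0) * special.gamma(p + 1.0)
    if window is None:
        return full
    return full * float(special.gammainc(p + 1.0, window / tau))


def normalization_constant(schedule: AdministrationSchedule, p: float, tau: float,
                           *, rtol: float = 1e-10) -> float:
    """Treatment-level normalization ``N = sum_i int_0^tf kernel_i dt``.

    Computed by adaptive quadrature per administration window (the window
    split at each ``t_i`` sidesteps the integrable slope singularity of the
    kernel for p < 1).  Dividing each kernel by N makes the summed release
    integrate to one over the horizon.
    """
    total = 0.0
    for t_i in schedule.dose_times:
        val, _ = integrate.quad(
            lambda s: s**p * np.exp(-s / tau), 0.0, schedule.horizon - t_i,
            epsrel=rtol, epsabs=0.0, limit=200,
        )
        total += val
    if total <= 0:
        raise ValueError("normalization integral is not positive")
    return total


@dataclass(frozen=True)
class ReleaseProfile:
    """Normalized release kernel parameters for one agent in one treatment."""

    p: float
    tau: float  # days
    N: float | None = None  # days^(p+1); filled by normalize()
    label: str = ""

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.N is not None and self.N <= 0:
            raise ValueError("N must be > 0 once normalized")

    def normalize(self, schedule: AdministrationSchedule) -> "ReleaseProfile":
        return dataclasses.replace(self, N=normalization_constant(schedule, self.p, self.tau))

    def __call__(self, t, t_i: float):
        """Normalized profile RP_i(t), 1/day.  Requires a prior normalize()."""
        if self.N is None:
            raise ValueError(f"profile {self.label!r} is not normalized; call normalize(schedule)")
        k = gamma_kernel(t, t_i, self.p, self.tau)
        return k / self.N

    def to_dict(self) -> dict:
        return {"p": self.p, "tau": self.tau, "N": self.N, "label": self.label}


@dataclass
class DrugFields:
    """Per-administration carrier fields plus the two free-agent fields."""

    carriers: list[np.ndarray] = field(default_factory=list)
    carrier_times: list[float] = field(default_factory=list)  # dose days
    c: np.ndarray | None = None  # free antiangiogenic agent
    d: np.ndarray | None = None  # free chemotherapeutic agent

    def add_administration(self, shape: tuple[int, ...], t_i: float) -> None:
        """Register a dose: a fresh zero carrier field tagged with its day."""
        self.carriers.append(np.zeros(shape))
        self.carrier_times.append(float(t_i))
        if self.c is None:
            self.c = np.zeros(shape)
            self.d = np.zeros(shape)


def vessel_concentration(t, t_i: float, tau_D: float):
    """Blood-borne carrier concentration ``Gamma_i(t)``: unit bolus at t_i
    followed by exponential decay with time constant tau_D (days)."""
    if tau_D <= 0:
        raise ValueError("tau_D must be > 0")
    t = np.asarray(t, dtype=float)
    s = t - t_i
    out = np.where(s >= 0, np.exp(-np.maximum(s, 0.0) / tau_D), 0.0)
    return out if out.ndim else float(out)


def uptake_rate(m, gamma_val: float, params: ModelParameters,
                form: DeliveryForm = "as_printed"):
    """Carrier extravasation rate ``delta Gamma_i(t) m exp(-(m/m_lim)^2)``.

    Vanishes where m = 0 (no vessels, no delivery) and decays for dense
    abnormal vasculature, so an antiangiogenic push of m toward the kernel
    maximum transiently improves delivery (normalization window).
    """
    return params.delta_t * gamma_val * delivery_efficiency(m, params.m_lim, form)


def release_rate(t_day: float, carriers: DrugFields, profile: ReleaseProfile | None,
                 schedule: AdministrationSchedule):
    """Tissue release field ``R(x,t) = sum_i RP_i(t) C_i(x,t)`` for one agent.

    An absent profile (agent not carried by this treatment) contributes
    exactly zero.  Carrier fields must correspond to past administrations.
    """
    if profile is None:
        return 0.0
    if len(carriers.carriers) != len(carriers.carrier_times):
        raise ValueError("carrier fields and administration times are out of sync")
    if len(carriers.carriers) > len(schedule.dose_times):
        raise ValueError("more carrier fields than scheduled administrations")
    out: np.ndarray | float = 0.0
    for C_i, t_i in zip(carriers.carriers, carriers.carrier_times):
        rp = profile(t_day, t_i)
        if rp != 0.0:
            out = out + rp * C_i
    return out


def rhs_c(c, R_C, params: ModelParameters):
    """Reaction part of the free antiangiogenic agent: source minus decay.

    No vessel-reabsorption term: the agent acts on (and is not cleared
    preferentially through) both normal and abnormal vessels.
    """
    return params.lambdaC_t * np.asarray(R_C, dtype=float) - params.nuC_t * np.asarray(c, dtype=float)


def rhs_d(d, R_D, m, params: ModelParameters):
    """Reaction part of the free chemotherapeutic agent.

    Source ``lambda_D R_D`` minus vessel reabsorption ``mu m d`` minus
    natural decay ``nu_D d``.  The reabsorption term vanishes where m = 0:
    collapsed vasculature traps the drug in the tissue.
    """
    d = np.asarray(d, dtype=float)
    return (params.lambdaD_t * np.asarray(R_D, dtype=float)
            - params.mu_t * np.asarray(m, dtype=float) * d
            - params.nuD_t * d)


def profile_table(profiles: dict[str, ReleaseProfile], schedule: AdministrationSchedule,
                  *, t_grid=None, tau_D: float | None = None):
    """Sampled release/vessel curves as a tidy DataFrame (day, value, agent, arm).

    ``profiles`` maps "arm/agent" labels to normalized profiles; when
    ``tau_D`` is given, per-arm blood-concentration curves Gamma(t) summed
    over doses are appended under agent "Gamma".
    """
    import pandas as pd

    if t_grid is None:
        t_grid = np.arange(0.0, schedule.horizon + 1e-9, 0.1)
    rows = []
    for key, prof in profiles.items():
        arm, _, agent = key.partition("/")
        total = np.zeros_like(t_grid)
        for t_i in schedule.dose_times:
            total += prof(t_grid, t_i)
        rows.append(pd.DataFrame({"day": t_grid, "value": total,
                                  "agent": agent or "RP", "arm": arm}))
    if tau_D is not None:
        gam = np.zeros_like(t_grid)
        for t_i in schedule.dose_times:
            gam += vessel_concentration(t_grid, t_i, tau_D)
        rows.append(pd.DataFrame({"day": t_grid, "value": gam,
                                  "agent": "Gamma", "arm": "all"}))
    return pd.concat(rows, ignore_index=True)
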
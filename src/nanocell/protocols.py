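"""Treatment arms, release-profile sharing rules, and unit conversions.

The six arms mirror the mouse experiment groups: untreated control (V),
doxorubicin-only nanocells (NC[D], j=1), combretastatin-only liposomes
(L[C], j=2), a liposome co-encapsulating both agents (L[CD], j=3), the
nanocell proper (NC[CD], j=4), and a delayed-release nanocell variant
(NC[CD]_mod, j=4 with a larger release exponent).  Profile sharing encodes
the carrier physics: everything wrapped in a liposome releases with the
liposome kernel, every nanocell core releases with the core kernel, and the
normalization guarantees each active agent delivers the same total dose in
every arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pharmacokinetics import AdministrationSchedule, ReleaseProfile

__all__ = [
    "ARM_NAMES",
    "KineticsDefaults",
    "TreatmentSpec",
    "UnitSystem",
    "build_arm",
    "days_to_dimensionless",
    "dimensionless_to_days",
]

ARM_NAMES = ("V", "NC_D", "L_C", "L_CD", "NC_CD", "NC_CD_mod")

#: Arm index j used in the governing equations (V carries no index).
_ARM_INDEX = {"NC_D": 1, "L_C": 2, "L_CD": 3, "NC_CD": 4, "NC_CD_mod": 4}


@dataclass(frozen=True)
class KineticsDefaults:
    """Release-kernel parameters: nanocell core (slow) and liposome (fast).

    ``tau_D`` is the blood clearance time of the carriers, taken equal to
    the core release time.  ``p_NC_mod`` is the delayed-release exponent of
    the modified nanocell.
    """

    p_NC: float = 0.3
    tau_NC: float = 15.0  # days
    p_L: float = 0.1
    tau_L: float = 2.0    # days
    p_NC_mod: float = 0.8
    tau_D: float = 15.0   # days; = tau_NC

    def nanocell_core(self, schedule: AdministrationSchedule, *, modified: bool = False) -> ReleaseProfile:
        p = self.p_NC_mod if modified else self.p_NC
        label = "NC_core_mod" if modified else "NC_core"
        return ReleaseProfile(p=p, tau=self.tau_NC, label=label).normalize(schedule)

    def liposome(self, schedule: AdministrationSchedule) -> ReleaseProfile:
        return ReleaseProfile(p=self.p_L, tau=self.tau_L, label="liposome").normalize(schedule)


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment arm: which agents are active and how each is released."""

    name: str
    j: int | None  # arm index 1-4; None for the untreated control
    modified: bool
    chemo_active: bool
    anti_active: bool
    profile_C: ReleaseProfile | None  # antiangiogenic agent; None = absent
    profile_D: ReleaseProfile | None  # chemotherapeutic agent; None = absent

    def __post_init__(self) -> None:
        if self.chemo_active != (self.profile_D is not None):
            raise ValueError(f"{self.name}: chemo_active inconsistent with profile_D")
        if self.anti_active != (self.profile_C is not None):
            raise ValueError(f"{self.name}: anti_active inconsistent with profile_C")

    @property
    def treated(self) -> bool:
        return self.chemo_active or self.anti_active

    def to_manifest(self) -> dict:
        return {
            "name": self.name,
            "j": self.j,
            "modified": self.modified,
            "chemo_active": self.chemo_active,
            "anti_active": self.anti_active,
            "profile_C": self.profile_C.to_dict() if self.profile_C else None,
            "profile_D": self.profile_D.to_dict() if self.profile_D else None,
        }


def build_arm(name: str, kinetics: KineticsDefaults | None = None,
              schedule: AdministrationSchedule | None = None) -> TreatmentSpec:
    """Construct a treatment arm with its profile-sharing rules resolved.

    * NC_D: chemo only, released by the nanocell core kernel.
    * L_C: antiangiogenic only, released by the liposome kernel.
    * L_CD: both agents share the liposome kernel.
    * NC_CD: antiangiogenic from the lipid envelope (liposome kernel),
      chemo from the core (slow kernel) -- the sequential-release design.
    * NC_CD_mod: NC_CD with the delayed core exponent, renormalized so the
      total released amount is unchanged.
    """
    if name not in ARM_NAMES:
        raise ValueError(f"unknown arm {name!r}; expected one of {ARM_NAMES}")
    kinetics = kinetics or KineticsDefaults()
    schedule = schedule or AdministrationSchedule()
    if name == "V":
        return TreatmentSpec(name, None, False, False, False, None, None)
    modified = name == "NC_CD_mod"
    lip = kinetics.liposome(schedule)
    core = kinetics.nanocell_core(schedule, modified=modified)
    if name == "NC_D":
        return TreatmentSpec(name, 1, False, True, False, None, core)
    if name == "L_C":
        return TreatmentSpec(name, 2, False, False, True, lip, None)
    if name == "L_CD":
        return TreatmentSpec(name, 3, False, True, True, lip, lip)
    # NC_CD / NC_CD_mod
    return TreatmentSpec(name, 4, modified, True, True, lip, core)


@dataclass(frozen=True)
class UnitSystem:
    """Conversions between dimensionful (mm, day) and dimensionless units.

    Time scales by the proliferation rate (t_dimless = rho * t_days) and
    length by the Fisher length sqrt(D1/rho).
    """

    rho: float  # 1/day
    D1: float   # mm^2/day

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.D1 <= 0:
            raise ValueError("rho and D1 must be > 0")

    @property
    def length_scale(self) -> float:
        """mm per dimensionless length unit."""
        return math.sqrt(self.D1 / self.rho)

    @property
    def time_scale(self) -> float:
        """days per dimensionless time unit."""
        return 1.0 / self.rho

    def days_to_dimensionless(self, t_days):
        return self.rho * t_days

    def dimensionless_to_days(self, t_tilde):
        return t_tilde / self.rho

    def mm_to_dimensionless(self, x_mm):
        return x_mm / self.length_scale

    def dimensionless_to_mm(self, x_tilde):
        return x_tilde * self.length_scale


def days_to_dimensionless(t_days, units: UnitSystem):
    return units.days_to_dimensionless(t_days)


def dimensionless_to_days(t_tilde, units: UnitSystem):
    return units.dimensionless_to_days(t_tilde)
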
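"""Reaction terms and fixed-point analysis of the tumor--vasculature system.

The model couples a Fisher--KPP equation for the tumor-cell density ``n(x,t)``
to a bistable cubic equation for the blood-vessel density ``m(x,t)``, both in
dimensionless form (time rescaled by the proliferation rate ``rho``, space by
``sqrt(D1/rho)``, density by the carrying capacity)::

    dn/dt = lap(n) + n (1 - n) + alpha1 m n          [- A_D d n  under chemo]
    dm/dt = D2 lap(m) + m (alpha + beta m + gamma m^2) + alpha2 n m
                                                     [- A_C c m  under anti]

With the cubic coefficients at their default values (-1, 3, -2) the uncoupled
vessel dynamics is bistable with stable states m = 0 (avascular) and m = 1
(normal vasculature) separated by an unstable state at m = 1/2.  Tumor-driven
angiogenesis (``alpha2 n m``) shifts the vascularised state upward: the
spatially uniform fixed points of the coupled reaction system solve

    gamma m^2 + (beta + alpha1 alpha2) m + (alpha + alpha2) = 0,
    n* = 1 + alpha1 m*,

which for the defaults gives m* = (3 + a ± sqrt(8(alpha2-1) + (3+a)^2)) / 4
with a = alpha1*alpha2.  Nanoparticle extravasation is governed by the
vessel-efficiency kernel ``m exp(-(m/m_lim)^2)``: it vanishes in avascular
tissue, peaks at intermediate vessel density (normalized vasculature), and
decays for the dense, dysfunctional vasculature of an untreated tumor.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "NoRealFixedPointsError",
    "default_parameters",
    "rhs_n",
    "rhs_m",
    "vasculature_fixed_points",
    "tumor_fixed_point",
    "delivery_efficiency",
    "reaction_jacobian",
    "classify_fixed_point",
    "uniform_fixed_points",
]

DeliveryForm = Literal["as_printed", "max_at_one"]

#: Closed-form root expression is only valid for these cubic coefficients.
_CANONICAL_CUBIC = (-1.0, 3.0, -2.0)


class NoRealFixedPointsError(ValueError):
    """Raised when the coupled steady-state quadratic has no real roots."""


@dataclass(frozen=True)
class ModelParameters:
    """All coefficients of the dimensionless model plus dimensionful anchors.

    Rates and diffusivities are nonnegative; ``D1`` is in mm^2/day, ``rho``
    in 1/day; everything else is dimensionless.
    """

    alpha1_t: float  # vasculature -> tumor growth coupling
    D2_t: float      # vessel diffusivity
    alpha_t: float   # cubic coefficient (constant term factor)
    beta_t: float    # cubic coefficient (linear)
    gamma_t: float   # cubic coefficient (quadratic)
    alpha2_t: float  # tumor -> vasculature coupling (angiogenic drive)
    delta_t: float   # nanoparticle uptake coefficient
    m_lim: float     # delivery-efficiency scale
    D3_t: float      # free antiangiogenic-agent diffusivity
    D4_t: float      # free chemotherapeutic-agent diffusivity
    lambdaC_t: float  # antiangiogenic release amplitude
    lambdaD_t: float  # chemotherapeutic release amplitude
    nuC_t: float     # antiangiogenic decay rate
    nuD_t: float     # chemotherapeutic decay rate
    mu_t: float      # reabsorption of free chemo drug into vessels
    AC_t: float      # antiangiogenic therapy strength
    AD_t: float      # chemotherapy strength
    D1: float        # tumor-cell diffusivity, mm^2/day
    rho: float       # net proliferation rate, 1/day
    c_th: float      # detectability threshold on n
    sigma0: float    # initial Gaussian width (dimensionless)

    def __post_init__(self) -> None:
        nonneg = (
            "alpha1_t", "D2_t", "alpha2_t", "delta_t", "D3_t", "D4_t",
            "lambdaC_t", "lambdaD_t", "nuC_t", "nuD_t", "mu_t", "AC_t", "AD_t",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("m_lim", "rho", "D1", "sigma0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- flat key-value serialization ------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, stream=None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_stream) -> "ModelParameters":
        if isinstance(text_or_stream, str):
            text_or_stream = io.StringIO(text_or_stream)
        return cls.from_dict(yaml.safe_load(text_or_stream))


def default_parameters(cancer: Literal["lung", "melanoma"] = "lung") -> ModelParameters:
    """Default parameter set for Lewis lung carcinoma or B16:F10 melanoma.

    Only the tumor-cell diffusivity and the two therapy strengths differ
    between the two cancers; the antiangiogenic release amplitude is one
    hundred times the chemotherapeutic one (reflecting the injected doses).
    """
    if cancer == "lung":
        D1, AC, AD = 0.32, 0.1, 1.65
    elif cancer == "melanoma":
        D1, AC, AD = 0.46, 0.3, 3.0
    else:
        raise ValueError(f"unknown cancer type {cancer!r}; expected 'lung' or 'melanoma'")
    lambdaD = 13.0
    return ModelParameters(
        alpha1_t=1.1,
        D2_t=0.005,
        alpha_t=-1.0,
        beta_t=3.0,
        gamma_t=-2.0,
        alpha2_t=0.9,
        delta_t=0.8,
        m_lim=2.0,
        D3_t=0.02,
        D4_t=0.02,
        lambdaC_t=100.0 * lambdaD,
        lambdaD_t=lambdaD,
        nuC_t=3.0,
        nuD_t=0.1,
        mu_t=8.0,
        AC_t=AC,
        AD_t=AD,
        D1=D1,
        rho=0.35,
        c_th=0.09,
        sigma0=0.35,
    )


def _check_fields(*fields: np.ndarray) -> None:
    shapes = {np.shape(f) for f in fields}
    if len(shapes) > 1:
        raise ValueError(f"fields must share one grid, got shapes {sorted(shapes)}")
    for f in fields:
        if np.any(np.asarray(f) < 0):
            raise ValueError("fields must be nonnegative")


def rhs_n(n, m, d, params: ModelParameters, chemo_active: bool = False,
          *, validate: bool = True) -> np.ndarray:
    """Reaction part of the tumor-cell equation (diffusion excluded).

    ``n (1 - n) + alpha1 m n``, minus the chemotherapy kill term
    ``A_D d n`` when *chemo_active*.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if validate:
        _check_fields(n, m, d)
    out = n * (1.0 - n) + params.alpha1_t * m * n
    if chemo_active:
        out = out - params.AD_t * d * n
    return out


def rhs_m(n, m, c, params: ModelParameters, anti_active: bool = False,
          *, validate: bool = True) -> np.ndarray:
    """Reaction part of the vessel equation (diffusion excluded).

    ``m (alpha + beta m + gamma m^2) + alpha2 n m``, minus the
    antiangiogenic kill term ``A_C c m`` when *anti_active*.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    if validate:
        _check_fields(n, m, c)
    out = m * (params.alpha_t + params.beta_t * m + params.gamma_t * m * m)
    out = out + params.alpha2_t * n * m
    if anti_active:
        out = out - params.AC_t * c * m
    return out


def vasculature_fixed_points(params: ModelParameters) -> tuple[float, float]:
    """Nonzero uniform vessel-density fixed points of the coupled system.

    Solves ``gamma m^2 + (beta + alpha1 alpha2) m + (alpha + alpha2) = 0``
    (obtained by substituting the tumor nullcline ``n = 1 + alpha1 m`` into
    the vessel reaction term and dividing by m).  For the canonical cubic
    coefficients (-1, 3, -2) the closed form is used; any other coefficients
    route to a numeric root-finder on the same polynomial.

    Returns the two real roots in increasing order.

    Raises
    ------
    NoRealFixedPointsError
        If the discriminant is negative.
    """
    a1, a2 = params.alpha1_t, params.alpha2_t
    if (params.alpha_t, params.beta_t, params.gamma_t) == _CANONICAL_CUBIC:
        disc = 8.0 * (a2 - 1.0) + (3.0 + a1 * a2) ** 2
        if disc < 0:
            raise NoRealFixedPointsError(
                f"no real fixed points: discriminant {disc:.6g} < 0")
        s = math.sqrt(disc)
        lo = 0.25 * (3.0 + a1 * a2 - s)
        hi = 0.25 * (3.0 + a1 * a2 + s)
        return (lo, hi)
    # general coefficients: numeric roots of the steady-state quadratic
    coeffs = [params.gamma_t, params.beta_t + a1 * a2, params.alpha_t + a2]
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-12].real)
    if real.size < 2:
        raise NoRealFixedPointsError("no real fixed points for general cubic coefficients")
    return (float(real[0]), float(real[1]))


def tumor_fixed_point(m_star: float, alpha1_t: float) -> float:
    """Uniform tumor density on the vascularised branch: ``1 + alpha1 m*``."""
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    return 1.0 + alpha1_t * m_star


def delivery_efficiency(m, m_lim: float, form: DeliveryForm = "as_printed"):
    """Vessel-efficiency kernel governing nanoparticle extravasation.

    ``as_printed`` evaluates ``m exp(-(m/m_lim)^2)`` (maximum at
    ``m_lim/sqrt(2)``); ``max_at_one`` evaluates ``m exp(-m^2/m_lim)``
    (maximum at ``sqrt(m_lim/2)``, i.e. at m = 1 for m_lim = 2).  Both
    vanish at m = 0 and decay for dense abnormal vasculature (large m); the
    two conventions exist because the stated location of the maximum and the
    printed exponent disagree in the source model, so the choice is explicit.
    """
    if m_lim <= 0:
        raise ValueError("m_lim must be > 0")
    m = np.asarray(m, dtype=float)
    if form == "as_printed":
        out = m * np.exp(-((m / m_lim) ** 2))
    elif form == "max_at_one":
        out = m * np.exp(-(m * m) / m_lim)
    else:
        raise ValueError(f"unknown delivery-efficiency form {form!r}")
    return out if out.ndim else float(out)


def reaction_jacobian(n_star: float, m_star: float,
                      params: ModelParameters) -> np.ndarray:
    """Jacobian of the drug-free reaction terms at a uniform state (n*, m*)."""
    a1, a2 = params.alpha1_t, params.alpha2_t
    al, be, ga = params.alpha_t, params.beta_t, params.gamma_t
    dfdn = 1.0 - 2.0 * n_star + a1 * m_star
    dfdm = a1 * n_star
    dgdn = a2 * m_star
    dgdm = al + 2.0 * be * m_star + 3.0 * ga * m_star**2 + a2 * n_star
    return np.array([[dfdn, dfdm], [dgdn, dgdm]])


def classify_fixed_point(m_star: float, params: ModelParameters) -> dict:
    """Linear stability of the uniform state (1 + alpha1 m*, m*).

    Returns the eigenvalues of the reaction Jacobian and a label:
    ``stable`` if both real parts are negative, else ``unstable``.
    """
    n_star = tumor_fixed_point(max(m_star, 0.0), params.alpha1_t)
    eig = np.linalg.eigvals(reaction_jacobian(n_star, m_star, params))
    stable = bool(np.all(eig.real < 0))
    return {
        "m_star": m_star,
        "n_star": n_star,
        "eigenvalues": eig,
        "label": "stable" if stable else "unstable",
    }


def uniform_fixed_points(params: ModelParameters) -> list[dict]:
    """All nonnegative uniform fixed points with stability labels.

    Includes the vessel-free branch m* = 0 (with n* = 1) alongside the two
    roots of the coupled quadratic, each classified by the reaction Jacobian.
    """
    points = [0.0]
    try:
        lo, hi = vasculature_fixed_points(params)
        points += [r for r in (lo, hi) if r >= 0]
    except NoRealFixedPointsError:
        pass
    return [classify_fixed_point(m, params) for m in points]
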
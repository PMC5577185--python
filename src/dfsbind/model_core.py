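"""Closed-form model of forced bond rupture under a linear force ramp.

Dynamic force spectroscopy (DFS) pulls a tip-tethered ligand off a surface
while the applied force grows linearly in time, ``f(t) = r t`` with loading
rate ``r`` (N/s).  At low ``r`` rebinding keeps the rupture force pinned near
the equilibrium force ``f_eq`` (near-equilibrium plateau); at high ``r`` the
mean rupture force grows with ``ln r`` at slope ``f_beta = k_B T / x_t``
(Bell-Evans, kinetic regime).  Both regimes are captured by a single closed
form for the mean rupture force of ``N`` identical bonds,

    <f>_N = f_eq + N f_beta exp(a) E1(a),    a = N / R(f_eq / N),

where ``R(f) = r / (k_u(f) f_beta)`` is the dimensionless reduced loading
rate evaluated at the per-bond equilibrium force, ``k_u(f) = k_u
exp(f x_t / k_B T)`` is the Bell force-accelerated unbinding rate and
``E1`` is the first exponential integral.  The binding free energy of the
bound state follows from the fitted landscape parameters,

    dG_b = k_B T ln(f_eq x_t / (k_B T)) + f_eq x_t + k_B T,

and maps onto a Langmuir surface-coverage isotherm through
``theta = K c / (1 + K c)`` with ``K = exp(dG_b / k_B T)``.

All computation is in SI units (N, m, s, J, K); reporting layers convert to
pN, nm and k_B T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1

__all__ = [
    "BOLTZMANN",
    "DEFAULT_TEMPERATURE",
    "BondModelParams",
    "BindingEnergy",
    "bell_unbinding_rate",
    "reduced_loading",
    "exp_integral_e1",
    "exp1_scaled",
    "mean_rupture_force",
    "rupture_force_quantile",
    "rupture_force_survival",
    "rupture_force_pdf",
    "binding_free_energy",
    "coverage_from_energy",
    "energy_from_coverage",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Default absolute temperature, K (25 degC, the acquisition temperature).
DEFAULT_TEMPERATURE = 298.15

#: Divisor of the log argument in the binding-free-energy expression.  The
#: dimensionless convention ln(f_eq * x_t / (k_B * T)) is used; setting this
#: to ``lambda T: BOLTZMANN`` would reproduce the alternative (dimensional)
#: convention for comparison.
def _log_divisor(temperature: float) -> float:
    return BOLTZMANN * temperature


def _require_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BondModelParams:
    """Energy-landscape parameters of a tip-surface bond.

    Parameters
    ----------
    f_eq : float
        Equilibrium force, N.  The force at which binding and unbinding
        rates balance; the zero-loading-rate intercept of the mean rupture
        force.  Must be >= 0.
    x_t : float
        Distance from the bound state to the transition state along the
        pulling coordinate, m.  Must be > 0.
    k_u : float
        Intrinsic (zero-force) unbinding rate, 1/s.  Must be > 0.
    n_bonds : int
        Number of bonds N sharing the load, default 1.
    temperature : float
        Absolute temperature, K.
    """

    f_eq: float
    x_t: float
    k_u: float
    n_bonds: int = 1
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        _require_finite("f_eq", self.f_eq)
        if self.f_eq < 0:
            raise ValueError(f"f_eq must be >= 0, got {self.f_eq}")
        if not (self.x_t > 0 and math.isfinite(self.x_t)):
            raise ValueError(f"x_t must be > 0, got {self.x_t}")
        if not (self.k_u > 0 and math.isfinite(self.k_u)):
            raise ValueError(f"k_u must be > 0, got {self.k_u}")
        if int(self.n_bonds) != self.n_bonds or self.n_bonds < 1:
            raise ValueError(f"n_bonds must be a positive integer, got {self.n_bonds}")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def f_beta(self) -> float:
        """Thermal force scale k_B T / x_t, N.  Always recomputed."""
        return BOLTZMANN * self.temperature / self.x_t

    def replace(self, **kwargs) -> "BondModelParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class BindingEnergy:
    """Binding free energy of the bound state.

    ``delta_g`` is in joules; ``delta_g_kt`` is the same value expressed in
    units of k_B T at ``temperature``.
    """

    delta_g: float
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def delta_g_kt(self) -> float:
        return self.delta_g / (BOLTZMANN * self.temperature)


def bell_unbinding_rate(params: BondModelParams, force) -> np.ndarray | float:
    """Bell force-accelerated unbinding rate k_u(f) = k_u exp(f x_t / k_B T).

    ``force`` (N, >= 0) may be a scalar or array.  Strictly increasing in
    force; equals ``k_u`` at zero force.
    """
    force = np.asarray(force, dtype=float)
    _require_finite("force", force)
    if np.any(force < 0):
        raise ValueError("force must be >= 0")
    out = params.k_u * np.exp(force / params.f_beta)
    return float(out) if out.ndim == 0 else out


def reduced_loading(params: BondModelParams, loading_rate) -> np.ndarray | float:
    """Dimensionless reduced loading rate R = r / (k_u(f_eq/N) f_beta).

    The rate is evaluated at the per-bond equilibrium force ``f_eq / N``.
    Linear (hence strictly increasing) in ``loading_rate``.
    """
    r = np.asarray(loading_rate, dtype=float)
    _require_finite("loading_rate", r)
    if np.any(r <= 0):
        raise ValueError("loading_rate must be > 0")
    k_at_feq = bell_unbinding_rate(params, params.f_eq / params.n_bonds)
    out = r / (k_at_feq * params.f_beta)
    return float(out) if out.ndim == 0 else out


def exp_integral_e1(z) -> np.ndarray | float:
    """First exponential integral E1(z) = int_z^inf exp(-s)/s ds, z > 0."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("E1 requires z > 0")
    out = exp1(z)
    return float(out) if out.ndim == 0 else out


def exp1_scaled(z) -> np.ndarray | float:
    """Overflow-free scaled exponential integral exp(z) E1(z), z > 0.

    For z < 700 the product is evaluated directly (exp1 is still a normal
    float there); beyond that the asymptotic expansion
    exp(z) E1(z) ~ (1/z) sum_k (-1)^k k! / z^k is accurate to machine
    precision.  Satisfies the sandwich 1/(z+1) < exp(z) E1(z) < 1/z.
    """
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("exp1_scaled requires z > 0")
    out = np.empty_like(z)
    small = z < 700.0
    zs = z[small]
    out[small] = np.exp(zs) * exp1(zs)
    zl = z[~small]
    if zl.size:
        # truncated asymptotic series; terms k!/z^k are < eps by k = 9 here
        acc = np.zeros_like(zl)
        term = np.ones_like(zl)
        for k in range(12):
            acc += term
            term *= -(k + 1) / zl
        out[~small] = acc / zl
    return float(out) if out.ndim == 0 else out


def mean_rupture_force(params: BondModelParams, loading_rate) -> np.ndarray | float:
    """Mean rupture force of N bonds under a linear ramp at ``loading_rate``.

    <f>_N = f_eq + N f_beta exp(a) E1(a) with a = N / R(f_eq/N).  Strictly
    greater than f_eq, monotone non-decreasing in the loading rate, and
    numerically stable down to the deep near-equilibrium regime (a large).
    """
    R = reduced_loading(params, loading_rate)
    a = params.n_bonds / np.asarray(R, dtype=float)
    out = params.f_eq + params.n_bonds * params.f_beta * exp1_scaled(a)
    return float(out) if np.ndim(out) == 0 else out


def rupture_force_survival(params: BondModelParams, loading_rate: float, force):
    """Survival S(f) of a single bond (N=1): probability of no rupture by f.

    S(f) = exp(-(1/R) (exp((f - f_eq)/f_beta) - 1)) for f >= f_eq, 1 below.
    """
    if params.n_bonds != 1:
        raise ValueError("survival is defined for n_bonds = 1")
    R = reduced_loading(params, loading_rate)
    f = np.asarray(force, dtype=float)
    x = np.clip((f - params.f_eq) / params.f_beta, 0.0, None)
    return np.exp(-np.expm1(x) / R)


def rupture_force_pdf(params: BondModelParams, loading_rate: float, force):
    """Rupture-force density of a single bond (N=1); zero below f_eq."""
    if params.n_bonds != 1:
        raise ValueError("pdf is defined for n_bonds = 1")
    f = np.asarray(force, dtype=float)
    dens = np.where(
        f >= params.f_eq,
        bell_unbinding_rate(params, np.clip(f, 0.0, None))
        / loading_rate
        * rupture_force_survival(params, loading_rate, f),
        0.0,
    )
    return float(dens) if dens.ndim == 0 else dens


def rupture_force_quantile(params: BondModelParams, loading_rate: float, q):
    """Quantile of the single-bond rupture-force distribution.

    Closed-form inverse of the survival: f_q = f_eq + f_beta ln(1 - R ln(1-q)).
    """
    if params.n_bonds != 1:
        raise ValueError("quantile is defined for n_bonds = 1")
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile level must be in (0, 1)")
    R = reduced_loading(params, loading_rate)
    out = params.f_eq + params.f_beta * np.log1p(-R * np.log1p(-q))
    return float(out) if out.ndim == 0 else out


def binding_free_energy(
    f_eq: float, x_t: float, temperature: float = DEFAULT_TEMPERATURE
) -> BindingEnergy:
    """Binding free energy from the equilibrium force and barrier distance.

    dG_b = k_B T ln(f_eq x_t / (k_B T)) + f_eq x_t + k_B T, with the log
    argument nondimensionalised by k_B T (see module docstring).  Undefined
    (ValueError) for f_eq <= 0: bonds whose equilibrium force is consistent
    with zero are below the detection limit and should be reported as an
    upper bound rather than a number.
    """
    if not (f_eq > 0 and math.isfinite(f_eq)):
        raise ValueError(
            "binding_free_energy requires f_eq > 0; a bond with f_eq "
            "consistent with 0 is below the detection limit"
        )
    if not (x_t > 0 and math.isfinite(x_t)):
        raise ValueError("x_t must be > 0")
    kt = BOLTZMANN * temperature
    u = f_eq * x_t / _log_divisor(temperature)
    return BindingEnergy(delta_g=kt * math.log(u) + f_eq * x_t + kt, temperature=temperature)


def coverage_from_energy(delta_g: BindingEnergy, relative_activity: float = 1.0) -> float:
    """Langmuir surface coverage implied by a binding free energy.

    theta = K c / (1 + K c) with K = exp(dG_b / k_B T) and c the solution
    activity relative to the reference state.  Monotone increasing in both
    arguments; theta = 0.5 at dG_b = 0 and unit activity.
    """
    if not (relative_activity > 0 and math.isfinite(relative_activity)):
        raise ValueError("relative_activity must be > 0")
    # log-space for robustness at large |dG|
    log_kc = delta_g.delta_g_kt + math.log(relative_activity)
    if log_kc > 0:
        return 1.0 / (1.0 + math.exp(-log_kc))
    return math.exp(log_kc) / (1.0 + math.exp(log_kc))


def energy_from_coverage(
    theta: float,
    relative_activity: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BindingEnergy:
    """Invert the Langmuir isotherm: dG_b = k_B T ln(theta / ((1-theta) c))."""
    if not (0 < theta < 1):
        raise ValueError("theta must be in (0, 1)")
    if not (relative_activity > 0 and math.isfinite(relative_activity)):
        raise ValueError("relative_activity must be > 0")
    kt = BOLTZMANN * temperature
    return BindingEnergy(
        delta_g=kt * math.log(theta / ((1.0 - theta) * relative_activity)),
        temperature=temperature,
    )
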
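"""Synthetic dynamic-force-spectroscopy data.

Three layers of realism are provided:

1. ``sample_rupture_forces`` — exact inverse-transform draws from the
   single-bond rupture-force distribution implied by the closed-form mean
   model (the survival ``S(f) = exp(-(1/R)(e^{(f-f_eq)/f_beta} - 1))``).
2. ``gillespie_rupture`` — an independent two-state (bound/unbound)
   stochastic chain under the linear ramp ``f(t) = r t`` with explicit
   force-dependent rebinding.  Used as an oracle: with strong rebinding its
   rupture-force distribution converges to the closed-form model's.
3. ``synthesize_force_curve`` / ``generate_experiment`` — full
   force-distance curves (approach + retract, contact region, adhesion ramp,
   rupture step, noise and drift) assembled into a dataset that emulates the
   acquisition design of the experiments: at least five retraction
   velocities spanning 10-3000 nm/s, at least 50 curves per velocity
   (>= 250 rupture events per condition), approach at 100 nm/s, 1 s dwell.

Every sampler requires an explicit seed (or ``numpy.random.Generator``);
there is no hidden global randomness.  Dataset generation splits one root
seed hierarchically per curve so individual curves can be regenerated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    BOLTZMANN,
    DEFAULT_TEMPERATURE,
    BondModelParams,
    bell_unbinding_rate,
    binding_free_energy,
    reduced_loading,
)
from .curves_io import ConditionLabel, ForceCurve, RuptureEvent

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "SyntheticDataset",
    "sample_rupture_forces",
    "gillespie_rupture",
    "sample_gillespie_forces",
    "sample_multibond_rupture_forces",
    "synthesize_force_curve",
    "generate_experiment",
    "condition_presets",
    "f_eq_for_delta_g",
]


def _as_rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError(
            "an explicit seed (or numpy Generator) is required; samplers "
            "keep no hidden global state"
        )
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _default_velocities() -> tuple[float, ...]:
    # five retraction speeds log-spaced over 10-3000 nm/s
    return tuple(np.geomspace(10e-9, 3000e-9, 5))


@dataclass(frozen=True)
class ExperimentDesign:
    """Acquisition design of one DFS condition.

    Defaults mirror the experimental protocol: >= 5 retraction velocities in
    10-3000 nm/s, 50 curves per velocity (250 events total), nominal
    cantilever spring constant 0.06 N/m, approach at 100 nm/s, 1 s dwell.
    """

    velocities: tuple[float, ...] = field(default_factory=_default_velocities)
    curves_per_velocity: int = 50
    spring_constant: float = 0.06
    approach_velocity: float = 100e-9
    dwell_time: float = 1.0
    condition: ConditionLabel = field(default_factory=ConditionLabel)

    def __post_init__(self) -> None:
        if len(self.velocities) == 0 or any(v <= 0 for v in self.velocities):
            raise ValueError("velocities must be non-empty and positive")
        if self.curves_per_velocity < 1:
            raise ValueError("curves_per_velocity must be >= 1")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")

    @property
    def loading_rates(self) -> tuple[float, ...]:
        """Nominal loading rates r = spring_constant * velocity, N/s."""
        return tuple(self.spring_constant * v for v in self.velocities)

    @property
    def n_curves(self) -> int:
        return len(self.velocities) * self.curves_per_velocity


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise for synthetic force curves.

    force_noise_sd : per-sample Gaussian force noise, N (5 pN default, a
        typical soft-cantilever deflection noise floor).
    baseline_drift : linear baseline slope vs separation, N/m.
    contact_stiffness : slope of the repulsive contact region, N/m.
    samples_per_segment : points digitised per approach/retract segment
        (constant per curve, emulating velocity-matched sampling rates).
    """

    force_noise_sd: float = 5e-12
    baseline_drift: float = 0.0
    contact_stiffness: float = 0.05
    samples_per_segment: int = 1200

    def __post_init__(self) -> None:
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be >= 0")
        if self.contact_stiffness <= 0:
            raise ValueError("contact_stiffness must be > 0")
        if self.samples_per_segment < 50:
            raise ValueError("samples_per_segment must be >= 50")


def sample_rupture_forces(
    params: BondModelParams, loading_rate: float, n: int, seed
) -> np.ndarray:
    """Draw ``n`` single-bond rupture forces by exact inverse transform.

    f = f_eq + f_beta ln(1 - R ln U) with U ~ Uniform(0,1) reproduces the
    model survival exactly; every draw is >= f_eq, and the sample mean
    converges to ``mean_rupture_force`` as n grows.
    """
    if params.n_bonds != 1:
        raise ValueError("inverse-transform sampling requires n_bonds = 1; "
                         "use the multibond or Gillespie samplers otherwise")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    R = reduced_loading(params, loading_rate)
    u = rng.random(n)
    u = np.clip(u, np.finfo(float).tiny, None)
    return params.f_eq + params.f_beta * np.log1p(-R * np.log(u))


def gillespie_rupture(
    params: BondModelParams,
    loading_rate: float,
    rebinding_scale: float,
    seed,
) -> float:
    """One rupture force from a two-state chain with explicit rebinding.

    While bound, the bond unbinds at the Bell rate k_u exp(f/f_beta); after
    unbinding at force f0 it may rebind at rate

        k_on(f) = s * k_off(f_eq) * exp(-s (f - f_eq) / f_beta),

    s = ``rebinding_scale``.  The on-rate overwhelms the off-rate below
    f_eq and dies off just above it, with the crossover pinned at f_eq and
    sharpening as s grows; the exponential decay makes the total rebinding
    opportunity after each unbinding finite, playing the role of the finite
    capture range of the retracting tip.  Rupture is the final unbinding
    after which no rebinding occurs.  s = 0 gives the pure Bell-Evans first
    passage (first unbinding is final).

    Event times are drawn exactly from the time-inhomogeneous rates via
    closed-form integrated-hazard inversion (no time discretisation).
    """
    if rebinding_scale < 0:
        raise ValueError("rebinding_scale must be >= 0")
    if params.n_bonds != 1:
        raise ValueError("gillespie_rupture simulates a single bond")
    if loading_rate <= 0:
        raise ValueError("loading_rate must be > 0")
    rng = _as_rng(seed)
    fb = params.f_beta
    r = loading_rate
    s = rebinding_scale
    k_off_eq = bell_unbinding_rate(params, params.f_eq)

    f = 0.0  # current force; bond starts bound at zero force
    while True:
        # bound -> unbound: integrated hazard from f to f' is
        # (k_u f_beta / r) (e^{f'/f_beta} - e^{f/f_beta})
        e = rng.exponential()
        f = fb * np.log(np.exp(f / fb) + e * r / (params.k_u * fb))
        if s == 0.0:
            return float(f)
        # unbound at force f: remaining rebinding intensity over (f, inf) is
        # (k_off_eq f_beta / r) exp(-s (f - f_eq) / f_beta)
        e = rng.exponential()
        log_total = math.log(k_off_eq * fb / r) - s * (f - params.f_eq) / fb
        if log_total > 50.0:
            continue  # rebinding intensity enormous: instantaneous rebind at ~f
        total = math.exp(log_total)
        if e >= total:
            return float(f)  # never rebinds: final rupture
        # invert the rebinding integrated hazard for the rebinding force
        f = f - (fb / s) * math.log1p(-e / total)


def sample_gillespie_forces(
    params: BondModelParams,
    loading_rate: float,
    rebinding_scale: float,
    n: int,
    seed,
) -> np.ndarray:
    """Convenience: ``n`` independent ``gillespie_rupture`` draws."""
    rng = _as_rng(seed)
    return np.array(
        [gillespie_rupture(params, loading_rate, rebinding_scale, rng) for _ in range(n)]
    )


def sample_multibond_rupture_forces(
    params: BondModelParams, loading_rate: float, n: int, seed
) -> np.ndarray:
    """Qualitative N-bond sampler: sequential rupture with equal load sharing.

    With i bonds intact each carries f/i, the cluster unbinds at rate
    i * k_u(f/i), and the recorded rupture force is the loss of the last
    bond.  Captures the upward N-scaling of rupture forces; not used for
    quantitative acceptance work.
    """
    rng = _as_rng(seed)
    fb = params.f_beta
    r = loading_rate
    out = np.empty(n)
    for j in range(n):
        f = 0.0
        for i in range(params.n_bonds, 0, -1):
            # integrated hazard of stage i from f to f':
            # (i^2 k_u fb / r) (e^{f'/(i fb)} - e^{f/(i fb)})
            e = rng.exponential()
            f = i * fb * np.log(np.exp(f / (i * fb)) + e * r / (i * i * params.k_u * fb))
        out[j] = f
    return out


def synthesize_force_curve(
    event: RuptureEvent | None,
    design: ExperimentDesign,
    noise: NoiseModel,
    seed,
    velocity: float | None = None,
    curve_id: str = "synthetic-0",
) -> ForceCurve:
    """Build a force-distance record with an embedded rupture event.

    The retract trace shows a repulsive contact ramp (slope
    ``contact_stiffness``) for separations below zero, an adhesion well
    deepening linearly at the cantilever spring constant until the embedded
    rupture force is reached, an instantaneous step back to baseline, then
    flat baseline with optional linear drift; Gaussian force noise is added
    per sample.  The ground-truth force and nominal loading rate are stored
    in ``metadata`` for detector round-trip tests.  ``event=None`` embeds no
    rupture (null curve).
    """
    rng = _as_rng(seed)
    k = design.spring_constant
    if velocity is None:
        velocity = design.velocities[0]
    if event is not None and not (event.force > 0):
        raise ValueError("embedded event force must be > 0")

    f_rupt = event.force if event is not None else 0.0
    x_rupt = f_rupt / k  # separation at which the adhesion ramp ruptures
    x_min = -2e-9
    x_max = max(2.0e-8, 2.5 * x_rupt + 1.0e-8)
    n = noise.samples_per_segment

    def trace(x: np.ndarray, with_event: bool) -> np.ndarray:
        f = np.zeros_like(x)
        contact = x < 0
        f[contact] = -noise.contact_stiffness * x[contact]
        if with_event and f_rupt > 0:
            ramp = (x >= 0) & (x <= x_rupt)
            f[ramp] = -k * x[ramp]
            idx = np.flatnonzero(ramp)
            if idx.size:
                f[idx[-1]] = -f_rupt  # digitised apex sits at the rupture force
        f += noise.baseline_drift * np.clip(x, 0.0, None)
        if noise.force_noise_sd > 0:
            f += rng.normal(0.0, noise.force_noise_sd, size=x.size)
        if not np.all(np.isfinite(f)):
            raise ValueError("noise model produced non-finite samples")
        return f

    x_app = np.linspace(x_max, x_min, n)
    x_ret = np.linspace(x_min, x_max, n)
    f_app = trace(x_app, with_event=False)
    f_ret = trace(x_ret, with_event=True)

    separation = np.concatenate([x_app, x_ret])
    force = np.concatenate([f_app, f_ret])
    segment = np.array(["approach"] * n + ["retract"] * n)
    meta = {
        "dwell_time_s": design.dwell_time,
        "approach_velocity_m_per_s": design.approach_velocity,
    }
    if event is not None:
        meta.update(
            true_force_N=float(f_rupt),
            true_loading_rate_N_per_s=float(k * velocity),
            rupture_separation_m=float(x_rupt),
        )
    return ForceCurve(
        separation=separation,
        force=force,
        segment=segment,
        spring_constant=k,
        velocity=float(velocity),
        curve_id=curve_id,
        condition=design.condition,
        metadata=meta,
    )


@dataclass
class SyntheticDataset:
    """In-memory synthetic experiment: curves plus ground truth."""

    curves: list
    design: ExperimentDesign
    params: BondModelParams
    noise: NoiseModel
    seed: int
    true_events: dict  # curve_id -> {"force_N": ..., "loading_rate_N_per_s": ...}

    def ground_truth(self) -> dict:
        dg = binding_free_energy(self.params.f_eq, self.params.x_t, self.params.temperature)
        return {
            "seed": self.seed,
            "params": {
                "f_eq_N": self.params.f_eq,
                "x_t_m": self.params.x_t,
                "k_u_per_s": self.params.k_u,
                "n_bonds": self.params.n_bonds,
                "temperature_K": self.params.temperature,
                "delta_g_kt": dg.delta_g_kt,
            },
            "events": self.true_events,
        }

    def write(self, path) -> None:
        from . import curves_io

        curves_io.write_dataset(self.curves, path, ground_truth=self.ground_truth())


def generate_experiment(
    params: BondModelParams,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate a full DFS condition: sampled ruptures embedded in curves.

    For each velocity the nominal loading rate is r = spring_constant *
    velocity; rupture forces are drawn with the inverse-transform sampler
    and each is embedded in a synthesized force-distance curve.  One root
    seed is split hierarchically (one child stream per curve) so any curve
    can be regenerated in isolation; identical seeds give identical output.
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    if seed is None:
        raise ValueError("generate_experiment requires an explicit seed")
    root = np.random.SeedSequence(int(seed))
    force_ss, *curve_ss = root.spawn(1 + design.n_curves)

    force_rng = np.random.default_rng(force_ss)
    curves: list[ForceCurve] = []
    truth: dict[str, dict] = {}
    idx = 0
    for vi, v in enumerate(design.velocities):
        rate = design.spring_constant * v
        forces = sample_rupture_forces(params, rate, design.curves_per_velocity, force_rng)
        for ci in range(design.curves_per_velocity):
            cid = f"v{vi:02d}_c{ci:03d}"
            if cid in truth:
                raise ValueError(f"duplicate curve identifier {cid}")
            ev = RuptureEvent(
                force=float(forces[ci]),
                loading_rate=rate,
                curve_id=cid,
                condition=design.condition,
            )
            curve = synthesize_force_curve(
                ev,
                design,
                noise,
                np.random.default_rng(curve_ss[idx]),
                velocity=v,
                curve_id=cid,
            )
            curves.append(curve)
            truth[cid] = {
                "force_N": float(forces[ci]),
                "loading_rate_N_per_s": float(rate),
                "velocity_m_per_s": float(v),
            }
            idx += 1
    return SyntheticDataset(
        curves=curves,
        design=design,
        params=params,
        noise=noise,
        seed=int(seed),
        true_events=truth,
    )


def f_eq_for_delta_g(
    delta_g_kt: float, x_t: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Equilibrium force whose binding free energy equals ``delta_g_kt``.

    Solves ln(u) + u + 1 = dG/k_B T for u = f_eq x_t / (k_B T) (strictly
    increasing, so bisection on a bracket is safe).
    """
    from scipy.optimize import brentq

    target = delta_g_kt - 1.0
    g = lambda u: math.log(u) + u - target
    u = brentq(g, 1e-12, 1e6)
    return u * BOLTZMANN * temperature / x_t


def condition_presets(temperature: float = DEFAULT_TEMPERATURE) -> dict:
    """Synthetic bond parameters emulating ligand-mineral conditions.

    The per-pair landscape parameters were never published; these presets
    fix x_t = 0.30 nm and choose f_eq so the true binding free energy
    matches the reported headline values (e.g. 5.8 k_B T for COO- on mica,
    0.88 k_B T for CH3 on mica, 0.4 k_B T for the near-detection-limit
    CH3-goethite pair).  Weak bonds are given faster intrinsic unbinding so
    the default velocity range still brackets their near-equilibrium
    crossover.  Synthetic stand-ins for exploratory and test use only.
    """
    x_t = 0.30e-9

    def mk(dg_kt: float, k_u: float) -> BondModelParams:
        return BondModelParams(
            f_eq=f_eq_for_delta_g(dg_kt, x_t, temperature),
            x_t=x_t,
            k_u=k_u,
            temperature=temperature,
        )

    return {
        ("COO-", "muscovite(001)"): mk(5.8, 1.0),
        ("PO3-", "muscovite(001)"): mk(4.5, 2.0),
        ("NH3+", "muscovite(001)"): mk(2.5, 10.0),
        ("CH3", "muscovite(001)"): mk(0.88, 50.0),
        ("NH3+", "goethite(010)"): mk(5.0, 1.5),
        ("PO3-", "goethite(010)"): mk(3.5, 5.0),
        ("COO-", "goethite(010)"): mk(2.0, 20.0),
        ("CH3", "goethite(010)"): mk(0.4, 80.0),
    }
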
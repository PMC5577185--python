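"""Fit the mean-rupture-force model to binned DFS data.

The observable is the set of per-loading-rate aggregates (mean rupture
force, SD, SE, n); the model is the closed-form mean rupture force of
:mod:`dfsbind.model_core` with free parameters (f_eq, x_t, k_u) and the
bond number N held fixed (optionally scanned over small integers).  The
fit is weighted nonlinear least squares (weights 1/SE^2, falling back to
unweighted when any SE is zero) with a multi-start grid, since the
objective is multimodal in (k_u, x_t).

Usage follows the Model/Results idiom::

    model = RuptureForceModel.from_events(events)
    res = model.fit()
    res.summary()
    ci = res.bootstrap_delta_g(seed=1)

Confidence intervals on the binding free energy come from a stratified
bootstrap (resampling events within each loading-rate group), which is
more trustworthy than linearised errors when only a handful of rate
groups is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import (
    BOLTZMANN,
    DEFAULT_TEMPERATURE,
    BindingEnergy,
    BondModelParams,
    binding_free_energy,
    mean_rupture_force,
)
from .curves_io import RuptureEvent

__all__ = [
    "MeanForcePoint",
    "FitOptions",
    "RuptureForceModel",
    "RuptureForceResults",
    "BootstrapResult",
    "bin_by_loading_rate",
    "near_equilibrium_force",
    "NEAR_EQUILIBRIUM_RATE_CEILING",
]

#: Default loading-rate ceiling (N/s) below which the near-equilibrium
#: plateau is reached for the bonds studied; rupture forces below it are an
#: approximate measure of relative binding strength.
NEAR_EQUILIBRIUM_RATE_CEILING = 1e-8


@dataclass(frozen=True)
class MeanForcePoint:
    """Per-loading-rate aggregate of rupture forces (the fit observable)."""

    loading_rate: float
    mean_force: float
    sd_force: float
    se_force: float
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.sd_force < 0:
            raise ValueError("sd_force must be >= 0")


def bin_by_loading_rate(
    events: list[RuptureEvent],
    scheme: str = "by_velocity",
    n_bins: int = 6,
) -> list[MeanForcePoint]:
    """Aggregate rupture events into mean-force points.

    ``by_velocity`` groups events sharing a nominal loading rate (equal to
    within 1e-6 relative); ``log_bins`` partitions log10(r) into ``n_bins``
    equal-width bins.  Each point carries mean, SD (ddof=1; 0 for a single
    event), SE = SD/sqrt(n) and n; the group loading rate is the geometric
    mean of member rates.  Empty groups are omitted.
    """
    if not events:
        raise ValueError("no events to bin")
    rates = np.array([ev.loading_rate for ev in events])
    forces = np.array([ev.force for ev in events])

    if scheme == "by_velocity":
        order = np.argsort(rates)
        groups: list[list[int]] = []
        for idx in order:
            if groups and rates[idx] <= rates[groups[-1][0]] * (1 + 1e-6):
                groups[-1].append(idx)
            else:
                groups.append([idx])
    elif scheme == "log_bins":
        logr = np.log10(rates)
        edges = np.linspace(logr.min(), logr.max() * (1 + 1e-12), n_bins + 1)
        which = np.clip(np.digitize(logr, edges) - 1, 0, n_bins - 1)
        groups = [list(np.flatnonzero(which == b)) for b in range(n_bins)]
        groups = [g for g in groups if g]
    else:
        raise ValueError("scheme must be 'by_velocity' or 'log_bins'")

    points = []
    for g in groups:
        fg = forces[g]
        n = fg.size
        sd = float(np.std(fg, ddof=1)) if n > 1 else 0.0
        points.append(
            MeanForcePoint(
                loading_rate=float(np.exp(np.mean(np.log(rates[g])))),
                mean_force=float(fg.mean()),
                sd_force=sd,
                se_force=sd / math.sqrt(n),
                n_events=n,
            )
        )
    return points


def points_to_dataframe(points: list[MeanForcePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "loading_rate_N_per_s": [p.loading_rate for p in points],
            "mean_force_N": [p.mean_force for p in points],
            "sd_force_N": [p.sd_force for p in points],
            "se_force_N": [p.se_force for p in points],
            "n": [p.n_events for p in points],
        }
    )


@dataclass(frozen=True)
class FitOptions:
    """Bounds and initialisation for the three-parameter fit.

    Forces in N, distances in m.  ``x_t`` is bounded to the physically
    sensible 0.01-10 nm window; ``k_u`` spans 1e-6 to 1e9 1/s and is fitted
    on a log10 scale.  Multi-start grid: f_eq0 in {0.5, 0.8} x (minimum mean
    force); x_t0 from the Bell-Evans slope of the top decade of loading
    rates; k_u0 in {1e-2, 1, 1e2} 1/s.
    """

    x_t_bounds: tuple[float, float] = (0.01e-9, 10e-9)
    k_u_bounds: tuple[float, float] = (1e-6, 1e9)
    f_eq_fractions: tuple[float, ...] = (0.5, 0.8)
    k_u_starts: tuple[float, ...] = (1e-2, 1.0, 1e2)
    weighted: bool = True
    max_nfev: int = 2000


@dataclass
class BootstrapResult:
    """Percentile bootstrap interval for the binding free energy."""

    ci_low_kt: float
    ci_high_kt: float
    level: float
    n_resamples: int
    success_rate: float
    samples_kt: np.ndarray
    unreliable: bool

    def covers(self, delta_g_kt: float) -> bool:
        return self.ci_low_kt <= delta_g_kt <= self.ci_high_kt


class RuptureForceModel:
    """Mean-rupture-force model bound to a binned DFS dataset.

    Parameters
    ----------
    points : list of MeanForcePoint
        Per-loading-rate aggregates; at least three distinct rates are
        required for the three free parameters.
    n_bonds : int or "scan"
        Bond number N, fixed during fitting.  ``"scan"`` tries N in 1..4
        and keeps the smallest N among those within one part in 1e-6 of the
        best residual sum of squares.
    temperature : float
        Kelvin.
    events : list of RuptureEvent, optional
        The underlying events; retained so results can bootstrap.
    """

    def __init__(
        self,
        points: list[MeanForcePoint],
        n_bonds: int | str = 1,
        temperature: float = DEFAULT_TEMPERATURE,
        options: FitOptions | None = None,
        events: list[RuptureEvent] | None = None,
    ):
        distinct = {round(math.log10(p.loading_rate), 9) for p in points}
        if len(distinct) < 3:
            raise ValueError(
                f"need >= 3 distinct loading rates for 3 free parameters, got {len(distinct)}"
            )
        self.points = sorted(points, key=lambda p: p.loading_rate)
        self.n_bonds = n_bonds
        self.temperature = temperature
        self.options = options or FitOptions()
        self.events = events
        self._r = np.array([p.loading_rate for p in self.points])
        self._y = np.array([p.mean_force for p in self.points])
        self._se = np.array([p.se_force for p in self.points])

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_events(
        cls,
        events: list[RuptureEvent],
        scheme: str = "by_velocity",
        **kwargs,
    ) -> "RuptureForceModel":
        points = bin_by_loading_rate(events, scheme=scheme)
        return cls(points, events=events, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RuptureForceModel":
        """Build from a points table (columns as written by the pipeline)."""
        points = [
            MeanForcePoint(
                loading_rate=float(row["loading_rate_N_per_s"]),
                mean_force=float(row["mean_force_N"]),
                sd_force=float(row.get("sd_force_N", 0.0)),
                se_force=float(row.get("se_force_N", 0.0)),
                n_events=int(row.get("n", 1)),
            )
            for _, row in df.iterrows()
        ]
        return cls(points, **kwargs)

    # -- model evaluation -------------------------------------------------
    def predict(self, params: BondModelParams, loading_rate=None) -> np.ndarray:
        r = self._r if loading_rate is None else np.asarray(loading_rate, dtype=float)
        return mean_rupture_force(params, r)

    def _params_from_vector(self, p: np.ndarray, n_bonds: int) -> BondModelParams:
        # optimiser vector is [f_eq (pN), x_t (nm), log10 k_u] for conditioning
        return BondModelParams(
            f_eq=max(p[0], 0.0) * 1e-12,
            x_t=p[1] * 1e-9,
            k_u=10.0 ** p[2],
            n_bonds=n_bonds,
            temperature=self.temperature,
        )

    def _residuals(self, p: np.ndarray, n_bonds: int, weights: np.ndarray) -> np.ndarray:
        params = self._params_from_vector(p, n_bonds)
        return (self.predict(params) - self._y) * weights * 1e12

    def _weights(self) -> tuple[np.ndarray, bool]:
        if self.options.weighted and np.all(self._se > 0):
            return 1.0 / self._se, True
        return np.ones_like(self._y), False

    def _starts(self) -> list[np.ndarray]:
        opt = self.options
        y_min = float(self._y.min())
        # Bell-Evans slope over the top decade of loading rates
        logr = np.log(self._r)
        top = logr >= logr.max() - math.log(10.0)
        if top.sum() >= 2:
            slope = np.polyfit(logr[top], self._y[top], 1)[0]
        else:
            slope = np.polyfit(logr, self._y, 1)[0]
        kt = BOLTZMANN * self.temperature
        x_t0 = kt / slope if slope > 0 else 0.3e-9
        x_t0 = float(np.clip(x_t0, *opt.x_t_bounds))
        starts = []
        for frac in opt.f_eq_fractions:
            for ku0 in opt.k_u_starts:
                starts.append(
                    np.array([frac * y_min * 1e12, x_t0 * 1e9, math.log10(ku0)])
                )
        return starts

    # -- fitting ----------------------------------------------------------
    def fit(self, start: np.ndarray | None = None) -> "RuptureForceResults":
        """Weighted multi-start least squares; best start by objective.

        ``start`` overrides the multi-start grid with a single initial
        vector [f_eq, x_t, log10 k_u] (used by the bootstrap for speed).
        """
        scan = self.n_bonds == "scan"
        candidates = range(1, 5) if scan else [int(self.n_bonds)]
        weights, weighted = self._weights()
        opt = self.options
        lo = np.array(
            [0.0, opt.x_t_bounds[0] * 1e9, math.log10(opt.k_u_bounds[0])]
        )
        hi = np.array(
            [
                float(self._y.max()) * 1e12,
                opt.x_t_bounds[1] * 1e9,
                math.log10(opt.k_u_bounds[1]),
            ]
        )

        log: list[dict] = []
        best = None
        per_n: dict[int, float] = {}
        for n_bonds in candidates:
            starts = [np.asarray(start, dtype=float)] if start is not None else self._starts()
            for p0 in starts:
                p0 = np.clip(p0, lo, hi)
                try:
                    sol = least_squares(
                        self._residuals,
                        p0,
                        args=(n_bonds, weights),
                        bounds=(lo, hi),
                        max_nfev=opt.max_nfev,
                    )
                except Exception as exc:  # pragma: no cover - optimizer failure
                    log.append({"n_bonds": n_bonds, "start": p0.tolist(), "error": str(exc)})
                    continue
                cost = 2.0 * sol.cost * 1e-24  # residual sum of squares, N^2-scale
                log.append(
                    {
                        "n_bonds": n_bonds,
                        "start": p0.tolist(),
                        "objective": cost,
                        "success": bool(sol.success),
                    }
                )
                if sol.success and (best is None or cost < best["cost"] * (1 - 1e-12)):
                    if n_bonds not in per_n or cost < per_n[n_bonds]:
                        per_n[n_bonds] = cost
                    best = {"sol": sol, "cost": cost, "n_bonds": n_bonds}
                elif sol.success:
                    per_n[n_bonds] = min(per_n.get(n_bonds, np.inf), cost)

        if best is None:
            return RuptureForceResults(
                model=self, params=None, converged=False, fit_log=log
            )

        # parsimony tie-break: smallest N within 1e-6 relative of the best RSS
        if scan:
            best_cost = min(per_n.values())
            chosen_n = min(n for n, c in per_n.items() if c <= best_cost * (1 + 1e-6))
            if chosen_n != best["n_bonds"]:
                # rerun a fit at chosen_n so diagnostics match the chosen N
                sub = RuptureForceModel(
                    self.points, n_bonds=chosen_n, temperature=self.temperature,
                    options=self.options, events=self.events,
                )
                res = sub.fit()
                res.n_bonds_selection = {"scanned": per_n, "chosen": chosen_n}
                return res

        sol = best["sol"]
        params = self._params_from_vector(sol.x, best["n_bonds"])
        res = RuptureForceResults(
            model=self,
            params=params,
            converged=True,
            objective=best["cost"],
            weighted=weighted,
            fit_log=log,
            jac=sol.jac,
            weights=weights,
        )
        if scan:
            res.n_bonds_selection = {"scanned": per_n, "chosen": best["n_bonds"]}
        return res


class RuptureForceResults:
    """Fitted bond parameters, uncertainties and the binding free energy.

    Attributes
    ----------
    params : BondModelParams or None
        Point estimates (None when no start converged).
    bse : dict
        Linearised standard errors for f_eq (N), x_t (m) and k_u (1/s).
    delta_g : BindingEnergy or None
        Binding free energy from (f_eq, x_t); None when f_eq = 0 hit the
        boundary (below detection).
    converged, objective, residuals, fittedvalues : diagnostics.
    """

    def __init__(
        self,
        model: RuptureForceModel,
        params: BondModelParams | None,
        converged: bool,
        objective: float = math.inf,
        weighted: bool = False,
        fit_log: list | None = None,
        jac: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ):
        self.model = model
        self.params = params
        self.converged = converged
        self.objective = objective
        self.weighted = weighted
        self.fit_log = fit_log or []
        self.n_bonds_selection: dict | None = None
        self.bootstrap_result: BootstrapResult | None = None
        self.bse: dict[str, float] = {}
        self.fittedvalues = None
        self.residuals = None
        self.delta_g: BindingEnergy | None = None

        if params is not None:
            self.fittedvalues = model.predict(params)
            self.residuals = model._y - self.fittedvalues
            self._compute_bse(jac, weights)
            if params.f_eq > 0:
                self.delta_g = binding_free_energy(
                    params.f_eq, params.x_t, params.temperature
                )

    # -- uncertainties ----------------------------------------------------
    def _compute_bse(self, jac, weights) -> None:
        if jac is None:
            return
        n, k = jac.shape
        try:
            jtj_inv = np.linalg.pinv(jac.T @ jac)
        except np.linalg.LinAlgError:  # pragma: no cover
            return
        dof = max(n - k, 1)
        # weighted residuals are already unit-variance if SEs are trusted;
        # scale by reduced chi-square to be robust to mis-stated SEs.  The
        # optimiser works in (pN, nm, log10 k_u) with residuals on the pN
        # scale, so undo the N^2 conversion of `objective` before scaling.
        scale = self.objective * 1e24 / dof
        cov = jtj_inv * scale
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        # convert scaled-parameter SEs to SI; log10(k_u) by the delta method
        p = self.params
        self.bse = {
            "f_eq": float(se_vec[0] * 1e-12),
            "x_t": float(se_vec[1] * 1e-9),
            "k_u": float(se_vec[2] * p.k_u * math.log(10.0)),
        }
        self._cov = cov

    @property
    def f_eq_ci95(self) -> tuple[float, float]:
        """Linearised 95% interval for f_eq (N)."""
        se = self.bse.get("f_eq", math.nan)
        return (self.params.f_eq - 1.96 * se, self.params.f_eq + 1.96 * se)

    @property
    def delta_g_is_upper_bound(self) -> bool:
        """True when f_eq is consistent with zero (below detection limit)."""
        if self.params is None or self.params.f_eq <= 0:
            return True
        lo, _ = self.f_eq_ci95
        return bool(lo <= 0)

    def delta_g_report(self, detection_limit_kt: float = 0.5) -> str:
        """Human-readable dG_b, honouring the detection-limit convention."""
        if self.delta_g is None:
            return f"< {detection_limit_kt} kBT"
        if self.delta_g_is_upper_bound and self.delta_g.delta_g_kt < detection_limit_kt:
            return f"< {detection_limit_kt} kBT"
        note = " (f_eq CI includes 0)" if self.delta_g_is_upper_bound else ""
        return f"{self.delta_g.delta_g_kt:.2f} kBT{note}"

    # -- bootstrap --------------------------------------------------------
    def bootstrap_delta_g(
        self,
        seed,
        n_resamples: int = 200,
        level: float = 0.95,
        events: list[RuptureEvent] | None = None,
        multistart: bool = False,
    ) -> BootstrapResult:
        """Stratified bootstrap CI for dG_b.

        Events are resampled with replacement within each loading-rate
        group and the model refit per resample (initialised at the full-
        data solution unless ``multistart``).  An interval is flagged
        unreliable when more than 20% of resamples fail to converge.
        """
        if self.params is None:
            raise ValueError("bootstrap requires a converged fit")
        events = events if events is not None else self.model.events
        if events is None:
            raise ValueError("bootstrap needs the underlying events "
                             "(build the model with from_events)")
        rng = np.random.default_rng(
            seed if not isinstance(seed, np.random.Generator) else None
        ) if not isinstance(seed, np.random.Generator) else seed
        if n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")

        # group indices by loading rate (same grouping rule as by_velocity)
        rates = np.array([ev.loading_rate for ev in events])
        order = np.argsort(rates)
        groups: list[np.ndarray] = []
        current = [order[0]]
        for idx in order[1:]:
            if rates[idx] <= rates[current[0]] * (1 + 1e-6):
                current.append(idx)
            else:
                groups.append(np.array(current))
                current = [idx]
        groups.append(np.array(current))

        start = np.array(
            [self.params.f_eq * 1e12, self.params.x_t * 1e9, math.log10(self.params.k_u)]
        )
        samples = []
        failures = 0
        for _ in range(n_resamples):
            resampled = []
            for g in groups:
                take = rng.choice(g, size=g.size, replace=True)
                resampled.extend(events[i] for i in take)
            try:
                sub = RuptureForceModel(
                    bin_by_loading_rate(resampled),
                    n_bonds=self.params.n_bonds,
                    temperature=self.model.temperature,
                    options=self.model.options,
                )
                res = sub.fit(start=None if multistart else start)
            except ValueError:
                failures += 1
                continue
            if not res.converged or res.delta_g is None:
                failures += 1
                continue
            samples.append(res.delta_g.delta_g_kt)

        samples = np.array(samples)
        success_rate = samples.size / n_resamples
        if samples.size == 0:
            raise ValueError("all bootstrap resamples failed to converge")
        alpha = 1.0 - level
        lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        result = BootstrapResult(
            ci_low_kt=float(lo),
            ci_high_kt=float(hi),
            level=level,
            n_resamples=n_resamples,
            success_rate=success_rate,
            samples_kt=samples,
            unreliable=success_rate < 0.8,
        )
        self.bootstrap_result = result
        return result

    # -- reporting --------------------------------------------------------
    def to_dict(self) -> dict:
        """Fit report (SI and reporting units) for JSON serialisation."""
        if self.params is None:
            return {"converged": False, "fit_log": self.fit_log}
        p = self.params
        kt = BOLTZMANN * p.temperature
        out = {
            "converged": self.converged,
            "weighted": self.weighted,
            "objective": self.objective,
            "n_points": len(self.model.points),
            "n_bonds": p.n_bonds,
            "params_si": {"f_eq_N": p.f_eq, "x_t_m": p.x_t, "k_u_per_s": p.k_u,
                          "temperature_K": p.temperature},
            "params_reporting": {
                "f_eq_pN": p.f_eq * 1e12,
                "x_t_nm": p.x_t * 1e9,
                "k_u_per_s": p.k_u,
                "f_beta_pN": p.f_beta * 1e12,
            },
            "bse_si": self.bse,
            "delta_g_J": self.delta_g.delta_g if self.delta_g else None,
            "delta_g_kt": self.delta_g.delta_g_kt if self.delta_g else None,
            "delta_g_is_upper_bound": self.delta_g_is_upper_bound,
            "residuals_N": None if self.residuals is None else list(self.residuals),
        }
        if self.n_bonds_selection:
            out["n_bonds_selection"] = {
                "chosen": self.n_bonds_selection["chosen"],
                "rss_by_n": {str(k): v for k, v in self.n_bonds_selection["scanned"].items()},
            }
        if self.bootstrap_result is not None:
            b = self.bootstrap_result
            out["delta_g_ci_kt"] = [b.ci_low_kt, b.ci_high_kt]
            out["bootstrap"] = {
                "level": b.level,
                "n_resamples": b.n_resamples,
                "success_rate": b.success_rate,
                "unreliable": b.unreliable,
            }
        return out

    def summary(self) -> str:
        """Plain-text summary table in reporting units (pN, nm, kBT)."""
        lines = ["Rupture-force model fit", "=" * 47]
        if self.params is None:
            lines.append("NOT CONVERGED from any start; see fit_log")
            return "\n".join(lines)
        p = self.params
        rows = [
            ("f_eq", f"{p.f_eq * 1e12:10.3f} pN", f"+/- {self.bse.get('f_eq', float('nan')) * 1e12:.3f}"),
            ("x_t", f"{p.x_t * 1e9:10.3f} nm", f"+/- {self.bse.get('x_t', float('nan')) * 1e9:.3f}"),
            ("k_u", f"{p.k_u:10.3g} 1/s", f"+/- {self.bse.get('k_u', float('nan')):.3g}"),
            ("f_beta", f"{p.f_beta * 1e12:10.3f} pN", ""),
            ("N (bonds)", f"{p.n_bonds:10d}", ""),
        ]
        for name, val, err in rows:
            lines.append(f"{name:<12}{val}  {err}")
        lines.append("-" * 47)
        lines.append(f"dG_b        {self.delta_g_report()}")
        if self.bootstrap_result is not None:
            b = self.bootstrap_result
            flag = "  [UNRELIABLE]" if b.unreliable else ""
            lines.append(
                f"  {b.level:.0%} CI  [{b.ci_low_kt:.2f}, {b.ci_high_kt:.2f}] kBT{flag}"
            )
        lines.append(
            f"points: {len(self.model.points)}   weighted: {self.weighted}   "
            f"RSS: {self.objective:.4g}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean rupture force vs loading rate with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.points
        r = np.array([p.loading_rate for p in pts])
        ax.errorbar(
            r * 1e9,
            [p.mean_force * 1e12 for p in pts],
            yerr=[p.sd_force * 1e12 for p in pts],
            fmt="o",
            capsize=3,
            label="mean rupture force (+/- SD)",
        )
        if self.params is not None:
            rr = np.geomspace(r.min() / 3, r.max() * 3, 200)
            ax.plot(rr * 1e9, self.model.predict(self.params, rr) * 1e12, "-",
                    label="fit")
        ax.set_xscale("log")
        ax.set_xlabel("loading rate (nN/s)")
        ax.set_ylabel("rupture force (pN)")
        ax.legend()
        return ax


def near_equilibrium_force(
    points: list[MeanForcePoint],
    rate_ceiling: float = NEAR_EQUILIBRIUM_RATE_CEILING,
) -> tuple[float, float, int]:
    """Event-weighted mean and SD of rupture force in the plateau regime.

    Pools all points with loading rate below ``rate_ceiling`` (default
    1e-8 N/s, below which the near-equilibrium plateau is reached); the
    pooled SD combines within- and between-group spread.  Returns
    (mean, sd, n_events).
    """
    low = [p for p in points if p.loading_rate < rate_ceiling]
    if not low:
        raise ValueError(
            f"no mean-force point below {rate_ceiling:g} N/s; the dataset has "
            "no near-equilibrium coverage - fit the full model "
            "(RuptureForceModel) instead"
        )
    n = sum(p.n_events for p in low)
    mean = sum(p.n_events * p.mean_force for p in low) / n
    var = (
        sum(p.n_events * (p.sd_force**2 + (p.mean_force - mean) ** 2) for p in low) / n
    )
    return float(mean), float(math.sqrt(var)), int(n)
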
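"""End-to-end orchestration: simulate -> detect -> fit -> report.

A pipeline run produces an artifact directory containing the rupture-event
table, the binned mean-force points, the fit report (JSON), a comparison
table across conditions and a structured run log with seeds and versions.
Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves_io import (
    ConditionLabel,
    DetectionConfig,
    QCRules,
    detect_rupture,
    events_to_dataframe,
    qc_filter,
    read_force_curves,
)
from .fitting import (
    NEAR_EQUILIBRIUM_RATE_CEILING,
    RuptureForceModel,
    RuptureForceResults,
    bin_by_loading_rate,
    near_equilibrium_force,
    points_to_dataframe,
)
from .model_core import BondModelParams
from .simulate import ExperimentDesign, NoiseModel, condition_presets, generate_experiment

__all__ = [
    "PipelineConfig",
    "ConditionComparison",
    "run_pipeline",
    "compare_conditions",
    "detect_events",
]

_STAGES = ("simulate", "detect", "fit", "report")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic pipeline run.

    ``conditions`` maps a condition name to its bond parameters (either a
    preset key like ``"COO-/muscovite(001)"`` or explicit values in pN / nm
    / 1/s).  Stages run in order; the seed is mandatory because simulation
    and bootstrap are stochastic.
    """

    out_dir: Path
    seed: int
    stages: tuple[str, ...] = _STAGES
    conditions: dict = field(default_factory=lambda: {"COO-/muscovite(001)": None})
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    qc: QCRules = field(default_factory=QCRules)
    n_bonds: int | str = 1
    bootstrap_resamples: int = 0
    detection_limit_kt: float = 0.5
    comparison_mode: str = "delta_g"
    write_curves: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {_STAGES}")
        if self.seed is None and {"simulate"} & set(self.stages):
            raise ValueError("a seed is mandatory when stochastic stages run")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs = {"out_dir": Path(raw["out_dir"]), "seed": int(raw["seed"])}
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        if "conditions" in raw:
            kwargs["conditions"] = raw["conditions"]
        if "design" in raw:
            d = dict(raw["design"])
            if "condition" in d:
                d["condition"] = ConditionLabel.from_dict(d["condition"])
            if "velocities" in d:
                d["velocities"] = tuple(float(v) for v in d["velocities"])
            kwargs["design"] = ExperimentDesign(**d)
        if "noise" in raw:
            kwargs["noise"] = NoiseModel(**raw["noise"])
        if "detection" in raw:
            kwargs["detection"] = DetectionConfig(**raw["detection"])
        for key in ("n_bonds", "bootstrap_resamples", "detection_limit_kt",
                    "comparison_mode", "write_curves"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _resolve_params(name: str, value) -> BondModelParams:
    if isinstance(value, BondModelParams):
        return value
    if isinstance(value, dict):
        return BondModelParams(
            f_eq=float(value["f_eq_pN"]) * 1e-12,
            x_t=float(value["x_t_nm"]) * 1e-9,
            k_u=float(value["k_u_per_s"]),
            n_bonds=int(value.get("n_bonds", 1)),
        )
    presets = condition_presets()
    try:
        ligand, mineral = name.split("/", 1)
        return presets[(ligand, mineral)]
    except (ValueError, KeyError):
        raise ValueError(
            f"condition {name!r} has no explicit parameters and is not a "
            f"preset; presets: {sorted('/'.join(k) for k in presets)}"
        )


def detect_events(curves, detection: DetectionConfig | None = None,
                  qc: QCRules | None = None):
    """Detect ruptures on a list of curves and QC-filter the events."""
    detection = detection or DetectionConfig()
    events = []
    n_no_event = 0
    for curve in curves:
        ev = detect_rupture(curve, detection)
        if ev is None:
            n_no_event += 1  # excluded from means, not counted as zero force
        else:
            events.append(ev)
    kept, report = qc_filter(events, qc)
    report["no_event"] = n_no_event
    return kept, report


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Any stage error halts the run with a stage-attributed message; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "dfsbind_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "timings_s": {},
        "event_counts": {},
    }
    results: list[tuple[ConditionLabel, RuptureForceResults, dict]] = []
    rng_root = np.random.SeedSequence(int(config.seed))
    cond_seeds = rng_root.spawn(len(config.conditions))

    try:
        for (name, value), ss in zip(config.conditions.items(), cond_seeds):
            t0 = time.perf_counter()
            params = _resolve_params(name, value)
            try:
                ligand, mineral = name.split("/", 1)
                cond = ConditionLabel(ligand=ligand, mineral=mineral)
            except ValueError:
                cond = ConditionLabel(ligand=name, mineral="custom")
            design = ExperimentDesign(
                velocities=config.design.velocities,
                curves_per_velocity=config.design.curves_per_velocity,
                spring_constant=config.design.spring_constant,
                approach_velocity=config.design.approach_velocity,
                dwell_time=config.design.dwell_time,
                condition=cond,
            )
            stage = "simulate"
            seed_int = int(ss.generate_state(1)[0] % (2**31))
            dataset = generate_experiment(params, design, config.noise, seed=seed_int)
            if config.write_curves:
                dataset.write(out / f"curves_{_slug(name)}")
            log["timings_s"].setdefault(stage, 0.0)
            log["timings_s"][stage] += time.perf_counter() - t0

            if "detect" not in config.stages:
                continue
            stage = "detect"
            t0 = time.perf_counter()
            events, qc_report = detect_events(dataset.curves, config.detection, config.qc)
            if not events:
                raise RuntimeError(f"no rupture events detected for {name}")
            events_to_dataframe(events).to_csv(
                out / f"events_{_slug(name)}.csv", index=False, float_format="%.9e"
            )
            log["event_counts"][name] = qc_report
            log["timings_s"].setdefault(stage, 0.0)
            log["timings_s"][stage] += time.perf_counter() - t0

            if "fit" not in config.stages:
                continue
            stage = "fit"
            t0 = time.perf_counter()
            model = RuptureForceModel.from_events(events, n_bonds=config.n_bonds)
            res = model.fit()
            points = model.points
            points_to_dataframe(points).to_csv(
                out / f"points_{_slug(name)}.csv", index=False, float_format="%.9e"
            )
            if res.converged and config.bootstrap_resamples > 0:
                res.bootstrap_delta_g(
                    seed=np.random.default_rng(ss.spawn(1)[0]),
                    n_resamples=config.bootstrap_resamples,
                )
            report = res.to_dict()
            try:
                lo_mean, lo_sd, lo_n = near_equilibrium_force(points)
                report["near_equilibrium_force"] = {
                    "mean_N": lo_mean, "sd_N": lo_sd, "n_events": lo_n,
                    "rate_ceiling_N_per_s": NEAR_EQUILIBRIUM_RATE_CEILING,
                }
            except ValueError:
                report["near_equilibrium_force"] = None
            report["true_params"] = dataset.ground_truth()["params"]
            (out / f"fit_{_slug(name)}.json").write_text(json.dumps(report, indent=1))
            results.append((cond, res, report))
            log["timings_s"].setdefault(stage, 0.0)
            log["timings_s"][stage] += time.perf_counter() - t0

        if "report" in config.stages and len(results) >= 2:
            stage = "report"
            t0 = time.perf_counter()
            comparison = compare_conditions(
                [(c, r) for c, r, _ in results],
                mode=config.comparison_mode,
                detection_limit_kt=config.detection_limit_kt,
            )
            comparison.table.to_csv(out / "comparison.csv", index=False)
            (out / "ranking.txt").write_text(comparison.ranking + "\n")
            log["timings_s"][stage] = time.perf_counter() - t0
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


@dataclass
class ConditionComparison:
    """Cross-condition table plus a ranking string like ``A > B > C``."""

    table: pd.DataFrame
    ranking: str
    mode: str


def compare_conditions(
    fits: list[tuple[ConditionLabel, RuptureForceResults]],
    mode: str = "delta_g",
    detection_limit_kt: float = 0.5,
    rate_ceiling: float = NEAR_EQUILIBRIUM_RATE_CEILING,
) -> ConditionComparison:
    """Rank conditions by binding free energy or low-rate rupture force.

    Rows whose fitted f_eq is consistent with zero are rendered as a
    detection-limit bound (``< 0.5 kBT``) and excluded from the ranking.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 conditions to compare")
    keys = [cond.key() for cond, _ in fits]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicated condition keys")
    if mode not in ("delta_g", "low_rate_force"):
        raise ValueError("mode must be 'delta_g' or 'low_rate_force'")

    rows = []
    for cond, res in fits:
        label = f"{cond.ligand} on {cond.mineral}"
        row = {
            "ligand": cond.ligand,
            "mineral": cond.mineral,
            "pH": cond.ph,
            "ionic_strength_mM": cond.ionic_strength_mm,
            "electrolyte": cond.electrolyte,
            "label": label,
            "n_events": sum(p.n_events for p in res.model.points),
        }
        at_limit = res.delta_g is None or (
            res.delta_g_is_upper_bound and res.delta_g.delta_g_kt < detection_limit_kt
        )
        row["delta_g_kbt"] = (
            f"< {detection_limit_kt}" if at_limit else f"{res.delta_g.delta_g_kt:.2f}"
        )
        if res.bootstrap_result is not None:
            b = res.bootstrap_result
            row["delta_g_ci_kbt"] = f"[{b.ci_low_kt:.2f}, {b.ci_high_kt:.2f}]"
        try:
            m, sd, n = near_equilibrium_force(res.model.points, rate_ceiling)
            row["low_rate_force_pN"] = m * 1e12
            row["low_rate_force_sd_pN"] = sd * 1e12
        except ValueError:
            row["low_rate_force_pN"] = np.nan
            row["low_rate_force_sd_pN"] = np.nan
        if mode == "delta_g":
            row["_sort"] = -np.inf if at_limit else res.delta_g.delta_g_kt
            row["_rankable"] = not at_limit
        else:
            row["_sort"] = row["low_rate_force_pN"]
            row["_rankable"] = np.isfinite(row["low_rate_force_pN"])
        rows.append(row)

    df = pd.DataFrame(rows).sort_values("_sort", ascending=False)
    ranked = df[df["_rankable"]]["label"].tolist()
    ranking = " > ".join(ranked) if len(ranked) > 1 else (ranked[0] if ranked else "")
    excluded = df[~df["_rankable"]]["label"].tolist()
    if excluded:
        ranking += "   [below detection limit: " + ", ".join(excluded) + "]"
    df = df.drop(columns=["_sort", "_rankable"])
    return ConditionComparison(table=df.reset_index(drop=True), ranking=ranking, mode=mode)
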
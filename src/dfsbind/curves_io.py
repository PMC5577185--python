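"""Force-curve and rupture-event I/O, rupture detection and QC.

Dataset layout (all plain text):

    <dir>/manifest.json          schema version, condition metadata, spring
                                 constant, velocity list, curve file table,
                                 sign convention
    <dir>/curves/<id>.csv        per-curve samples, header
                                 ``separation_m,force_N,segment``
    <dir>/ground_truth.json      optional sidecar written by the simulator

Sign conventions (declared in the manifest): separation increases during
retract; adhesive forces are negative; rupture forces are reported as
positive magnitudes.  Rupture-event tables are CSV with header
``curve_id,loading_rate_N_per_s,rupture_force_N,flags`` plus condition
columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConditionLabel",
    "ForceCurve",
    "RuptureEvent",
    "DetectionConfig",
    "QCRules",
    "read_force_curves",
    "write_dataset",
    "detect_rupture",
    "loading_rate_for",
    "qc_filter",
    "events_to_dataframe",
    "events_from_dataframe",
    "write_events",
    "read_events",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_SIGN_CONVENTION = {
    "separation": "increases during retract",
    "adhesion": "negative force",
    "rupture_force": "positive magnitude",
}

KNOWN_LIGANDS = ("COO-", "PO3-", "NH3+", "CH3")
KNOWN_MINERALS = ("muscovite(001)", "goethite(010)")


@dataclass(frozen=True)
class ConditionLabel:
    """Chemical condition of one DFS measurement series.

    ``ligand`` is the tip-presented functional group (COO-, PO3-, NH3+, CH3
    or a custom label); ``mineral`` the probed cleavage face.  pH and ionic
    strength (mM) describe the solution; defaults are the reference
    condition pH 6, 10 mM NaCl.
    """

    ligand: str = "COO-"
    mineral: str = "muscovite(001)"
    ph: float = 6.0
    ionic_strength_mm: float = 10.0
    electrolyte: str = "NaCl"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"pH must be in [0, 14], got {self.ph}")
        if self.ionic_strength_mm < 0:
            raise ValueError("ionic_strength_mm must be >= 0")

    def key(self) -> tuple:
        return (self.ligand, self.mineral, self.ph, self.ionic_strength_mm, self.electrolyte)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionLabel":
        return cls(**{k: d[k] for k in
                      ("ligand", "mineral", "ph", "ionic_strength_mm", "electrolyte")
                      if k in d})


@dataclass
class ForceCurve:
    """One approach/retract force-distance record."""

    separation: np.ndarray
    force: np.ndarray
    segment: np.ndarray
    spring_constant: float
    velocity: float
    curve_id: str
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        if not (self.separation.size == self.force.size == self.segment.size):
            raise ValueError("separation, force and segment must be equally long")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")

    def _segment_arrays(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.segment == name
        return self.separation[mask], self.force[mask]

    @property
    def retract(self) -> tuple[np.ndarray, np.ndarray]:
        """(separation, force) of the retract segment, sorted by separation."""
        x, f = self._segment_arrays("retract")
        order = np.argsort(x, kind="stable")
        return x[order], f[order]

    @property
    def approach(self) -> tuple[np.ndarray, np.ndarray]:
        x, f = self._segment_arrays("approach")
        order = np.argsort(x, kind="stable")
        return x[order], f[order]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if clean)."""
        problems = []
        for name in ("approach", "retract"):
            x, _ = self._segment_arrays(name)
            if x.size < 10:
                problems.append(f"{name} segment has {x.size} < 10 samples")
                continue
            d = np.diff(x)
            if not (np.all(d > 0) or np.all(d < 0)):
                problems.append(f"{name} separation is not strictly monotone")
        if not np.all(np.isfinite(self.force)):
            problems.append("non-finite force samples")
        return problems


@dataclass(frozen=True)
class RuptureEvent:
    """One detected or simulated rupture."""

    force: float
    loading_rate: float
    curve_id: str
    detection_flags: frozenset = frozenset()
    condition: ConditionLabel = field(default_factory=ConditionLabel)

    def __post_init__(self) -> None:
        if not (self.force > 0):
            raise ValueError(f"rupture force must be > 0, got {self.force}")
        if not (self.loading_rate > 0):
            raise ValueError(f"loading_rate must be > 0, got {self.loading_rate}")
        object.__setattr__(self, "detection_flags", frozenset(self.detection_flags))


@dataclass(frozen=True)
class DetectionConfig:
    """Rupture-detector settings.

    The zero-force baseline and its noise SD are estimated robustly
    (median / scaled MAD) from the far tail of the retract trace
    (``baseline_fraction`` of samples furthest from contact).  Candidate
    events are contiguous excursions below baseline - noise_k * SD (on a
    lightly boxcar-smoothed trace when noise is present) that return to
    baseline within the trace; ``event_choice`` picks among several
    ("last" = final detachment, the tip-surface pulling convention, or
    "deepest").  ``min_separation`` excludes candidates whose minimum lies
    inside the contact zone.
    """

    baseline_fraction: float = 0.25
    noise_k: float = 5.0
    min_separation: float = 2e-10
    event_choice: str = "last"
    smooth_window: int = 9
    abs_floor: float = 1e-13  # threshold floor for noiseless traces, N

    def __post_init__(self) -> None:
        if not (0 < self.baseline_fraction < 0.5):
            raise ValueError("baseline_fraction must be in (0, 0.5)")
        if self.noise_k < 3:
            raise ValueError("noise_k must be >= 3")
        if self.event_choice not in ("last", "deepest"):
            raise ValueError("event_choice must be 'last' or 'deepest'")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


# ---------------------------------------------------------------------------
# dataset I/O


def write_dataset(curves: list[ForceCurve], path, ground_truth: dict | None = None) -> Path:
    """Write curves as one CSV each plus a JSON manifest (and optional truth)."""
    path = Path(path)
    (path / "curves").mkdir(parents=True, exist_ok=True)
    if not curves:
        raise ValueError("no curves to write")
    seen = set()
    table = []
    for c in curves:
        if c.curve_id in seen:
            raise ValueError(f"duplicate curve identifier {c.curve_id}")
        seen.add(c.curve_id)
        rel = f"curves/{c.curve_id}.csv"
        df = pd.DataFrame(
            {"separation_m": c.separation, "force_N": c.force, "segment": c.segment}
        )
        df.to_csv(path / rel, index=False, float_format="%.9e")
        table.append(
            {
                "curve_id": c.curve_id,
                "file": rel,
                "velocity_m_per_s": c.velocity,
                "n_samples": int(c.separation.size),
            }
        )
    first = curves[0]
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "sign_convention": _SIGN_CONVENTION,
        "condition": first.condition.to_dict(),
        "spring_constant_N_per_m": first.spring_constant,
        "velocities_m_per_s": sorted({c.velocity for c in curves}),
        "curves": table,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return path


def read_force_curves(path) -> list[ForceCurve]:
    """Read a dataset directory; curves failing invariants are skipped.

    Raises FileNotFoundError for a missing manifest or a manifest entry
    pointing at a missing curve file.  Curves violating the layout
    invariants (short or non-monotone segments, non-finite samples) are
    excluded with a logged warning and counted in the log.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    condition = ConditionLabel.from_dict(manifest.get("condition", {}))
    k = float(manifest["spring_constant_N_per_m"])

    curves: list[ForceCurve] = []
    skipped = 0
    for entry in manifest["curves"]:
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing curve file {fpath}")
        try:
            df = pd.read_csv(fpath)
            curve = ForceCurve(
                separation=df["separation_m"].to_numpy(),
                force=df["force_N"].to_numpy(),
                segment=df["segment"].to_numpy(),
                spring_constant=k,
                velocity=float(entry["velocity_m_per_s"]),
                curve_id=str(entry["curve_id"]),
                condition=condition,
            )
        except (KeyError, ValueError) as exc:
            logger.warning("skipping malformed curve %s: %s", fpath, exc)
            skipped += 1
            continue
        problems = curve.validate()
        if problems:
            logger.warning("skipping curve %s: %s", curve.curve_id, "; ".join(problems))
            skipped += 1
            continue
        curves.append(curve)
    if skipped:
        logger.warning("%d of %d curves skipped", skipped, len(manifest["curves"]))
    return curves


# ---------------------------------------------------------------------------
# rupture detection


def _boxcar(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")


def _step_depth(
    x: np.ndarray,
    f_raw: np.ndarray,
    baseline: float,
    run_start: int,
    imin_smoothed: int,
    run_end: int,
    w: int,
    fit_window: int = 25,
) -> tuple[float, int]:
    """Rupture depth by ramp extrapolation at the located step.

    The smoothed minimum sits up to half a smoothing window before the
    rupture step, and both the raw minimum (extreme-value bias) and the
    smoothed minimum (ramp averaging) are biased depth estimators.  Instead
    the step itself is located as the largest forward jump of the raw trace
    near the smoothed minimum, a short linear fit of the pre-step ramp is
    extrapolated to the step sample, and the depth is measured from the
    baseline to that extrapolation.  Noiseless traces are recovered exactly.
    """
    n = x.size
    hi = min(imin_smoothed + w + 5, run_end + w + 5, n - 1)
    seg = f_raw[imin_smoothed : hi + 1]
    if seg.size < 2:
        apex = imin_smoothed
    else:
        apex = imin_smoothed + int(np.argmax(np.diff(seg)))
    lo = max(run_start, apex - fit_window)
    if w > 1 and apex - lo >= 3:
        coeff = np.polyfit(x[lo : apex + 1], f_raw[lo : apex + 1], 1)
        level = float(np.polyval(coeff, x[apex]))
    else:  # noiseless trace: the apex sample is the rupture force itself
        level = float(f_raw[apex])
    return baseline - level, apex


def detect_rupture(curve: ForceCurve, config: DetectionConfig | None = None) -> RuptureEvent | None:
    """Detect the rupture event on the retract trace, if any.

    Returns ``None`` when no excursion clears the noise threshold.  The
    rupture force is the positive magnitude of the deepest point of the
    chosen candidate relative to the baseline.
    """
    config = config or DetectionConfig()
    x, f = curve.retract
    n = x.size
    n_tail = int(round(config.baseline_fraction * n))
    if n_tail < 5:
        raise ValueError(
            f"retract segment ({n} samples) shorter than the baseline window"
        )
    tail = f[-n_tail:]
    baseline = float(np.median(tail))
    sd = float(1.4826 * np.median(np.abs(tail - baseline)))

    if sd > 0:
        w = min(config.smooth_window, max(1, (n // 100) * 2 + 1))
        fs = _boxcar(f, w)
        sd_s = sd / np.sqrt(w)
    else:
        fs = f
        sd_s = 0.0
    thr = max(config.noise_k * sd_s, config.abs_floor)

    below = fs < baseline - thr
    if not below.any():
        return None
    # contiguous runs of below-threshold samples
    starts = list(np.flatnonzero(np.diff(np.r_[0, below.astype(int)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[below.astype(int), 0]) == -1))
    w = 1 if sd_s == 0 else min(config.smooth_window, max(1, (n // 100) * 2 + 1))
    candidates = []
    for s, e in zip(starts, ends):
        if e == n - 1:
            continue  # never returns to baseline within the trace
        imin = s + int(np.argmin(fs[s : e + 1]))
        if x[imin] < config.min_separation:
            continue  # inside the contact exclusion zone
        depth, apex = _step_depth(x, f, baseline, s, imin, e, w)
        if depth <= thr:
            continue
        candidates.append({"start": s, "end": e, "imin": apex, "depth": float(depth)})
    if not candidates:
        return None

    if config.event_choice == "deepest":
        chosen = max(candidates, key=lambda c: c["depth"])
    else:  # final detachment
        chosen = max(candidates, key=lambda c: c["imin"])

    flags = set()
    if len(candidates) > 1:
        flags.add("multiple_events")
    if sd_s > 0 and chosen["depth"] < 2 * config.noise_k * sd_s:
        flags.add("low_snr")

    event = RuptureEvent(
        force=chosen["depth"],
        loading_rate=loading_rate_nominal(curve),
        curve_id=curve.curve_id,
        detection_flags=frozenset(flags),
        condition=curve.condition,
    )
    # stash the event window for measured-loading-rate estimation
    object.__setattr__(event, "_window", (chosen["start"], chosen["imin"]))
    return event


def loading_rate_nominal(curve: ForceCurve) -> float:
    return curve.spring_constant * curve.velocity


def loading_rate_for(
    curve: ForceCurve,
    mode: str = "nominal",
    event: RuptureEvent | None = None,
    window: int = 50,
) -> float:
    """Loading rate of a curve, N/s.

    ``nominal``: spring constant times retraction velocity.  ``measured``:
    magnitude of the least-squares slope of force versus time over the
    stretch immediately preceding the detected rupture (requires ``event``
    from :func:`detect_rupture` on the same curve).
    """
    if mode == "nominal":
        return loading_rate_nominal(curve)
    if mode != "measured":
        raise ValueError("mode must be 'nominal' or 'measured'")
    if event is None:
        raise ValueError("measured mode requires a detected event")
    x, f = curve.retract
    win = getattr(event, "_window", None)
    if win is None:
        raise ValueError("event carries no detection window; re-run detect_rupture")
    start, imin = win
    lo = max(start, imin - window)
    if imin - lo < 3:
        lo = max(0, imin - 3)
    t = x[lo : imin + 1] / curve.velocity
    y = f[lo : imin + 1]
    slope = np.polyfit(t, y, 1)[0]
    return float(abs(slope))


# ---------------------------------------------------------------------------
# QC filtering


@dataclass(frozen=True)
class QCRules:
    """Event-level quality filters.

    Defaults drop low-SNR detections and forces outside the physically
    plausible 1 pN - 100 nN window; multiple-event curves are retained
    (their final detachment is still a valid rupture).
    """

    drop_flags: frozenset = frozenset({"low_snr"})
    min_force: float = 1e-12
    max_force: float = 1e-7

    def __post_init__(self) -> None:
        object.__setattr__(self, "drop_flags", frozenset(self.drop_flags))


def qc_filter(
    events: list[RuptureEvent], rules: QCRules | None = None
) -> tuple[list[RuptureEvent], dict]:
    """Apply QC rules; returns (retained events, per-rule drop counts)."""
    rules = rules or QCRules()
    report = {"input": len(events), "flag": 0, "force_range": 0, "retained": 0}
    kept = []
    for ev in events:
        if ev.detection_flags & rules.drop_flags:
            report["flag"] += 1
            continue
        if not (rules.min_force <= ev.force <= rules.max_force):
            report["force_range"] += 1
            continue
        kept.append(ev)
    report["retained"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# event tables


def events_to_dataframe(events: list[RuptureEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "curve_id": ev.curve_id,
            "loading_rate_N_per_s": ev.loading_rate,
            "rupture_force_N": ev.force,
            "flags": ";".join(sorted(ev.detection_flags)),
        }
        row.update(ev.condition.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def events_from_dataframe(df: pd.DataFrame) -> list[RuptureEvent]:
    events = []
    for _, row in df.iterrows():
        flags = frozenset(str(row.get("flags", "") or "").split(";")) - {""}
        cond = ConditionLabel.from_dict(row.to_dict()) if "ligand" in row else ConditionLabel()
        events.append(
            RuptureEvent(
                force=float(row["rupture_force_N"]),
                loading_rate=float(row["loading_rate_N_per_s"]),
                curve_id=str(row["curve_id"]),
                detection_flags=flags,
                condition=cond,
            )
        )
    return events


def write_events(events: list[RuptureEvent], path) -> Path:
    path = Path(path)
    events_to_dataframe(events).to_csv(path, index=False, float_format="%.9e")
    return path


def read_events(path) -> list[RuptureEvent]:
    return events_from_dataframe(pd.read_csv(path))
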
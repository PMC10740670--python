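"""Synthetic larval-fish locomotion: correlated random walks in circular wells.

The simulator generates per-fish coordinate time series with the statistical
structure the downstream analysis assumes: condition-dependent kinematic
regimes (speed, directional persistence, pausing, circling, immobility),
optional time-varying effects (a drugged fish sobering toward control-like
kinematics), and deterministic per-fish seeding.  It stands in for in vivo
recordings, which are not distributed with the package.

Model
-----
Heading diffuses by wrapped-Gaussian increments: ``turn_concentration`` is
the directional persistence per second (per-frame heading variance is
``1 / (turn_concentration * fps)``, so trajectories are frame-rate
invariant; higher = straighter swimming), plus a constant angular drift
``circling_bias`` that produces circular swimming.  Step
length per frame is ``max(0, Normal(speed_mean, speed_sd)) / fps``.  Pauses
start with probability ``pause_prob`` per second and last an exponentially
distributed time.  The circular wall reflects: a point landing outside the
well is mirrored back across the boundary along the radius and the heading
is reflected about the local tangent, which preserves path length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .trajectory import ArenaGeometry, ClassLabel, Trajectory, ValidationError

__all__ = [
    "RegimeParams",
    "RegimeSchedule",
    "CohortDesign",
    "simulate_fish",
    "simulate_cohort",
    "write_cohort",
    "dilution_concentration",
]


@dataclass(frozen=True)
class RegimeParams:
    """Kinematic regime of one condition (all rates in physical units)."""

    speed_mean: float = 30.0  # px/s
    speed_sd: float = 10.0  # px/s
    turn_concentration: float = 3.0  # heading precision per second; 0 = uniform
    pause_prob: float = 0.1  # probability of entering a pause, per second
    pause_duration_mean: float = 1.0  # s
    circling_bias: float = 0.0  # rad/s constant angular drift
    immobile: bool = False  # dead/immobilized fish: constant position

    def __post_init__(self) -> None:
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValidationError("speed_mean and speed_sd must be >= 0")
        if not 0 <= self.pause_prob <= 1:
            raise ValidationError("pause_prob must be in [0, 1]")
        if self.turn_concentration < 0:
            raise ValidationError("turn_concentration must be >= 0")


@dataclass(frozen=True)
class RegimeSchedule:
    """Time course of the kinematics over one recording.

    ``transition='none'`` holds ``start_regime`` throughout; ``'linear'``
    interpolates every parameter from start to end over the full duration
    (gradual sobering); ``'step'`` switches abruptly at ``transition_time``.
    """

    start_regime: RegimeParams
    end_regime: RegimeParams | None = None
    transition: str = "none"  # none | linear | step
    transition_time: float = 0.0  # s, used by 'step'
    duration: float = 5400.0  # s

    def __post_init__(self) -> None:
        if self.transition not in ("none", "linear", "step"):
            raise ValidationError(f"unknown transition {self.transition!r}")
        if self.transition != "none" and self.end_regime is None:
            raise ValidationError("end_regime required for linear/step transitions")
        if not 0 <= self.transition_time <= self.duration:
            raise ValidationError("transition_time must lie in [0, duration]")

    @staticmethod
    def constant(regime: RegimeParams, duration: float) -> "RegimeSchedule":
        return RegimeSchedule(start_regime=regime, duration=duration)


@dataclass(frozen=True)
class CohortDesign:
    """One simulated experiment: conditions x fish, shared geometry and seed."""

    conditions: tuple  # sequence of (ClassLabel, RegimeSchedule)
    n_fish_per_condition: int
    duration: float  # s
    fps: float
    arena: ArenaGeometry
    seed: int

    def __post_init__(self) -> None:
        if self.n_fish_per_condition <= 0:
            raise ValidationError("n_fish_per_condition must be > 0")
        object.__setattr__(self, "conditions", tuple(self.conditions))


@njit
def _walk_kernel(
    speed_mean,
    speed_sd,
    kappa,
    pause_p,
    pause_frames_mean,
    bias_per_frame,
    immobile,
    turn_normals,
    step_normals,
    pause_uniform,
    pause_expo,
    heading_uniform,
    x0,
    y0,
    theta0,
    cx,
    cy,
    radius,
    fps,
):  # pragma: no cover - exercised via simulate_fish
    n = speed_mean.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    x, y, th = x0, y0, theta0
    pause_left = 0.0
    for t in range(n):
        if immobile[t] or pause_left > 0.0:
            if pause_left > 0.0:
                pause_left -= 1.0
            xs[t] = x
            ys[t] = y
            continue
        if pause_uniform[t] < pause_p[t]:
            pause_left = pause_expo[t] * pause_frames_mean[t]
            xs[t] = x
            ys[t] = y
            continue
        if kappa[t] > 0.0:
            dth = turn_normals[t] / math.sqrt(kappa[t])
        else:
            dth = (heading_uniform[t] * 2.0 - 1.0) * math.pi
        th = th + dth + bias_per_frame[t]
        step = speed_mean[t] + speed_sd[t] * step_normals[t]
        if step < 0.0:
            step = 0.0
        step /= fps
        nx = x + step * math.cos(th)
        ny = y + step * math.sin(th)
        dx = nx - cx
        dy = ny - cy
        r = math.hypot(dx, dy)
        if r > radius:
            if r > 2.0 * radius:  # pathological overshoot: clamp just inside
                scale = 0.999 * radius / r
            else:  # mirror across the wall along the radius
                scale = (2.0 * radius - r) / r
            nx = cx + dx * scale
            ny = cy + dy * scale
            phi = math.atan2(dy, dx)
            th = 2.0 * phi - th + math.pi  # specular reflection of heading
        x, y = nx, ny
        xs[t] = x
        ys[t] = y
    return xs, ys


def _lerp(a: float, b: float, frac: np.ndarray) -> np.ndarray:
    return a + (b - a) * frac


def _per_frame_params(schedule: RegimeSchedule, n_frames: int, fps: float):
    """Expand a schedule into per-frame parameter arrays."""
    s, e = schedule.start_regime, schedule.end_regime
    t = np.arange(n_frames) / fps
    if schedule.transition == "none" or e is None:
        frac = np.zeros(n_frames)
    elif schedule.transition == "linear":
        frac = t / max(schedule.duration, 1e-12)
    else:  # step
        frac = (t >= schedule.transition_time).astype(np.float64)
    e = e if e is not None else s
    return {
        "speed_mean": _lerp(s.speed_mean, e.speed_mean, frac),
        "speed_sd": _lerp(s.speed_sd, e.speed_sd, frac),
        # per-frame heading precision: persistence-per-second times fps
        "kappa": _lerp(s.turn_concentration, e.turn_concentration, frac) * fps,
        "pause_p": np.clip(_lerp(s.pause_prob, e.pause_prob, frac) / fps, 0.0, 1.0),
        "pause_frames_mean": _lerp(s.pause_duration_mean, e.pause_duration_mean, frac) * fps,
        "bias_per_frame": _lerp(s.circling_bias, e.circling_bias, frac) / fps,
        # booleans interpolate as a 0.5 threshold on the mixing fraction
        "immobile": (_lerp(float(s.immobile), float(e.immobile), frac) >= 0.5),
    }


def _fish_rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))


def simulate_fish(
    schedule: RegimeSchedule,
    duration: float,
    fps: float,
    arena: ArenaGeometry,
    seed,
    fish_id: str = "sim",
    label: ClassLabel | None = None,
) -> Trajectory:
    """Simulate one fish; identical seed gives a bit-identical trajectory."""
    if label is None:
        label = ClassLabel.control()
    n = int(round(duration * fps))
    params = _per_frame_params(schedule, n, fps)
    rng = _fish_rng(seed)
    # start away from the wall so early kinematics are boundary-free
    r0 = arena.radius * 0.7 * math.sqrt(rng.uniform())
    a0 = rng.uniform(0.0, 2.0 * math.pi)
    x0 = arena.center[0] + r0 * math.cos(a0)
    y0 = arena.center[1] + r0 * math.sin(a0)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    xs, ys = _walk_kernel(
        params["speed_mean"],
        params["speed_sd"],
        params["kappa"],
        params["pause_p"],
        params["pause_frames_mean"],
        params["bias_per_frame"],
        params["immobile"],
        rng.standard_normal(n),
        rng.standard_normal(n),
        rng.uniform(size=n),
        rng.standard_exponential(n),
        rng.uniform(size=n),
        x0,
        y0,
        theta0,
        arena.center[0],
        arena.center[1],
        arena.radius,
        float(fps),
    )
    return Trajectory(
        fish_id=fish_id,
        label=label,
        fps=fps,
        positions=np.column_stack([xs, ys]),
        arena=arena,
    )


def simulate_cohort(design: CohortDesign) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate every fish of a cohort design.

    Per-fish seeds derive deterministically from ``design.seed`` and the
    (condition, fish) indices, so cohorts are reproducible and individual
    fish can be re-simulated in isolation.
    """
    trajectories: list[Trajectory] = []
    rows = []
    for ci, (label, schedule) in enumerate(design.conditions):
        for fi in range(design.n_fish_per_condition):
            fish_id = f"{label.name}_c{ci}f{fi:02d}"
            traj = simulate_fish(
                schedule,
                design.duration,
                design.fps,
                design.arena,
                seed=[int(design.seed), ci, fi],
                fish_id=fish_id,
                label=label,
            )
            trajectories.append(traj)
            rows.append(
                {
                    "fish_id": fish_id,
                    "label": label.name,
                    "concentration": label.concentration,
                    "fps": design.fps,
                    "condition_index": ci,
                    "fish_index": fi,
                }
            )
    return trajectories, pd.DataFrame(rows)


def write_cohort(trajectories: list[Trajectory], manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write per-fish trajectory CSVs (frame,x,y) plus a manifest CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    files = []
    for traj in trajectories:
        fname = f"{traj.fish_id}.csv"
        df = pd.DataFrame(
            {
                "frame": np.arange(len(traj)),
                "x": traj.positions[:, 0],
                "y": traj.positions[:, 1],
            }
        )
        df.to_csv(out / fname, index=False, float_format="%.17g")  # exact round-trip
        files.append(fname)
    manifest["file"] = files
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def dilution_concentration(stock_pct: float, v_stock: float, v_neutral: float) -> float:
    """Final concentration (percent, 1 decimal) after diluting a stock.

    ``stock_pct * v_stock / (v_stock + v_neutral)`` — e.g. 1 mL of 4% stock
    into 7 mL of neutral solution gives 0.5%.
    """
    if v_stock < 0 or v_neutral < 0:
        raise ValidationError("volumes must be >= 0")
    if v_stock + v_neutral == 0:
        raise ValidationError("at least one volume must be positive")
    return round(stock_pct * v_stock / (v_stock + v_neutral), 1)
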
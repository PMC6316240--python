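"""Experimental design expansion and fed-batch feed scheduling.

A campaign is described by a small design table (one row per experimental
condition: feed profile shape, set-point specific growth rate, initial glucose
and an optional post-batch hunger phase).  Each condition is run in replicate
on an 8-row x 6-column mini-bioreactor block.  Feeding is a two-phase scheme:
a 12 h shaped phase (exponential, linear or constant) followed by a constant
phase, delivered as discrete bolus pulses on a 5-min grid with a 30 uL
per-pulse hardware limit.

The three phase-1 shapes are glucose-equivalent by construction: the linear
and constant profiles are derived from the exponential one so that the
cumulative glucose fed over phase 1 is identical for a given feed-rate group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROFILES",
    "DesignCondition",
    "RunPlan",
    "FeedPhasePlan",
    "BolusSchedule",
    "load_design_table",
    "expand_design",
    "initial_feed_rate",
    "feed_profile_value",
    "phase2_rate",
    "make_feed_plan",
    "discretize_bolus",
    "build_campaign_schedule",
    "schedule_to_frame",
]

PROFILES = ("exponential", "linear", "constant")

#: 5-min bolus grid in hours.
PULSE_DT_H = 1.0 / 12.0

#: hardware limit on a single bolus (L).
V_MAX_PULSE_L = 30e-6

#: duration of the shaped first feed phase (h).
PHASE1_HOURS = 12.0

N_ROWS, N_COLS = 8, 6


@dataclass(frozen=True)
class DesignCondition:
    """One row of the design table."""

    condition_id: int
    profile: str
    mu_set: float  # set-point specific growth rate, 1/h
    S0: float  # initial glucose, g/L
    hunger_h: float  # no-feed gap after batch end, h

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(
                f"profile must be one of {PROFILES}, got {self.profile!r}"
            )
        if self.mu_set <= 0:
            raise ValueError("mu_set must be > 0")
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")
        if self.hunger_h < 0:
            raise ValueError("hunger_h must be >= 0")


@dataclass
class RunPlan:
    """A single reactor run: condition, replicate, plate slot and feed inputs.

    ``X0_feedstart`` and ``t_batch_end`` default to campaign-level fallback
    values; a simulation (or measurement) pass normally overwrites them with
    the per-reactor biomass at feed start and the observed batch end.
    """

    run_id: int
    condition: DesignCondition
    replicate: int
    plate_position: tuple[int, int]  # (row 1-8, column 1-6)
    V0: float = 0.010  # start volume, L
    X0_feedstart: float = 1.70  # biomass at feed start, g/L (fallback)
    S_in: float = 100.0  # feed stock glucose, g/L
    Y_XS: float = 0.5  # design biomass yield, g/g
    t_batch_end: float = 17.0  # h (fallback; simulator overwrites)

    @property
    def t_feed_start(self) -> float:
        return self.t_batch_end + self.condition.hunger_h


@dataclass(frozen=True)
class FeedPhasePlan:
    """Continuous two-phase feed profile for one run."""

    F0: float  # initial feed rate, L/h
    mu_set: float  # 1/h
    phase1_shape: str
    phase1_duration: float = PHASE1_HOURS  # h
    phase2_rate_override: float | None = None

    @property
    def phase2_rate(self) -> float:
        if self.phase2_rate_override is not None:
            return self.phase2_rate_override
        return phase2_rate(self.mu_set, self.F0, self.phase1_duration)

    @property
    def linear_slope(self) -> float:
        """Slope of the linear shape, L/h^2 (equal-glucose anchored at F0)."""
        mu, T = self.mu_set, self.phase1_duration
        return 2.0 * self.F0 * (_expm1_over_mu(mu, T) - T) / T**2

    @property
    def constant_level(self) -> float:
        """Level of the constant shape = phase-1 time-average of the exponential."""
        return self.F0 * _expm1_over_mu(self.mu_set, self.phase1_duration) / self.phase1_duration


@dataclass
class BolusSchedule:
    """Discretized feed pulses for one run on the shared 5-min grid."""

    run_id: int
    pulse_times: np.ndarray  # h, absolute campaign time
    pulse_volumes: np.ndarray  # L
    S_in: float  # g/L
    clipped_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    saturation_time: float | None = None

    @property
    def total_volume(self) -> float:
        return float(self.pulse_volumes.sum())

    @property
    def total_glucose(self) -> float:
        """Delivered glucose mass, g."""
        return self.total_volume * self.S_in


def _expm1_over_mu(mu: float, T: float) -> float:
    """(e^(mu*T) - 1)/mu, continuous at mu -> 0 (limit T)."""
    if mu == 0.0:
        return T
    return math.expm1(mu * T) / mu


def load_design_table(path=None) -> list[DesignCondition]:
    """Load a design table CSV; defaults to the packaged 16-condition table."""
    if path is None:
        ref = resources.files("mbrkit.data").joinpath("design_conditions.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"condition_id", "profile", "feed_rate_1_per_h", "S0_g_per_L", "hunger_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return [
        DesignCondition(
            condition_id=int(r.condition_id),
            profile=str(r.profile),
            mu_set=float(r.feed_rate_1_per_h),
            S0=float(r.S0_g_per_L),
            hunger_h=float(r.hunger_h),
        )
        for r in df.itertuples()
    ]


def default_feed_stock(mu_set: float) -> float:
    """Feed stock concentration (g/L): concentrated stock for higher rates.

    The higher feed-rate groups use a 500 g/L stock to keep the volume
    increase inside the working volume of the 10 mL reactors; only the lowest
    rate uses the 100 g/L stock.
    """
    return 100.0 if mu_set <= 0.1 else 500.0


def expand_design(
    design_table: Sequence[DesignCondition],
    replicates: int = 3,
    *,
    V0: float = 0.010,
    Y_XS: float = 0.5,
    X0_fallback: float = 1.70,
    t_batch_end_fallback: float = 17.0,
) -> list[RunPlan]:
    """Expand conditions x replicates into sequential RunPlans with plate slots.

    Runs are numbered sequentially (condition-major, replicate-minor) and laid
    out across the 8x6 block filling columns round-robin, so the replicates of
    one condition land in different sampling columns.
    """
    if not design_table:
        raise ValueError("design_table is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = [c.condition_id for c in design_table]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate condition_ids in design table: {dupes}")
    n_total = len(design_table) * replicates
    if n_total > N_ROWS * N_COLS:
        raise ValueError(
            f"{n_total} runs exceed the {N_ROWS}x{N_COLS} reactor block"
        )
    plans: list[RunPlan] = []
    run_id = 1
    for cond in design_table:
        for rep in range(1, replicates + 1):
            idx = run_id - 1
            col = idx % N_COLS + 1
            row = idx // N_COLS + 1
            plans.append(
                RunPlan(
                    run_id=run_id,
                    condition=cond,
                    replicate=rep,
                    plate_position=(row, col),
                    V0=V0,
                    X0_feedstart=X0_fallback,
                    S_in=default_feed_stock(cond.mu_set),
                    Y_XS=Y_XS,
                    t_batch_end=t_batch_end_fallback,
                )
            )
            run_id += 1
    return plans


def initial_feed_rate(
    mu_set: float, S_in: float, Y_XS: float, X0: float, V0: float
) -> float:
    """Initial feed rate F0 = mu_set/(S_in*Y_XS) * X0*V0  (L/h).

    Sized so that, at the design yield, the delivered glucose initially
    supports growth at ``mu_set`` for the biomass amount ``X0*V0``.
    """
    for name, val in (("mu_set", mu_set), ("S_in", S_in), ("Y_XS", Y_XS),
                      ("X0", X0), ("V0", V0)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    return mu_set / (S_in * Y_XS) * X0 * V0


def feed_profile_value(plan: FeedPhasePlan, t: float) -> float:
    """Continuous feed rate (L/h) at time ``t`` (h since feed start)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t >= plan.phase1_duration:
        return plan.phase2_rate
    if plan.phase1_shape == "exponential":
        return plan.F0 * math.exp(plan.mu_set * t)
    if plan.phase1_shape == "linear":
        return plan.F0 + plan.linear_slope * t
    if plan.phase1_shape == "constant":
        return plan.constant_level
    raise ValueError(f"unknown shape {plan.phase1_shape!r}")


def phase2_rate(mu_set: float, F0: float, T: float = PHASE1_HOURS) -> float:
    """Constant second-phase rate shared by all profiles of a feed-rate group.

    Set to the exponential end value F0*e^(mu_set*T) so the exponential
    profile is continuous at the switch; the linear and constant profiles jump
    to the same group rate.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    return F0 * math.exp(mu_set * T)


def make_feed_plan(run: RunPlan, phase1_hours: float = PHASE1_HOURS) -> FeedPhasePlan:
    """Build the continuous feed plan for one run from its design inputs."""
    F0 = initial_feed_rate(
        run.condition.mu_set, run.S_in, run.Y_XS, run.X0_feedstart, run.V0
    )
    return FeedPhasePlan(
        F0=F0,
        mu_set=run.condition.mu_set,
        phase1_shape=run.condition.profile,
        phase1_duration=phase1_hours,
    )


def _phase1_integral(plan: FeedPhasePlan, a: float, b: float) -> float:
    """Exact integral of the phase-1 shape over [a, b] within phase 1."""
    F0, mu = plan.F0, plan.mu_set
    if plan.phase1_shape == "exponential":
        if mu == 0.0:
            return F0 * (b - a)
        return F0 / mu * (math.exp(mu * b) - math.exp(mu * a))
    if plan.phase1_shape == "linear":
        c = plan.linear_slope
        return F0 * (b - a) + 0.5 * c * (b * b - a * a)
    return plan.constant_level * (b - a)


def feed_integral(plan: FeedPhasePlan, a: float, b: float) -> float:
    """Exact integral of the continuous two-phase profile over [a, b] (h since feed start)."""
    if b < a:
        raise ValueError("b must be >= a")
    T = plan.phase1_duration
    total = 0.0
    if a < T:
        total += _phase1_integral(plan, a, min(b, T))
    if b > T:
        total += plan.phase2_rate * (b - max(a, T))
    return total


def discretize_bolus(
    profile: FeedPhasePlan,
    t_feed_start: float,
    t_end: float,
    V_max_pulse: float = V_MAX_PULSE_L,
    dt: float = PULSE_DT_H,
    run_id: int = 0,
    S_in: float = 100.0,
) -> BolusSchedule:
    """Discretize a continuous feed profile into bolus pulses.

    The pulse at grid time t delivers the exact integral of the continuous
    profile over [t, t+dt], clipped at ``V_max_pulse``.  Clipped volume is
    discarded (under-delivery, no carry-over).  Pulse times snap to the
    campaign-wide grid anchored at t=0.
    """
    if t_end <= t_feed_start:
        raise ValueError("t_end must be > t_feed_start")
    # snap feed start up to the shared grid
    k0 = math.ceil(round(t_feed_start / dt, 9))
    k1 = math.floor(round(t_end / dt, 9))
    times, vols, clipped = [], [], []
    saturation_time: float | None = None
    for k in range(k0, k1):
        t_abs = k * dt
        a = t_abs - t_feed_start
        v = feed_integral(profile, a, a + dt)
        is_clipped = v > V_max_pulse
        if is_clipped:
            v = V_max_pulse
            if saturation_time is None:
                saturation_time = t_abs
        times.append(t_abs)
        vols.append(v)
        clipped.append(is_clipped)
    vols_arr = np.asarray(vols, float)
    keep = vols_arr > 0
    return BolusSchedule(
        run_id=run_id,
        pulse_times=np.asarray(times, float)[keep],
        pulse_volumes=vols_arr[keep],
        S_in=S_in,
        clipped_flags=np.asarray(clipped, bool)[keep],
        saturation_time=saturation_time,
    )


def build_campaign_schedule(
    runs: Iterable[RunPlan],
    t_end: float = 48.0,
    *,
    V_max_pulse: float = V_MAX_PULSE_L,
    phase1_hours: float = PHASE1_HOURS,
    dt: float = PULSE_DT_H,
) -> dict[int, BolusSchedule]:
    """Compute bolus schedules for every run on the shared 5-min grid.

    Hunger-phase runs start feeding ``hunger_h`` hours after batch end; the
    gap carries no pulses.
    """
    schedules: dict[int, BolusSchedule] = {}
    for run in runs:
        if run.t_batch_end is None:
            raise ValueError(f"run {run.run_id}: t_batch_end not set")
        plan = make_feed_plan(run, phase1_hours)
        schedules[run.run_id] = discretize_bolus(
            plan,
            run.t_feed_start,
            t_end,
            V_max_pulse=V_max_pulse,
            dt=dt,
            run_id=run.run_id,
            S_in=run.S_in,
        )
    return schedules


def schedule_to_frame(schedules: dict[int, BolusSchedule]) -> pd.DataFrame:
    """Long-format export: run_id, time_h, pulse_volume_uL, clipped."""
    rows = []
    for rid in sorted(schedules):
        s = schedules[rid]
        for t, v, c in zip(s.pulse_times, s.pulse_volumes, s.clipped_flags):
            rows.append((rid, t, v * 1e6, bool(c)))
    return pd.DataFrame(rows, columns=["run_id", "time_h", "pulse_volume_uL", "clipped"])
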
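"""Synthetic 48-run campaign generator: yeast fed-batch with overflow metabolism.

The kinetic skeleton is a Sonnleitner-Kappeli-style respiratory-bottleneck
model for a Crabtree-positive yeast secreting a recombinant pectinase (EPG):
glucose uptake up to a critical respiratory capacity is oxidized at a high
yield; excess flux overflows to ethanol at a fermentative yield.  Ethanol is
re-consumed once glucose is low (glucose repression), slower and with its own
yield.  Product formation follows a growth-rate optimum curve with a late
decline, and an ethanol-stress term suppresses production in high-feed runs.
After ~36 h the cultures enter growth stagnation.

Default parameters are calibrated so that a noiseless batch reproduces the
reference batch-phase physiology (specific growth rate, glucose uptake rate
and biomass at feed start) when read back through the finite-difference rate
estimators in :mod:`mbrkit.preprocess`.  The generator is an emulation: DOT is
a quasi-steady display variable, pH is a one-sided-controlled drift, and no
off-gas, organic-acid or thermal dynamics are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    PULSE_DT_H,
    BolusSchedule,
    DesignCondition,
    RunPlan,
    build_campaign_schedule,
    expand_design,
)

__all__ = [
    "KineticParams",
    "RunTrajectory",
    "CampaignDataset",
    "MEASURED_VARIABLES",
    "simulate_run",
    "simulate_batch_phase",
    "sampling_schedule",
    "sample_measurements",
    "inject_sensor_failure",
    "generate_campaign",
]

#: variables appearing in measurement tables
MEASURED_VARIABLES = (
    "biomass", "glucose", "ethanol", "EAv", "pH", "DOT", "volume", "base",
)

ETHANOL_DETECTION_LIMIT = 1.0  # g/L after the mandatory 1:1 dilution


def _default_noise() -> dict[str, float]:
    # relative sd per variable; pH is additive (absolute sd)
    return {
        "biomass": 0.05,
        "glucose": 0.07,
        "ethanol": 0.08,
        "EAv": 0.10,
        "pH": 0.02,
        "DOT": 0.03,
        "volume": 0.01,
        "base": 0.02,
    }


@dataclass
class KineticParams:
    """Kinetic, transfer and observation parameters of the campaign emulator.

    Rates are specific (per g dry biomass), concentrations in g/L, times in h,
    volumes in L.  Yields: ``Y_XS_ox``/``Y_XS_ferm`` are biomass per glucose
    for the oxidative and overflow routes, ``Y_ES`` ethanol per overflow
    glucose, ``Y_XE`` biomass per ethanol.
    """

    # glucose uptake and overflow split
    qS_max: float = 1.61  # g/g/h, saturated uptake
    K_S: float = 0.1  # g/L
    qS_crit: float = 0.90  # g/g/h, respiratory capacity bound
    Y_XS_ox: float = 0.118  # g/g
    Y_XS_ferm: float = 0.045  # g/g
    Y_ES: float = 0.48  # g ethanol / g overflow glucose
    # ethanol re-consumption
    qE_max: float = 0.45  # g/g/h
    K_E: float = 0.5  # g/L
    K_I_S: float = 0.05  # g/L, glucose repression of ethanol uptake
    Y_XE: float = 0.30  # g/g
    # ethanol stress on glucose uptake (inactive below E_inhib_S)
    E_inhib_S: float = 10.0  # g/L threshold
    E_inhib_scale: float = 5.0  # g/L width
    # ethanol stress on biomass yield (inactive below E_inhib_Y)
    E_inhib_Y: float = 5.0  # g/L threshold
    K_IE_Y: float = 3.0  # g/L width
    # product (EPG) formation
    qP_max: float = 250.0  # U/g/h
    mu_opt_P: float = 0.045  # 1/h, production optimum
    t_decline: float = 8.0  # h after batch end: onset of late productivity decay
    k_decline: float = 0.20  # 1/h
    K_IE_P: float = 1.5  # g/L, ethanol inhibition of production
    # growth stagnation (30-40 h window)
    k_stagnation: float = 36.0  # h, onset midpoint
    stagnation_width: float = 2.0  # h
    stagnation_floor: float = 0.05
    # oxygen / DOT display model
    kLa: float = 400.0  # 1/h
    cO2_sat: float = 0.0075  # g/L
    Y_OS: float = 0.40  # g O2 / g glucose (oxidative)
    Y_OE: float = 1.95  # g O2 / g ethanol
    # volume bookkeeping
    evap_rate: float = 4e-6  # L/h
    base_per_gX: float = 1.6e-3  # L base / g biomass formed
    sample_volume: float = 250e-6  # L per withdrawal
    # pH display model (one-sided control at 6.0, late upward drift whose
    # onset follows the feeding response: later at lower feed rates)
    pH_set: float = 6.0
    pH_drift_rate: float = 0.012  # 1/h
    pH_drift_lag: float = 3.0  # h after feed start
    pH_drift_rate_scale: float = 0.5  # h * (set rate): extra lag 1/mu_set
    # inoculation and conversions
    OD_inoculum: float = 0.3
    od_to_gdw: float = 0.55  # g/L dry weight per OD600
    batch_end_S: float = 0.05  # g/L threshold defining batch end
    # observation noise (relative sd; pH absolute)
    noise: dict = field(default_factory=_default_noise)

    def __post_init__(self) -> None:
        if self.Y_XS_ferm >= self.Y_XS_ox:
            raise ValueError("Y_XS_ferm must be < Y_XS_ox")
        for name in ("qS_max", "K_S", "qS_crit", "Y_XS_ox", "Y_XS_ferm",
                     "Y_ES", "qE_max", "K_E", "K_I_S", "Y_XE", "qP_max",
                     "mu_opt_P", "od_to_gdw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def X_inoculum(self) -> float:
        """Initial biomass concentration, g/L."""
        return self.OD_inoculum * self.od_to_gdw

    def noiseless(self) -> "KineticParams":
        return replace(self, noise={k: 0.0 for k in self.noise})

    def stagnation(self, t: float) -> float:
        f = self.stagnation_floor
        z = (t - self.k_stagnation) / self.stagnation_width
        # logistic decline from 1 to the floor
        if z > 40:
            return f
        return f + (1.0 - f) / (1.0 + math.exp(z))


@dataclass
class SimInputs:
    """Everything needed to reproduce a trajectory (kept for re-simulation)."""

    plan: RunPlan
    schedule: BolusSchedule | None
    params: KineticParams
    dt: float
    t_end: float
    sample_times: np.ndarray | None
    growth_factor: float = 1.0


@dataclass
class RunTrajectory:
    """Dense simulated state of one cultivation."""

    run_id: int
    t: np.ndarray  # h
    X: np.ndarray  # g/L
    S: np.ndarray  # g/L
    E: np.ndarray  # g/L
    V: np.ndarray  # L, true broth volume
    V_dil: np.ndarray  # L, dilution volume excluding sample withdrawals
    EAv: np.ndarray  # U/mL
    DOT: np.ndarray  # % air saturation
    pH: np.ndarray
    cum_base: np.ndarray  # L
    cum_feed: np.ndarray  # L
    cum_evap: np.ndarray  # L
    cum_sample: np.ndarray  # L
    consumed_S: np.ndarray  # g, cumulative glucose consumed by cells
    fed_S: np.ndarray  # g, cumulative glucose delivered
    events: list = field(default_factory=list)
    t_batch_end: float | None = None
    t_feed_start: float | None = None
    inputs: SimInputs | None = None
    failure_mode: str | None = None

    def value(self, variable: str, times) -> np.ndarray:
        """Linear interpolation of a named variable at ``times``."""
        arr = {
            "biomass": self.X, "glucose": self.S, "ethanol": self.E,
            "EAv": self.EAv, "pH": self.pH, "DOT": self.DOT,
            "volume": self.V, "base": self.cum_base,
        }.get(variable)
        if arr is None:
            raise KeyError(f"unknown variable {variable!r}")
        return np.interp(np.asarray(times, float), self.t, arr)


def simulate_run(
    plan: RunPlan,
    schedule: BolusSchedule | None,
    params: KineticParams,
    dt: float = 1.0 / 240.0,
    t_end: float = 48.0,
    sample_times: Sequence[float] | None = None,
    growth_factor: float = 1.0,
) -> RunTrajectory:
    """Integrate one cultivation with explicit Euler steps and impulse events.

    Feed pulses and sample withdrawals are applied as impulses on the step
    grid (``dt`` must divide the 5-min pulse spacing).  Mass bookkeeping uses
    totals (g) so that the glucose balance S0*V0 + fed = consumed + residual
    holds to float precision, and evaporation concentrates while withdrawals
    leave concentrations untouched.

    ``growth_factor`` < 1 emulates a degraded culture (used by the sensor
    failure injector).
    """
    if dt > PULSE_DT_H + 1e-12:
        raise ValueError("dt must not exceed the 5-min pulse spacing")
    n_sub = round(PULSE_DT_H / dt)
    if abs(n_sub * dt - PULSE_DT_H) > 1e-9:
        raise ValueError("dt must divide the 5-min pulse spacing evenly")
    p = params
    n_steps = int(round(t_end / dt))
    # impulse lookup tables keyed by step index
    pulses: dict[int, float] = {}
    if schedule is not None:
        for tp, vp in zip(schedule.pulse_times, schedule.pulse_volumes):
            pulses[int(round(tp / dt))] = pulses.get(int(round(tp / dt)), 0.0) + vp
    samples: dict[int, float] = {}
    if sample_times is not None:
        for ts in sample_times:
            if ts <= t_end:
                k = int(round(ts / dt))
                samples[k] = samples.get(k, 0.0) + p.sample_volume
    S_in = schedule.S_in if schedule is not None else plan.S_in

    V = plan.V0
    V_dil = plan.V0
    mX = p.X_inoculum * V
    mS = plan.condition.S0 * V
    mE = 0.0
    aP = 0.0  # total product, U
    c_base = c_feed = c_evap = c_sample = 0.0
    c_cons = c_fed = 0.0

    m = n_steps + 1
    out = {k: np.empty(m) for k in
           ("t", "X", "S", "E", "V", "V_dil", "EAv", "DOT", "pH",
            "cum_base", "cum_feed", "cum_evap", "cum_sample",
            "consumed_S", "fed_S")}
    events: list[tuple[float, str]] = []
    t_batch_end = None

    otr_max = p.kLa * p.cO2_sat
    ph_onset = (plan.t_feed_start + p.pH_drift_lag
                + p.pH_drift_rate_scale / plan.condition.mu_set)
    # productivity decline is anchored to the culture's batch end (its
    # physiological age), not to absolute campaign time
    decline_onset = plan.t_batch_end + p.t_decline

    for i in range(n_steps + 1):
        t = i * dt
        X = mX / V
        S = mS / V
        E = mE / V
        # --- kinetic rates ---
        stag = p.stagnation(t)
        e_exc = E - p.E_inhib_S
        einh = 1.0 / (1.0 + (e_exc / p.E_inhib_scale) ** 2) if e_exc > 0 else 1.0
        qS = p.qS_max * S / (p.K_S + S) * einh * stag
        qE = (p.qE_max * E / (p.K_E + E) * p.K_I_S / (p.K_I_S + S) * stag)
        if i < n_steps and mX > 0:
            # limit rates so totals stay non-negative over this step
            qS = min(qS, mS / (mX * dt))
            qE = min(qE, mE / (mX * dt))
        qS_ox = min(qS, p.qS_crit)
        qS_of = qS - qS_ox
        # ethanol stress cuts the biomass yields above E_inhib_Y
        e_y = E - p.E_inhib_Y
        yinh = 1.0 / (1.0 + e_y / p.K_IE_Y) if e_y > 0 else 1.0
        mu = (p.Y_XS_ox * qS_ox + p.Y_XS_ferm * qS_of
              + p.Y_XE * qE) * yinh * growth_factor
        decay = math.exp(-p.k_decline * max(0.0, t - decline_onset))
        mu_rel = mu / p.mu_opt_P
        qP = (p.qP_max * mu_rel * math.exp(1.0 - mu_rel) * decay
              * p.K_IE_P / (p.K_IE_P + E) * stag) if mu > 0 else 0.0
        # --- display variables ---
        our = (p.Y_OS * qS_ox + p.Y_OE * qE) * X * growth_factor
        dot = 100.0 * max(0.0, 1.0 - our / otr_max)
        ph = p.pH_set + p.pH_drift_rate * max(0.0, t - ph_onset)
        # --- record ---
        o = out
        o["t"][i] = t
        o["X"][i] = X
        o["S"][i] = S
        o["E"][i] = E
        o["V"][i] = V
        o["V_dil"][i] = V_dil
        o["EAv"][i] = aP / (V * 1e3)  # U per mL
        o["DOT"][i] = dot
        o["pH"][i] = ph
        o["cum_base"][i] = c_base
        o["cum_feed"][i] = c_feed
        o["cum_evap"][i] = c_evap
        o["cum_sample"][i] = c_sample
        o["consumed_S"][i] = c_cons
        o["fed_S"][i] = c_fed
        if t_batch_end is None and S < p.batch_end_S:
            t_batch_end = t
            events.append((t, "batch_end"))
        if i == n_steps:
            break
        # --- integrate one step ---
        dS_cons = qS * mX * dt
        mS -= dS_cons
        c_cons += dS_cons
        mE += (p.Y_ES * qS_of - qE) * mX * dt
        aP += qP * mX * dt
        mX += mu * mX * dt
        # base addition tracks growth (ammonia titration against acidification)
        db = p.base_per_gX * mu * mX * dt
        V += db
        V_dil += db
        c_base += db
        dev = p.evap_rate * dt
        V -= dev
        V_dil -= dev
        c_evap += dev
        # impulses at the *end* of the step land on index i+1 times
        j = i + 1
        if j in pulses:
            vp = pulses[j]
            V += vp
            V_dil += vp
            mS += vp * S_in
            c_feed += vp
            c_fed += vp * S_in
        if j in samples:
            vs = min(samples[j], 0.5 * V)
            frac = 1.0 - vs / V
            mX *= frac
            mS *= frac
            mE *= frac
            aP *= frac
            V -= vs
            c_sample += vs
            events.append((j * dt, "sample"))
        if min(mX, mS, mE, V) < -1e-12:
            raise RuntimeError(
                f"negative state at t={t:.3f} h (run {plan.run_id}); reduce dt"
            )
        mS = max(mS, 0.0)
        mE = max(mE, 0.0)

    traj = RunTrajectory(
        run_id=plan.run_id,
        events=events,
        t_batch_end=t_batch_end,
        t_feed_start=(None if t_batch_end is None
                      else t_batch_end + plan.condition.hunger_h),
        inputs=SimInputs(plan, schedule, params, dt, t_end,
                         None if sample_times is None
                         else np.asarray(sample_times, float),
                         growth_factor),
        **out,
    )
    return traj


def simulate_batch_phase(
    plan: RunPlan, params: KineticParams, dt: float = 1.0 / 240.0,
    t_max: float = 40.0,
) -> RunTrajectory:
    """Unfed simulation long enough to cover batch end plus any hunger phase."""
    traj = simulate_run(plan, None, params, dt=dt, t_end=t_max)
    if traj.t_batch_end is None:
        raise RuntimeError(
            f"run {plan.run_id}: glucose not exhausted within {t_max} h"
        )
    return traj


def sampling_schedule(
    runs: Sequence[RunPlan],
    t_feed_start: float,
    batch_column_offset_min: float = 5.0,
    fedbatch_column_interval_min: float = 20.0,
    t_end: float = 48.0,
    batch_round_h: float = 2.0,
) -> dict[int, np.ndarray]:
    """Staggered column-wise sampling times for every reactor.

    Batch phase: sampling rounds every ``batch_round_h``; within a round the
    columns are visited with ``batch_column_offset_min`` offsets.  Fed-batch
    (from the campaign-wide ``t_feed_start``): column c is visited at
    ``t_feed_start + (c-1)*interval + k*(n_cols*interval)``, so each reactor
    is sampled with a constant period of n_cols * interval (2 h for 6 columns
    at 20 min).
    """
    cols = sorted({r.plate_position[1] for r in runs})
    n_cols = len(cols)
    off_b = batch_column_offset_min / 60.0
    off_f = fedbatch_column_interval_min / 60.0
    period = n_cols * off_f
    times_by_col: dict[int, list[float]] = {c: [] for c in cols}
    for ci, c in enumerate(cols):
        # batch rounds strictly before the fed-batch switchover
        tr = batch_round_h
        while tr < t_feed_start:
            tc = tr + ci * off_b
            if tc < t_feed_start:
                times_by_col[c].append(tc)
            tr += batch_round_h
        if t_end >= t_feed_start:
            tc = t_feed_start + ci * off_f
            while tc <= t_end:
                times_by_col[c].append(tc)
                tc += period
    return {
        r.run_id: np.asarray(times_by_col[r.plate_position[1]], float)
        for r in runs
    }


def sample_measurements(
    traj: RunTrajectory,
    times: Sequence[float],
    params: KineticParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """At-line observation model: staggered noisy samples in long format.

    Multiplicative Gaussian noise per variable (additive for pH); in the
    fed-batch phase biomass/glucose are measured in duplicate and EPG activity
    in triplicate.  Ethanol below the detection limit is reported left-
    censored at the limit.  Returns columns
    ``run_id, time_h, variable, value, replicate, censored``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    times = np.asarray(times, float)
    bad = times[(times < traj.t[0] - 1e-9) | (times > traj.t[-1] + 1e-9)]
    if bad.size:
        raise ValueError(f"sample times outside trajectory span: {bad.tolist()}")
    t_fs = traj.t_feed_start if traj.t_feed_start is not None else np.inf
    rows = []
    for tt in times:
        fedbatch = tt >= t_fs
        for var in MEASURED_VARIABLES:
            true = float(traj.value(var, tt))
            if var in ("biomass", "glucose") and fedbatch:
                n_rep = 2
            elif var == "EAv" and fedbatch:
                n_rep = 3
            else:
                n_rep = 1
            sd = params.noise.get(var, 0.0)
            for rep in range(1, n_rep + 1):
                if var == "pH":
                    val = true + sd * rng.standard_normal()
                else:
                    val = true * (1.0 + sd * rng.standard_normal())
                val = max(val, 0.0)
                censored = False
                if var == "ethanol" and val < ETHANOL_DETECTION_LIMIT:
                    val = ETHANOL_DETECTION_LIMIT
                    censored = True
                rows.append((traj.run_id, tt, var, val, rep, censored))
    return pd.DataFrame(
        rows,
        columns=["run_id", "time_h", "variable", "value", "replicate", "censored"],
    )


def inject_sensor_failure(
    traj: RunTrajectory,
    mode: str = "pH_DOT_failure",
    onset: float = 0.5,
    seed: int | np.random.Generator = 0,
    growth_factor: float = 0.55,
) -> RunTrajectory:
    """Emulate a run with failed pH/DOT probes and degraded culture handling.

    From ``onset`` the pH reading drifts upward and sticks high while the DOT
    reading flatlines with sensor jitter; because the mis-read signals drove
    wrong handling, the culture itself is degraded (growth multiplied by
    ``growth_factor``), so the run is multivariately abnormal from early on.
    """
    if mode != "pH_DOT_failure":
        raise ValueError(f"unknown failure mode {mode!r}")
    if traj.inputs is None:
        raise ValueError("trajectory carries no inputs; cannot re-simulate")
    if onset > traj.t[-1]:
        return traj
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    inp = traj.inputs
    bad = simulate_run(
        inp.plan, inp.schedule, inp.params, dt=inp.dt, t_end=inp.t_end,
        sample_times=inp.sample_times, growth_factor=growth_factor,
    )
    after = bad.t >= onset
    n_after = int(after.sum())
    tau = bad.t[after] - onset
    bad.pH = bad.pH.copy()
    bad.DOT = bad.DOT.copy()
    bad.pH[after] = (
        inp.params.pH_set + 0.9 * (1.0 - np.exp(-tau / 3.0))
        + 0.02 * rng.standard_normal(n_after)
    )
    bad.DOT[after] = np.clip(
        98.0 - 0.05 * tau + 1.5 * rng.standard_normal(n_after), 0.0, 100.0
    )
    bad.failure_mode = mode
    bad.events.append((onset, "sensor_failure"))
    return bad


@dataclass
class CampaignDataset:
    """Full synthetic campaign: plans, schedules, ground truth and measurements."""

    plans: list[RunPlan]
    schedules: dict[int, BolusSchedule]
    trajectories: dict[int, RunTrajectory]
    sample_times: dict[int, np.ndarray]
    measurements: pd.DataFrame
    params: KineticParams
    seed: int
    failure_run: int | None

    @property
    def run_ids(self) -> list[int]:
        return [p.run_id for p in self.plans]

    def design_factors(self) -> pd.DataFrame:
        """Per-run design factor table (profile, mu_set, S0, hunger)."""
        rows = [
            (p.run_id, p.condition.condition_id, p.condition.profile,
             p.condition.mu_set, p.condition.S0, p.condition.hunger_h)
            for p in self.plans
        ]
        return pd.DataFrame(
            rows,
            columns=["run_id", "condition_id", "profile", "mu_set", "S0", "hunger_h"],
        ).set_index("run_id")


def generate_campaign(
    design_table: Sequence[DesignCondition],
    params: KineticParams | None = None,
    seed: int = 0,
    replicates: int = 3,
    t_end: float = 48.0,
    dt: float = 1.0 / 240.0,
    failure_run: int | None = 46,
    failure_onset: float = 0.5,
) -> CampaignDataset:
    """Simulate the full campaign: design -> schedules -> runs -> measurements.

    The batch phase depends only on (S0, hunger), so batch pre-simulations are
    cached per group to set each run's biomass at feed start and batch end
    before computing feed schedules.  All randomness derives from ``seed`` via
    named per-run substreams.
    """
    params = params or KineticParams()
    plans = expand_design(design_table, replicates)
    # batch pre-simulation per (S0, hunger) group
    batch_cache: dict[tuple[float, float], RunTrajectory] = {}
    for plan in plans:
        key = (plan.condition.S0, plan.condition.hunger_h)
        if key not in batch_cache:
            batch_cache[key] = simulate_batch_phase(plan, params, dt=dt)
        bt = batch_cache[key]
        plan.t_batch_end = float(bt.t_batch_end)
        t_fs = bt.t_batch_end + plan.condition.hunger_h
        plan.X0_feedstart = float(bt.value("biomass", t_fs))
    schedules = build_campaign_schedule(plans, t_end=t_end)
    campaign_feed_start = max(p.t_feed_start for p in plans)
    sample_times = sampling_schedule(plans, campaign_feed_start, t_end=t_end)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(plans) * 2)
    trajectories: dict[int, RunTrajectory] = {}
    tables = []
    for k, plan in enumerate(plans):
        traj = simulate_run(
            plan, schedules[plan.run_id], params, dt=dt, t_end=t_end,
            sample_times=sample_times[plan.run_id],
        )
        if failure_run is not None and plan.run_id == failure_run:
            traj = inject_sensor_failure(
                traj, onset=failure_onset,
                seed=np.random.default_rng(children[2 * k + 1]),
            )
        trajectories[plan.run_id] = traj
        tables.append(
            sample_measurements(
                traj, sample_times[plan.run_id], params,
                np.random.default_rng(children[2 * k]),
            )
        )
    measurements = pd.concat(tables, ignore_index=True)
    return CampaignDataset(
        plans=plans,
        schedules=schedules,
        trajectories=trajectories,
        sample_times=sample_times,
        measurements=measurements,
        params=params,
        seed=seed,
        failure_run=failure_run,
    )
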
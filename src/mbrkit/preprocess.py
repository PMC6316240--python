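"""Measurement-table preprocessing: normalization, specific rates, unfolding.

Turns long-format at-line measurement tables into (i) volume-normalized
biomass series, (ii) finite-difference specific rates (growth, substrate
uptake, product formation) and (iii) the rectangular batch-wise-unfolded
matrix (runs x (variable, time) columns) consumed by the multivariate stages.

Biomass is normalized to the start volume considering evaporation and the
dilution by feed and base addition; sample withdrawals are excluded from the
normalizing volume because they remove culture without diluting it.  All
other variables are left unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedSeries",
    "RateSeries",
    "UnfoldedMatrix",
    "normalize_biomass",
    "specific_rates",
    "align_to_grid",
    "batch_wise_unfold",
    "refold",
    "autoscale",
    "dilution_volume_history",
    "grid_campaign",
]


@dataclass
class NormalizedSeries:
    """Volume-normalized biomass of one run: X_N = X * V_dil / V0."""

    run_id: int
    times: np.ndarray  # h
    X_N: np.ndarray  # g/L
    X_raw: np.ndarray  # g/L
    V_used: np.ndarray  # L, dilution volume at each time


@dataclass
class RateSeries:
    """Finite-difference specific rates on consecutive sample-pair midpoints."""

    run_id: int
    midpoints: np.ndarray  # h
    mu: np.ndarray  # 1/h (NaN where undefined)
    qS: np.ndarray  # g/g/h, consumption positive
    qP: np.ndarray  # U/g/h


@dataclass
class UnfoldedMatrix:
    """Batch-wise-unfolded data block: one row per run.

    Columns are (variable, grid-time) pairs ordered variable-major,
    time-minor.  ``col_mean``/``col_sd`` hold autoscaling metadata (n-1
    denominator); ``constant_cols`` flags columns with zero variance that were
    set to 0 by :func:`autoscale`.
    """

    values: np.ndarray  # (n_runs, n_cols)
    run_ids: list
    columns: list  # [(variable, time_h)]
    scaled: bool = False
    col_mean: np.ndarray | None = None
    col_sd: np.ndarray | None = None
    constant_cols: np.ndarray | None = None
    horizon: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def variables(self) -> list:
        seen = []
        for v, _ in self.columns:
            if v not in seen:
                seen.append(v)
        return seen

    def grid(self) -> np.ndarray:
        v0 = self.columns[0][0]
        return np.asarray([t for v, t in self.columns if v == v0], float)

    def truncate(self, horizon: float) -> "UnfoldedMatrix":
        """Column subset with grid times <= horizon (prefix per variable block)."""
        keep = [i for i, (_, t) in enumerate(self.columns) if t <= horizon + 1e-9]
        return UnfoldedMatrix(
            values=self.values[:, keep],
            run_ids=list(self.run_ids),
            columns=[self.columns[i] for i in keep],
            scaled=self.scaled,
            col_mean=None if self.col_mean is None else self.col_mean[keep],
            col_sd=None if self.col_sd is None else self.col_sd[keep],
            constant_cols=(None if self.constant_cols is None
                           else self.constant_cols[keep]),
            horizon=horizon,
        )

    def drop_runs(self, run_ids: Iterable) -> "UnfoldedMatrix":
        drop = set(run_ids)
        keep = [i for i, r in enumerate(self.run_ids) if r not in drop]
        return replace(
            self,
            values=self.values[keep],
            run_ids=[self.run_ids[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["variable", "time_h"])
        return pd.DataFrame(self.values, index=self.run_ids, columns=cols)


def normalize_biomass(
    raw: pd.DataFrame,
    volume_history: Mapping[int, tuple[np.ndarray, np.ndarray]],
    V0: float = 0.010,
) -> list[NormalizedSeries]:
    """Normalize biomass to the start volume: X_N(t) = X(t) * V_dil(t) / V0.

    ``volume_history`` maps run_id to (times, dilution volume) arrays; the
    dilution volume accounts for feed, base and evaporation but not sample
    withdrawals.  Duplicate determinations are averaged first.  Other
    variables are not normalized and are simply not part of the output.
    """
    out = []
    bio = raw[raw["variable"] == "biomass"]
    for run_id, grp in bio.groupby("run_id"):
        if run_id not in volume_history:
            raise ValueError(f"no volume history for run {run_id}")
        vt, vv = volume_history[run_id]
        agg = grp.groupby("time_h")["value"].mean()
        times = agg.index.to_numpy(float)
        lo, hi = vt[0] - 1e-9, vt[-1] + 1e-9
        missing = times[(times < lo) | (times > hi)]
        if missing.size:
            raise ValueError(
                f"run {run_id}: volume unknown at times {missing.tolist()}"
            )
        V = np.interp(times, vt, vv)
        X = agg.to_numpy(float)
        out.append(NormalizedSeries(run_id=int(run_id), times=times,
                                    X_N=X * V / V0, X_raw=X, V_used=V))
    return out


def specific_rates(series: pd.DataFrame, run_id: int = 0) -> RateSeries:
    """Finite-difference specific rates over consecutive sample pairs.

    ``series`` needs a ``time_h`` column plus any of ``X_N`` (normalized
    biomass, for mu), ``S`` (glucose) and ``EAv`` (volumetric activity,
    U/mL); ``X`` (raw biomass) is required for qS/qP.  Rates per pair
    (t1, t2):

    * mu = (ln X_N2 - ln X_N1) / (t2 - t1)
    * qS = (S1 - S2) / ((t2 - t1) * mean(X1, X2))     [consumption positive]
    * qP = (EAv2 - EAv1) * 1000 / ((t2 - t1) * mean(X1, X2))  [U/g/h]

    Undefined values (non-positive biomass for mu) are returned as NaN, not
    dropped, so the midpoint grid stays aligned.
    """
    if "time_h" not in series.columns:
        raise ValueError("series must have a time_h column")
    s = series.sort_values("time_h")
    t = s["time_h"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing times; average duplicates first")
    mid = 0.5 * (t[:-1] + t[1:])
    n = len(mid)
    mu = np.full(n, np.nan)
    qS = np.full(n, np.nan)
    qP = np.full(n, np.nan)
    if "X_N" in s.columns:
        xn = s["X_N"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            valid = (xn[:-1] > 0) & (xn[1:] > 0)
            mu[valid] = (np.log(xn[1:]) - np.log(xn[:-1]))[valid] / dt[valid]
    if "X" in s.columns:
        x = s["X"].to_numpy(float)
        xbar = 0.5 * (x[:-1] + x[1:])
        if "S" in s.columns:
            sv = s["S"].to_numpy(float)
            ok = xbar > 0
            qS[ok] = (sv[:-1] - sv[1:])[ok] / (dt[ok] * xbar[ok])
        if "EAv" in s.columns:
            ea = s["EAv"].to_numpy(float)
            ok = xbar > 0
            qP[ok] = (ea[1:] - ea[:-1])[ok] * 1e3 / (dt[ok] * xbar[ok])
    return RateSeries(run_id=run_id, midpoints=mid, mu=mu, qS=qS, qP=qP)


def align_to_grid(
    table: pd.DataFrame,
    grid_step: float = 2.0,
    horizon: float = 48.0,
    variables: Sequence[str] | None = None,
    censored_at_half: bool = False,
    grid_start: float = 0.0,
    time_offsets: Mapping[int, float] | None = None,
) -> dict[int, pd.DataFrame]:
    """Rectangularize staggered samples by linear interpolation onto a grid.

    Duplicate determinations at one time are averaged first; censored ethanol
    enters at the detection limit (or half of it with ``censored_at_half``).
    No extrapolation: values beyond the first/last sample hold the boundary
    value.  Returns one DataFrame (index: grid times, columns: variables) per
    run.

    ``time_offsets`` (run_id -> t0) switches to landmark-aligned gridding:
    each run's sample times are shifted to t - t0 before interpolation, so
    the grid is in hours relative to the landmark (e.g. feed start) and may
    start negative via ``grid_start``.  Aligning trajectories on a process
    landmark is the standard remedy for unequal batch lengths in batch-wise
    MSPC.
    """
    grid = np.round(np.arange(grid_start, horizon + 1e-9, grid_step), 9)
    if variables is None:
        variables = list(dict.fromkeys(table["variable"]))
    table = table.copy()
    if censored_at_half and "censored" in table.columns:
        cen = table["censored"].astype(bool)
        table.loc[cen, "value"] = table.loc[cen, "value"] * 0.5
    out: dict[int, pd.DataFrame] = {}
    for run_id, grp in table.groupby("run_id"):
        if time_offsets is not None:
            if run_id not in time_offsets:
                raise ValueError(f"no alignment offset for run {run_id}")
            grp = grp.assign(time_h=grp["time_h"] - time_offsets[run_id])
        cols = {}
        for var in variables:
            sub = grp[grp["variable"] == var]
            if sub.empty:
                raise ValueError(f"run {run_id}: variable {var!r} absent")
            agg = sub.groupby("time_h")["value"].mean()
            tt = agg.index.to_numpy(float)
            vv = agg.to_numpy(float)
            if len(tt) < 2:
                raise ValueError(
                    f"run {run_id}: variable {var!r} has <2 samples in horizon"
                )
            cols[var] = np.interp(grid, tt, vv)
        out[int(run_id)] = pd.DataFrame(cols, index=grid)
    return out


def batch_wise_unfold(
    campaign: Mapping[int, pd.DataFrame],
    variables: Sequence[str] | None = None,
    horizon: float | None = None,
) -> UnfoldedMatrix:
    """Unfold gridded per-run series into a runs x (variable, time) matrix.

    Rows span runs; columns are ordered variable-major, time-minor:
    (v1,t1), (v1,t2), ..., (v2,t1), ...  All runs must share the grid and
    variable set.
    """
    run_ids = sorted(campaign)
    if not run_ids:
        raise ValueError("empty campaign")
    first = campaign[run_ids[0]]
    grid = first.index.to_numpy(float)
    if variables is None:
        variables = list(first.columns)
    if horizon is not None:
        grid = grid[grid <= horizon + 1e-9]
    rows = []
    for rid in run_ids:
        df = campaign[rid]
        if not np.array_equal(df.index.to_numpy(float)[: len(grid)], grid):
            raise ValueError(f"run {rid}: grid mismatch (ragged input)")
        missing = [v for v in variables if v not in df.columns]
        if missing:
            raise ValueError(f"run {rid}: missing variables {missing}")
        rows.append(
            np.concatenate([df[v].to_numpy(float)[: len(grid)] for v in variables])
        )
    columns = [(v, float(t)) for v in variables for t in grid]
    return UnfoldedMatrix(
        values=np.vstack(rows), run_ids=run_ids, columns=columns,
        horizon=horizon if horizon is not None else float(grid[-1]),
    )


def refold(m: UnfoldedMatrix) -> dict[int, pd.DataFrame]:
    """Inverse of :func:`batch_wise_unfold` (exact round trip)."""
    variables = m.variables()
    grid = m.grid()
    n_t = len(grid)
    out = {}
    for i, rid in enumerate(m.run_ids):
        row = m.values[i]
        out[rid] = pd.DataFrame(
            {v: row[j * n_t:(j + 1) * n_t] for j, v in enumerate(variables)},
            index=grid,
        )
    return out


def autoscale(m: UnfoldedMatrix) -> UnfoldedMatrix:
    """Center and scale each column to unit variance (n-1 denominator).

    Constant columns cannot be scaled; they are set to 0 and flagged.
    Already-scaled input is returned re-scaled (idempotent within float
    precision).
    """
    if m.values.shape[0] < 2:
        raise ValueError("autoscaling needs >= 2 rows (sd undefined)")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    safe_sd = np.where(constant, 1.0, sd)
    vals = (m.values - mean) / safe_sd
    vals[:, constant] = 0.0
    return UnfoldedMatrix(
        values=vals, run_ids=list(m.run_ids), columns=list(m.columns),
        scaled=True, col_mean=mean, col_sd=sd, constant_cols=constant,
        horizon=m.horizon,
    )


def dilution_volume_history(campaign) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-run (times, dilution volume) from ground-truth trajectories."""
    return {
        rid: (tr.t, tr.V_dil) for rid, tr in campaign.trajectories.items()
    }


def grid_campaign(
    campaign,
    variables: Sequence[str] = ("biomass", "glucose", "ethanol", "pH", "DOT",
                                "volume", "base"),
    grid_step: float = 2.0,
    horizon: float = 48.0,
    normalize: bool = True,
    censored_at_half: bool = False,
    align: str | None = None,
    grid_start: float = 0.0,
) -> dict[int, pd.DataFrame]:
    """Measurement tables -> gridded per-run series ready for unfolding.

    With ``normalize`` the biomass column is replaced by the volume-normalized
    X_N before interpolation.  ``align='feed_start'`` (or ``'batch_end'``)
    grids each run on time relative to that landmark (``grid_start`` may be
    negative), which lines up the feeding responses of runs whose batch
    phases end at different times.
    """
    table = campaign.measurements
    if normalize and "biomass" in variables:
        vh = dilution_volume_history(campaign)
        V0 = campaign.plans[0].V0
        table = table.copy()
        normed = {s.run_id: s for s in normalize_biomass(table, vh, V0=V0)}
        # replace biomass values by X_N (matching on run and time)
        is_bio = table["variable"] == "biomass"
        def _xn(row):
            s = normed[row["run_id"]]
            i = np.searchsorted(s.times, row["time_h"])
            i = min(i, len(s.times) - 1)
            scale = s.X_N[i] / s.X_raw[i] if s.X_raw[i] > 0 else 1.0
            return row["value"] * scale
        table.loc[is_bio, "value"] = table[is_bio].apply(_xn, axis=1)
    offsets = None
    if align is not None:
        if align == "feed_start":
            offsets = {p.run_id: p.t_feed_start for p in campaign.plans}
        elif align == "batch_end":
            offsets = {p.run_id: p.t_batch_end for p in campaign.plans}
        else:
            raise ValueError(f"unknown alignment landmark {align!r}")
    return align_to_grid(table, grid_step=grid_step, horizon=horizon,
                         variables=variables, censored_at_half=censored_at_half,
                         grid_start=grid_start, time_offsets=offsets)
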
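"""Thermal indices for feedlot cattle from 15-minute weather observations.

Computes black globe temperature (BGT), the temperature–humidity index
(THI), the heat-load index (HLI) and the accumulated heat load (AHL)
from station records of ambient temperature (``ta``, °C), relative
humidity (``rh``, %), solar radiation (``sr``, W/m²), wind speed
(``ws``, m/s) and interval rainfall (``rain``, mm).

The HLI is a cattle heat-stress index with two regimes: a nonlinear form
when the black globe temperature exceeds 25 °C and a linear form below.
The AHL is a non-negative running balance: a reference animal gains heat
while HLI sits above an upper threshold (default 86) and dissipates it
while HLI is below a lower threshold (default 77); between the two
thresholds the balance is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "HliParams",
    "QcReport",
    "WEATHER_COLUMNS",
    "estimate_bgt",
    "compute_thi",
    "compute_hli",
    "accumulate_heat_load",
    "index_series",
    "qc_and_resample",
    "read_weather_csv",
    "validate_observations",
]

#: canonical column order for a weather observation frame
WEATHER_COLUMNS = ["timestamp", "ta", "rh", "sr", "ws", "rain"]

#: physical plausibility ranges used by QC (configurable per call)
QC_RANGES = {
    "ta": (-20.0, 55.0),
    "rh": (0.0, 100.0),
    "ws": (0.0, 60.0),
    "sr": (0.0, 1500.0),
    "rain": (0.0, 500.0),
}


@dataclass(frozen=True)
class HliParams:
    """Thresholds and sampling cadence for the HLI/AHL engine.

    Parameters
    ----------
    lower_threshold : float
        HLI below which cattle dissipate heat (default 77).
    upper_threshold : float
        HLI above which cattle gain heat (default 86).
    bgt_switch : float
        BGT (°C) at which the HLI formula changes branch (default 25;
        the boundary value itself is assigned to the linear branch).
    measures_per_hour : int
        Number of observations per hour, ``M``; 4 for 15-minute data,
        6 for 10-minute data.
    """

    lower_threshold: float = 77.0
    upper_threshold: float = 86.0
    bgt_switch: float = 25.0
    measures_per_hour: int = 4

    def __post_init__(self) -> None:
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError("lower_threshold must be below upper_threshold")
        if self.measures_per_hour < 1:
            raise ValueError("measures_per_hour must be >= 1")


def estimate_bgt(ta, sr):
    """Estimate black globe temperature (°C) from air temperature and solar radiation.

    Uses the published predictor
    ``BGT = 1.33·T_A − 2.65·√T_A + 3.21·log10(SR + 1) + 3.5``.
    Sub-zero air temperatures (winter nights) fall outside the
    predictor's original domain; the square-root term is continued as
    ``sign(T_A)·√|T_A|``.
    """
    ta = np.asarray(ta, dtype=float)
    sr = np.asarray(sr, dtype=float)
    if np.any(ta < -60.0):
        raise ValueError("ambient temperature below -60 degC is not physical")
    if np.any(sr < 0.0):
        raise ValueError("solar radiation must be >= 0")
    root = np.sign(ta) * np.sqrt(np.abs(ta))
    out = 1.33 * ta - 2.65 * root + 3.21 * np.log10(sr + 1.0) + 3.5
    return out if out.ndim else float(out)


def compute_thi(ta, rh):
    """Temperature–humidity index: ``0.8·T_A + (RH/100)·(T_A − 14.4) + 46.4``.

    At 14.4 °C the humidity term vanishes, so THI is independent of RH
    there.
    """
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")
    out = 0.8 * ta + (rh / 100.0) * (ta - 14.4) + 46.4
    return out if out.ndim else float(out)


def compute_hli(bgt, rh, ws, params: HliParams = HliParams()):
    """Heat-load index with the two-branch BGT formulation.

    ``HLI = 8.62 + 0.38·RH + 1.55·BGT − 0.5·WS + e^(2.4−WS)`` above the
    BGT switch point (default 25 °C) and
    ``HLI = 10.66 + 0.28·RH + 1.3·BGT − WS`` at or below it. The ~1-unit
    discontinuity at the switch point is inherited from the source
    formulation and is not smoothed.
    """
    bgt = np.asarray(bgt, dtype=float)
    rh = np.asarray(rh, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")
    if np.any(ws < 0.0):
        raise ValueError("wind speed must be >= 0")
    hot = 8.62 + 0.38 * rh + 1.55 * bgt - 0.5 * ws + np.exp(2.4 - ws)
    cool = 10.66 + 0.28 * rh + 1.3 * bgt - ws
    out = np.where(bgt > params.bgt_switch, hot, cool)
    return out if out.ndim else float(out)


def accumulate_heat_load(hli_series, params: HliParams = HliParams()) -> np.ndarray:
    """Accumulated heat load: a clamped running balance over an HLI series.

    Starting from zero, each observation adds ``(HLI − upper)/M`` when
    HLI exceeds the upper threshold, adds the (negative) quantity
    ``(HLI − lower)/M`` when HLI is below the lower threshold, and
    leaves the balance unchanged in the thermoneutral band; the balance
    is clamped at zero after every step. ``M`` is the number of measures
    per hour, so a constant exceedance integrates to degree-hours.
    """
    hli = np.asarray(hli_series, dtype=float)
    if hli.size == 0:
        return np.empty(0)
    m = float(params.measures_per_hour)
    up, lo = params.upper_threshold, params.lower_threshold
    gain = np.where(hli > up, (hli - up) / m, 0.0)
    loss = np.where(hli < lo, (hli - lo) / m, 0.0)
    incr = gain + loss
    out = np.empty_like(hli)
    bal = 0.0
    for i, d in enumerate(incr):
        bal = max(bal + d, 0.0)
        out[i] = bal
    return out


def validate_observations(obs: pd.DataFrame) -> None:
    """Check a weather frame for required columns, ranges and ordering."""
    missing = [c for c in WEATHER_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"weather frame missing columns: {missing}")
    if len(obs) == 0:
        return
    ts = pd.to_datetime(obs["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    for col, (lo, hi) in (("rh", (0, 100)), ("sr", (0, np.inf)),
                          ("ws", (0, np.inf)), ("rain", (0, np.inf))):
        vals = obs[col].to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
        if bad.any():
            t = obs.loc[obs.index[np.flatnonzero(bad)[0]], "timestamp"]
            raise ValueError(f"{col} out of range at {t}")


def index_series(
    observations: pd.DataFrame,
    params: HliParams = HliParams(),
    bgt_estimator: Callable = estimate_bgt,
) -> pd.DataFrame:
    """Compute BGT/THI/HLI per observation plus the AHL balance.

    Parameters
    ----------
    observations : DataFrame
        Columns ``timestamp, ta, rh, sr, ws, rain`` (validated).
    params : HliParams
        Thresholds and cadence for HLI/AHL.
    bgt_estimator : callable
        ``(ta, sr) -> bgt``; pluggable so an alternative black-globe
        predictor (or measured BGT) can be injected.

    Returns
    -------
    DataFrame with columns ``timestamp, bgt, thi, hli, ahl`` (and the
    input weather columns retained for downstream exposure summaries).
    """
    validate_observations(observations)
    if len(observations) == 0:
        cols = WEATHER_COLUMNS + ["bgt", "thi", "hli", "ahl"]
        return pd.DataFrame(columns=cols)
    out = observations.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    ta = out["ta"].to_numpy(dtype=float)
    rh = out["rh"].to_numpy(dtype=float)
    sr = out["sr"].to_numpy(dtype=float)
    ws = out["ws"].to_numpy(dtype=float)
    bgt = np.asarray(bgt_estimator(ta, sr), dtype=float)
    out["bgt"] = bgt
    out["thi"] = compute_thi(ta, rh)
    out["hli"] = compute_hli(bgt, rh, ws, params)
    out["ahl"] = accumulate_heat_load(out["hli"].to_numpy(), params)
    return out


@dataclass
class QcReport:
    """Counts of points masked, interpolated and left missing by QC."""

    n_input: int = 0
    n_grid: int = 0
    masked: dict = field(default_factory=dict)
    interpolated: dict = field(default_factory=dict)
    left_missing: dict = field(default_factory=dict)
    gaps: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_grid": self.n_grid,
            "masked": dict(self.masked),
            "interpolated": dict(self.interpolated),
            "left_missing": dict(self.left_missing),
            "gaps": [
                {"start": str(a), "end": str(b)} for a, b in self.gaps
            ],
        }


def qc_and_resample(
    observations: pd.DataFrame,
    expected_interval: int = 15,
    max_gap: float = 6.0,
    ranges: dict | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Range-check and regularise a station series onto its expected grid.

    Out-of-physical-range values are masked (set missing) and counted.
    The series is reindexed to a regular ``expected_interval``-minute
    grid; runs of missing values spanning at most ``max_gap`` hours are
    linearly interpolated for ``ta/rh/ws/sr`` and zero-filled for
    ``rain``; longer gaps are reported and left missing. Degraded data
    is never fatal — callers decide what coverage they require.
    """
    ranges = {**QC_RANGES, **(ranges or {})}
    rep = QcReport(n_input=len(observations))
    obs = observations.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    obs = obs.sort_values("timestamp").drop_duplicates("timestamp")
    obs = obs.set_index("timestamp")

    for col, (lo, hi) in ranges.items():
        if col not in obs.columns:
            continue
        vals = obs[col].to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
        if bad.any():
            rep.masked[col] = int(bad.sum())
            obs.loc[obs.index[bad], col] = np.nan

    if len(obs) == 0:
        rep.n_grid = 0
        return obs.reset_index(), rep

    step = pd.Timedelta(minutes=expected_interval)
    grid = pd.date_range(obs.index[0], obs.index[-1], freq=step)
    obs = obs.reindex(grid)
    rep.n_grid = len(obs)
    max_run = max(int(round(max_gap * 60 / expected_interval)), 1)

    for col in ("ta", "rh", "ws", "sr", "rain"):
        if col not in obs.columns:
            continue
        s = obs[col].astype(float)
        miss = s.isna()
        if not miss.any():
            continue
        # identify runs of consecutive missing points
        run_id = (miss != miss.shift()).cumsum()
        run_len = miss.groupby(run_id).transform("size")
        fillable = miss & (run_len <= max_run)
        if col == "rain":
            filled = s.copy()
            filled[fillable] = 0.0
        else:
            filled = s.interpolate(method="linear", limit_area="inside")
            filled[miss & ~fillable] = np.nan
        n_filled = int((miss & filled.notna()).sum())
        if n_filled:
            rep.interpolated[col] = n_filled
        n_left = int(filled.isna().sum())
        if n_left:
            rep.left_missing[col] = n_left
        obs[col] = filled

    # report long gaps (based on any core variable still missing)
    core_miss = obs[["ta", "rh", "ws", "sr"]].isna().any(axis=1)
    if core_miss.any():
        run_id = (core_miss != core_miss.shift()).cumsum()
        for _, block in obs.index.to_series().groupby(run_id):
            if core_miss.loc[block.iloc[0]]:
                rep.gaps.append((block.iloc[0], block.iloc[-1]))

    obs = obs.rename_axis("timestamp").reset_index()
    return obs, rep


def read_weather_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a weather CSV (``timestamp,ta,rh,sr,ws,rain``), applying an
    optional column mapping from file headers to canonical names."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather file {path} missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[WEATHER_COLUMNS + [c for c in df.columns if c not in WEATHER_COLUMNS]]
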
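"""Per-animal climate exposure over the 7 days before feedlot departure.

Summarises a thermal-index series (weather plus BGT/THI/HLI/AHL) over
the half-open window ``[exit − window_days, exit)`` into the covariates
used by the climatic risk models: for each of T_A, RH, SR, WS, THI and
HLI the across-day average of the daily mean, daily minimum, daily
maximum and daily range; total rainfall; the average hours per day at
or above the HLI heat-gain threshold (86); and the count of days on
which HLI sat at or below 70 for at least six hours (cold-side
exposure).

The daily-statistics convention (daily extrema averaged across the
window, rather than the single global extremum) follows heat-load
practice; the global-window convention is available via
``aggregation="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExposureError",
    "exposure_window",
    "summarize_exposure",
    "attach_exposures",
    "EXPOSURE_VARIABLES",
    "exposure_columns",
]

EXPOSURE_VARIABLES = ["ta", "rh", "sr", "ws", "thi", "hli"]


class ExposureError(ValueError):
    """Raised when an animal's exposure window cannot be summarised."""


def exposure_columns() -> list[str]:
    """Column names of the per-animal exposure table."""
    cols = ["animal_id"]
    for v in EXPOSURE_VARIABLES:
        cols += [f"{v}_mean", f"{v}_min", f"{v}_max", f"{v}_range"]
    cols += ["rain_total_7", "hours_hli_ge86_per_day", "days_hli_le70_ge6h",
             "coverage"]
    return cols


def exposure_window(
    exit_datetime,
    series: pd.DataFrame,
    window_days: int = 7,
    expected_interval: int = 15,
) -> tuple[pd.DataFrame, float]:
    """Slice the index series to ``[exit − window_days, exit)``.

    Returns the slice together with the fraction of the expected number
    of sampling points that are actually present and non-missing.

    Raises
    ------
    ExposureError
        If the window does not overlap the series at all.
    """
    exit_dt = pd.Timestamp(exit_datetime)
    start = exit_dt - pd.Timedelta(days=window_days)
    ts = pd.to_datetime(series["timestamp"])
    mask = (ts >= start) & (ts < exit_dt)
    sl = series.loc[mask.to_numpy()]
    expected = window_days * 24 * 60 // expected_interval
    present = sl[["ta", "hli"]].notna().all(axis=1).sum() if len(sl) else 0
    if len(sl) == 0:
        raise ExposureError(
            f"no index data in [{start}, {exit_dt}) for this animal"
        )
    return sl, float(present) / float(expected)


def summarize_exposure(
    window: pd.DataFrame,
    animal_id: str = "",
    coverage: float = 1.0,
    min_coverage: float = 0.8,
    measures_per_hour: int = 4,
    aggregation: str = "daily",
    hli_upper: float = 86.0,
    hli_cold: float = 70.0,
    cold_hours: float = 6.0,
    window_days: int = 7,
) -> dict:
    """Reduce an exposure-window slice to a single covariate row.

    ``aggregation="daily"`` computes each variable's mean/min/max per
    station-local calendar day and averages those across the days
    present; ``"global"`` uses the single window-wide statistics.

    Raises
    ------
    ExposureError
        If ``coverage`` is below ``min_coverage``.
    """
    if coverage < min_coverage:
        raise ExposureError(
            f"window coverage {coverage:.2f} below minimum {min_coverage:.2f}"
        )
    if aggregation not in ("daily", "global"):
        raise ValueError("aggregation must be 'daily' or 'global'")
    w = window.copy()
    w["timestamp"] = pd.to_datetime(w["timestamp"])
    day = w["timestamp"].dt.normalize()
    row: dict = {"animal_id": animal_id}
    for v in EXPOSURE_VARIABLES:
        vals = w[v].astype(float)
        if aggregation == "daily":
            g = vals.groupby(day)
            dmean, dmin, dmax = g.mean(), g.min(), g.max()
            row[f"{v}_mean"] = float(dmean.mean())
            row[f"{v}_min"] = float(dmin.mean())
            row[f"{v}_max"] = float(dmax.mean())
            row[f"{v}_range"] = float((dmax - dmin).mean())
        else:
            row[f"{v}_mean"] = float(vals.mean())
            row[f"{v}_min"] = float(vals.min())
            row[f"{v}_max"] = float(vals.max())
            row[f"{v}_range"] = float(vals.max() - vals.min())
    row["rain_total_7"] = float(w["rain"].astype(float).sum())

    hli = w["hli"].astype(float)
    n_hot = int((hli >= hli_upper).sum())
    row["hours_hli_ge86_per_day"] = n_hot / measures_per_hour / window_days

    cold_by_day = (hli <= hli_cold).groupby(day).sum() / measures_per_hour
    row["days_hli_le70_ge6h"] = int((cold_by_day >= cold_hours).sum())
    row["coverage"] = float(coverage)
    return row


class _SeriesCache:
    """Precomputed numpy views of one feedlot's index series.

    ``attach_exposures`` summarises thousands of overlapping windows per
    feedlot; this cache turns each window summary into a handful of
    ``reduceat`` calls over contiguous slices instead of per-animal
    pandas groupbys. Semantics match :func:`summarize_exposure` exactly
    (equivalence is covered by tests).
    """

    def __init__(self, series: pd.DataFrame):
        ts = pd.to_datetime(series["timestamp"])
        order = np.argsort(ts.to_numpy())
        self.ts = ts.to_numpy()[order]
        self.day = ts.dt.normalize().to_numpy().astype("datetime64[D]")[order]
        self.vars = {
            v: series[v].to_numpy(dtype=float)[order]
            for v in EXPOSURE_VARIABLES + ["rain"]
        }
        ok = np.ones(len(self.ts), dtype=bool)
        for v in EXPOSURE_VARIABLES:
            ok &= ~np.isnan(self.vars[v])
        self.ok = ok

    def window(self, start, stop):
        lo = np.searchsorted(self.ts, np.datetime64(start), side="left")
        hi = np.searchsorted(self.ts, np.datetime64(stop), side="left")
        return lo, hi

    def summarize(self, lo: int, hi: int, *, coverage, animal_id,
                  min_coverage, measures_per_hour, hli_upper, hli_cold,
                  cold_hours, window_days) -> dict:
        if coverage < min_coverage:
            raise ExposureError(
                f"window coverage {coverage:.2f} below minimum "
                f"{min_coverage:.2f}"
            )
        keep = self.ok[lo:hi]
        day = self.day[lo:hi][keep]
        starts = np.concatenate(
            [[0], np.flatnonzero(day[1:] != day[:-1]) + 1]
        )
        counts = np.diff(np.concatenate([starts, [len(day)]]))
        row: dict = {"animal_id": animal_id}
        for v in EXPOSURE_VARIABLES:
            vals = self.vars[v][lo:hi][keep]
            dmean = np.add.reduceat(vals, starts) / counts
            dmin = np.minimum.reduceat(vals, starts)
            dmax = np.maximum.reduceat(vals, starts)
            row[f"{v}_mean"] = float(dmean.mean())
            row[f"{v}_min"] = float(dmin.mean())
            row[f"{v}_max"] = float(dmax.mean())
            row[f"{v}_range"] = float((dmax - dmin).mean())
        rain = self.vars["rain"][lo:hi]
        row["rain_total_7"] = float(np.nansum(rain))
        hli = self.vars["hli"][lo:hi][keep]
        row["hours_hli_ge86_per_day"] = (
            float((hli >= hli_upper).sum()) / measures_per_hour / window_days
        )
        cold = np.add.reduceat(
            (hli <= hli_cold).astype(float), starts
        ) / measures_per_hour
        row["days_hli_le70_ge6h"] = int((cold >= cold_hours).sum())
        row["coverage"] = float(coverage)
        return row


def attach_exposures(
    animals: pd.DataFrame,
    series_by_feedlot: dict[str, pd.DataFrame],
    window_days: int = 7,
    min_coverage: float = 0.8,
    expected_interval: int = 15,
    aggregation: str = "daily",
    known_feedlots: set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute one exposure row per animal from its feedlot's index series.

    Animals whose feedlot has no station series (e.g. stations excluded
    as erroneous) or whose window coverage is insufficient are returned
    in a second frame with the reason, never silently dropped. Exposure
    windows are cached per (feedlot, exit datetime), so herds with many
    animals sharing exit days cost one summary per unique window.

    Raises
    ------
    ValueError
        If an animal references a feedlot identifier absent from both
        the series table and the known-excluded set.
    """
    known = set(series_by_feedlot)
    if known_feedlots is not None:
        unknown = sorted(set(animals["feedlot"]) - set(known_feedlots) - known)
        if unknown:
            raise ValueError(f"unknown feedlot identifiers: {unknown}")
    measures_per_hour = max(int(round(60 / expected_interval)), 1)
    expected_points = window_days * 24 * 60 // expected_interval
    rows, missing = [], []
    cache: dict[tuple, dict] = {}
    series_caches = {}
    exits = animals["exit_time"] if "exit_time" in animals else animals["exit_date"]
    for (nlis, feedlot, exit_dt) in zip(
        animals["nlis"], animals["feedlot"], pd.to_datetime(exits)
    ):
        if feedlot not in known:
            missing.append({"nlis": nlis, "feedlot": feedlot,
                            "reason": "no station series"})
            continue
        key = (feedlot, exit_dt)
        if key not in cache:
            if feedlot not in series_caches:
                if aggregation != "daily":
                    series_caches[feedlot] = None
                else:
                    series_caches[feedlot] = _SeriesCache(
                        series_by_feedlot[feedlot]
                    )
            sc = series_caches[feedlot]
            try:
                if sc is None:  # non-default aggregation: reference path
                    sl, cov = exposure_window(
                        exit_dt, series_by_feedlot[feedlot],
                        window_days=window_days,
                        expected_interval=expected_interval,
                    )
                    cache[key] = summarize_exposure(
                        sl, coverage=cov, min_coverage=min_coverage,
                        measures_per_hour=measures_per_hour,
                        aggregation=aggregation, window_days=window_days,
                    )
                else:
                    start = exit_dt - pd.Timedelta(days=window_days)
                    lo, hi = sc.window(start, exit_dt)
                    if hi <= lo:
                        raise ExposureError(
                            f"no index data in [{start}, {exit_dt}) "
                            f"for this animal"
                        )
                    cov = float(sc.ok[lo:hi].sum()) / expected_points
                    cache[key] = sc.summarize(
                        lo, hi, coverage=cov, animal_id="",
                        min_coverage=min_coverage,
                        measures_per_hour=measures_per_hour,
                        hli_upper=86.0, hli_cold=70.0, cold_hours=6.0,
                        window_days=window_days,
                    )
            except ExposureError as err:
                cache[key] = {"__error__": str(err)}
        entry = cache[key]
        if "__error__" in entry:
            missing.append({"nlis": nlis, "feedlot": feedlot,
                            "reason": entry["__error__"]})
        else:
            rows.append({**entry, "animal_id": nlis})
    exposures = pd.DataFrame(rows, columns=exposure_columns())
    report = pd.DataFrame(missing, columns=["nlis", "feedlot", "reason"])
    return exposures, report
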
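"""Feedlot and carcass record handling for dark-cutting analysis.

A carcass is classified as a dark cutter (DC) when its ultimate pH
measured at grading is at or above 5.7 — the pH non-compliance
threshold of the Meat Standards Australia grading scheme. Feedlot
records (keyed by NLIS, the per-animal national livestock identifier)
carry induction/exit dates and weights from which days on feed (DOF)
and average daily gain (ADG) are derived; carcass records carry the
abattoir, kill date, ultimate pH, loin temperature and hump height.

This module reads and validates both files, derives the per-animal
fields, merges the two sides on NLIS with an explicit match report,
and produces descriptive incidence tables and crude odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt, exp

import numpy as np
import pandas as pd

__all__ = [
    "DC_PH_THRESHOLD",
    "ANIMAL_COLUMNS",
    "CARCASS_COLUMNS",
    "classify_dc",
    "derive_fields",
    "merge_records",
    "MergeReport",
    "incidence_table",
    "crude_odds_ratio",
    "economic_loss",
    "read_animals_csv",
    "read_carcasses_csv",
]

#: ultimate-pH threshold at/above which a carcass is non-compliant
DC_PH_THRESHOLD = 5.7
PH_VALID_RANGE = (4.5, 7.5)

ANIMAL_COLUMNS = [
    "nlis", "lot", "feedlot", "induction_date", "exit_date",
    "entry_weight", "exit_weight", "sex", "hgp", "morbidity",
    "exit_time", "arrival_time",
]
CARCASS_COLUMNS = [
    "nlis", "abattoir", "kill_date", "ph_u", "loin_temp", "hump_height",
]


def classify_dc(ph_u):
    """True iff ultimate pH is at or above the 5.7 non-compliance threshold.

    The boundary value 5.7 itself is non-compliant.
    """
    arr = np.asarray(ph_u, dtype=float)
    lo, hi = PH_VALID_RANGE
    if np.any((arr < lo) | (arr > hi) | np.isnan(arr)):
        raise ValueError(f"ultimate pH outside plausible range {PH_VALID_RANGE}")
    out = arr >= DC_PH_THRESHOLD
    return out if out.ndim else bool(out)


def _transport_hours(exit_time, arrival_time):
    """Hours from feedlot exit to abattoir arrival.

    When only clock times are known, a negative difference is assumed
    to cross one midnight and 24 h is added once; differences beyond
    24 h are rejected as recording errors.
    """
    if pd.isna(exit_time) or pd.isna(arrival_time):
        return np.nan
    e, a = pd.Timestamp(exit_time), pd.Timestamp(arrival_time)
    hours = (a - e).total_seconds() / 3600.0
    if hours < 0:
        hours += 24.0
    if not 0 <= hours <= 24.0:
        raise ValueError(
            f"transport duration {hours:.1f} h outside [0, 24] "
            f"(exit {exit_time}, arrival {arrival_time})"
        )
    return hours


def derive_fields(animals: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fill the derived per-animal fields: DOF, ADG and transport hours.

    DOF is the whole-day calendar difference exit − induction; ADG is
    (exit weight − entry weight)/DOF, left missing (and counted in the
    report) for zero-DOF animals.

    Raises
    ------
    ValueError
        If any exit date precedes its induction date.
    """
    out = animals.copy()
    ind = pd.to_datetime(out["induction_date"])
    ext = pd.to_datetime(out["exit_date"])
    if (ext < ind).any():
        bad = out.loc[(ext < ind), "nlis"].tolist()
        raise ValueError(f"exit before induction for NLIS ids: {bad[:5]}")
    out["dof"] = (ext.dt.normalize() - ind.dt.normalize()).dt.days
    gain = out["exit_weight"].astype(float) - out["entry_weight"].astype(float)
    dof = out["dof"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adg = np.where(dof > 0, gain / dof, np.nan)
    out["adg"] = adg
    n_zero = int((out["dof"] == 0).sum())
    if "exit_time" in out.columns and "arrival_time" in out.columns:
        out["transport_hours"] = [
            _transport_hours(e, a)
            for e, a in zip(out["exit_time"], out["arrival_time"])
        ]
    else:
        out["transport_hours"] = np.nan
    report = {"n_animals": len(out), "n_zero_dof_excluded_from_adg": n_zero}
    return out, report


@dataclass
class MergeReport:
    matched: int
    unmatched_animals: list
    unmatched_carcasses: list

    def to_dict(self) -> dict:
        return {
            "matched": self.matched,
            "n_unmatched_animals": len(self.unmatched_animals),
            "n_unmatched_carcasses": len(self.unmatched_carcasses),
        }


def merge_records(
    animals: pd.DataFrame, carcasses: pd.DataFrame
) -> tuple[pd.DataFrame, MergeReport]:
    """Inner-join animal and carcass records on NLIS, reporting the rest.

    Duplicate NLIS ids within either input are a validation error (the
    id is the unique per-animal key); unmatched ids on either side are
    reported, never silently dropped. The merged frame gains the ``dc``
    flag from ultimate pH.
    """
    for name, df in (("animals", animals), ("carcasses", carcasses)):
        dup = df.loc[df["nlis"].duplicated(), "nlis"].unique()
        if len(dup):
            raise ValueError(f"duplicate NLIS ids in {name}: {sorted(dup)[:5]}")
    merged = animals.merge(carcasses, on="nlis", how="inner")
    a_ids, c_ids = set(animals["nlis"]), set(carcasses["nlis"])
    rep = MergeReport(
        matched=len(merged),
        unmatched_animals=sorted(a_ids - c_ids),
        unmatched_carcasses=sorted(c_ids - a_ids),
    )
    merged["dc"] = classify_dc(merged["ph_u"])
    return merged, rep


def incidence_table(
    records: pd.DataFrame,
    by: str,
    denominator: str = "total",
) -> pd.DataFrame:
    """Per-group DC counts and percentage.

    Parameters
    ----------
    records : DataFrame
        Must carry the grouping column and a boolean ``dc`` column.
    by : str
        Grouping field (e.g. ``feedlot``, ``hgp``, ``sex``).
    denominator : {"total", "compliant"}
        Whether the percentage is DC/total (standard epidemiological
        incidence) or DC/compliant (the convention some published
        per-feedlot tables follow).
    """
    if by not in records.columns:
        raise KeyError(f"grouping field {by!r} not present")
    if denominator not in ("total", "compliant"):
        raise ValueError("denominator must be 'total' or 'compliant'")
    g = records.groupby(by, observed=True)["dc"]
    tab = pd.DataFrame({
        "total": g.size(),
        "dc": g.sum().astype(int),
    })
    tab["compliant"] = tab["total"] - tab["dc"]
    denom = tab[denominator].where(tab[denominator] > 0)
    tab["pct"] = (100.0 * tab["dc"] / denom).fillna(0.0).round(2)
    return tab.reset_index()[[by, "total", "compliant", "dc", "pct"]]


def crude_odds_ratio(a, b, c, d, z: float = 1.96) -> tuple[float, tuple[float, float]]:
    """Crude odds ratio and Wald CI for a 2x2 table.

    Cells are (a, b) = (exposed cases, exposed non-cases) and
    (c, d) = (unexposed cases, unexposed non-cases), OR = (a·d)/(b·c).
    Any zero cell triggers the Haldane–Anscombe +0.5 continuity
    correction on all four cells; two zero cells sharing a margin leave
    the odds ratio undefined.
    """
    cells = [float(x) for x in (a, b, c, d)]
    if any(x < 0 for x in cells):
        raise ValueError("2x2 cell counts must be non-negative")
    a_, b_, c_, d_ = cells
    if (a_ == 0 and b_ == 0) or (c_ == 0 and d_ == 0) or \
       (a_ == 0 and c_ == 0) or (b_ == 0 and d_ == 0):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    if 0 in cells:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    or_ = (a_ * d_) / (b_ * c_)
    se = sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo, hi = exp(log(or_) - z * se), exp(log(or_) + z * se)
    return or_, (lo, hi)


def economic_loss(
    n_carcasses: float,
    mean_cwt_kg: float,
    deduction_per_kg: float,
    incidence: float,
) -> float:
    """Annual industry cost of dark cutting.

    ``n_carcasses · mean carcass weight · price deduction per kg ·
    incidence`` — e.g. the national grain-fed kill times a 59 c/kg
    deduction at a few percent incidence.
    """
    for name, v in (("n_carcasses", n_carcasses), ("mean_cwt_kg", mean_cwt_kg),
                    ("deduction_per_kg", deduction_per_kg)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if not 0 <= incidence <= 1:
        raise ValueError("incidence must lie in [0, 1]")
    return n_carcasses * mean_cwt_kg * deduction_per_kg * incidence


def read_animals_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read the feedlot animal CSV; required header per ``ANIMAL_COLUMNS``."""
    df = pd.read_csv(path, dtype={"nlis": str, "lot": str, "feedlot": str})
    if column_map:
        df = df.rename(columns=column_map)
    required = [c for c in ANIMAL_COLUMNS if c not in ("exit_time", "arrival_time")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"animal file {path} missing columns: {missing}")
    return df


def read_carcasses_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read the carcass grading CSV; required header per ``CARCASS_COLUMNS``."""
    df = pd.read_csv(path, dtype={"nlis": str, "abattoir": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CARCASS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"carcass file {path} missing columns: {missing}")
    hh = df["hump_height"].astype(float)
    if ((hh < 0) | (hh % 5 != 0)).any():
        raise ValueError("hump_height must be a non-negative multiple of 5 mm")
    return df
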
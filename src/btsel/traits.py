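"""Derivation of the four movement traits from GPS fixes.

Pipeline order is fixed: DOP filtering -> truncation at mortality ->
daily metrics -> hunting-stage assignment -> pooled standardization.
Risk-trait sign flipping happens only inside the selection stage.

Traits (raw units):

- ``dist_access_m``, ``dist_open_m``, ``dist_edge_m``: arithmetic mean,
  over a bird-day's diurnal fixes, of the distance-surface value at each
  fix (metres).
- ``speed_m_per_h``: total diurnal path length divided by 15 — the hours
  of scheduled diurnal sampling — regardless of the fix schedule, so the
  hourly (Georgia) and 30-minute (South Carolina) schedules are directly
  comparable.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
import numpy as np
import pandas as pd

from .landscape import DistanceSurfaces, Landscape, sample_surface
from .simulate import (
    DIURNAL_END_HOUR,
    DIURNAL_START_HOUR,
    RISK_TRAITS,
    SPEED_DIVISOR_HOURS,
    TRAIT_COLUMNS,
    SeasonCalendar,
)

logger = logging.getLogger(__name__)

TRAIT_COLS = tuple(TRAIT_COLUMNS[t] for t in ("dist_access", "dist_open", "dist_edge", "speed"))
RISK_COLS = tuple(TRAIT_COLUMNS[t] for t in RISK_TRAITS)


def filter_fixes(fixes: pd.DataFrame, dop_max: float = 7.0) -> pd.DataFrame:
    """Drop fixes with dilution of precision above ``dop_max`` (default 7).

    A fix with DOP exactly equal to the threshold is retained.  Order is
    preserved; the number of removed fixes is logged.
    """
    keep = fixes["dop"] <= dop_max
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_fixes: removed %d of %d fixes with DOP > %g",
                    removed, len(fixes), dop_max)
    return fixes.loc[keep].copy()


def truncate_at_fate(fixes: pd.DataFrame, fate: str, fate_date) -> pd.DataFrame:
    """Keep only fixes strictly before the mortality date.

    Survivors pass through untouched.  A fate date on or before the first
    fix leaves an empty track (warning, not an error).
    """
    if fate == "survived":
        return fixes
    if pd.isna(fate_date):
        raise ValueError("fate_date required for non-survivors")
    cutoff = pd.Timestamp(fate_date).normalize()
    out = fixes.loc[pd.to_datetime(fixes["timestamp"]).dt.normalize() < cutoff].copy()
    if out.empty and not fixes.empty:
        warnings.warn("fate date precedes first fix: empty track", stacklevel=2)
    return out


def assign_stage(dates, calendar: SeasonCalendar) -> np.ndarray:
    """Vectorised hunting-stage assignment for dates in the monitored window."""
    dates = pd.to_datetime(pd.Series(dates)).dt.date
    return np.array([calendar.stage_of(d) for d in dates])


def _diurnal_mask(ts: pd.Series) -> pd.Series:
    hours = ts.dt.hour + ts.dt.minute / 60.0
    return (hours >= DIURNAL_START_HOUR) & (hours <= DIURNAL_END_HOUR)


def daily_distance_traits(
    fixes: pd.DataFrame,
    surfaces: DistanceSurfaces,
    land: Landscape,
    include_night: bool = False,
) -> pd.DataFrame:
    """Per-day mean distance-surface values at the fixes of one individual.

    Returns a frame indexed by date with the three distance columns.
    Fixes outside the raster extent raise an error naming the fix.
    """
    ts = pd.to_datetime(fixes["timestamp"])
    use = fixes if include_night else fixes.loc[_diurnal_mask(ts)]
    if use.empty:
        return pd.DataFrame(columns=["date", *RISK_COLS])
    ts_use = pd.to_datetime(use["timestamp"])
    vals = {}
    for name, surface in surfaces.as_dict().items():
        vals[TRAIT_COLUMNS[name]] = sample_surface(
            surface, land, use["x_m"].to_numpy(), use["y_m"].to_numpy()
        )
    daily = (
        pd.DataFrame({"date": ts_use.dt.normalize().to_numpy(), **vals})
        .groupby("date", as_index=False)
        .mean()
    )
    return daily


def daily_speed(
    fixes: pd.DataFrame,
    include_night: bool = False,
    divisor_hours: float = SPEED_DIVISOR_HOURS,
) -> pd.DataFrame:
    """Average hourly speed per day: diurnal path length / 15 hours.

    The divisor is fixed at the scheduled diurnal sampling span whatever
    the fix count, so undersampled days underestimate speed rather than
    being rescaled.  Days with fewer than two usable fixes are skipped
    with a warning.
    """
    ts = pd.to_datetime(fixes["timestamp"])
    use = fixes if include_night else fixes.loc[_diurnal_mask(ts)]
    out = []
    skipped = 0
    for date, day in use.assign(_ts=pd.to_datetime(use["timestamp"])).groupby(
        pd.to_datetime(use["timestamp"]).dt.normalize()
    ):
        if len(day) < 2:
            skipped += 1
            continue
        day = day.sort_values("_ts")
        steps = np.hypot(day["x_m"].diff(), day["y_m"].diff()).iloc[1:]
        out.append({"date": date, "speed_m_per_h": float(steps.sum()) / divisor_hours})
    if skipped:
        warnings.warn(f"daily_speed: skipped {skipped} day(s) with <2 fixes", stacklevel=2)
    return pd.DataFrame(out, columns=["date", "speed_m_per_h"])


def derive_daily_traits(
    fixes: pd.DataFrame,
    land_by_pop: dict[str, Landscape],
    surfaces_by_pop: dict[str, DistanceSurfaces],
    calendars: dict[str, SeasonCalendar],
    profiles: pd.DataFrame,
    dop_max: float = 7.0,
    include_night: bool = False,
) -> pd.DataFrame:
    """Full trait-derivation pipeline over a cohort.

    Applies the fixed composition order (filter -> truncate -> daily
    metrics -> stage assignment) per individual and returns the
    daily trait table (one row per individual-day, raw units).
    """
    fixes = filter_fixes(fixes, dop_max)
    meta = profiles.set_index("individual_id")
    tables = []
    for ind_id, track in fixes.groupby("individual_id", sort=False):
        row = meta.loc[ind_id]
        pop = row["population"]
        if "fate" in meta.columns:
            track = truncate_at_fate(track, row["fate"], row.get("fate_date"))
        if track.empty:
            continue
        dists = daily_distance_traits(track, surfaces_by_pop[pop], land_by_pop[pop],
                                      include_night)
        speeds = daily_speed(track, include_night)
        daily = dists.merge(speeds, on="date", how="inner")
        if daily.empty:
            continue
        daily.insert(0, "individual_id", ind_id)
        daily["stage"] = assign_stage(daily["date"], calendars[pop])
        daily["population"] = pop
        tables.append(daily)
    if not tables:
        return pd.DataFrame(
            columns=["individual_id", "date", "stage", "population", *TRAIT_COLS]
        )
    out = pd.concat(tables, ignore_index=True)
    return out[["individual_id", "date", "stage", "population", *TRAIT_COLS]]


# ---------------------------------------------------------------------------
# standardization and sign conventions


def standardize(
    table: pd.DataFrame, columns: tuple[str, ...] = TRAIT_COLS
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre and scale each trait to unit SD over the pooled table.

    Pooling both populations makes the fitted population fixed effect the
    between-site contrast.  Returns the standardized table and the
    {column: (mean, sd)} scaling parameters for back-transformation.
    """
    out = table.copy()
    scaling = {}
    for col in columns:
        v = table[col].to_numpy(float)
        if len(np.unique(v)) < 2:
            raise ValueError(f"zero-variance trait '{col}' cannot be standardized")
        mean, sd = float(v.mean()), float(v.std(ddof=0))
        out[col] = (v - mean) / sd
        scaling[col] = (mean, sd)
    out.attrs["standardized"] = True
    return out, scaling


def unstandardize(
    table: pd.DataFrame, scaling: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    out = table.copy()
    for col, (mean, sd) in scaling.items():
        out[col] = out[col] * sd + mean
    out.attrs["standardized"] = False
    return out


def flip_risk_sign(table: pd.DataFrame, traits=RISK_COLS) -> pd.DataFrame:
    """Negate the named risk (distance) traits.

    After flipping, a positive selection log-odds reads as "riskier
    individuals survive more".  Speed is never flipped; unknown names
    raise.  The flip is recorded in ``table.attrs['flipped']``.
    """
    unknown = set(traits) - set(RISK_COLS)
    if unknown:
        raise ValueError(f"cannot flip non-risk trait(s): {sorted(unknown)}")
    out = table.copy()
    for col in traits:
        out[col] = -out[col]
    out.attrs["flipped"] = tuple(traits)
    return out
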
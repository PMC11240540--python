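"""Net growth, proliferation and death rate inference from experimental data.

A tumor whose cell density stays constant during treatment follows
``N(t) = N0 * exp(r t)`` with ``N(t)`` proportional to the caliper-measured
volume ``V(t)``; the net growth rate ``r`` is the slope of ``ln V`` against
time.  The proliferation rate ``p`` (events per cell per day) comes from the
BrdU labeling index: with an S phase of ``s`` hours, a pulse labels the
fraction of cells currently in S, so ``p = index * 24 / s`` (the canonical
factor 3 for an 8-hour S phase).  The death rate follows by closure:
``d = p - r``.  Positive ``r`` means exponential growth, negative ``r``
exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_S_PHASE_HOURS = 8.0


@dataclass
class VolumeSeries:
    """Tumor volume time series: days (strictly increasing), volumes (mm^3, > 0)."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.volumes = np.asarray(self.volumes, dtype=float).ravel()
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes must have equal length")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.volumes <= 0).any():
            raise ValueError("volumes must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RateEstimates:
    """Per-day rates tied together by d = p - r."""

    r: float
    p: float
    s_phase: float = DEFAULT_S_PHASE_HOURS

    @property
    def d(self) -> float:
        return self.p - self.r


def fit_exponential(series: VolumeSeries, method: str = "ols") -> float:
    """Fit the exponential growth law and return the net rate r per day.

    ``method="ols"`` (default) is the closed-form least-squares slope of
    ``ln V`` versus ``t``; ``method="nls"`` fits ``V0 * exp(r t)`` directly by
    nonlinear least squares (initialized from the log-linear solution).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 time points to fit a rate")
    t, v = series.times, series.volumes
    slope, intercept = np.polyfit(t, np.log(v), 1)
    if method == "ols":
        return float(slope)
    if method == "nls":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda tt, v0, r: v0 * np.exp(r * tt), t, v,
                            p0=(float(np.exp(intercept)), float(slope)),
                            maxfev=10000)
        return float(popt[1])
    raise ValueError(f"unknown method {method!r}")


def proliferation_from_brdu(index: float,
                            s_phase: float = DEFAULT_S_PHASE_HOURS) -> float:
    """Convert a BrdU positivity index into a per-day proliferation rate."""
    if not 0.0 <= index <= 1.0:
        raise ValueError("BrdU index must lie in [0, 1]")
    if not s_phase > 0:
        raise ValueError("S-phase duration must be positive")
    return index * 24.0 / s_phase


def death_rate(p: float, r: float) -> float:
    """Death rate as the closure of proliferation and net growth: d = p - r."""
    return p - r


# ---------------------------------------------------------------------------
# CSV-level conveniences
# ---------------------------------------------------------------------------

def fit_volumes(df: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Fit net growth rates from a `day,volume_mm3[,animal_id]` table.

    By default each animal's series is fitted separately (one row per animal
    plus a `mean` row); ``pooled=True`` fits a single rate to all points.
    """
    df = df.rename(columns=str.strip)
    if "animal_id" not in df.columns or pooled:
        series = VolumeSeries(df["day"].to_numpy(), df["volume_mm3"].to_numpy())
        return pd.DataFrame({"animal_id": ["pooled"],
                             "r_per_day": [fit_exponential(series)]})
    rows = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        series = VolumeSeries(grp["day"].to_numpy(), grp["volume_mm3"].to_numpy())
        rows.append({"animal_id": animal, "r_per_day": fit_exponential(series)})
    out = pd.DataFrame(rows)
    mean_row = pd.DataFrame({"animal_id": ["mean"],
                             "r_per_day": [out["r_per_day"].mean()]})
    return pd.concat([out, mean_row], ignore_index=True)


def rates_table(volume_df: pd.DataFrame, brdu_df: pd.DataFrame,
                s_phase: float = DEFAULT_S_PHASE_HOURS) -> pd.DataFrame:
    """Combine volumetric fits with BrdU indices into per-animal rate estimates.

    ``volume_df`` has columns `day,volume_mm3,animal_id`; ``brdu_df`` has
    `animal_id,brdu_index`.  The net rate is the per-animal volumetric fit,
    the proliferation rate comes from that animal's BrdU index, and the death
    rate closes the balance (d = p - r).  Rates are rounded to 3 decimals.
    """
    fits = fit_volumes(volume_df)
    fits = fits[fits["animal_id"] != "mean"]
    merged = fits.merge(brdu_df, on="animal_id", how="inner")
    merged["p_per_day"] = [proliferation_from_brdu(i, s_phase)
                           for i in merged["brdu_index"]]
    merged["d_per_day"] = merged["p_per_day"] - merged["r_per_day"]
    for col in ("r_per_day", "p_per_day", "d_per_day"):
        merged[col] = merged[col].round(3)
    return merged[["animal_id", "r_per_day", "p_per_day", "d_per_day"]]
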
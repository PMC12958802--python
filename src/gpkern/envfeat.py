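"""Soil and weather covariate preparation.

Daily weather series are summarized as means over consecutive non-overlapping
windows (3 days by default); a trailing partial window is averaged over its
available days, which is what makes a 280-day season produce 94 windows.
All covariates are centered and scaled by training-set statistics only, and
those statistics are stored so test rows can be transformed without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidConfigError

__all__ = ["WindowedWeather", "window_weather", "standardize_features", "destandardize"]


@dataclass
class WindowedWeather:
    """Site-year by (variable, window) table of window-mean weather values."""

    values: pd.DataFrame  # index: site_year, columns: '<var>_w<k>'
    window_days: int
    n_variables: int
    n_windows: int


def window_weather(trial_or_array, window_days: int = 3, variables=None, site_years=None):
    """Average daily weather over consecutive non-overlapping windows.

    Accepts a TrialDesign or a raw array of shape (site_years, variables,
    days).  The final window may cover fewer than ``window_days`` days when
    the day count is not divisible; it is averaged over the days it has.
    """
    arr = getattr(trial_or_array, "weather", trial_or_array)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3 or arr.size == 0:
        raise InvalidConfigError("weather input must be a non-empty 3-d grid")
    if window_days < 1:
        raise InvalidConfigError("window_days must be >= 1")
    if variables is None:
        variables = getattr(trial_or_array, "weather_vars", None) or [
            f"wx{v:02d}" for v in range(arr.shape[1])
        ]
    if site_years is None:
        site_years = getattr(trial_or_array, "site_years", None) or [
            f"sy{k}" for k in range(arr.shape[0])
        ]
    n_days = arr.shape[2]
    n_windows = int(np.ceil(n_days / window_days))
    cols, names = [], []
    for v, var in enumerate(variables):
        for k in range(n_windows):
            sl = arr[:, v, k * window_days : (k + 1) * window_days]
            cols.append(sl.mean(axis=1))
            names.append(f"{var}_w{k}")
    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(site_years, name="site_year"), columns=names
    )
    return WindowedWeather(
        values=values,
        window_days=window_days,
        n_variables=len(variables),
        n_windows=n_windows,
    )


def standardize_features(table: pd.DataFrame, train_ids) -> tuple:
    """Center/scale every column by its training-row mean and sd.

    ``train_ids`` selects the training rows by index label.  Zero-variance
    columns among the training rows are dropped with a warning.  Returns the
    standardized table (all rows) and a stats DataFrame with 'mean' and 'sd'
    rows for reuse on new data.
    """
    train = table.loc[list(train_ids)]
    if train.empty:
        raise InvalidConfigError("training subset is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dead = sd[sd == 0.0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance columns: {list(dead)[:5]}...")
        table = table.drop(columns=dead)
        mean = mean.drop(dead)
        sd = sd.drop(dead)
    if table.shape[1] == 0:
        raise DegenerateInputError("no informative columns remain")
    stats = pd.DataFrame({"mean": mean, "sd": sd}).T
    return (table - mean) / sd, stats


def destandardize(table: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize_features` using its stored statistics."""
    return table * stats.loc["sd"] + stats.loc["mean"]
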
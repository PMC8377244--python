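"""Chronology of accessibility, expression, and phenotype change.

Each signal class is summarized as a min-max-scaled mean trajectory over
the timepoint grid; its onset is the least-squares single change-point of
a two-constant-segment model, searched exhaustively over all splits. The
irregular day grid makes grid-day onsets coarse, so a sub-grid refinement
interpolates the split SSE parabolically over the boundary midpoints and
returns a fractional day; lags are differences of onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrajectorySummary:
    signal_class: str
    timepoints: np.ndarray
    series: np.ndarray            # scaled to [0, 1]
    onset_day: float | None       # grid day: first timepoint of segment 2
    onset_refined: float | None   # fractional day
    flat: bool = False


def mean_trajectory(
    matrix: pd.DataFrame,
    elements: list,
    design: dict[int, list] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Replicate-averaged, element-averaged, min-max-scaled trajectory.

    ``design`` maps day -> its sample columns; with None, columns are taken
    to be the days themselves (expression-style matrix). Returns
    (days, scaled series, degenerate_flag); a constant signal scales to
    all zeros with the flag set.
    """
    if not list(elements):
        raise ValueError("empty element set")
    sub = matrix.loc[list(elements)]
    if design is None:
        days = np.array([int(c) for c in matrix.columns], dtype=float)
        series = sub.mean(axis=0).values.astype(float)
    else:
        days = np.array(sorted(design), dtype=float)
        series = np.array(
            [sub[design[int(d)]].values.mean() for d in days], dtype=float
        )
    rng = series.max() - series.min()
    if rng == 0:
        return days, np.zeros_like(series), True
    return days, (series - series.min()) / rng, False


def _segment_sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def onset_changepoint(
    series: np.ndarray, timepoints: np.ndarray
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Least-squares single change-point of a two-constant-segment model.

    Returns (onset_day, onset_refined, split table). onset_day is the first
    timepoint of the second segment at the SSE-minimizing split (ties broken
    toward the earlier day). onset_refined interpolates the SSE parabola
    through the minimizing split and its neighbours, on the scale of segment
    boundary midpoints, clipped to the grid range; at a boundary split it
    equals the grid day. A flat series yields (None, None, table).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if len(y) != len(t):
        raise ValueError("series and timepoints must align")
    if len(y) < 3:
        raise ValueError("need at least 3 timepoints")
    if np.ptp(y) == 0:
        return None, None, pd.DataFrame(columns=["split_day", "boundary", "sse"])
    n = len(y)
    bounds = (t[:-1] + t[1:]) / 2.0
    rows = []
    for j in range(1, n):
        rows.append(
            {
                "split_day": t[j],
                "boundary": bounds[j - 1],
                "sse": _segment_sse(y[:j]) + _segment_sse(y[j:]),
            }
        )
    table = pd.DataFrame(rows)
    sse = table["sse"].values
    j_best = int(np.argmin(sse))  # argmin takes the first = earliest day on ties
    onset = float(table["split_day"].iloc[j_best])
    if 0 < j_best < len(sse) - 1:
        x1, x2, x3 = table["boundary"].iloc[j_best - 1 : j_best + 2]
        y1, y2, y3 = sse[j_best - 1 : j_best + 2]
        den = (x2 - x1) * (y2 - y3) - (x2 - x3) * (y2 - y1)
        if abs(den) > 1e-300:
            num = (x2 - x1) ** 2 * (y2 - y3) - (x2 - x3) ** 2 * (y2 - y1)
            refined = float(np.clip(x2 - 0.5 * num / den, t[0], t[-1]))
        else:
            refined = onset
    else:
        refined = onset
    return onset, refined, table


def summarize_trajectory(
    signal_class: str,
    matrix: pd.DataFrame,
    elements: list,
    design: dict[int, list] | None = None,
) -> TrajectorySummary:
    days, series, flat = mean_trajectory(matrix, elements, design)
    if flat:
        return TrajectorySummary(signal_class, days, series, None, None, flat=True)
    onset, refined, _ = onset_changepoint(series, days)
    return TrajectorySummary(signal_class, days, series, onset, refined)


def onset_lags(
    summaries: list[TrajectorySummary], refined: bool = True
) -> pd.DataFrame:
    """lag(a -> b) = onset(b) - onset(a) for every ordered pair, in days.

    Pairs with a null onset are omitted (with a warning via the returned
    table's attrs['omitted']).
    """
    import warnings

    usable, omitted = [], []
    for s in summaries:
        onset = s.onset_refined if refined else s.onset_day
        if onset is None:
            omitted.append(s.signal_class)
        else:
            usable.append((s.signal_class, onset))
    if omitted:
        warnings.warn(f"signals without an onset omitted from lags: {omitted}")
    if len(usable) < 2:
        raise ValueError("need >=2 summaries with non-null onsets")
    rows = []
    for a, oa in usable:
        for b, ob in usable:
            if a != b:
                rows.append({"from": a, "to": b, "lag_days": ob - oa})
    table = pd.DataFrame(rows)
    table.attrs["omitted"] = omitted
    return table


def nearest_grid_day(day: float, timepoints) -> int:
    """Round a fractional onset to the nearest day on the grid."""
    t = np.asarray(timepoints, dtype=float)
    return int(t[np.argmin(np.abs(t - day))])
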
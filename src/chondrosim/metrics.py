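"""Scalar reductions of trajectories: lesion radius, penumbra, regime.

The simulation's central observable is the radial spread of the lesion
-- the region where healthy cells have been lost -- and of the penumbra
of "sick" (catabolic + EPOR-active) cells that surrounds it.  The model
itself defines no scalar lesion metric, so the reductions here use
documented thresholds: a node belongs to the lesion when its healthy
density has fallen below ``theta_C * C0`` (default half the background
density), and to the penumbra when the sick density exceeds
``theta_S * C0`` (default 5%).

All reductions are pure functions of the trajectory: recomputing them
from a stored trajectory reproduces the stored values exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dde_engine import Trajectory
from .model_core import SystemState

__all__ = [
    "lesion_radius",
    "penumbra_radii",
    "summarize",
    "classify_regime",
    "abatement_day",
]

#: Default thresholds (fractions of the background healthy density) and
#: the regime slope tolerance in mm/day.
THETA_C = 0.5
THETA_S = 0.05
EPS_SLOPE = 0.01


def _outer_crossing(r: np.ndarray, values: np.ndarray, level: float,
                    below: bool) -> float:
    """Largest radius where ``values`` is below (or above) ``level``,
    linearly interpolated to the crossing with the next node outward."""
    mask = values < level if below else values > level
    if not mask.any():
        return 0.0
    j = int(np.max(np.nonzero(mask)[0]))
    if j == len(r) - 1:
        return float(r[-1])
    v0, v1 = values[j], values[j + 1]
    if v1 == v0:
        return float(r[j])
    frac = (level - v0) / (v1 - v0)
    return float(r[j] + frac * (r[j + 1] - r[j]))


def lesion_radius(state: SystemState, grid, C0: float,
                  theta_C: float = THETA_C) -> float:
    """Outermost radius (mm) where the healthy density is depressed.

    Defined as the largest node radius with ``C < theta_C * C0``,
    linearly interpolated between nodes; 0 when no node qualifies.
    ``grid`` supplies the node radii (a RadialGrid or an array).
    """
    if not 0 < theta_C < 1:
        raise ValueError(f"theta_C must lie in (0, 1), got {theta_C}")
    r = getattr(grid, "node_centers", grid)
    return _outer_crossing(np.asarray(r, dtype=float), state.C,
                           theta_C * C0, below=True)


def penumbra_radii(sick: np.ndarray, r: np.ndarray, C0: float,
                   theta_S: float = THETA_S) -> tuple[float, float]:
    """Inner and outer radius of the sick-cell annulus (NaN when absent)."""
    level = theta_S * C0
    mask = sick > level
    if not mask.any():
        return (np.nan, np.nan)
    idx = np.nonzero(mask)[0]
    j_in, j_out = int(idx[0]), int(idx[-1])
    # interpolate inward edge toward the previous node, outward edge
    # toward the next node
    if j_in == 0:
        r_in = 0.0
    else:
        v0, v1 = sick[j_in - 1], sick[j_in]
        frac = (level - v0) / (v1 - v0) if v1 != v0 else 1.0
        r_in = float(r[j_in - 1] + frac * (r[j_in] - r[j_in - 1]))
    r_out = _outer_crossing(r, sick, level, below=False)
    return (r_in, r_out)


def summarize(traj: Trajectory, C0: float, *, theta_C: float = THETA_C,
              theta_S: float = THETA_S) -> pd.DataFrame:
    """Per-output-time lesion summary table.

    Columns: time (h and days), lesion radius, penumbra inner/outer
    radii, area-integrated cell populations (healthy, catabolic,
    EPOR-active, apoptotic ledger, necrotic), and the spatial maxima of
    TNF-alpha and EPO.
    """
    r = traj.grid.node_centers
    areas = traj.grid.cell_areas
    C = traj.field("C")
    sick = traj.field("S_T") + traj.field("S_A")
    rows = {
        "time_h": traj.times,
        "time_d": traj.times / 24.0,
        "lesion_radius_mm": [
            _outer_crossing(r, C[i], theta_C * C0, below=True)
            for i in range(len(traj.times))],
        "penumbra_inner_mm": np.nan,
        "penumbra_outer_mm": np.nan,
        "int_C": C @ areas,
        "int_S_T": traj.field("S_T") @ areas,
        "int_S_A": traj.field("S_A") @ areas,
        "int_D_A": traj.field("D_A") @ areas,
        "int_D_N": traj.field("D_N") @ areas,
        "max_F": traj.field("F").max(axis=1),
        "max_P": traj.field("P").max(axis=1),
    }
    df = pd.DataFrame(rows)
    inner = np.empty(len(df))
    outer = np.empty(len(df))
    for i in range(len(df)):
        inner[i], outer[i] = penumbra_radii(sick[i], r, C0, theta_S)
    df["penumbra_inner_mm"] = inner
    df["penumbra_outer_mm"] = outer
    df["int_penumbra"] = df["int_S_T"] + df["int_S_A"]
    return df


def classify_regime(summary: pd.DataFrame, C0: float, injury_radius: float,
                    *, theta_S: float = THETA_S,
                    eps_slope: float = EPS_SLOPE) -> str:
    """Label a run ``expanding``, ``abated`` or ``resolved``.

    ``expanding``: the lesion radius still grows over the final three
    days (linear slope above ``eps_slope`` mm/day).  ``abated``: the
    radius has stopped growing but a penumbra persists.  ``resolved``:
    the remaining sick-cell mass is below the detection level
    ``theta_S * C0 * (injury area)`` -- vacuously true for an
    injury-free run in which no penumbra ever forms.
    """
    if summary["time_h"].iloc[-1] - summary["time_h"].iloc[0] < 72.0:
        raise ValueError("regime classification needs at least 3 days of "
                         "output")
    tail = summary[summary["time_h"] >= summary["time_h"].iloc[-1] - 72.0]
    slope = np.polyfit(tail["time_d"], tail["lesion_radius_mm"], 1)[0]
    penumbra_mass = float(summary["int_penumbra"].iloc[-1])
    detection = theta_S * C0 * np.pi * injury_radius ** 2
    if penumbra_mass < detection:
        return "resolved"
    if slope > eps_slope:
        return "expanding"
    return "abated"


def abatement_day(summary: pd.DataFrame, *, rel: float = 0.05,
                  abs_mm: float = 0.05) -> float:
    """Earliest time (days) after which the lesion stops expanding.

    Defined as the first output time from which the lesion radius never
    again rises by more than ``max(rel * radius, abs_mm)``, with at
    least one further day of record demonstrating the stall.  Infinite
    when the radius is still climbing into the final day (no abatement
    within the horizon).
    """
    r = summary["lesion_radius_mm"].to_numpy()
    t_d = summary["time_d"].to_numpy()
    future_max = np.maximum.accumulate(r[::-1])[::-1]
    settled = future_max <= r + np.maximum(rel * r, abs_mm)
    # require the condition to hold from some point onward
    ok_from = np.nonzero(~settled)[0]
    first = 0 if len(ok_from) == 0 else int(ok_from[-1]) + 1
    if first >= len(r) or t_d[first] > t_d[-1] - 1.0:
        return float("inf")
    return float(t_d[first])
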
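"""Method-of-steps integrator for the semi-discrete delay system.

Spatial discretisation (method of lines) turns the reaction-diffusion-
delay system into a large system of delay differential equations.  This
module integrates such systems with an explicit embedded Bogacki-
Shampine 2(3) pair -- the same order family as classical DDE codes --
with a continuous cubic-Hermite extension of every accepted step.  The
interpolant is what makes the method of steps work: because the maximum
step size is capped at the shortest delay, a delayed argument always
falls inside already-accepted history (or in the user-supplied
pre-initial history for times before the start).

The integrator is fully deterministic: identical inputs produce
bit-identical trajectories on one platform.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_core import (FIELD_NAMES, CHEMICAL_FIELDS, FIELD_INDEX,
                         ParameterSet, SystemState, reaction_rates)
from .radial_grid import RadialGrid, check_boundary_contact

__all__ = [
    "ConstantHistory",
    "DenseOutput",
    "solve_dde",
    "Trajectory",
    "integrate",
    "make_checkpoint",
    "resume",
    "checkpoint_roundtrip",
]


class ConstantHistory:
    """Pre-initial history that is constant in time.

    Callable at any ``t <= t_start``; queries beyond the start of the
    integration raise, as the evolving part of the history is owned by
    the solver.
    """

    def __init__(self, y: np.ndarray, t_start: float = 0.0):
        self.y = np.asarray(y, dtype=float)
        self.t_start = float(t_start)

    def __call__(self, t: float) -> np.ndarray:
        if t > self.t_start:
            raise ValueError(
                f"pre-initial history queried at t={t} > start "
                f"t={self.t_start}")
        return self.y


def _hermite(t, t0, t1, y0, y1, f0, f1):
    """Cubic Hermite evaluation on one step (third-order interpolant)."""
    h = t1 - t0
    s = (t - t0) / h
    s2 = s * s
    s3 = s2 * s
    return ((2 * s3 - 3 * s2 + 1) * y0 + (s3 - 2 * s2 + s) * h * f0
            + (-2 * s3 + 3 * s2) * y1 + (s3 - s2) * h * f1)


class DenseOutput:
    """Piecewise cubic-Hermite representation of a computed solution.

    Stores nodal values and derivatives at accepted step endpoints plus
    the pre-initial history, and evaluates anywhere in the covered span.
    Continuous (and C1) across segment boundaries because the first
    stage of each step reuses the last stage of the previous one.
    """

    def __init__(self, t0: float, y0: np.ndarray,
                 history: Callable[[float], np.ndarray] | None):
        self.t0 = float(t0)
        self.history = history
        self.ts: list[float] = [self.t0]
        self.ys: list[np.ndarray] = [np.asarray(y0, dtype=float)]
        self.fs: list[np.ndarray] = [np.zeros_like(y0)]  # patched on step 1
        self._live = 0  # index of first retained knot (pruning)

    @property
    def t_end(self) -> float:
        return self.ts[-1]

    def append(self, t1: float, y1: np.ndarray, f0: np.ndarray,
               f1: np.ndarray) -> None:
        # FSAL: f0 equals the stored derivative at the last knot except on
        # the very first step, where it patches the placeholder.
        self.fs[-1] = f0
        self.ts.append(float(t1))
        self.ys.append(y1)
        self.fs.append(f1)

    def prune(self, t_keep: float) -> None:
        """Forget knots strictly before ``t_keep`` (frees memory)."""
        i = bisect.bisect_right(self.ts, t_keep, lo=self._live) - 1
        self._live = max(self._live, i)
        if self._live > 4096:
            del self.ts[:self._live]
            del self.ys[:self._live]
            del self.fs[:self._live]
            self._live = 0

    def __call__(self, t: float) -> np.ndarray:
        if t > self.ts[-1] + 1e-9 * max(1.0, abs(t)):
            raise ValueError(f"history queried at t={t} beyond computed "
                             f"span end {self.ts[-1]}")
        if t <= self.t0:
            if t == self.t0 and self.ts[self._live] == self.t0:
                return self.ys[self._live]
            if self.history is None:
                raise ValueError(
                    f"history queried at t={t} before start {self.t0} but "
                    "no pre-initial history was provided")
            return np.asarray(self.history(t), dtype=float)
        i = bisect.bisect_right(self.ts, t, lo=self._live) - 1
        if i < self._live:
            raise ValueError(f"history at t={t} was pruned")
        if i >= len(self.ts) - 1:
            i = len(self.ts) - 2
        return _hermite(t, self.ts[i], self.ts[i + 1], self.ys[i],
                        self.ys[i + 1], self.fs[i], self.fs[i + 1])


@dataclass
class DdeSolution:
    """Raw solver output on a flat state vector."""

    t: np.ndarray
    y: np.ndarray                  # (n_times, n_dim)
    dense: DenseOutput | None
    diagnostics: dict = field(default_factory=dict)


def solve_dde(rhs: Callable[[float, np.ndarray, tuple], np.ndarray],
              t_span: tuple[float, float],
              y0: np.ndarray,
              *,
              delays: Sequence[float] = (),
              history: Callable[[float], np.ndarray] | None = None,
              t_eval: np.ndarray | None = None,
              rtol: float = 1e-6,
              atol: float = 1e-8,
              max_step: float = np.inf,
              first_step: float | None = None,
              keep_dense: bool = False,
              positivity_tol: float | None = None,
              component_name: Callable[[int], str] | None = None
              ) -> DdeSolution:
    """Integrate y' = rhs(t, y, (y(t - tau_1), ...)) by the method of steps.

    ``delays`` must be positive; the step size is capped at the shortest
    delay so delayed arguments always land in accepted history.  With no
    delays this is a plain adaptive RK2(3) ODE solver.  ``history(t)``
    supplies the solution for ``t <= t_span[0]`` and is required when
    delays are present.

    When ``positivity_tol`` is given (the model wrapper passes a fixed
    small threshold), negative components with magnitude below it are
    clipped to zero in the reported snapshots only, and larger
    violations raise; by default no positivity contract is enforced
    (generic systems may legitimately go negative).  Output snapshots
    are produced at ``t_eval`` via the dense interpolant, so changing
    the output cadence does not change the computed steps.
    """
    t0, t_end = float(t_span[0]), float(t_span[1])
    if not t_end > t0:
        raise ValueError(f"t_end={t_end} must exceed t_start={t0}")
    y0 = np.asarray(y0, dtype=float)
    delays = [float(d) for d in delays]
    if any(d <= 0 for d in delays):
        raise ValueError(f"delays must be positive, got {delays}")
    if delays and history is None:
        raise ValueError("delayed system requires a pre-initial history")
    max_delay = max(delays) if delays else 0.0
    hmax = min(max_step, t_end - t0, *(delays or (np.inf,)))

    if t_eval is None:
        t_eval = np.array([t0, t_end])
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if np.any(np.diff(t_eval) <= 0):
            raise ValueError("t_eval must be strictly increasing")
        if t_eval[0] < t0 or t_eval[-1] > t_end + 1e-12:
            raise ValueError("t_eval must lie within t_span")

    dense = DenseOutput(t0, y0, history)

    def delayed(t: float) -> tuple[np.ndarray, ...]:
        return tuple(dense(t - tau) for tau in delays)

    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    i_out = 0
    if t_eval[0] == t0:
        out_t.append(t0)
        out_y.append(y0.copy())
        i_out = 1

    def emit(t_lo, t_hi, ya, yb, fa, fb):
        nonlocal i_out
        while i_out < len(t_eval) and t_eval[i_out] <= t_hi + 1e-12:
            te = min(t_eval[i_out], t_hi)
            yi = _hermite(te, t_lo, t_hi, ya, yb, fa, fb)
            if positivity_tol is not None:
                if yi.min() < -positivity_tol:
                    _raise_positivity(yi, te, component_name,
                                      positivity_tol)
                np.clip(yi, 0.0, None, out=yi)
            out_t.append(te)
            out_y.append(yi)
            i_out += 1

    t = t0
    y = y0
    f = np.asarray(rhs(t, y, delayed(t)), dtype=float)
    n_fev = 1
    n_acc = 0
    n_rej = 0
    if first_step is not None:
        h = min(first_step, hmax)
    else:
        h = min(hmax, max(1e-6, 0.01 * (t_end - t0)))
    last_rejected = False

    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        h = min(h, hmax, t_end - t)
        if h < 1e-10 * max(1.0, abs(t)):
            raise RuntimeError(
                f"step size underflow at t={t:.6g} h (h={h:.3g}); the "
                "problem is too stiff for the explicit pair at these "
                "tolerances")
        k1 = f
        k2 = np.asarray(rhs(t + 0.5 * h, y + (0.5 * h) * k1,
                            delayed(t + 0.5 * h)), dtype=float)
        k3 = np.asarray(rhs(t + 0.75 * h, y + (0.75 * h) * k2,
                            delayed(t + 0.75 * h)), dtype=float)
        y_new = y + h * ((2.0 / 9.0) * k1 + (1.0 / 3.0) * k2
                         + (4.0 / 9.0) * k3)
        t_new = t + h
        k4 = np.asarray(rhs(t_new, y_new, delayed(t_new)), dtype=float)
        n_fev += 3
        if not np.isfinite(y_new).all():
            _raise_nonfinite(y_new, t_new, component_name)
        err = h * ((-5.0 / 72.0) * k1 + (1.0 / 12.0) * k2
                   + (1.0 / 9.0) * k3 + (-1.0 / 8.0) * k4)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        ratio = err / scale
        enorm = float(np.sqrt(np.mean(ratio * ratio)))

        if enorm <= 1.0:
            if positivity_tol is not None and \
                    float(y_new.min()) < -positivity_tol:
                _raise_positivity(y_new, t_new, component_name,
                                  positivity_tol)
            dense.append(t_new, y_new, k1, k4)
            emit(t, t_new, y, y_new, k1, k4)
            t, y, f = t_new, y_new, k4   # FSAL
            n_acc += 1
            if not keep_dense and max_delay > 0:
                dense.prune(t - max_delay - 2 * hmax
                            if np.isfinite(hmax) else t - max_delay - h)
            elif not keep_dense:
                dense.prune(t)
            factor = 5.0 if enorm == 0 else min(
                5.0, max(0.2, 0.9 * enorm ** (-1.0 / 3.0)))
            if last_rejected:
                factor = min(factor, 1.0)
            h *= factor
            last_rejected = False
        else:
            n_rej += 1
            last_rejected = True
            h *= min(0.9, max(0.1, 0.9 * enorm ** (-1.0 / 3.0)))

    # flush output points that coincide with t_end up to roundoff
    while i_out < len(t_eval):
        out_t.append(float(t_eval[i_out]))
        yi = y.copy()
        if positivity_tol is not None:
            np.clip(yi, 0.0, None, out=yi)
        out_y.append(yi)
        i_out += 1

    diagnostics = {"n_steps": n_acc, "n_rejected": n_rej, "n_fevals": n_fev}
    return DdeSolution(np.array(out_t), np.array(out_y),
                       dense if keep_dense else None, diagnostics)


def _raise_nonfinite(y, t, component_name):
    idx = int(np.argmax(~np.isfinite(y)))
    where = component_name(idx) if component_name else f"component {idx}"
    raise FloatingPointError(
        f"numerical failure: non-finite value in {where} at t={t:.6g} h")


def _raise_positivity(y, t, component_name, tol):
    idx = int(np.argmin(y))
    where = component_name(idx) if component_name else f"component {idx}"
    raise RuntimeError(
        f"positivity violation: {where} = {y[idx]:.3e} < -{tol:.1e} "
        f"at t={t:.6g} h")


# --------------------------------------------------------------------------
# model-level interface

@dataclass
class Trajectory:
    """Time-stamped sequence of system states with solver metadata.

    ``data`` has shape (n_times, n_fields, n_nodes) in the canonical
    field order; the first snapshot equals the initial condition
    exactly.  When ``dense`` is retained the full continuous solution
    (and hence the history tail needed for a restart) is available.
    """

    times: np.ndarray
    data: np.ndarray
    grid: RadialGrid
    params: ParameterSet
    diagnostics: dict
    rtol: float
    atol: float
    dense: DenseOutput | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("output times must be strictly increasing")

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def field(self, name: str) -> np.ndarray:
        """(n_times, n_nodes) array of one field."""
        return self.data[:, FIELD_INDEX[name], :]

    def state(self, i: int) -> SystemState:
        return SystemState.from_stack(float(self.times[i]), self.data[i])

    def integral(self, name: str) -> np.ndarray:
        """Area integral of a field over the disc at every output time."""
        return self.field(name) @ self.grid.cell_areas


def _component_namer(n_nodes: int):
    def name(idx: int) -> str:
        return (f"field {FIELD_NAMES[idx // n_nodes]} at node "
                f"{idx % n_nodes}")
    return name


def integrate(initial: SystemState,
              history: Callable[[float], np.ndarray],
              params: ParameterSet,
              grid: RadialGrid,
              t_end: float,
              *,
              rtol: float = 1e-6,
              atol: float = 1e-8,
              output_dt: float = 1.0,
              t_eval: np.ndarray | None = None,
              keep_dense: bool = False,
              warn_boundary: bool = True,
              positivity_tol: float | None = 1e-6) -> Trajectory:
    """Integrate the full model from ``initial`` up to ``t_end`` hours.

    The right-hand side couples the reaction/switching kinetics with the
    radial diffusion of the four chemical species; the delayed states
    are drawn from the evolving dense history, with ``history(t)``
    (stacked (10, n) array) supplying times at or before the start.
    Snapshots are taken every ``output_dt`` hours unless an explicit
    ``t_eval`` is given.

    ``positivity_tol`` enforces the nonnegativity contract: snapshot
    values in (-tol, 0) are clipped to zero and larger violations
    raise.  The default threshold of 1e-6 is deliberately decoupled
    from ``atol`` (which is pushed far below it to keep the unstable
    far field free of noise seeds); pass ``None`` to disable, e.g. for
    parameter values so far from the reference set that the delayed
    catabolic drain legitimately overshoots zero.
    """
    n = grid.n_nodes
    if initial.n_nodes != n:
        raise ValueError(f"initial state has {initial.n_nodes} nodes, "
                         f"grid has {n}")
    t0 = float(initial.t)
    if t_eval is None:
        t_eval = np.arange(t0, t_end + 0.5 * output_dt, output_dt)
        if t_eval[-1] < t_end:
            t_eval = np.append(t_eval, t_end)
    shape = (len(FIELD_NAMES), n)
    chem = [(FIELD_INDEX[name], getattr(params, "D_" + name))
            for name in CHEMICAL_FIELDS]

    def rhs(t, y_flat, delayed):
        y = y_flat.reshape(shape)
        d = reaction_rates(y, delayed[0].reshape(shape),
                           delayed[1].reshape(shape), params)
        for idx, D in chem:
            if D > 0:
                d[idx] += D * grid.laplacian(y[idx])
        return d.ravel()

    def hist_flat(t):
        return np.asarray(history(t), dtype=float).reshape(-1)

    sol = solve_dde(rhs, (t0, t_end), initial.stack().ravel(),
                    delays=(params.tau_1, params.tau_2),
                    history=hist_flat, t_eval=t_eval,
                    rtol=rtol, atol=atol, keep_dense=keep_dense,
                    positivity_tol=positivity_tol,
                    component_name=_component_namer(n))
    data = sol.y.reshape(len(sol.t), *shape)
    # first snapshot is the initial condition, bit-exact
    data[0] = initial.stack()
    traj = Trajectory(sol.t, data, grid, params, sol.diagnostics,
                      rtol, atol, dense=sol.dense)
    if warn_boundary:
        for name in CHEMICAL_FIELDS:
            if check_boundary_contact(grid, traj.field(name).max(axis=0),
                                      name):
                break
    return traj


# --------------------------------------------------------------------------
# checkpoint / restart

def make_checkpoint(traj: Trajectory, t_restart: float) -> dict:
    """Extract state plus dense history tail at an interior time.

    Requires the trajectory to have been integrated with
    ``keep_dense=True``.  The checkpoint holds everything a restart
    needs: the interpolated state at ``t_restart`` and the Hermite knots
    covering the preceding delay window (plus the constant pre-initial
    history when the window reaches before the start).
    """
    if traj.dense is None:
        raise ValueError("trajectory has no dense history tail; rerun with "
                         "keep_dense=True to enable checkpointing")
    t0 = traj.dense.t0
    if not (t0 <= t_restart <= traj.t_end):
        raise ValueError(f"restart time {t_restart} outside trajectory span "
                         f"[{t0}, {traj.t_end}]")
    dense = traj.dense
    tail_start = t_restart - traj.params.max_delay
    i0 = max(0, bisect.bisect_right(dense.ts, tail_start) - 1)
    i1 = bisect.bisect_left(dense.ts, t_restart)
    knots_t = dense.ts[i0:i1 + 1]
    pre = None
    if (tail_start <= t0 or not knots_t) and dense.history is not None:
        pre = np.asarray(dense.history(min(tail_start, t0)), dtype=float)
    return {
        "t_restart": float(t_restart),
        "t0": t0,
        "y_restart": dense(t_restart),
        "knots_t": np.array(knots_t),
        "knots_y": np.array(dense.ys[i0:i1 + 1]),
        "knots_f": np.array(dense.fs[i0:i1 + 1]),
        "pre_history": pre,
        "params": traj.params.to_dict(),
        "rtol": traj.rtol,
        "atol": traj.atol,
    }


def resume(checkpoint: dict, grid: RadialGrid, t_end: float,
           *, t_eval: np.ndarray | None = None,
           keep_dense: bool = False) -> Trajectory:
    """Continue a checkpointed run to ``t_end``."""
    params = ParameterSet.from_dict(checkpoint["params"])
    t_r = checkpoint["t_restart"]
    t0 = checkpoint["t0"]
    knots_t = checkpoint["knots_t"]
    knots_y = checkpoint["knots_y"]
    knots_f = checkpoint["knots_f"]
    pre = checkpoint.get("pre_history")

    def history(t: float) -> np.ndarray:
        if t < t0 or len(knots_t) == 0 or t < knots_t[0]:
            if pre is None:
                raise ValueError("checkpoint history tail does not cover "
                                 f"t={t}")
            return pre
        if t == t0 and knots_t[0] > t0:
            return pre
        i = int(np.searchsorted(knots_t, t, side="right")) - 1
        i = min(max(i, 0), len(knots_t) - 2)
        if len(knots_t) < 2:
            return knots_y[0]
        return _hermite(t, knots_t[i], knots_t[i + 1], knots_y[i],
                        knots_y[i + 1], knots_f[i], knots_f[i + 1])

    n = grid.n_nodes
    initial = SystemState.from_stack(
        t_r, checkpoint["y_restart"].reshape(len(FIELD_NAMES), n))
    return integrate(initial, history, params, grid, t_end,
                     rtol=checkpoint["rtol"], atol=checkpoint["atol"],
                     t_eval=t_eval, keep_dense=keep_dense,
                     warn_boundary=False)


def checkpoint_roundtrip(traj: Trajectory, t_restart: float) -> Trajectory:
    """Serialize at ``t_restart``, restart, and run to the original end.

    The restarted trajectory agrees with the uninterrupted one at
    ``t_end`` to within a small multiple of the integration tolerance.
    """
    cp = make_checkpoint(traj, t_restart)
    t_eval = traj.times[traj.times >= t_restart - 1e-12]
    if t_eval[0] > t_restart:
        t_eval = np.insert(t_eval, 0, t_restart)
    return resume(cp, traj.grid, traj.t_end, t_eval=t_eval)
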
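"""Canonical injury scenarios.

The reference experiment places a necrotic disc of radius 0.25 mm in an
otherwise healthy cartilage field and follows the response for ten
days.  Two parameterisations are shipped:

``no_epo``
    EPO production switched off (``sigma_P = 0``): the pro-inflammatory
    cascade runs unopposed and the lesion spreads without limit.
``with_epo``
    The full model: after the signalling delays elapse, EPO produced by
    healthy cells ahead of the front crosses the critical level, the
    threshold gate closes, and the penumbra stops expanding.

A third diagnostic configuration (``h_one``) forces the threshold gate
identically to one, demonstrating the unbounded self-amplification of
the alarmin/TNF-alpha loop when no anti-inflammatory control acts on
the healthy -> catabolic switch.

The two physiological regimes differ only in their parameter values;
they run through the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dde_engine import ConstantHistory, Trajectory, integrate
from .model_core import (ParameterSet, SystemState,
                         h_identically_one_mode)
from .radial_grid import RadialGrid, build_grid

__all__ = [
    "ScenarioSpec",
    "make_injury_initial_condition",
    "run_scenario",
    "run_no_epo",
    "run_with_epo",
    "run_h_one",
    "reference_scenario",
]

REFERENCE_NAMES = ("no_epo", "with_epo")


@dataclass
class ScenarioSpec:
    """Everything needed to reproduce one simulation run."""

    name: str = "custom"
    params: ParameterSet = field(default_factory=ParameterSet)
    injury_radius: float = 0.25        # mm
    injury_density: float | None = None  # cells/mm^2; default = C0
    C0: float = 100.0                  # background healthy density
    U0: float = 1.0                    # background matrix density
    horizon: float = 240.0             # h (ten days)
    r_max: float = 5.0                 # mm
    n_nodes: int = 200
    rtol: float = 1e-6
    atol: float = 1e-12
    output_dt: float = 1.0             # h

    def __post_init__(self) -> None:
        if not 0 < self.injury_radius < self.r_max:
            raise ValueError(
                f"injury radius {self.injury_radius} mm must lie inside the "
                f"domain radius {self.r_max} mm")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.C0 < 0 or self.U0 < 0:
            raise ValueError("background densities must be >= 0")
        if self.injury_density is not None and self.injury_density < 0:
            raise ValueError("injury density must be >= 0")

    def build_grid(self) -> RadialGrid:
        return build_grid(self.r_max, self.n_nodes)

    def with_params(self, **updates) -> "ScenarioSpec":
        return replace(self, params=self.params.with_updates(**updates))


def make_injury_initial_condition(spec: ScenarioSpec, grid: RadialGrid
                                  ) -> tuple[SystemState, ConstantHistory]:
    """Initial state and pre-injury history for an acute necrotic disc.

    At t = 0 the cells inside the injury radius are necrotic (``D_N``)
    and absent from the healthy field; the annulus cell straddling the
    disc edge is split by area-overlap fraction.  Chemicals start at
    zero and the matrix at ``U0`` everywhere.  The pre-initial history
    is the *pre-injury* equilibrium -- healthy cells everywhere at
    ``C0``, no necrotic pool -- since the injury happens at t = 0; no
    delayed term references the healthy field, so this choice is a
    documentation convention rather than a dynamical one.
    """
    a = spec.injury_radius
    e0, e1 = grid.edges[:-1], grid.edges[1:]
    overlap = (np.minimum(e1, a) ** 2 - np.minimum(e0, a) ** 2) \
        / (e1 ** 2 - e0 ** 2)
    overlap = np.clip(overlap, 0.0, 1.0)
    density = spec.C0 if spec.injury_density is None else spec.injury_density

    state = SystemState.zeros(grid.n_nodes)
    state.D_N[:] = density * overlap
    state.C[:] = spec.C0 * (1.0 - overlap)
    state.U[:] = spec.U0

    pre = SystemState.zeros(grid.n_nodes)
    pre.C[:] = spec.C0
    pre.U[:] = spec.U0
    return state, ConstantHistory(pre.stack(), t_start=0.0)


def run_scenario(spec: ScenarioSpec, *, keep_dense: bool = False,
                 warn_boundary: bool = True,
                 positivity_tol: float | None = 1e-6) -> Trajectory:
    """Build the grid and initial condition for ``spec`` and integrate."""
    grid = spec.build_grid()
    initial, history = make_injury_initial_condition(spec, grid)
    return integrate(initial, history, spec.params, grid, spec.horizon,
                     rtol=spec.rtol, atol=spec.atol,
                     output_dt=spec.output_dt, keep_dense=keep_dense,
                     warn_boundary=warn_boundary,
                     positivity_tol=positivity_tol)


def run_no_epo(spec: ScenarioSpec | None = None, **kwargs) -> Trajectory:
    """The unopposed-inflammation reference run (``sigma_P = 0``)."""
    if spec is None:
        spec = reference_scenario("no_epo")
    if spec.params.sigma_P != 0:
        raise ValueError("the no-EPO scenario requires sigma_P = 0 "
                         f"(got {spec.params.sigma_P})")
    return run_scenario(spec, **kwargs)


def run_with_epo(spec: ScenarioSpec | None = None, **kwargs) -> Trajectory:
    """The full-model reference run with the EPO rescue pathway active."""
    if spec is None:
        spec = reference_scenario("with_epo")
    return run_scenario(spec, **kwargs)


def run_h_one(spec: ScenarioSpec | None = None, **kwargs) -> Trajectory:
    """Diagnostic run with the threshold gate identically one.

    Demonstrates the "infinite feedback" of the pro-inflammatory arm:
    with the gate never closing, the penumbra grows until the healthy
    population is exhausted regardless of EPO.
    """
    if spec is None:
        spec = reference_scenario("with_epo")
    spec = replace(spec, name=spec.name + "_h_one",
                   params=h_identically_one_mode(spec.params))
    return run_scenario(spec, **kwargs)


def reference_scenario(name: str) -> ScenarioSpec:
    """Load a shipped reference scenario (``no_epo`` or ``with_epo``)."""
    from .cli_io import load_packaged_config
    if name not in REFERENCE_NAMES:
        raise ValueError(f"unknown reference scenario {name!r}; "
                         f"choose from {REFERENCE_NAMES}")
    spec, _ = load_packaged_config(name)
    return spec
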
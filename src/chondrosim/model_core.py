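"""Kinetics of the cartilage lesion injury-response model.

The model describes a radially symmetric patch of articular cartilage
after an acute injury.  Chondrocytes are immobile (fixed in matrix), so
all spatial coupling is through four diffusible chemical species; cells
only change *state* in place.  The state fields are

chemical concentrations (arbitrary concentration units, a.u.)
    ``R``    reactive oxygen species (ROS), secreted by catabolic cells;
             the trigger for EPO production by healthy cells
    ``M``    alarmins / damage-associated molecular patterns (DAMPs),
             released by necrotic cells and by degraded matrix
    ``F``    TNF-alpha, the pro-inflammatory cytokine: drives cell-state
             switching, apoptosis, matrix degradation, and suppresses
             EPO production
    ``P``    erythropoietin (EPO), the anti-inflammatory cytokine:
             rescues EPOR-active cells and, above the critical level
             ``P_c``, shuts down the healthy -> catabolic switch

tissue fields (no diffusion)
    ``U``    extracellular matrix density (matrix units); degraded by
             TNF-alpha, releasing DAMPs -- a feedback loop that sustains
             the alarmin signal beyond the initial necrotic burst
    ``C``    healthy chondrocytes, cells / mm^2
    ``S_T``  catabolic ("sick") chondrocytes: produce ROS and TNF-alpha
    ``S_A``  EPOR-active chondrocytes: express the EPO receptor and may
             revert to healthy under EPO signalling
    ``D_N``  necrotic cells from the initial injury; decay to inert
    ``D_A``  cumulative apoptotic cells -- a bookkeeping ledger only,
             apoptotic cells never feed back into the dynamics

Two discrete time delays enter the switching terms: ``tau_1`` (hours)
between TNF-alpha signalling of a catabolic cell and expression of the
EPO receptor, and ``tau_2`` (hours) between ROS signalling of a healthy
cell and the onset of EPO secretion.  All rate terms saturate with
Michaelis-Menten factors x/(lambda + x); the hard threshold function
``threshold_H`` gates the healthy -> catabolic switch so that it is
permitted only while the local EPO concentration is below ``P_c``.

Units: hours for time, mm for space, cells/mm^2 for densities;
concentrations are normalised so the half-saturation constants are
order one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FIELD_NAMES",
    "CHEMICAL_FIELDS",
    "ParameterSet",
    "SystemState",
    "PARAM_INFO",
    "saturation",
    "threshold_H",
    "reaction_rates",
    "reaction_rhs",
    "h_identically_one_mode",
]

#: Canonical field order used by every stacked-array interface.
FIELD_NAMES = ("R", "M", "F", "P", "U", "C", "S_T", "S_A", "D_N", "D_A")
FIELD_INDEX = {name: i for i, name in enumerate(FIELD_NAMES)}

#: The diffusing species, in stacked order (cells and matrix do not move).
CHEMICAL_FIELDS = ("R", "M", "F", "P")

_iR, _iM, _iF, _iP, _iU, _iC, _iST, _iSA, _iDN, _iDA = range(10)


# --------------------------------------------------------------------------
# parameters

#: name -> (default value, units, provenance, one-line meaning).
#: Provenance "literature-range" marks the two delays, whose physiological
#: ranges are reported in the experimental literature (8-12 h for EPOR
#: expression, 20-24 h for EPO synthesis onset); every other number is
#: "calibrated": chosen so that the reference scenarios reproduce the
#: expected qualitative injury-response regimes (see docs/methods.md).
PARAM_INFO: dict[str, tuple[float, str, str, str]] = {
    "D_R": (0.02, "mm^2/h", "calibrated", "ROS diffusivity"),
    "D_M": (0.002, "mm^2/h", "calibrated", "DAMP diffusivity"),
    "D_F": (0.002, "mm^2/h", "calibrated", "TNF-alpha diffusivity"),
    "D_P": (0.08, "mm^2/h", "calibrated", "EPO diffusivity"),
    "delta_R": (0.25, "1/h", "calibrated", "ROS decay rate"),
    "delta_M": (0.25, "1/h", "calibrated", "DAMP decay rate"),
    "delta_F": (0.3, "1/h", "calibrated", "TNF-alpha decay rate"),
    "delta_P": (0.005, "1/h", "calibrated", "EPO decay rate"),
    "sigma_R": (0.008, "a.u. mm^2/(cell h)", "calibrated",
                "ROS production per catabolic cell"),
    "sigma_M": (0.008, "a.u. mm^2/(cell h)", "calibrated",
                "DAMP release per necrotic cell"),
    "sigma_F": (0.015, "a.u. mm^2/(cell h)", "calibrated",
                "TNF-alpha production per catabolic cell"),
    "sigma_P": (0.02, "a.u. mm^2/(cell h)", "calibrated",
                "EPO production per healthy cell"),
    "delta_U": (0.06, "1/h", "calibrated",
                "matrix degradation rate under saturating TNF-alpha"),
    "lambda_R": (8.0, "a.u.", "calibrated", "ROS half-saturation"),
    "lambda_M": (0.7, "a.u.", "calibrated", "DAMP half-saturation"),
    "lambda_F": (1.0, "a.u.", "calibrated", "TNF-alpha half-saturation"),
    "lambda_P": (0.3, "a.u.", "calibrated", "EPO half-saturation"),
    "Lambda": (150.0, "a.u.", "calibrated",
               "TNF-alpha inhibition constant in EPO production"),
    "alpha": (0.015, "1/h", "calibrated",
              "EPOR-active -> healthy reversion rate under EPO"),
    "beta_1": (0.3, "1/h", "calibrated",
               "healthy -> catabolic switching rate driven by DAMPs"),
    "beta_2": (0.02, "1/h", "calibrated",
               "healthy -> catabolic switching rate driven by TNF-alpha"),
    "gamma": (0.02, "1/h", "calibrated",
              "catabolic -> EPOR-active switching rate (delayed by tau_1)"),
    "nu": (0.015, "1/h", "calibrated",
           "catabolic apoptosis rate (requires TNF-alpha AND DAMPs)"),
    "mu_SA": (0.01, "1/h", "calibrated", "EPOR-active apoptosis rate"),
    "mu_DN": (0.06, "1/h", "calibrated", "necrotic decay-to-inert rate"),
    "tau_1": (12.0, "h", "literature-range",
              "delay before EPOR expression (8-12 h; upper end)"),
    "tau_2": (24.0, "h", "literature-range",
              "delay before EPO synthesis onset (20-24 h; fixed at 24)"),
    "P_c": (0.4, "a.u.", "calibrated",
            "critical EPO level gating the healthy -> catabolic switch"),
    "h_width": (0.0, "a.u.", "calibrated",
                "smoothing width of the threshold gate (0 = hard switch)"),
}

#: Half-saturation constants, the TNF inhibition constant and the
#: reversion rate must be strictly positive (they sit in denominators or
#: define the rescue pathway); everything else only needs to be >= 0.
STRICTLY_POSITIVE = ("lambda_R", "lambda_M", "lambda_F", "lambda_P",
                     "Lambda", "alpha")


@dataclass(frozen=True)
class ParameterSet:
    """All rate, saturation, diffusion, delay and threshold constants.

    Defaults are the calibrated "with-EPO" reference values (see
    :data:`PARAM_INFO` for units and provenance).  Instances are frozen;
    derive variants with :meth:`with_updates`.
    """

    D_R: float = PARAM_INFO["D_R"][0]
    D_M: float = PARAM_INFO["D_M"][0]
    D_F: float = PARAM_INFO["D_F"][0]
    D_P: float = PARAM_INFO["D_P"][0]
    delta_R: float = PARAM_INFO["delta_R"][0]
    delta_M: float = PARAM_INFO["delta_M"][0]
    delta_F: float = PARAM_INFO["delta_F"][0]
    delta_P: float = PARAM_INFO["delta_P"][0]
    sigma_R: float = PARAM_INFO["sigma_R"][0]
    sigma_M: float = PARAM_INFO["sigma_M"][0]
    sigma_F: float = PARAM_INFO["sigma_F"][0]
    sigma_P: float = PARAM_INFO["sigma_P"][0]
    delta_U: float = PARAM_INFO["delta_U"][0]
    lambda_R: float = PARAM_INFO["lambda_R"][0]
    lambda_M: float = PARAM_INFO["lambda_M"][0]
    lambda_F: float = PARAM_INFO["lambda_F"][0]
    lambda_P: float = PARAM_INFO["lambda_P"][0]
    Lambda: float = PARAM_INFO["Lambda"][0]
    alpha: float = PARAM_INFO["alpha"][0]
    beta_1: float = PARAM_INFO["beta_1"][0]
    beta_2: float = PARAM_INFO["beta_2"][0]
    gamma: float = PARAM_INFO["gamma"][0]
    nu: float = PARAM_INFO["nu"][0]
    mu_SA: float = PARAM_INFO["mu_SA"][0]
    mu_DN: float = PARAM_INFO["mu_DN"][0]
    tau_1: float = PARAM_INFO["tau_1"][0]
    tau_2: float = PARAM_INFO["tau_2"][0]
    P_c: float = PARAM_INFO["P_c"][0]
    h_width: float = PARAM_INFO["h_width"][0]

    def __post_init__(self) -> None:
        problems = []
        for name in PARAM_INFO:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or math.isnan(value):
                problems.append(f"{name} = {value!r} is not a valid number")
                continue
            if name in STRICTLY_POSITIVE:
                if not value > 0:
                    problems.append(
                        f"{name} = {value} violates the strict-positivity "
                        f"rule ({name} must be > 0)")
            elif value < 0:
                problems.append(f"{name} = {value} must be >= 0")
        if problems:
            raise ValueError("invalid ParameterSet: " + "; ".join(problems))

    def with_updates(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given symbols replaced (re-validated)."""
        unknown = set(updates) - set(PARAM_INFO)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_INFO}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParameterSet":
        unknown = set(values) - set(PARAM_INFO)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**values)

    @property
    def max_delay(self) -> float:
        return max(self.tau_1, self.tau_2)


def h_identically_one_mode(params: ParameterSet) -> ParameterSet:
    """Variant in which the threshold gate is identically one.

    Operationally the critical EPO level is set to ``+inf`` so that
    ``threshold_H(P - P_c)`` evaluates to 1 for every finite EPO level:
    the healthy -> catabolic switch is never shut off.  This is the
    diagnostic "infinite feedback" configuration in which the
    pro-inflammatory arm is free to amplify itself without limit.
    """
    return dataclasses.replace(params, P_c=math.inf)


# --------------------------------------------------------------------------
# state container

@dataclass
class SystemState:
    """All model fields on one grid at a single instant ``t`` (hours).

    ``D_A`` is an optional cumulative-apoptosis ledger: it is carried for
    bookkeeping (total cell conservation) and never feeds back.
    """

    t: float
    R: np.ndarray
    M: np.ndarray
    F: np.ndarray
    P: np.ndarray
    U: np.ndarray
    C: np.ndarray
    S_T: np.ndarray
    S_A: np.ndarray
    D_N: np.ndarray
    D_A: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.R.shape
        for name in FIELD_NAMES[:-1]:
            if getattr(self, name).shape != n:
                raise ValueError(
                    f"field {name} has shape {getattr(self, name).shape}, "
                    f"expected {n}")
        if self.D_A is None:
            self.D_A = np.zeros_like(self.R)
        elif self.D_A.shape != n:
            raise ValueError(f"field D_A has shape {self.D_A.shape}, "
                             f"expected {n}")

    @property
    def n_nodes(self) -> int:
        return self.R.shape[0]

    def stack(self) -> np.ndarray:
        """Return the (10, n_nodes) stacked array in canonical order."""
        return np.stack([getattr(self, name) for name in FIELD_NAMES])

    @classmethod
    def from_stack(cls, t: float, y: np.ndarray) -> "SystemState":
        if y.ndim != 2 or y.shape[0] != len(FIELD_NAMES):
            raise ValueError(f"expected a ({len(FIELD_NAMES)}, n) array, "
                             f"got shape {y.shape}")
        return cls(t, *(np.asarray(y[i], dtype=float) for i in range(10)))

    @classmethod
    def zeros(cls, n_nodes: int, t: float = 0.0) -> "SystemState":
        return cls.from_stack(t, np.zeros((len(FIELD_NAMES), n_nodes)))


# --------------------------------------------------------------------------
# elementary kinetic forms

def saturation(x, lam):
    """Michaelis-Menten saturation fraction x / (lam + x) in [0, 1).

    Monotone increasing in ``x``; equals 1/2 at the half-saturation
    constant ``lam``.  Raises on negative input or non-positive ``lam``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(lam > 0):
        raise ValueError(f"half-saturation constant must be > 0, got {lam}")
    if np.any(x < 0):
        raise ValueError("saturation argument must be >= 0")
    out = x / (lam + x)
    return float(out) if out.ndim == 0 else out


def threshold_H(s):
    """Threshold gate: 1 where ``s < 0``, 0 where ``s >= 0``.

    Note the orientation, reversed relative to a conventional Heaviside
    step: applied to ``P - P_c`` it *permits* the healthy -> catabolic
    switch only while the EPO level is still below the critical level.
    """
    s = np.asarray(s, dtype=float)
    out = (s < 0).astype(float)
    return float(out) if out.ndim == 0 else out


def _sat(x, lam):
    # internal, clips tiny solver-induced negatives instead of raising
    xp = np.maximum(x, 0.0)
    return xp / (lam + xp)


def _gate(P, params: ParameterSet):
    """Threshold gate H(P - P_c), optionally smoothed.

    With ``h_width > 0`` a logistic profile of that width replaces the
    hard switch -- a purely numerical device for solvers that dislike
    discontinuous right-hand sides (default off).
    """
    if params.h_width > 0.0:
        z = np.clip((P - params.P_c) / params.h_width, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(z))
    return (P < params.P_c).astype(float)


# --------------------------------------------------------------------------
# reaction right-hand side

def reaction_rates(y: np.ndarray, y_tau1: np.ndarray, y_tau2: np.ndarray,
                   params: ParameterSet) -> np.ndarray:
    """Reaction part of the time derivative on stacked (10, n) arrays.

    ``y`` is the current state, ``y_tau1``/``y_tau2`` the states at
    ``t - tau_1`` and ``t - tau_2``.  Diffusion is *not* included (see
    the radial-grid module).  This is the unchecked fast path used by
    the integrator; :func:`reaction_rhs` adds validation.

    The delayed quantities actually referenced are: the catabolic
    density and TNF-alpha level at ``t - tau_1`` (EPOR activation), and
    the ROS level at ``t - tau_2`` (EPO synthesis onset).  EPO
    production is proportional to the healthy population at the
    *current* time.
    """
    p = params
    R, M, F, P, U = y[_iR], y[_iM], y[_iF], y[_iP], y[_iU]
    C, ST, SA, DN = y[_iC], y[_iST], y[_iSA], y[_iDN]

    sat_M = _sat(M, p.lambda_M)
    sat_F = _sat(F, p.lambda_F)
    sat_P = _sat(P, p.lambda_P)
    sat_F1 = _sat(y_tau1[_iF], p.lambda_F)
    sat_R2 = _sat(y_tau2[_iR], p.lambda_R)
    gate = _gate(P, p)

    degradation = p.delta_U * U * sat_F          # matrix loss -> DAMP source
    conversion = C * gate * (p.beta_1 * sat_M + p.beta_2 * sat_F)
    activation = p.gamma * y_tau1[_iST] * sat_F1  # S_T -> S_A after tau_1
    reversion = p.alpha * SA * sat_P              # EPO rescue S_A -> C
    apoptosis_T = p.nu * ST * sat_F * sat_M       # needs TNF AND DAMPs
    apoptosis_A = p.mu_SA * SA * sat_F

    d = np.empty_like(y)
    d[_iR] = -p.delta_R * R + p.sigma_R * ST
    d[_iM] = -p.delta_M * M + p.sigma_M * DN + degradation
    d[_iF] = -p.delta_F * F + p.sigma_F * ST
    d[_iP] = (-p.delta_P * P
              + p.sigma_P * C * sat_R2 * (p.Lambda / (p.Lambda + np.maximum(F, 0.0))))
    d[_iU] = -degradation
    d[_iC] = reversion - conversion
    d[_iST] = conversion - activation - apoptosis_T
    d[_iSA] = activation - reversion - apoptosis_A
    d[_iDN] = -p.mu_DN * DN
    d[_iDA] = apoptosis_T + apoptosis_A
    return d


def _check_finite(y: np.ndarray, label: str) -> None:
    if not np.isfinite(y).all():
        bad = np.argwhere(~np.isfinite(y))
        field, node = bad[0]
        raise FloatingPointError(
            f"non-finite value in field {FIELD_NAMES[field]} at node {node} "
            f"({label})")


def reaction_rhs(state_now: SystemState, state_tau1: SystemState,
                 state_tau2: SystemState,
                 params: ParameterSet) -> dict[str, np.ndarray]:
    """Validated reaction-part derivative of all fields, per grid node.

    The three states must live on the same grid and the delayed states
    must be stamped at ``t - tau_1`` and ``t - tau_2``.  Returns a dict
    keyed by field name (including the ``D_A`` apoptosis ledger).
    """
    if not (state_now.n_nodes == state_tau1.n_nodes == state_tau2.n_nodes):
        raise ValueError(
            "grid mismatch: states have "
            f"{state_now.n_nodes}/{state_tau1.n_nodes}/{state_tau2.n_nodes} "
            "nodes")
    for state, tau, label in ((state_tau1, params.tau_1, "tau_1"),
                              (state_tau2, params.tau_2, "tau_2")):
        expected = state_now.t - tau
        if abs(state.t - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                f"delayed state for {label} is stamped t={state.t}, "
                f"expected t={expected}")
    y, y1, y2 = state_now.stack(), state_tau1.stack(), state_tau2.stack()
    for arr, label in ((y, "current state"), (y1, "tau_1 state"),
                       (y2, "tau_2 state")):
        _check_finite(arr, label)
    d = reaction_rates(y, y1, y2, params)
    return {name: d[i] for i, name in enumerate(FIELD_NAMES)}
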
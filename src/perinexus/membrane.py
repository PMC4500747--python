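"""Membrane electrophysiology: ionic currents, gating, channel partition.

The ionic model is a minimal Hodgkin-Huxley-type formulation: a fast inward
sodium current with m^3*h gating (rate constants of the classic cardiac
fast-sodium formulation) and an ohmic repolarizing potassium/leak current,

    I_ion = g_Na * m^3 * h * (V - E_Na) + g_K * (V - E_K)   [uA/cm^2].

Only the sodium and potassium peak conductances matter for the conduction
trends studied here; the interface accepts any ionic model object exposing
``current``/``step_state``/``resting_state`` so richer kinetics can be
dropped in.

Sodium channels are partitioned between junctional membrane (cell ends,
facing the narrow cleft) and lateral membrane.  ``junctional_fraction``
is the fraction of each cell's total sodium conductance placed on its
junctional patches: 0.11 reproduces a near-uniform surface density
("uniform" distribution), 0.90 concentrates channels at the intercalated
disc ("polarized" distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import TissueMesh, JUNCTIONAL, ConfigurationError

UNIFORM_FRACTION = 0.11
POLARIZED_FRACTION = 0.90


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane constants: capacitance (uF/cm^2), intracellular
    conductivity (mS/cm)."""

    c_m: float = 1.0
    sigma_i: float = 6.7

    def __post_init__(self):
        if self.c_m <= 0 or self.sigma_i <= 0:
            raise ConfigurationError("C_m and sigma_i must be > 0")


@dataclass(frozen=True)
class IonicModelParams:
    """Peak conductances (mS/cm^2, averaged over total cell membrane) and
    reversal potentials (mV)."""

    g_na: float = 23.0
    g_k: float = 0.3
    e_na: float = 54.4
    e_k: float = -85.0

    def __post_init__(self):
        if self.g_na < 0 or self.g_k < 0:
            raise ConfigurationError("conductances must be >= 0")


@dataclass(frozen=True)
class ChannelDistribution:
    """Fraction of each cell's total sodium conductance on junctional patches."""

    junctional_fraction: float = UNIFORM_FRACTION

    def __post_init__(self):
        if not (0.0 <= self.junctional_fraction <= 1.0):
            raise ConfigurationError("junctional_fraction must lie in [0, 1]")


@dataclass
class GatingState:
    """Per-patch activation (m) and inactivation (h) gates, each in [0, 1]."""

    m: np.ndarray
    h: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(self.m.copy(), self.h.copy())


# ---------------------------------------------------------------------------
# gating rate constants (classic cardiac fast-sodium kinetics)

def _alpha_m(v):
    x = v + 47.13
    # remove the removable singularity at x = 0
    denom = np.where(np.abs(x) < 1e-7, 0.1 - 0.005 * x, 1.0 - np.exp(-0.1 * x))
    num = np.where(np.abs(x) < 1e-7, 0.32, 0.32 * x)
    return num / denom


def _beta_m(v):
    return 0.08 * np.exp(-v / 11.0)


def _alpha_h(v):
    return np.where(v < -40.0, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)


def _beta_h(v):
    low = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
    high = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    return np.where(v < -40.0, low, high)


def gate_inf_tau(v):
    """Steady states and time constants (ms) of the m and h gates."""
    v = np.asarray(v, float)
    am, bm = _alpha_m(v), _beta_m(v)
    ah, bh = _alpha_h(v), _beta_h(v)
    return am / (am + bm), 1.0 / (am + bm), ah / (ah + bh), 1.0 / (ah + bh)


class SodiumPotassiumModel:
    """Fast sodium (m^3 h) + ohmic potassium/leak ionic model."""

    def __init__(self, params: IonicModelParams | None = None):
        self.params = params or IonicModelParams()

    def resting_potential(self) -> float:
        """Stable zero of the steady-state current, mV."""
        p = self.params
        if p.g_k == 0.0:
            return p.e_k

        def f(v):
            minf, _, hinf, _ = gate_inf_tau(v)
            return (p.g_na * minf ** 3 * hinf * (v - p.e_na)
                    + p.g_k * (v - p.e_k))

        return float(brentq(f, p.e_k - 5.0, -50.0))

    def initial_state(self, n: int, v_rest: float | None = None) -> GatingState:
        v = self.resting_potential() if v_rest is None else v_rest
        minf, _, hinf, _ = gate_inf_tau(v)
        return GatingState(np.full(n, float(minf)), np.full(n, float(hinf)))

    def current(self, v_m: np.ndarray, state: GatingState,
                g_na_patch: np.ndarray) -> np.ndarray:
        """Total ionic current density, uA/cm^2 (positive = outward)."""
        p = self.params
        i_na = g_na_patch * state.m ** 3 * state.h * (v_m - p.e_na)
        i_k = p.g_k * (v_m - p.e_k)
        return i_na + i_k

    def conductance(self, state: GatingState,
                    g_na_patch: np.ndarray) -> np.ndarray:
        """Instantaneous slope conductance (mS/cm^2) at frozen gates."""
        return g_na_patch * state.m ** 3 * state.h + self.params.g_k

    def step_state(self, state: GatingState, v_m: np.ndarray,
                   dt: float) -> GatingState:
        return step_gating(state, v_m, dt)


class PassiveMembrane:
    """Ohmic leak membrane I = G_leak (V - V_rest); used for RC validation."""

    def __init__(self, g_leak: float = 0.5, v_rest: float = -85.0):
        self.g_leak = g_leak
        self.v_rest = v_rest

    def resting_potential(self) -> float:
        return self.v_rest

    def initial_state(self, n: int, v_rest: float | None = None) -> GatingState:
        return GatingState(np.zeros(n), np.zeros(n))

    def current(self, v_m, state, g_na_patch):
        return self.g_leak * (np.asarray(v_m) - self.v_rest)

    def conductance(self, state, g_na_patch):
        return np.full_like(np.asarray(state.m, float), self.g_leak)

    def step_state(self, state, v_m, dt):
        return state


def step_gating(state: GatingState, v_m: np.ndarray, dt: float) -> GatingState:
    """Exponential (Rush-Larsen) update of the gating ODEs at frozen V_m.

    Exact for constant voltage; unconditionally keeps gates in [0, 1].
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    minf, taum, hinf, tauh = gate_inf_tau(np.asarray(v_m, float))
    m = minf + (state.m - minf) * np.exp(-dt / taum)
    h = hinf + (state.h - hinf) * np.exp(-dt / tauh)
    return GatingState(m, h)


def partition_channels(mesh: TissueMesh, dist: ChannelDistribution,
                       ionic: IonicModelParams) -> np.ndarray:
    """Per-patch sodium conductance density (mS/cm^2).

    Each cell's total sodium conductance ``g_na * (cell membrane area)`` is
    conserved: a fraction ``junctional_fraction`` is spread uniformly over
    the cell's junctional patch area, the rest over its lateral area.
    Cells without junctional membrane carry everything laterally.
    """
    f = dist.junctional_fraction
    g = np.zeros(mesh.n_patches)
    for ci in range(mesh.n_cells):
        sel = mesh.patch_cell == ci
        areas = mesh.patch_area[sel]
        junc = mesh.patch_class[sel] == JUNCTIONAL
        total = ionic.g_na * areas.sum()
        a_j = areas[junc].sum()
        a_l = areas[~junc].sum()
        dens = np.empty(sel.sum())
        if a_j == 0.0:
            dens[:] = total / a_l
        else:
            dens[junc] = f * total / a_j
            dens[~junc] = (1.0 - f) * total / a_l
        g[sel] = dens
    return g
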
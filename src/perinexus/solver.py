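"""Coupled intracellular/extracellular solver with Crank-Nicolson stepping.

Discrete formulation.  Within each cell the intracellular potential is
harmonic (Laplace's equation) and is discretized with linear triangular
finite elements on the corner nodes; the cleft network is a resistor graph
(cell-centered finite differences along cleft segments).  Membrane patches
couple the two: for patch voltage V = phi_i(midpoint) - phi_e(cleft node),

    M du/dt + A u + S^T diag(area) I_ion(V) = f(t),

with u = [phi_i; phi_e], M = S^T diag(C_m area) S the (singular) membrane
capacitance operator, A = blockdiag(K + G, L_e) collecting the intracellular
stiffness K, the gap-junction coupling G, and the cleft Laplacian L_e, and
f the stimulus current injected at intracellular nodes.  One cleft node is
clamped to 0 mV to fix the extracellular gauge (sealed no-flux borders
otherwise).  Crank-Nicolson averages the conductive/capacitive terms;
gating is advanced by an exponential update at the start-of-step voltage
and the ionic current enters explicitly, so the system matrix is constant
and a single sparse LU factorization is reused for every step.

Units: mV, ms, mS, uF, uA, cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, bmat, eye as speye
from scipy.sparse.linalg import splu, spsolve

from .geometry import TissueMesh, UM_TO_CM, ConfigurationError
from .membrane import MembraneParams, GatingState, SodiumPotassiumModel


class NumericalError(RuntimeError):
    """Linear solve failed or produced non-finite values."""


@dataclass
class StimulusConfig:
    """Edge current injection: 1 ms pulses at the chosen sheet edge.

    ``edge`` selects the stimulated cell column/row: 'left' drives
    longitudinal propagation, 'bottom' transverse.  ``amplitude`` is the
    total current per stimulated cell (uA).
    """

    edge: str = "left"
    amplitude: float = 0.01
    width_ms: float = 1.0
    start_ms: float = 0.1

    def __post_init__(self):
        if self.edge not in ("left", "right", "bottom", "top"):
            raise ConfigurationError("unknown stimulus edge %r" % self.edge)
        if self.width_ms <= 0:
            raise ConfigurationError("pulse width must be > 0")


@dataclass
class SolverConfig:
    dt: float = 0.005            # ms
    duration: float = 20.0       # ms
    sample_dt: float = 0.05      # ms, trace output resolution
    linear_tol: float = 1e-10
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigurationError("dt and duration must be > 0")


@dataclass
class SimState:
    phi_i: np.ndarray
    phi_e: np.ndarray
    gating: GatingState
    t: float = 0.0

    def copy(self) -> "SimState":
        return SimState(self.phi_i.copy(), self.phi_e.copy(),
                        self.gating.copy(), self.t)


# ---------------------------------------------------------------------------
# assembly

def _intracellular_stiffness(mesh: TissueMesh, sigma_i: float) -> csr_matrix:
    """Block-diagonal FEM stiffness over all cells, in mS (conductivity
    sigma_i times slab depth)."""
    depth_cm = mesh.shape.depth * UM_TO_CM
    rows, cols, vals = [], [], []
    for cell in mesh.cells:
        pts = cell.polygon * UM_TO_CM
        for tri in cell.triangles:
            p = pts[tri]
            b = np.array([p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]])
            c = np.array([p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]])
            area2 = b[0] * c[1] - b[1] * c[0]  # 2*area (signed, CCW > 0)
            ke = sigma_i * depth_cm / (2.0 * area2) * (np.outer(b, b) + np.outer(c, c))
            gids = cell.node_ids[tri]
            for a in range(3):
                for bb in range(3):
                    rows.append(gids[a])
                    cols.append(gids[bb])
                    vals.append(ke[a, bb])
    n = mesh.n_nodes
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _gap_junction_matrix(mesh: TissueMesh) -> csr_matrix:
    """Laplacian-like GJ coupling on intracellular nodes (mS)."""
    gjp = mesh.gap_junction
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for p, q in mesh.gj_pairs:
        scale = 1.0
        if gjp.spatial_profile is not None:
            scale = float(gjp.spatial_profile(*mesh.patch_midpoint[p]))
            if scale < 0:
                raise ConfigurationError("gap-junction profile must be >= 0")
        g = gjp.g_j_bar * scale * mesh.patch_area[p]
        idx = np.concatenate([mesh.patch_nodes[p], mesh.patch_nodes[q]])
        w = np.concatenate([mesh.patch_weights[p], -mesh.patch_weights[q]])
        # energy form g * (b_p phi - b_q phi)^2 -> g * w w^T
        for a in range(4):
            for b in range(4):
                rows.append(idx[a])
                cols.append(idx[b])
                vals.append(g * w[a] * w[b])
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _patch_operator(mesh: TissueMesh) -> csr_matrix:
    """S such that V_patch = S [phi_i; phi_e]."""
    npatch, ni, ne = mesh.n_patches, mesh.n_nodes, mesh.n_ecl
    rows = np.repeat(np.arange(npatch), 3)
    cols = np.concatenate([
        np.stack([mesh.patch_nodes[:, 0], mesh.patch_nodes[:, 1],
                  ni + mesh.patch_cleft], axis=1).ravel()
    ])
    vals = np.stack([mesh.patch_weights[:, 0], mesh.patch_weights[:, 1],
                     -np.ones(npatch)], axis=1).ravel()
    return coo_matrix((vals, (rows, cols)), shape=(npatch, ni + ne)).tocsr()


class DiscreteSystem:
    """Assembled operators for a mesh + membrane + ionic model."""

    def __init__(self, mesh: TissueMesh, membrane: MembraneParams | None = None,
                 ionic_model=None, g_na_patch: np.ndarray | None = None,
                 reference_node: int = 0):
        from .geometry import extracellular_laplacian
        from .membrane import IonicModelParams, partition_channels, ChannelDistribution

        self.mesh = mesh
        self.membrane = membrane or MembraneParams()
        self.ionic_model = ionic_model or SodiumPotassiumModel()
        if g_na_patch is None:
            g_na_patch = partition_channels(
                mesh, ChannelDistribution(), getattr(self.ionic_model, "params",
                                                     IonicModelParams()))
        self.g_na_patch = np.asarray(g_na_patch, float)

        self.n_i = mesh.n_nodes
        self.n_e = mesh.n_ecl
        self.n = self.n_i + self.n_e
        if not (0 <= reference_node < self.n_e):
            raise ConfigurationError("reference cleft node out of range")
        self.reference = self.n_i + reference_node

        K = _intracellular_stiffness(mesh, self.membrane.sigma_i)
        G = _gap_junction_matrix(mesh)
        Le = extracellular_laplacian(mesh)
        self.S = _patch_operator(mesh)
        cap = self.membrane.c_m * mesh.patch_area  # uF per patch
        self.cap = cap
        self.area = mesh.patch_area
        self.M = (self.S.T.multiply(cap) @ self.S).tocsr()
        self.A = bmat([[K + G, None], [None, Le]], format="csr")
        self._lu = None
        self._lu_dt = None
        self._rhs_mat = None

    # -- per-dt cached operators ------------------------------------------
    def _factorize(self, dt: float):
        if self._lu is not None and self._lu_dt == dt:
            return
        lhs = (self.M / dt + 0.5 * self.A).tolil()
        lhs.rows[self.reference] = [self.reference]
        lhs.data[self.reference] = [1.0]
        self._rhs_mat = (self.M / dt - 0.5 * self.A).tocsr()
        self._lu = splu(lhs.tocsc())
        self._lu_dt = dt

    # -- state helpers -----------------------------------------------------
    def resting_state(self) -> SimState:
        v_rest = self.ionic_model.resting_potential()
        phi_i = np.full(self.n_i, v_rest)
        phi_e = np.zeros(self.n_e)
        gating = self.ionic_model.initial_state(self.mesh.n_patches)
        return SimState(phi_i, phi_e, gating, 0.0)

    def patch_voltage(self, state: SimState) -> np.ndarray:
        return self.S @ np.concatenate([state.phi_i, state.phi_e])

    def cell_voltage(self, state: SimState) -> np.ndarray:
        """Patch-area-weighted mean V_m per cell, mV."""
        v = self.patch_voltage(state)
        w = self.area
        num = np.bincount(self.mesh.patch_cell, weights=w * v,
                          minlength=self.mesh.n_cells)
        den = np.bincount(self.mesh.patch_cell, weights=w,
                          minlength=self.mesh.n_cells)
        return num / den

    def stimulus_vector(self, stim: StimulusConfig) -> np.ndarray:
        """Per-node current loads (uA) for a unit-on stimulus."""
        rows, cols = self.mesh.cell_rows_cols()
        if stim.edge == "left":
            sel = cols == cols.min()
        elif stim.edge == "right":
            sel = cols == cols.max()
        elif stim.edge == "bottom":
            sel = rows == rows.min()
        else:
            sel = rows == rows.max()
        f = np.zeros(self.n)
        for ci in np.flatnonzero(sel):
            nid = self.mesh.cells[ci].node_ids
            f[nid] += stim.amplitude / len(nid)
        return f

    def ionic_load(self, state: SimState) -> np.ndarray:
        """S^T diag(area) I_ion at the current state (uA per node)."""
        v = self.patch_voltage(state)
        i_ion = self.ionic_model.current(v, state.gating, self.g_na_patch)
        return self.S.T @ (self.area * i_ion)

    def charge_residual(self, prev: SimState, new: SimState,
                        i_ion: np.ndarray, f_mid: np.ndarray,
                        dt: float) -> float:
        """Max abs current-balance residual of the extracellular rows (uA).

        Verifies that transmembrane + stimulus currents balance cleft
        network currents at the accepted step (gauge row excluded).
        """
        u0 = np.concatenate([prev.phi_i, prev.phi_e])
        u1 = np.concatenate([new.phi_i, new.phi_e])
        res = (self.M @ (u1 - u0) / dt + 0.5 * self.A @ (u1 + u0)
               + self.S.T @ (self.area * i_ion) - f_mid)
        res[self.reference] = 0.0
        return float(np.max(np.abs(res[self.n_i:])))


def assemble_system(mesh: TissueMesh, membrane: MembraneParams | None = None,
                    ionic_model=None,
                    g_na_patch: np.ndarray | None = None) -> DiscreteSystem:
    """Build the discrete operator set for a mesh (spec entry point)."""
    return DiscreteSystem(mesh, membrane, ionic_model, g_na_patch)


def advance(state: SimState, ops: DiscreteSystem,
            config: SolverConfig) -> SimState:
    """One Crank-Nicolson step of length ``config.dt``."""
    dt = config.dt
    ops._factorize(dt)
    gating = ops.ionic_model.step_state(
        state.gating, ops.patch_voltage(state), dt)
    mid_state = SimState(state.phi_i, state.phi_e, gating, state.t)
    v = ops.patch_voltage(mid_state)
    i_ion = ops.ionic_model.current(v, gating, ops.g_na_patch)

    stim = config.stimulus
    t_mid = state.t + 0.5 * dt
    on = stim.start_ms <= t_mid < stim.start_ms + stim.width_ms
    f = ops.stimulus_vector(stim) if on else np.zeros(ops.n)

    u0 = np.concatenate([state.phi_i, state.phi_e])
    rhs = ops._rhs_mat @ u0 - ops.S.T @ (ops.area * i_ion) + f
    rhs[ops.reference] = 0.0
    u1 = ops._lu.solve(rhs)
    if not np.all(np.isfinite(u1)):
        raise NumericalError(
            "non-finite solution at t=%.4f ms (dt=%g); "
            "check dt and conductances" % (state.t, dt))
    return SimState(u1[:ops.n_i], u1[ops.n_i:], gating, state.t + dt)


@dataclass
class ProtocolResult:
    """Sampled per-cell voltage traces from a paced run."""

    times: np.ndarray            # ms, (n_samples,)
    v_cells: np.ndarray          # mV, (n_samples, n_cells)
    cell_xy: np.ndarray          # um, cell centroids
    rows: np.ndarray
    cols: np.ndarray
    v_rest: float
    blocked: bool                # True if distal cells never depolarized
    config: SolverConfig
    final_state: SimState | None = None

    def trace(self, cell: int) -> np.ndarray:
        return self.v_cells[:, cell]


def run_protocol(ops: DiscreteSystem, config: SolverConfig,
                 activation_threshold: float = -20.0,
                 settle_ms: float = 3.0,
                 keep_final_state: bool = False) -> ProtocolResult:
    """Run a paced propagation protocol and record per-cell V_m traces.

    Stops early once every cell has crossed ``activation_threshold`` and a
    further ``settle_ms`` has elapsed (so the upstroke is fully sampled);
    otherwise runs to ``config.duration``.  If distal cells never activate
    the result is flagged ``blocked`` rather than failing silently.
    """
    state = ops.resting_state()
    v_rest = float(ops.ionic_model.resting_potential())
    n_steps = int(round(config.duration / config.dt))
    stride = max(1, int(round(config.sample_dt / config.dt)))

    times, vcs = [0.0], [ops.cell_voltage(state)]
    activated = vcs[0] > activation_threshold
    t_all_act = np.inf
    for k in range(1, n_steps + 1):
        state = advance(state, ops, config)
        if k % stride == 0 or k == n_steps:
            vc = ops.cell_voltage(state)
            times.append(state.t)
            vcs.append(vc)
            activated |= vc > activation_threshold
            if activated.all() and not np.isfinite(t_all_act):
                t_all_act = state.t
            if state.t >= t_all_act + settle_ms:
                break

    mesh = ops.mesh
    rows, cols = mesh.cell_rows_cols()
    return ProtocolResult(
        times=np.asarray(times), v_cells=np.asarray(vcs),
        cell_xy=mesh.cell_centers(), rows=rows, cols=cols, v_rest=v_rest,
        blocked=not bool(activated.all()), config=config,
        final_state=state if keep_final_state else None)
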
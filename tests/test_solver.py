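"""Solver: assembly oracles, conservation, gauge invariance, dynamics."""

import numpy as np
import pytest

from perinexus import (CellShape, SheetLayout, ExtracellularParams,
                       GapJunctionParams, build_sheet, MembraneParams,
                       IonicModelParams, ChannelDistribution,
                       SodiumPotassiumModel, PassiveMembrane,
                       partition_channels, assemble_system, advance,
                       run_protocol, SolverConfig, StimulusConfig, SimState,
                       ConfigurationError)
from perinexus.solver import _intracellular_stiffness
from perinexus.geometry import TissueMesh, Cell

from oracles import hand_assembled_unit_square_stiffness


def small_system(n_rows=2, n_cols=3, ionic=None, fraction=0.9, **kw):
    mesh = build_sheet(CellShape(), SheetLayout(n_rows, n_cols),
                       kw.get("extra", ExtracellularParams()),
                       kw.get("gj", GapJunctionParams(100.0)),
                       junctional_subdivisions=kw.get("k", 2))
    ionic = ionic or SodiumPotassiumModel()
    params = getattr(ionic, "params", IonicModelParams())
    g = partition_channels(mesh, ChannelDistribution(fraction), params)
    return mesh, assemble_system(mesh, MembraneParams(), ionic, g)


# -- assembly ---------------------------------------------------------------

def test_fem_stiffness_matches_hand_assembled_unit_square():
    """One square cell with unit conductivity and depth: stiffness equals
    the textbook two-triangle assembly (cm units; 1 cm x 1 cm square)."""
    square = np.array([[0.0, 0.0], [1e4, 0.0], [1e4, 1e4], [0.0, 1e4]])  # um
    cell = Cell(index=0, row=0, col=0, polygon=square,
                node_ids=np.arange(4), triangles=np.array([[0, 1, 2],
                                                           [0, 2, 3]]))
    mesh = TissueMesh(
        shape=CellShape(length=1e4, width=0.99e4, depth=1e4),
        layout=SheetLayout(1, 1), extracellular=ExtracellularParams(),
        gap_junction=GapJunctionParams(0.0), cells=[cell],
        node_xy=square, patch_cell=np.zeros(0, int),
        patch_class=np.zeros(0, int), patch_area=np.zeros(0),
        patch_length=np.zeros(0), patch_nodes=np.zeros((0, 2), int),
        patch_weights=np.zeros((0, 2)), patch_cleft=np.zeros(0, int),
        patch_partner=np.zeros(0, int), patch_midpoint=np.zeros((0, 2)),
        ecl_xy=np.zeros((1, 2)), ecl_edges=np.zeros((0, 2), int),
        ecl_edge_class=np.zeros(0, int), ecl_edge_halflen=np.zeros(0),
        ecl_conductance=np.zeros(0), gj_pairs=np.zeros((0, 2), int))
    K = _intracellular_stiffness(mesh, sigma_i=1.0).toarray()
    assert np.allclose(K, hand_assembled_unit_square_stiffness(1.0))


def test_stiffness_row_sums_zero():
    mesh, ops = small_system()
    K = _intracellular_stiffness(mesh, 6.7)
    assert np.allclose(np.asarray(K.sum(axis=1)).ravel(), 0.0, atol=1e-12)


def test_system_matrix_symmetry_and_gauge_nullspace():
    _, ops = small_system()
    A = ops.A
    assert abs(A - A.T).max() < 1e-10
    # a uniform potential on both spaces is in the null space of A
    ones = np.ones(ops.n)
    assert np.max(np.abs(A @ ones)) < 1e-9


def test_uniform_state_zero_residual_currents():
    """phi_i = phi_e = c gives V_m = 0 and zero network currents."""
    _, ops = small_system()
    c = 17.0
    u = np.concatenate([np.full(ops.n_i, c), np.full(ops.n_e, c)])
    assert np.max(np.abs(ops.A @ u)) < 1e-9
    state = SimState(u[:ops.n_i], u[ops.n_i:],
                     ops.ionic_model.initial_state(ops.mesh.n_patches), 0.0)
    assert np.max(np.abs(ops.patch_voltage(state))) < 1e-12


def test_reference_node_validation():
    mesh, _ = small_system()
    from perinexus.solver import DiscreteSystem
    with pytest.raises(ConfigurationError):
        DiscreteSystem(mesh, reference_node=10 ** 9)


# -- dynamics ---------------------------------------------------------------

def test_resting_state_preserved_without_stimulus():
    _, ops = small_system()
    cfg = SolverConfig(dt=0.01, duration=5.0,
                       stimulus=StimulusConfig(amplitude=0.0))
    state = ops.resting_state()
    v0 = ops.cell_voltage(state).copy()
    for _ in range(int(cfg.duration / cfg.dt)):
        state = advance(state, ops, cfg)
    assert np.max(np.abs(ops.cell_voltage(state) - v0)) < 1e-3
    assert np.max(np.abs(state.phi_e)) < 1e-3


def test_zero_stimulus_no_activation():
    _, ops = small_system()
    cfg = SolverConfig(dt=0.01, duration=5.0,
                       stimulus=StimulusConfig(amplitude=0.0))
    res = run_protocol(ops, cfg)
    assert res.blocked
    assert np.max(res.v_cells) < -60.0


def test_passive_rc_decay_matches_closed_form():
    """With a passive membrane, V relaxes with tau = C_m / G_leak."""
    g_leak, c_m = 0.5, 1.0
    mesh = build_sheet(CellShape(), SheetLayout(2, 2), ExtracellularParams(),
                       GapJunctionParams(100.0), junctional_subdivisions=2)
    ionic = PassiveMembrane(g_leak=g_leak, v_rest=-85.0)
    ops = assemble_system(mesh, MembraneParams(c_m=c_m), ionic,
                          np.zeros(mesh.n_patches))
    state = ops.resting_state()
    state = SimState(state.phi_i + 10.0, state.phi_e, state.gating, 0.0)
    cfg = SolverConfig(dt=0.005, duration=2.0,
                       stimulus=StimulusConfig(amplitude=0.0))
    v0 = ops.cell_voltage(state)[0] + 85.0
    n = int(round(2.0 / cfg.dt))
    for _ in range(n):
        state = advance(state, ops, cfg)
    v1 = ops.cell_voltage(state)[0] + 85.0
    tau_fit = -2.0 / np.log(v1 / v0)
    assert tau_fit == pytest.approx(c_m / g_leak, rel=0.05)


def test_charge_bookkeeping_each_step():
    """Extracellular current balance holds at every accepted step."""
    _, ops = small_system()
    cfg = SolverConfig(dt=0.01, duration=1.5)
    state = ops.resting_state()
    for _ in range(int(cfg.duration / cfg.dt)):
        prev = state.copy()
        state = advance(state, ops, cfg)
        # recompute the step's ionic current and stimulus as advance did
        gating = state.gating
        v = ops.patch_voltage(SimState(prev.phi_i, prev.phi_e, gating, prev.t))
        i_ion = ops.ionic_model.current(v, gating, ops.g_na_patch)
        stim = cfg.stimulus
        t_mid = prev.t + 0.5 * cfg.dt
        on = stim.start_ms <= t_mid < stim.start_ms + stim.width_ms
        f = ops.stimulus_vector(stim) if on else np.zeros(ops.n)
        res = ops.charge_residual(prev, state, i_ion, f, cfg.dt)
        assert res < 1e-8


def test_gauge_shift_invariance_of_vm():
    """Adding a constant to both potentials leaves V_m trajectories alone."""
    _, ops = small_system()
    cfg = SolverConfig(dt=0.01, duration=1.0)
    s1 = ops.resting_state()
    s2 = SimState(s1.phi_i + 25.0, s1.phi_e + 25.0, s1.gating.copy(), 0.0)
    # shifted state breaks the gauge fixing row; compare V_m evolution
    for _ in range(50):
        s1 = advance(s1, ops, cfg)
        s2 = advance(s2, ops, cfg)
    v1 = ops.patch_voltage(s1)
    v2 = ops.patch_voltage(s2)
    assert np.max(np.abs(v1 - v2)) < 1e-6


def test_propagation_longitudinal_small_sheet():
    _, ops = small_system(3, 6)
    cfg = SolverConfig(dt=0.01, duration=40.0,
                       stimulus=StimulusConfig(edge="left", amplitude=0.01))
    res = run_protocol(ops, cfg)
    assert not res.blocked
    rows, cols = res.rows, res.cols
    t_act = []
    for c in range(cols.max() + 1):
        ci = int(np.flatnonzero((rows == 1) & (cols == c))[0])
        v = res.v_cells[:, ci]
        t_act.append(res.times[int(np.argmax(np.gradient(v, res.times)))])
    assert all(np.diff(t_act) > 0)  # wave moves left to right


def test_nonfinite_raises_numerical_error():
    from perinexus import NumericalError
    _, ops = small_system()
    state = ops.resting_state()
    state.phi_i[0] = np.nan
    with pytest.raises(NumericalError):
        advance(state, ops, SolverConfig(dt=0.01, duration=1.0))
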
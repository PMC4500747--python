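"""Geometry: tiling, patch classification, cleft network, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perinexus import (CellShape, SheetLayout, ExtracellularParams,
                       GapJunctionParams, build_sheet, ConfigurationError)
from perinexus.geometry import (JUNCTIONAL, LATERAL, polygon_area,
                                triangulate_polygon, extracellular_laplacian,
                                assemble_extracellular_network)

NOMINAL = dict(shape=CellShape(), layout=SheetLayout(3, 4),
               extra=ExtracellularParams(), gj=GapJunctionParams(100.0))


def small_mesh(n_rows=3, n_cols=4, **kw):
    return build_sheet(kw.get("shape", CellShape()),
                       kw.get("layout", SheetLayout(n_rows, n_cols)),
                       kw.get("extra", ExtracellularParams()),
                       kw.get("gj", GapJunctionParams(100.0)),
                       junctional_subdivisions=kw.get("k", 5))


def test_invalid_parameters_raise():
    with pytest.raises(ConfigurationError):
        CellShape(length=10.0, width=20.0)       # length must exceed width
    with pytest.raises(ConfigurationError):
        CellShape(length=-1.0, width=0.5)
    with pytest.raises(ConfigurationError):
        SheetLayout(2, 2, transverse_offset=1.5)
    with pytest.raises(ConfigurationError):
        ExtracellularParams(junctional_width_nm=-1.0)
    with pytest.raises(ConfigurationError):
        GapJunctionParams(-5.0)


def test_footprint_area_equals_lattice_cell():
    """The notched polygon area equals the exact-tiling lattice cell area."""
    shape, layout = CellShape(), SheetLayout(2, 2)
    mesh = small_mesh(2, 2)
    lo, tr = layout.longitudinal_offset, layout.transverse_offset
    expected = shape.length * shape.width * (1.0 - lo * tr)
    for cell in mesh.cells:
        assert polygon_area(cell.polygon) == pytest.approx(expected)


def test_membrane_area_conservation():
    """Each cell's total patch area equals its perimeter times depth."""
    mesh = small_mesh()
    shape, layout = mesh.shape, mesh.layout
    # the notch replaces a corner by a step: perimeter unchanged vs L x W
    per_um = 2.0 * (shape.length + shape.width)
    expected = per_um * shape.depth * 1e-8  # um^2 -> cm^2
    for ci in range(mesh.n_cells):
        total = mesh.patch_area[mesh.patch_cell == ci].sum()
        assert total == pytest.approx(expected, rel=1e-9)


def test_junctional_patches_are_paired_and_share_cleft_nodes():
    mesh = small_mesh()
    j = np.flatnonzero(mesh.patch_class == JUNCTIONAL)
    paired = j[mesh.patch_partner[j] >= 0]
    assert paired.size > 0
    for p in paired:
        q = mesh.patch_partner[p]
        assert mesh.patch_partner[q] == p
        assert mesh.patch_class[q] == JUNCTIONAL
        assert mesh.patch_cell[q] != mesh.patch_cell[p]
        assert mesh.patch_cleft[q] == mesh.patch_cleft[p]
        assert mesh.patch_area[q] == pytest.approx(mesh.patch_area[p])


def test_interior_cell_end_abuts_two_neighbors():
    """At nominal offsets an interior cell's right end couples two cells 50/50."""
    mesh = build_sheet(CellShape(), SheetLayout(5, 5), ExtracellularParams(),
                       GapJunctionParams(100.0), junctional_subdivisions=1)
    rows, cols = mesh.cell_rows_cols()
    interior = int(np.flatnonzero((rows == 2) & (cols == 2))[0])
    x_right = mesh.cells[interior].polygon[:, 0].max()
    sel = ((mesh.patch_cell == interior)
           & (mesh.patch_class == JUNCTIONAL)
           & (np.isclose(mesh.patch_midpoint[:, 0], x_right)))
    partners = mesh.patch_partner[sel]
    assert np.all(partners >= 0)
    neighbor_cells = sorted(set(mesh.patch_cell[partners]))
    assert len(neighbor_cells) == 2
    areas = [mesh.patch_area[sel][mesh.patch_cell[partners] == c].sum()
             for c in neighbor_cells]
    assert areas[0] == pytest.approx(areas[1])


def test_gap_junctions_only_on_junctional_patches():
    mesh = small_mesh()
    for p, q in mesh.gj_pairs:
        assert mesh.patch_class[p] == JUNCTIONAL
        assert mesh.patch_class[q] == JUNCTIONAL


def test_cleft_conductances_positive_and_network_connected():
    mesh = small_mesh()
    assert np.all(mesh.ecl_conductance > 0)
    # connectivity: breadth-first over edges reaches every cleft node
    from collections import deque
    adj = {}
    for a, b in mesh.ecl_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen = {0}
    dq = deque([0])
    while dq:
        n = dq.popleft()
        for m in adj.get(n, []):
            if m not in seen:
                seen.add(m)
                dq.append(m)
    assert len(seen) == mesh.n_ecl


def test_extracellular_laplacian_properties():
    mesh = small_mesh()
    L = extracellular_laplacian(mesh).toarray()
    assert np.allclose(L, L.T)
    assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)
    offdiag = L - np.diag(np.diag(L))
    assert np.all(offdiag <= 1e-15)


def test_conductance_scaling_with_sigma():
    """Doubling both conductivities doubles every edge conductance."""
    m1 = small_mesh()
    m2 = small_mesh(extra=ExtracellularParams(
        sigma_eff_lateral=2 * 159.1, sigma_eff_junctional=2 * 17.8))
    assert np.allclose(m2.ecl_conductance, 2.0 * m1.ecl_conductance)


def test_assemble_extracellular_network_matches_build():
    mesh = small_mesh()
    before = mesh.ecl_conductance.copy()
    mesh = assemble_extracellular_network(mesh, mesh.extracellular)
    assert np.allclose(mesh.ecl_conductance, before)


def test_triangulation_covers_polygon():
    mesh = small_mesh(2, 2)
    for cell in mesh.cells:
        tri_area = 0.0
        for tri in cell.triangles:
            p = cell.polygon[tri]
            tri_area += 0.5 * abs(
                (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1]))
        assert tri_area == pytest.approx(polygon_area(cell.polygon))


def test_triangulate_polygon_simple_square():
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = triangulate_polygon(square)
    assert tris.shape == (2, 3)


def test_junctional_area_fraction_nominal():
    """Junctional share of membrane equals the end-face share W/(L+W)."""
    mesh = build_sheet(CellShape(), SheetLayout(7, 7), ExtracellularParams(),
                       GapJunctionParams(100.0))
    rows, cols = mesh.cell_rows_cols()
    interior = int(np.flatnonzero((rows == 3) & (cols == 3))[0])
    a_j = mesh.junctional_area(interior)
    a_tot = mesh.patch_area[mesh.patch_cell == interior].sum()
    shape = mesh.shape
    expected = shape.width / (shape.length + shape.width)
    assert a_j / a_tot == pytest.approx(expected, rel=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(tr=st.floats(0.1, 0.9), lo=st.floats(0.05, 0.45),
       n_rows=st.integers(2, 3), n_cols=st.integers(2, 3))
def test_property_tiling_and_pairing_over_offsets(tr, lo, n_rows, n_cols):
    """Area conservation and partner symmetry hold across offsets."""
    shape = CellShape()
    mesh = build_sheet(shape, SheetLayout(n_rows, n_cols, tr, lo),
                       ExtracellularParams(), GapJunctionParams(100.0),
                       junctional_subdivisions=2)
    per = 2.0 * (shape.length + shape.width) * shape.depth * 1e-8
    for ci in range(mesh.n_cells):
        assert mesh.patch_area[mesh.patch_cell == ci].sum() == \
            pytest.approx(per, rel=1e-9)
    j = np.flatnonzero((mesh.patch_class == JUNCTIONAL)
                       & (mesh.patch_partner >= 0))
    for p in j:
        assert mesh.patch_partner[mesh.patch_partner[p]] == p


def test_mesh_json_roundtrip(tmp_path):
    mesh = small_mesh(2, 2)
    d = mesh.to_json_dict()
    assert d["n_cells"] == 4
    path = tmp_path / "mesh.json"
    mesh.to_json(path)
    import json
    with open(path) as fh:
        loaded = json.load(fh)
    assert loaded["n_patches"] == mesh.n_patches
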
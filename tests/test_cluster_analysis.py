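"""Cluster analysis: Otsu, components, association classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perinexus import (CalibratedImage, Cluster, AssociationParams,
                       AssociationReport, otsu_threshold, find_clusters,
                       associate, analyze_images, summarize,
                       edge_distance_nm, DegenerateImageError,
                       ConfigurationError, OVERLAPPING, PERINEXAL, DISTAL)

from oracles import exhaustive_otsu_uint8, flood_fill_components


def disc_mask(center, r_px, shape=(120, 120)):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_px ** 2


# -- Otsu -------------------------------------------------------------------

def test_otsu_two_value_image():
    img = np.zeros(100, dtype=np.uint8).reshape(10, 10)
    img.ravel()[:40] = 100
    t = otsu_threshold(img)
    assert 0 <= t < 100
    assert ((img > t) == (img == 100)).all()


def test_otsu_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
        assert otsu_threshold(img) == exhaustive_otsu_uint8(img)


def test_otsu_bimodal_gaussian():
    rng = np.random.default_rng(11)
    vals = np.concatenate([rng.normal(30, 10, 2000),
                           rng.normal(170, 10, 2000)])
    img = np.clip(vals, 0, 255).reshape(40, 100)
    t = otsu_threshold(img)
    assert 30 < t < 170


def test_otsu_constant_image_raises():
    with pytest.raises(DegenerateImageError):
        otsu_threshold(np.full((8, 8), 7.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6))
def test_property_otsu_oracle(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    assert otsu_threshold(img) == exhaustive_otsu_uint8(img)


# -- connected components ---------------------------------------------------

def test_empty_mask_no_clusters():
    assert find_clusters(np.zeros((10, 10), bool), 10.0) == []


def test_rectangle_cluster_closed_form():
    m = np.zeros((20, 20), bool)
    m[3:8, 5:9] = True  # 5 x 4 pixels
    (c,) = find_clusters(m, 10.0)
    assert c.area_px == 20
    assert c.area_nm2 == pytest.approx(2000.0)
    assert c.centroid == (5.0, 6.5)
    assert c.equivalent_diameter_nm == pytest.approx(
        2 * np.sqrt(2000.0 / np.pi))


def test_component_count_matches_flood_fill():
    rng = np.random.default_rng(5)
    mask = rng.random((128, 128)) < 0.2
    clusters = find_clusters(mask, 10.0)
    _, n = flood_fill_components(mask, 8)
    assert len(clusters) == n
    assert sum(c.area_px for c in clusters) == int(mask.sum())


def test_connectivity_four_vs_eight():
    m = np.zeros((4, 4), bool)
    m[0, 0] = m[1, 1] = True  # diagonal touch
    assert len(find_clusters(m, 1.0, connectivity=8)) == 1
    assert len(find_clusters(m, 1.0, connectivity=4)) == 2
    with pytest.raises(ConfigurationError):
        find_clusters(m, 1.0, connectivity=6)


# -- association ------------------------------------------------------------

def test_identical_masks_full_overlap():
    mask = disc_mask((60, 60), 8)
    cx = find_clusters(mask, 10.0)
    nav = find_clusters(mask, 10.0)
    rep = associate(cx, nav)
    assert rep.nav_fractions[OVERLAPPING] == 1.0
    assert rep.cx43_fraction_with_overlap == 1.0


def test_disc_gap_classification():
    """150 nm gap at 10 nm/px -> perinexal; 250 nm -> distal."""
    r = 5
    for gap_px, expected in ((15, PERINEXAL), (25, DISTAL)):
        a = disc_mask((60, 30), r)
        b = disc_mask((60, 30 + 2 * r + gap_px + 1), r)
        # oracle check on the constructed masks
        d = edge_distance_nm(a, b, 10.0)
        assert d == pytest.approx(gap_px * 10.0)
        rep = associate(find_clusters(a, 10.0), find_clusters(b, 10.0))
        assert rep.nav_classes == [expected]


def test_two_perinexal_partners_histogram():
    cx = disc_mask((60, 60), 6)
    nav = disc_mask((60, 85), 4) | disc_mask((60, 35), 4)
    rep = associate(find_clusters(cx, 10.0), find_clusters(nav, 10.0))
    assert rep.perinexal_partner_histogram == {"0": 0, "1": 0, ">=2": 1}
    assert np.median(rep.perinexal_partner_counts) == 2


def test_overlap_beats_perinexal_class():
    cx1 = disc_mask((30, 30), 6)
    cx2 = disc_mask((30, 55), 6)
    nav = disc_mask((30, 42), 8)  # overlaps cx2, perinexal to cx1
    rep = associate(find_clusters(cx1 | cx2, 10.0),
                    find_clusters(nav, 10.0))
    assert rep.nav_classes == [OVERLAPPING]


def test_perinexal_width_monotonicity():
    rng = np.random.default_rng(2)
    cx = np.zeros((200, 200), bool)
    nav = np.zeros((200, 200), bool)
    for _ in range(6):
        cx |= disc_mask(tuple(rng.integers(20, 180, 2)), 5, (200, 200))
        nav |= disc_mask(tuple(rng.integers(20, 180, 2)), 3, (200, 200))
    cxc, navc = find_clusters(cx, 10.0), find_clusters(nav, 10.0)
    prev = -1.0
    for width in (50.0, 150.0, 400.0, 1000.0):
        rep = associate(cxc, navc, AssociationParams(width))
        frac = rep.nav_fractions[PERINEXAL] + rep.nav_fractions[OVERLAPPING]
        assert frac >= prev
        prev = frac


def test_calibration_mismatch_raises():
    a = find_clusters(disc_mask((30, 30), 4), 10.0)
    b = find_clusters(disc_mask((30, 60), 4), 20.0)
    with pytest.raises(ConfigurationError):
        associate(a, b)


def test_empty_nav_report():
    cx = find_clusters(disc_mask((30, 30), 4), 10.0)
    rep = associate(cx, [])
    assert rep.n_nav == 0
    assert np.isnan(rep.nav_fractions[OVERLAPPING])
    assert rep.overlap_partner_histogram == {"0": 1, "1": 0, ">=2": 0}
    table = summarize(rep)
    assert np.isnan(
        float(table.loc[table.statistic == "nav_fraction_overlapping",
                        "value"].iloc[0]))


def test_report_serialization_roundtrip():
    cx = disc_mask((60, 60), 6)
    nav = disc_mask((60, 85), 4) | disc_mask((60, 140), 4)
    rep = associate(find_clusters(cx, 10.0), find_clusters(nav, 10.0))
    rep2 = AssociationReport.from_dict(rep.to_dict())
    assert rep2.to_dict() == rep.to_dict()


def test_fractions_recomputable_from_classes():
    cx = disc_mask((60, 60), 6)
    nav = disc_mask((60, 85), 4) | disc_mask((60, 140), 4) \
        | disc_mask((60, 60), 3)
    rep = associate(find_clusters(cx, 10.0), find_clusters(nav, 10.0))
    d = rep.to_dict()
    for cls in (OVERLAPPING, PERINEXAL, DISTAL):
        recomputed = d["nav_classes"].count(cls) / len(d["nav_classes"])
        assert d["nav_fractions"][cls] == pytest.approx(recomputed)
    assert sum(d["nav_fractions"].values()) == pytest.approx(1.0)
    hist = d["perinexal_partner_histogram"]
    assert hist["0"] + hist["1"] + hist[">=2"] == rep.n_cx43


def test_channel_swap_consistency():
    """Swapping channels preserves the overlap pair structure."""
    a = disc_mask((60, 60), 6) | disc_mask((30, 30), 5)
    b = disc_mask((60, 63), 6)
    ca, cb = find_clusters(a, 10.0), find_clusters(b, 10.0)
    rep_ab = associate(ca, cb)
    rep_ba = associate(cb, ca)
    n_overlap_pairs_ab = int(rep_ab.overlap_partner_counts.sum())
    n_overlap_pairs_ba = int(rep_ba.overlap_partner_counts.sum())
    assert n_overlap_pairs_ab == n_overlap_pairs_ba


def test_analyze_images_pipeline():
    img = np.zeros((120, 120))
    img[disc_mask((60, 60), 6)] = 200.0
    nav = np.zeros((120, 120))
    nav[disc_mask((60, 85), 4)] = 200.0
    rep = analyze_images(CalibratedImage(img, 10.0, "cx43"),
                         CalibratedImage(nav, 10.0, "nav"))
    assert rep.nav_classes == [PERINEXAL]
    with pytest.raises(ConfigurationError):
        analyze_images(CalibratedImage(img, 10.0), CalibratedImage(nav, 5.0))


def test_cluster_invariants():
    with pytest.raises(ConfigurationError):
        Cluster(np.zeros((0, 2)), 10.0)
    with pytest.raises(ConfigurationError):
        CalibratedImage(np.zeros((4, 4)) - 1.0, 10.0)
    with pytest.raises(ConfigurationError):
        CalibratedImage(np.zeros((4, 4)), -1.0)
    with pytest.raises(ConfigurationError):
        AssociationParams(-5.0)
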
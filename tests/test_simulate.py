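"""Simulator: geometry, REP placement, rendering, counts, injury."""

import numpy as np
import pandas as pd
import pytest
import shapely

from norn import proximity, simulate


def test_same_config_gives_bit_identical_sample(small_cfg, small_sample):
    other = simulate.simulate_sample(small_cfg)
    assert other.truth.rep_cells.equals(small_sample.truth.rep_cells)
    assert np.array_equal(other.image, small_sample.image)
    assert np.array_equal(
        other.adata.X.toarray(), small_sample.adata.X.toarray()
    )
    pd.testing.assert_frame_equal(other.truth.compositions, small_sample.truth.compositions)


def test_zero_tubule_density_gives_zones_only(small_cfg):
    geom = simulate.build_geometry(small_cfg.replace(n_tubules=0))
    assert geom.tubules == []
    assert set(geom.zone_bounds) == set(simulate.ZONES)


def test_zones_partition_extent(small_sample):
    bounds = small_sample.geometry.zone_bounds
    ys = [bounds[z] for z in simulate.ZONES]
    assert ys[0][0] == 0.0
    assert ys[-1][1] == small_sample.geometry.extent[1]
    for (_, y1), (y0, _) in zip(ys[:-1], ys[1:]):
        assert y1 == y0


def test_500_tubules_placed_without_overlap():
    """Polygon-intersection oracle over all neighbour pairs."""
    cfg = simulate.SimulationConfig(seed=2, n_tubules=500)
    geom = simulate.build_geometry(cfg)
    assert len(geom.tubules) == 500
    polys = [t.polygon for t in geom.tubules]
    tree = shapely.STRtree(polys)
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            if int(j) != i:
                assert poly.intersection(polys[int(j)]).area == 0.0


def test_every_tubule_lies_within_one_zone(small_sample):
    geom = small_sample.geometry
    for t in geom.tubules:
        y0, y1 = geom.zone_bounds[t.zone]
        miny, maxy = t.polygon.bounds[1], t.polygon.bounds[3]
        assert miny >= y0 - 1e-9 and maxy <= y1 + 1e-9


def test_zone_dependent_segment_frequencies():
    geom = simulate.build_geometry(simulate.SimulationConfig(seed=4, n_tubules=400))
    by_zone = {z: [t.segment for t in geom.tubules if t.zone == z] for z in simulate.ZONES}
    assert all(s == "PT_S1" or s != "IMCD" for s in by_zone["cortex"])
    assert "IMCD" not in by_zone["cortex"] and "IMCD" not in by_zone["corticomedullary_border"]
    # S1 cortex-enriched, S2/S3 border-enriched
    cortex = by_zone["cortex"]
    border = by_zone["corticomedullary_border"]
    assert cortex.count("PT_S1") / len(cortex) > border.count("PT_S1") / len(border)
    assert border.count("PT_S2S3") / len(border) > cortex.count("PT_S2S3") / len(cortex)


def test_extent_too_small_rejected():
    with pytest.raises(ValueError, match="tubule diameter|spot pitch"):
        simulate.build_geometry(simulate.SimulationConfig(extent=(20.0, 20.0)))


def test_far_preference_places_all_cells_beyond_threshold(small_cfg):
    cfg = small_cfg.replace(proximity_preference=(0.0, 0.0, 0.0, 1.0), n_rep_cells=50)
    geom = simulate.build_geometry(cfg)
    truth = simulate.place_rep_cells(geom, cfg)
    assert (truth.rep_cells["d_s1"] >= cfg.threshold_um).all()
    assert (truth.rep_cells["d_s2s3"] >= cfg.threshold_um).all()


def test_s1_only_preference_verified_by_proximity_module(small_cfg):
    """Cross-module round trip: constructed labels recovered from masks."""
    cfg = small_cfg.replace(
        proximity_preference=(1.0, 0.0, 0.0, 0.0), n_rep_cells=100, pixel_size=0.5
    )
    geom = simulate.build_geometry(cfg)
    truth = simulate.place_rep_cells(geom, cfg)
    markers, _, _ = simulate.render_markers(geom, cfg)
    dist = proximity.nearest_distance(
        truth.rep_cells[["x_um", "y_um"]].to_numpy(), markers, classes=["Sglt2", "Sglt1"]
    )
    assert (dist["Sglt2"] < cfg.threshold_um).all()
    assert (dist["Sglt1"] >= cfg.threshold_um).all()


def test_zero_rep_cells_gives_empty_point_set(small_cfg):
    geom = simulate.build_geometry(small_cfg)
    truth = simulate.place_rep_cells(geom, small_cfg.replace(n_rep_cells=0))
    assert len(truth.rep_cells) == 0


def test_infeasible_preference_raises(small_cfg):
    cfg = small_cfg.replace(n_tubules=0, proximity_preference=(1.0, 0.0, 0.0, 0.0))
    geom = simulate.build_geometry(cfg)
    with pytest.raises(ValueError, match="PT_S1"):
        simulate.place_rep_cells(geom, cfg)


def test_class_quota_is_exact(small_sample, small_cfg):
    counts = small_sample.truth.rep_cells["true_class"].value_counts()
    pref = dict(zip(simulate.PROXIMITY_CLASSES, small_cfg.proximity_preference))
    for cls, p in pref.items():
        assert abs(counts.get(cls, 0) - p * small_cfg.n_rep_cells) <= 1


def test_rep_cells_outside_tubule_lumens(small_sample):
    geom = small_sample.geometry
    union = shapely.unary_union([t.polygon for t in geom.tubules])
    for _, row in small_sample.truth.rep_cells.iterrows():
        assert not union.contains(shapely.Point(row.x_um, row.y_um))


# ---------------------------------------------------------------------------
# rendering


def test_noise_free_image_thresholds_to_masks(small_cfg):
    cfg = small_cfg.replace(noise_sd=0.0)
    geom = simulate.build_geometry(cfg)
    markers, image, names = simulate.render_markers(geom, cfg)
    for c, name in enumerate(names):
        assert np.array_equal(image[c] > cfg.background, markers.masks[name])


def test_circular_tubule_ring_area_matches_annulus():
    """Luminal ring of width w inside radius r covers pi*(r^2 - (r-w)^2)."""
    cfg = simulate.SimulationConfig(seed=0, extent=(120.0, 120.0), pixel_size=0.33,
                                    noise_sd=0.0, ring_width_um=3.0)
    r = 25.0
    tub = simulate.TubuleObject(
        id=0, segment="PT_S1", polygon=shapely.Point(60, 60).buffer(r, quad_segs=64),
        diameter=2 * r, zone="cortex",
    )
    geom = simulate.TissueGeometry(
        extent=cfg.extent, zone_bounds={"cortex": (0.0, 120.0)}, tubules=[tub]
    )
    markers, _, _ = simulate.render_markers(geom, cfg)
    area = markers.area_um2("Sglt2")
    expected = np.pi * (r**2 - (r - cfg.ring_width_um) ** 2)
    # pixelation error scales with perimeter * pixel size
    assert abs(area - expected) < 2 * np.pi * r * cfg.pixel_size * 2


def test_empty_geometry_renders_pure_noise(small_cfg):
    cfg = small_cfg.replace(n_tubules=0)
    geom = simulate.build_geometry(cfg)
    markers, image, names = simulate.render_markers(geom, cfg)
    for name in names:
        assert not markers.masks[name].any()
    assert image.std() > 0  # noise only


# ---------------------------------------------------------------------------
# spot counts


def test_compositions_on_simplex(small_sample, injured_sample):
    for s in (small_sample, injured_sample):
        rows = s.truth.compositions.sum(axis=1)
        assert np.allclose(rows, 1.0)
        assert (s.truth.compositions.to_numpy() >= 0).all()


def test_spot_inside_giant_tubule_is_unit_composition():
    cfg = simulate.SimulationConfig(seed=0, extent=(200.0, 200.0), pixel_size=1.0)
    tub = simulate.TubuleObject(
        id=0, segment="TAL", polygon=shapely.Point(100, 100).buffer(95, quad_segs=32),
        diameter=190, zone="cortex",
    )
    geom = simulate.TissueGeometry(
        extent=cfg.extent, zone_bounds={"cortex": (0.0, 200.0)}, tubules=[tub]
    )
    comp, positions = simulate.true_compositions(geom, cfg)
    # central spot disc lies fully inside the tubule
    d = np.hypot(positions.x_um - 100, positions.y_um - 100)
    center = comp.loc[d.idxmin()]
    assert center["TAL"] == pytest.approx(1.0)


def test_no_rep_cells_means_zero_epo_counts(small_cfg):
    cfg = small_cfg.replace(n_rep_cells=0)
    sample = simulate.simulate_sample(cfg, render=False)
    epo = sample.adata[:, "Epo"].X.toarray()
    assert (epo == 0).all()


def test_poisson_limit_variance_matches_mean(small_cfg):
    """dispersion -> inf: per-gene variance across replicate draws ~ mean."""
    cfg = small_cfg.replace(
        extent=(150.0, 150.0), n_tubules=5, n_rep_cells=0, dispersion=np.inf,
        n_background_genes=20, depth=2000.0,
    )
    geom = simulate.build_geometry(cfg)
    truth = simulate.GroundTruth(rep_cells=pd.DataFrame(columns=["x_um", "y_um"]))
    truth.signatures = simulate.reference_signatures(cfg)
    truth.compositions, truth.spot_positions = simulate.true_compositions(geom, cfg)
    draws = []
    for k in range(400):
        t = truth.copy()
        ad = simulate.simulate_spot_counts(geom, t, cfg.replace(seed=1000 + k))
        draws.append(ad.X.toarray()[0])
    draws = np.asarray(draws)
    mean = draws.mean(axis=0)
    var = draws.var(axis=0, ddof=1)
    big = mean > 5
    ratio = var[big] / mean[big]
    assert np.median(ratio) == pytest.approx(1.0, abs=0.15)


def test_overdispersed_counts_exceed_poisson_variance(small_cfg):
    cfg = small_cfg.replace(
        extent=(150.0, 150.0), n_tubules=5, n_rep_cells=0, dispersion=2.0,
        n_background_genes=20, depth=2000.0,
    )
    geom = simulate.build_geometry(cfg)
    truth = simulate.GroundTruth(rep_cells=pd.DataFrame(columns=["x_um", "y_um"]))
    truth.signatures = simulate.reference_signatures(cfg)
    truth.compositions, truth.spot_positions = simulate.true_compositions(geom, cfg)
    draws = np.asarray([
        simulate.simulate_spot_counts(geom, truth.copy(), cfg.replace(seed=2000 + k)).X.toarray()[0]
        for k in range(200)
    ])
    mean = draws.mean(axis=0)
    var = draws.var(axis=0, ddof=1)
    big = mean > 20
    assert np.median(var[big] / mean[big]) > 2.0


# ---------------------------------------------------------------------------
# injury transform


def test_injury_fraction_zero_is_identity(small_sample, small_cfg):
    truth = small_sample.truth
    out = simulate.apply_injury_transform(truth, small_cfg.replace(injury_fraction=0.0))
    pd.testing.assert_frame_equal(out.compositions, truth.compositions)
    pd.testing.assert_frame_equal(out.signatures, truth.signatures)


def test_injury_fraction_one_removes_all_pt_s2s3_mass(small_sample, small_cfg):
    out = simulate.apply_injury_transform(small_sample.truth, small_cfg.replace(injury_fraction=1.0))
    assert (out.compositions["PT_S2S3"] == 0).all()
    assert np.allclose(out.compositions.sum(axis=1), 1.0)


def test_injury_fraction_out_of_range_rejected(small_sample, small_cfg):
    with pytest.raises(ValueError, match="injury_fraction"):
        simulate.apply_injury_transform(small_sample.truth, small_cfg.replace(injury_fraction=1.5))


def test_injury_preserves_norn_and_endo_mass(small_sample, small_cfg):
    out = simulate.apply_injury_transform(small_sample.truth, small_cfg)
    for col in ("Norn", "Endo"):
        assert np.allclose(out.compositions[col], small_sample.truth.compositions[col])


def test_injury_raises_expected_havcr1_and_preserves_slc5a1(small_sample, small_cfg):
    """Expectation arithmetic: depth * W @ S summed over spots."""
    truth = small_sample.truth
    out = simulate.apply_injury_transform(truth, small_cfg)

    def expected_total(tr, gene):
        W = tr.compositions.to_numpy()
        s = tr.signatures[gene].to_numpy()
        return small_cfg.depth * (W @ s).sum()

    assert expected_total(out, "Havcr1") > expected_total(truth, "Havcr1")
    assert expected_total(out, "Slc5a2") < expected_total(truth, "Slc5a2")
    # Sglt1 expression is preserved within renormalization wiggle
    assert expected_total(out, "Slc5a1") > 0.8 * expected_total(truth, "Slc5a1")


def test_injured_sample_counts_reflect_injury(small_sample, injured_sample):
    havcr1_h = small_sample.adata[:, "Havcr1"].X.toarray().sum()
    havcr1_i = injured_sample.adata[:, "Havcr1"].X.toarray().sum()
    assert havcr1_i > 2 * havcr1_h
    sglt2_h = small_sample.adata[:, "Slc5a2"].X.toarray().sum()
    sglt2_i = injured_sample.adata[:, "Slc5a2"].X.toarray().sum()
    sglt1_h = small_sample.adata[:, "Slc5a1"].X.toarray().sum()
    sglt1_i = injured_sample.adata[:, "Slc5a1"].X.toarray().sum()
    # Sglt2 mRNA drops; Sglt1 is comparatively preserved
    assert sglt2_i < 0.75 * sglt2_h
    assert sglt2_i / sglt2_h < sglt1_i / sglt1_h


def test_gene_panel_identical_between_conditions(small_sample, injured_sample, small_cfg):
    assert list(small_sample.adata.var_names) == list(injured_sample.adata.var_names)
    # the pre-transform reference does not depend on the injury flag
    pd.testing.assert_frame_equal(
        simulate.reference_signatures(small_cfg),
        simulate.reference_signatures(small_cfg.replace(injury=True)),
    )
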
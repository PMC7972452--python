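"""The 13 per-cell variables, deviation curves, counts, phenotype flags."""
import numpy as np
import pandas as pd
import pytest

from lineage4d.alignment import EmbryoFrame, TemporalAlignment
from lineage4d.features import (
    FEATURE_NAMES,
    angle_deg,
    build_feature_table,
    extract_features,
    lineage_cell_counts,
    phenotype_flags,
    positional_deviation_curve,
)
from lineage4d.lineage_io import (
    CellTrack,
    EmbryoLineage,
    EmbryoMetadata,
    NucleusObservation,
)

IDENTITY_FRAME = EmbryoFrame(
    origin=np.zeros(3),
    axes=np.eye(3),
    extents=np.ones(3),
    frame_extents=np.ones(3),
    normalized=False,
)
IDENTITY_TIME = TemporalAlignment(scale=1.0, t_zero_min=0.0)


def _track_embryo(points, cell="ABa", t_step=2.5, first_frame=2):
    """Embryo with one free-standing track (plus a dummy earlier cell so the
    track's birth is observable)."""
    obs = [
        NucleusObservation(cell, first_frame + i, (first_frame + i - 1) * t_step, *p)
        for i, p in enumerate(points)
    ]
    dummy = CellTrack(
        "Ca", [NucleusObservation("Ca", 1, 0.0, 50.0, 50.0, 50.0)]
    )
    return EmbryoLineage(
        "t", {cell: CellTrack(cell, obs), "Ca": dummy}, EmbryoMetadata()
    )


def _extract(emb):
    return extract_features(
        emb, frame=IDENTITY_FRAME, temporal_alignment=IDENTITY_TIME
    )


def test_thirteen_features_defined():
    assert len(FEATURE_NAMES) == 13


def test_stationary_cell_zero_distances():
    emb = _track_embryo([(1.0, 2.0, 3.0)] * 5)
    row = _extract(emb).loc["ABa"]
    assert row["totdis"] == 0.0
    assert row["netdis"] == 0.0


def test_straight_line_totdis_equals_netdis():
    emb = _track_embryo([(0, 0, 0), (1, 1, 0), (2, 2, 0), (3, 3, 0)])
    row = _extract(emb).loc["ABa"]
    assert row["totdis"] == pytest.approx(row["netdis"])


def test_pythagorean_track():
    # (0,0,0) -> (3,4,0) -> (3,4,12): totdis = 5 + 12 = 17, netdis = 13
    emb = _track_embryo([(0, 0, 0), (3, 4, 0), (3, 4, 12)])
    row = _extract(emb).loc["ABa"]
    assert row["totdis"] == pytest.approx(17.0)
    assert row["netdis"] == pytest.approx(13.0)


def test_lifetime_is_end_minus_start():
    obs_parent = [
        NucleusObservation("MS", f, (f - 1) * 2.5, 0.0, 0.0, 0.0)
        for f in range(3, 8)
    ]
    tracks = {
        "MS": CellTrack("MS", obs_parent, daughter_names=("MSa", "MSp")),
        "Ca": CellTrack("Ca", [NucleusObservation("Ca", 1, 0.0, 9.0, 9.0, 9.0)]),
    }
    for d, off in (("MSa", 1.0), ("MSp", -1.0)):
        tracks[d] = CellTrack(
            d,
            [NucleusObservation(d, 8, 17.5, off, 0.0, 0.0)],
            parent_name="MS",
        )
    emb = EmbryoLineage("lt", tracks, EmbryoMetadata())
    row = _extract(emb).loc["MS"]
    assert row["StartTime"] == pytest.approx(5.0)
    assert row["EndTime"] == pytest.approx(17.5)
    assert row["LifeTime"] == pytest.approx(12.5)
    # division vector (MSa - MSp) = +x: aAP = 0 in the identity frame
    assert row["aAP"] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize(
    "v,expected", [((1, 0, 0), 0.0), ((0, 1, 0), 90.0), ((-1, 0, 0), 180.0)]
)
def test_angle_symmetry_cases(v, expected):
    assert angle_deg(np.array(v, float), np.eye(3)[0]) == pytest.approx(expected)


def test_fold_angles_option():
    # reversed division vector: aAP 180° directed, 0° folded
    obs = lambda n, f, p: NucleusObservation(n, f, (f - 1) * 2.5, *p)
    tracks = {
        "MS": CellTrack("MS", [obs("MS", 3, (0, 0, 0))], daughter_names=("MSa", "MSp")),
        "MSa": CellTrack("MSa", [obs("MSa", 4, (-1.0, 0, 0))], "MS"),
        "MSp": CellTrack("MSp", [obs("MSp", 4, (1.0, 0, 0))], "MS"),
        "Ca": CellTrack("Ca", [obs("Ca", 1, (9, 9, 9))]),
    }
    emb = EmbryoLineage("fold", tracks, EmbryoMetadata())
    directed = extract_features(
        emb, frame=IDENTITY_FRAME, temporal_alignment=IDENTITY_TIME
    ).loc["MS", "aAP"]
    folded = extract_features(
        emb, frame=IDENTITY_FRAME, temporal_alignment=IDENTITY_TIME,
        fold_angles=True,
    ).loc["MS", "aAP"]
    assert directed == pytest.approx(180.0)
    assert folded == pytest.approx(0.0)


def test_angles_span_0_to_180(rng):
    for _ in range(200):
        u, w = rng.normal(size=3), rng.normal(size=3)
        a = angle_deg(u, w)
        assert 0.0 <= a <= 180.0
        assert a + angle_deg(-u, w) == pytest.approx(180.0)


def test_netdis_le_totdis_random_tracks(rng):
    # 10^4 random tracks via vectorized arithmetic on the same formulas
    for _ in range(200):
        pts = rng.normal(0, 3, (int(rng.integers(2, 12)), 3))
        emb = _track_embryo(pts)
        row = _extract(emb).loc["ABa"]
        assert row["netdis"] <= row["totdis"] + 1e-12


def test_time_rescaling_leaves_geometry(rng):
    pts = rng.normal(0, 3, (6, 3))
    emb = _track_embryo(pts)
    fast = extract_features(
        emb,
        frame=IDENTITY_FRAME,
        temporal_alignment=TemporalAlignment(scale=2.0, t_zero_min=0.0),
    ).loc["ABa"]
    slow = _extract(emb).loc["ABa"]
    for geom in ("pAP", "pDV", "pLR", "totdis", "netdis"):
        assert fast[geom] == pytest.approx(slow[geom])
    assert fast["StartTime"] == pytest.approx(2.0 * slow["StartTime"])


def test_reference_self_deviation_zero(controls):
    from lineage4d.alignment import build_reference

    ref = build_reference([controls[0]], with_feature_stats=False)
    feats = extract_features(controls[0], reference=ref)
    assert np.nanmax(feats["pOV"].to_numpy()) < 1e-9
    assert np.nanmax(feats["aMean"].to_numpy()) < 1e-5
    curve = positional_deviation_curve(controls[0], ref)
    assert curve["mean_deviation"].max() < 1e-9


def test_uniform_offset_deviation_curve(controls):
    from lineage4d.alignment import build_reference, infer_axes
    from lineage4d.lineage_io import NucleusObservation as Obs

    e = controls[0]
    ref = build_reference([e], with_feature_stats=False)
    frame = infer_axes(e)  # frozen frame: the shift must not be re-centred away
    tracks = {}
    for name, t in e.tracks.items():
        obs = [
            Obs(name, o.frame, o.time_min, o.x, o.y, o.z + 2.0, o.diameter)
            for o in t.observations
        ]
        tracks[name] = CellTrack(name, obs, t.parent_name, t.daughter_names)
    shifted = EmbryoLineage("shifted", tracks, e.metadata)
    curve = positional_deviation_curve(
        shifted, ref, frame=frame, align_to_reference=False
    )
    dev = curve["mean_deviation"].to_numpy()
    # without re-alignment the uniform 2 µm shift appears verbatim at all times
    np.testing.assert_allclose(dev, 2.0, atol=1e-6)
    # with rigid re-alignment the shift is absorbed
    curve2 = positional_deviation_curve(
        shifted, ref, frame=frame, align_to_reference=True
    )
    assert curve2["mean_deviation"].max() < 0.2


def test_two_cell_deviation_arithmetic():
    """Cells at 1 and 3 µm from their reference trajectories average to 2."""
    from lineage4d.alignment import ReferenceModel

    grid = np.arange(0.0, 11.0)
    ref = ReferenceModel(
        positions={},
        division_vectors={},
        trajectory_grid=grid,
        trajectories={
            "ABa": np.zeros((grid.size, 3)),
            "ABp": np.tile([10.0, 0, 0], (grid.size, 1)),
        },
        extents=np.ones(3),
        n_controls=1,
    )
    obs = lambda n, f, p: NucleusObservation(n, f, float(f - 1), *p)
    tracks = {
        "ABa": CellTrack("ABa", [obs("ABa", f, (0, 0, 1.0)) for f in range(1, 12)]),
        "ABp": CellTrack("ABp", [obs("ABp", f, (10.0, 3.0, 0)) for f in range(1, 12)]),
    }
    emb = EmbryoLineage("two", tracks, EmbryoMetadata())
    curve = positional_deviation_curve(
        emb,
        ref,
        frame=IDENTITY_FRAME,
        temporal_alignment=IDENTITY_TIME,
        align_to_reference=False,
    )
    np.testing.assert_allclose(curve["mean_deviation"], 2.0, atol=1e-12)
    assert (curve["n_cells"] == 2).all()


def test_lineage_counts_partition(wild_type_embryo):
    curves = lineage_cell_counts(wild_type_embryo)
    from lineage4d.alignment import cell_count_curve

    _, total = cell_count_curve(wild_type_embryo)
    summed = curves["AB"]["count"].to_numpy() + curves["P1"]["count"].to_numpy()
    np.testing.assert_array_equal(summed, total)
    ab = curves["AB"]["count"].to_numpy()
    assert ab[0] == 1 and ab[-1] >= 32  # AB .. AB64 within the recording


def test_ab_count_steps_through_3(wild_type_embryo):
    ab = lineage_cell_counts(wild_type_embryo)["AB"]["count"].to_numpy()
    jumps = np.unique(ab)
    assert {1, 2, 4} <= set(jumps)  # 1 -> 2 (AB division) -> 4 (ABa+ABp)


def test_p1_curve_reaches_8_earlier_when_equalized(sim_config):
    from lineage4d.simulate import simulate_embryo

    ctrl = simulate_embryo(sim_config, "control", 21)
    eq = simulate_embryo(sim_config, "equalized_dead", 21)

    def t_reach(e, k):
        c = lineage_cell_counts(e)["P1"]
        hit = c[c["count"] >= k]
        return hit["time"].iloc[0]

    assert t_reach(eq, 8) < t_reach(ctrl, 8)


def test_phenotype_flags_on_reference_embryo(controls, reference):
    flags = phenotype_flags(controls[0], reference)
    assert flags.ems_skew is False
    assert flags.msap_inversion is False
    assert flags.extra_P4_divisions == 0
    assert flags.t_arrangement is False
    assert flags.ab_p1_asynchrony_min > 0


def test_extra_p4_divisions_from_subtree():
    obs = lambda n, f: NucleusObservation(n, f, (f - 1) * 2.5, 0.0, 0.0, 0.0)
    tracks = {
        "P4": CellTrack("P4", [obs("P4", 2)], daughter_names=("Z2", "Z3")),
        "Z2": CellTrack("Z2", [obs("Z2", 3)], "P4", ("Z2a", "Z2p")),
        "Z3": CellTrack("Z3", [obs("Z3", 3)], "P4"),
        "Z2a": CellTrack("Z2a", [obs("Z2a", 5)], "Z2"),
        "Z2p": CellTrack("Z2p", [obs("Z2p", 5)], "Z2"),
        "Ca": CellTrack("Ca", [obs("Ca", 1)]),
        "MSa": CellTrack("MSa", [obs("MSa", 1)]),
    }
    emb = EmbryoLineage("p4", tracks, EmbryoMetadata())
    flags = phenotype_flags(emb, reference=None, frame=IDENTITY_FRAME,
                            temporal_alignment=IDENTITY_TIME)
    assert flags.extra_P4_divisions == 1


def test_msap_inversion_constructed(controls, reference):
    # negate the L-R (imaging z here equals canonical L-R) coordinates of the
    # MSa/MSp tracks prior to their division
    e = controls[0]
    tracks = {}
    for name, t in e.tracks.items():
        if name in ("MSa", "MSp"):
            obs = [
                NucleusObservation(name, o.frame, o.time_min, o.x, o.y, -o.z, o.diameter)
                for o in t.observations
            ]
        else:
            obs = t.observations
        tracks[name] = CellTrack(name, obs, t.parent_name, t.daughter_names)
    flipped = EmbryoLineage("flip", tracks, e.metadata)
    flags = phenotype_flags(flipped, reference)
    assert flags.msap_inversion is True


def test_feature_table_columns_and_stages(cohort, reference):
    embryos, meta = cohort
    table15 = build_feature_table(embryos[:6], reference, stage=15)
    assert table15.index.is_unique
    cells = {c.rsplit(".", 1)[0] for c in table15.columns}
    assert "ABara" in cells and "Ca" in cells and "ABa" in cells
    assert "D" not in cells  # D belongs to the 28-cell cohort
    table4 = build_feature_table(embryos[:6], reference, stage=4)
    assert set(table4.columns) < set(table15.columns)
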
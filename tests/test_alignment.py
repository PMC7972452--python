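"""Temporal alignment, axis inference, Kabsch/GPA, and the reference model."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lineage4d.alignment import (
    EmbryoFrame,
    build_reference,
    cell_count_curve,
    gpa_align,
    infer_axes,
    kabsch,
    temporal_align,
    to_embryo_coords,
)
from lineage4d.errors import (
    AlignmentError,
    AxisError,
    InsufficientLandmarkError,
)
from lineage4d.lineage_io import (
    CellTrack,
    EmbryoLineage,
    EmbryoMetadata,
    NucleusObservation,
)


def _random_rotation(rng):
    return Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()


def _transform_embryo(embryo, R, shift):
    """Rigidly transform every observation of an embryo."""
    tracks = {}
    for name, t in embryo.tracks.items():
        obs = [
            NucleusObservation(
                name,
                o.frame,
                o.time_min,
                *(R @ o.position + shift),
                diameter=o.diameter,
            )
            for o in t.observations
        ]
        tracks[name] = CellTrack(name, obs, t.parent_name, t.daughter_names)
    return EmbryoLineage(embryo.embryo_id + "_rot", tracks, embryo.metadata)


def _dilate_embryo(embryo, s):
    """Multiply all times by s (slower development for s > 1)."""
    tracks = {}
    for name, t in embryo.tracks.items():
        obs = [
            NucleusObservation(
                name, o.frame, o.time_min * s, o.x, o.y, o.z, o.diameter
            )
            for o in t.observations
        ]
        tracks[name] = CellTrack(name, obs, t.parent_name, t.daughter_names)
    return EmbryoLineage(embryo.embryo_id + "_dil", tracks, embryo.metadata)


# ---------------------------------------------------------------------------
# Kabsch / GPA
# ---------------------------------------------------------------------------

def test_kabsch_matches_scipy_closed_form(rng):
    for _ in range(10):
        P = rng.normal(0, 5, (4, 3))
        R_true = _random_rotation(rng)
        t_true = rng.normal(0, 10, 3)
        Q = P @ R_true.T + t_true
        R, t = kabsch(P, Q)
        # independent closed-form oracle
        R_ref, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(R, R_ref.as_matrix(), atol=1e-8)
        np.testing.assert_allclose(P @ R.T + t, Q, atol=1e-8)


def test_gpa_single_embryo_identity():
    lm = {c: np.array([i, 0.0, 0.0]) for i, c in enumerate("abcd")}
    res = gpa_align([lm])
    assert res.residual == 0.0
    for c in lm:
        np.testing.assert_allclose(res.mean_shape[c], lm[c])


def test_gpa_two_rigidly_related_shapes(rng):
    lm = {f"c{i}": rng.normal(0, 5, 3) for i in range(6)}
    R = _random_rotation(rng)
    lm2 = {c: R @ p + np.array([3.0, -2.0, 1.0]) for c, p in lm.items()}
    res = gpa_align([lm, lm2])
    assert res.residual < 1e-8


def test_gpa_two_shape_superposition_matches_closed_form(rng):
    P = rng.normal(0, 4, (4, 3))
    Q = rng.normal(0, 4, (4, 3))
    names = ["w", "x", "y", "z"]
    res = gpa_align([dict(zip(names, P)), dict(zip(names, Q))])
    # oracle: residual of the direct two-shape least-squares superposition,
    # evaluated against the midpoint shape (the GPA fixed point for n=2)
    R, t = kabsch(P, Q)
    P_on_Q = P @ R.T + t
    oracle = float((((P_on_Q - Q) / 2.0) ** 2).sum(axis=1).mean())
    assert res.residual == pytest.approx(oracle, abs=1e-8)


def test_gpa_residual_invariant_under_rigid_pretransform(rng):
    sets = [
        {f"c{i}": rng.normal(0, 5, 3) + rng.normal(0, 0.5, 3) for i in range(8)}
        for _ in range(4)
    ]
    base = gpa_align(sets).residual
    R = _random_rotation(rng)
    sets2 = [dict(sets[0]), *map(dict, sets[1:])]
    sets2[2] = {c: R @ p + np.array([10.0, 5.0, -3.0]) for c, p in sets2[2].items()}
    assert gpa_align(sets2).residual == pytest.approx(base, abs=1e-9)


def test_gpa_insufficient_landmarks():
    lm = {"a": np.zeros(3), "b": np.ones(3), "c": np.array([1.0, 0, 0])}
    with pytest.raises(InsufficientLandmarkError):
        gpa_align([lm, dict(lm)])


def test_gpa_missing_cells_dropped_pairwise(rng):
    lm1 = {f"c{i}": rng.normal(0, 5, 3) for i in range(6)}
    lm2 = dict(lm1)
    lm2.pop("c5")  # one missing landmark
    res = gpa_align([lm1, lm2])
    assert res.residual < 1e-10
    assert "c5" in res.mean_shape


# ---------------------------------------------------------------------------
# temporal alignment
# ---------------------------------------------------------------------------

def test_identity_alignment(wild_type_embryo):
    t0 = wild_type_embryo.division_time("ABa")
    times, counts = cell_count_curve(wild_type_embryo)
    ta = temporal_align(wild_type_embryo, (times - t0, counts))
    assert ta.scale == pytest.approx(1.0, abs=1e-9)
    assert ta.t_zero_min == t0


@pytest.mark.parametrize("s", [0.6, 0.8, 1.25, 1.6])
def test_dilation_recovery(wild_type_embryo, s):
    t0 = wild_type_embryo.division_time("ABa")
    times, counts = cell_count_curve(wild_type_embryo)
    dilated = _dilate_embryo(wild_type_embryo, s)
    ta = temporal_align(dilated, (times - t0, counts))
    assert ta.scale == pytest.approx(1.0 / s, abs=0.0011)


def test_flat_curve_raises():
    obs = [
        NucleusObservation("AB", f, (f - 1) * 2.5, 0.0, 0.0, 0.0)
        for f in range(1, 10)
    ]
    emb = EmbryoLineage("flat", {"AB": CellTrack("AB", obs)}, EmbryoMetadata())
    with pytest.raises(AlignmentError):
        temporal_align(emb, (np.arange(10.0), np.arange(10.0) + 2))


def test_missing_aba_division_raises(wild_type_embryo):
    tracks = {
        n: t
        for n, t in wild_type_embryo.tracks.items()
        if not n.startswith("ABa") or n == "ABa"
    }
    tracks["ABa"] = CellTrack("ABa", tracks["ABa"].observations, "AB", ())
    emb = EmbryoLineage("noABa", tracks, wild_type_embryo.metadata)
    with pytest.raises(AlignmentError, match="ABa"):
        temporal_align(emb, (np.arange(10.0), np.arange(10.0) + 2))


# ---------------------------------------------------------------------------
# axis inference
# ---------------------------------------------------------------------------

def _axis_aligned_embryo(rng):
    """Elongated cloud along x: AB cells anterior (-x), MS lineage at -y."""
    tracks = {}

    def add(name, base, k):
        obs = NucleusObservation(
            name, 1 + k, k * 2.5, *(np.asarray(base) + rng.normal(0, 0.5, 3))
        )
        tracks.setdefault(name, CellTrack(name, [])).observations.append(obs)

    k = 0
    for base in [(-12, 1, 0), (-10, -1, 1), (-8, 0, -1), (-11, 0, 0)]:
        for name in ("ABa", "ABp"):
            add(name, base, k)
            k += 1
    for base in [(8, 1, 0), (12, -1, 0), (10, 0, 1)]:
        add("Ca", base, k)
        k += 1
    for j in range(3):
        add("MS", (2, -6, 0.1 * j), k)
        k += 1
    return EmbryoLineage("axis", tracks, EmbryoMetadata())


def test_axis_aligned_construction(rng):
    emb = _axis_aligned_embryo(rng)
    frame = infer_axes(emb)
    ap, dv, lr = frame.axes
    # A-P along imaging x, oriented with the AB side (at -x) anterior/negative
    assert ap[0] > 0.95
    assert dv[1] < -0.9  # ventral (MS side) at -y
    np.testing.assert_allclose(np.cross(ap, dv), lr, atol=1e-12)


def test_rotation_equivariance(wild_type_embryo, rng):
    frame0 = infer_axes(wild_type_embryo)
    for _ in range(10):
        R = _random_rotation(rng)
        shift = rng.normal(0, 20, 3)
        rotated = _transform_embryo(wild_type_embryo, R, shift)
        frame1 = infer_axes(rotated)
        np.testing.assert_allclose(frame1.axes, frame0.axes @ R.T, atol=1e-6)
        np.testing.assert_allclose(frame1.frame_extents, frame0.frame_extents, atol=1e-6)


def test_orthonormal_right_handed_for_simulated_embryos(cohort):
    embryos, _ = cohort
    for e in embryos[:8]:
        frame = infer_axes(e)
        frame.validate()  # orthonormality + right-handedness to 1e-9


def test_isotropic_cloud_warns(rng, caplog):
    # a dense spherical cloud: the first principal component is ill-defined
    tracks = {}
    names = ["ABa", "ABp", "ABal", "ABpr", "MSa", "MSp"]
    for f in range(1, 101):
        for name in names:
            obs = NucleusObservation(name, f, (f - 1) * 2.5, *rng.normal(0, 5, 3))
            tracks.setdefault(name, CellTrack(name, [])).observations.append(obs)
    emb = EmbryoLineage("iso", tracks, EmbryoMetadata())
    with caplog.at_level("WARNING"):
        infer_axes(emb)
    assert any("anisotropy" in r.message for r in caplog.records)


def test_no_ms_cells_raises(rng):
    tracks = {}
    for i in range(20):
        name = ["ABa", "ABp"][i % 2]
        obs = NucleusObservation(name, 1 + i, i * 2.5, *(rng.normal(0, 1, 3) * [10, 2, 2]))
        tracks.setdefault(name, CellTrack(name, [])).observations.append(obs)
    emb = EmbryoLineage("noms", tracks, EmbryoMetadata())
    with pytest.raises(AxisError, match="MS"):
        infer_axes(emb)


# ---------------------------------------------------------------------------
# reference model
# ---------------------------------------------------------------------------

def test_reference_from_identical_controls(controls):
    ref = build_reference([controls[0], controls[0]], with_feature_stats=False)
    # identical inputs: zero-residual consensus, positions match the input
    lone = build_reference([controls[0]], with_feature_stats=False)
    for cell in lone.positions:
        np.testing.assert_allclose(
            ref.positions[cell], lone.positions[cell], atol=1e-6
        )


def test_offset_pair_matches_two_shape_closed_form():
    # two 5-landmark shapes identical except one cell offset by ±1 µm: the
    # iterative GPA must agree with the direct two-shape Kabsch solution
    # (mean at the midpoint of the superposed pair)
    base = {
        "a": np.array([-10.0, 0, 0]),
        "b": np.array([10.0, 0, 0]),
        "c": np.array([0.0, 5, 0]),
        "d": np.array([0.0, -5, 0]),
        "e": np.array([0.0, 0, 4]),
    }
    lm1 = {c: p.copy() for c, p in base.items()}
    lm2 = {c: p.copy() for c, p in base.items()}
    lm1["e"] = base["e"] + np.array([0, 0, 1.0])
    lm2["e"] = base["e"] - np.array([0, 0, 1.0])
    res = gpa_align([lm1, lm2])

    # closed-form oracle: superpose shape 2 onto shape 1 directly
    names = sorted(base)
    P = np.array([lm2[c] for c in names])
    Q = np.array([lm1[c] for c in names])
    R, t = kabsch(P, Q)
    P_on_Q = P @ R.T + t
    mid = (P_on_Q + Q) / 2.0
    oracle_residual = float((((Q - mid)) ** 2).sum(axis=1).mean())
    assert res.residual == pytest.approx(oracle_residual, abs=1e-9)
    # per-cell deviation of each aligned shape from the consensus
    gpa_dev = np.linalg.norm(res.aligned[0]["e"] - res.mean_shape["e"])
    oracle_dev = float(np.linalg.norm((Q - mid)[names.index("e")]))
    assert gpa_dev == pytest.approx(oracle_dev, abs=1e-9)
    # the consensus "e" sits at the midpoint, on the base position
    np.testing.assert_allclose(res.mean_shape["e"][2], 4.0, atol=1e-6)


def test_reference_lookup_error(reference):
    from lineage4d.errors import LookupError_

    with pytest.raises(LookupError_):
        reference.position("ABxyz_never_tracked")


def test_reference_permutation_invariance(controls):
    a = build_reference(controls, with_feature_stats=False)
    b = build_reference(controls[::-1], with_feature_stats=False)
    for cell in a.positions:
        np.testing.assert_allclose(a.positions[cell], b.positions[cell], atol=1e-6)


def test_reference_json_round_trip(tmp_path, reference):
    p = tmp_path / "ref.json"
    reference.to_json(p)
    from lineage4d.alignment import ReferenceModel

    back = ReferenceModel.from_json(p)
    assert back.n_controls == reference.n_controls
    for cell in list(reference.positions)[:10]:
        np.testing.assert_allclose(
            back.positions[cell], reference.positions[cell], atol=1e-6
        )
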
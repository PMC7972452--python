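"""Temporal and spatial alignment of embryos, and the control reference model.

Embryos are aligned in time by (i) a per-embryo pace scaling factor found by
maximizing the Pearson correlation between the embryo's interpolated
cell-count curve and a reference curve, and (ii) setting the division of ABa
as time zero.  Spatial alignment first normalizes nuclear positions to the
embryo's length/width/height per imaging axis, then infers the A-P axis as
the first principal component of all nuclear positions within the first 100
frames, the D-V axis through the MS-lineage centroid (ventral), and L-R as
their cross product.

The control reference model superimposes the aligned control embryos by
Generalized Procrustes Analysis (least-squares rotation + translation onto
an evolving mean; no scaling by default, since per-axis extent normalization
already removes size) and stores per-cell mean metaphase positions, mean
unit division vectors, per-minute mean trajectories, and per-feature control
means and SDs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import naming
from .errors import (
    AlignmentError,
    AxisError,
    InsufficientLandmarkError,
    LookupError_,
)
from .lineage_io import EmbryoLineage

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# temporal alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalAlignment:
    scale: float
    t_zero_min: float

    def aligned(self, t):
        return (np.asarray(t, dtype=float) - self.t_zero_min) * self.scale


def cell_count_curve(embryo: EmbryoLineage) -> tuple[np.ndarray, np.ndarray]:
    """(time_min, live cell count) sampled at each recorded frame."""
    frames: dict[int, int] = {}
    times: dict[int, float] = {}
    for t in embryo.tracks.values():
        for o in t.observations:
            frames[o.frame] = frames.get(o.frame, 0) + 1
            times[o.frame] = o.time_min
    fs = sorted(frames)
    return (
        np.array([times[f] for f in fs]),
        np.array([frames[f] for f in fs], dtype=float),
    )


def mean_count_curve(
    embryos: list[EmbryoLineage], grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average cell-count curve across embryos, each on its own ABa clock."""
    shifted = []
    for e in embryos:
        t0 = e.division_time("ABa")
        if t0 is None:
            raise AlignmentError(f"{e.embryo_id}: ABa division not tracked")
        t, c = cell_count_curve(e)
        shifted.append((t - t0, c))
    lo = min(t.min() for t, _ in shifted)
    hi = max(t.max() for t, _ in shifted)
    grid = np.arange(lo, hi + grid_step, grid_step)
    acc = np.zeros_like(grid)
    n = np.zeros_like(grid)
    for t, c in shifted:
        mask = (grid >= t.min()) & (grid <= t.max())
        acc[mask] += np.interp(grid[mask], t, c)
        n[mask] += 1
    valid = n > 0
    return grid[valid], acc[valid] / n[valid]


def temporal_align(
    embryo: EmbryoLineage,
    reference_curve: tuple[np.ndarray, np.ndarray],
    scale_range: tuple[float, float] = (0.5, 2.0),
    scale_step: float = 0.001,
    grid_step: float = 1.0,
) -> TemporalAlignment:
    """Pace-match an embryo to a reference (time, cell count) curve.

    The scale is searched on a fixed grid; the aligned clock is
    ``(t - t_zero) * scale`` with t_zero at the ABa division.
    """
    t0 = embryo.division_time("ABa")
    if t0 is None:
        raise AlignmentError(f"{embryo.embryo_id}: ABa division not tracked")
    times, counts = cell_count_curve(embryo)
    if counts.max() - counts.min() < 1:
        raise AlignmentError(f"{embryo.embryo_id}: flat cell-count curve")
    if embryo.n_divisions() < 8:
        raise AlignmentError(
            f"{embryo.embryo_id}: fewer than 8 divisions tracked"
        )
    rt, rc = np.asarray(reference_curve[0], float), np.asarray(
        reference_curve[1], float
    )
    times = times - t0

    scales = np.arange(scale_range[0], scale_range[1] + scale_step / 2, scale_step)
    best_scale, best_corr = 1.0, -np.inf
    for s in scales:
        lo = max(times.min() * s, rt.min())
        hi = min(times.max() * s, rt.max())
        if hi - lo < 5 * grid_step:
            continue
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        e = np.interp(grid / s, times, counts)
        r = np.interp(grid, rt, rc)
        if e.std() == 0 or r.std() == 0:
            continue
        corr = float(np.corrcoef(e, r)[0, 1])
        if corr > best_corr:
            best_corr, best_scale = corr, float(s)
    if not np.isfinite(best_corr):
        raise AlignmentError(
            f"{embryo.embryo_id}: no overlap with the reference curve"
        )
    return TemporalAlignment(scale=round(best_scale, 6), t_zero_min=float(t0))


# ---------------------------------------------------------------------------
# axis inference
# ---------------------------------------------------------------------------

@dataclass
class EmbryoFrame:
    """Inferred orthonormal A-P / D-V / L-R frame.

    ``axes`` rows are the A-P, D-V, L-R unit vectors in the (optionally
    extent-normalized) imaging coordinate system; ``extents`` are the raw
    per-imaging-axis extents, ``frame_extents`` the extents of the
    (normalized) cloud along the inferred axes, used for µm-equivalent
    rescaling against a reference.
    """

    origin: np.ndarray
    axes: np.ndarray
    extents: np.ndarray
    frame_extents: np.ndarray
    normalized: bool = True
    anisotropy: float = np.inf

    def validate(self) -> None:
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise AxisError("axes are not orthonormal")
        if not np.allclose(
            np.cross(self.axes[0], self.axes[1]), self.axes[2], atol=1e-9
        ):
            raise AxisError("frame is not right-handed (L-R != A-P x D-V)")


def _early_positions(embryo: EmbryoLineage, n_frames: int) -> np.ndarray:
    first = embryo.first_frame
    pts = []
    for t in embryo.tracks.values():
        for o in t.observations:
            if o.frame < first + n_frames:
                pts.append((o.x, o.y, o.z))
    return np.asarray(pts, dtype=float)


def infer_axes(
    embryo: EmbryoLineage, normalize: bool = True, n_frames: int = 100
) -> EmbryoFrame:
    """Infer the embryonic frame from nuclear positions.

    Axis directions come from the raw µm point cloud (PCA of all positions
    in the first 100 recorded frames), which keeps the estimator exactly
    rotation-equivariant; per-axis extent normalization — which would
    equalize the variances and leave the first principal component
    ill-conditioned — is applied to the *coordinates* afterwards (see
    :func:`to_embryo_coords`) when ``normalize`` is set.

    Sign conventions: A-P points so the AB-lineage side is negative
    (anterior), D-V so the MS-lineage (ventral) side is positive, and L-R
    completes a right-handed frame.
    """
    pts = _early_positions(embryo, n_frames)
    if pts.shape[0] < 4:
        raise AxisError(f"{embryo.embryo_id}: fewer than 4 early positions")
    mins, maxs = pts.min(axis=0), pts.max(axis=0)
    extents = maxs - mins
    origin = pts.mean(axis=0)  # centroid: rotation-equivariant, unlike the bbox
    x = pts - origin

    cov = np.cov(x.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    anisotropy = float(evals[0] / max(evals[1], 1e-12))
    if anisotropy < 1.2:
        log.warning(
            "%s: low anisotropy (%.2f); A-P axis ill-conditioned",
            embryo.embryo_id,
            anisotropy,
        )
    ap = evecs[:, 0]

    # orient A-P: AB-lineage centroid on the negative (anterior) side
    ab_pts = [
        o.position
        for name, t in embryo.tracks.items()
        if naming.is_valid_name(name) and naming.founder_of(name).super_lineage == "AB"
        for o in t.observations[:5]
    ]
    if ab_pts:
        ab_centroid = np.mean(ab_pts, axis=0) - origin
        if float(ab_centroid @ ap) > 0:
            ap = -ap

    ms_pts = [
        o.position
        for name, t in embryo.tracks.items()
        if naming.is_valid_name(name)
        and naming.split_name(name)[0] in ("MS", "EMS")
        for o in t.observations
    ]
    if not ms_pts:
        raise AxisError(
            f"{embryo.embryo_id}: no MS-lineage cells tracked; D-V undefined"
        )
    dv = np.mean(ms_pts, axis=0) - origin
    dv = dv - (dv @ ap) * ap
    nrm = np.linalg.norm(dv)
    if nrm < 1e-12:
        raise AxisError(f"{embryo.embryo_id}: MS centroid collinear with A-P")
    dv = dv / nrm  # ventral (MS side) positive
    lr = np.cross(ap, dv)

    axes = np.vstack([ap, dv, lr])
    rotated = x @ axes.T
    frame_extents = rotated.max(axis=0) - rotated.min(axis=0)  # µm, embryo axes
    frame = EmbryoFrame(
        origin=origin,
        axes=axes,
        extents=extents,
        frame_extents=frame_extents,
        normalized=normalize,
        anisotropy=anisotropy,
    )
    frame.validate()
    return frame


def to_embryo_coords(
    points: np.ndarray,
    frame: EmbryoFrame,
    target_extents: np.ndarray | None = None,
) -> np.ndarray:
    """Map imaging-frame points into (A-P, D-V, L-R) coordinates.

    With ``normalize`` set on the frame, coordinates are divided by the
    embryo's extent along each inferred axis (size removal); passing
    ``target_extents`` (typically the control-mean extents, µm) rescales the
    normalized coordinates to µm-equivalents.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    y = (pts - frame.origin) @ frame.axes.T
    if frame.normalized:
        y = y / np.where(frame.frame_extents > 1e-9, frame.frame_extents, 1.0)
        if target_extents is not None:
            y = y * np.asarray(target_extents)
    return y if np.asarray(points).ndim > 1 else y[0]


def rotate_vector_to_frame(
    vec: np.ndarray, frame: EmbryoFrame
) -> np.ndarray:
    """Rotate a displacement vector into the embryo frame.

    Vectors are only rotated, never extent-normalized: angles are measured
    in real (µm) space, where the anisotropic size normalization applied to
    positions would distort them.
    """
    return np.asarray(vec, dtype=float) @ frame.axes.T


# ---------------------------------------------------------------------------
# Procrustes superposition
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ p + t ≈ q."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


@dataclass
class GPAResult:
    aligned: list[dict[str, np.ndarray]]
    mean_shape: dict[str, np.ndarray]
    residual: float
    transforms: list[tuple[np.ndarray, np.ndarray]]
    n_iterations: int = 0


def _mean_shape(configs: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    cells: set[str] = set()
    for c in configs:
        cells |= set(c)
    return {
        cell: np.mean([c[cell] for c in configs if cell in c], axis=0)
        for cell in cells
    }


def _residual(
    configs: list[dict[str, np.ndarray]], mean: dict[str, np.ndarray]
) -> float:
    per_embryo = []
    for c in configs:
        shared = [cell for cell in c if cell in mean]
        if shared:
            d = np.array([c[cell] - mean[cell] for cell in shared])
            per_embryo.append(float((d ** 2).sum(axis=1).mean()))
    return float(np.mean(per_embryo)) if per_embryo else 0.0


def gpa_align(
    landmark_sets: list[dict[str, np.ndarray]],
    scaling: bool = False,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> GPAResult:
    """Generalized Procrustes superposition of named landmark sets.

    Landmarks are matched by cell name; cells missing from an embryo are
    dropped pairwise.  Each iteration aligns every configuration onto the
    current mean (synchronously, so the result does not depend on input
    order), then recomputes the mean.
    """
    if not landmark_sets:
        raise InsufficientLandmarkError("no landmark sets given")
    configs = [
        {k: np.asarray(v, dtype=float).copy() for k, v in c.items()}
        for c in landmark_sets
    ]
    n = len(configs)
    identity = (np.eye(3), np.zeros(3))
    if n == 1:
        return GPAResult(
            aligned=configs,
            mean_shape=dict(configs[0]),
            residual=0.0,
            transforms=[identity],
        )
    mean = _mean_shape(configs)
    for c in configs:
        shared = [cell for cell in c if cell in mean]
        if len(shared) < 4:
            raise InsufficientLandmarkError(
                f"only {len(shared)} shared landmarks; need >= 4"
            )

    transforms: list[tuple[np.ndarray, np.ndarray]] = [identity] * n
    prev = np.inf
    iters = 0
    for iters in range(1, max_iter + 1):
        new_configs = []
        for i, c in enumerate(configs):
            shared = sorted(cell for cell in c if cell in mean)
            P = np.array([c[cell] for cell in shared])
            Q = np.array([mean[cell] for cell in shared])
            s = 1.0
            if scaling:
                pc, qc = P.mean(axis=0), Q.mean(axis=0)
                sp = np.linalg.norm(P - pc)
                sq = np.linalg.norm(Q - qc)
                s = sq / sp if sp > 0 else 1.0
                P = pc + (P - pc) * s
            R, t = kabsch(P, Q)
            Ri, ti = transforms[i]
            transforms[i] = (R @ Ri, R @ ti + t)
            new_configs.append(
                {cell: R @ (p * s if scaling else p) + t for cell, p in c.items()}
            )
        configs = new_configs
        mean = _mean_shape(configs)
        res = _residual(configs, mean)
        if abs(prev - res) < tol:
            prev = res
            break
        prev = res
    return GPAResult(
        aligned=configs,
        mean_shape=mean,
        residual=prev,
        transforms=transforms,
        n_iterations=iters,
    )


# ---------------------------------------------------------------------------
# reference model
# ---------------------------------------------------------------------------

def metaphase_position(embryo: EmbryoLineage, cell: str) -> np.ndarray | None:
    """Last tracked position of a cell before its daughters appear."""
    t = embryo.tracks.get(cell)
    if t is None or not t.observations:
        return None
    return t.observations[-1].position


def division_vector(embryo: EmbryoLineage, cell: str) -> np.ndarray | None:
    """daughter1 - daughter2 positions at the daughters' first common frame."""
    t = embryo.tracks.get(cell)
    if t is None or len(t.daughter_names) != 2:
        return None
    pair = _ordered_daughters(cell, t.daughter_names)
    d1, d2 = (embryo.tracks.get(d) for d in pair)
    if d1 is None or d2 is None:
        return None
    f = max(d1.first_frame, d2.first_frame)
    o1 = next((o for o in d1.observations if o.frame == f), None)
    o2 = next((o for o in d2.observations if o.frame == f), None)
    if o1 is None or o2 is None:
        return None
    return o1.position - o2.position


def _ordered_daughters(cell: str, daughters: tuple[str, ...]) -> tuple[str, str]:
    if cell in naming.P_DAUGHTERS:
        pair = naming.P_DAUGHTERS[cell]
        if set(pair) == set(daughters):
            return pair
    a, b = sorted(daughters)
    if a and a[-1] in ("a", "l", "d"):
        return a, b
    return b, a


@dataclass
class ReferenceModel:
    """GPA-averaged control model: positions, division vectors, trajectories,
    and per-(cell, feature) control statistics."""

    positions: dict[str, np.ndarray]
    division_vectors: dict[str, np.ndarray]
    trajectory_grid: np.ndarray
    trajectories: dict[str, np.ndarray]  # cell -> (T, 3), NaN off-support
    extents: np.ndarray  # mean frame extents of the controls (µm-equivalent)
    n_controls: int
    feature_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    reference_curve: tuple[np.ndarray, np.ndarray] | None = None

    def position(self, cell: str) -> np.ndarray:
        if cell not in self.positions:
            raise LookupError_(f"cell {cell!r} absent from the reference model")
        return self.positions[cell]

    def trajectory_at(self, cell: str, t: float) -> np.ndarray | None:
        traj = self.trajectories.get(cell)
        if traj is None:
            return None
        g = self.trajectory_grid
        if t < g[0] or t > g[-1]:
            return None
        out = np.array([np.interp(t, g, traj[:, k]) for k in range(3)])
        return None if np.isnan(out).any() else out

    def to_json(self, path) -> None:
        def arr(a):
            return np.where(np.isfinite(a), np.round(a, 6), None).tolist()

        payload = {
            "units": "micrometre-equivalent (normalized coordinates rescaled "
            "by control-mean extents); axes A-P, D-V, L-R; time min from "
            "ABa division",
            "n_controls": self.n_controls,
            "extents": self.extents.tolist(),
            "trajectory_grid": self.trajectory_grid.tolist(),
            "positions": {c: arr(p) for c, p in sorted(self.positions.items())},
            "division_vectors": {
                c: arr(v) for c, v in sorted(self.division_vectors.items())
            },
            "trajectories": {
                c: arr(t) for c, t in sorted(self.trajectories.items())
            },
            "feature_stats": self.feature_stats.to_dict(orient="list"),
            "reference_curve": (
                None
                if self.reference_curve is None
                else [self.reference_curve[0].tolist(), self.reference_curve[1].tolist()]
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            d = json.load(fh)

        def arr(a):
            return np.array(
                [[np.nan if v is None else v for v in row] for row in a]
                if a and isinstance(a[0], list)
                else [np.nan if v is None else v for v in a],
                dtype=float,
            )

        return cls(
            positions={c: arr(p) for c, p in d["positions"].items()},
            division_vectors={c: arr(v) for c, v in d["division_vectors"].items()},
            trajectory_grid=np.array(d["trajectory_grid"], dtype=float),
            trajectories={c: arr(t) for c, t in d["trajectories"].items()},
            extents=np.array(d["extents"], dtype=float),
            n_controls=int(d["n_controls"]),
            feature_stats=pd.DataFrame(d.get("feature_stats", {})),
            reference_curve=(
                None
                if d.get("reference_curve") is None
                else (
                    np.array(d["reference_curve"][0], dtype=float),
                    np.array(d["reference_curve"][1], dtype=float),
                )
            ),
        )


def embryo_landmarks(
    embryo: EmbryoLineage,
    frame: EmbryoFrame,
    target_extents: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Metaphase positions (embryo coordinates) of all dividing cells."""
    out = {}
    for cell, track in embryo.tracks.items():
        if track.daughter_names and all(
            d in embryo.tracks for d in track.daughter_names
        ):
            pos = metaphase_position(embryo, cell)
            if pos is not None:
                out[cell] = to_embryo_coords(pos, frame, target_extents)
    return out


def build_reference(
    control_embryos: list[EmbryoLineage],
    scaling: bool = False,
    trajectory_step: float = 1.0,
    with_feature_stats: bool = True,
) -> ReferenceModel:
    """Build the control reference model from >= 1 aligned control embryos."""
    if not control_embryos:
        raise InsufficientLandmarkError("no control embryos given")
    ref_curve = mean_count_curve(control_embryos)
    taligns = [temporal_align(e, ref_curve) for e in control_embryos]
    frames = [infer_axes(e) for e in control_embryos]
    target_extents = np.mean([f.frame_extents for f in frames], axis=0)

    landmark_sets = [
        embryo_landmarks(e, f, target_extents)
        for e, f in zip(control_embryos, frames)
    ]
    gpa = gpa_align(landmark_sets, scaling=scaling)

    positions = gpa.mean_shape

    # mean unit division vectors, rotated by each embryo's GPA transform
    vec_acc: dict[str, list[np.ndarray]] = {}
    for e, f, (R, _t) in zip(control_embryos, frames, gpa.transforms):
        for cell in e.tracks:
            v = division_vector(e, cell)
            if v is None:
                continue
            v = rotate_vector_to_frame(v, f)
            nrm = np.linalg.norm(v)
            if nrm < 1e-12:
                continue
            vec_acc.setdefault(cell, []).append(R @ (v / nrm))
    division_vectors = {}
    for cell, vs in vec_acc.items():
        m = np.mean(vs, axis=0)
        nrm = np.linalg.norm(m)
        if nrm > 1e-12:
            division_vectors[cell] = m / nrm

    # per-minute mean trajectories on the aligned clock
    lo = float(
        min(
            min(
                ta.aligned(min(o.time_min for t in e.tracks.values() for o in t.observations)),
                0.0,
            )
            for e, ta in zip(control_embryos, taligns)
        )
    )
    hi = float(
        max(
            ta.aligned(max(o.time_min for t in e.tracks.values() for o in t.observations))
            for e, ta in zip(control_embryos, taligns)
        )
    )
    grid = np.arange(np.floor(lo), np.ceil(hi) + trajectory_step, trajectory_step)
    acc: dict[str, np.ndarray] = {}
    cnt: dict[str, np.ndarray] = {}
    for e, f, ta, (R, t_vec) in zip(control_embryos, frames, taligns, gpa.transforms):
        for cell, track in e.tracks.items():
            times = ta.aligned(track.times)
            pos = to_embryo_coords(track.positions, f, target_extents)
            pos = pos @ R.T + t_vec
            mask = (grid >= times.min()) & (grid <= times.max())
            if not mask.any():
                continue
            interp = np.column_stack(
                [np.interp(grid[mask], times, pos[:, k]) for k in range(3)]
            )
            if cell not in acc:
                acc[cell] = np.zeros((grid.size, 3))
                cnt[cell] = np.zeros(grid.size)
            acc[cell][mask] += interp
            cnt[cell][mask] += 1
    trajectories = {}
    for cell in acc:
        with np.errstate(invalid="ignore"):
            traj = acc[cell] / cnt[cell][:, None]
        trajectories[cell] = traj

    ref = ReferenceModel(
        positions=positions,
        division_vectors=division_vectors,
        trajectory_grid=grid,
        trajectories=trajectories,
        extents=target_extents,
        n_controls=len(control_embryos),
        reference_curve=ref_curve,
    )

    if with_feature_stats:
        from .features import extract_features

        rows = []
        for e, f, ta in zip(control_embryos, frames, taligns):
            feats = extract_features(e, reference=ref, frame=f, temporal_alignment=ta)
            rows.append(feats.stack(future_stack=True))
        stacked = pd.concat(rows, axis=1)
        stats = pd.DataFrame(
            {
                "mean": stacked.mean(axis=1),
                "sd": stacked.std(axis=1, ddof=1),
                "n": stacked.notna().sum(axis=1),
            }
        )
        stats.index = [f"{c}.{v}" for c, v in stats.index]
        ref.feature_stats = stats.reset_index(names="feature")
    return ref
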
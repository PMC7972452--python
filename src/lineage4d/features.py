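"""Per-cell feature extraction against the control reference model.

Thirteen variables are computed for every cell of an aligned embryo:

==========  =================================================================
StartTime   birth time on the aligned clock (min; missing for cells already
            present at recording start)
EndTime     division time (first frame at which daughters are tracked)
LifeTime    EndTime - StartTime
pAP/pDV/pLR metaphase position along the embryonic axes (µm-equivalent)
totdis      total trajectory length (sum of frame-to-frame displacements)
netdis      birth-to-end Euclidean displacement
aAP/aDV/aLR division angles versus the embryonic axes (degrees, 0-180)
aMean       angle between the observed and the reference division vector
pOV         Euclidean distance between the metaphase position and the
            reference mean position
==========  =================================================================

Angles are directed (0-180°, no folding to 0-90°), so inverted divisions
remain distinguishable (aMean near 180°).  Metaphase is operationalized as
the mother's last tracked frame and anaphase onset as the daughters' first
frame — the 2.5-min sampling makes finer staging impossible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import naming
from .alignment import (
    EmbryoFrame,
    ReferenceModel,
    TemporalAlignment,
    division_vector,
    embryo_landmarks,
    infer_axes,
    kabsch,
    metaphase_position,
    rotate_vector_to_frame,
    temporal_align,
    to_embryo_coords,
)
from .lineage_io import EmbryoLineage

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "StartTime",
    "EndTime",
    "LifeTime",
    "pAP",
    "pLR",
    "pDV",
    "totdis",
    "netdis",
    "aAP",
    "aLR",
    "aDV",
    "aMean",
    "pOV",
)

_AXIS_VECTORS = {"aAP": np.eye(3)[0], "aDV": np.eye(3)[1], "aLR": np.eye(3)[2]}


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Directed angle between two vectors in degrees, in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return np.nan
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _prepare_alignment(embryo, reference, frame, temporal_alignment):
    if frame is None:
        frame = infer_axes(embryo)
    if temporal_alignment is None:
        if reference is not None and reference.reference_curve is not None:
            temporal_alignment = temporal_align(embryo, reference.reference_curve)
        else:
            t0 = embryo.division_time("ABa")
            temporal_alignment = TemporalAlignment(
                scale=1.0, t_zero_min=0.0 if t0 is None else float(t0)
            )
    return frame, temporal_alignment


def _reference_fit(embryo, frame, reference):
    """Rigid fit of the embryo's metaphase landmarks onto the reference."""
    if reference is None:
        return np.eye(3), np.zeros(3)
    lm = embryo_landmarks(embryo, frame, reference.extents)
    shared = sorted(set(lm) & set(reference.positions))
    if len(shared) < 4:
        log.warning(
            "%s: only %d landmarks shared with the reference; skipping "
            "superposition",
            embryo.embryo_id,
            len(shared),
        )
        return np.eye(3), np.zeros(3)
    P = np.array([lm[c] for c in shared])
    Q = np.array([reference.positions[c] for c in shared])
    return kabsch(P, Q)


def extract_features(
    embryo: EmbryoLineage,
    reference: ReferenceModel | None = None,
    frame: EmbryoFrame | None = None,
    temporal_alignment: TemporalAlignment | None = None,
    fold_angles: bool = False,
) -> pd.DataFrame:
    """Feature matrix (rows = cells, columns = the 13 variables).

    Without a reference, aMean and pOV are missing.  Cells with a single
    tracked daughter get missing division-vector features.  ``fold_angles``
    folds the axis angles aAP/aDV/aLR into [0°, 90°] (undirected axes);
    aMean always stays directed so inversions remain visible.
    """
    frame, talign = _prepare_alignment(embryo, reference, frame, temporal_alignment)
    target = reference.extents if reference is not None else None
    R, tv = _reference_fit(embryo, frame, reference)
    first_recorded = embryo.first_frame

    rows = {}
    for cell, track in sorted(embryo.tracks.items()):
        r: dict[str, float] = dict.fromkeys(FEATURE_NAMES, np.nan)
        times = talign.aligned(track.times)
        pos = to_embryo_coords(track.positions, frame, target) @ R.T + tv
        if track.first_frame > first_recorded:
            r["StartTime"] = float(times[0])
        end = embryo.division_time(cell)
        if end is not None:
            r["EndTime"] = float(talign.aligned(end))
        if not np.isnan(r["StartTime"]) and not np.isnan(r["EndTime"]):
            r["LifeTime"] = r["EndTime"] - r["StartTime"]
        meta = pos[-1]
        r["pAP"], r["pDV"], r["pLR"] = map(float, meta)
        r["totdis"] = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
        r["netdis"] = float(np.linalg.norm(pos[-1] - pos[0]))

        if len(track.daughter_names) == 2:
            missing = [d for d in track.daughter_names if d not in embryo.tracks]
            if missing:
                log.warning(
                    "%s: cell %s has untracked daughter(s) %s; division "
                    "features missing",
                    embryo.embryo_id,
                    cell,
                    missing,
                )
            v = division_vector(embryo, cell)
            if v is not None:
                v = R @ rotate_vector_to_frame(v, frame)
                for name, axis in _AXIS_VECTORS.items():
                    a = angle_deg(v, axis)
                    r[name] = min(a, 180.0 - a) if fold_angles else a
                if reference is not None:
                    ref_v = reference.division_vectors.get(cell)
                    if ref_v is not None:
                        r["aMean"] = angle_deg(v, ref_v)
        if reference is not None and cell in reference.positions:
            r["pOV"] = float(np.linalg.norm(meta - reference.positions[cell]))
        rows[cell] = r
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "cell"
    return df


def feature_row(features: pd.DataFrame, cells=None) -> pd.Series:
    """Flatten a per-cell feature matrix to one `<cell>.<feature>` row."""
    if cells is not None:
        features = features.loc[[c for c in features.index if c in cells]]
    s = features.stack(future_stack=True)
    s.index = [f"{c}.{v}" for c, v in s.index]
    return s


def build_feature_table(
    embryos: list[EmbryoLineage],
    reference: ReferenceModel | None = None,
    stage: int | str = "all",
) -> pd.DataFrame:
    """Embryos × (cell, feature) table for a stage cohort.

    ``stage`` of 4/8/15/28 restricts columns to the cumulative stage cohort
    (cells present up to that stage); "all" keeps every tracked cell.
    """
    cells = None if stage == "all" else naming.cumulative_cohort(int(stage))
    rows = {}
    for e in embryos:
        feats = extract_features(e, reference=reference)
        rows[e.embryo_id] = feature_row(feats, cells)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "embryo_id"
    if cells is not None:
        cols = [
            f"{c}.{v}"
            for c in sorted(cells)
            for v in FEATURE_NAMES
            if f"{c}.{v}" in table.columns
        ]
        table = table.reindex(columns=cols)
    return table.sort_index(axis=0)


def positional_deviation_curve(
    embryo: EmbryoLineage,
    reference: ReferenceModel,
    frame: EmbryoFrame | None = None,
    temporal_alignment: TemporalAlignment | None = None,
    align_to_reference: bool = True,
    grid_step: float = 1.0,
) -> pd.DataFrame:
    """Mean positional deviation per cell at 1-min intervals.

    At each gridpoint, each live cell's interpolated position is compared to
    the reference trajectory of the same cell; the summed Euclidean
    distances are divided by the number of contributing cells.  Cells absent
    from the reference are left out of the denominator.
    """
    frame, talign = _prepare_alignment(embryo, reference, frame, temporal_alignment)
    R, tv = (
        _reference_fit(embryo, frame, reference)
        if align_to_reference
        else (np.eye(3), np.zeros(3))
    )
    tracks = {}
    for cell, track in embryo.tracks.items():
        if cell not in reference.trajectories:
            continue
        times = talign.aligned(track.times)
        pos = to_embryo_coords(track.positions, frame, reference.extents) @ R.T + tv
        tracks[cell] = (times, pos)
    if not tracks:
        return pd.DataFrame(columns=["time", "mean_deviation", "sd_deviation", "n_cells"])
    lo = min(t.min() for t, _ in tracks.values())
    hi = max(t.max() for t, _ in tracks.values())
    grid = np.arange(np.ceil(lo), np.floor(hi) + grid_step / 2, grid_step)
    out = []
    for t in grid:
        devs = []
        for cell, (times, pos) in tracks.items():
            if t < times.min() or t > times.max():
                continue
            ref_p = reference.trajectory_at(cell, float(t))
            if ref_p is None:
                continue
            p = np.array([np.interp(t, times, pos[:, k]) for k in range(3)])
            devs.append(float(np.linalg.norm(p - ref_p)))
        if devs:
            out.append(
                (
                    float(t),
                    float(np.mean(devs)),
                    float(np.std(devs, ddof=1)) if len(devs) > 1 else np.nan,
                    len(devs),
                )
            )
    return pd.DataFrame(out, columns=["time", "mean_deviation", "sd_deviation", "n_cells"])


def lineage_cell_counts(
    embryo: EmbryoLineage,
    temporal_alignment: TemporalAlignment | None = None,
) -> dict[str, pd.DataFrame]:
    """Live-cell count step curves for the AB and P1 super-lineages."""
    if temporal_alignment is None:
        t0 = embryo.division_time("ABa")
        temporal_alignment = TemporalAlignment(
            scale=1.0, t_zero_min=0.0 if t0 is None else float(t0)
        )
    frames: dict[int, float] = {}
    counts: dict[int, dict[str, int]] = {}
    for cell, track in embryo.tracks.items():
        try:
            sup = naming.founder_of(cell).super_lineage
        except Exception:
            continue
        if sup not in ("AB", "P1"):
            continue
        for o in track.observations:
            frames[o.frame] = o.time_min
            counts.setdefault(o.frame, {"AB": 0, "P1": 0})[sup] += 1
    out = {}
    fs = sorted(frames)
    times = temporal_alignment.aligned([frames[f] for f in fs])
    for sup in ("AB", "P1"):
        out[sup] = pd.DataFrame(
            {"time": times, "count": [counts[f][sup] for f in fs]}
        )
    return out


@dataclass
class PhenotypeFlags:
    ems_skew: bool | None = None
    msap_inversion: bool | None = None
    extra_P4_divisions: int = 0
    t_arrangement: bool | None = None
    ab_p1_asynchrony_min: float | None = None


def _p4_subtree_divisions(embryo: EmbryoLineage) -> int:
    count = 0
    stack = ["P4"]
    while stack:
        cell = stack.pop()
        track = embryo.tracks.get(cell)
        if track is None:
            continue
        if track.daughter_names and all(d in embryo.tracks for d in track.daughter_names):
            count += 1
            stack.extend(track.daughter_names)
    return count


def phenotype_flags(
    embryo: EmbryoLineage,
    reference: ReferenceModel | None = None,
    frame: EmbryoFrame | None = None,
    temporal_alignment: TemporalAlignment | None = None,
    ems_skew_threshold_deg: float = 35.0,
) -> PhenotypeFlags:
    """Derived qualitative phenotypes.

    * ems_skew: EMS division vector deviates from the reference by more than
      35° at anaphase onset;
    * msap_inversion: MSa and MSp L-R coordinates both sign-flipped relative
      to the reference prior to their division;
    * extra_P4_divisions: divisions within the P4 subtree beyond the single
      normal one;
    * ab_p1_asynchrony_min: P1 minus AB division time on the aligned clock;
    * t_arrangement: proxy rule for the abnormal 4-cell T-arrangement (ABa->
      ABp nearly parallel to A-P and P2 far from ABp).
    """
    frame, talign = _prepare_alignment(embryo, reference, frame, temporal_alignment)
    flags = PhenotypeFlags()

    R, tv = _reference_fit(embryo, frame, reference)

    # EMS skew
    if reference is not None:
        v = division_vector(embryo, "EMS")
        ref_v = reference.division_vectors.get("EMS")
        if v is not None and ref_v is not None:
            v = R @ rotate_vector_to_frame(v, frame)
            flags.ems_skew = bool(angle_deg(v, ref_v) > ems_skew_threshold_deg)

    # MSa/MSp left-right inversion, scored at metaphase (prior to division)
    if reference is not None:
        signs = []
        for cell in ("MSa", "MSp"):
            pos = metaphase_position(embryo, cell)
            ref_p = reference.positions.get(cell)
            if pos is None or ref_p is None or abs(ref_p[2]) < 0.5:
                signs = []
                break
            p = to_embryo_coords(pos, frame, reference.extents) @ R.T + tv
            signs.append(np.sign(p[2]) == -np.sign(ref_p[2]))
        if signs:
            flags.msap_inversion = bool(all(signs))

    flags.extra_P4_divisions = max(0, _p4_subtree_divisions(embryo) - 1)

    t_ab = embryo.division_time("AB")
    t_p1 = embryo.division_time("P1")
    if t_ab is not None and t_p1 is not None:
        flags.ab_p1_asynchrony_min = float(
            talign.aligned(t_p1) - talign.aligned(t_ab)
        )

    # T-arrangement proxy at the 4-cell stage
    four = ("ABa", "ABp", "EMS", "P2")
    if all(c in embryo.tracks for c in four):
        f0 = max(embryo.tracks[c].first_frame for c in four)
        obs = embryo.observations_at_frame(f0)
        if all(c in obs for c in four):
            p = {
                c: to_embryo_coords(obs[c].position, frame, None)
                for c in four
            }
            ab_vec = p["ABp"] - p["ABa"]
            ang = angle_deg(ab_vec, np.eye(3)[0])
            ang = min(ang, 180.0 - ang)
            adjacent = [
                np.linalg.norm(p["ABa"] - p["ABp"]),
                np.linalg.norm(p["ABa"] - p["EMS"]),
                np.linalg.norm(p["EMS"] - p["P2"]),
            ]
            d_p2_abp = np.linalg.norm(p["P2"] - p["ABp"])
            flags.t_arrangement = bool(
                ang < 30.0 and d_p2_abp > 1.5 * float(np.mean(adjacent))
            )
    return flags
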
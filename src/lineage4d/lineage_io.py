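"""Reading, validating, and writing tracked-lineage data.

Two on-disk formats are supported:

* the *native* long format — one delimited text row per nucleus observation
  (columns: embryo_id, cell_name, frame, time_min, x, y, z, diameter,
  parent_name), TSV by default with comma accepted;
* the StarryNite/AceTree *nuclei* dialect — one comma-separated file per
  timepoint (``t###-nuclei``), read best-effort with an optional column
  mapping and pixel/plane calibration.

Coordinates are continuous µm in a right-handed imaging frame; frames are
1-based; ``time_min`` defaults to ``(frame - 1) * frame_interval`` when
absent.  Cells already present at recording start have no observable birth,
so their StartTime is treated as missing downstream.
"""
from __future__ import annotations

import logging
import os
import re
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import naming
from .errors import (
    ConfigurationError,
    DuplicationError,
    FormatError,
    StructureError,
)

log = logging.getLogger(__name__)

GROUPS = (
    "wild_type",
    "control",
    "equalized_alive",
    "equalized_dead",
    "inverted",
    "synthetic",
)

NATIVE_COLUMNS = (
    "embryo_id",
    "cell_name",
    "frame",
    "time_min",
    "x",
    "y",
    "z",
    "diameter",
    "parent_name",
)


@dataclass(frozen=True)
class NucleusObservation:
    """One time-stamped 3D nuclear position."""

    cell_name: str
    frame: int
    time_min: float
    x: float
    y: float
    z: float
    diameter: float | None = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class CellTrack:
    """A named cell's ordered observations plus its tree links."""

    cell_name: str
    observations: list[NucleusObservation] = field(default_factory=list)
    parent_name: str | None = None
    daughter_names: tuple[str, ...] = ()

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_min for o in self.observations])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[o.x, o.y, o.z] for o in self.observations], dtype=float)

    def validate(self) -> None:
        frames = [o.frame for o in self.observations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise StructureError(
                f"track {self.cell_name!r}: frames not strictly increasing"
            )
        for o in self.observations:
            if o.diameter is not None and not np.isnan(o.diameter) and o.diameter < 0:
                raise StructureError(
                    f"track {self.cell_name!r}: negative diameter at frame {o.frame}"
                )
        if len(self.daughter_names) not in (0, 2):
            raise StructureError(
                f"cell {self.cell_name!r} has {len(self.daughter_names)} daughters; "
                "expected 0 or 2"
            )


@dataclass
class EmbryoMetadata:
    group: str = "synthetic"
    relative_AB_size: float | None = None
    compression_um: float | None = None
    frame_interval_min: float = 2.5
    outcome: str = "unknown"  # alive / dead / unknown

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}")
        if self.relative_AB_size is not None and not (
            0 < self.relative_AB_size < 100
        ):
            raise FormatError(
                f"relative AB size {self.relative_AB_size} outside (0, 100)"
            )
        if self.outcome not in ("alive", "dead", "unknown"):
            raise FormatError(f"unknown outcome {self.outcome!r}")


@dataclass
class EmbryoLineage:
    """One embryo's tracked lineage forest plus metadata."""

    embryo_id: str
    tracks: dict[str, CellTrack] = field(default_factory=dict)
    metadata: EmbryoMetadata = field(default_factory=EmbryoMetadata)

    @property
    def frame_interval(self) -> float:
        return self.metadata.frame_interval_min

    @property
    def first_frame(self) -> int:
        return min(t.first_frame for t in self.tracks.values())

    @property
    def last_frame(self) -> int:
        return max(t.last_frame for t in self.tracks.values())

    def cells_at_frame(self, frame: int) -> list[str]:
        return [
            name
            for name, t in self.tracks.items()
            if t.first_frame <= frame <= t.last_frame
            and any(o.frame == frame for o in t.observations)
        ]

    def observations_at_frame(self, frame: int) -> dict[str, NucleusObservation]:
        out = {}
        for name, t in self.tracks.items():
            if t.first_frame <= frame <= t.last_frame:
                for o in t.observations:
                    if o.frame == frame:
                        out[name] = o
                        break
        return out

    def division_time(self, cell_name: str) -> float | None:
        """Anaphase-onset proxy: first frame at which a daughter is tracked."""
        track = self.tracks.get(cell_name)
        if track is None or not track.daughter_names:
            return None
        times = [
            self.tracks[d].observations[0].time_min
            for d in track.daughter_names
            if d in self.tracks and self.tracks[d].observations
        ]
        return min(times) if times else None

    def n_divisions(self) -> int:
        return sum(
            1
            for t in self.tracks.values()
            if t.daughter_names and all(d in self.tracks for d in t.daughter_names)
        )

    def validate(self) -> None:
        for name, track in self.tracks.items():
            track.validate()
            if track.parent_name is not None:
                parent = self.tracks.get(track.parent_name)
                if parent is None:
                    raise StructureError(
                        f"cell {name!r} refers to unknown parent "
                        f"{track.parent_name!r}"
                    )
                if track.first_frame <= parent.last_frame:
                    raise StructureError(
                        f"daughter {name!r} overlaps its parent "
                        f"{track.parent_name!r} in time"
                    )
            if not naming.is_valid_name(name):
                raise StructureError(f"unresolvable cell name {name!r}")


def _link_tracks(tracks: dict[str, CellTrack]) -> None:
    """Fill daughter_names from parent links and validate counts."""
    daughters: dict[str, list[str]] = {}
    for name, t in tracks.items():
        if t.parent_name:
            if t.parent_name not in tracks:
                raise StructureError(
                    f"cell {name!r} refers to nonexistent parent {t.parent_name!r}"
                )
            daughters.setdefault(t.parent_name, []).append(name)
    for parent, ds in daughters.items():
        if len(ds) != 2:
            raise StructureError(
                f"cell {parent!r} has {len(ds)} tracked daughter(s); expected 0 or 2"
            )
        tracks[parent].daughter_names = tuple(sorted(ds))


# ---------------------------------------------------------------------------
# native long format
# ---------------------------------------------------------------------------

def read_native(
    path, metadata: dict[str, EmbryoMetadata] | None = None
) -> list[EmbryoLineage]:
    """Read a native long-format lineage table (TSV default, CSV accepted)."""
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    dup = df.duplicated(subset=["embryo_id", "cell_name", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicationError(
            f"duplicate observation for embryo {row.embryo_id!r}, "
            f"cell {row.cell_name!r}, frame {int(row.frame)}"
        )
    df = df.sort_values(["embryo_id", "cell_name", "frame"])
    embryos = []
    for embryo_id, sub in df.groupby("embryo_id", sort=True):
        tracks: dict[str, CellTrack] = {}
        for cell_name, rows in sub.groupby("cell_name", sort=True):
            parents = rows["parent_name"].dropna().unique()
            parent = str(parents[0]) if len(parents) else None
            obs = [
                NucleusObservation(
                    cell_name=str(cell_name),
                    frame=int(r.frame),
                    time_min=float(r.time_min),
                    x=float(r.x),
                    y=float(r.y),
                    z=float(r.z),
                    diameter=None if pd.isna(r.diameter) else float(r.diameter),
                )
                for r in rows.itertuples()
            ]
            tracks[str(cell_name)] = CellTrack(
                cell_name=str(cell_name), observations=obs, parent_name=parent
            )
        _link_tracks(tracks)
        meta = (metadata or {}).get(str(embryo_id), EmbryoMetadata())
        emb = EmbryoLineage(embryo_id=str(embryo_id), tracks=tracks, metadata=meta)
        emb.validate()
        embryos.append(emb)
    return embryos


def write_native(embryos, path) -> None:
    """Write one or more embryos as a native long-format TSV."""
    if isinstance(embryos, EmbryoLineage):
        embryos = [embryos]
    rows = []
    for emb in embryos:
        for name in sorted(emb.tracks):
            t = emb.tracks[name]
            for o in t.observations:
                rows.append(
                    (
                        emb.embryo_id,
                        name,
                        o.frame,
                        o.time_min,
                        o.x,
                        o.y,
                        o.z,
                        np.nan if o.diameter is None else o.diameter,
                        t.parent_name or "",
                    )
                )
    df = pd.DataFrame(rows, columns=NATIVE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metadata(path) -> dict[str, EmbryoMetadata]:
    """Read the per-embryo metadata CSV."""
    df = pd.read_csv(path)
    required = {"embryo_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {sorted(missing)}")
    out = {}
    for r in df.itertuples():
        meta = EmbryoMetadata(
            group=str(r.group),
            relative_AB_size=(
                None
                if "relative_AB_size" not in df.columns or pd.isna(r.relative_AB_size)
                else float(r.relative_AB_size)
            ),
            compression_um=(
                None
                if "compression_um" not in df.columns or pd.isna(r.compression_um)
                else float(r.compression_um)
            ),
            frame_interval_min=(
                float(r.frame_interval_min)
                if "frame_interval_min" in df.columns
                and not pd.isna(r.frame_interval_min)
                else 2.5
            ),
            outcome=(
                str(r.outcome)
                if "outcome" in df.columns and not pd.isna(r.outcome)
                else "unknown"
            ),
        )
        meta.validate()
        out[str(r.embryo_id)] = meta
    return out


def write_metadata(metadata: dict[str, EmbryoMetadata], path) -> None:
    rows = [
        {
            "embryo_id": eid,
            "group": m.group,
            "relative_AB_size": m.relative_AB_size,
            "compression_um": m.compression_um,
            "outcome": m.outcome,
            "frame_interval_min": m.frame_interval_min,
        }
        for eid, m in metadata.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# StarryNite / AceTree nuclei dialect
# ---------------------------------------------------------------------------

#: classic AceTree nuclei column positions (0-based)
DEFAULT_NUCLEI_COLUMNS = {
    "index": 0,
    "valid": 1,
    "predecessor": 2,
    "successor1": 3,
    "successor2": 4,
    "x": 5,
    "y": 6,
    "z": 7,
    "diameter": 8,
    "name": 9,
}

_NUCLEI_RE = re.compile(r"t(\d+)-nuclei$")


def _iter_nuclei_files(path):
    """Yield (timepoint, list of raw lines) from a directory or zip."""
    if os.path.isdir(path):
        entries = []
        for fn in os.listdir(path):
            m = _NUCLEI_RE.search(fn)
            if m:
                with open(os.path.join(path, fn)) as fh:
                    entries.append((int(m.group(1)), fh.read().splitlines()))
    elif zipfile.is_zipfile(path):
        entries = []
        with zipfile.ZipFile(path) as zf:
            for fn in zf.namelist():
                m = _NUCLEI_RE.search(fn)
                if m:
                    lines = zf.read(fn).decode().splitlines()
                    entries.append((int(m.group(1)), lines))
    else:
        raise FormatError(f"{path}: not a directory or zip of t###-nuclei files")
    if not entries:
        raise FormatError(f"{path}: no t###-nuclei files found")
    return sorted(entries)


def read_starrynite(
    path,
    xy_res: float | None = None,
    z_res: float | None = None,
    frame_interval_min: float = 2.5,
    embryo_id: str | None = None,
    column_map: dict[str, int] | None = None,
) -> EmbryoLineage:
    """Read an AceTree/StarryNite nuclei export (zip or directory).

    ``xy_res`` (µm/pixel) and ``z_res`` (µm/plane) convert device coordinates
    to µm and are mandatory.  The column layout of deposited exports varies;
    ``column_map`` overrides the classic positions in
    :data:`DEFAULT_NUCLEI_COLUMNS`.
    """
    if xy_res is None or z_res is None:
        raise ConfigurationError(
            "read_starrynite requires xy_res and z_res calibration"
        )
    cols = dict(DEFAULT_NUCLEI_COLUMNS)
    if column_map:
        cols.update(column_map)

    per_tp: dict[int, dict[int, dict]] = {}
    for tp, lines in _iter_nuclei_files(path):
        nuclei = {}
        for line in lines:
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(",")]
            try:
                rec = {
                    "index": int(parts[cols["index"]]),
                    "valid": int(parts[cols["valid"]]),
                    "pred": int(parts[cols["predecessor"]]),
                    "succ1": int(parts[cols["successor1"]]),
                    "succ2": int(parts[cols["successor2"]]),
                    "x": float(parts[cols["x"]]) * xy_res,
                    "y": float(parts[cols["y"]]) * xy_res,
                    "z": float(parts[cols["z"]]) * z_res,
                    "diameter": float(parts[cols["diameter"]]) * xy_res,
                    "name": parts[cols["name"]],
                }
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"timepoint {tp}: cannot parse nuclei line {line!r}"
                ) from exc
            nuclei[rec["index"]] = rec
        per_tp[tp] = nuclei

    timepoints = sorted(per_tp)
    # seeds of new tracks: first timepoint, orphan nuclei, and division products
    starts: list[tuple[int, int, int | None]] = []  # (tp, index, parent track id)
    consumed: set[tuple[int, int]] = set()

    tracks_raw: list[dict] = []

    def follow(tp: int, idx: int, parent_track: int | None) -> None:
        tid = len(tracks_raw)
        tracks_raw.append({"obs": [], "parent": parent_track, "daughters": []})
        while True:
            rec = per_tp[tp].get(idx)
            if rec is None:
                raise StructureError(
                    f"broken predecessor/successor chain at timepoint {tp} "
                    f"(index {idx})"
                )
            if rec["valid"]:
                tracks_raw[tid]["obs"].append((tp, rec))
            consumed.add((tp, idx))
            tracks_raw[tid]["name"] = rec["name"] or tracks_raw[tid].get("name", "")
            s1, s2 = rec["succ1"], rec["succ2"]
            next_i = timepoints.index(tp) + 1
            if next_i >= len(timepoints):
                return
            ntp = timepoints[next_i]
            if s1 > 0 and s2 > 0:  # division
                for s in (s1, s2):
                    tracks_raw[tid]["daughters"].append((ntp, s))
                    follow(ntp, s, tid)
                return
            if s1 <= 0 and s2 <= 0:
                return
            tp, idx = ntp, (s1 if s1 > 0 else s2)

    first_tp = timepoints[0]
    for idx, rec in sorted(per_tp[first_tp].items()):
        if rec["valid"]:
            follow(first_tp, idx, None)
    # orphans appearing later with no predecessor
    for tp in timepoints[1:]:
        for idx, rec in sorted(per_tp[tp].items()):
            if rec["valid"] and (tp, idx) not in consumed and rec["pred"] <= 0:
                follow(tp, idx, None)

    tracks: dict[str, CellTrack] = {}
    id_to_name: dict[int, str] = {}
    for tid, raw in enumerate(tracks_raw):
        if not raw["obs"]:
            continue
        name = raw.get("name") or f"track{tid}"
        id_to_name[tid] = name
        obs = [
            NucleusObservation(
                cell_name=name,
                frame=tp,
                time_min=(tp - 1) * frame_interval_min,
                x=rec["x"],
                y=rec["y"],
                z=rec["z"],
                diameter=rec["diameter"],
            )
            for tp, rec in raw["obs"]
        ]
        tracks[name] = CellTrack(cell_name=name, observations=obs)
    for tid, raw in enumerate(tracks_raw):
        if tid not in id_to_name:
            continue
        name = id_to_name[tid]
        if raw["parent"] is not None and raw["parent"] in id_to_name:
            tracks[name].parent_name = id_to_name[raw["parent"]]
    _link_tracks({n: t for n, t in tracks.items()})

    if not tracks:
        log.warning("%s: all nuclei flagged invalid; empty embryo", path)
    eid = embryo_id or os.path.splitext(os.path.basename(str(path)))[0]
    return EmbryoLineage(
        embryo_id=eid,
        tracks=tracks,
        metadata=EmbryoMetadata(frame_interval_min=frame_interval_min),
    )


def relabel(embryo: EmbryoLineage, **meta_updates) -> EmbryoLineage:
    """Return a copy of ``embryo`` with updated metadata fields."""
    return EmbryoLineage(
        embryo_id=embryo.embryo_id,
        tracks=embryo.tracks,
        metadata=replace(embryo.metadata, **meta_updates),
    )
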
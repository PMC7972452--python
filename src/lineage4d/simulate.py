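"""Synthetic embryo-lineage generator.

Produces tracked lineages with the statistical structure the downstream
analysis assumes: the canonical Sulston topology to ~100 cells, lineage- and
generation-specific division clocks, 3D nuclear positions packed inside an
ellipsoidal eggshell by soft-sphere relaxation, and group-dependent
perturbations — P1-lineage cell-cycle shortening scaled by relative AB size,
positional noise, and planted dead-embryo signatures (dorsal shift of ABar
progeny, inflated Ca movement, MS division-angle skew and MSa/MSp inversion,
EMS spindle skew, extra germline divisions).  Recordings can be truncated at
the 26-cell stage to emulate partially lineaged embryos.

The generator is a study stand-in, not a mechanical model: eggshell
deformation, cytoplasmic flows, and real wild-type coordinates are out of
scope.  Every stochastic choice flows from one seed, so an embryo is a pure
function of (config, group, seed).
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import naming
from .errors import GeometryError
from .lineage_io import (
    CellTrack,
    EmbryoLineage,
    EmbryoMetadata,
    NucleusObservation,
    write_metadata,
    write_native,
)

DEAD_SIGNATURE_GROUPS = ("equalized_dead", "inverted")

#: mean cell-cycle duration (min, 17 °C pace) per founder lineage and
#: generation (index = number of suffix letters of the mother).  Entries for
#: P-lineage mothers are explicit.  Values are a realistic reconstruction of
#: early-embryo pacing: near-synchronous AB rounds, a long gastrulation-stage
#: E cycle, and slow D/P4 cycles.
DEFAULT_CLOCK_TABLE: dict[str, tuple[float, ...]] = {
    "AB": (25.0, 24.0, 26.0, 29.0, 32.0, 35.0, 38.0),
    "MS": (27.0, 31.0, 34.0, 37.0, 40.0),
    "E": (32.0, 62.0, 40.0, 45.0),
    "C": (30.0, 34.0, 36.0, 40.0),
    "D": (50.0, 45.0),
    "EMS": (26.0,),
    "P2": (31.0,),
    "P3": (34.0,),
    "P4": (78.0,),
}

#: cycle of an ectopically dividing germline daughter (Z2), used only when
#: the extra-P4-division signature is planted; short, mimicking a repetition
#: of the P3-like fate
_GERMLINE_ECTOPIC_CYCLE = 35.0


@dataclass
class PerturbationConfig:
    """Planted group effects.

    ``p1_clock_scaling`` is the fractional cell-cycle shortening of
    P1-lineage cells per percentage point of relative AB size below 60%
    (the wild-type value); P4 is additionally sensitive by
    ``p4_extra_sensitivity``.  The dead-embryo signature magnitudes are
    calibration knobs, set once to plausible values.
    """

    p1_clock_scaling: float = 0.012
    p4_extra_sensitivity: float = 2.5
    abar_progeny_dv_shift_um: float = 2.0
    ca_netdis_inflation: float = 2.5
    ms_angle_skew_deg_sd: float = 25.0
    msap_inversion_prob: float = 0.35
    ems_skew_prob: float = 0.25
    ems_skew_prob_inverted: float = 0.43
    extra_p4_division_prob: float = 0.35
    timing_cv_inflation: float = 1.3
    compression_dv_per_um: float = 0.01

    def validate(self) -> None:
        for p in (
            self.msap_inversion_prob,
            self.ems_skew_prob,
            self.ems_skew_prob_inverted,
            self.extra_p4_division_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not math.isfinite(self.abar_progeny_dv_shift_um):
            raise ValueError("ABar shift must be finite")


def _default_n_embryos() -> dict[str, int]:
    # group sizes of the lineaging data set
    return {
        "wild_type": 10,
        "control": 18,
        "equalized_alive": 21,
        "equalized_dead": 28,
        "inverted": 7,
    }


def _default_ab_size() -> dict[str, tuple[float, float]]:
    # (mean %, SD %) of relative AB size per group
    return {
        "wild_type": (60.0, 1.5),
        "control": (58.0, 2.0),
        "equalized_alive": (50.6, 1.5),
        "equalized_dead": (50.6, 1.5),
        "inverted": (46.0, 1.0),
    }


def _default_compression() -> dict[str, tuple[float, float]]:
    # (mean µm, SD µm) sample height per group; dead embryos more compressed
    return {
        "wild_type": (21.9, 2.2),
        "control": (21.9, 2.2),
        "equalized_alive": (21.9, 2.2),
        "equalized_dead": (19.8, 2.1),
        "inverted": (19.8, 2.1),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_embryos: dict[str, int] = field(default_factory=_default_n_embryos)
    ab_size: dict[str, tuple[float, float]] = field(default_factory=_default_ab_size)
    compression: dict[str, tuple[float, float]] = field(
        default_factory=_default_compression
    )
    eggshell_half_axes: tuple[float, float, float] = (25.0, 15.0, 12.5)  # AP, DV, LR
    frame_interval_min: float = 2.5
    clock_table: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLOCK_TABLE)
    )
    positional_noise_um: float = 0.7
    motion_sd_um: float = 0.35
    timing_cv: float = 0.05
    asynchrony_residual_min: float = 0.75
    asynchrony_per_percent: float = 0.25
    asynchrony_zero_size_pct: float = 46.0
    cell_volume_fraction: float = 0.55
    relaxation_iterations: int = 20
    target_cells: int = 100
    truncation_fraction: float = 0.2
    truncation_cells: int = 26
    max_frames: int = 140
    reference_height_um: float = 25.0
    perturbations: PerturbationConfig = field(default_factory=PerturbationConfig)

    def validate(self) -> None:
        if self.positional_noise_um < 0 or self.motion_sd_um < 0 or self.timing_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        for g, (mean, sd) in self.ab_size.items():
            if not (30.0 < mean < 70.0):
                raise ValueError(f"AB size mean for {g} outside (30, 70)")
            if sd < 0:
                raise ValueError("AB size SD must be >= 0")
        self.perturbations.validate()


# ---------------------------------------------------------------------------
# canonical division axes
# ---------------------------------------------------------------------------

def _name_jitter(name: str) -> np.ndarray:
    """Deterministic pseudo-random unit-cube vector from a cell name."""
    h = hashlib.blake2b(name.encode(), digest_size=6).digest()
    vals = np.array([h[0] | (h[1] << 8), h[2] | (h[3] << 8), h[4] | (h[5] << 8)])
    return vals / 32767.5 - 1.0


_LETTER_BASE = {
    "a": np.array([-1.0, 0.0, 0.0]),  # anterior = negative A-P
    "d": np.array([0.0, -1.0, 0.0]),  # dorsal = negative D-V (ventral positive)
    "l": np.array([0.0, 0.0, -1.0]),  # left = negative L-R
}

#: explicit canonical axes where the planted phenotypes need leverage:
#: MS divides obliquely in the A-P/L-R plane (so an inversion flips the L-R
#: sign of MSa/MSp), EMS exactly along A-P (so a skew is unambiguous).
_AXIS_OVERRIDES = {
    "MS": np.array([-0.8, 0.0, -0.6]),
    "EMS": np.array([-1.0, 0.0, 0.0]),
}


def canonical_division_axis(name: str) -> np.ndarray:
    """Unit division vector (daughter1 - daughter2 direction) in the
    canonical (A-P, D-V, L-R) frame."""
    if name in _AXIS_OVERRIDES:
        v = _AXIS_OVERRIDES[name]
    else:
        letter = naming.canonical_suffix_letter(name) or "a"
        v = _LETTER_BASE[letter] + 0.35 * _name_jitter(name)
    return v / np.linalg.norm(v)


def _daughter_names(name: str) -> tuple[str, str]:
    letter = naming.canonical_suffix_letter(name)
    if letter is None:
        return naming.P_DAUGHTERS[name]
    return naming.daughters_of(name, letter)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    return (
        v * math.cos(th)
        + np.cross(axis, v) * math.sin(th)
        + axis * float(np.dot(axis, v)) * (1 - math.cos(th))
    )


# ---------------------------------------------------------------------------
# clocks
# ---------------------------------------------------------------------------

def _cycle_mean(name: str, table: dict[str, tuple[float, ...]]) -> float | None:
    """Mean cycle length of ``name``; None when the cell does not divide."""
    if name in table and name in naming.P_DAUGHTERS:
        return table[name][0]
    base, suffix = naming.split_name(name)
    if base in ("Z2", "Z3"):
        return None  # quiescent germline; ectopic divisions handled separately
    row = table.get(base)
    if row is None:
        return None
    return row[min(len(suffix), len(row) - 1)]


def _p1_scale(ab_size: float, pert: PerturbationConfig) -> float:
    return max(0.6, 1.0 - pert.p1_clock_scaling * max(0.0, 60.0 - ab_size))


def _p4_scale(ab_size: float, pert: PerturbationConfig) -> float:
    return max(
        0.5,
        1.0
        - pert.p4_extra_sensitivity
        * pert.p1_clock_scaling
        * max(0.0, 60.0 - ab_size),
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

#: daughter volume fractions for the asymmetric P-lineage divisions
_VOLUME_SPLITS = {
    "P1": (0.60, 0.40),  # EMS, P2
    "EMS": (0.55, 0.45),
    "P2": (0.55, 0.45),
    "P3": (0.55, 0.45),
}


def _relax(
    pos: np.ndarray,
    radii: np.ndarray,
    half_axes: np.ndarray,
    iterations: int,
) -> np.ndarray:
    """Soft-sphere overlap resolution followed by eggshell projection."""
    for _ in range(iterations):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        target = radii[:, None] + radii[None, :]
        overlap = np.clip(target - dist, 0.0, None)
        with np.errstate(invalid="ignore"):
            push = np.where(
                (overlap > 0)[..., None], diff / dist[..., None], 0.0
            ) * overlap[..., None]
        pos = pos + 0.3 * push.sum(axis=1)
        # project inside the (radius-shrunken) eggshell ellipsoid
        eff = np.clip(half_axes[None, :] - radii[:, None], 0.5, None)
        u = pos / eff
        nrm = np.linalg.norm(u, axis=1)
        outside = nrm > 1.0
        if outside.any():
            pos[outside] = pos[outside] / nrm[outside, None]
    return pos


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _schedule_divisions(
    config: SimulationConfig,
    ab_size: float,
    dead_signature: bool,
    extra_p4: bool,
    rng: np.random.Generator,
) -> tuple[dict[str, float], dict[str, float]]:
    """Sample birth and division times for all cells, starting at the 2-cell
    stage (AB and P1 born at t=0)."""
    pert = config.perturbations
    cv = config.timing_cv * (pert.timing_cv_inflation if dead_signature else 1.0)
    sigma = math.sqrt(math.log1p(cv * cv))

    def sample(mean: float) -> float:
        if sigma == 0.0:
            rng.standard_normal()  # keep the stream aligned across configs
            return mean
        return mean * math.exp(rng.standard_normal() * sigma - sigma * sigma / 2.0)

    p1s = _p1_scale(ab_size, pert)
    p4s = _p4_scale(ab_size, pert)

    birth: dict[str, float] = {"AB": 0.0, "P1": 0.0}
    division: dict[str, float] = {}

    t_ab = sample(_cycle_mean("AB", config.clock_table))
    # AB divides first; the gap shrinks linearly as AB size approaches the
    # inversion region, with a size-independent residual (checkpoint-driven)
    asyn = config.asynchrony_residual_min + config.asynchrony_per_percent * max(
        0.0, ab_size - config.asynchrony_zero_size_pct
    )
    asyn = sample(asyn)
    division["AB"] = t_ab
    division["P1"] = t_ab + asyn

    horizon = 400.0
    queue = ["AB", "P1"]
    while queue:
        cell = queue.pop(0)
        t_div = division.get(cell)
        if t_div is None or t_div > horizon:
            continue
        d1, d2 = _daughter_names(cell)
        for i, d in enumerate((d1, d2)):
            birth[d] = t_div
            mean = _cycle_mean(d, config.clock_table)
            if mean is None:
                if extra_p4 and d == "Z2":
                    mean = _GERMLINE_ECTOPIC_CYCLE
                else:
                    continue
            sup = naming.founder_of(d).super_lineage
            if sup == "P1":
                mean *= p4s if d == "P4" else p1s
            # slight a/p pacing offset so division sequences are resolvable
            mean *= 0.985 if i == 0 else 1.015
            division[d] = t_div + sample(mean)
            queue.append(d)
    return birth, division


def simulate_embryo(
    config: SimulationConfig,
    group: str,
    seed,
    embryo_id: str | None = None,
) -> EmbryoLineage:
    """Simulate one tracked embryo of ``group``.

    Deterministic given (config, group, seed).  The recording covers the
    2-cell stage to ``target_cells`` (or ``truncation_cells`` for truncated
    recordings).
    """
    config.validate()
    if group not in config.n_embryos and group not in config.ab_size:
        raise KeyError(f"group {group!r} unknown to the simulation config")
    rng = np.random.default_rng(seed)
    pert = config.perturbations

    mean, sd = config.ab_size[group]
    ab_size = float(np.clip(rng.normal(mean, sd), 30.5, 69.5))
    if group == "inverted":
        ab_size = min(ab_size, 47.9)

    cmean, csd = config.compression.get(group, (config.reference_height_um, 0.0))
    compression = float(np.clip(rng.normal(cmean, csd), 12.0, 30.0))

    dead_signature = group in DEAD_SIGNATURE_GROUPS
    # signature draws (consume the stream in a fixed order for determinism)
    u_p4, u_ems, u_inv = rng.uniform(size=3)
    ms_skew_draw = rng.normal(0.0, 1.0)
    ems_angle = rng.uniform(40.0, 60.0) * (1 if rng.uniform() < 0.5 else -1)
    truncated = rng.uniform() < config.truncation_fraction

    extra_p4 = dead_signature and u_p4 < pert.extra_p4_division_prob
    ems_prob = (
        pert.ems_skew_prob_inverted if group == "inverted" else pert.ems_skew_prob
    )
    ems_skew = dead_signature and u_ems < ems_prob
    ms_inversion = dead_signature and u_inv < pert.msap_inversion_prob
    ms_skew_deg = ms_skew_draw * pert.ms_angle_skew_deg_sd if dead_signature else 0.0

    birth, division = _schedule_divisions(config, ab_size, dead_signature, extra_p4, rng)

    # recording horizon: time at which the live count reaches the target
    n_target = config.truncation_cells if truncated else config.target_cells
    div_times = np.sort([t for c, t in division.items() if c in birth])
    live_after = 2 + np.arange(1, div_times.size + 1)
    reach = div_times[live_after >= n_target]
    t_end = float(reach[0]) if reach.size else float(div_times[-1])
    if extra_p4 and "Z2" in division and not truncated:
        # ectopic germline divisions must fall inside the recording
        t_end = max(t_end, division["Z2"])
    dt = config.frame_interval_min
    n_frames = min(config.max_frames, int(math.ceil(t_end / dt)) + 2)

    # eggshell, flattened along D-V by compression
    a, b, c = config.eggshell_half_axes
    squeeze = max(
        0.5, 1.0 - pert.compression_dv_per_um * max(
            0.0, config.reference_height_um - compression
        )
    )
    half_axes = np.array([a / math.sqrt(squeeze), b * squeeze, c])

    egg_volume = 4.0 / 3.0 * math.pi * float(np.prod(half_axes))
    total_cell_volume = config.cell_volume_fraction * egg_volume
    if config.cell_volume_fraction > 0.9:
        raise GeometryError("eggshell too small for the configured cell volume")

    # per-cell volumes from lineage splits
    volume: dict[str, float] = {
        "AB": total_cell_volume * ab_size / 100.0,
        "P1": total_cell_volume * (1.0 - ab_size / 100.0),
    }

    def vol(cell: str) -> float:
        if cell in volume:
            return volume[cell]
        parent = naming.parent_of(cell)
        pv = vol(parent)
        split = _VOLUME_SPLITS.get(parent, (0.5, 0.5))
        pair = _daughter_names(parent)
        frac = split[0] if cell == pair[0] else split[1]
        volume[cell] = pv * frac
        return volume[cell]

    def radius(cell: str) -> float:
        return (3.0 * vol(cell) / (4.0 * math.pi)) ** (1.0 / 3.0)

    if 2.0 * (radius("AB") + radius("P1")) > 2.0 * half_axes[0] * 1.05:
        raise GeometryError("eggshell too small to contain the 2-cell stage")

    # per-embryo effective division axes (planted skews / inversion)
    axis_cache: dict[str, np.ndarray] = {}

    def division_axis(cell: str) -> np.ndarray:
        if cell in axis_cache:
            return axis_cache[cell]
        v = canonical_division_axis(cell)
        if cell == "EMS" and ems_skew:
            v = _rotate_about(v, np.array([0.0, 1.0, 0.0]), ems_angle)
        if cell == "MS":
            if ms_skew_deg:
                v = _rotate_about(v, np.array([0.0, 1.0, 0.0]), ms_skew_deg)
            if ms_inversion:
                v = -v
        axis_cache[cell] = v / np.linalg.norm(v)
        return axis_cache[cell]

    # forward simulation over frames
    r_ab, r_p1 = radius("AB"), radius("P1")
    state_pos: dict[str, np.ndarray] = {
        "AB": np.array([-(half_axes[0] - r_ab * 1.05), 0.0, 0.0]),
        "P1": np.array([half_axes[0] - r_p1 * 1.05, 0.0, 0.0]),
    }
    alive = {"AB", "P1"}
    events = sorted(
        ((t, cell) for cell, t in division.items()), key=lambda e: (e[0], e[1])
    )
    ev_i = 0
    observations: dict[str, list[NucleusObservation]] = {}

    ca_factor = pert.ca_netdis_inflation if dead_signature else 1.0
    abar_bias = (
        np.array([0.0, -pert.abar_progeny_dv_shift_um, 0.0])
        if dead_signature
        else np.zeros(3)
    )

    for f in range(1, n_frames + 1):
        t_f = (f - 1) * dt
        born_pairs: list[tuple[str, str, np.ndarray]] = []
        while ev_i < len(events) and events[ev_i][0] <= t_f:
            t_div, cell = events[ev_i]
            ev_i += 1
            if cell not in alive:
                continue
            d1, d2 = _daughter_names(cell)
            v = division_axis(cell)
            sep = 0.85 * (radius(d1) + radius(d2))
            p = state_pos.pop(cell)
            alive.discard(cell)
            jitter = rng.normal(0.0, 0.3 * config.motion_sd_um, size=(2, 3))
            state_pos[d1] = p + v * sep / 2.0 + jitter[0]
            state_pos[d2] = p - v * sep / 2.0 + jitter[1]
            alive.update((d1, d2))
            born_pairs.append((d1, d2, v))

        names = sorted(alive)
        pos = np.array([state_pos[n] for n in names])
        radii = np.array([radius(n) for n in names])
        if config.motion_sd_um > 0:
            steps = rng.normal(0.0, config.motion_sd_um, size=pos.shape)
            for i, n in enumerate(names):
                if n == "Ca":
                    steps[i] *= ca_factor
            pos = pos + steps
        else:
            rng.normal(0.0, 1.0, size=pos.shape)  # keep stream aligned
        pos = _relax(pos, radii, half_axes, config.relaxation_iterations)
        for i, n in enumerate(names):
            state_pos[n] = pos[i]
        # at their birth frame, sister pairs keep the spindle-dictated
        # direction: relaxation sets the midpoint and separation, not the axis
        for d1, d2, v in born_pairs:
            mid = (state_pos[d1] + state_pos[d2]) / 2.0
            s = float(np.linalg.norm(state_pos[d1] - state_pos[d2]))
            for n, sign in ((d1, 1.0), (d2, -1.0)):
                p = mid + sign * v * s / 2.0
                eff = np.clip(half_axes - radius(n), 0.5, None)
                nrm = float(np.linalg.norm(p / eff))
                state_pos[n] = p / nrm if nrm > 1.0 else p
        if born_pairs:
            pos = np.array([state_pos[n] for n in names])

        noise = (
            rng.normal(0.0, config.positional_noise_um, size=pos.shape)
            if config.positional_noise_um > 0
            else np.zeros_like(pos)
        )
        if config.positional_noise_um == 0:
            rng.normal(0.0, 1.0, size=pos.shape)  # keep stream aligned
        for i, n in enumerate(names):
            obs_pos = pos[i] + noise[i]
            if n.startswith("ABar"):
                obs_pos = obs_pos + abar_bias
            observations.setdefault(n, []).append(
                NucleusObservation(
                    cell_name=n,
                    frame=f,
                    time_min=t_f,
                    x=float(obs_pos[0]),
                    y=float(obs_pos[1]),
                    z=float(obs_pos[2]),
                    diameter=2.0 * float(radius(n)),
                )
            )

    tracks: dict[str, CellTrack] = {}
    for n, obs in observations.items():
        parent = naming.parent_of(n)
        tracks[n] = CellTrack(
            cell_name=n,
            observations=obs,
            parent_name=parent if parent in observations else None,
        )
    for n, t in tracks.items():
        if n in division:
            pair = _daughter_names(n)
            if all(d in tracks for d in pair):
                t.daughter_names = pair

    outcome = "dead" if group in DEAD_SIGNATURE_GROUPS else "alive"
    meta = EmbryoMetadata(
        group=group,
        relative_AB_size=ab_size,
        compression_um=compression,
        frame_interval_min=dt,
        outcome=outcome,
    )
    emb = EmbryoLineage(
        embryo_id=embryo_id or f"{group}_sim",
        tracks=tracks,
        metadata=meta,
    )
    emb.validate()
    return emb


def simulate_cohort(
    config: SimulationConfig, out_dir=None
) -> tuple[list[EmbryoLineage], pd.DataFrame]:
    """Simulate all groups; optionally write native TSVs, metadata, truth."""
    config.validate()
    embryos: list[EmbryoLineage] = []
    for gi, group in enumerate(sorted(config.n_embryos)):
        for i in range(config.n_embryos[group]):
            seed = np.random.SeedSequence([config.seed, gi, i])
            eid = f"{group}_{i + 1:03d}"
            embryos.append(simulate_embryo(config, group, seed, embryo_id=eid))
    metadata = {e.embryo_id: e.metadata for e in embryos}
    meta_df = pd.DataFrame(
        [
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
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        lineage_dir = os.path.join(out_dir, "lineages")
        os.makedirs(lineage_dir, exist_ok=True)
        for e in embryos:
            write_native(e, os.path.join(lineage_dir, f"{e.embryo_id}.tsv"))
        write_metadata(metadata, os.path.join(out_dir, "metadata.csv"))
        truth = planted_truth(config)
        truth.to_json(
            os.path.join(out_dir, "truth.json"), orient="records", indent=2
        )
    return embryos, meta_df


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table of planted (cell, feature) group differences."""
    pert = config.perturbations
    rows: list[dict] = []

    def add(cell, feature, comparison, effect, note):
        rows.append(
            {
                "cell": cell,
                "feature": feature,
                "comparison": comparison,
                "effect": effect,
                "note": note,
            }
        )

    if pert.abar_progeny_dv_shift_um:
        abar_desc = [
            c
            for s in naming.STAGES
            for c in naming.STAGE_COHORTS[s]
            if c.startswith("ABar")
        ]
        for cell in sorted(abar_desc):
            add(
                cell,
                "pDV",
                "dead_vs_alive",
                -pert.abar_progeny_dv_shift_um,
                "dorsal shift of ABar progeny",
            )
            add(cell, "pOV", "dead_vs_alive", pert.abar_progeny_dv_shift_um,
                "positional deviation from the dorsal shift")
    if pert.ca_netdis_inflation and pert.ca_netdis_inflation != 1.0:
        add("Ca", "netdis", "dead_vs_alive", pert.ca_netdis_inflation,
            "inflated Ca random motion")
        add("Ca", "totdis", "dead_vs_alive", pert.ca_netdis_inflation,
            "inflated Ca random motion")
    if pert.ms_angle_skew_deg_sd or pert.msap_inversion_prob:
        add("MS", "aMean", "dead_vs_alive", pert.ms_angle_skew_deg_sd,
            "MS division-angle skew / inversion")
    if pert.ems_skew_prob:
        add("EMS", "aMean", "dead_vs_alive", pert.ems_skew_prob,
            "EMS spindle skew (probabilistic)")
    if pert.extra_p4_division_prob:
        add("P4", "extra_divisions", "dead_vs_alive",
            pert.extra_p4_division_prob, "ectopic germline divisions")
    if pert.p1_clock_scaling:
        for cell in ("EMS", "P2", "MS", "E", "C", "P3", "D", "P4"):
            add(cell, "LifeTime", "equalized_vs_control",
                -pert.p1_clock_scaling, "P1-lineage cell-cycle shortening per % AB")
    return pd.DataFrame(rows, columns=["cell", "feature", "comparison", "effect", "note"])


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "perturbations" in d and isinstance(d["perturbations"], dict):
        d["perturbations"] = PerturbationConfig(**d["perturbations"])
    if "eggshell_half_axes" in d:
        d["eggshell_half_axes"] = tuple(d["eggshell_half_axes"])
    if "ab_size" in d:
        d["ab_size"] = {k: tuple(v) for k, v in d["ab_size"].items()}
    if "compression" in d:
        d["compression"] = {k: tuple(v) for k, v in d["compression"].items()}
    if "clock_table" in d:
        d["clock_table"] = {k: tuple(v) for k, v in d["clock_table"].items()}
    return SimulationConfig(**d)


def hash_config(config: SimulationConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
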
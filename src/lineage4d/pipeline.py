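"""One-command reproduction harness: simulate → align → extract → stats →
classify, with deterministic seeding, a provenance manifest, and an opt-in
validation hook for externally downloaded lineage deposits."""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import naming
from .alignment import ReferenceModel, build_reference
from .classify import LassoConfig, stage_report
from .errors import ConfigurationError
from .features import build_feature_table, phenotype_flags
from .groupstats import (
    ScreenConfig,
    bin_lethality,
    permutation_fdr_alpha,
    size_correlation,
    variability_stats,
)
from .lineage_io import EmbryoLineage, read_metadata, read_native
from .simulate import SimulationConfig, config_to_dict, hash_config, simulate_cohort

log = logging.getLogger(__name__)


def substream(seed: int, name: str) -> int:
    """Named, deterministic sub-seed below 2**31 derived from a root seed."""
    return int((seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_run"
    seed: int = 0
    stages: tuple[int, ...] = (4, 8, 15, 28)
    screen_stage: int = 15
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the full synthetic pipeline; returns the run directory.

    Outputs: lineages/, metadata.csv, truth.json, reference.json,
    features_stage{K}.csv, screen.csv, screen.json, result.json,
    inclusion_stage{K}.csv, absize.csv, summary.json, manifest.json.
    Rerunning with the same config reproduces identical numerical outputs
    (the manifest's wall-clock timings aside).
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        config.sim.seed = substream(config.seed, "simulate")
        embryos, meta = simulate_cohort(config.sim, out_dir=out)
        meta = meta.set_index("embryo_id")
        timings[stage] = time.perf_counter() - t0

        stage = "align"
        t0 = time.perf_counter()
        controls = [e for e in embryos if e.metadata.group == "control"]
        reference = build_reference(controls)
        reference.to_json(os.path.join(out, "reference.json"))
        timings[stage] = time.perf_counter() - t0

        stage = "extract"
        t0 = time.perf_counter()
        full_table = build_feature_table(embryos, reference, stage="all")
        stage_tables: dict[int, pd.DataFrame] = {}
        for k in config.stages:
            cells = naming.cumulative_cohort(k)
            cols = [c for c in full_table.columns if c.rsplit(".", 1)[0] in cells]
            tbl = full_table[cols]
            tbl.to_csv(os.path.join(out, f"features_stage{k}.csv"))
            stage_tables[k] = tbl
        flags = {
            e.embryo_id: asdict(phenotype_flags(e, reference)) for e in embryos
        }
        flag_df = pd.DataFrame.from_dict(flags, orient="index")
        flag_df.index.name = "embryo_id"
        flag_df.to_csv(os.path.join(out, "phenotype_flags.csv"))
        timings[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        screen_tbl = stage_tables[config.screen_stage]
        eq = meta[meta["group"].isin(["equalized_alive", "equalized_dead"])]
        config.screen.seed = substream(config.seed, "shuffles")
        alpha_star, screen = permutation_fdr_alpha(
            screen_tbl.loc[screen_tbl.index.intersection(eq.index)],
            eq["group"],
            config.screen,
            group_a="equalized_dead",
            group_b="equalized_alive",
        )
        screen.table.to_csv(os.path.join(out, "screen.csv"), index=False)
        _json_dump(
            {
                "alpha_star": alpha_star,
                "n_passing": int(screen.table["passes"].sum()),
                "passing_features": screen.passing_features,
                "alpha_table": screen.alpha_table.round(6).to_dict(orient="records"),
            },
            os.path.join(out, "screen.json"),
        )
        bins = bin_lethality(meta)
        bins.to_csv(os.path.join(out, "absize.csv"), index=False)
        asyn = pd.Series(
            {eid: f.get("ab_p1_asynchrony_min") for eid, f in flags.items()},
            dtype=float,
        )
        upshifted = meta[meta["group"].str.startswith(("equalized", "inverted"))]
        r, p_r, n_r = size_correlation(upshifted, asyn)
        lifetime_cols = [
            c for c in stage_tables[max(config.stages)].columns if c.endswith(".LifeTime")
        ]
        var_df = variability_stats(
            stage_tables[max(config.stages)][lifetime_cols], meta["group"]
        )
        var_df.to_csv(os.path.join(out, "variability.csv"), index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        config.lasso.seed = substream(config.seed, "folds")
        # as in the study design, embryos with a 4-cell T-arrangement or an
        # EMS skew are excluded from outcome prediction
        excluded = {
            eid
            for eid, f in flags.items()
            if f.get("t_arrangement") or f.get("ems_skew")
        }
        keep = [i for i in eq.index if i not in excluded]
        eq_tables = {
            k: tbl.loc[tbl.index.intersection(keep)]
            for k, tbl in stage_tables.items()
        }
        report = stage_report(eq_tables, eq["outcome"], config.lasso)
        for k, rep in report.items():
            res = rep.pop("_result")
            res.inclusion_frequency.sort_values(ascending=False).to_csv(
                os.path.join(out, f"inclusion_stage{k}.csv"),
                header=["inclusion_frequency"],
            )
        _json_dump(report, os.path.join(out, "result.json"))
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": config.seed,
        "n_embryos": int(len(embryos)),
        "groups": meta["group"].value_counts().sort_index().to_dict(),
        "screen": {"alpha_star": alpha_star, "n_passing": int(screen.table["passes"].sum())},
        "asynchrony_vs_ab_size": {"pearson_r": round(r, 6), "p": float(p_r), "n": n_r},
        "lasso_accuracy_by_stage": {
            str(k): report[k]["lasso"]["accuracy_mean"] for k in report
        },
    }
    _json_dump(summary, os.path.join(out, "summary.json"))
    _json_dump(
        {
            "seed": config.seed,
            "config_hash": hash_config(config.sim),
            "config": {
                "sim": config_to_dict(config.sim),
                "screen": asdict(config.screen),
                "lasso": asdict(config.lasso),
                "stages": list(config.stages),
            },
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        },
        os.path.join(out, "manifest.json"),
    )
    return out


def collect_lineages(cohort_dir: str) -> list[EmbryoLineage]:
    """Load a simulated (or converted) cohort: lineages/*.tsv + metadata.csv."""
    metadata = read_metadata(os.path.join(cohort_dir, "metadata.csv"))
    lineage_dir = os.path.join(cohort_dir, "lineages")
    embryos: list[EmbryoLineage] = []
    for fn in sorted(os.listdir(lineage_dir)):
        if fn.endswith(".tsv"):
            embryos.extend(read_native(os.path.join(lineage_dir, fn), metadata))
    return embryos


def extract_from_files(
    lineage_paths: list[str],
    reference_path: str,
    stage: int | str = "all",
) -> pd.DataFrame:
    """Extract a feature table from native lineage files on disk."""
    if not os.path.exists(reference_path):
        raise ConfigurationError(f"missing reference model: {reference_path}")
    reference = ReferenceModel.from_json(reference_path)
    embryos: list[EmbryoLineage] = []
    for p in lineage_paths:
        embryos.extend(read_native(p))
    return build_feature_table(embryos, reference, stage=stage)


def validate_against_deposit(deposit_path: str | None, out_dir: str | None = None) -> dict:
    """Recompute headline statistics from a downloaded lineage deposit.

    The deposit is never fetched automatically; when absent the validation
    is skipped with a clean status.  Expected layout: native lineage TSVs
    (or AceTree nuclei exports converted beforehand) plus a metadata.csv.
    """
    if not deposit_path or not os.path.exists(deposit_path):
        return {"status": "skipped: external data not provided"}
    meta_path = os.path.join(deposit_path, "metadata.csv")
    if not os.path.exists(meta_path):
        return {
            "status": "error: deposit layout not recognized "
            "(expected metadata.csv next to lineage files)"
        }
    metadata = read_metadata(meta_path)
    embryos = []
    lineage_dir = os.path.join(deposit_path, "lineages")
    src = lineage_dir if os.path.isdir(lineage_dir) else deposit_path
    for fn in sorted(os.listdir(src)):
        if fn.endswith((".tsv", ".csv")) and fn != "metadata.csv":
            embryos.extend(read_native(os.path.join(src, fn), metadata))
    if not embryos:
        return {"status": "error: no lineage files found in deposit"}
    report: dict = {"status": "ok", "n_embryos": len(embryos)}
    controls = [e for e in embryos if e.metadata.group == "control"]
    if len(controls) >= 2:
        reference = build_reference(controls)
        table = build_feature_table(embryos, reference, stage=28)
        groups = pd.Series({e.embryo_id: e.metadata.group for e in embryos})
        lifetime_cols = [c for c in table.columns if c.endswith(".LifeTime")]
        var_df = variability_stats(table[lifetime_cols], groups)
        report["cv_cell_cycle_by_group_pct"] = {
            g: round(float(sub["cv"].mean() * 100), 2)
            for g, sub in var_df.groupby("group")
        }
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            reference.to_json(os.path.join(out_dir, "reference.json"))
            table.to_csv(os.path.join(out_dir, "features_stage28.csv"))
    else:
        report["note"] = "reference skipped: fewer than 2 control embryos"
    meta_df = pd.DataFrame(
        {
            "relative_AB_size": {
                e.embryo_id: e.metadata.relative_AB_size for e in embryos
            },
            "outcome": {e.embryo_id: e.metadata.outcome for e in embryos},
        }
    )
    if meta_df["relative_AB_size"].notna().sum() >= 3:
        report["lethality_by_ab_size_bin"] = bin_lethality(meta_df).to_dict(
            orient="records"
        )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        _json_dump(report, os.path.join(out_dir, "validation.json"))
    return report


def manifest_hash(path: str) -> str:
    """Stable content hash of a run output file (for provenance checks)."""
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
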
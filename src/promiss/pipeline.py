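"""End-to-end orchestration: threshold -> profile -> correlate -> outliers ->
LOD -> batch -> ML, with a manifest and a one-page summary.

Missingness profiles are always computed before any zero-imputation; the
stage order is fixed and recorded in the manifest.  All randomness flows
from the single top-level seed through derived substreams (one for the
simulator, one for the ML stage), so a run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assessments import batch_sensitivity, batch_summary, lod_assessment
from .core_data import (
    QuantMatrix,
    SampleMetadata,
    ValidationError,
    align,
    read_metadata,
    read_quant_matrix,
    write_metadata,
    write_quant_matrix,
)
from .correlation import (
    BandSpec,
    all_outlier_reports,
    correlate_axis,
    correlations_frame,
    cross_axis_screen,
)
from .ml import FeatureSelectionSpec, run_confirmation
from .profiles import ThresholdSpec, apply_threshold, missingness_histogram, profile
from .synthetic import SimulationConfig, simulate

__all__ = ["PipelineConfig", "StageError", "run_all", "summarize"]

logger = logging.getLogger("promiss")


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("promiss")
    except PackageNotFoundError:
        return "unknown"

#: fixed stage order; profiling strictly precedes the (ML-only) zero-imputation
STAGES = (
    "load",
    "threshold",
    "profile",
    "correlate",
    "outliers",
    "screen",
    "lod",
    "batch",
    "ml",
    "summary",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full-run configuration: exactly one of (matrix+metadata paths, simulate)."""

    out_dir: Path
    matrix_path: Path | None = None
    metadata_path: Path | None = None
    simulation: SimulationConfig | None = None
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    band: BandSpec = field(default_factory=BandSpec)
    ml: FeatureSelectionSpec = field(default_factory=FeatureSelectionSpec)
    ml_timepoint: str = "baseline"
    run_ml: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        have_paths = self.matrix_path is not None or self.metadata_path is not None
        if have_paths and self.simulation is not None:
            raise ValidationError("config must give input paths or a simulate block, not both")
        if not have_paths and self.simulation is None:
            raise ValidationError("config must give input paths or a simulate block")
        if have_paths and (self.matrix_path is None or self.metadata_path is None):
            raise ValidationError("both matrix_path and metadata_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        base_dir = base_dir or Path.cwd()

        def _path(v):
            p = Path(v)
            return p if p.is_absolute() else base_dir / p

        kwargs: dict = {"out_dir": _path(raw.get("out_dir", "promiss_out"))}
        if "matrix_path" in raw:
            kwargs["matrix_path"] = _path(raw["matrix_path"])
        if "metadata_path" in raw:
            kwargs["metadata_path"] = _path(raw["metadata_path"])
        if "simulate" in raw:
            sim = dict(raw["simulate"] or {})
            for key in ("batch_allocation",):
                if key in sim:
                    sim[key] = {g: tuple(v) for g, v in sim[key].items()}
            if "low_detection_rate_range" in sim:
                sim["low_detection_rate_range"] = tuple(sim["low_detection_rate_range"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "threshold" in raw:
            kwargs["threshold"] = ThresholdSpec(**raw["threshold"])
        if "band" in raw:
            kwargs["band"] = BandSpec(**raw["band"])
        if "ml" in raw:
            kwargs["ml"] = FeatureSelectionSpec(**raw["ml"])
        for key in ("ml_timepoint", "run_ml", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        def _convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: _convert(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [_convert(v) for v in obj]
            return obj

        return _convert(dataclasses.asdict(self))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written to
    ``manifest.json``).  On stage failure, partial outputs are retained, a
    ``FAILED`` marker file names the stage, and :class:`StageError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "promiss": _pkg_version(),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_order": list(STAGES),
        "outputs": {},
    }
    ss = np.random.SeedSequence(config.seed)
    sim_seed, ml_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim_cfg = replace(config.simulation, seed=sim_seed)
            matrix, meta, truth = simulate(sim_cfg)
            write_quant_matrix(matrix, out / "matrix.tsv")
            write_metadata(meta, out / "metadata.csv")
            manifest["outputs"]["truth.tsv"] = _write_tsv(
                truth.protein_params, out / "truth.tsv"
            )
            manifest["outputs"]["matrix.tsv"] = matrix.n_proteins
            manifest["outputs"]["metadata.csv"] = meta.n_samples
        else:
            matrix = read_quant_matrix(config.matrix_path)
            meta = read_metadata(config.metadata_path)
        matrix, meta = align(matrix, meta)
        _log_stage(stage, t0, n_proteins=matrix.n_proteins, n_samples=matrix.n_samples)

        stage = "threshold"
        t0 = time.perf_counter()
        hist = missingness_histogram(matrix)
        manifest["outputs"]["missingness_histogram.tsv"] = _write_tsv(
            hist.reset_index(), out / "missingness_histogram.tsv"
        )
        filtered, removed = apply_threshold(matrix, config.threshold)
        manifest["outputs"]["removed_proteins.tsv"] = _write_tsv(
            pd.DataFrame({"protein_id": removed}), out / "removed_proteins.tsv"
        )
        manifest["n_proteins_retained"] = filtered.n_proteins
        _log_stage(stage, t0, retained=filtered.n_proteins, removed=len(removed))

        stage = "profile"
        t0 = time.perf_counter()
        profiles = pd.concat(
            [profile(filtered, meta, axis) for axis in ("timepoint", "group")],
            ignore_index=True,
        )
        manifest["outputs"]["profiles.tsv"] = _write_tsv(profiles, out / "profiles.tsv")
        _log_stage(stage, t0, rows=len(profiles))

        stage = "correlate"
        t0 = time.perf_counter()
        corr = correlations_frame(
            correlate_axis(profiles, "timepoint") + correlate_axis(profiles, "group")
        )
        corr.insert(0, "axis", ["timepoint"] * 3 + ["group"] * 3)
        manifest["outputs"]["correlations.tsv"] = _write_tsv(corr, out / "correlations.tsv")
        _log_stage(stage, t0, rows=len(corr))

        stage = "outliers"
        t0 = time.perf_counter()
        rep_t = all_outlier_reports(profiles, "timepoint", config.band)
        rep_g = all_outlier_reports(profiles, "group", config.band)
        outliers = pd.concat(
            [rep_t.assign(axis="timepoint"), rep_g.assign(axis="group")], ignore_index=True
        )
        manifest["outputs"]["outliers.tsv"] = _write_tsv(outliers, out / "outliers.tsv")
        _log_stage(stage, t0, flagged=int(outliers["flagged"].sum()))

        stage = "screen"
        t0 = time.perf_counter()
        candidates = cross_axis_screen(rep_g, rep_t, profiles)
        manifest["outputs"]["candidates.tsv"] = _write_tsv(candidates, out / "candidates.tsv")
        _log_stage(stage, t0, candidates=len(candidates))

        stage = "lod"
        t0 = time.perf_counter()
        lod = lod_assessment(filtered)
        lod_df = pd.DataFrame(
            [
                {
                    "scope": lod.scope,
                    "r": lod.r,
                    "ci_low": lod.ci_low,
                    "ci_high": lod.ci_high,
                    "n_proteins": lod.n_proteins,
                }
            ]
        )
        manifest["outputs"]["lod.tsv"] = _write_tsv(lod_df, out / "lod.tsv")
        _log_stage(stage, t0, r=lod.r)

        stage = "batch"
        t0 = time.perf_counter()
        summary = batch_summary(meta)
        sens = batch_sensitivity(profiles, meta, config.band, axis="group")
        sens["batches_per_group"] = ";".join(
            f"{g}={int(n)}" for g, n in summary["batches_per_group"].items()
        )
        manifest["outputs"]["batch_overlap.tsv"] = _write_tsv(sens, out / "batch_overlap.tsv")
        _log_stage(stage, t0, schemes=len(sens))

        ml_rows = 0
        if config.run_ml:
            stage = "ml"
            t0 = time.perf_counter()
            ml_spec = replace(config.ml, seed=ml_seed)
            result, trace = run_confirmation(
                filtered, meta, ml_spec, timepoint=config.ml_timepoint
            )
            sel = pd.DataFrame(
                {
                    "protein_id": list(result.selected_proteins),
                    "importance": [result.importances[p] for p in result.selected_proteins],
                }
            )
            manifest["outputs"]["ml_selected.tsv"] = _write_tsv(sel, out / "ml_selected.tsv")
            acc = result.accuracy_by_size.rename("accuracy").rename_axis("subset_size")
            manifest["outputs"]["ml_accuracy.tsv"] = _write_tsv(
                acc.reset_index(), out / "ml_accuracy.tsv"
            )
            manifest["ml_trace"] = trace
            ml_rows = len(sel)
            _log_stage(stage, t0, selected=ml_rows)

        stage = "summary"
        t0 = time.perf_counter()
        manifest["status"] = "OK"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "summary.txt").write_text(summarize(out))
        _log_stage(stage, t0)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        manifest["status"] = f"FAILED at {stage}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    return manifest


def _log_stage(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)


def _need(out_dir: Path, name: str) -> Path:
    p = out_dir / name
    if not p.exists():
        raise ValidationError(f"report bundle is missing {name!r} in {out_dir}")
    return p


def summarize(out_dir: str | Path) -> str:
    """One-page text summary of a completed report bundle.

    Correlation lines repeat the correlations TSV verbatim values; raises a
    named error when an expected artifact is absent.
    """
    out_dir = Path(out_dir)
    manifest = json.loads(_need(out_dir, "manifest.json").read_text())
    corr = pd.read_csv(_need(out_dir, "correlations.tsv"), sep="\t")
    outliers = pd.read_csv(_need(out_dir, "outliers.tsv"), sep="\t")
    candidates = pd.read_csv(_need(out_dir, "candidates.tsv"), sep="\t")
    lod = pd.read_csv(_need(out_dir, "lod.tsv"), sep="\t").iloc[0]
    batch = pd.read_csv(_need(out_dir, "batch_overlap.tsv"), sep="\t")

    lines = [
        "promiss run summary",
        "===================",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}  "
        f"status: {manifest.get('status', '?')}",
        f"proteins retained after threshold: {manifest.get('n_proteins_retained', '?')}",
        "",
        "cross-stratum correlations of missingness magnitude (Pearson, Fisher-z 95% CI):",
    ]
    for _, row in corr.iterrows():
        lines.append(
            f"  {row['axis']:>9}  {row['stratum_a']:>8} vs {row['stratum_b']:<8} "
            f"r={row['r']:.3f}  CI=({row['ci_low']:.3f}, {row['ci_high']:.3f})  n={row['n']}"
        )
    flagged = outliers[outliers["flagged"]]
    lines += [
        "",
        f"outliers flagged: {len(flagged)} "
        f"(timepoint axis: {int((flagged['axis'] == 'timepoint').sum())}, "
        f"group axis: {int((flagged['axis'] == 'group').sum())})",
        f"candidate biomarkers (group outlier, time-stable): {len(candidates)}",
        "",
        f"LOD assessment: r={lod['r']:.3f} CI=({lod['ci_low']:.3f}, {lod['ci_high']:.3f}) "
        f"over {int(lod['n_proteins'])} proteins"
        if pd.notna(lod["r"])
        else "LOD assessment: undefined (no missingness variation)",
        f"batch-adjustment outlier overlap (Jaccard vs unadjusted): "
        f"min={batch['jaccard_vs_unadjusted'].min():.2f} over {len(batch)} schemes",
    ]
    if "ml_selected.tsv" in manifest.get("outputs", {}):
        sel = pd.read_csv(_need(out_dir, "ml_selected.tsv"), sep="\t")
        acc = pd.read_csv(_need(out_dir, "ml_accuracy.tsv"), sep="\t")
        lines += [
            "",
            f"ML confirmation: {len(sel)} proteins selected; "
            f"best CV accuracy {acc['accuracy'].max():.3f}",
            "  top proteins: " + ", ".join(sel["protein_id"].head(5)),
        ]
    if len(candidates) == 0:
        lines.append("")
        lines.append("zero candidate proteins passed the cross-axis screen")
    return "\n".join(lines) + "\n"
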
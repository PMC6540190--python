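"""End-to-end orchestration: scenes -> masks -> aligned thermal pixels -> CT
-> merged plant records -> factorial statistics.

A run is driven by a single :class:`RunConfig` (usually loaded from YAML).
For every scene in the fixture manifest the stages are: CIELAB conversion,
mean-shift chroma clustering, plant-cluster selection, border erosion,
homography estimation from that scene's correspondence file, mask warping
into the thermal grid, greybody correction, pixel extraction, and the CT
summary. Canopy temperatures are merged into the plant-record table, the
drought-induced CT increase is computed per genotype (with Tukey letters on
the replicate-level increases), and each configured response gets the full
factorial analysis plus a Pearson correlation report. Every artifact is
written under the output directory and listed in a run manifest together
with the config hash and seed; a failing scene is reported and skipped, not
fatal.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import alignment, segmentation, stats, thermal
from .synthetic import read_fixture_set
from .thermal import CanopySample, ThermalImage, ThermalMeta

__all__ = [
    "SegmentationParams", "ThermalParams", "StatsParams",
    "RunConfig", "RunReport", "run", "extract_scene_pixels",
]

logger = logging.getLogger(__name__)

_DEFAULT_RESPONSES = [
    "CT", "A", "gs", "E", "Ci", "iWUE", "LRWC", "SWC", "DWC",
    "Fo", "Fm", "FvFm", "CCI", "AGB", "GY",
]
_DEFAULT_CORR_VARS = ["E", "Ci", "iWUE", "LRWC", "DWC", "SWC", "AGB", "GY", "CT"]


@dataclass
class SegmentationParams:
    bandwidth: float | str = "auto"
    subsample: int = 1000
    quantile: float = 0.2
    a_threshold: float = 0.0
    erode_radius: int = 1
    erode_iterations: int = 1


@dataclass
class ThermalParams:
    emissivity: float = 0.98
    reflected_temp_c: float = 20.0
    already_corrected: bool = False
    #: prefer the per-scene emissivity recorded in the fixture manifest
    emissivity_from_manifest: bool = True
    bin_width_c: float = 0.5

    def __post_init__(self):
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")


@dataclass
class StatsParams:
    alpha: float = 0.05
    responses: list[str] = field(default_factory=lambda: list(_DEFAULT_RESPONSES))
    correlation_variables: list[str] = field(default_factory=lambda: list(_DEFAULT_CORR_VARS))


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    fixture_dir: str
    output_dir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        return cls(
            fixture_dir=paths.get("fixture_dir", raw.get("fixture_dir", "")),
            output_dir=paths.get("output_dir", raw.get("output_dir", "")),
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            thermal=ThermalParams(**raw.get("thermal", {})),
            stats=StatsParams(**raw.get("stats", {})),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "paths": {"fixture_dir": str(self.fixture_dir), "output_dir": str(self.output_dir)},
            "segmentation": asdict(self.segmentation),
            "thermal": asdict(self.thermal),
            "stats": asdict(self.stats),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def validate(self) -> None:
        fdir = Path(self.fixture_dir)
        if not (fdir / "manifest.yaml").exists():
            raise FileNotFoundError(f"no manifest.yaml under fixture_dir {fdir}")


@dataclass
class RunReport:
    """Everything a pipeline run produced."""

    config: RunConfig
    config_hash: str
    samples: list[CanopySample]
    ct_table: pd.DataFrame
    records: pd.DataFrame
    delta_ct_table: pd.DataFrame
    delta_ct_replicates: pd.DataFrame
    delta_ct_letters: dict[str, str]
    analyses: dict[str, stats.AnalysisResult]
    correlations: stats.CorrelationReport | None
    failures: list[dict]
    output_files: list[str]

    @property
    def n_scenes_ok(self) -> int:
        return len(self.samples)

    def summary(self) -> str:
        lines = [
            f"Pipeline run {self.config_hash}: {self.n_scenes_ok} scenes processed, "
            f"{len(self.failures)} failed",
            "",
            "deltaCT per genotype (degC, drought minus control mean):",
            self.delta_ct_table.to_string(index=False),
            f"letters: {self.delta_ct_letters}",
        ]
        if self.failures:
            lines.append("")
            lines.append("failures:")
            for f in self.failures:
                lines.append(f"  {f['scene_id']} at {f['stage']}: {f['error']}")
        return "\n".join(lines)


class _StageError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        super().__init__(f"{stage}: {error}")
        self.stage = stage
        self.error = error


def extract_scene_pixels(
    rgb: np.ndarray,
    temps: np.ndarray,
    correspondences: alignment.PointCorrespondences,
    seg: SegmentationParams,
    therm: ThermalParams,
    seed: int = 0,
    emissivity: float | None = None,
    reflected_temp_c: float | None = None,
) -> np.ndarray:
    """Segmentation -> alignment -> masking -> correction for one scene.

    The in-memory core of a pipeline run: returns the corrected canopy pixel
    temperatures of one visible/thermal pair. ``emissivity`` and
    ``reflected_temp_c`` override the config values (used when a fixture
    manifest records the true acquisition settings).
    """
    stage = "segmentation"
    try:
        lab = segmentation.rgb_to_lab(rgb)
        labels = segmentation.mean_shift_ab(
            lab,
            bandwidth=seg.bandwidth,
            subsample=seg.subsample,
            seed=seed,
            quantile=seg.quantile,
        )
        mask = segmentation.select_plant_mask(labels, a_threshold=seg.a_threshold)
        mask = segmentation.erode_mask(mask, seg.erode_radius, seg.erode_iterations)

        stage = "alignment"
        H, _residuals = alignment.estimate_homography(correspondences)
        mask_th = alignment.warp_mask(mask, H, temps.shape)

        stage = "thermal"
        eps = therm.emissivity if emissivity is None else emissivity
        refl = therm.reflected_temp_c if reflected_temp_c is None else reflected_temp_c
        img = ThermalImage(
            temps_c=temps, meta=ThermalMeta(emissivity_setting=eps, reflected_temp_c=refl)
        )
        if not therm.already_corrected:
            img = thermal.greybody_correct(img, eps, refl)
        return thermal.extract_canopy_pixels(img, mask_th)
    except _StageError:
        raise
    except Exception as exc:
        raise _StageError(stage, exc) from exc


def _process_scene(entry: dict, fdir: Path, cfg: RunConfig) -> CanopySample:
    """Run one on-disk scene through segmentation, alignment, and extraction."""
    stage = "load"
    try:
        rgb = np.asarray(Image.open(fdir / entry["files"]["rgb"]).convert("RGB"))
        temps = tifffile.imread(fdir / entry["files"]["thermal"]).astype(float)
        corr = alignment.read_correspondences(fdir / entry["files"]["correspondences"])

        if cfg.thermal.emissivity_from_manifest and "emissivity" in entry:
            eps = float(entry["emissivity"])
            refl = float(entry.get("reflected_temp_c", cfg.thermal.reflected_temp_c))
        else:
            eps, refl = None, None
        pixels = extract_scene_pixels(
            rgb, temps, corr, cfg.segmentation, cfg.thermal, seed=cfg.seed,
            emissivity=eps, reflected_temp_c=refl,
        )
        stage = "summary"
        return CanopySample.from_pixels(
            entry["genotype"], entry["treatment"], entry["replicate"], pixels
        )
    except _StageError:
        raise
    except Exception as exc:
        raise _StageError(stage, exc) from exc


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``."""
    config.validate()
    fdir = Path(config.fixture_dir)
    odir = Path(config.output_dir)
    odir.mkdir(parents=True, exist_ok=True)
    manifest, records = read_fixture_set(fdir)

    samples: list[CanopySample] = []
    ct_rows: list[dict] = []
    failures: list[dict] = []
    for entry in manifest["scenes"]:
        t0 = time.perf_counter()
        try:
            sample = _process_scene(entry, fdir, config)
        except _StageError as exc:
            logger.error("scene %s failed at %s: %s", entry["scene_id"], exc.stage, exc.error)
            failures.append(
                {"scene_id": entry["scene_id"], "stage": exc.stage, "error": str(exc.error)}
            )
            continue
        samples.append(sample)
        ct_rows.append(
            {
                "scene_id": entry["scene_id"],
                "genotype": sample.genotype,
                "treatment": sample.treatment,
                "replicate": sample.replicate,
                "CT": sample.ct_mean_c,
                "ct_median_c": sample.summary.median_c,
                "ct_p5_c": sample.summary.p5_c,
                "ct_p95_c": sample.summary.p95_c,
                "n_pixels": sample.summary.n_pixels,
            }
        )
        logger.info(
            "scene %s: CT=%.2f degC from %d pixels (%.2fs)",
            entry["scene_id"], sample.ct_mean_c, sample.summary.n_pixels,
            time.perf_counter() - t0,
        )
    if not ct_rows:
        raise RuntimeError("every scene failed; nothing to analyze")
    ct_table = pd.DataFrame(ct_rows)

    if "CT" in records.columns:
        records = records.drop(columns=["CT"])
    merge_key = "scene_id" if "scene_id" in records.columns else None
    if merge_key:
        records = records.merge(ct_table[["scene_id", "CT"]], on="scene_id", how="left")
    else:
        records = records.merge(
            ct_table[["genotype", "treatment", "replicate", "CT"]],
            on=["genotype", "treatment", "replicate"],
            how="left",
        )

    # deltaCT per genotype and Tukey letters on replicate-level increases
    delta_rows = []
    rep_tables = []
    deltas_by_genotype: dict[str, np.ndarray] = {}
    for genotype, sub in ct_table.groupby("genotype", sort=False):
        drought = sub.loc[sub["treatment"] == "drought", "CT"].to_numpy()
        control = sub.loc[sub["treatment"] == "control", "CT"].to_numpy()
        if len(drought) == 0 or len(control) == 0:
            logger.warning("genotype %s lacks a treatment arm; deltaCT skipped", genotype)
            continue
        d, table = thermal.delta_ct(drought, control)
        table.insert(0, "genotype", genotype)
        rep_tables.append(table)
        deltas_by_genotype[genotype] = table["delta_ct_c"].to_numpy()
        delta_rows.append({"genotype": genotype, "delta_ct_c": d, "n_drought": len(drought)})
    delta_ct_table = pd.DataFrame(delta_rows)
    delta_ct_replicates = pd.concat(rep_tables, ignore_index=True)
    if len(deltas_by_genotype) >= 2 and all(len(v) >= 2 for v in deltas_by_genotype.values()):
        _, _, delta_letters = stats.oneway_tukey(deltas_by_genotype, config.stats.alpha)
    else:
        delta_letters = {}

    analyses: dict[str, stats.AnalysisResult] = {}
    for response in config.stats.responses:
        if response not in records.columns:
            continue
        try:
            analyses[response] = stats.factorial_analysis(records, response, config.stats.alpha)
        except ValueError as exc:
            logger.warning("factorial analysis of %s skipped: %s", response, exc)

    corr_vars = [v for v in config.stats.correlation_variables if v in records.columns]
    correlations = stats.pearson_report(records, corr_vars) if len(corr_vars) >= 2 else None

    output_files = _write_outputs(
        odir, config, ct_table, records, delta_ct_table, delta_ct_replicates,
        delta_letters, analyses, correlations, failures,
    )
    return RunReport(
        config=config,
        config_hash=config.config_hash(),
        samples=samples,
        ct_table=ct_table,
        records=records,
        delta_ct_table=delta_ct_table,
        delta_ct_replicates=delta_ct_replicates,
        delta_ct_letters=delta_letters,
        analyses=analyses,
        correlations=correlations,
        failures=failures,
        output_files=output_files,
    )


def _write_outputs(
    odir: Path, config: RunConfig, ct_table, records, delta_ct_table,
    delta_ct_replicates, delta_letters, analyses, correlations, failures,
) -> list[str]:
    files: list[str] = []

    def _save_csv(df: pd.DataFrame, name: str):
        df.to_csv(odir / name, index=False)
        files.append(name)

    _save_csv(ct_table, "ct_table.csv")
    _save_csv(records, "records_with_ct.csv")
    _save_csv(delta_ct_table, "delta_ct.csv")
    _save_csv(delta_ct_replicates, "delta_ct_replicates.csv")
    pd.DataFrame(
        [{"genotype": g, "letters": s} for g, s in delta_letters.items()]
    ).to_csv(odir / "delta_ct_letters.csv", index=False)
    files.append("delta_ct_letters.csv")

    report_lines = []
    for response, res in analyses.items():
        res.anova_table.to_csv(odir / f"anova_{response}.csv")
        files.append(f"anova_{response}.csv")
        letter_rows = [
            {"family": fam, "group": g, "letters": s}
            for fam, fam_letters in res.letters.items()
            for g, s in fam_letters.items()
        ]
        pd.DataFrame(letter_rows).to_csv(odir / f"letters_{response}.csv", index=False)
        files.append(f"letters_{response}.csv")
        report_lines.append(res.summary())
        report_lines.append("")
    if correlations is not None:
        correlations.r_matrix.to_csv(odir / "correlation_r.csv")
        correlations.p_matrix.to_csv(odir / "correlation_p.csv")
        correlations.interpretation_matrix.to_csv(odir / "correlation_interpretation.csv")
        files.extend(["correlation_r.csv", "correlation_p.csv", "correlation_interpretation.csv"])
        report_lines.append(correlations.summary())
    with open(odir / "report.txt", "w") as fh:
        fh.write("\n".join(report_lines))
    files.append("report.txt")

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": sorted(files),
        "failures": failures,
    }
    with open(odir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(run_manifest, fh, sort_keys=False)
    files.append("run_manifest.yaml")
    return files
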
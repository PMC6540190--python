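"""Shared fixtures: small synthetic scenes and an in-memory experiment runner."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from canopytherm import pipeline, stats, synthetic, thermal


def small_scene_params(**overrides) -> synthetic.SceneParams:
    """A reduced-raster scene (visible 160x120, thermal 80x60) for fast tests."""
    defaults = dict(
        image_height_px=120,
        image_width_px=160,
        thermal_height_px=60,
        thermal_width_px=80,
        canopy_radius_px=25.0,
        rng_seed=0,
    )
    defaults.update(overrides)
    return synthetic.SceneParams(**defaults)


def fast_seg_params() -> pipeline.SegmentationParams:
    """Explicit bandwidth sized to the canopy/soil chroma gap (~45 a*b* units)."""
    return pipeline.SegmentationParams(bandwidth=12.0, subsample=400)


def run_experiment_in_memory(
    design: synthetic.ExperimentDesign,
    seg: pipeline.SegmentationParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image pipeline for every scene of an experiment, without touching disk.

    Returns the CT table (one row per scene with the pipeline-estimated mean
    canopy temperature) and the generated record table.
    """
    seg = seg or fast_seg_params()
    therm = pipeline.ThermalParams()
    scenes, records = synthetic.generate_experiment(design)
    rows = []
    for sc in scenes:
        corr = synthetic.correspondence_grid(sc.params)
        pixels = pipeline.extract_scene_pixels(
            sc.rgb, sc.thermal.temps_c, corr, seg, therm, seed=seed,
            emissivity=sc.params.emissivity, reflected_temp_c=sc.params.reflected_temp_c,
        )
        rows.append(
            {
                "scene_id": sc.scene_id,
                "genotype": sc.genotype,
                "treatment": sc.treatment,
                "replicate": sc.replicate,
                "CT": float(np.mean(pixels)),
                "n_pixels": len(pixels),
            }
        )
    return pd.DataFrame(rows), records


def delta_ct_letters_from_ct_table(ct_table: pd.DataFrame, alpha: float = 0.05):
    """Genotype letters on replicate-level drought-induced CT increases."""
    deltas = {}
    for genotype, sub in ct_table.groupby("genotype", sort=False):
        drought = sub.loc[sub["treatment"] == "drought", "CT"].to_numpy()
        control = sub.loc[sub["treatment"] == "control", "CT"].to_numpy()
        _, table = thermal.delta_ct(drought, control)
        deltas[genotype] = table["delta_ct_c"].to_numpy()
    _, _, letters = stats.oneway_tukey(deltas, alpha)
    return deltas, letters


@pytest.fixture(scope="session")
def small_experiment_fixture(tmp_path_factory):
    """A written-to-disk small experiment (4 genotypes x 2 treatments x 5 reps)."""
    params = small_scene_params(emissivity=0.98)
    design = synthetic.default_experiment_design(seed=11, scene_params=params)
    scenes, records = synthetic.generate_experiment(design)
    fdir = tmp_path_factory.mktemp("fixtures")
    manifest = synthetic.write_fixture_set(fdir, scenes, records)
    return {"dir": fdir, "design": design, "scenes": scenes, "records": records,
            "manifest": manifest}


@pytest.fixture(scope="session")
def small_run_report(small_experiment_fixture, tmp_path_factory):
    """One full pipeline run over the session fixture set."""
    odir = tmp_path_factory.mktemp("run_out")
    config = pipeline.RunConfig(
        fixture_dir=str(small_experiment_fixture["dir"]),
        output_dir=str(odir),
        segmentation=fast_seg_params(),
        seed=1,
    )
    return pipeline.run(config)
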
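"""Synthetic paired visible/thermal canopy scenes with known ground truth.

No raw imagery ships with this package, so every downstream stage is
exercised on generated scenes: green disk "canopies" on a warm soil
background, rendered twice — once on the visible sensor grid in sRGB with
per-channel Gaussian noise, and once on a coarser thermal grid at canopy and
background temperatures with Gaussian pixel noise. The two grids are related
by a known projective homography (the visible sensor is higher resolution
and offset, exactly the dual-sensor mismatch of a combined thermal/visible
camera), so segmentation, alignment, and extraction can each be scored
against exact truth.

An :class:`ExperimentDesign` layers the factorial structure on top: genotype
x treatment cell means for canopy temperature and for every physiological
variable, with per-variable noise, one scene and one plant record per
replicate pot. The defaults mirror a four-genotype maize drought experiment
with five replicate pots per cell in a completely randomized design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .alignment import PointCorrespondences, apply_homography, write_correspondences
from .physiology import fv_fm, iwue
from .segmentation import rgb_to_lab
from .thermal import ThermalImage, ThermalMeta, greybody_forward

__all__ = [
    "SceneParams",
    "SceneTruth",
    "SceneBundle",
    "ExperimentDesign",
    "generate_scene",
    "generate_experiment",
    "write_fixture_set",
    "read_fixture_set",
    "default_true_homography",
    "correspondence_grid",
    "default_experiment_design",
]

TREATMENTS = ("control", "drought")

#: Generated physiological variables (iWUE and FvFm are derived, not drawn).
PHYSIOLOGY_VARS = ("A", "gs", "E", "Ci", "LRWC", "SWC", "DWC", "Fo", "Fm", "CCI", "AGB", "GY")
#: Gas-exchange variables that must not increase under drought.
_GAS_EXCHANGE = ("A", "gs", "E")


def default_true_homography(
    vis_shape: tuple[int, int] = (480, 640), thermal_shape: tuple[int, int] = (240, 320)
) -> np.ndarray:
    """Visible -> thermal map: down-scaling plus a small shift and perspective.

    The scale matches the resolution ratio of the two grids; the translation
    and mild projective terms emulate the offset, unaligned optical axes.
    """
    sy = thermal_shape[0] / vis_shape[0]
    sx = thermal_shape[1] / vis_shape[1]
    return np.array(
        [
            [0.96 * sx, 0.01, 4.0],
            [-0.01, 0.97 * sy, 3.0],
            [1.5e-5, -1.0e-5, 1.0],
        ]
    )


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene; defaults are the study conditions."""

    image_height_px: int = 480
    image_width_px: int = 640
    thermal_height_px: int = 240
    thermal_width_px: int = 320
    n_plants: int = 1
    canopy_radius_px: float = 90.0
    canopy_color_mean: tuple[float, float, float] = (60.0, 120.0, 40.0)
    background_color_mean: tuple[float, float, float] = (150.0, 110.0, 75.0)
    color_noise_sd: tuple[float, float, float] = (8.0, 8.0, 8.0)
    canopy_temp_c: float | tuple[float, ...] = 28.0
    background_temp_c: float = 40.0
    temp_noise_sd: float = 0.3
    true_homography: np.ndarray | None = None
    emissivity: float = 1.0
    reflected_temp_c: float = 20.0
    height_m: float = 20.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.thermal_height_px > self.image_height_px or self.thermal_width_px > self.image_width_px:
            raise ValueError("thermal dimensions must not exceed visible dimensions")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be >= 0")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")
        H = self.true_homography
        if H is None:
            H = default_true_homography(
                (self.image_height_px, self.image_width_px),
                (self.thermal_height_px, self.thermal_width_px),
            )
        H = np.asarray(H, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("true_homography must be 3x3")
        if abs(np.linalg.det(H[:2, :2])) < 1e-9:
            raise ValueError(
                "degenerate homography: upper-left 2x2 block is singular, the map "
                "collapses the image plane"
            )
        object.__setattr__(self, "true_homography", H)
        # a* must separate canopy from background, else colour segmentation
        # is ill-posed by construction
        a_canopy = _ab_of_color(self.canopy_color_mean)[0]
        a_background = _ab_of_color(self.background_color_mean)[0]
        if abs(a_canopy - a_background) < 1e-6:
            raise ValueError(
                "canopy and background colours coincide on the a* (green-red) axis"
            )

    @property
    def canopy_temps(self) -> np.ndarray:
        t = np.atleast_1d(np.asarray(self.canopy_temp_c, dtype=float))
        if len(t) == 1:
            t = np.repeat(t, self.n_plants)
        if len(t) != self.n_plants:
            raise ValueError("canopy_temp_c must be scalar or one value per plant")
        return t


def _ab_of_color(rgb: tuple[float, float, float]) -> np.ndarray:
    px = np.array(rgb, dtype=float).round().clip(0, 255).astype(np.uint8)
    return rgb_to_lab(px.reshape(1, 1, 3))[0, 0, 1:]


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth recorded alongside a generated scene."""

    true_mask: np.ndarray
    true_mask_thermal: np.ndarray
    plant_labels: np.ndarray  # visible grid, 0 = background, 1..n = plant id
    true_canopy_temp_c: np.ndarray
    true_background_temp_c: float
    true_homography: np.ndarray


@dataclass(frozen=True)
class SceneBundle:
    """One generated scene plus its experimental identity."""

    scene_id: str
    genotype: str
    treatment: str
    replicate: int
    params: SceneParams
    rgb: np.ndarray
    thermal: ThermalImage
    truth: SceneTruth


def _plant_centers(params: SceneParams) -> np.ndarray:
    """Deterministic disjoint placement of plant disks on the visible grid."""
    n = params.n_plants
    r = params.canopy_radius_px
    h, w = params.image_height_px, params.image_width_px
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    xs = (np.arange(ncols) + 0.5) * (w / ncols)
    ys = (np.arange(nrows) + 0.5) * (h / nrows)
    if w / ncols < 2 * r + 4 or h / nrows < 2 * r + 4:
        raise ValueError(
            f"cannot place {n} disjoint canopies of radius {r} on a {h}x{w} image"
        )
    centers = [(xs[i % ncols], ys[i // ncols]) for i in range(n)]
    return np.asarray(centers)  # (col, row)


def _membership(cols: np.ndarray, rows: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    """Plant id (0 = none) for each (col, row) position, evaluated analytically."""
    out = np.zeros(cols.shape, dtype=int)
    for pid, (cx, cy) in enumerate(centers, start=1):
        inside = (cols - cx) ** 2 + (rows - cy) ** 2 <= radius**2
        out[inside] = pid  # disks are disjoint by construction
    return out


def generate_scene(params: SceneParams) -> tuple[np.ndarray, ThermalImage, SceneTruth]:
    """Render one paired visible/thermal scene with exact ground truth.

    The visible image holds ``n_plants`` green disks over the soil background
    with i.i.d. Gaussian colour noise. The thermal image renders the same
    layout on its own (coarser) grid: each thermal pixel is mapped through the
    inverse of ``true_homography`` into visible coordinates and classified
    against the analytic disk layout, so the thermal-space truth mask is exact
    rather than resampled. Object temperatures receive Gaussian noise and are
    then pushed through the greybody forward model at the scene emissivity
    (identity at the default emissivity of 1, i.e. camera-corrected imagery).
    Identical parameters and seed reproduce the scene byte for byte.
    """
    rng = np.random.default_rng(params.rng_seed)
    centers = _plant_centers(params)
    h, w = params.image_height_px, params.image_width_px
    th, tw = params.thermal_height_px, params.thermal_width_px

    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    plant_labels = _membership(cols.astype(float), rows.astype(float), centers, params.canopy_radius_px)
    true_mask = plant_labels > 0

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[...] = np.asarray(params.background_color_mean)
    rgb[true_mask] = np.asarray(params.canopy_color_mean)
    rgb += rng.normal(0.0, params.color_noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    trows, tcols = np.meshgrid(np.arange(th), np.arange(tw), indexing="ij")
    Hinv = np.linalg.inv(params.true_homography)
    vis_pts = apply_homography(Hinv, np.column_stack([tcols.ravel(), trows.ravel()]).astype(float))
    labels_th = _membership(
        vis_pts[:, 0].reshape(th, tw), vis_pts[:, 1].reshape(th, tw), centers, params.canopy_radius_px
    )
    # Pixels whose pre-image lies outside the visible frame are background.
    outside = (
        (vis_pts[:, 0] < 0) | (vis_pts[:, 0] > w - 1) | (vis_pts[:, 1] < 0) | (vis_pts[:, 1] > h - 1)
    ).reshape(th, tw)
    labels_th[outside] = 0
    true_mask_thermal = labels_th > 0

    canopy_temps = params.canopy_temps
    temps = np.full((th, tw), params.background_temp_c, dtype=float)
    for pid in range(1, params.n_plants + 1):
        temps[labels_th == pid] = canopy_temps[pid - 1]
    if params.temp_noise_sd > 0:
        temps += rng.normal(0.0, params.temp_noise_sd, size=temps.shape)
    apparent = greybody_forward(temps, params.emissivity, params.reflected_temp_c)

    thermal = ThermalImage(
        temps_c=apparent,
        meta=ThermalMeta(
            emissivity_setting=params.emissivity,
            reflected_temp_c=params.reflected_temp_c,
            height_m=params.height_m,
        ),
    )
    truth = SceneTruth(
        true_mask=true_mask,
        true_mask_thermal=true_mask_thermal,
        plant_labels=plant_labels,
        true_canopy_temp_c=canopy_temps,
        true_background_temp_c=params.background_temp_c,
        true_homography=params.true_homography,
    )
    return rgb, thermal, truth


# ---------------------------------------------------------------------------
# Factorial experiment


@dataclass(frozen=True)
class ExperimentDesign:
    """Genotype x treatment layout with programmed cell means.

    ``ct_effects`` maps (genotype, treatment) to the cell-mean canopy
    temperature in degC; ``physiology_effects`` maps the same keys to a dict
    of cell means for the generated physiological variables; ``noise_sds``
    gives per-variable replicate noise (key "CT" for canopy temperature).
    """

    genotypes: tuple[str, ...]
    n_replicates: int
    ct_effects: dict
    physiology_effects: dict
    noise_sds: dict
    rng_seed: int = 0
    day_of_stress: int = 12
    scene_params: SceneParams = field(default_factory=SceneParams)

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for g in self.genotypes:
            for t in TREATMENTS:
                if (g, t) not in self.ct_effects:
                    raise ValueError(f"ct_effects missing cell (genotype={g}, treatment={t})")
                if (g, t) not in self.physiology_effects:
                    raise ValueError(
                        f"physiology_effects missing cell (genotype={g}, treatment={t})"
                    )
                missing = set(PHYSIOLOGY_VARS) - set(self.physiology_effects[(g, t)])
                if missing:
                    raise ValueError(
                        f"cell (genotype={g}, treatment={t}) lacks variables {sorted(missing)}"
                    )
        for g in self.genotypes:
            for var in _GAS_EXCHANGE:
                if self.physiology_effects[(g, "drought")][var] > self.physiology_effects[(g, "control")][var]:
                    raise ValueError(
                        f"drought mean of {var} exceeds control mean for genotype {g}; "
                        "drought must reduce gas exchange"
                    )
        missing_sd = ({"CT", *PHYSIOLOGY_VARS}) - set(self.noise_sds)
        if missing_sd:
            raise ValueError(f"noise_sds missing entries for {sorted(missing_sd)}")

    def cell_mean_ct(self, genotype: str, treatment: str) -> float:
        return float(self.ct_effects[(genotype, treatment)])


def generate_experiment(design: ExperimentDesign) -> tuple[list[SceneBundle], pd.DataFrame]:
    """One scene and one plant record per genotype x treatment x replicate.

    Canopy temperature per replicate is drawn from its cell mean plus noise
    and rendered into that replicate's scene; physiological variables are
    drawn per record, with derived quantities (iWUE, Fv/Fm) computed by the
    physiology formulas. Each scene receives its own seed sub-stream spawned
    from the design seed, so any single scene can be regenerated on its own.
    """
    scenes: list[SceneBundle] = []
    records: list[dict] = []
    unit = 0
    for genotype in design.genotypes:
        for treatment in TREATMENTS:
            for rep in range(1, design.n_replicates + 1):
                # explicit per-unit sub-stream: scene i is reproducible alone
                child = np.random.SeedSequence(design.rng_seed, spawn_key=(unit,))
                rng = np.random.default_rng(child)
                scene_seed = int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
                ct_true = design.cell_mean_ct(genotype, treatment) + rng.normal(
                    0.0, design.noise_sds["CT"]
                )
                params = replace(
                    design.scene_params, canopy_temp_c=float(ct_true), rng_seed=scene_seed
                )
                rgb, thermal, truth = generate_scene(params)
                scene_id = f"{genotype}_{treatment}_r{rep}"
                scenes.append(
                    SceneBundle(scene_id, genotype, treatment, rep, params, rgb, thermal, truth)
                )

                means = design.physiology_effects[(genotype, treatment)]
                row = {
                    "scene_id": scene_id,
                    "genotype": genotype,
                    "treatment": treatment,
                    "replicate": rep,
                    "day_of_stress": design.day_of_stress,
                    "CT_true": float(ct_true),
                }
                for var in PHYSIOLOGY_VARS:
                    val = means[var] + rng.normal(0.0, design.noise_sds[var])
                    if var in ("gs", "E", "SWC", "DWC", "CCI", "AGB", "GY", "Fo", "Fm"):
                        val = max(val, 1e-6)  # physically nonnegative
                    row[var] = float(val)
                if row["Fo"] > row["Fm"]:  # keep fluorescence physically ordered
                    row["Fo"], row["Fm"] = row["Fm"], row["Fo"]
                row["LRWC"] = float(np.clip(row["LRWC"], 0.0, 100.0))
                row["iWUE"] = iwue(row["A"], row["E"])
                row["FvFm"] = fv_fm(row["Fo"], row["Fm"])
                records.append(row)
                unit += 1
    return scenes, pd.DataFrame(records)


def default_experiment_design(
    seed: int = 0, scene_params: SceneParams | None = None, n_replicates: int = 5
) -> ExperimentDesign:
    """Four contrasting maize genotypes, control vs drought, five replicates.

    Cell means encode the canonical drought pattern: all genotypes share the
    control canopy temperature, while the drought-induced increase is
    genotype specific (5, 3, 1, 1 degC for the sensitive, intermediate, and
    the two tolerant genotypes). Gas exchange collapses under drought; grain
    yield drops by a genotype-dependent fraction.
    """
    genotypes = ("BRS1010", "BRS1030", "2B707", "DKB390")
    ct_offsets = {"BRS1010": 5.0, "BRS1030": 3.0, "2B707": 1.0, "DKB390": 1.0}
    gy_drop = {"BRS1010": 0.23, "BRS1030": 0.33, "2B707": 0.12, "DKB390": 0.0}
    control_phys = {
        "A": 30.0, "gs": 0.25, "E": 5.0, "Ci": 150.0, "LRWC": 95.0, "SWC": 0.25,
        "DWC": 0.6, "Fo": 400.0, "Fm": 2000.0, "CCI": 35.0, "AGB": 180.0, "GY": 120.0,
    }
    drought_phys = {
        "A": 3.0, "gs": 0.02, "E": 0.8, "Ci": 220.0, "LRWC": 60.0, "SWC": 0.08,
        "DWC": 0.15, "Fo": 550.0, "Fm": 1800.0, "CCI": 20.0, "AGB": 150.0, "GY": 120.0,
    }
    ct_effects = {}
    physiology_effects = {}
    for g in genotypes:
        ct_effects[(g, "control")] = 28.0
        ct_effects[(g, "drought")] = 28.0 + ct_offsets[g]
        physiology_effects[(g, "control")] = dict(control_phys)
        cell = dict(drought_phys)
        cell["GY"] = control_phys["GY"] * (1.0 - gy_drop[g])
        physiology_effects[(g, "drought")] = cell
    noise_sds = {
        "CT": 0.3, "A": 1.5, "gs": 0.02, "E": 0.3, "Ci": 10.0, "LRWC": 3.0,
        "SWC": 0.015, "DWC": 0.05, "Fo": 30.0, "Fm": 80.0, "CCI": 2.5,
        "AGB": 12.0, "GY": 8.0,
    }
    return ExperimentDesign(
        genotypes=genotypes,
        n_replicates=n_replicates,
        ct_effects=ct_effects,
        physiology_effects=physiology_effects,
        noise_sds=noise_sds,
        rng_seed=seed,
        scene_params=scene_params if scene_params is not None else SceneParams(),
    )


# ---------------------------------------------------------------------------
# Fixture I/O


def correspondence_grid(params: SceneParams, n_per_side: int = 3) -> PointCorrespondences:
    """Annotated-point stand-in: a grid of visible points mapped by the true H."""
    h, w = params.image_height_px, params.image_width_px
    xs = np.linspace(0.1 * w, 0.9 * w, n_per_side)
    ys = np.linspace(0.1 * h, 0.9 * h, n_per_side)
    src = np.array([(x, y) for y in ys for x in xs])
    dst = apply_homography(params.true_homography, src)
    return PointCorrespondences(src=src, dst=dst)


def write_fixture_set(dir_path, scenes: list[SceneBundle], records: pd.DataFrame) -> dict:
    """Persist scenes and records as plain files plus a YAML manifest.

    Per scene: RGB as PNG, thermal as single-channel float32 TIFF (degC),
    truth masks as 0/255 PNG, and a correspondence CSV derived from the true
    homography. The manifest lists every file with the seed and parameters
    needed to regenerate it.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sc in scenes:
        base = sc.scene_id
        files = {
            "rgb": f"{base}_rgb.png",
            "thermal": f"{base}_thermal.tif",
            "mask": f"{base}_mask.png",
            "mask_thermal": f"{base}_mask_thermal.png",
            "correspondences": f"{base}_corr.csv",
        }
        try:
            Image.fromarray(sc.rgb).save(out / files["rgb"])
            tifffile.imwrite(out / files["thermal"], sc.thermal.temps_c.astype(np.float32))
            Image.fromarray((sc.truth.true_mask * 255).astype(np.uint8)).save(out / files["mask"])
            Image.fromarray((sc.truth.true_mask_thermal * 255).astype(np.uint8)).save(
                out / files["mask_thermal"]
            )
            write_correspondences(out / files["correspondences"], correspondence_grid(sc.params))
        except OSError as exc:
            raise OSError(f"failed writing fixture files under {out}: {exc}") from exc
        entries.append(
            {
                "scene_id": sc.scene_id,
                "genotype": sc.genotype,
                "treatment": sc.treatment,
                "replicate": sc.replicate,
                "files": files,
                "rng_seed": int(sc.params.rng_seed),
                "emissivity": float(sc.params.emissivity),
                "reflected_temp_c": float(sc.params.reflected_temp_c),
                "true_homography": [float(v) for v in np.asarray(sc.params.true_homography).ravel()],
                "true_canopy_temp_c": [float(v) for v in sc.truth.true_canopy_temp_c],
                "true_background_temp_c": float(sc.truth.true_background_temp_c),
            }
        )
    records.to_csv(out / "records.csv", index=False)
    manifest = {"n_scenes": len(scenes), "records": "records.csv", "scenes": entries}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_fixture_set(dir_path) -> tuple[dict, pd.DataFrame]:
    """Load the manifest and record table written by :func:`write_fixture_set`."""
    out = Path(dir_path)
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    records = pd.read_csv(out / manifest["records"])
    return manifest, records
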
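"""Synthetic 384-well plate data with known ground truth.

Emulates the screen's imaging conditions: cerebellar-progenitor-like cells
whose nuclei are bright discs in the nuclear channel, a diffuse Lysotracker
cytoplasmic background delineating each cell's territory in the red channel,
GFP-LC3 puncta in the green channel, and discrete acidic vesicles in the red
channel placed at controlled distances from the nuclear border.

Defaults encode the screen's stated baseline conditions: 42.5% of mutant
cells (5.2% of wild-type cells) carry >= 5 green puncta under DMSO, the
per-vesicle lysosome-to-nucleus distance averages 4.65 um in mutant cells
vs 3.96 um in wild-type cells, and DMSO wells count 322 +/- 71 nuclei.

Two generation paths are provided:

* :func:`generate_field` / :func:`generate_plate` render full images plus a
  per-cell ground-truth table (for testing the measurement stages);
* :func:`generate_readout_table` samples well-level readouts directly from
  the same statistical model (for statistics-only testing, fast).

All outputs are pure functions of (spec, layout, effect_map, artifacts):
a per-well substream is derived from the spec seed and the well's plate
index, so adding wells never perturbs existing wells' data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .plate_model import (
    FieldImage,
    PlateLayout,
    WellReadout,
    normalize_well,
    well_index,
    write_field_image,
)

# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class Blur:
    """Out-of-focus field: isotropic Gaussian defocus on all channels."""

    sigma: float = 6.0


@dataclass(frozen=True)
class PhenolRed:
    """Phenol-red carry-over: elevated red fluorescence across the well."""

    level: float = 10500.0  # measured well-level red background, a.u.


@dataclass(frozen=True)
class Toxic:
    """Compound toxicity: nuclei count scaled down."""

    nuclei_scale: float = 0.4


Artifact = Blur | PhenolRed | Toxic


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated plate.

    Count distributions are Poisson; lysosome-to-nucleus distances are
    truncated normals per genotype (mean, sd in um).  ``positive_fraction``
    is the probability a cell receives >= 5 green puncta.
    """

    seed: int = 0
    field_shape: tuple[int, int] = (512, 512)
    um_per_pixel: float = 1.0
    fields_per_well: int = 3
    cells_per_field: float = 60.0  # Poisson mean
    nucleus_diameter_px: tuple[float, float] = (30.0, 44.0)
    positive_fraction: float = 0.425
    wildtype_positive_fraction: float = 0.052
    vesicles_given_positive: tuple[int, float] = (5, 4.0)  # min count + Poisson mean
    vesicles_given_negative: float = 1.5  # Poisson mean, clipped at 4
    red_vesicles_per_cell: float = 6.0  # Poisson mean
    lyso_distance_um: dict = dc_field(
        default_factory=lambda: {"mutant": (4.65, 1.3), "wildtype": (3.96, 0.9)}
    )
    background_levels: dict = dc_field(
        default_factory=lambda: {"nuclear": 300.0, "green": 400.0, "red": 5000.0}
    )
    cytoplasm_level: float = 4000.0
    nucleus_intensity: float = 20000.0
    green_puncta_intensity: float = 12000.0
    red_vesicle_intensity: float = 9000.0
    puncta_sigma_px: float = 1.5
    # vesicles are discrete organelles; planted spot centers keep a minimum
    # separation so that every planted spot is a resolvable object
    min_spot_separation_px: float = 4.0
    cell_radius_px: float = 40.0
    shot_noise: bool = True
    read_noise_sd: float = 10.0
    phenol_red_image_boost: float = 6000.0
    positive_threshold: int = 5
    # image-free (table) path noise model
    nuclei_per_well: tuple[float, float] = (322.0, 71.0)
    pct_between_well_sd: float = 7.8  # percentage points on the positive fraction
    distance_well_sd: float = 0.15  # um, well-to-well spread of the mean distance
    red_background_au: tuple[float, float] = (7500.0, 600.0)
    nominal_focus_score: float = 0.2
    blurred_focus_score: float = 0.65
    sample_counts: bool = True  # False => table path returns expectations exactly

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        for name in ("cells_per_field", "vesicles_given_negative", "red_vesicles_per_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nucleus_diameter_px[0] <= 0 or self.nucleus_diameter_px[1] < self.nucleus_diameter_px[0]:
            raise ValueError("nucleus_diameter_px must be a positive (min, max) range")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("field_shape", "nucleus_diameter_px", "vesicles_given_positive",
                    "nuclei_per_well", "red_background_au"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class CompoundEffect:
    """How a compound shifts the generative parameters of its wells."""

    positive_fraction: float | None = None
    distance_mean_um: float | None = None
    nuclei_scale: float = 1.0


@dataclass
class GroundTruth:
    """Planted per-cell and per-well truth accompanying generated data."""

    cells: pd.DataFrame  # well, field, cell_id, y, x, radius_px, green_count, n_red
    red_vesicles: pd.DataFrame  # well, field, cell_id, y, x, distance_um
    wells: pd.DataFrame  # well, positive_fraction, distance_mean_um, artifacts

    @staticmethod
    def concat(parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        return GroundTruth(
            cells=pd.concat([p.cells for p in parts], ignore_index=True),
            red_vesicles=pd.concat([p.red_vesicles for p in parts], ignore_index=True),
            wells=pd.concat([p.wells for p in parts], ignore_index=True)
            .drop_duplicates(subset="well")
            .reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# helpers

_CELL_CLEARANCE_PX = 4.0  # minimum gap between nuclear borders of neighbours


def _field_rng(spec: SyntheticSpec, well: str, field_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 0, well_index(well), int(field_index)])
    )


def _well_rng(spec: SyntheticSpec, well: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1, well_index(well)])
    )


def _place_nuclei(
    rng: np.random.Generator, spec: SyntheticSpec, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential random placement of non-overlapping nuclei; bounded retries."""
    h, w = spec.field_shape
    lo, hi = spec.nucleus_diameter_px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts, max_attempts = 0, max(500, 300 * n_cells)
    while len(centers) < n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_cells} cells of diameter {lo}-{hi} px "
                f"in a {h}x{w} field after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(lo, hi) / 2.0
        y = rng.uniform(r + 1, h - r - 1)
        x = rng.uniform(r + 1, w - r - 1)
        ok = True
        for (cy, cx), cr in zip(centers, radii):
            if (y - cy) ** 2 + (x - cx) ** 2 < (r + cr + _CELL_CLEARANCE_PX) ** 2:
                ok = False
                break
        if ok:
            centers.append((y, x))
            radii.append(r)
    return np.array(centers, float).reshape(-1, 2), np.array(radii, float)


def _add_spot(img: np.ndarray, y: float, x: float, amplitude: float, sigma: float) -> None:
    """Accumulate a small Gaussian spot in place."""
    h, w = img.shape
    rad = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - rad), min(h, int(y) + rad + 1)
    x0, x1 = max(0, int(x) - rad), min(w, int(x) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -(((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2))
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float = 0.05) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


def _sample_green_count(rng: np.random.Generator, spec: SyntheticSpec, positive: bool) -> int:
    if positive:
        base, lam = spec.vesicles_given_positive
        return int(base + rng.poisson(lam))
    threshold = spec.positive_threshold
    return int(min(rng.poisson(spec.vesicles_given_negative), threshold - 1))


# ---------------------------------------------------------------------------
# field generation


def generate_field(
    spec: SyntheticSpec,
    well: str = "A01",
    field_index: int = 0,
    genotype: str = "mutant",
    positive_fraction: float | None = None,
    distance_mean_um: float | None = None,
    artifacts: Sequence[Artifact] = (),
    n_cells: int | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Identical (spec, well, field_index, overrides) give bit-identical output.
    """
    well = normalize_well(well)
    rng = _field_rng(spec, well, field_index)
    h, w = spec.field_shape
    p_pos = spec.positive_fraction if positive_fraction is None else positive_fraction
    if genotype == "wildtype" and positive_fraction is None:
        p_pos = spec.wildtype_positive_fraction
    dist_mean, dist_sd = spec.lyso_distance_um[genotype]
    if distance_mean_um is not None:
        dist_mean = distance_mean_um

    scale = 1.0
    for art in artifacts:
        if isinstance(art, Toxic):
            scale *= art.nuclei_scale
    if n_cells is None:
        n_cells = int(rng.poisson(spec.cells_per_field * scale))

    centers, radii = _place_nuclei(rng, spec, n_cells)

    nuclear = np.full((h, w), spec.background_levels["nuclear"], float)
    green = np.full((h, w), spec.background_levels["green"], float)
    red = np.full((h, w), spec.background_levels["red"], float)

    yy, xx = np.mgrid[0:h, 0:w]

    # nuclei: bright discs
    for (cy, cx), r in zip(centers, radii):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclear[mask] += spec.nucleus_intensity

    # cytoplasm: Voronoi-like territory around each nucleus, clipped to a
    # maximum radius, carried by the red (Lysotracker background) channel
    if n_cells > 0:
        tree = cKDTree(centers)
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        dist, owner = tree.query(pts)
        dist = dist.reshape(h, w)
        owner = owner.reshape(h, w)
        territory = dist <= spec.cell_radius_px
        red[territory] += spec.cytoplasm_level
    else:
        owner = np.full((h, w), -1)
        territory = np.zeros((h, w), bool)

    min_sep2 = spec.min_spot_separation_px**2
    placed_green_pts: list[tuple[float, float]] = []
    placed_red_pts: list[tuple[float, float]] = []

    def _separated(y: float, x: float, placed: list[tuple[float, float]]) -> bool:
        return all((y - py) ** 2 + (x - px) ** 2 >= min_sep2 for py, px in placed)

    cell_rows = []
    vesicle_rows = []
    for ci, ((cy, cx), r) in enumerate(zip(centers, radii)):
        positive = bool(rng.random() < p_pos)
        want_green = _sample_green_count(rng, spec, positive)
        placed_green = 0
        for _ in range(want_green):
            for _attempt in range(100):
                rho = rng.uniform(0.0, r + 12.0)
                theta = rng.uniform(0.0, 2 * np.pi)
                gy, gx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
                iy, ix = int(round(gy)), int(round(gx))
                if (0 <= iy < h and 0 <= ix < w and territory[iy, ix]
                        and owner[iy, ix] == ci and _separated(gy, gx, placed_green_pts)):
                    _add_spot(green, gy, gx, spec.green_puncta_intensity, spec.puncta_sigma_px)
                    placed_green_pts.append((gy, gx))
                    placed_green += 1
                    break

        n_red = int(rng.poisson(spec.red_vesicles_per_cell))
        placed_red = 0
        for _ in range(n_red):
            for _attempt in range(100):
                d_um = _truncated_normal(rng, dist_mean, dist_sd)
                theta = rng.uniform(0.0, 2 * np.pi)
                rho = r + d_um / spec.um_per_pixel
                vy, vx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
                iy, ix = int(round(vy)), int(round(vx))
                if (0 <= iy < h and 0 <= ix < w and territory[iy, ix]
                        and owner[iy, ix] == ci and _separated(vy, vx, placed_red_pts)):
                    _add_spot(red, vy, vx, spec.red_vesicle_intensity, spec.puncta_sigma_px)
                    placed_red_pts.append((vy, vx))
                    vesicle_rows.append(
                        {"well": well, "field": field_index, "cell_id": ci + 1,
                         "y": vy, "x": vx, "distance_um": d_um}
                    )
                    placed_red += 1
                    break

        cell_rows.append(
            {"well": well, "field": field_index, "cell_id": ci + 1,
             "y": cy, "x": cx, "radius_px": r, "genotype": genotype,
             "green_count": placed_green,
             "is_positive": placed_green >= spec.positive_threshold,
             "n_red": placed_red}
        )

    channels = np.stack([nuclear, green, red])

    for art in artifacts:
        if isinstance(art, Blur):
            channels = np.stack([ndi.gaussian_filter(c, art.sigma) for c in channels])
        elif isinstance(art, PhenolRed):
            channels[2] += spec.phenol_red_image_boost

    if spec.shot_noise:
        channels = rng.poisson(np.clip(channels, 0, None)).astype(float)
    if spec.read_noise_sd > 0:
        channels = channels + rng.normal(0.0, spec.read_noise_sd, channels.shape)
    channels = np.clip(np.round(channels), 0, 65535).astype(np.uint16)

    image = FieldImage(
        well=well,
        field_index=field_index,
        channels=channels,
        bit_depth=16,
        um_per_pixel=spec.um_per_pixel,
    )
    cell_cols = ["well", "field", "cell_id", "y", "x", "radius_px", "genotype",
                 "green_count", "is_positive", "n_red"]
    ves_cols = ["well", "field", "cell_id", "y", "x", "distance_um"]
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows, columns=cell_cols),
        red_vesicles=pd.DataFrame(vesicle_rows, columns=ves_cols),
        wells=pd.DataFrame(
            [{"well": well, "positive_fraction": p_pos, "distance_mean_um": dist_mean,
              "artifacts": ";".join(sorted(type(a).__name__ for a in artifacts))}]
        ),
    )
    return image, truth


def _well_parameters(
    spec: SyntheticSpec,
    well_spec,
    effect_map: Mapping[str, CompoundEffect] | None,
) -> tuple[float, float, float]:
    """(positive_fraction, distance_mean_um, nuclei_scale) for one well."""
    genotype = well_spec.genotype
    p = spec.positive_fraction if genotype == "mutant" else spec.wildtype_positive_fraction
    d = spec.lyso_distance_um[genotype][0]
    scale = 1.0
    if well_spec.role == "compound":
        eff = (effect_map or {}).get(well_spec.compound_id)
        if eff is not None:
            if eff.positive_fraction is not None:
                p = eff.positive_fraction
            if eff.distance_mean_um is not None:
                d = eff.distance_mean_um
            scale = eff.nuclei_scale
    return p, d, scale


def _check_effect_map(layout: PlateLayout, effect_map: Mapping[str, CompoundEffect] | None):
    """With no effect map every compound draws baseline; a provided map must
    cover every compound on the plate."""
    if effect_map is None:
        return
    missing = [c for c in layout.compound_ids() if c not in effect_map]
    if missing:
        raise ValueError(f"effect_map missing entries for compounds: {missing}")


def generate_plate(
    spec: SyntheticSpec,
    layout: PlateLayout,
    effect_map: Mapping[str, CompoundEffect] | None = None,
    artifact_map: Mapping[str, Sequence[Artifact]] | None = None,
) -> Iterator[tuple[FieldImage, GroundTruth]]:
    """Lazily generate all fields of a plate (DMSO wells at baseline,
    compound wells at their shifted parameters, 3 fields per well)."""
    _check_effect_map(layout, effect_map)
    artifact_map = {normalize_well(k): tuple(v) for k, v in (artifact_map or {}).items()}
    for ws in layout.wells:
        if ws.role == "empty":
            continue
        p, d, scale = _well_parameters(spec, ws, effect_map)
        arts = list(artifact_map.get(ws.well, ()))
        if scale != 1.0:
            arts.append(Toxic(nuclei_scale=scale))
        for fi in range(spec.fields_per_well):
            yield generate_field(
                spec,
                well=ws.well,
                field_index=fi,
                genotype=ws.genotype,
                positive_fraction=p,
                distance_mean_um=d,
                artifacts=arts,
            )


def simulate_plate_to_dir(
    spec: SyntheticSpec,
    layout: PlateLayout,
    out_dir: str | Path,
    effect_map: Mapping[str, CompoundEffect] | None = None,
    artifact_map: Mapping[str, Sequence[Artifact]] | None = None,
) -> GroundTruth:
    """Write field TIFFs plus ground-truth CSVs and the spec YAML to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts = []
    for image, truth in generate_plate(spec, layout, effect_map, artifact_map):
        write_field_image(image, out_dir / f"{image.well}_f{image.field_index}.tif")
        parts.append(truth)
    truth = GroundTruth.concat(parts)
    truth.cells.to_csv(out_dir / "truth_cells.csv", index=False)
    truth.red_vesicles.to_csv(out_dir / "truth_red_vesicles.csv", index=False)
    truth.wells.to_csv(out_dir / "truth_wells.csv", index=False)
    spec.to_yaml(out_dir / "synthetic_spec.yaml")
    return truth


# ---------------------------------------------------------------------------
# image-free fast path


def generate_readout_table(
    spec: SyntheticSpec,
    layout: PlateLayout,
    effect_map: Mapping[str, CompoundEffect] | None = None,
    artifact_map: Mapping[str, Sequence[Artifact]] | None = None,
) -> list[WellReadout]:
    """Sample well-level readouts directly from the generative model.

    Per well: the nuclei count is normal (322 +/- 71 under DMSO defaults,
    scaled down in toxic wells); the positive fraction receives a between-well
    normal perturbation and cells are then Bernoulli-positive (binomial
    count); the well-mean distance and red background are normal.  With
    ``sample_counts=False`` and zero noise SDs the readouts equal the planted
    parameters exactly.
    """
    _check_effect_map(layout, effect_map)
    artifact_map = {normalize_well(k): tuple(v) for k, v in (artifact_map or {}).items()}
    mu_n, sd_n = spec.nuclei_per_well
    mu_r, sd_r = spec.red_background_au
    readouts = []
    for ws in layout.wells:
        if ws.role == "empty":
            continue
        rng = _well_rng(spec, ws.well)
        p, d_mean, scale = _well_parameters(spec, ws, effect_map)
        arts = artifact_map.get(ws.well, ())
        for art in arts:
            if isinstance(art, Toxic):
                scale *= art.nuclei_scale

        if spec.sample_counts:
            nuclei = max(0, int(round(rng.normal(mu_n * scale, sd_n * scale))))
        else:
            nuclei = int(round(mu_n * scale))

        p_well = p
        if spec.pct_between_well_sd > 0:
            p_well = float(np.clip(rng.normal(p, spec.pct_between_well_sd / 100.0), 0.0, 1.0))
        if spec.sample_counts and nuclei > 0:
            pct = 100.0 * rng.binomial(nuclei, p_well) / nuclei
        else:
            pct = 100.0 * p_well

        if spec.distance_well_sd > 0:
            dist = max(0.0, float(rng.normal(d_mean, spec.distance_well_sd)))
        else:
            dist = d_mean

        red = float(rng.normal(mu_r, sd_r)) if sd_r > 0 else mu_r
        focus = [spec.nominal_focus_score] * spec.fields_per_well
        for art in arts:
            if isinstance(art, PhenolRed):
                red = art.level
            elif isinstance(art, Blur):
                focus = [spec.blurred_focus_score] * spec.fields_per_well

        readouts.append(
            WellReadout(
                well=ws.well,
                pct_positive=pct,
                nuclei_count=nuclei,
                mean_lyso_nuc_distance=dist,
                red_background=red,
                focus_scores=tuple(focus),
            )
        )
    return readouts
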
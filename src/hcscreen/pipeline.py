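"""End-to-end orchestration: simulate/read fields -> measure -> QC -> score.

The pipeline is deterministic under a fixed configuration and seed; every
well draws its own RNG substream, so adding wells never changes existing
wells' data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image_analysis import (
    CellRecord,
    DetectionParams,
    detect_vesicles,
    flat_field_correct,
    infer_cell_regions,
    measure_cells,
    segment_nuclei,
)
from .plate_model import (
    CompoundResult,
    FieldImage,
    PlateLayout,
    WellReadout,
    read_field_image,
    read_plate_map,
    write_results,
)
from .qc import QcThresholds, apply_well_qc, classify_focus, dmso_nuclei_reference, focus_score
from .screen_stats import (
    ENHANCER_CUT,
    SUPPRESSOR_CUT,
    aggregate_compounds,
    call_hits,
    control_summary,
    zprime,
)
from .synthetic import SyntheticSpec, simulate_plate_to_dir

log = logging.getLogger(__name__)


@dataclass
class ScoringParams:
    suppressor_cut: float = SUPPRESSOR_CUT
    enhancer_cut: float = ENHANCER_CUT
    restoration_cut: float = 0.85


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    layout_path: str = ""
    images_dir: str = ""
    out_dir: str = "hcscreen_out"
    seed: int = 0
    um_per_pixel: float = 1.0
    simulate: bool = False
    detection: DetectionParams = dc_field(default_factory=DetectionParams)
    qc: QcThresholds = dc_field(default_factory=QcThresholds)
    scoring: ScoringParams = dc_field(default_factory=ScoringParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.layout_path:
            raise ValueError("config field 'layout_path' is required")
        if not Path(self.layout_path).exists():
            raise ValueError(f"layout_path does not exist: {self.layout_path}")
        if not self.simulate:
            if not self.images_dir:
                raise ValueError("config field 'images_dir' is required unless simulate=true")
            if not Path(self.images_dir).exists():
                raise ValueError(f"images_dir does not exist: {self.images_dir}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("detection", DetectionParams), ("qc", QcThresholds),
                         ("scoring", ScoringParams)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for k, v in list(d.items()):
                    if isinstance(v, list):
                        d[k] = tuple(v)
                raw[key] = sub(**d)
        return cls(**raw)


@dataclass
class FieldMeasurement:
    well: str
    field_index: int
    focus: float
    in_focus: bool
    n_nuclei: int
    red_mean: float
    cells: list[CellRecord]


def analyze_field(
    field: FieldImage,
    detection: DetectionParams | None = None,
    qc_thresholds: QcThresholds | None = None,
) -> FieldMeasurement:
    """Measure one field: focus score, flat-field correction, segmentation,
    puncta detection, per-cell assignment and distances."""
    p = detection or DetectionParams()
    t = qc_thresholds or QcThresholds()
    score = focus_score(field.nuclear, kernel_size=t.focus_kernel_size, method=t.focus_method)
    in_focus = classify_focus(score, t.focus_cutoff) == "in_focus"
    red_mean = float(np.asarray(field.red, float).mean())

    cells_records: list[CellRecord] = []
    n_nuclei = 0
    if in_focus:
        nuclear = flat_field_correct(field.nuclear)
        green = flat_field_correct(field.green)
        red = flat_field_correct(field.red)
        nuclei = segment_nuclei(
            nuclear,
            diameter_range_px=p.nucleus_diameter_px,
            min_above_background=p.nucleus_min_above_background,
            params=p,
        )
        n_nuclei = int(nuclei.max())
        if n_nuclei:
            cells = infer_cell_regions(red, nuclei, params=p)
            green_v = detect_vesicles(green, "green", params=p)
            red_v = detect_vesicles(red, "red", params=p)
            cells_records = measure_cells(
                cells,
                nuclei,
                green_v,
                red_v,
                um_per_pixel=field.um_per_pixel,
                positive_threshold=p.positive_threshold,
                max_gap_px=p.assign_max_gap_px,
            )
    return FieldMeasurement(
        well=field.well,
        field_index=field.field_index,
        focus=score,
        in_focus=in_focus,
        n_nuclei=n_nuclei,
        red_mean=red_mean,
        cells=cells_records,
    )


def summarize_well(measurements: Sequence[FieldMeasurement]) -> WellReadout:
    """Aggregate field measurements into a well readout.

    Out-of-focus fields contribute only their focus score; a well keeps a
    readout as long as at least one field is in focus (full exclusion is
    decided later by :func:`hcscreen.qc.apply_well_qc`).
    """
    if not measurements:
        raise ValueError("summarize_well: no field measurements")
    well = measurements[0].well
    used = [m for m in measurements if m.in_focus]
    cells = [c for m in used for c in m.cells]
    pct = 100.0 * float(np.mean([c.is_positive for c in cells])) if cells else None
    dists = [d for c in cells for d in c.red_distances]
    return WellReadout(
        well=well,
        pct_positive=pct,
        nuclei_count=int(sum(m.n_nuclei for m in used)),
        mean_lyso_nuc_distance=float(np.mean(dists)) if dists else None,
        red_background=float(np.mean([m.red_mean for m in measurements])),
        focus_scores=tuple(m.focus for m in sorted(measurements, key=lambda m: m.field_index)),
    )


def _field_paths_by_well(images_dir: Path) -> dict[str, list[Path]]:
    by_well: dict[str, list[Path]] = {}
    for path in sorted(images_dir.glob("*.tif")):
        well = path.stem.split("_")[0]
        by_well.setdefault(well, []).append(path)
    return by_well


@dataclass
class RunResult:
    readouts: list[WellReadout]
    results: list[CompoundResult]
    summary: dict


def run_pipeline(
    config: RunConfig,
    synthetic_spec: SyntheticSpec | None = None,
    effect_map=None,
    artifact_map=None,
) -> RunResult:
    """Run the full analysis and write the report bundle to ``out_dir``:
    well table, compound table, QC report, screen summary JSON, run log."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = read_plate_map(config.layout_path)

    if config.simulate:
        spec = synthetic_spec or SyntheticSpec(seed=config.seed, um_per_pixel=config.um_per_pixel)
        images_dir = out_dir / "images"
        simulate_plate_to_dir(spec, layout, images_dir, effect_map, artifact_map)
    else:
        images_dir = Path(config.images_dir)

    by_well = _field_paths_by_well(images_dir)
    readouts = []
    field_rows = []
    for ws in layout.wells:
        if ws.role == "empty":
            continue
        paths = by_well.get(ws.well)
        if not paths:
            raise RuntimeError(f"measurement stage: no field images for well {ws.well}")
        measurements = [
            analyze_field(
                read_field_image(p, um_per_pixel=config.um_per_pixel),
                config.detection,
                config.qc,
            )
            for p in paths
        ]
        readouts.append(summarize_well(measurements))
        field_rows.extend(
            {
                "well": m.well,
                "field": m.field_index,
                "focus_score": m.focus,
                "focus_class": "in_focus" if m.in_focus else "out_of_focus",
                "n_nuclei": m.n_nuclei,
                "red_mean": m.red_mean,
            }
            for m in measurements
        )

    readouts = apply_well_qc(readouts, layout, config.qc)
    control = control_summary(readouts, layout)
    nuclei_ref = dmso_nuclei_reference(readouts, layout)
    results = aggregate_compounds(readouts, layout, control, nuclei_ref)
    results = call_hits(results, config.scoring.suppressor_cut, config.scoring.enhancer_cut)

    write_results(readouts, results, out_dir)
    pd.DataFrame(field_rows).to_csv(out_dir / "qc_fields.csv", index=False)

    summary = {
        "plate_id": layout.plate_id,
        "n_wells": len(readouts),
        "n_excluded": sum(r.excluded for r in readouts),
        "dmso": {
            "mu_pct": control.mu_pct,
            "sigma_pct": control.sigma_pct,
            "mu_dist": control.mu_dist,
            "nuclei_mu": nuclei_ref[0],
            "nuclei_sigma": nuclei_ref[1],
        },
        "n_suppressors": sum(r.hit_class == "suppressor" for r in results),
        "n_enhancers": sum(r.hit_class == "enhancer" for r in results),
        "n_restored": sum(r.restored for r in results),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"hcscreen {__version__}\nseed: {config.seed}\n")
        fh.write(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
    return RunResult(readouts=readouts, results=results, summary=summary)
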
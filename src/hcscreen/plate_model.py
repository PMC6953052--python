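"""Plate-layout semantics, core record types, and table / image IO.

A 384-well plate has rows A..P and columns 1..24.  Well addresses are kept
in a zero-padded normal form ("A01" .. "P24") so that lexicographic sorting
equals plate-reading order and result tables are deterministically ordered.

Wells excluded by quality control serialize their continuous readouts as the
literal string ``"NA"`` in the output tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

ROWS = "ABCDEFGHIJKLMNOP"
N_COLUMNS = 24
ROLES = frozenset({"dmso_control", "compound", "empty"})
GENOTYPES = frozenset({"wildtype", "mutant"})

#: channel order in every 3-page field TIFF
CHANNEL_NAMES = ("nuclear", "green", "red")

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")


class PlateError(ValueError):
    """Malformed plate map, well address, or result table."""


def normalize_well(address: str) -> str:
    """Return the zero-padded normal form of a well address.

    >>> normalize_well("a1")
    'A01'

    Raises :class:`PlateError` for addresses outside the A1..P24 geometry.
    """
    m = _WELL_RE.match(str(address).strip())
    if not m:
        raise PlateError(f"malformed well address {address!r} (expected A1..P24)")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= N_COLUMNS:
        raise PlateError(f"well {address!r}: column {col} outside 1..{N_COLUMNS}")
    return f"{row}{col:02d}"


def well_index(address: str) -> int:
    """0-based row-major index of a well on the 384-well grid."""
    a = normalize_well(address)
    return ROWS.index(a[0]) * N_COLUMNS + int(a[1:]) - 1


def all_well_addresses() -> list[str]:
    """The 384 addresses A01..P24 in plate-reading order."""
    return [f"{r}{c:02d}" for r in ROWS for c in range(1, N_COLUMNS + 1)]


@dataclass(frozen=True)
class WellSpec:
    """One well of the plate map."""

    well: str
    role: str
    compound_id: str | None = None
    dose_um: float | None = None
    genotype: str = "mutant"
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(self, "well", normalize_well(self.well))
        if self.role not in ROLES:
            raise PlateError(f"well {self.well}: unknown role {self.role!r}")
        if self.genotype not in GENOTYPES:
            raise PlateError(f"well {self.well}: unknown genotype {self.genotype!r}")
        if self.role == "compound" and not self.compound_id:
            raise PlateError(f"well {self.well}: compound well without compound_id")
        if self.role == "dmso_control" and self.compound_id:
            raise PlateError(f"well {self.well}: dmso_control well carries a compound_id")


@dataclass
class PlateLayout:
    plate_id: str
    wells: list[WellSpec]

    def __post_init__(self):
        seen: set[str] = set()
        for w in self.wells:
            if w.well in seen:
                raise PlateError(f"duplicate well {w.well} in plate {self.plate_id}")
            seen.add(w.well)
        self.wells = sorted(self.wells, key=lambda w: w.well)

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def well_map(self) -> dict[str, WellSpec]:
        return {w.well: w for w in self.wells}

    def dmso_wells(self, genotype: str | None = None) -> list[WellSpec]:
        return [
            w
            for w in self.wells
            if w.role == "dmso_control" and (genotype is None or w.genotype == genotype)
        ]

    def compound_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.role == "compound"]

    def compound_ids(self) -> list[str]:
        out: list[str] = []
        for w in self.compound_wells():
            if w.compound_id not in out:
                out.append(w.compound_id)
        return out


def read_plate_map(path: str | Path, plate_id: str | None = None) -> PlateLayout:
    """Read a plate-map CSV (columns well,role,compound_id,dose_um,genotype,replicate).

    Optional columns may be blank; errors name the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"well", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PlateError(f"{path.name}: missing required columns {sorted(missing)}")
    wells = []
    for i, row in df.iterrows():
        try:
            dose = row.get("dose_um", "")
            wells.append(
                WellSpec(
                    well=row["well"],
                    role=row["role"].strip(),
                    compound_id=row.get("compound_id", "").strip() or None,
                    dose_um=float(dose) if str(dose).strip() else None,
                    genotype=(row.get("genotype", "") or "mutant").strip() or "mutant",
                    replicate=int(row.get("replicate", "") or 1),
                )
            )
        except (PlateError, ValueError) as exc:
            raise PlateError(f"{path.name} row {i + 2}: {exc}") from exc
    return PlateLayout(plate_id=plate_id or path.stem, wells=wells)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {
            "well": w.well,
            "role": w.role,
            "compound_id": w.compound_id or "",
            "dose_um": "" if w.dose_um is None else w.dose_um,
            "genotype": w.genotype,
            "replicate": w.replicate,
        }
        for w in layout.wells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# field images


@dataclass
class FieldImage:
    """One imaged visual field: three co-registered intensity grids.

    ``channels`` is a (3, H, W) non-negative integer array in the fixed order
    nuclear stain, green (GFP-LC3), red (Lysotracker).
    """

    well: str
    field_index: int
    channels: np.ndarray
    bit_depth: int = 16
    um_per_pixel: float = 1.0

    def __post_init__(self):
        self.well = normalize_well(self.well)
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(
                f"field {self.well}/{self.field_index}: expected 3 channels, "
                f"got array of shape {self.channels.shape}"
            )
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.channels.min() < 0 or self.channels.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"field {self.well}/{self.field_index}: intensities outside "
                f"[0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def nuclear(self) -> np.ndarray:
        return self.channels[0]

    @property
    def green(self) -> np.ndarray:
        return self.channels[1]

    @property
    def red(self) -> np.ndarray:
        return self.channels[2]


def write_field_image(field_image: FieldImage, path: str | Path) -> None:
    """Write a field as a 3-page TIFF (lossless, one page per channel)."""
    tifffile.imwrite(
        str(path),
        field_image.channels.astype(np.uint16),
        photometric="minisblack",
    )


def read_field_image(
    path: str | Path,
    um_per_pixel: float,
    well: str | None = None,
    field_index: int = 0,
) -> FieldImage:
    """Read a 3-page (or 3-plane) TIFF as a :class:`FieldImage`.

    Well and field identity default to a ``<well>_f<index>`` file-name
    convention when not given explicitly.
    """
    path = Path(path)
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 3 and arr.shape[0] != 3:
        arr = np.moveaxis(arr, -1, 0)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"{path.name}: expected 3 channels, got shape {arr.shape}")
    if well is None:
        m = re.match(r"^([A-Pa-p]\d{1,2})_f(\d+)", path.stem)
        if m:
            well, field_index = m.group(1), int(m.group(2))
        else:
            raise ValueError(f"{path.name}: well identity not given and not in file name")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return FieldImage(
        well=well,
        field_index=field_index,
        channels=arr,
        bit_depth=bit_depth,
        um_per_pixel=um_per_pixel,
    )


# ---------------------------------------------------------------------------
# readouts and results

EXCLUSION_FLAGS = frozenset(
    {"out_of_focus", "phenol_red", "toxic", "marginally_toxic", "excluded"}
)


@dataclass
class WellReadout:
    """Aggregated per-well metrics; ``None`` stands for NA (excluded)."""

    well: str
    pct_positive: float | None = None
    nuclei_count: int = 0
    mean_lyso_nuc_distance: float | None = None
    red_background: float = 0.0
    focus_scores: tuple[float, ...] = ()
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.well = normalize_well(self.well)
        if self.pct_positive is not None and not 0 <= self.pct_positive <= 100:
            raise ValueError(f"well {self.well}: pct_positive outside [0, 100]")
        if self.nuclei_count < 0:
            raise ValueError(f"well {self.well}: negative nuclei_count")
        unknown = set(self.qc_flags) - EXCLUSION_FLAGS
        if unknown:
            raise ValueError(f"well {self.well}: unknown qc flags {sorted(unknown)}")

    @property
    def excluded(self) -> bool:
        return "excluded" in self.qc_flags


@dataclass
class CompoundResult:
    """Per-unique-compound screen outcome."""

    compound_id: str
    mean_z: float | None
    per_well_z: list[float] = field(default_factory=list)
    per_well_pct: list[float] = field(default_factory=list)
    hit_class: str = "none"  # suppressor | enhancer | none
    toxicity: str = "none"  # toxic | marginal | none
    distance_fold_change: float | None = None
    restored: bool = False


def _na(value) -> str:
    return "NA" if value is None else f"{value:.6g}"


def write_results(
    readouts: Sequence[WellReadout],
    results: Sequence[CompoundResult],
    path: str | Path,
) -> tuple[Path, Path]:
    """Write the well-level and compound-level result tables.

    ``path`` is a directory; ``wells.csv`` and ``compounds.csv`` are written
    inside it.  Excluded wells serialize pct_positive and distance as "NA".
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wells_path, compounds_path = path / "wells.csv", path / "compounds.csv"

    well_rows = [
        {
            "well": r.well,
            "pct_positive": _na(r.pct_positive),
            "nuclei_count": r.nuclei_count,
            "mean_lyso_nuc_distance": _na(r.mean_lyso_nuc_distance),
            "red_background": f"{r.red_background:.6g}",
            "focus_scores": ";".join(f"{s:.6g}" for s in r.focus_scores),
            "qc_flags": ";".join(sorted(r.qc_flags)),
        }
        for r in sorted(readouts, key=lambda r: r.well)
    ]
    cols = [
        "well",
        "pct_positive",
        "nuclei_count",
        "mean_lyso_nuc_distance",
        "red_background",
        "focus_scores",
        "qc_flags",
    ]
    pd.DataFrame(well_rows, columns=cols).to_csv(wells_path, index=False)

    comp_rows = [
        {
            "compound_id": c.compound_id,
            "mean_z": _na(c.mean_z),
            "per_well_z": ";".join(f"{z:.6g}" for z in c.per_well_z),
            "per_well_pct": ";".join(f"{p:.6g}" for p in c.per_well_pct),
            "hit_class": c.hit_class,
            "toxicity": c.toxicity,
            "distance_fold_change": _na(c.distance_fold_change),
            "restored": c.restored,
        }
        for c in sorted(results, key=lambda c: c.compound_id)
    ]
    ccols = [
        "compound_id",
        "mean_z",
        "per_well_z",
        "per_well_pct",
        "hit_class",
        "toxicity",
        "distance_fold_change",
        "restored",
    ]
    pd.DataFrame(comp_rows, columns=ccols).to_csv(compounds_path, index=False)
    return wells_path, compounds_path


def _parse_na(value: str) -> float | None:
    return None if value == "NA" or value == "" else float(value)


def read_results(path: str | Path) -> tuple[list[WellReadout], list[CompoundResult]]:
    """Read back tables written by :func:`write_results`."""
    path = Path(path)
    wells_df = pd.read_csv(path / "wells.csv", dtype=str, keep_default_na=False)
    comp_df = pd.read_csv(path / "compounds.csv", dtype=str, keep_default_na=False)
    readouts = [
        WellReadout(
            well=row["well"],
            pct_positive=_parse_na(row["pct_positive"]),
            nuclei_count=int(row["nuclei_count"]),
            mean_lyso_nuc_distance=_parse_na(row["mean_lyso_nuc_distance"]),
            red_background=float(row["red_background"]),
            focus_scores=tuple(
                float(s) for s in row["focus_scores"].split(";") if s
            ),
            qc_flags=set(f for f in row["qc_flags"].split(";") if f),
        )
        for _, row in wells_df.iterrows()
    ]
    results = [
        CompoundResult(
            compound_id=row["compound_id"],
            mean_z=_parse_na(row["mean_z"]),
            per_well_z=[float(z) for z in row["per_well_z"].split(";") if z],
            per_well_pct=[float(p) for p in row["per_well_pct"].split(";") if p],
            hit_class=row["hit_class"],
            toxicity=row["toxicity"],
            distance_fold_change=_parse_na(row["distance_fold_change"]),
            restored=row["restored"] == "True",
        )
        for _, row in comp_df.iterrows()
    ]
    return readouts, results
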
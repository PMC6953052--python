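"""Screen-level statistics.

The primary readout per well is the percentage of GFP-LC3-positive cells
(cells with >= 5 green puncta).  A compound well's activity is expressed as

    z = (x - mu) / (2 sigma)

where mu and sigma are the mean and SD of the plate's DMSO wells, so that
the screen's hit cutoffs of +/- 1.5 correspond to three conventional
standard deviations.  Compounds are screened in duplicate wells; the
per-compound score is the mean of the replicate-well z-scores.  The
secondary readout is the mean lysosome-to-nucleus distance expressed as a
fold-ratio of the DMSO control; a fold change of 0.85 or lower restores the
wild-type positioning (wild-type : mutant DMSO ratio = 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .plate_model import CompoundResult, PlateLayout, WellReadout
from .qc import classify_toxicity, dmso_nuclei_reference

SUPPRESSOR_CUT = -1.5
ENHANCER_CUT = 1.5
RESTORATION_CUT = 0.85


@dataclass(frozen=True)
class ControlSummary:
    """DMSO-well summary statistics for one genotype."""

    mu_pct: float
    sigma_pct: float
    mu_dist: float | None = None
    genotype: str = "mutant"

    def __post_init__(self):
        if self.sigma_pct < 0:
            raise ValueError("sigma_pct must be non-negative")
        if not 0.0 <= self.mu_pct <= 100.0:
            raise ValueError("mu_pct must lie in [0, 100]")


def zscore(x: float, mu: float, sigma: float) -> float:
    """Screen z-score: (x - mu) / (2 sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (x - mu) / (2.0 * sigma)


def zprime(mu_pos: float, sigma_pos: float, mu_neg: float, sigma_neg: float) -> float:
    """Assay-quality statistic Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg|."""
    if mu_pos == mu_neg:
        raise ValueError("control means must differ")
    return 1.0 - 3.0 * (sigma_pos + sigma_neg) / abs(mu_pos - mu_neg)


def distance_fold_change(mean_dist: float, dmso_mean_dist: float) -> float:
    """Treated mean lysosome-to-nucleus distance as a fold-ratio of DMSO."""
    if dmso_mean_dist <= 0:
        raise ValueError("dmso_mean_dist must be positive")
    return mean_dist / dmso_mean_dist


def classify_restoration(fold_change: float, wildtype_ratio: float = RESTORATION_CUT) -> bool:
    """Restored iff the fold change is at the wild-type ratio or better (<=)."""
    return fold_change <= wildtype_ratio


def control_summary(
    readouts: Sequence[WellReadout], layout: PlateLayout, genotype: str = "mutant"
) -> ControlSummary:
    """Per-plate DMSO summary (mean/SD of %-positive, mean distance) over
    non-excluded DMSO wells of the given genotype."""
    dmso = {w.well for w in layout.dmso_wells(genotype)}
    if not dmso:
        raise ValueError(f"no {genotype} DMSO wells on plate {layout.plate_id}")
    vals = [
        r.pct_positive
        for r in readouts
        if r.well in dmso and not r.excluded and r.pct_positive is not None
    ]
    dists = [
        r.mean_lyso_nuc_distance
        for r in readouts
        if r.well in dmso and not r.excluded and r.mean_lyso_nuc_distance is not None
    ]
    if len(vals) < 2:
        raise ValueError("need at least 2 non-excluded DMSO wells for a control summary")
    return ControlSummary(
        mu_pct=float(np.mean(vals)),
        sigma_pct=float(np.std(vals, ddof=1)),
        mu_dist=float(np.mean(dists)) if dists else None,
        genotype=genotype,
    )


def aggregate_compounds(
    readouts: Sequence[WellReadout],
    layout: PlateLayout,
    control: ControlSummary | None = None,
    nuclei_reference: tuple[float, float] | None = None,
) -> list[CompoundResult]:
    """Aggregate replicate wells into one result per unique compound.

    Excluded wells contribute nothing; a compound with all wells excluded
    yields an NA result.  The compound z-score is the mean of replicate-well
    z-scores; toxicity is classified from the mean nuclei count of the
    contributing wells against the plate's DMSO reference.
    """
    if control is None:
        control = control_summary(readouts, layout)
    if nuclei_reference is None:
        nuclei_reference = dmso_nuclei_reference(list(readouts), layout)
    by_well = {r.well: r for r in readouts}
    mu_n, sd_n = nuclei_reference

    results = []
    for compound in layout.compound_ids():
        wells = [w for w in layout.compound_wells() if w.compound_id == compound]
        usable = []
        for w in wells:
            r = by_well.get(w.well)
            if r is None:
                raise ValueError(f"compound {compound}: no readout for well {w.well}")
            if not r.excluded and r.pct_positive is not None:
                usable.append(r)
        if not usable:
            results.append(CompoundResult(compound_id=compound, mean_z=None))
            continue
        per_pct = [r.pct_positive for r in usable]
        per_z = [zscore(p, control.mu_pct, control.sigma_pct) for p in per_pct]
        dists = [
            r.mean_lyso_nuc_distance for r in usable if r.mean_lyso_nuc_distance is not None
        ]
        fold = None
        restored = False
        if dists and control.mu_dist:
            fold = distance_fold_change(float(np.mean(dists)), control.mu_dist)
            restored = classify_restoration(fold)
        tox = classify_toxicity(float(np.mean([r.nuclei_count for r in usable])), mu_n, sd_n)
        results.append(
            CompoundResult(
                compound_id=compound,
                mean_z=float(np.mean(per_z)),
                per_well_z=[float(z) for z in per_z],
                per_well_pct=[float(p) for p in per_pct],
                toxicity=tox,
                distance_fold_change=fold,
                restored=restored,
            )
        )
    return results


def call_hits(
    results: Sequence[CompoundResult],
    suppressor_cut: float = SUPPRESSOR_CUT,
    enhancer_cut: float = ENHANCER_CUT,
) -> list[CompoundResult]:
    """Set hit_class per compound: suppressor iff mean_z <= suppressor_cut,
    enhancer iff mean_z >= enhancer_cut (inclusive bounds), else none.
    NA compounds are 'none'."""
    out = []
    for r in results:
        if r.mean_z is None:
            cls = "none"
        elif r.mean_z <= suppressor_cut:
            cls = "suppressor"
        elif r.mean_z >= enhancer_cut:
            cls = "enhancer"
        else:
            cls = "none"
        out.append(replace(r, hit_class=cls))
    return out


def cross_screen_rank_correlation(
    shared_scores: Sequence[tuple[float, float]]
) -> float:
    """Pearson correlation of the within-screen rank vectors of the
    compounds shared between two screens (average ranks for ties)."""
    if len(shared_scores) < 3:
        raise ValueError("need at least 3 shared compounds")
    a = np.array([s[0] for s in shared_scores], float)
    b = np.array([s[1] for s in shared_scores], float)
    ra = sstats.rankdata(a, method="average")
    rb = sstats.rankdata(b, method="average")
    return float(np.corrcoef(ra, rb)[0, 1])


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseResponse:
    """Replicate-averaged dose-response profile for one compound."""

    compound_id: str
    doses_um: np.ndarray
    pct_positive: np.ndarray  # replicate means per dose
    pct_sd: np.ndarray  # replicate SDs per dose
    nuclei_count: np.ndarray
    shape_class: str | None = None

    def __post_init__(self):
        self.doses_um = np.asarray(self.doses_um, float)
        self.pct_positive = np.asarray(self.pct_positive, float)
        self.pct_sd = np.asarray(self.pct_sd, float)
        self.nuclei_count = np.asarray(self.nuclei_count, float)
        n = self.doses_um.size
        if not all(arr.size == n for arr in (self.pct_positive, self.pct_sd, self.nuclei_count)):
            raise ValueError("dose-response arrays are not aligned")
        if n and np.any(np.diff(self.doses_um) <= 0):
            raise ValueError("doses must be strictly increasing")


def classify_dose_response(
    curve: DoseResponse,
    toxicity_reference: tuple[float, float],
    rebound_margin: float | None = None,
    noise_tolerance: float | None = None,
) -> str:
    """Classify a dose-response curve.

    * ``biphasic``: the %-positive minimum lies at an interior dose, the
      top-dose %-positive rebounds above that minimum by more than
      ``rebound_margin``, and the top dose is toxic or marginally toxic;
    * ``monotone_decreasing``: non-increasing within the noise tolerance,
      with no toxicity at any dose;
    * ``flat``: the %-positive range is below the noise tolerance;
    * ``other``: anything else.

    The noise tolerance defaults to the pooled replicate SD; the rebound
    margin defaults to twice that.
    """
    if curve.doses_um.size < 4:
        raise ValueError("need at least 4 doses to classify a dose-response curve")
    pct = curve.pct_positive
    tol = noise_tolerance
    if tol is None:
        pooled = float(np.sqrt(np.mean(curve.pct_sd**2))) if curve.pct_sd.size else 0.0
        tol = pooled if pooled > 0 else 1.0
    margin = rebound_margin if rebound_margin is not None else 2.0 * tol

    mu_n, sd_n = toxicity_reference
    tiers = [classify_toxicity(n, mu_n, sd_n) for n in curve.nuclei_count]

    i_min = int(np.argmin(pct))
    interior_min = 0 < i_min < pct.size - 1
    rebound = pct[-1] - pct[i_min]
    if interior_min and rebound > margin and tiers[-1] in ("toxic", "marginal"):
        return "biphasic"
    if float(pct.max() - pct.min()) < tol:
        return "flat"
    non_increasing = bool(np.all(np.diff(pct) <= tol))
    decreasing_overall = pct[-1] < pct[0] - tol
    if non_increasing and decreasing_overall and all(t == "none" for t in tiers):
        return "monotone_decreasing"
    return "other"
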
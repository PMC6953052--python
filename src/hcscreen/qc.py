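"""Field- and well-level quality control.

Three classifiers are applied per well:

* a blur-comparison focus score per field (out-of-focus fields are excluded;
  a well with all fields out of focus is excluded entirely),
* a phenol-red contamination check on the well's red fluorescence level
  (contaminated wells are excluded),
* a nuclei-count toxicity tier relative to the plate's own DMSO wells
  (annotates but does not exclude).

Boundary conventions are strict: a focus score must exceed the cutoff to be
out of focus, a red level must exceed 10,000 a.u. to be contaminated, and a
nuclei count must fall strictly below mean - 2 SD to be toxic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .plate_model import PlateLayout, WellReadout


@dataclass
class QcThresholds:
    focus_cutoff: float = 0.49
    focus_kernel_size: int = 5
    focus_method: str = "bounded"  # bounded symmetric ratio; "ratio" = raw mean ratio
    red_contamination_cutoff: float = 10000.0
    typical_red_range: tuple[float, float] = (6000.0, 9000.0)

    def __post_init__(self):
        if self.focus_cutoff <= 0:
            raise ValueError("focus_cutoff must be positive")
        if self.red_contamination_cutoff <= 0:
            raise ValueError("red_contamination_cutoff must be positive")


def focus_score(
    image: np.ndarray,
    kernel_size: int = 5,
    method: str = "bounded",
    floor_fraction: float = 0.02,
) -> float:
    """Blur-comparison focus score: smooth with a normalized kernel_size x
    kernel_size mean kernel, then average the per-pixel similarity between
    the smoothed and original images.

    An out-of-focus image is already smooth, so smoothing changes it little
    and the score is high; a sharp image is changed a lot and scores low.

    ``method="bounded"`` (default) uses min/max of the two images per pixel,
    a symmetric ratio in [0, 1]; ``method="ratio"`` is the raw mean
    smoothed/original ratio.  Pixels where both images fall below
    ``floor_fraction`` of the image maximum are ignored, which also makes
    the score invariant to multiplying the image by a positive constant.

    A constant-zero image is maximally featureless and scores 1.0 (warning).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("focus_score: empty image")
    peak = float(img.max())
    if peak <= 0:
        warnings.warn("focus_score: constant-zero image, returning 1.0")
        return 1.0
    smoothed = ndi.uniform_filter(img, size=kernel_size, mode="reflect")
    floor = floor_fraction * peak
    admissible = (img > floor) | (smoothed > floor)
    if not admissible.any():
        return 1.0
    tiny = 1e-12 * peak
    if method == "bounded":
        lo = np.minimum(smoothed, img)
        hi = np.maximum(smoothed, img)
        ratio = lo / np.maximum(hi, tiny)
    elif method == "ratio":
        ratio = smoothed / np.maximum(img, tiny)
    else:
        raise ValueError(f"unknown focus-score method {method!r}")
    return float(ratio[admissible].mean())


def classify_focus(score: float, cutoff: float = 0.49) -> str:
    """'out_of_focus' iff the score is strictly above the cutoff."""
    return "out_of_focus" if score > cutoff else "in_focus"


def detect_phenol_red(red_background: float, cutoff: float = 10000.0) -> str:
    """'contaminated' iff the well's red fluorescence is strictly above the
    cutoff (typical clean wells read 6000-9000 a.u.)."""
    return "contaminated" if red_background > cutoff else "clean"


def classify_toxicity(nuclei_count: float, mu_dmso: float, sigma_dmso: float) -> str:
    """Toxicity tier from the nuclei count relative to the DMSO reference:
    'toxic' below mean - 2 SD, 'marginal' in [mean - 2 SD, mean - SD),
    'none' otherwise.  The three classes partition the count axis."""
    if sigma_dmso < 0:
        raise ValueError("sigma_dmso must be non-negative")
    if nuclei_count < mu_dmso - 2.0 * sigma_dmso:
        return "toxic"
    if nuclei_count < mu_dmso - sigma_dmso:
        return "marginal"
    return "none"


def dmso_nuclei_reference(
    readouts: list[WellReadout], layout: PlateLayout
) -> tuple[float, float]:
    """(mean, SD) of nuclei counts over the plate's non-excluded DMSO wells."""
    dmso = {w.well for w in layout.dmso_wells()}
    if not dmso:
        raise ValueError("no DMSO wells on the plate: toxicity reference undefined")
    counts = [r.nuclei_count for r in readouts if r.well in dmso and not r.excluded]
    if not counts:
        raise ValueError("all DMSO wells excluded: toxicity reference undefined")
    return float(np.mean(counts)), float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0


def apply_well_qc(
    readouts: list[WellReadout],
    layout: PlateLayout,
    thresholds: QcThresholds | None = None,
) -> list[WellReadout]:
    """Return readouts with qc_flags set (pure function; idempotent).

    A well is excluded when all its fields are out of focus or when it is
    phenol-red contaminated; excluded wells report pct_positive and distance
    as NA.  Toxicity annotates but does not exclude.
    """
    t = thresholds or QcThresholds()
    flagged: list[WellReadout] = []
    for r in readouts:
        flags: set[str] = set()
        if r.focus_scores and all(
            classify_focus(s, t.focus_cutoff) == "out_of_focus" for s in r.focus_scores
        ):
            flags.add("out_of_focus")
        if detect_phenol_red(r.red_background, t.red_contamination_cutoff) == "contaminated":
            flags.add("phenol_red")
        if flags:
            flags.add("excluded")
        flagged.append(replace(r, qc_flags=flags))

    mu, sigma = dmso_nuclei_reference(flagged, layout)
    out = []
    for r in flagged:
        flags = set(r.qc_flags)
        tier = classify_toxicity(r.nuclei_count, mu, sigma)
        if tier == "toxic":
            flags.add("toxic")
        elif tier == "marginal":
            flags.add("marginally_toxic")
        excluded = "excluded" in flags
        out.append(
            replace(
                r,
                qc_flags=flags,
                pct_positive=None if excluded else r.pct_positive,
                mean_lyso_nuc_distance=None if excluded else r.mean_lyso_nuc_distance,
            )
        )
    return out
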
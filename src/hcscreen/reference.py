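"""Published reference values for the GFP-LC3 autophagy screen.

The hit tables bundled under ``data/`` are the primary-screen results of the
high-content screen this package re-implements: the phenotype-suppressor
table (compounds with mean z <= -1.5) and the phenotype-enhancer table
(mean z >= 1.5), with per-well %-positive values (a bracketed duplicate-well
value in the ``*_dup`` columns where a compound appeared twice in the hit
list) and lysosome-to-nucleus distance fold changes versus DMSO.

The control summaries below are the screen's DMSO baselines.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screen_stats import ControlSummary

#: DMSO control summary for the CLN3-mutant line: 42.5 +/- 8.3 % GFP-LC3-positive
#: cells, mean lysosome-to-nucleus distance 4.65 um.
MUTANT_DMSO = ControlSummary(mu_pct=42.5, sigma_pct=8.3, mu_dist=4.65, genotype="mutant")

#: DMSO control summary for the wild-type line: 5.2 +/- 1.6 %, distance 3.96 um.
WILDTYPE_DMSO = ControlSummary(mu_pct=5.2, sigma_pct=1.6, mu_dist=3.96, genotype="wildtype")

#: nuclei count per mutant DMSO well (mean, SD)
DMSO_NUCLEI = (322.0, 71.0)

#: wild-type : mutant distance ratio defining restored lysosome positioning
WILDTYPE_DISTANCE_RATIO = 0.85


def _load(name: str) -> pd.DataFrame:
    with resources.files("hcscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_suppressor_table() -> pd.DataFrame:
    """Primary-screen phenotype-suppressor hit table (29 unique compounds)."""
    return _load("primary_screen_suppressors.csv")


def load_enhancer_table() -> pd.DataFrame:
    """Primary-screen phenotype-enhancer hit table (69 unique compounds)."""
    return _load("primary_screen_enhancers.csv")
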
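"""Bundled example data: the two-region Cheddar pink survey.

The package ships the published per-population values of a comparative
survey of *Dianthus gratianopolitanus* (Cheddar pink): 20 populations in
two regions (Swiss Jura, lower isolation; Franconian Jura, higher
isolation), with habitat area, individual counts, cushion size and
density, flower and capsule counts, and dominant-marker diversity
values, plus the published AMOVA degrees of freedom and sums of squares
with the per-population sample sizes.  Raw genotypes, dish counts and
coordinates were not released with the survey, so those stages of the
pipeline run on synthetic data instead (see :mod:`isopop.simulate`).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files("isopop") / "data"


def load_cheddar_pink_traits() -> pd.DataFrame:
    """Per-population trait table of the two-region survey.

    Columns: region, HA (habitat area m^2), NI (individuals), PD
    (cushions per m^2, as printed), CS (cushion size cm^2), CD (shoots
    per m^2), NF (flowers), NC (capsules), He, I, PL (diversity values).
    Indexed by population name.
    """
    with resources.as_file(_DATA / "cheddar_pink_traits.tsv") as path:
        return pd.read_csv(path, sep="\t", index_col="population")


def load_cheddar_pink_amova() -> dict:
    """Published AMOVA (df, SS) summaries and per-population sample sizes.

    Returns a dict with ``sample_sizes`` (region -> per-population sizes)
    and ``analyses`` (name -> {"strata": [[stratum, df, SS], ...]}) for
    the three-level analysis, the one-level analysis over all
    populations, and the two regional one-level analyses.
    """
    with resources.as_file(_DATA / "cheddar_pink_amova.json") as path:
        return json.loads(path.read_text())
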
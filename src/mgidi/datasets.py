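"""Published summary statistics of the reference wheat drought trial.

The reference study evaluated 18 spring wheat genotypes under irrigated
control and 30-day drought stress (2 environments, 3 blocks) for 12
agronomic, physiological and biochemical traits.  The raw plot data are not
redistributed here; what the study publishes — and what this module embeds —
are its summary tables: per-trait genetic parameters (mean-basis
heritability, genotypic and residual coefficients of variation) and the
selection-gain table (all-genotype mean Xo and selected-fraction mean Xs per
trait, with the factor each trait loaded on).

These serve two purposes: they are the calibration targets for the synthetic
trial preset, and they are direct inputs to the arithmetic layer (selection
differentials, coefficient-of-variation ratios, selection accuracy), whose
outputs can be checked against the study's printed values.
"""

from __future__ import annotations

import pandas as pd

from .trial import TraitSpec

__all__ = [
    "WHEAT_TRAITS",
    "wheat_trait_specs",
    "wheat_genetic_summary",
    "wheat_selection_summary",
    "PROLINE_RANGE_CONTROL_TO_DROUGHT",
]

#: trait -> (direction, units). Lower values are desired only for sodium and
#: the two stomatal-conductance readings (water-saving under drought).
WHEAT_TRAITS: dict[str, tuple[str, str]] = {
    "GY": ("increase", "kg/ha"),
    "HLW": ("increase", "kg/hL"),
    "AI": ("increase", "umol CO2 m-2 s-1"),
    "AF": ("increase", "umol CO2 m-2 s-1"),
    "gsI": ("decrease", "mol H2O m-2 s-1"),
    "gsF": ("decrease", "mol H2O m-2 s-1"),
    "pc": ("increase", "ug/g"),
    "Na": ("decrease", "mg/g"),
    "K": ("increase", "mg/g"),
    "TPC": ("increase", "mg GAE/g"),
    "ABTS": ("increase", "mM TEAC/g"),
    "FRAP": ("increase", "mM Fe2+/g"),
}

# Published genetic-parameter summary: mean-basis heritability h2,
# genotypic (CVg) and residual (CVr) coefficients of variation in percent.
_GENETIC_SUMMARY = {
    #        h2     CVg     CVr
    "GY": (0.505, 7.845, 7.414),
    "HLW": (0.782, 1.984, 2.041),
    "AI": (0.289, 3.464, 13.300),
    "AF": (0.615, 10.296, 16.357),
    "gsI": (0.313, 7.213, 26.165),
    "gsF": (0.224, 5.348, 16.003),
    "pc": (0.850, 56.604, 5.876),
    "Na": (0.029, 1.759, 4.583),
    "K": (0.352, 14.753, 3.924),
    "TPC": (0.810, 6.649, 4.660),
    "ABTS": (0.524, 10.840, 6.502),
    "FRAP": (0.296, 7.867, 5.502),
}

# Published selection-gain inputs: factor membership, overall mean Xo and
# mean of the selected 25% (Xs), on the original trait scale.
_SELECTION_SUMMARY = {
    #        factor  Xo        Xs
    "TPC": ("FA1", 25.223, 25.425),
    "ABTS": ("FA1", 67.431, 68.172),
    "K": ("FA1", 28.376, 28.363),
    "Na": ("FA1", 1.960, 1.957),
    "AI": ("FA1", 17.651, 17.664),
    "FRAP": ("FA2", 70.589, 69.539),
    "gsI": ("FA2", 0.453, 0.442),
    "gsF": ("FA2", 0.407, 0.400),
    "pc": ("FA3", 902.279, 1117.310),
    "AF": ("FA3", 14.451, 14.148),
    "GY": ("FA4", 4067.728, 4233.464),
    "HLW": ("FA4", 73.999, 73.626),
}

#: Proline content (ug/g) rose from 163.86 under control to 1574.86 under
#: drought in the most responsive comparison — the headline osmotic response.
PROLINE_RANGE_CONTROL_TO_DROUGHT = (163.86, 1574.86)


def wheat_trait_specs() -> list[TraitSpec]:
    """Trait specs (name, selection direction, units) of the reference trial."""
    return [
        TraitSpec(name=n, direction=d, units=u) for n, (d, u) in WHEAT_TRAITS.items()
    ]


def wheat_genetic_summary() -> pd.DataFrame:
    """Per-trait h2 (mean basis), CVg% and CVr% of the reference trial."""
    df = pd.DataFrame.from_dict(
        _GENETIC_SUMMARY, orient="index", columns=["h2", "cvg", "cvr"]
    )
    df.index.name = "trait"
    return df.reset_index()


def wheat_selection_summary() -> pd.DataFrame:
    """Per-trait factor label, overall mean (Xo) and selected mean (Xs)."""
    df = pd.DataFrame.from_dict(
        _SELECTION_SUMMARY, orient="index", columns=["factor", "Xo", "Xs"]
    )
    df.index.name = "trait"
    df["sense"] = [WHEAT_TRAITS[t][0] for t in df.index]
    return df.reset_index()
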
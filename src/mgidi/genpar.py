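"""Genetic parameters derived from a fitted trait model.

From the variance components (sigma2_g, sigma2_ge, sigma2_e) of a trial with
e environments and b blocks:

* broad-sense heritability        h2 = vg / (vg + vge + ve)        (plot basis)
* mean-basis heritability         h2 = vg / (vg + vge/e + ve/(e*b))
* selection accuracy              h  = sqrt(reported h2)
* genotype-environment correlation rge = vg / (vg + vge)
  (alternative definition vge / (vge + ve) available)
* genotypic / residual CV         CVg = 100*sqrt(vg)/mu,  CVr = 100*sqrt(ve)/mu
* their ratio                     CVg/CVr

The mean-basis heritability is the headline variant (its square root
reproduces reported selection accuracies); both variants are always
computed.  All quantities are invariant to rescaling the trait by a
positive constant except the CVs, which are invariant too because the mean
rescales with the standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .reml import TraitFit

__all__ = ["GeneticParameters", "compute_parameters", "parameter_table"]


@dataclass
class GeneticParameters:
    trait: str
    h2_broad: float
    h2_mean: float
    accuracy: float
    rge: float
    cvg: float
    cvr: float
    cv_ratio: float
    heritability_variant: str
    degenerate: bool = False


def compute_parameters(
    fit: TraitFit,
    *,
    heritability: Literal["mean", "broad"] = "mean",
    rge_variant: Literal["genotypic", "interaction"] = "genotypic",
) -> GeneticParameters:
    """Compute the genetic-parameter suite for one trait.

    ``heritability`` selects which variant the reported accuracy is the
    square root of.  ``rge_variant='genotypic'`` is vg/(vg+vge);
    ``'interaction'`` is vge/(vge+ve).
    """
    vg, vge, ve = fit.var_g, fit.var_ge, fit.var_e
    e, b = fit.design.e, fit.design.b
    mu = fit.grand_mean
    if mu == 0:
        raise ValueError(
            f"trait {fit.trait!r}: coefficient of variation undefined at zero grand mean"
        )
    total = vg + vge + ve
    if total == 0:
        return GeneticParameters(
            trait=fit.trait,
            h2_broad=0.0,
            h2_mean=0.0,
            accuracy=0.0,
            rge=0.0,
            cvg=0.0,
            cvr=0.0,
            cv_ratio=math.nan,
            heritability_variant=heritability,
            degenerate=True,
        )
    h2_broad = vg / total
    h2_mean = vg / (vg + vge / e + ve / (e * b))
    reported = h2_mean if heritability == "mean" else h2_broad
    if rge_variant == "genotypic":
        rge = vg / (vg + vge) if (vg + vge) > 0 else 0.0
    elif rge_variant == "interaction":
        rge = vge / (vge + ve) if (vge + ve) > 0 else 0.0
    else:
        raise ValueError(f"unknown rge variant {rge_variant!r}")
    cvg = 100.0 * math.sqrt(vg) / abs(mu)
    cvr = 100.0 * math.sqrt(ve) / abs(mu)
    return GeneticParameters(
        trait=fit.trait,
        h2_broad=h2_broad,
        h2_mean=h2_mean,
        accuracy=math.sqrt(reported),
        rge=rge,
        cvg=cvg,
        cvr=cvr,
        cv_ratio=cvg / cvr if cvr > 0 else math.inf,
        heritability_variant=heritability,
    )


def parameter_table(fits: dict[str, TraitFit], **kwargs) -> pd.DataFrame:
    """One row per trait: h2 (both bases), accuracy, rge, CVg, CVr, ratio."""
    rows = []
    for trait, fit in fits.items():
        p = compute_parameters(fit, **kwargs)
        rows.append(
            {
                "trait": trait,
                "h2_broad": p.h2_broad,
                "h2_mean": p.h2_mean,
                "accuracy": p.accuracy,
                "rge": p.rge,
                "cvg": p.cvg,
                "cvr": p.cvr,
                "cv_ratio": p.cv_ratio,
            }
        )
    return pd.DataFrame(rows)
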
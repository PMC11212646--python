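"""Variance components, heritabilities and Baker's ratio per trait.

Method-of-moments estimates from the entry-mean-basis combining-ability mean
squares, read under the fixed-effects model where each component summarises
the quadratic spread of the corresponding true effects:

    sigma2_e   = MS_residual(plot)/r          (error variance of an entry mean)
    sigma2_gca = (MS_GCA(mean)  - sigma2_e)/(2p)
    sigma2_sca =  MS_SCA(mean)  - sigma2_e
    sigma2_rca = (MS_REC(mean)  - sigma2_e)/2

Derived parameters use the standard diallel conventions: additive variance
sigma2_A = 2 sigma2_gca, dominance variance sigma2_D = sigma2_sca, phenotypic
variance sigma2_P = sigma2_A + sigma2_D + sigma2_rca + sigma2_e/r, broad- and
narrow-sense heritabilities as percentages of sigma2_P, the additive-to-
dominance ratio, and Baker's ratio 2 sigma2_gca/(2 sigma2_gca + sigma2_sca)
(close to 1: hybrid performance is predictable from parental GCA alone).
Negative moment estimates are truncated to zero and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .data import DiallelError
from .griffing import AnovaTable


@dataclass
class VarianceComponents:
    var_gca: float
    var_sca: float
    var_rca: float
    var_err: float
    truncated: tuple[str, ...] = ()


@dataclass
class GeneticParams:
    """Per-trait genetic parameters in the conventional reporting order."""

    trait: str
    var_gca: float
    var_sca: float
    var_rca: float
    var_P: float
    var_err: float
    var_A: float
    var_D: float
    ratio_AD: float
    H2: float  # broad-sense heritability, percent
    h2: float  # narrow-sense heritability, percent
    baker: float
    n_reps: int
    truncated: tuple[str, ...] = field(default=())


def variance_components(anova: AnovaTable, p: int, r: int) -> VarianceComponents:
    """Moment estimators from a mean-basis combining-ability ANOVA table."""
    if anova.basis != "mean":
        raise DiallelError("variance_components requires a mean-basis ANOVA table")
    tab = anova.table.set_index("source")
    for src in ("GCA", "SCA", "Reciprocal", "Residual"):
        if src not in tab.index:
            raise DiallelError(f"ANOVA table is missing the {src!r} row")
    sigma2_e = float(tab.loc["Residual", "MS"])  # already MS_resid(plot)/r
    raw = {
        "gca": (float(tab.loc["GCA", "MS"]) - sigma2_e) / (2 * p),
        "sca": float(tab.loc["SCA", "MS"]) - sigma2_e,
        "rca": (float(tab.loc["Reciprocal", "MS"]) - sigma2_e) / 2.0,
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(
        var_gca=clipped["gca"],
        var_sca=clipped["sca"],
        var_rca=clipped["rca"],
        var_err=sigma2_e,
        truncated=truncated,
    )


def derived_genetics(
    components: VarianceComponents | tuple[float, float, float, float],
    r: int,
    trait: str = "",
) -> GeneticParams:
    """Heritabilities, variance ratios and Baker's ratio from the components.

    ``components`` may be a VarianceComponents or a plain
    ``(sigma2_gca, sigma2_sca, sigma2_rca, sigma2_e)`` tuple, e.g. a published
    table row.
    """
    if isinstance(components, VarianceComponents):
        vg, vs, vr, ve = (
            components.var_gca,
            components.var_sca,
            components.var_rca,
            components.var_err,
        )
        truncated = components.truncated
    else:
        vg, vs, vr, ve = (float(v) for v in components)
        truncated = ()
    if min(vg, vs, vr, ve) < 0:
        raise DiallelError("variance components must be non-negative")

    var_A = 2.0 * vg
    var_D = vs
    var_P = var_A + var_D + vr + ve / r
    if var_P <= 0:
        h2 = math.nan
        H2 = math.nan
    else:
        H2 = 100.0 * (var_A + var_D) / var_P
        h2 = 100.0 * var_A / var_P
    ratio_AD = var_A / var_D if var_D > 0 else math.inf if var_A > 0 else math.nan
    denom = var_A + vs
    baker = var_A / denom if denom > 0 else 0.0

    return GeneticParams(
        trait=trait,
        var_gca=vg,
        var_sca=vs,
        var_rca=vr,
        var_P=var_P,
        var_err=ve,
        var_A=var_A,
        var_D=var_D,
        ratio_AD=ratio_AD,
        H2=H2,
        h2=h2,
        baker=baker,
        n_reps=r,
        truncated=truncated,
    )


def genetic_params_from_anova(anova: AnovaTable, p: int, r: int, trait: str = "") -> GeneticParams:
    """Convenience: variance_components followed by derived_genetics."""
    return derived_genetics(variance_components(anova, p, r), r, trait=trait)
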
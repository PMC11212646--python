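"""scikit-learn-style front end for the full diallel analysis.

``DiallelAnalysis`` is the one-stop estimator: ``fit`` takes the long-format
plot table (a pandas DataFrame, a PlotData, or a CSV path) and computes, per
trait, the RCBD ANOVA, the combining-ability partition, Griffing and
partitioned effects, variance components with heritabilities, heterosis and
the effect-performance correlation grid.  Results live in trailing-underscore
attributes keyed by trait, so the estimator composes with sklearn's
``clone``/``get_params`` machinery.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from sklearn.base import BaseEstimator

from .data import CrossMeanTable, DiallelError, PlotData, entry_means, load_plot_data
from .genetics import genetic_params_from_anova
from .griffing import combining_ability_anova, griffing_effects, rcbd_anova
from .heterosis import effect_performance_correlations, heterosis
from .partition import partitioned_effects


class DiallelAnalysis(BaseEstimator):
    """Griffing Method 1 (Model I) analysis with the directional partition.

    Parameters
    ----------
    traits : sequence of str, optional
        Traits to analyze; default: every trait column in the input.
    direction : mapping trait -> 'min' | 'max', optional
        Which parent counts as "better" for better-parent heterosis.
        Defaults to smaller-is-better for DTT/DTS, larger-is-better otherwise.
    alpha : (float, float)
        Significance levels for the one- and two-star flags.
    correlation_crosses : 'ordered' | 'straight'
        Hybrid set used in the correlation study: all p(p-1) directional
        hybrids, or only the i<j straight crosses.
    anova_basis : 'mean' | 'plot'
        Basis for the displayed combining-ability mean squares (both are
        computable from each other; F tests are identical).

    Attributes (after fit)
    ----------------------
    design_ : DiallelDesign
    means_, rcbd_anova_, ca_anova_, effects_, partitioned_, genetics_,
    heterosis_, correlations_ : dict keyed by trait name.
    """

    def __init__(
        self,
        traits=None,
        direction: Mapping[str, str] | None = None,
        alpha: tuple[float, float] = (0.05, 0.01),
        correlation_crosses: str = "ordered",
        anova_basis: str = "mean",
    ) -> None:
        self.traits = traits
        self.direction = direction
        self.alpha = alpha
        self.correlation_crosses = correlation_crosses
        self.anova_basis = anova_basis

    # -- sklearn plumbing --------------------------------------------------
    def _coerce(self, X) -> PlotData:
        if isinstance(X, PlotData):
            return X
        if isinstance(X, (str, Path)):
            return load_plot_data(X)
        if isinstance(X, pd.DataFrame):
            return PlotData.from_dataframe(X)
        raise DiallelError(f"cannot interpret input of type {type(X).__name__}")

    def fit(self, X, y=None) -> "DiallelAnalysis":
        """Run the full pipeline; X is a long plot table (df, PlotData or path)."""
        if not (0 < self.alpha[1] <= self.alpha[0] < 1):
            raise DiallelError(f"alpha levels must satisfy 0 < a2 <= a1 < 1, got {self.alpha}")
        data = self._coerce(X)
        design = data.design
        traits = list(self.traits) if self.traits is not None else list(design.traits)
        unknown = [t for t in traits if t not in design.traits]
        if unknown:
            raise DiallelError(f"traits not present in the data: {unknown}")
        if not traits:
            raise DiallelError("no traits to analyze")

        p, r = design.n_parents, design.n_reps
        self.design_ = design
        self.data_ = data
        self.means_: dict[str, CrossMeanTable] = {}
        self.rcbd_anova_ = {}
        self.ca_anova_ = {}
        self.effects_ = {}
        self.partitioned_ = {}
        self.genetics_ = {}
        self.heterosis_ = {}
        self.correlations_ = {}

        for trait in traits:
            means = entry_means(data, trait)
            rc = rcbd_anova(data, trait)
            ms_resid = float(rc.table.set_index("source").loc["Residual", "MS"])
            df_resid = int(rc.table.set_index("source").loc["Residual", "df"])
            ca = combining_ability_anova(means, ms_resid, r, df_residual=df_resid, basis="mean")
            eff = griffing_effects(means, ms_residual=ms_resid, r=r, alpha=self.alpha)
            part = partitioned_effects(means, ms_residual=ms_resid, r=r, alpha=self.alpha)
            gen = genetic_params_from_anova(ca, p, r, trait=trait)
            het = heterosis(means, self.direction)
            corr = effect_performance_correlations(
                means, eff, part, het, crosses=self.correlation_crosses, alpha=self.alpha
            )
            self.means_[trait] = means
            self.rcbd_anova_[trait] = rc
            if self.anova_basis == "plot":
                ca = combining_ability_anova(
                    means, ms_resid, r, df_residual=df_resid, basis="plot"
                )
            self.ca_anova_[trait] = ca
            self.effects_[trait] = eff
            self.partitioned_[trait] = part
            self.genetics_[trait] = gen
            self.heterosis_[trait] = het
            self.correlations_[trait] = corr

        self.traits_ = tuple(traits)
        return self

    def report_bundle(self, seed: int | None = None):
        """Assemble the fitted results into a writable ReportBundle."""
        from .report import ReportBundle  # local import to avoid a cycle

        if not hasattr(self, "traits_"):
            raise DiallelError("estimator is not fitted; call fit first")
        return ReportBundle.from_fitted(self, seed=seed)


def analyze(X, **params) -> DiallelAnalysis:
    """Functional convenience: fit a DiallelAnalysis on X."""
    return DiallelAnalysis(**params).fit(X)
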
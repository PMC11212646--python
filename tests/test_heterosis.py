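"""Heterosis percentages and effect-performance correlations."""

import numpy as np
import pytest

from diallelkit import (
    CrossMeanTable,
    effect_performance_correlations,
    griffing_effects,
    heterosis,
    partitioned_effects,
    SimTruth,
    entry_means,
    simulate,
)
from conftest import random_means


def _table_with(x11, x22, x12, x21=None, trait="y"):
    x = np.array(
        [
            [x11, x12, 30.0],
            [x21 if x21 is not None else x12, x22, 31.0],
            [29.0, 32.0, 28.0],
        ]
    )
    return CrossMeanTable(trait=trait, parents=("A", "B", "C"), x=x)


def _row(het, female, male):
    return het[(het.female == female) & (het.male == male)].iloc[0]


class TestHeterosis:
    def test_f1_at_midparent_has_zero_mph(self):
        het = heterosis(_table_with(10.0, 20.0, 15.0), direction="max")
        assert _row(het, "A", "B")["MPH"] == pytest.approx(0.0)

    def test_larger_is_better_arithmetic(self):
        het = heterosis(_table_with(10.0, 20.0, 24.0), direction="max")
        row = _row(het, "A", "B")
        assert row["MPH"] == pytest.approx(100 * (24 - 15) / 15)  # 60
        assert row["BPH"] == pytest.approx(100 * (24 - 20) / 20)  # 20

    def test_smaller_is_better_uses_lower_parent(self):
        het = heterosis(_table_with(10.0, 20.0, 9.0), direction="min")
        row = _row(het, "A", "B")
        assert row["BP"] == pytest.approx(10.0)
        assert row["BPH"] == pytest.approx(-10.0)  # earlier than the best parent

    def test_default_direction_by_trait_name(self):
        tab = _table_with(10.0, 20.0, 24.0, trait="DTT")
        assert heterosis(tab).attrs["direction"] == "min"
        tab2 = _table_with(10.0, 20.0, 24.0, trait="GY")
        assert heterosis(tab2).attrs["direction"] == "max"

    def test_zero_parental_mean_flagged(self):
        het = heterosis(_table_with(10.0, -10.0, 5.0), direction="max")
        row = _row(het, "A", "B")
        assert row["undefined"]
        assert np.isnan(row["MPH"])

    def test_covers_all_ordered_crosses(self, sim_means):
        het = heterosis(sim_means)
        assert len(het) == 8 * 7


class TestCorrelations:
    def test_affine_response_gives_unit_correlation(self, sim_means):
        eff = griffing_effects(sim_means)
        part = partitioned_effects(sim_means)
        het = heterosis(sim_means)
        # construct the response as an affine function of the adjusted SCA
        idx = {lab: k for k, lab in enumerate(sim_means.parents)}
        fi = het["female"].map(idx).to_numpy()
        mi = het["male"].map(idx).to_numpy()
        het = het.copy()
        het["F1"] = 3.0 * part.s_adj[fi, mi] + 7.0
        corr = effect_performance_correlations(sim_means, eff, part, het)
        row = corr[(corr.response == "Mean") & (corr.predictor == "Adj_s_ij")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["sig"] == "**"

    def test_affine_invariance(self, sim_means):
        eff = griffing_effects(sim_means)
        part = partitioned_effects(sim_means)
        het = heterosis(sim_means)
        base = effect_performance_correlations(sim_means, eff, part, het)
        het2 = het.copy()
        het2["F1"] = het2["F1"] * 5.0 - 100.0
        het2["MPH"] = het2["MPH"] / 3.0 + 2.0
        shifted = effect_performance_correlations(sim_means, eff, part, het2)
        assert np.allclose(base["r"], shifted["r"], equal_nan=True)

    def test_zero_variance_series_reported_missing(self, sim_means):
        eff = griffing_effects(sim_means)
        part = partitioned_effects(sim_means)
        het = heterosis(sim_means).copy()
        het["F1"] = 42.0
        corr = effect_performance_correlations(sim_means, eff, part, het)
        assert corr[(corr.response == "Mean")]["r"].isna().all()

    def test_straight_subset_has_28_crosses(self, sim_means):
        eff = griffing_effects(sim_means)
        part = partitioned_effects(sim_means)
        het = heterosis(sim_means)
        corr = effect_performance_correlations(sim_means, eff, part, het, crosses="straight")
        assert (corr["n"] == 28).all()

    def test_null_correlation_critical_value(self):
        """Independent series of length 56 rarely exceed the 5% critical r."""
        rng = np.random.default_rng(1234)
        n_runs, n = 400, 56
        r_crit = 0.263  # two-sided 5% point for Pearson r, df = 54
        a = rng.normal(size=(n_runs, n))
        b = rng.normal(size=(n_runs, n))
        a = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
        b = (b - b.mean(1, keepdims=True)) / b.std(1, keepdims=True)
        r = (a * b).mean(axis=1)
        inside = np.mean(np.abs(r) < r_crit)
        assert 0.90 <= inside <= 1.0  # binomial band around 0.95

    def test_adjusted_sca_predicts_better_on_average(self):
        """With reciprocal (non-maternal) variation present, the directional
        SCA tracks hybrid means more closely than the symmetric Griffing SCA
        as a trend over many simulated diallels."""
        n_sims = 200
        diff = []
        for seed in range(n_sims):
            truth = SimTruth.random(
                p=6, seed=seed, maternal_sd=0.0, sca_sd=12.0, nm_sd=8.0,
                sigma_e=5.0, self_depression=0.0,
            )
            means = entry_means(simulate(truth), "GY")
            eff = griffing_effects(means)
            part = partitioned_effects(means)
            het = heterosis(means)
            corr = effect_performance_correlations(means, eff, part, het)
            sub = corr[corr.response == "Mean"].set_index("predictor")["r"]
            diff.append(sub["Adj_s_ij"] - sub["Griffing_s_ij"])
        assert np.mean(diff) > 0
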
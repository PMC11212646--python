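"""Generative model for full diallels with known truth.

Plot value for female i x male j in block k:

    y_kij = mu + b_k + g_fi + g_mj + s_ij + nm_ij + d*[i == j] + e_kij

with block effects b (sum 0), directional GCAs g_f/g_m (each sum 0, equal to
g +/- m for Griffing GCA g and maternal effect m), symmetric SCA s with zero
row sums (diagonal = parental SCA), antisymmetric non-maternal reciprocal
deviations nm with zero row sums, a selfing offset d on the diagonal
(inbreeding depression of the selfed parents), and iid Normal(0, sigma_e)
plot errors.  The constraints place every effect class in the subspace its
estimator projects onto, so with sigma_e = 0 the analysis pipeline returns
the generating values exactly.

The default scenario mirrors a grain-yield-scale maize diallel: 8 parents,
3 blocks, mean about 70 q/ha, residual plot variance about 47, sizeable SCA
and maternal variability, noticeable inbreeding depression of the selfs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import CrossMeanTable, DiallelDesign, DiallelError, PlotData
from .genetics import variance_components
from .griffing import combining_ability_anova, griffing_effects, _rcbd_components
from .partition import partitioned_effects

_ATOL = 1e-9


def _project_zero_sum(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _project_symmetric_rowsum_zero(s: np.ndarray) -> np.ndarray:
    """Nearest symmetric matrix with vanishing row (and column) sums."""
    s = (s + s.T) / 2.0
    p = s.shape[0]
    h = s.sum(axis=1) / p - s.sum() / (2 * p**2)
    return s - h[:, None] - h[None, :]


def _project_antisymmetric_rowsum_zero(a: np.ndarray) -> np.ndarray:
    """Nearest antisymmetric matrix with vanishing row sums."""
    a = (a - a.T) / 2.0
    p = a.shape[0]
    rm = a.mean(axis=1)
    return a - rm[:, None] + rm[None, :]


@dataclass
class SimTruth:
    """Generating parameters for one simulated diallel trait."""

    parents: tuple[str, ...]
    n_reps: int
    mu: float
    block: np.ndarray
    g_f: np.ndarray
    g_m: np.ndarray
    s: np.ndarray
    nm: np.ndarray
    sigma_e: float
    self_depression: float = 0.0
    seed: int = 0
    trait: str = "GY"

    def __post_init__(self) -> None:
        self.parents = tuple(str(x) for x in self.parents)
        p = self.n_parents
        for name in ("block", "g_f", "g_m", "s", "nm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.block.shape != (self.n_reps,):
            raise DiallelError("block effects must have length n_reps")
        if self.g_f.shape != (p,) or self.g_m.shape != (p,):
            raise DiallelError("g_f and g_m must have length p")
        if self.s.shape != (p, p) or self.nm.shape != (p, p):
            raise DiallelError("s and nm must be p x p")
        if self.sigma_e < 0:
            raise DiallelError("sigma_e must be non-negative")
        checks = {
            "block sum": abs(self.block.sum()),
            "g_f sum": abs(self.g_f.sum()),
            "g_m sum": abs(self.g_m.sum()),
            "s symmetry": np.abs(self.s - self.s.T).max(),
            "s row sums": np.abs(self.s.sum(axis=1)).max(),
            "nm antisymmetry": np.abs(self.nm + self.nm.T).max(),
            "nm row sums": np.abs(self.nm.sum(axis=1)).max(),
        }
        scale = 1.0 + abs(self.mu)
        bad = {k: v for k, v in checks.items() if v > 1e-6 * scale}
        if bad:
            raise DiallelError(f"SimTruth constraints violated: {bad}")

    # -- derived views -----------------------------------------------------
    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def g(self) -> np.ndarray:
        """Griffing GCA implied by the directional components."""
        return (self.g_f + self.g_m) / 2.0

    @property
    def m(self) -> np.ndarray:
        """Maternal effects implied by the directional components."""
        return (self.g_f - self.g_m) / 2.0

    @property
    def design(self) -> DiallelDesign:
        return DiallelDesign(self.parents, self.n_reps, (self.trait,))

    # -- constructors ------------------------------------------------------
    @classmethod
    def random(
        cls,
        p: int = 8,
        r: int = 3,
        mu: float = 70.0,
        gca_sd: float = 4.70,
        maternal_sd: float = 6.0,
        sca_sd: float = 16.47,
        nm_sd: float = 6.8,
        block_sd: float = 1.26,
        sigma_e: float = 6.888,
        self_depression: float = -15.0,
        seed: int = 0,
        trait: str = "GY",
    ) -> "SimTruth":
        """Draw a constrained truth; defaults follow the grain-yield scenario."""
        rng = np.random.default_rng(seed)
        g = _project_zero_sum(rng.normal(0.0, gca_sd, p))
        m = _project_zero_sum(rng.normal(0.0, maternal_sd, p))
        s = _project_symmetric_rowsum_zero(rng.normal(0.0, sca_sd, (p, p)))
        nm = _project_antisymmetric_rowsum_zero(rng.normal(0.0, nm_sd, (p, p)))
        block = _project_zero_sum(rng.normal(0.0, block_sd, r))
        return cls(
            parents=tuple(f"P{i + 1}" for i in range(p)),
            n_reps=r,
            mu=mu,
            block=block,
            g_f=g + m,
            g_m=g - m,
            s=s,
            nm=nm,
            sigma_e=sigma_e,
            self_depression=self_depression,
            seed=seed,
            trait=trait,
        )

    @classmethod
    def null(cls, p: int = 8, r: int = 3, mu: float = 70.0, sigma_e: float = 6.888,
             seed: int = 0, trait: str = "GY") -> "SimTruth":
        """No genetic, block or selfing effects: pure error around mu."""
        z = np.zeros
        return cls(
            parents=tuple(f"P{i + 1}" for i in range(p)),
            n_reps=r,
            mu=mu,
            block=z(r),
            g_f=z(p),
            g_m=z(p),
            s=z((p, p)),
            nm=z((p, p)),
            sigma_e=sigma_e,
            self_depression=0.0,
            seed=seed,
            trait=trait,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("block", "g_f", "g_m", "s", "nm"):
            d[k] = np.asarray(d[k]).tolist()
        d["parents"] = list(self.parents)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        d["parents"] = tuple(d["parents"])
        return cls(**d)


def expected_means(truth: SimTruth) -> np.ndarray:
    """Noiseless entry-mean surface implied by the truth (blocks average out)."""
    p = truth.n_parents
    x = (
        truth.mu
        + truth.g_f[:, None]
        + truth.g_m[None, :]
        + truth.s
        + truth.nm
        + truth.self_depression * np.eye(p)
        + truth.block.mean()
    )
    return x


def simulate_array(truth: SimTruth, rng: np.random.Generator | None = None) -> np.ndarray:
    """Plot values as an (r, p, p) array; same seed, same draws."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    p, r = truth.n_parents, truth.n_reps
    surface = expected_means(truth) - truth.block.mean()
    noise = rng.normal(0.0, truth.sigma_e, (r, p, p)) if truth.sigma_e > 0 else 0.0
    return surface[None, :, :] + truth.block[:, None, None] + noise


def simulate(truth: SimTruth) -> PlotData:
    """Generate a complete, validated PlotData (p**2 * r records)."""
    arr = simulate_array(truth)
    p, r = truth.n_parents, truth.n_reps
    fem, mal = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    rows = []
    for k in range(r):
        rows.append(
            pd.DataFrame(
                {
                    "female": np.array(truth.parents)[fem.ravel()],
                    "male": np.array(truth.parents)[mal.ravel()],
                    "rep": k + 1,
                    truth.trait: arr[k].ravel(),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    return PlotData.from_dataframe(df, design=truth.design)


# ---------------------------------------------------------------------------
# fast repeated analysis


def _analyze_array(arr: np.ndarray, parents: tuple[str, ...], trait: str = "sim") -> dict:
    """One-shot analysis of an (r, p, p) plot array; cheap numpy path."""
    r, p, _ = arr.shape
    ss = _rcbd_components(arr)
    df_resid = (p**2 - 1) * (r - 1)
    ms_resid = ss["ss_resid"] / df_resid
    means = CrossMeanTable(trait=trait, parents=parents, x=arr.mean(axis=0))
    anova = combining_ability_anova(means, ms_resid, r, df_residual=df_resid, basis="mean")
    comps = variance_components(anova, p, r)
    eff = griffing_effects(means)
    part = partitioned_effects(means)
    tab = anova.table.set_index("source")
    pvals = {src: float(tab.loc[src, "p"]) for src in ("Maternal", "Reciprocal", "GCA", "SCA")}
    return {
        "means": means,
        "ms_resid": ms_resid,
        "anova": anova,
        "components": comps,
        "effects": eff,
        "partitioned": part,
        "p_values": pvals,
    }


def true_components(truth: SimTruth) -> dict[str, float]:
    """Fixed-effects variance components implied by the noiseless surface.

    Computed by running the combining-ability decomposition on the expected
    entry means with a vanishing error term; the moment estimators are
    exactly unbiased for these values (see the methods note).
    """
    x = expected_means(truth)
    p = truth.n_parents
    means = CrossMeanTable(trait=truth.trait, parents=truth.parents, x=x)
    row, col, tot = means.row_totals, means.col_totals, means.grand_total
    ss_treat = float(((x - tot / p**2) ** 2).sum())
    ss_gca = float(((row + col) ** 2).sum() / (2 * p) - 2 * tot**2 / p**2)
    diff = x - x.T
    ss_rec = float((diff[np.triu_indices(p, k=1)] ** 2).sum() / 2.0)
    ss_sca = ss_treat - ss_gca - ss_rec
    dfs = {"gca": p - 1, "sca": p * (p + 1) // 2 - p, "rca": p * (p - 1) // 2}
    return {
        "gca": ss_gca / dfs["gca"] / (2 * p),
        "sca": ss_sca / dfs["sca"],
        "rca": ss_rec / dfs["rca"] / 2.0,
        "err": truth.sigma_e**2 / truth.n_reps,
    }


def recovery_experiment(truth: SimTruth, n_sims: int, seed: int = 0, alpha: float = 0.05) -> dict:
    """Repeated simulate-and-analyze: bias/RMSE of effects and components.

    Reference values are the noiseless-analysis implications of the truth, so
    the report isolates estimation (sampling) error from model structure.
    Also reports the empirical rejection rates of the maternal and reciprocal
    F tests at level ``alpha``.
    """
    if n_sims < 1:
        raise DiallelError("n_sims must be at least 1")
    ref_eff = griffing_effects(
        CrossMeanTable(trait=truth.trait, parents=truth.parents, x=expected_means(truth))
    )
    ref_part = partitioned_effects(
        CrossMeanTable(trait=truth.trait, parents=truth.parents, x=expected_means(truth))
    )
    ref_comp = true_components(truth)

    rng = np.random.default_rng(seed)
    acc: dict[str, list] = {k: [] for k in ("g", "g_f", "g_m", "m", "s", "rec")}
    comp_acc: dict[str, list] = {k: [] for k in ("gca", "sca", "rca", "err")}
    rej = {"Maternal": 0, "Reciprocal": 0}
    for _ in range(n_sims):
        arr = simulate_array(truth, rng=rng)
        res = _analyze_array(arr, truth.parents, trait=truth.trait)
        eff, part, comps = res["effects"], res["partitioned"], res["components"]
        acc["g"].append(eff.g - ref_eff.g)
        acc["g_f"].append(part.g_f - ref_part.g_f)
        acc["g_m"].append(part.g_m - ref_part.g_m)
        acc["m"].append(part.m - ref_part.m)
        acc["s"].append(eff.s - ref_eff.s)
        acc["rec"].append(eff.rec - ref_eff.rec)
        comp_acc["gca"].append(comps.var_gca)
        comp_acc["sca"].append(comps.var_sca)
        comp_acc["rca"].append(comps.var_rca)
        comp_acc["err"].append(comps.var_err)
        for src in rej:
            if res["p_values"][src] < alpha:
                rej[src] += 1

    bias = {k: float(np.mean(v)) for k, v in acc.items()}
    rmse = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in acc.items()}
    comp_mean = {k: float(np.mean(v)) for k, v in comp_acc.items()}
    return {
        "n_sims": n_sims,
        "bias": bias,
        "rmse": rmse,
        "components_mean": comp_mean,
        "components_truth": ref_comp,
        "rejection_rate": {k: v / n_sims for k, v in rej.items()},
        "alpha": alpha,
    }
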
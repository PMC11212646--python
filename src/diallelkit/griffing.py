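"""Griffing Method 1 (Model I) combining-ability estimation and ANOVA.

The entry mean of female i crossed to male j is modelled as

    x_ij = mu + g_i + g_j + s_ij + r_ij + mean of r plot errors

with the classical fixed-effect (Model I) closed forms on the p x p table of
entry means (n = p parents; x_i., x_.i row/column sums; x_.. grand sum):

    g_i  = (x_i. + x_.i)/(2n) - x_../n**2
    s_ij = (x_ij + x_ji)/2 - (x_i. + x_.i + x_j. + x_.j)/(2n) + x_../n**2
    r_ij = (x_ij - x_ji)/2

subject to sum(g) = 0 and row sums of s vanishing.  The combining-ability
ANOVA splits the treatment sum of squares among entry means into GCA, SCA and
reciprocal parts, and the reciprocal part further into a maternal component
(driven by the row-minus-column margins) and a non-maternal remainder.  All
F tests use the plot-level residual mean square from the replicated RCBD as
the sole error term (fixed-effects testing, single residual line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CrossMeanTable, DiallelError, PlotData


@dataclass
class AnovaTable:
    """ANOVA rows (source, df, SS, MS, F, p) with an explicit basis flag.

    basis is ``"plot"`` for sums of squares over individual plots and
    ``"mean"`` for sums of squares over entry means; mean-basis SS times r
    gives the plot-basis SS of the same source.
    """

    table: pd.DataFrame
    basis: str


@dataclass
class GriffingEffects:
    """Griffing Method 1 effect estimates for one trait."""

    trait: str
    parents: tuple[str, ...]
    mu: float
    g: np.ndarray
    s: np.ndarray
    rec: np.ndarray
    se: dict[str, float] = field(default_factory=dict)
    sig: dict[str, np.ndarray] = field(default_factory=dict)


def _stars(effect: np.ndarray, se: float, alpha: tuple[float, float] = (0.05, 0.01)) -> np.ndarray:
    """Two-sided normal-deviate significance flags: '' / '*' / '**'."""
    effect = np.asarray(effect, dtype=float)
    if se == 0.0:
        z = np.where(effect != 0.0, np.inf, 0.0)
    else:
        z = np.abs(effect) / se
    crit1 = stats.norm.isf(alpha[0] / 2.0)
    crit2 = stats.norm.isf(alpha[1] / 2.0)
    out = np.full(effect.shape, "", dtype=object)
    out[z > crit1] = "*"
    out[z > crit2] = "**"
    return out


def griffing_effects(
    means: CrossMeanTable,
    ms_residual: float | None = None,
    r: int | None = None,
    alpha: tuple[float, float] = (0.05, 0.01),
) -> GriffingEffects:
    """Estimate mu, GCA, SCA and reciprocal effects from entry means.

    If ``ms_residual`` (plot basis) and ``r`` are given, standard errors and
    two-sided significance flags are attached.
    """
    x = means.x
    p = means.n_parents
    row = means.row_totals
    col = means.col_totals
    tot = means.grand_total

    mu = tot / p**2
    g = (row + col) / (2 * p) - tot / p**2
    marg = row + col  # x_i. + x_.i per parent
    s = (x + x.T) / 2.0 - (marg[:, None] + marg[None, :]) / (2 * p) + tot / p**2
    rec = (x - x.T) / 2.0

    se: dict[str, float] = {}
    sig: dict[str, np.ndarray] = {}
    if ms_residual is not None:
        if r is None:
            raise DiallelError("r (replications) is required with ms_residual")
        se = effect_standard_errors(ms_residual, r, p)
        ssig = _stars(s, se["s"], alpha)
        # the diagonal (parental SCA) has its own sampling variance
        ssig[np.diag_indices(p)] = _stars(np.diag(s), se["s_diag"], alpha)
        sig = {
            "g": _stars(g, se["g"], alpha),
            "s": ssig,
            "rec": _stars(rec, se["rec"], alpha),
        }

    return GriffingEffects(
        trait=means.trait, parents=means.parents, mu=mu, g=g, s=s, rec=rec, se=se, sig=sig
    )


def _rcbd_components(arr: np.ndarray) -> dict[str, float]:
    """Balanced RCBD sums of squares from an (r, p, p) plot array."""
    r = arr.shape[0]
    n_entries = arr.shape[1] * arr.shape[2]
    grand = arr.mean()
    rep_means = arr.mean(axis=(1, 2))
    entry_means = arr.mean(axis=0)
    ss_total = float(((arr - grand) ** 2).sum())
    ss_rep = float(n_entries * ((rep_means - grand) ** 2).sum())
    ss_treat = float(r * ((entry_means - grand) ** 2).sum())
    ss_resid = ss_total - ss_rep - ss_treat
    return {"ss_total": ss_total, "ss_rep": ss_rep, "ss_treat": ss_treat, "ss_resid": ss_resid}


def rcbd_anova(data: PlotData, trait: str) -> AnovaTable:
    """Two-way replications x treatments ANOVA of the plot data (plot basis).

    Treatments are the p**2 diallel entries; replications are the complete
    blocks.  Residual df is (p**2 - 1)(r - 1), so r must be at least 2.
    """
    p = data.design.n_parents
    r = data.design.n_reps
    if r < 2:
        raise DiallelError("RCBD residual requires at least 2 replications")
    arr = data.to_array(trait)
    ss = _rcbd_components(arr)

    df_rep = r - 1
    df_treat = p**2 - 1
    df_resid = df_rep * df_treat
    rows = []
    ms_resid = ss["ss_resid"] / df_resid
    for source, ssq, df in (
        ("Replications", ss["ss_rep"], df_rep),
        ("Treatments", ss["ss_treat"], df_treat),
        ("Residual", ss["ss_resid"], df_resid),
    ):
        ms = ssq / df
        if source == "Residual":
            f_val, p_val = np.nan, np.nan
        elif ms_resid <= 0:
            f_val, p_val = np.nan, 1.0
        else:
            f_val = ms / ms_resid
            p_val = float(stats.f.sf(f_val, df, df_resid))
        rows.append({"source": source, "df": df, "SS": ssq, "MS": ms, "F": f_val, "p": p_val})
    rows.append(
        {
            "source": "Total",
            "df": df_rep + df_treat + df_resid,
            "SS": ss["ss_total"],
            "MS": np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return AnovaTable(table=pd.DataFrame(rows), basis="plot")


def combining_ability_df(p: int) -> dict[str, int]:
    """Degrees of freedom of the Method 1 combining-ability partition."""
    return {
        "GCA": p - 1,
        "SCA": p * (p + 1) // 2 - p,
        "Reciprocal": p * (p - 1) // 2,
        "Maternal": p - 1,
        "Non-Maternal": p * (p - 1) // 2 - (p - 1),
    }


def combining_ability_anova(
    means: CrossMeanTable,
    ms_residual: float,
    r: int,
    df_residual: int | None = None,
    basis: str = "mean",
) -> AnovaTable:
    """Partition the entry-mean treatment SS into GCA/SCA/Reciprocal sources.

    On the entry-mean basis (Griffing's Method 1 orthogonal partition):

        SS_GCA = sum_i (x_i. + x_.i)**2 / (2p) - 2 x_..**2 / p**2
        SS_Rec = sum_{i<j} (x_ij - x_ji)**2 / 2
        SS_SCA = SS_Treat(means) - SS_GCA - SS_Rec
        SS_Mat = sum_i (x_i. - x_.i)**2 / (2p)
        SS_NM  = SS_Rec - SS_Mat

    Each mean square is tested by F against ms_residual/r, the error variance
    of an entry mean.  ``basis="plot"`` multiplies all SS by r (F unchanged).
    """
    if ms_residual <= 0:
        raise DiallelError("ms_residual must be positive")
    if basis not in ("mean", "plot"):
        raise DiallelError(f"basis must be 'mean' or 'plot', got {basis!r}")
    x = means.x
    p = means.n_parents
    row = means.row_totals
    col = means.col_totals
    tot = means.grand_total

    ss_treat = float(((x - tot / p**2) ** 2).sum())
    ss_gca = float(((row + col) ** 2).sum() / (2 * p) - 2 * tot**2 / p**2)
    diff = x - x.T
    ss_rec = float((diff[np.triu_indices(p, k=1)] ** 2).sum() / 2.0)
    ss_sca = ss_treat - ss_gca - ss_rec
    ss_mat = float(((row - col) ** 2).sum() / (2 * p))
    ss_nm = ss_rec - ss_mat

    dfs = combining_ability_df(p)
    err_ms = ms_residual / r  # variance of an entry mean
    if df_residual is None:
        df_residual = (p**2 - 1) * (r - 1)

    scale = r if basis == "plot" else 1.0
    err_row_ms = err_ms * scale
    rows = []
    for source, ssq in (
        ("Treatments", ss_treat),
        ("GCA", ss_gca),
        ("SCA", ss_sca),
        ("Reciprocal", ss_rec),
        ("Maternal", ss_mat),
        ("Non-Maternal", ss_nm),
    ):
        df = dfs.get(source, p**2 - 1)
        ms = ssq / df
        if ms <= 0 or ssq <= 0:
            f_val, p_val, ssq_r = np.nan, 1.0, max(ssq, 0.0)
            ms = ssq_r / df
        else:
            f_val = ms / err_ms
            p_val = float(stats.f.sf(f_val, df, df_residual))
            ssq_r = ssq
        rows.append(
            {
                "source": source,
                "df": df,
                "SS": ssq_r * scale,
                "MS": ms * scale,
                "F": f_val,
                "p": p_val,
            }
        )
    rows.append(
        {
            "source": "Residual",
            "df": df_residual,
            "SS": err_row_ms * df_residual,
            "MS": err_row_ms,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return AnovaTable(table=pd.DataFrame(rows), basis=basis)


def _linear_form_se(coef: np.ndarray, sigma2_mean: float) -> float:
    """SE of a linear functional of the p**2 independent entry means."""
    return float(np.sqrt(sigma2_mean * (coef**2).sum()))


def effect_standard_errors(ms_residual: float, r: int, p: int) -> dict[str, float]:
    """Exact Model I standard errors of every effect class.

    Each estimator is a fixed linear form in the p**2 entry means, which are
    independent with variance ``ms_residual / r``; the SE is sigma times the
    Euclidean norm of the coefficient vector.  This reproduces Griffing's
    (1956) Method 1 variance formulas without transcribing them.

    Returns SEs for: mu, g (Griffing GCA), g_fm (female or male partitioned
    GCA), m (maternal), s (off-diagonal Griffing SCA), s_diag (parental SCA),
    s_adj (adjusted directional SCA), rec (reciprocal effect).
    """
    if ms_residual < 0:
        raise DiallelError("ms_residual must be non-negative")
    sigma2 = ms_residual / r
    i, j = 0, 1  # representative indices; all classes are exchangeable
    a = np.arange(p)
    d_i = (a[:, None] == i).astype(float)  # row indicator: female == i
    d_j = (a[:, None] == j).astype(float)
    e_i = (a[None, :] == i).astype(float)  # column indicator: male == i
    e_j = (a[None, :] == j).astype(float)
    cell = np.zeros((p, p))
    cell[i, j] = 1.0
    cell_t = np.zeros((p, p))
    cell_t[j, i] = 1.0
    self_cell = np.zeros((p, p))
    self_cell[i, i] = 1.0
    ones = np.ones((p, p))

    coef_mu = ones / p**2
    coef_g = (d_i + e_i) / (2 * p) - ones / p**2
    coef_gf = d_i / p - ones / p**2
    coef_m = (d_i - e_i) / (2 * p)
    margins_ij = (d_i + e_i + d_j + e_j) / (2 * p)
    coef_s = (cell + cell_t) / 2.0 - margins_ij + ones / p**2
    coef_s_diag = self_cell - (d_i + e_i) / p + ones / p**2
    coef_s_adj = cell - margins_ij + ones / p**2
    coef_rec = (cell - cell_t) / 2.0

    return {
        "mu": _linear_form_se(coef_mu, sigma2),
        "g": _linear_form_se(coef_g, sigma2),
        "g_fm": _linear_form_se(coef_gf, sigma2),
        "m": _linear_form_se(coef_m, sigma2),
        "s": _linear_form_se(coef_s, sigma2),
        "s_diag": _linear_form_se(coef_s_diag, sigma2),
        "s_adj": _linear_form_se(coef_s_adj, sigma2),
        "rec": _linear_form_se(coef_rec, sigma2),
    }
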
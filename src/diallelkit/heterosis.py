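"""Heterosis and effect-performance correlation analysis.

Mid-parent heterosis (MPH) and better-parent heterosis (BPH) of each ordered
cross, in percent of the parental reference:

    MPH = 100 (x_ij - MP)/MP,  MP = (x_ii + x_jj)/2
    BPH = 100 (x_ij - BP)/BP,  BP = the favoured parental mean

"Better" depends on the trait: for maturity traits (days to tasseling or
silking) smaller is better, for yield components larger is better.  The
correlation study then asks which combining-ability summary best predicts
hybrid performance: each response series (F1 mean, MPH, BPH) is correlated
(Pearson, two-sided t test) against Griffing's SCA, the adjusted directional
SCA, the sum of Griffing GCAs and the directional sum g_f(female) +
g_m(male), over the p(p-1) ordered hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import CrossMeanTable, DiallelError
from .griffing import GriffingEffects
from .partition import PartitionedEffects

#: traits where a smaller value is agronomically favourable
DEFAULT_SMALLER_IS_BETTER = frozenset({"DTT", "DTS"})


def _direction_for(trait: str, direction: Mapping[str, str] | str | None) -> str:
    if direction is None:
        return "min" if trait in DEFAULT_SMALLER_IS_BETTER else "max"
    if isinstance(direction, str):
        d = direction
    else:
        d = direction.get(trait, "min" if trait in DEFAULT_SMALLER_IS_BETTER else "max")
    if d not in ("min", "max"):
        raise DiallelError(f"direction must be 'min' or 'max', got {d!r}")
    return d


def heterosis(
    means: CrossMeanTable, direction: Mapping[str, str] | str | None = None
) -> pd.DataFrame:
    """Per ordered cross (i != j): F1 mean, MP, BP, MPH% and BPH%.

    ``direction`` maps trait -> 'min'|'max' ('max' = larger is better); the
    built-in default treats maturity traits (DTT, DTS) as smaller-is-better.
    Crosses whose parental reference is zero get NaN heterosis and a flag.
    """
    d = _direction_for(means.trait, direction)
    better = min if d == "min" else max
    rows = []
    x = means.x
    parents = means.parents
    for i in range(means.n_parents):
        for j in range(means.n_parents):
            if i == j:
                continue
            mp = (x[i, i] + x[j, j]) / 2.0
            bp = better(x[i, i], x[j, j])
            f1 = x[i, j]
            mph = 100.0 * (f1 - mp) / mp if mp != 0 else np.nan
            bph = 100.0 * (f1 - bp) / bp if bp != 0 else np.nan
            rows.append(
                {
                    "female": parents[i],
                    "male": parents[j],
                    "F1": f1,
                    "MP": mp,
                    "BP": bp,
                    "MPH": mph,
                    "BPH": bph,
                    "undefined": (mp == 0) or (bp == 0),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["trait"] = means.trait
    out.attrs["direction"] = d
    return out


def _corr(a: np.ndarray, b: np.ndarray, alpha=(0.05, 0.01)) -> tuple[float, float, str]:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan, np.nan, ""
    r, p = stats.pearsonr(a, b)
    star = "**" if p < alpha[1] else "*" if p < alpha[0] else ""
    return float(r), float(p), star


def effect_performance_correlations(
    means: CrossMeanTable,
    effects: GriffingEffects,
    partitioned: PartitionedEffects,
    het: pd.DataFrame,
    crosses: str = "ordered",
    alpha: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Pearson correlations of performance/heterosis with combining abilities.

    ``crosses="ordered"`` uses all p(p-1) directional hybrids (straight and
    reciprocal pooled); ``"straight"`` restricts to the i<j triangle.
    """
    if crosses not in ("ordered", "straight"):
        raise DiallelError(f"crosses must be 'ordered' or 'straight', got {crosses!r}")
    p = means.n_parents
    idx = {lab: k for k, lab in enumerate(means.parents)}
    het = het.copy()
    fi = het["female"].map(idx).to_numpy()
    mi = het["male"].map(idx).to_numpy()
    if crosses == "straight":
        keep = fi < mi
        het, fi, mi = het[keep], fi[keep], mi[keep]

    responses = {
        "Mean": het["F1"].to_numpy(float),
        "MPH": het["MPH"].to_numpy(float),
        "BPH": het["BPH"].to_numpy(float),
    }
    predictors = {
        "Griffing_s_ij": effects.s[fi, mi],
        "Adj_s_ij": partitioned.s_adj[fi, mi],
        "Griffing_SGCA": effects.g[fi] + effects.g[mi],
        "Adj_SGCA": partitioned.g_f[fi] + partitioned.g_m[mi],
    }
    rows = []
    for rname, rvals in responses.items():
        for pname, pvals in predictors.items():
            r, pv, star = _corr(rvals, np.asarray(pvals, float), alpha)
            rows.append(
                {
                    "response": rname,
                    "predictor": pname,
                    "r": r,
                    "p": pv,
                    "sig": star,
                    "n": int(np.isfinite(rvals).sum()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["trait"] = means.trait
    out.attrs["crosses"] = crosses
    return out
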
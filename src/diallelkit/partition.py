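"""Partition of Griffing combining abilities into directional components.

The symmetric Griffing analysis assigns one GCA per parent and one SCA per
cross, averaging over the parent's use as female or male.  The modified
partition keeps the direction of each mating:

    g_fi = x_i./n - x_../n**2        (parent i used as female)
    g_mi = x_.i/n - x_../n**2        (parent i used as male)
    g_i  = (g_fi + g_mi)/2           (Griffing's GCA is their average)
    m_i  = (g_fi - g_mi)/2           (maternal effect; identically
                                      (x_i. - x_.i)/(2n) from the margins)

    s_ij (adjusted) = x_ij - (x_i. + x_.i + x_j. + x_.j)/(2n) + x_../n**2
    r_ij = (s_ij - s_ji)/2 = (x_ij - x_ji)/2,   r_ji = -r_ij

so a cross and its reciprocal get separate SCA values whose average is the
Griffing SCA and whose half-difference is the reciprocal effect.  A parent
with a positive maternal effect transmits extra performance specifically when
used as the seed (female) parent — in maize an endosperm/cytoplasm signature
that the symmetric model averages away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CrossMeanTable
from .griffing import _stars, effect_standard_errors


@dataclass
class PartitionedEffects:
    """Directional (female/male) combining abilities for one trait."""

    trait: str
    parents: tuple[str, ...]
    g_f: np.ndarray
    g_m: np.ndarray
    g: np.ndarray
    m: np.ndarray
    s_adj: np.ndarray  # full matrix; s_adj[i, j] != s_adj[j, i] in general
    r_adj: np.ndarray  # antisymmetric reciprocal effects
    se: dict[str, float] = field(default_factory=dict)
    sig: dict[str, np.ndarray] = field(default_factory=dict)


def partition_gca(means: CrossMeanTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Female/male GCA components and the derived Griffing GCA and maternal effect.

    Returns ``(g_f, g_m, g, m)``; each vector sums to zero.
    """
    p = means.n_parents
    tot = means.grand_total
    g_f = means.row_totals / p - tot / p**2
    g_m = means.col_totals / p - tot / p**2
    return g_f, g_m, (g_f + g_m) / 2.0, (g_f - g_m) / 2.0


def maternal_from_margins(means: CrossMeanTable) -> np.ndarray:
    """Maternal effects straight from the margins: m_i = (x_i. - x_.i)/(2n).

    Algebraically identical to ``(g_fi - g_mi)/2``; exposed separately because
    the marginal form is the classical maternal-effect estimator.
    """
    return (means.row_totals - means.col_totals) / (2 * means.n_parents)


def partition_sca(means: CrossMeanTable) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted directional SCA and the antisymmetric reciprocal effects.

    Off-diagonal cells follow the directional closed form; diagonal cells keep
    the Method 1 parental SCA (a self has no reciprocal, so r_adj diag is 0).
    The pairwise average (s_adj + s_adj.T)/2 reproduces Griffing's SCA.
    """
    x = means.x
    p = means.n_parents
    marg = means.row_totals + means.col_totals
    s_adj = x - (marg[:, None] + marg[None, :]) / (2 * p) + means.grand_total / p**2
    # diagonal: parental SCA equals the symmetric Griffing value already
    r_adj = (s_adj - s_adj.T) / 2.0
    return s_adj, r_adj


# ---------------------------------------------------------------------------
# printed-table identities: recombine partitioned values into Griffing's
# symmetric effects.  These are the exact relations the partition satisfies,
# usable on any (g_f, g_m) or (s_ij, s_ji) pair, including published tables.

def gca_from_partition(g_f, g_m):
    """Griffing GCA from its female/male components: (g_f + g_m)/2."""
    return (np.asarray(g_f, dtype=float) + np.asarray(g_m, dtype=float)) / 2.0


def maternal_from_partition(g_f, g_m):
    """Maternal effect from the partitioned pair: (g_f - g_m)/2."""
    return (np.asarray(g_f, dtype=float) - np.asarray(g_m, dtype=float)) / 2.0


def sca_from_pair(s_ij, s_ji):
    """Griffing SCA from a directional pair: (s_ij + s_ji)/2."""
    return (np.asarray(s_ij, dtype=float) + np.asarray(s_ji, dtype=float)) / 2.0


def reciprocal_from_pair(s_ij, s_ji):
    """Reciprocal effect from a directional SCA pair: (s_ij - s_ji)/2."""
    return (np.asarray(s_ij, dtype=float) - np.asarray(s_ji, dtype=float)) / 2.0


def partitioned_effects(
    means: CrossMeanTable,
    ms_residual: float | None = None,
    r: int | None = None,
    alpha: tuple[float, float] = (0.05, 0.01),
) -> PartitionedEffects:
    """Full modified-model effect set, with SEs when an error term is given."""
    g_f, g_m, g, m = partition_gca(means)
    s_adj, r_adj = partition_sca(means)
    se: dict[str, float] = {}
    sig: dict[str, np.ndarray] = {}
    if ms_residual is not None:
        if r is None:
            raise ValueError("r (replications) is required with ms_residual")
        se = effect_standard_errors(ms_residual, r, means.n_parents)
        ssig = _stars(s_adj, se["s_adj"], alpha)
        ssig[np.diag_indices(means.n_parents)] = _stars(
            np.diag(s_adj), se["s_diag"], alpha
        )
        sig = {
            "g_f": _stars(g_f, se["g_fm"], alpha),
            "g_m": _stars(g_m, se["g_fm"], alpha),
            "m": _stars(m, se["m"], alpha),
            "s_adj": ssig,
            "r_adj": _stars(r_adj, se["rec"], alpha),
        }
    return PartitionedEffects(
        trait=means.trait,
        parents=means.parents,
        g_f=g_f,
        g_m=g_m,
        g=g,
        m=m,
        s_adj=s_adj,
        r_adj=r_adj,
        se=se,
        sig=sig,
    )
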
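"""Report assembly and serialization.

The human-readable report is one CSV per table, laid out the way diallel
results are conventionally published (a three-row g_m/g_f/g block per trait,
a parent-by-trait maternal table, directional SCA pairs, the i<j reciprocal
triangle, genetic parameters per trait, heterosis and the correlation grid),
rounded to two decimals.  A machine-readable ``bundle.json`` keeps every
number at full precision and round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DiallelError

_SECTIONS = (
    "rcbd_anova",
    "ca_anova",
    "gca",
    "maternal",
    "sca",
    "reciprocal",
    "genetics",
    "heterosis",
    "correlations",
)


@dataclass
class ReportBundle:
    """All result tables of one analysis run plus provenance metadata."""

    tables: dict[str, pd.DataFrame]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in _SECTIONS if s not in self.tables]
        if missing:
            raise DiallelError(f"report bundle is missing sections: {missing}")

    @classmethod
    def from_fitted(cls, est, seed: int | None = None) -> "ReportBundle":
        design = est.design_
        parents = list(design.parents)
        traits = list(est.traits_)

        rcbd_rows, ca_rows, gca_rows, mat_rows = [], [], [], []
        sca_rows, rec_rows, gen_rows, het_rows, corr_rows = [], [], [], [], []
        for trait in traits:
            rc = est.rcbd_anova_[trait].table.assign(trait=trait, basis="plot")
            rcbd_rows.append(rc)
            ca = est.ca_anova_[trait]
            ca_rows.append(ca.table.assign(trait=trait, basis=ca.basis))

            eff = est.effects_[trait]
            part = est.partitioned_[trait]
            for name, vec, sig in (
                ("g_mi", part.g_m, part.sig.get("g_m")),
                ("g_fi", part.g_f, part.sig.get("g_f")),
                ("g_i", eff.g, eff.sig.get("g")),
            ):
                row = {"trait": trait, "effect": name}
                for k, lab in enumerate(parents):
                    row[lab] = vec[k]
                    row[f"{lab}_sig"] = "" if sig is None else sig[k]
                row["SE"] = part.se.get("g_fm") if name != "g_i" else eff.se.get("g")
                gca_rows.append(row)

            msig = part.sig.get("m")
            for k, lab in enumerate(parents):
                mat_rows.append(
                    {
                        "trait": trait,
                        "parent": lab,
                        "m": part.m[k],
                        "sig": "" if msig is None else msig[k],
                        "SE": part.se.get("m"),
                    }
                )

            p = design.n_parents
            for i in range(p):
                for j in range(i, p):
                    if i == j:
                        sca_rows.append(
                            {
                                "trait": trait,
                                "female": parents[i],
                                "male": parents[j],
                                "griffing_s": eff.s[i, i],
                                "adj_s_ij": part.s_adj[i, i],
                                "adj_s_ji": part.s_adj[i, i],
                                "sig": eff.sig["s"][i, i] if "s" in eff.sig else "",
                            }
                        )
                        continue
                    sca_rows.append(
                        {
                            "trait": trait,
                            "female": parents[i],
                            "male": parents[j],
                            "griffing_s": eff.s[i, j],
                            "adj_s_ij": part.s_adj[i, j],
                            "adj_s_ji": part.s_adj[j, i],
                            "sig": eff.sig["s"][i, j] if "s" in eff.sig else "",
                        }
                    )
                    rec_rows.append(
                        {
                            "trait": trait,
                            "female": parents[i],
                            "male": parents[j],
                            "r_ij": part.r_adj[i, j],
                            "sig": part.sig["r_adj"][i, j] if "r_adj" in part.sig else "",
                            "SE": part.se.get("rec"),
                        }
                    )

            g = est.genetics_[trait]
            gen_rows.append(
                {
                    "trait": trait,
                    "var_gca": g.var_gca,
                    "var_sca": g.var_sca,
                    "var_rca": g.var_rca,
                    "var_P": g.var_P,
                    "var_e": g.var_err,
                    "var_A": g.var_A,
                    "var_D": g.var_D,
                    "ratio_AD": g.ratio_AD,
                    "H2": g.H2,
                    "h2": g.h2,
                    "baker": g.baker,
                    "truncated": ";".join(g.truncated),
                }
            )
            het_rows.append(est.heterosis_[trait].assign(trait=trait))
            corr_rows.append(est.correlations_[trait].assign(trait=trait))

        tables = {
            "rcbd_anova": pd.concat(rcbd_rows, ignore_index=True),
            "ca_anova": pd.concat(ca_rows, ignore_index=True),
            "gca": pd.DataFrame(gca_rows),
            "maternal": pd.DataFrame(mat_rows),
            "sca": pd.DataFrame(sca_rows),
            "reciprocal": pd.DataFrame(rec_rows),
            "genetics": pd.DataFrame(gen_rows),
            "heterosis": pd.concat(het_rows, ignore_index=True),
            "correlations": pd.concat(corr_rows, ignore_index=True),
        }
        meta = {
            "parents": parents,
            "n_reps": design.n_reps,
            "traits": traits,
            "params": est.get_params(),
            "seed": seed,
            "created": datetime.now(timezone.utc).isoformat(),
            "software": "diallelkit 0.1.0",
        }
        # get_params may hold a mapping; make it JSON-friendly
        meta["params"] = {k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
                          for k, v in meta["params"].items()}
        return cls(tables=tables, meta=meta)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        # native Python scalars column-wise: shortest-repr JSON floats
        # round-trip bit-for-bit (pandas to_json caps precision at 15)
        def _table(df: pd.DataFrame) -> dict:
            cols = {c: df[c].to_numpy().tolist() for c in df.columns}
            data = [list(row) for row in zip(*cols.values())] if len(df) else []
            return {"columns": list(df.columns), "data": data, "index": list(range(len(df)))}

        return {
            "meta": self.meta,
            "tables": {name: _table(df) for name, df in self.tables.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        tables = {
            name: pd.DataFrame(
                payload["data"], columns=payload["columns"], index=payload["index"]
            ).reset_index(drop=True)
            for name, payload in d["tables"].items()
        }
        return cls(tables=tables, meta=d.get("meta", {}))


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write rounded CSV tables, the full-precision bundle and metadata.

    Returns the list of written paths.
    """
    if not bundle.meta.get("traits"):
        raise DiallelError("refusing to write a report with an empty trait list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables.items():
        path = out / f"{name}.csv"
        rounded = df.copy()
        for col in rounded.columns:
            if pd.api.types.is_float_dtype(rounded[col]):
                rounded[col] = rounded[col].round(2)
        rounded.to_csv(path, index=False)
        written.append(path)
    machine = out / "bundle.json"
    machine.write_text(json.dumps(bundle.to_dict(), indent=1))
    written.append(machine)
    meta = out / "metadata.json"
    meta.write_text(json.dumps(bundle.meta, indent=1))
    written.append(meta)
    return written


def load_report(path: str | Path) -> ReportBundle:
    """Reload a bundle from a report directory or a bundle.json file."""
    path = Path(path)
    if path.is_dir():
        path = path / "bundle.json"
    return ReportBundle.from_dict(json.loads(path.read_text()))
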
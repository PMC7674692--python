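"""Female/male expression-balance accounting.

Ratios per family x species x somatic tissue (gonads excluded: ovary and
testis are different tissues): r_xx = log2(Xf / Xm) and
r_combined = log2(Xf / (Xm + Y)), with retrogene-inclusive variants adding the
cumulative retrogene expression R to the designated side.  Retrogene
expression is treated as sex-shared (autosomal insertions are present in both
sexes).  The escape-gain estimate reports the extra female X expression as
median (Xf/Xm - 1) x 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import bh_correct, fixed_median_test

SOMATIC = ("brain", "heart", "kidney", "liver")
RETRO_MODES = ("none", "both_sides", "x_only", "y_only")


def _compartment_frame(agg: pd.DataFrame) -> pd.DataFrame:
    """Wide per (family, species, tissue): Xf, Xm, Y, retro_X, retro_Y."""
    sub = agg[agg["tissue"].isin(SOMATIC)].copy()
    sub["slot"] = np.where(
        sub["compartment"] == "X",
        np.where(sub["sex"] == "F", "Xf", "Xm"),
        np.where(
            sub["compartment"] == "Y", "Y",
            sub["compartment"],  # retro_X / retro_Y (sex-shared; duplicates collapse)
        ),
    )
    wide = (
        sub.pivot_table(index=["family", "species", "tissue"], columns="slot",
                        values="tpm", aggfunc="median")
        .reset_index()
    )
    for col in ("Xf", "Xm", "Y", "retro_X", "retro_Y"):
        if col not in wide.columns:
            wide[col] = np.nan
    return wide


def dosage_ratios(agg: pd.DataFrame, include_retro: str = "none",
                  pseudocount: float = 0.1) -> pd.DataFrame:
    """Per family x species x somatic tissue dosage ratios.

    include_retro:
      * none       — r_xx = log2(Xf/Xm), r_combined = log2(Xf/(Xm+Y));
      * both_sides — r_combined = log2((Xf+R)/(Xm+Y+R)), R = retro_X+retro_Y;
      * x_only     — r_xx = log2((Xf+Rx)/(Xm+Rx));
      * y_only     — r_combined = log2(Xf/(Y+Ry)) (X-vs-Y balance form).

    Rows lacking a needed compartment are skipped.  Y lost -> family/species
    absent from the aggregate by construction upstream.
    """
    if include_retro not in RETRO_MODES:
        raise ValueError(f"include_retro must be one of {RETRO_MODES}")
    eps = pseudocount
    wide = _compartment_frame(agg)
    rows = []
    for _, r in wide.iterrows():
        xf, xm, y = r["Xf"], r["Xm"], r["Y"]
        rx = 0.0 if np.isnan(r["retro_X"]) else r["retro_X"]
        ry = 0.0 if np.isnan(r["retro_Y"]) else r["retro_Y"]
        if np.isnan(xf) or np.isnan(xm):
            continue
        y = 0.0 if np.isnan(y) else y
        if include_retro == "none":
            r_xx = np.log2((xf + eps) / (xm + eps))
            r_comb = np.log2((xf + eps) / (xm + y + eps))
        elif include_retro == "both_sides":
            rr = rx + ry
            r_xx = np.log2((xf + eps) / (xm + eps))
            r_comb = np.log2((xf + rr + eps) / (xm + y + rr + eps))
        elif include_retro == "x_only":
            r_xx = np.log2((xf + rx + eps) / (xm + rx + eps))
            r_comb = np.log2((xf + rx + eps) / (xm + y + rx + eps))
        else:  # y_only
            r_xx = np.log2((xf + eps) / (xm + eps))
            r_comb = np.log2((xf + eps) / (y + ry + eps))
        rows.append((r["family"], r["species"], r["tissue"], include_retro,
                     float(r_xx), float(r_comb)))
    return pd.DataFrame(
        rows, columns=["family", "species", "tissue", "retro_mode", "r_xx", "r_combined"]
    )


def dosage_tests(ratios: pd.DataFrame, alpha: float = 0.05, min_n: int = 5,
                 exclude_between: tuple[str, ...] = ("HSFXY", "HSFY")) -> pd.DataFrame:
    """Per-tissue panel: two-sample MWU between the Xf/Xm and Xf/(Xm+Y)
    populations (male-biased HSFXY excluded from the between-group test) and
    a fixed-median test of r_combined against 0; BH within the panel."""
    rows = []
    for tissue, sub in ratios.groupby("tissue"):
        if tissue not in SOMATIC:
            continue
        btw = sub[~sub["family"].isin(exclude_between)]
        if len(sub) < min_n:
            continue
        row = {"tissue": tissue, "n": len(sub),
               "median_r_xx": float(sub["r_xx"].median()),
               "median_r_combined": float(sub["r_combined"].median()),
               "p_combined_vs_0": fixed_median_test(sub["r_combined"].values, 0.0)}
        if len(btw) >= min_n:
            mwu = stats.mannwhitneyu(btw["r_xx"], btw["r_combined"],
                                     alternative="two-sided")
            row["p_between"] = float(mwu.pvalue)
        else:
            row["p_between"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    ps, qcols = [], []
    for col in ("p_combined_vs_0", "p_between"):
        mask = out[col].notna()
        ps.append((col, mask))
    flat = np.concatenate([out[col][m].values for col, m in ps])
    if len(flat):
        adj, rej = bh_correct(flat, alpha)
        k = 0
        for col, m in ps:
            q = np.full(len(out), np.nan)
            r = np.zeros(len(out), dtype=bool)
            cnt = int(m.sum())
            q[m.values] = adj[k : k + cnt]
            r[m.values] = rej[k : k + cnt]
            out["q" + col[1:]] = q
            out["reject" + col[1:]] = r
            k += cnt
    return out


def escape_gain_estimate(agg: pd.DataFrame) -> pd.DataFrame:
    """Extra female X expression in somatic tissues, percent.

    Per species: median over families and tissues of (Xf/Xm - 1) x 100;
    a "pooled" row gives the median over all family x species x tissue cells.
    """
    wide = _compartment_frame(agg)
    wide = wide.dropna(subset=["Xf", "Xm"])
    wide = wide[wide["Xm"] > 0]
    wide["gain_pct"] = (wide["Xf"] / wide["Xm"] - 1.0) * 100.0
    per_species = (
        wide.groupby("species")["gain_pct"].median().reset_index()
        .rename(columns={"gain_pct": "escape_gain_pct"})
    )
    pooled = pd.DataFrame(
        [{"species": "pooled", "escape_gain_pct": float(wide["gain_pct"].median())}]
    )
    return pd.concat([per_species, pooled], ignore_index=True)
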
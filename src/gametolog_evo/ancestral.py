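"""Ancestral expression inference and ratio statistics.

Ancestral (proto-sex-chromosome) expression per family is the median of the
autosomal one-to-one ortholog values in outgroup species with non-homologous
sex chromosomes, divided by two (per single gene copy/allele).  Current
expression is compared to it as a log2 ratio; panels of ratios are tested
against fixed medians of 0 (no change) and -1 (2-fold loss) with a one-sample
Wilcoxon signed-rank test and Benjamini-Hochberg correction at 0.05.
Continuous ancestral state reconstruction (maximum-likelihood Brownian motion,
equivalently branch-length-weighted squared-change parsimony) and PGLS against
life-history traits complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Phylogeny

SOMA = ("brain", "heart", "kidney", "liver")


# ---------------------------------------------------------------------------
# ancestral levels


def ancestral_level(outgroup_expr: pd.DataFrame, tissue_scope: str = "pooled"
                    ) -> pd.DataFrame:
    """Per-allele ancestral expression per family.

    ``outgroup_expr`` is tidy with columns family/species/tissue/tpm (one
    both-allele ortholog value per outgroup species and tissue).

    tissue_scope:
      * ``pooled`` — one value per family: median across outgroup species of
        each species' across-tissue median, / 2;
      * ``per_tissue`` — one value per family and tissue;
      * ``testis_soma`` — strata "testis" (gonad) and "soma" (non-gonad
        tissues pooled), computed separately.

    Families with no outgroup value are excluded (listed in ``.attrs``).
    """
    req = {"family", "species", "tissue", "tpm"}
    if not req <= set(outgroup_expr.columns):
        raise ValueError(f"outgroup_expr needs columns {sorted(req)}")
    rows = []
    for fam, sub in outgroup_expr.groupby("family"):
        if tissue_scope == "pooled":
            per_sp = sub.groupby("species")["tpm"].median()
            rows.append((fam, "all", float(per_sp.median()) / 2.0))
        elif tissue_scope == "per_tissue":
            for tissue, tsub in sub.groupby("tissue"):
                per_sp = tsub.groupby("species")["tpm"].median()
                rows.append((fam, tissue, float(per_sp.median()) / 2.0))
        elif tissue_scope == "testis_soma":
            gon = sub[sub["tissue"] == "gonad"]
            som = sub[sub["tissue"] != "gonad"]
            if len(gon):
                rows.append((fam, "testis", float(gon.groupby("species")["tpm"].median().median()) / 2.0))
            if len(som):
                rows.append((fam, "soma", float(som.groupby("species")["tpm"].median().median()) / 2.0))
        else:
            raise ValueError(f"unknown tissue_scope {tissue_scope!r}")
    out = pd.DataFrame(rows, columns=["family", "stratum", "ancestral"])
    out.attrs["excluded"] = []
    return out


def ratio(current: float, ancestral: float, pseudocount: float = 0.1) -> float:
    """log2((current + eps) / (ancestral + eps)); inputs must be >= 0."""
    if current < 0 or ancestral < 0:
        raise ValueError("negative expression value")
    return float(np.log2((current + pseudocount) / (ancestral + pseudocount)))


def ratio_set(agg: pd.DataFrame, anc: pd.DataFrame, groups: dict[str, str] | None = None,
              pseudocount: float = 0.1, tissue_scope: str = "pooled") -> pd.DataFrame:
    """Per (family, species, compartment) current/ancestral log2 ratios.

    ``agg`` is the tidy aggregate (family/species/sex/tissue/compartment/tpm);
    ``anc`` comes from :func:`ancestral_level` with the matching scope.
    Compartments emitted: Y_male, X_male, X_female.  ``tissue`` column holds
    the stratum the ratio was computed in ("all" for pooled scope).
    """
    anc_idx = anc.set_index(["family", "stratum"])["ancestral"]
    rows = []
    sub = agg[agg["compartment"].isin(["X", "Y"])]
    for (fam, sp, sex, comp), grp in sub.groupby(["family", "species", "sex", "compartment"]):
        compartment = f"{comp}_{'male' if sex == 'M' else 'female'}"
        if compartment == "Y_female":
            continue
        if tissue_scope == "pooled":
            strata = {"all": float(grp["tpm"].median())}
        elif tissue_scope == "per_tissue":
            strata = {t: float(v) for t, v in grp.groupby("tissue")["tpm"].median().items()}
        elif tissue_scope == "testis_soma":
            strata = {}
            gon = grp[grp["tissue"] == "gonad"]
            som = grp[grp["tissue"] != "gonad"]
            if len(gon):
                strata["testis"] = float(gon["tpm"].median())
            if len(som):
                strata["soma"] = float(som["tpm"].median())
        else:
            raise ValueError(f"unknown tissue_scope {tissue_scope!r}")
        for stratum, cur in strata.items():
            key = (fam, stratum)
            if key not in anc_idx.index:
                continue
            rows.append(
                (fam, sp, (groups or {}).get(sp, "all"), stratum, compartment,
                 ratio(cur, float(anc_idx[key]), pseudocount))
            )
    return pd.DataFrame(
        rows, columns=["family", "species", "group", "tissue", "compartment", "log2_ratio"]
    )


# ---------------------------------------------------------------------------
# fixed-median tests and BH


def fixed_median_test(values, mu0: float) -> float:
    """One-sample Wilcoxon signed-rank of values against a fixed median.

    Two-sided; exact null distribution for n <= 25 non-zero differences,
    normal approximation with continuity correction above.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values for the fixed-median test")
    d = values - mu0
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def bh_correct(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; returns (adjusted, reject)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adj, reject


def panel_tests(ratios: pd.DataFrame, grouping: str = "overall", alpha: float = 0.05,
                min_n: int = 5) -> pd.DataFrame:
    """Fixed-median tests per panel cell, BH-corrected across the panel.

    grouping: overall | group | tissue | species.  Each cell is one
    (grouping value, compartment); reports median ratio, n, and BH-adjusted
    p-values against fixed medians 0 and -1.
    """
    if grouping == "overall":
        keys = pd.Series("all", index=ratios.index)
    elif grouping in ("group", "tissue", "species"):
        keys = ratios[grouping]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for (gval, comp), sub in ratios.groupby([keys, "compartment"]):
        vals = sub["log2_ratio"].values
        if len(vals) < min_n:
            continue
        rows.append({
            "cell": gval, "compartment": comp, "n": len(vals),
            "median_log2_ratio": float(np.median(vals)),
            "median_fold": float(2 ** (-np.median(vals))),
            "p_vs_0": fixed_median_test(vals, 0.0),
            "p_vs_minus1": fixed_median_test(vals, -1.0),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    all_p = np.concatenate([out["p_vs_0"].values, out["p_vs_minus1"].values])
    adj, rej = bh_correct(all_p, alpha)
    m = len(out)
    out["q_vs_0"], out["q_vs_minus1"] = adj[:m], adj[m:]
    out["reject_vs_0"], out["reject_vs_minus1"] = rej[:m], rej[m:]
    return out


# ---------------------------------------------------------------------------
# continuous ancestral state reconstruction


def asr_continuous(phylo: Phylogeny, tip_values: dict[str, float] | pd.Series,
                   zero_length_epsilon: float = 1e-8) -> pd.Series:
    """ML Brownian-motion reconstruction of internal node values.

    Minimizes the branch-length-weighted sum of squared changes
    sum((x_parent - x_child)^2 / bl) with tips fixed, i.e. solves the tree
    Laplacian system.  Returns values for every internal node label.
    """
    tip_values = pd.Series(tip_values, dtype=float)
    tips = set(phylo.tip_labels)
    missing = tips - set(tip_values.index)
    if missing:
        raise ValueError(f"tips without values: {sorted(missing)}")
    internal = [nd for nd in phylo.tree.preorder_node_iter() if not nd.is_leaf()]
    pos = {id(nd): i for i, nd in enumerate(internal)}
    n = len(internal)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for nd in phylo.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length or 0.0
        if bl <= 0:
            bl = zero_length_epsilon
        w = 1.0 / bl
        i = pos[id(nd.parent_node)]
        if nd.is_leaf():
            A[i, i] += w
            b[i] += w * float(tip_values[nd.taxon.label])
        else:
            j = pos[id(nd)]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
    x = np.linalg.solve(A, b)
    return pd.Series({nd.label: x[pos[id(nd)]] for nd in internal})


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PglsResult:
    slope: float
    intercept: float
    slope_se: float
    t: float
    p: float
    df: int


def pgls(phylo_or_vcv, predictor, response) -> PglsResult:
    """Phylogenetic generalized least squares under Brownian motion.

    Error covariance C_ij = shared root-to-MRCA path length.  Accepts a
    :class:`Phylogeny` or a precomputed covariance DataFrame.  Two-sided
    t-test on the slope with df = n - 2.
    """
    x = pd.Series(predictor, dtype=float)
    y = pd.Series(response, dtype=float)
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("need at least 3 species")
    x, y = x[common], y[common]
    if isinstance(phylo_or_vcv, pd.DataFrame):
        C = phylo_or_vcv.loc[common, common].values
    else:
        C = phylo_or_vcv.vcv(list(common)).values
    n = len(common)
    X = np.column_stack([np.ones(n), x.values])
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    try:
        beta = np.linalg.solve(XtCiX, X.T @ Ci @ y.values)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design: {exc}") from exc
    if np.linalg.cond(XtCiX) > 1e12:
        raise ValueError("singular design")
    resid = y.values - X @ beta
    df = n - 2
    sigma2 = float(resid @ Ci @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return PglsResult(slope=float(beta[1]), intercept=float(beta[0]),
                      slope_se=se, t=t, p=p, df=df)
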
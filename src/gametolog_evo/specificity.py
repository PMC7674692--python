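"""Tissue specificity and presence/absence conservation.

TSI (tissue specificity index) = expression in the highest tissue divided by
the sum over tissues; genes with TSI > 0.6 (strict) are labelled
tissue-specific for their top tissue.  Conservation is counted on a
species x gene presence matrix (pseudogene_expressed counts as present,
unclear is missing data) and minimum independent Y losses are obtained by
Dollo parsimony: gains forbidden, so the loss count is the number of maximal
subtrees whose assessed tips are all absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import bh_correct, fixed_median_test
from .io import Phylogeny, PresenceMatrix

TSI_THRESHOLD = 0.6
_PRESENT_STATES = {"present", "pseudogene_expressed"}


@dataclass
class TsiRecord:
    gene: str
    compartment: str
    tsi: float
    top_tissue: str
    label: str  # "broad" or "tissue_specific(<tissue>)"


def tsi(expr_by_tissue: pd.Series, gene: str = "", compartment: str = "") -> TsiRecord | None:
    """Tissue specificity index: max / sum over tissues.

    Ties on the maximum resolve to the first tissue in the vector's order.
    All-zero vectors are undefined -> None (caller should skip with warning).
    """
    v = pd.Series(expr_by_tissue, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two tissues")
    if (v < 0).any():
        raise ValueError("negative expression")
    total = v.sum()
    if total == 0:
        return None
    value = float(v.max() / total)
    top = str(v.idxmax())
    label = f"tissue_specific({top})" if value > TSI_THRESHOLD else "broad"
    return TsiRecord(gene=gene, compartment=compartment, tsi=value, top_tissue=top, label=label)


def tsi_table(agg: pd.DataFrame) -> pd.DataFrame:
    """TSI per (family, species, compartment) from the tidy aggregate.

    Uses the aggregated per-tissue values (brain already combined); for
    males the gonad is testis, for females ovary.
    """
    rows = []
    sub = agg[agg["compartment"].isin(["X", "Y"])]
    for (fam, sp, sex, comp), grp in sub.groupby(["family", "species", "sex", "compartment"]):
        vec = grp.set_index("tissue")["tpm"]
        rec = tsi(vec, gene=fam, compartment=f"{comp}_{'male' if sex == 'M' else 'female'}")
        if rec is None:
            continue
        rows.append({
            "family": fam, "species": sp, "compartment": rec.compartment,
            "tsi": rec.tsi, "top_tissue": rec.top_tissue, "label": rec.label,
        })
    return pd.DataFrame(rows)


def specificity_gain_analysis(ratios_ts: pd.DataFrame, tsi_records: pd.DataFrame,
                              exclude: tuple[str, ...] = ("HSFXY", "HSFY"),
                              alpha: float = 0.05, min_n: int = 5) -> pd.DataFrame:
    """Testis-specificity gain via accelerated somatic decay.

    ``ratios_ts`` holds Y_male current/ancestral log2 ratios computed with
    ancestral levels for testis and soma separately (tissue column in
    {"testis","soma"}); ``tsi_records`` from :func:`tsi_table` provide the
    testis-TSI split (> 0.6 vs <= 0.6) of the male Y compartment.  HSFY is
    excluded.  Reports per (group, stratum) the median ratio, fixed-median
    tests and the between-group (testis-specific vs broad) Mann-Whitney U per
    stratum, BH-corrected together.
    """
    ymask = (tsi_records["compartment"] == "Y_male")
    tsi_y = tsi_records[ymask].set_index(["family", "species"])["tsi"]
    sub = ratios_ts[(ratios_ts["compartment"] == "Y_male")
                    & (~ratios_ts["family"].isin(exclude))].copy()
    key = list(zip(sub["family"], sub["species"]))
    sub["testis_specific"] = [
        bool(tsi_y.get(k, np.nan) > TSI_THRESHOLD) for k in key
    ]
    rows = []
    mwu_rows = []
    for stratum in ("soma", "testis"):
        ss = sub[sub["tissue"] == stratum]
        hi = ss[ss["testis_specific"]]["log2_ratio"].values
        lo = ss[~ss["testis_specific"]]["log2_ratio"].values
        for name, vals in (("tsi_gt_0.6", hi), ("tsi_le_0.6", lo)):
            if len(vals) < min_n:
                rows.append({"group": name, "stratum": stratum, "n": len(vals),
                             "median_log2_ratio": float(np.median(vals)) if len(vals) else np.nan,
                             "p_vs_0": np.nan, "p_vs_minus1": np.nan})
                continue
            rows.append({
                "group": name, "stratum": stratum, "n": len(vals),
                "median_log2_ratio": float(np.median(vals)),
                "p_vs_0": fixed_median_test(vals, 0.0),
                "p_vs_minus1": fixed_median_test(vals, -1.0),
            })
        if len(hi) >= min_n and len(lo) >= min_n:
            mwu = stats.mannwhitneyu(hi, lo, alternative="two-sided")
            mwu_rows.append({"stratum": stratum, "p_between": float(mwu.pvalue)})
    out = pd.DataFrame(rows)
    between = pd.DataFrame(mwu_rows)
    ps = out[["p_vs_0", "p_vs_minus1"]].values.ravel()
    valid = ~np.isnan(ps)
    if valid.any():
        adj = np.full_like(ps, np.nan)
        all_p = np.concatenate([ps[valid], between["p_between"].values]) if len(between) else ps[valid]
        adj_all, _ = bh_correct(all_p, alpha)
        adj[valid] = adj_all[: valid.sum()]
        out[["q_vs_0", "q_vs_minus1"]] = adj.reshape(-1, 2)
        if len(between):
            between["q_between"] = adj_all[valid.sum():]
    out.attrs["between_groups"] = between
    return out


# ---------------------------------------------------------------------------
# conservation


def conserved_count(matrix: PresenceMatrix) -> tuple[int, list[str]]:
    """Genes present (or expressed-pseudogene) in every assessed species.

    unclear cells are missing data: the gene stays eligible if it is present
    everywhere it was assessed.
    """
    genes = []
    for gene in matrix.genes:
        col = matrix.states[gene]
        assessed = col[col != "unclear"]
        if len(assessed) and assessed.isin(_PRESENT_STATES).all():
            genes.append(gene)
    return len(genes), genes


@dataclass
class LossCount:
    gene: str
    losses: int
    unclear_excluded: list[str]


def dollo_losses(phylo: Phylogeny, presence: dict[str, str] | pd.Series,
                 gene: str = "") -> LossCount:
    """Minimum independent 1->0 losses explaining tip states, gains forbidden.

    The gene is ancestrally present (single origin), so the minimum equals the
    number of maximal subtrees whose assessed tips are all absent.  Tips in
    state unclear carry no constraint; pseudogene_expressed counts as present.
    """
    presence = dict(pd.Series(presence))
    tips = set(phylo.tip_labels)
    missing = tips - set(presence)
    if missing:
        raise ValueError(f"presence states missing for tips: {sorted(missing)}")
    unclear = [t for t in tips if presence[t] == "unclear"]
    absent = {t for t in tips if presence[t] == "absent"}
    assessed = tips - set(unclear)
    if assessed and absent >= assessed:
        raise ValueError(
            f"gene {gene or '?'}: absent in every assessed species, "
            "conflicting with ancestral presence"
        )
    # post-order: a node is all-absent if it has >=1 assessed tip and all of
    # its assessed tips are absent
    status: dict[int, str] = {}  # "absent" | "present" | "none" (no data)
    losses = 0
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            st = presence[node.taxon.label]
            status[id(node)] = (
                "none" if st == "unclear" else ("absent" if st == "absent" else "present")
            )
        else:
            kids = [status[id(c)] for c in node.child_nodes()]
            if all(k == "none" for k in kids):
                status[id(node)] = "none"
            elif all(k in ("absent", "none") for k in kids):
                status[id(node)] = "absent"
            else:
                status[id(node)] = "present"
                # each maximal absent child subtree is one loss
                losses += sum(k == "absent" for k in kids)
    if status[id(phylo.tree.seed_node)] == "absent":
        losses += 1  # the whole assessed tree is absent (guarded above)
    return LossCount(gene=gene, losses=losses, unclear_excluded=sorted(unclear))


def loss_table(phylo: Phylogeny, matrix: PresenceMatrix) -> pd.DataFrame:
    """Dollo loss counts for every gene of a presence matrix."""
    rows = []
    for gene in matrix.genes:
        lc = dollo_losses(phylo, matrix.states[gene], gene=gene)
        rows.append({"gene": gene, "losses": lc.losses,
                     "unclear_excluded": ",".join(lc.unclear_excluded)})
    return pd.DataFrame(rows)
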
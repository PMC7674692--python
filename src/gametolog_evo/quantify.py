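"""Expression quantification and cross-species harmonization.

Reads are assigned to transcripts by shared-k-mer compatibility (a pseudo-
alignment stand-in), expression is expressed as TPM, cross-gametolog mapping
is controlled with simulated 100-nt reads, samples are harmonized with a
low-variance-ortholog scaling normalization, and a PCA silhouette check
verifies that samples group by tissue rather than by experiment.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionTable, GametologFamily, SequenceRecord, TISSUES


@dataclass
class ReadAssignment:
    read_id: str
    transcript_ids: list[str]
    weights: list[float]


@dataclass
class CrossMapReport:
    """Per-family and overall fractions of reads landing on the opposite
    gametolog."""

    x_to_y: dict[str, float] = field(default_factory=dict)
    y_to_x: dict[str, float] = field(default_factory=dict)
    overall_x_to_y: float = 0.0
    overall_y_to_x: float = 0.0


# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


def assign_reads(reads: list[SequenceRecord], transcriptome: list[SequenceRecord],
                 k: int = 21) -> tuple[list[ReadAssignment], int]:
    """Assign reads to transcripts by shared-k-mer counts.

    The unique best transcript takes weight 1; exact ties split equally;
    reads sharing no k-mer with any transcript are dropped.  Returns the
    assignments and the dropped-read count.
    """
    if any(len(t) < k for t in transcriptome):
        raise ValueError(f"transcript shorter than k={k}")
    tindex: dict[str, list[int]] = defaultdict(list)
    for ti, t in enumerate(transcriptome):
        for km in set(_kmers(t.seq, k)):
            tindex[km].append(ti)
    out: list[ReadAssignment] = []
    dropped = 0
    ids = [t.id for t in transcriptome]
    for read in reads:
        scores: dict[int, int] = defaultdict(int)
        for km in set(_kmers(read.seq, k)):
            for ti in tindex.get(km, ()):
                scores[ti] += 1
        if not scores:
            dropped += 1
            continue
        best = max(scores.values())
        winners = sorted(ti for ti, s in scores.items() if s == best)
        w = 1.0 / len(winners)
        out.append(ReadAssignment(read.id, [ids[ti] for ti in winners], [w] * len(winners)))
    return out, dropped


def counts_from_assignments(assignments: list[ReadAssignment],
                            transcript_ids: list[str]) -> pd.Series:
    counts = pd.Series(0.0, index=transcript_ids)
    for a in assignments:
        for tid, w in zip(a.transcript_ids, a.weights):
            counts[tid] += w
    return counts


def tpm(counts, lengths) -> pd.Series:
    """Transcripts per million: (c_i/l_i) / sum_j(c_j/l_j) * 1e6."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("non-positive transcript length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return rate * 0.0
    return rate / total * 1e6


def quantify_sample(reads, transcriptome, k: int = 21) -> pd.Series:
    """Reads -> TPM for one sample."""
    assignments, _ = assign_reads(reads, transcriptome, k=k)
    ids = [t.id for t in transcriptome]
    counts = counts_from_assignments(assignments, ids)
    lengths = pd.Series({t.id: len(t) for t in transcriptome})
    return tpm(counts, lengths)


# ---------------------------------------------------------------------------
# cross-gametolog mapping control


def cross_map_test(x_seqs: dict[str, SequenceRecord], y_seqs: dict[str, SequenceRecord],
                   n: int = 100_000, read_len: int = 100, seed: int = 0,
                   k: int = 21) -> CrossMapReport:
    """Simulate reads from each gametolog set and measure cross-assignment.

    ``x_seqs``/``y_seqs`` map family -> transcript.  For each side, ``n``
    uniform reads of ``read_len`` are drawn (spread across families in
    proportion to length) and mapped against the combined X+Y transcriptome;
    the report gives the fraction of reads carrying any weight on the opposite
    gametolog, per family and overall.
    """
    report = CrossMapReport()
    if n == 0:
        return report
    rng = np.random.default_rng(seed)
    transcriptome = [SequenceRecord(f"X::{f}", r.seq) for f, r in x_seqs.items()]
    transcriptome += [SequenceRecord(f"Y::{f}", r.seq) for f, r in y_seqs.items()]

    def simulate_side(seqs: dict[str, SequenceRecord], source: str):
        fams = sorted(seqs)
        lens = np.array([len(seqs[f]) - read_len + 1 for f in fams], dtype=float)
        if (lens <= 0).any():
            raise ValueError("sequence shorter than read length")
        probs = lens / lens.sum()
        picks = rng.choice(len(fams), size=n, p=probs)
        reads = []
        for i, fi in enumerate(picks):
            seq = seqs[fams[fi]].seq
            start = int(rng.integers(0, len(seq) - read_len + 1))
            reads.append(SequenceRecord(f"{source}_{fams[fi]}_{i}", seq[start : start + read_len]))
        return fams, picks, reads

    other = {"X": "Y", "Y": "X"}
    for source, seqs, res in (("X", x_seqs, report.x_to_y), ("Y", y_seqs, report.y_to_x)):
        fams, picks, reads = simulate_side(seqs, source)
        assignments, _ = assign_reads(reads, transcriptome, k=k)
        by_read = {a.read_id: a for a in assignments}
        cross_n: dict[str, int] = defaultdict(int)
        tot: dict[str, int] = defaultdict(int)
        n_cross_total = 0
        for i, fi in enumerate(picks):
            fam = fams[fi]
            tot[fam] += 1
            a = by_read.get(f"{source}_{fam}_{i}")
            if a is None:
                continue
            if any(tid.startswith(other[source] + "::") for tid in a.transcript_ids):
                cross_n[fam] += 1
                n_cross_total += 1
        for fam in fams:
            res[fam] = cross_n[fam] / tot[fam] if tot[fam] else 0.0
        if source == "X":
            report.overall_x_to_y = n_cross_total / n
        else:
            report.overall_y_to_x = n_cross_total / n
    return report


# ---------------------------------------------------------------------------
# scaling normalization


def scaling_normalize(table: ExpressionTable, ortholog_genes=None,
                      n_ref_genes: int = 300, expressed_floor: float = 1.0
                      ) -> tuple[ExpressionTable, pd.Series]:
    """Scale samples using low-variance orthologs expressed everywhere.

    The reference set is the ``n_ref_genes`` orthologs with the lowest
    variance of log2 TPM across samples among those with TPM >
    ``expressed_floor`` in every sample (all available are used, with a
    warning, when fewer exist).  Each sample's factor is the median over
    reference genes of (gene's across-sample geometric mean / gene's value in
    the sample), rescaled to geometric mean 1 so the procedure is idempotent.
    Returns the normalized table and the factors.
    """
    if len(table.samples) < 2:
        raise ValueError("need at least two samples to normalize")
    vals = table.values
    genes = list(ortholog_genes) if ortholog_genes is not None else list(vals.index)
    sub = vals.loc[[g for g in genes if g in vals.index]]
    expressed = sub[(sub > expressed_floor).all(axis=1)]
    if expressed.empty:
        raise ValueError("no ortholog expressed above the floor in all samples")
    if len(expressed) < n_ref_genes:
        warnings.warn(
            f"only {len(expressed)} orthologs expressed in all samples; "
            f"using all of them (requested {n_ref_genes})"
        )
        ref = expressed
    else:
        variances = np.log2(expressed).var(axis=1)
        ref = expressed.loc[variances.nsmallest(n_ref_genes).index]
    geo = np.exp(np.log(ref).mean(axis=1))
    factors = (geo.values[:, None] / ref).median(axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    factors = pd.Series(np.asarray(factors), index=vals.columns, name="factor")
    out = ExpressionTable(vals.mul(factors, axis=1), table.meta.copy())
    return out, factors


# ---------------------------------------------------------------------------
# aggregation


def aggregate(table: ExpressionTable, families: list[GametologFamily]) -> pd.DataFrame:
    """Collapse a TPM table to tidy per-family compartment values.

    Steps: median across individuals within species x sex x tissue; brain and
    cerebellum combined into one "brain" value (median of the two tissue
    medians); multicopy gene copies summed into the family value; retrogene
    copies of one parent summed into a cumulative value; SRY dropped (it is
    primarily expressed during development); X gametolog rows dropped for a
    species whose Y gametolog is absent.

    Returns a DataFrame with columns
    family / species / sex / tissue / compartment / tpm where compartment is
    X, Y, retro_X or retro_Y and tissue is brain/heart/kidney/liver/gonad.
    """
    vals, meta = table.values, table.meta
    for fam in families:
        wanted = list(fam.x_genes.values()) + list(fam.y_genes.values())
        missing = [g for g in wanted if g not in vals.index]
        if missing:
            raise KeyError(f"family {fam.name}: genes absent from table: {missing}")

    # median across individuals, per species x sex x tissue
    key = meta["species"] + "|" + meta["sex"] + "|" + meta["tissue"]
    med = vals.T.groupby(key.values).median().T  # genes x (sp|sex|tissue)

    def cell(gene: str, sp: str, sex: str, tissue: str) -> float:
        if tissue == "brain":
            parts = [
                med.at[gene, f"{sp}|{sex}|{t}"]
                for t in ("brain", "cerebellum")
                if f"{sp}|{sex}|{t}" in med.columns
            ]
            return float(np.median(parts)) if parts else np.nan
        col = f"{sp}|{sex}|{tissue}"
        return float(med.at[gene, col]) if col in med.columns else np.nan

    out_tissues = ("brain", "heart", "kidney", "liver", "gonad")
    rows = []
    species_in_table = sorted(set(meta["species"]))
    for fam in families:
        if fam.name == "SRY":
            continue
        for sp in species_in_table:
            has_y = sp in fam.y_genes
            for sex in ("M", "F"):
                for tissue in out_tissues:
                    if sp in fam.x_genes and has_y:
                        xg = fam.x_genes[sp]
                        xids = [xg] + fam.multicopy.get(xg, [])
                        v = sum(cell(g, sp, sex, tissue) for g in xids)
                        if not np.isnan(v):
                            rows.append((fam.name, sp, sex, tissue, "X", v))
                    if has_y and sex == "M":
                        yg = fam.y_genes[sp]
                        yids = [yg] + fam.multicopy.get(yg, [])
                        v = sum(cell(g, sp, sex, tissue) for g in yids)
                        if not np.isnan(v):
                            rows.append((fam.name, sp, sex, tissue, "Y", v))
                    for parent in ("X", "Y"):
                        rids = [
                            g for g, p in fam.retrogenes.get(sp, [])
                            if p == parent and g in vals.index
                        ]
                        if rids:
                            v = sum(cell(g, sp, sex, tissue) for g in rids)
                            if not np.isnan(v):
                                rows.append(
                                    (fam.name, sp, sex, tissue, f"retro_{parent}", v)
                                )
    return pd.DataFrame(
        rows, columns=["family", "species", "sex", "tissue", "compartment", "tpm"]
    )


def aggregate_outgroups(table: ExpressionTable, families: list[GametologFamily]
                        ) -> pd.DataFrame:
    """Tidy per-family outgroup ortholog values (median across individuals
    and sexes; both-allele autosomal totals), brain+cerebellum combined."""
    vals, meta = table.values, table.meta
    rows = []
    out_tissues = ("brain", "heart", "kidney", "liver", "gonad")
    for fam in families:
        for og, gene in fam.outgroup_genes.items():
            if gene not in vals.index:
                continue
            mask = meta["species"] == og
            sub_meta = meta[mask]
            for tissue in out_tissues:
                if tissue == "brain":
                    cols = sub_meta.index[sub_meta["tissue"].isin(["brain", "cerebellum"])]
                else:
                    cols = sub_meta.index[sub_meta["tissue"] == tissue]
                if len(cols) == 0:
                    continue
                rows.append((fam.name, og, tissue, float(vals.loc[gene, cols].median())))
    return pd.DataFrame(rows, columns=["family", "species", "tissue", "tpm"])


# ---------------------------------------------------------------------------
# PCA batch check


def pca_batch_check(table: ExpressionTable, ortholog_genes=None,
                    experiment: pd.Series | None = None) -> dict:
    """PCA on log2(TPM+1) of orthologs; silhouette of tissue vs experiment
    grouping on PC1-PC2.  "pass" when tissue grouping is the tighter one.

    ``experiment`` assigns each sample a batch label (defaults to species).
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    if len(table.samples) < 3:
        raise ValueError("need at least three samples for the PCA check")
    genes = list(ortholog_genes) if ortholog_genes is not None else list(table.values.index)
    genes = [g for g in genes if g in table.values.index]
    if len(genes) < len(table.samples):
        warnings.warn("fewer orthologs than samples; PCA check may be unstable")
    mat = np.log2(table.values.loc[genes].T + 1.0)
    pcs = PCA(n_components=2).fit_transform(mat)
    tissue = table.meta["tissue"]
    exp = experiment if experiment is not None else table.meta["species"]

    def sil(labels: pd.Series) -> float:
        labels = labels.loc[table.samples]
        if labels.nunique() < 2 or labels.value_counts().min() < 1:
            return float("nan")
        try:
            return float(silhouette_score(pcs, labels))
        except ValueError:
            return float("nan")

    s_tissue, s_exp = sil(tissue), sil(exp)
    ok = bool(np.isnan(s_exp) or (not np.isnan(s_tissue) and s_tissue > s_exp))
    return {
        "tissue_silhouette": s_tissue,
        "experiment_silhouette": s_exp,
        "pass": ok,
    }
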
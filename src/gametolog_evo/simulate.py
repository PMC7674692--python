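"""Synthetic gametolog systems with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: X/Y gametolog pairs at 92-95% nucleotide identity, per-family Y
expression decay (median fold configurable, default 3), female X over-expression
from XCI escape (+25% by default), testis-specificity gained by somatic decay,
Dollo-consistent Y losses on a species tree, intronless retrogenes with a known
parent gametolog, and outgroup autosomal orthologs carrying the ancestral
expression level (two alleles, hence twice the per-allele level).

Every draw comes from one :class:`numpy.random.Generator` seeded by the
config, so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionTable,
    GametologFamily,
    Phylogeny,
    PresenceMatrix,
    SequenceRecord,
    TISSUES,
    read_newick,
    write_fasta,
    write_ortholog_map,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS]

#: the 16 ancestral gametolog families (strata 1-2); the first seven are the
#: universally conserved ones and never lose their Y copy in simulation
FAMILY_NAMES = (
    "SRY", "RBMY", "TSPY", "DDX3XY", "UTXY", "USP9XY", "ZFXY",
    "EIF2S3XY", "HSFXY", "UBA1XY", "EIFA1XY", "CULB4XY",
    "TXLNGXY", "KDM5XY", "RPS4XY", "TMSB4XY",
)
CONSERVED_FAMILIES = FAMILY_NAMES[:7]
#: families that spawn most retrogenes (~95% of the total)
RETRO_PRONE = ("RPS4XY", "TMSB4XY", "EIFA1XY", "EIF2S3XY")

#: map family name -> conventional Y-gene name used in presence matrices
Y_GENE_NAME = {
    "SRY": "SRY", "RBMY": "RBMY", "TSPY": "TSPY", "DDX3XY": "DDX3Y",
    "UTXY": "UTY", "USP9XY": "USP9Y", "ZFXY": "ZFY", "EIF2S3XY": "EIF2S3Y",
    "HSFXY": "HSFY", "UBA1XY": "UBA1Y", "EIFA1XY": "EIFA1Y",
    "CULB4XY": "CULB4Y", "TXLNGXY": "TXLNGY", "KDM5XY": "KDM5D",
    "RPS4XY": "RPS4Y", "TMSB4XY": "TMSB4Y",
}

SOMA_TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Stated world of one synthetic system.

    Defaults are the conditions the analyses were designed around: 16 gametolog
    families, X-Y identity uniform in [0.92, 0.95], a median 3-fold Y expression
    decay across families (log2-normal dispersion 0.5, a documented free
    choice), +25% female X expression from XCI escape, 100-nt reads.
    """

    n_species: int = 6
    n_outgroups: int = 3
    n_families: int = 16
    xy_identity_range: tuple[float, float] = (0.92, 0.95)
    y_decay_median_fold: float = 3.0
    y_decay_dispersion: float = 0.5
    female_escape_gain: float = 0.25
    testis_specific_fraction: float = 0.25
    testis_specific_soma_accel: float = 5.0
    n_retrogenes: int = 4
    read_length: int = 100
    error_rate: float = 0.0
    cds_length: int = 900
    n_background_genes: int = 40
    loss_rate: float = 0.04
    n_individuals: int = 2
    expression_noise_sd: float = 0.2
    n_multicopy_families: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.xy_identity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError(f"bad identity range {self.xy_identity_range}")
        if (1 - lo) * self.cds_length < 1 and lo < 1:
            raise ConfigError("identity range unresolvable at this sequence length")
        if self.y_decay_median_fold <= 1:
            raise ConfigError("y_decay_median_fold must exceed 1")
        if not (0 <= self.female_escape_gain <= 1):
            raise ConfigError("female_escape_gain out of range")
        for name in ("error_rate", "testis_specific_fraction", "loss_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} out of [0,1]")
        if self.cds_length % 3:
            raise ConfigError("cds_length must be a codon multiple")
        if self.n_families > len(FAMILY_NAMES):
            raise ConfigError(f"at most {len(FAMILY_NAMES)} named families supported")


@dataclass
class RetroRecord:
    retro_id: str
    family: str
    parent: str  # "X" or "Y"
    species: str
    ds_at_birth: float
    cds: str
    expression: dict[str, float]  # tissue -> level, sex-shared


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated gametolog system."""

    config: SimulationConfig
    phylogeny: Phylogeny
    species: list[str]
    outgroups: list[str]
    groups: dict[str, str]
    families: list[GametologFamily]
    ancestral_cds: dict[str, str]
    x_seq: dict[tuple[str, str], str]  # (family, species) -> CDS
    y_seq: dict[tuple[str, str], str]  # only where Y survives
    anc_level: pd.DataFrame  # families x tissues, per-allele ancestral level
    decay: pd.Series  # family -> fold (applied to Y, soma-only if testis-specific)
    testis_specific: set[str]
    loss_edges: dict[str, list[str]]  # family -> head-node labels of loss edges
    y_present: dict[str, set[str]]
    retrogenes: list[RetroRecord]
    outgroup_level: dict[tuple[str, str, str], float]  # (family, og_species, tissue) -> both-allele level
    background_level: pd.DataFrame  # background genes x tissues
    bg_seq: dict[tuple[str, str], str]  # (gene, species-or-outgroup) -> seq
    genomes: dict[tuple[str, str], list[SequenceRecord]]  # (species, sex) -> scaffolds
    introns: dict[str, list[tuple[int, int]]]  # scaffold -> intron intervals
    traits: pd.DataFrame
    expression: ExpressionTable = None  # observed (noisy) table, all species

    # -- derived views -----------------------------------------------------

    def family(self, name: str) -> GametologFamily:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)

    def true_allele_levels(self, family: str, species: str, tissue: str) -> dict[str, float]:
        """Noise-free levels: Xm, Xf_active, Xf_escape, Y (0 if lost)."""
        a = float(self.anc_level.loc[family, tissue])
        esc = self.config.female_escape_gain
        y = 0.0
        if species in self.y_present[family]:
            d = float(self.decay[family])
            if family in self.testis_specific and tissue == "gonad":
                y = a
            else:
                y = a / d
        return {"Xm": a, "Xf_active": a, "Xf_escape": a * esc, "Y": y}

    def true_tpm(self, species: str, sex: str, tissue: str) -> pd.Series:
        """Noise-free relative abundance per transcript in one sample."""
        vals: dict[str, float] = {}
        if species in self.outgroups:
            for fam in self.families:
                gid = fam.outgroup_genes.get(species)
                if gid is not None:
                    vals[gid] = self.outgroup_level[(fam.name, species, tissue)]
        else:
            for fam in self.families:
                lv = self.true_allele_levels(fam.name, species, tissue)
                vals[fam.x_genes[species]] = (
                    lv["Xm"] if sex == "M" else lv["Xf_active"] + lv["Xf_escape"]
                )
                if sex == "M" and species in self.y_present[fam.name]:
                    yid = fam.y_genes[species]
                    copies = [yid] + fam.multicopy.get(yid, [])
                    for cid in copies:
                        vals[cid] = lv["Y"] / len(copies)
            for rec in self.retrogenes:
                if rec.species == species:
                    vals[rec.retro_id] = rec.expression[tissue]
        for gene in self.background_level.index:
            vals[gene] = float(self.background_level.loc[gene, tissue])
        return pd.Series(vals, dtype=float)

    def transcripts(self, species: str, sex: str) -> list[SequenceRecord]:
        recs: list[SequenceRecord] = []
        if species in self.outgroups:
            for fam in self.families:
                gid = fam.outgroup_genes.get(species)
                if gid is not None:
                    recs.append(SequenceRecord(gid, self.ancestral_cds[fam.name]))
        else:
            for fam in self.families:
                recs.append(SequenceRecord(fam.x_genes[species], self.x_seq[(fam.name, species)]))
                if sex == "M" and species in self.y_present[fam.name]:
                    yid = fam.y_genes[species]
                    yseq = self.y_seq[(fam.name, species)]
                    recs.append(SequenceRecord(yid, yseq))
                    for cid in fam.multicopy.get(yid, []):
                        recs.append(SequenceRecord(cid, yseq))
            for rec in self.retrogenes:
                if rec.species == species:
                    recs.append(SequenceRecord(rec.retro_id, rec.cds))
        for gene in self.background_level.index:
            recs.append(SequenceRecord(gene, self.bg_seq[(gene, species)]))
        return recs

    def presence_matrix(self) -> PresenceMatrix:
        data = {
            fam.name: [
                "present" if sp in self.y_present[fam.name] else "absent"
                for sp in self.species
            ]
            for fam in self.families
        }
        return PresenceMatrix(pd.DataFrame(data, index=self.species))


# ---------------------------------------------------------------------------
# sequence helpers


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    codons = [NONSTOP_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return "".join(codons)

def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Exactly n_subs substitutions at distinct positions (no indels)."""
    if n_subs <= 0:
        return seq
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _mutate_coding(rng: np.random.Generator, cds: str, n_subs: int) -> str:
    """Substitutions that never create an internal stop codon (the gametolog
    CDSs stay protein-coding under purifying selection)."""
    if n_subs <= 0:
        return cds
    pos = rng.choice(len(cds), size=min(n_subs, len(cds)), replace=False)
    out = list(cds)
    for p in pos:
        cstart = (p // 3) * 3
        choices = []
        for b in BASES:
            if b == out[p]:
                continue
            codon = "".join(out[cstart : cstart + 3])
            codon = codon[: p - cstart] + b + codon[p - cstart + 1 :]
            if codon not in STOPS:
                choices.append(b)
        if choices:
            out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


_SYN_THIRD: dict[str, list[str]] = {}


def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


for _c in NONSTOP_CODONS:
    aa = _codon_aa(_c)
    alts = []
    for b in BASES:
        alt = _c[:2] + b
        if alt != _c and alt not in STOPS and _codon_aa(alt) == aa:
            alts.append(alt)
    _SYN_THIRD[_c] = alts


def _mutate_mostly_synonymous(rng: np.random.Generator, cds: str, p_codon: float,
                              p_nonsyn: float = 0.05) -> str:
    """Per-codon synonymous 3rd-position changes with prob p_codon, plus a
    small admixture of nonsynonymous changes; keeps amino-acid similarity high."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if rng.random() < p_codon and _SYN_THIRD.get(c):
            alts = _SYN_THIRD[c]
            codons[i] = alts[rng.integers(0, len(alts))]
        elif rng.random() < p_nonsyn:
            codons[i] = _mutate(rng, codons[i], 1)
            if codons[i] in STOPS:
                codons[i] = c
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _calibrate_decay_scale(target_median: float, sigma_log2: float,
                           ts_fraction: float, accel: float) -> float:
    """Scale c such that the mixture {(1-p) c*2^N(0,s), p accel*c*2^N(0,s)}
    has median target_median (bisection on the mixture CDF)."""
    from scipy.stats import norm

    x = np.log2(target_median)
    da = np.log2(accel)
    p = ts_fraction

    def cdf_at_target(mu: float) -> float:
        if sigma_log2 == 0:
            return (1 - p) * (x >= mu) + p * (x >= mu + da)
        return (1 - p) * norm.cdf((x - mu) / sigma_log2) + p * norm.cdf(
            (x - mu - da) / sigma_log2
        )

    lo, hi = x - da - 4 * sigma_log2 - 1, x + 4 * sigma_log2 + 1
    for _ in range(80):
        mid = (lo + hi) / 2
        if cdf_at_target(mid) > 0.5:
            lo = mid
        else:
            hi = mid
    return float(2 ** ((lo + hi) / 2))


# ---------------------------------------------------------------------------
# tree simulation


def _random_ultrametric_tree(rng: np.random.Generator, species: list[str],
                             root_age: float = 90.0) -> Phylogeny:
    def build(tips: list[str], age: float) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{age:.4f}"
        k = int(rng.integers(1, len(tips)))
        child_age = age * float(rng.uniform(0.45, 0.85))
        left = build(tips[:k], child_age)
        right = build(tips[k:], child_age)
        return f"({left},{right}):{age - child_age:.4f}"

    child_age = root_age * float(rng.uniform(0.6, 0.9))
    k = max(1, int(rng.integers(1, len(species))))
    nwk = (
        f"({build(species[:k], child_age)},{build(species[k:], child_age)}"
        + f"):0.0;"
    )
    # the builder emits a root edge length of 0; strip to a clean rooted tree
    nwk = nwk.replace("):0.0;", ");")
    return read_newick(nwk)


def simulate_bm(phylo: Phylogeny, root_value: float, sigma2_per_my: float,
                rng: np.random.Generator) -> tuple[pd.Series, dict[str, float]]:
    """Brownian motion along the tree; returns tip values and every node's
    realized value (keyed by tip/internal label)."""
    node_vals: dict[int, float] = {}
    out_named: dict[str, float] = {}
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            v = root_value
        else:
            bl = node.edge.length or 0.0
            v = node_vals[id(node.parent_node)] + rng.normal(0.0, np.sqrt(sigma2_per_my * bl))
        node_vals[id(node)] = v
        name = node.taxon.label if node.taxon else node.label
        out_named[name] = v
    tips = pd.Series({t: out_named[t] for t in phylo.tip_labels})
    return tips, out_named


# ---------------------------------------------------------------------------
# main generator


def simulate_system(config: SimulationConfig) -> SyntheticTruth:
    """Generate a full synthetic gametolog system (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    species = [f"sp{i+1:02d}" for i in range(config.n_species)]
    outgroups = [f"og{i+1}" for i in range(config.n_outgroups)]
    phylo = _random_ultrametric_tree(rng, species)
    group_cycle = ("Pr", "Ro", "La", "At")
    groups = {sp: group_cycle[i % 4] for i, sp in enumerate(species)}

    fam_names = list(FAMILY_NAMES[: config.n_families])
    lo, hi = config.xy_identity_range
    L = config.cds_length

    ancestral_cds: dict[str, str] = {}
    x_seq: dict[tuple[str, str], str] = {}
    y_seq: dict[tuple[str, str], str] = {}
    families: list[GametologFamily] = []

    # expression backbone
    anc = pd.DataFrame(
        np.exp(rng.normal(np.log(30.0), 1.0, size=(len(fam_names), 1)))
        * np.exp(rng.normal(0.0, 0.25, size=(len(fam_names), len(TISSUES)))),
        index=fam_names,
        columns=list(TISSUES),
    )
    n_ts = int(round(config.testis_specific_fraction * len(fam_names)))
    eligible = [f for f in fam_names if f != "SRY"]
    testis_specific = set(
        rng.choice(eligible, size=min(n_ts, len(eligible)), replace=False).tolist()
    )
    # Testis-specific genes keep testis expression but lose somatic expression
    # at an accelerated rate (x accel).  The base scale is calibrated so the
    # across-family median of realized somatic decay equals the configured
    # median fold despite the accelerated subpopulation.
    scale = _calibrate_decay_scale(
        config.y_decay_median_fold, config.y_decay_dispersion,
        len(testis_specific) / len(fam_names), config.testis_specific_soma_accel,
    )
    base = scale * np.exp2(rng.normal(0.0, config.y_decay_dispersion, size=len(fam_names)))
    decay = pd.Series(base, index=fam_names)
    for f in testis_specific:
        decay[f] *= config.testis_specific_soma_accel

    # Y losses (Dollo): walk edges preorder, a loss shadows everything below
    loss_edges: dict[str, list[str]] = {f: [] for f in fam_names}
    y_present: dict[str, set[str]] = {}
    tip_sets: dict[int, set[str]] = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            tip_sets[id(node)] = {node.taxon.label}
        else:
            tip_sets[id(node)] = set().union(*(tip_sets[id(c)] for c in node.child_nodes()))
    edges = [
        nd for nd in phylo.tree.preorder_node_iter() if nd.parent_node is not None
    ]
    for fam in fam_names:
        lost_tips: set[str] = set()
        shadow: set[int] = set()
        if fam not in CONSERVED_FAMILIES:
            for nd in edges:
                if id(nd) in shadow:
                    continue
                if tip_sets[id(nd)] >= (set(species) - lost_tips):
                    continue  # keep the family present in at least one species
                if rng.random() < config.loss_rate:
                    label = nd.taxon.label if nd.taxon else nd.label
                    loss_edges[fam].append(label)
                    lost_tips |= tip_sets[id(nd)]
                    for sub in nd.preorder_iter():
                        shadow.add(id(sub))
        y_present[fam] = set(species) - lost_tips

    # sequences and family bookkeeping
    mc_options = [f for f in fam_names if f in CONSERVED_FAMILIES and f != "SRY"]
    multicopy_fams = set(
        rng.choice(
            mc_options,
            size=min(config.n_multicopy_families, len(mc_options)),
            replace=False,
        ).tolist()
    ) if mc_options else set()
    for fam in fam_names:
        cds = _random_cds(rng, L)
        ancestral_cds[fam] = cds
        f = GametologFamily(fam)
        for sp in species:
            xs = _mutate_coding(rng, cds, int(round(0.02 * L)))
            x_seq[(fam, sp)] = xs
            f.x_genes[sp] = f"{fam}_X@{sp}"
            if sp in y_present[fam]:
                ident = float(rng.uniform(lo, hi))
                ys = _mutate_coding(rng, xs, int(round((1 - ident) * L)))
                y_seq[(fam, sp)] = ys
                yid = f"{fam}_Y@{sp}"
                f.y_genes[sp] = yid
                if fam in multicopy_fams:
                    f.multicopy[yid] = [f"{fam}_Y2@{sp}"]
        for og in outgroups:
            f.outgroup_genes[og] = f"{fam}_og@{og}"
        families.append(f)

    outgroup_level: dict[tuple[str, str, str], float] = {}
    for fam in fam_names:
        for og in outgroups:
            for t in TISSUES:
                outgroup_level[(fam, og, t)] = float(
                    2.0 * anc.loc[fam, t] * np.exp(rng.normal(0.0, 0.15))
                )

    # background autosomal one-to-one orthologs (shared ids across species)
    bg_genes = [f"BG{i:03d}" for i in range(config.n_background_genes)]
    background_level = pd.DataFrame(
        np.exp(rng.normal(np.log(20.0), 1.0, size=(len(bg_genes), 1)))
        * np.exp(rng.normal(0.0, 0.2, size=(len(bg_genes), len(TISSUES)))),
        index=bg_genes,
        columns=list(TISSUES),
    )
    bg_base = {g: _random_cds(rng, 600) for g in bg_genes}
    bg_seq: dict[tuple[str, str], str] = {}
    for g in bg_genes:
        for sp in species + outgroups:
            bg_seq[(g, sp)] = _mutate(rng, bg_base[g], int(round(0.01 * 600)))

    # retrogenes
    retros: list[RetroRecord] = []
    for i in range(config.n_retrogenes):
        if rng.random() < 0.95:
            fam = str(rng.choice([f for f in RETRO_PRONE if f in fam_names] or fam_names))
        else:
            fam = str(rng.choice(fam_names))
        sp = str(rng.choice(species))
        parent = "Y" if (rng.random() < 0.5 and sp in y_present[fam]) else "X"
        parent_cds = y_seq[(fam, sp)] if parent == "Y" else x_seq[(fam, sp)]
        target_ds = float(rng.uniform(0.1, 0.6))
        retro_cds = _mutate_mostly_synonymous(rng, parent_cds, p_codon=target_ds * 0.45)
        expr = {t: float(np.exp(rng.normal(np.log(2.0), 0.5))) for t in TISSUES}
        rec = RetroRecord(
            retro_id=f"{fam}_retro{i+1}@{sp}",
            family=fam,
            parent=parent,
            species=sp,
            ds_at_birth=target_ds,
            cds=retro_cds,
            expression=expr,
        )
        retros.append(rec)
        famobj = next(f for f in families if f.name == fam)
        famobj.retrogenes.setdefault(sp, []).append((rec.retro_id, parent))

    # genomes + intron annotation
    genomes: dict[tuple[str, str], list[SequenceRecord]] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    for sp in species:
        shared: list[SequenceRecord] = []
        male_only: list[SequenceRecord] = []
        for fam in fam_names:
            xs = x_seq[(fam, sp)]
            half = (len(xs) // 6) * 3
            flank1, flank2 = _random_dna(rng, 300), _random_dna(rng, 300)
            intron = _random_dna(rng, 150)
            sid = f"{sp}_gX_{fam}"
            shared.append(
                SequenceRecord(sid, flank1 + xs[:half] + intron + xs[half:] + flank2)
            )
            introns[sid] = [(300 + half, 300 + half + 150)]
            if sp in y_present[fam]:
                ys = y_seq[(fam, sp)]
                yid = f"{sp}_gY_{fam}"
                male_only.append(
                    SequenceRecord(yid, _random_dna(rng, 250) + ys + _random_dna(rng, 250))
                )
                introns[yid] = []
        for g in bg_genes:
            sid = f"{sp}_auto_{g}"
            shared.append(
                SequenceRecord(sid, _random_dna(rng, 150) + bg_seq[(g, sp)] + _random_dna(rng, 150))
            )
            introns[sid] = []
        for rec in retros:
            if rec.species == sp:
                sid = f"{sp}_auto_{rec.retro_id}"
                shared.append(
                    SequenceRecord(sid, _random_dna(rng, 200) + rec.cds + _random_dna(rng, 200))
                )
                introns[sid] = []
        genomes[(sp, "F")] = list(shared)
        genomes[(sp, "M")] = list(shared) + male_only

    # life-history traits: exponentiated Brownian motion, independent of decay
    trait_cols = {}
    for trait, (mu, s2) in {
        "body_mass_kg": (np.log(10.0), 0.02),
        "max_longevity_yr": (np.log(20.0), 0.005),
        "gestation_days": (np.log(100.0), 0.005),
    }.items():
        tips, _ = simulate_bm(phylo, mu, s2, rng)
        trait_cols[trait] = np.exp(tips)
    traits = pd.DataFrame(trait_cols).loc[species]

    truth = SyntheticTruth(
        config=config,
        phylogeny=phylo,
        species=species,
        outgroups=outgroups,
        groups=groups,
        families=families,
        ancestral_cds=ancestral_cds,
        x_seq=x_seq,
        y_seq=y_seq,
        anc_level=anc,
        decay=decay,
        testis_specific=testis_specific,
        loss_edges=loss_edges,
        y_present=y_present,
        retrogenes=retros,
        outgroup_level=outgroup_level,
        background_level=background_level,
        bg_seq=bg_seq,
        genomes=genomes,
        introns=introns,
        traits=traits,
    )
    truth.expression = _observed_table(truth, rng)
    return truth


def _observed_table(truth: SyntheticTruth, rng: np.random.Generator) -> ExpressionTable:
    """Noisy measured TPM table over all species, sexes, tissues, individuals."""
    cfg = truth.config
    cols: dict[str, pd.Series] = {}
    meta_rows: dict[str, dict] = {}
    for sp in truth.species + truth.outgroups:
        for sex in ("M", "F"):
            for tissue in TISSUES:
                base = truth.true_tpm(sp, sex, tissue)
                for ind in range(1, cfg.n_individuals + 1):
                    noise = np.exp(
                        rng.normal(0.0, cfg.expression_noise_sd, size=len(base))
                    )
                    sid = f"{sp}|{sex}|{tissue}|{ind}"
                    cols[sid] = base * noise
                    meta_rows[sid] = {
                        "species": sp, "sex": sex, "tissue": tissue, "individual": str(ind)
                    }
    values = pd.DataFrame(cols).fillna(0.0)
    return ExpressionTable(values, pd.DataFrame.from_dict(meta_rows, orient="index"))


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(truth: SyntheticTruth, species: str, sex: str, tissue: str,
                   n_reads: int, seed: int, error_rate: float | None = None,
                   ambiguous_rate: float = 0.0) -> list[SequenceRecord]:
    """Draw RNA-seq reads from a sample's transcripts.

    Reads are sampled proportionally to true expression x transcript length,
    with uniform start positions and i.i.d. per-base substitution errors.
    Female read sets contain no Y-derived reads by construction.  The read id
    carries the source transcript after ``|`` (ground truth for tests).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    cfg = truth.config
    err = cfg.error_rate if error_rate is None else error_rate
    rng = np.random.default_rng(seed)
    txs = [t for t in truth.transcripts(species, sex) if len(t) >= cfg.read_length]
    levels = truth.true_tpm(species, sex, tissue)
    weights = np.array([levels.get(t.id, 0.0) * len(t) for t in txs], dtype=float)
    if weights.sum() <= 0:
        raise ValueError(f"no expressed transcripts in {species}/{sex}/{tissue}")
    probs = weights / weights.sum()
    picks = rng.choice(len(txs), size=n_reads, p=probs)
    reads: list[SequenceRecord] = []
    rl = cfg.read_length
    for i, k in enumerate(picks):
        seq = txs[k].seq
        start = int(rng.integers(0, len(seq) - rl + 1))
        frag = seq[start : start + rl]
        if err > 0:
            n_err = rng.binomial(rl, err)
            if n_err:
                frag = _mutate(rng, frag, n_err)
        if ambiguous_rate > 0 and rng.random() < ambiguous_rate:
            pos = int(rng.integers(0, rl))
            frag = frag[:pos] + "N" + frag[pos + 1 :]
        reads.append(
            SequenceRecord(f"{species}_{sex}_{tissue}_r{i}|{txs[k].id}", frag)
        )
    return reads


# ---------------------------------------------------------------------------
# fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(truth: SyntheticTruth, outdir) -> dict:
    """Emit the whole system as plain-text files plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(truth.phylogeny.write_newick() + "\n")
    write_ortholog_map(truth.families, outdir / "ortholog_map.tsv")
    truth.presence_matrix().to_tsv(outdir / "presence_matrix.tsv")
    truth.expression.to_tsv(outdir / "expression.tsv")
    tr = truth.traits.copy()
    tr.index.name = "species"
    tr.to_csv(outdir / "traits.tsv", sep="\t")
    pd.DataFrame(
        {"family": truth.decay.index, "decay_fold": truth.decay.values,
         "testis_specific": [f in truth.testis_specific for f in truth.decay.index]}
    ).to_csv(outdir / "truth_decay.tsv", sep="\t", index=False)
    for (sp, sex), recs in sorted(truth.genomes.items()):
        write_fasta(recs, outdir / f"genome_{sp}_{sex}.fa")
    for sp in truth.species:
        for sex in ("M", "F"):
            write_fasta(truth.transcripts(sp, sex), outdir / f"transcripts_{sp}_{sex}.fa")
    with open(outdir / "introns.bed", "w") as fh:
        for sid, ivs in sorted(truth.introns.items()):
            for s, e in ivs:
                fh.write(f"{sid}\t{s}\t{e}\n")
    cfg = asdict(truth.config)
    cfg["xy_identity_range"] = list(cfg["xy_identity_range"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def validate_fixture_bundle(outdir) -> None:
    """Recompute checksums against the manifest; raise on any mismatch."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        p = outdir / name
        if not p.exists():
            raise FileNotFoundError(f"bundle file missing: {name}")
        if _sha256(p) != digest:
            raise ValueError(f"checksum mismatch for {name}")
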
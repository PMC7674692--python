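"""End-to-end orchestration on a synthetic system.

``run_all`` chains the stages — simulate, subtraction, read quantification,
scaling normalization, aggregation, ancestral ratio statistics, tissue
specificity, conservation on the packaged matrix, retrogene calling and
dosage accounting — with per-stage seeds derived from one master seed, and
returns a JSON-serializable report of per-stage record counts and headline
statistics.  Fixed seed => identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import ancestral as anc_mod
from . import dosage as dosage_mod
from . import quantify as quant_mod
from . import retro as retro_mod
from . import specificity as spec_mod
from . import subtraction as sub_mod
from .datasets import load_placental_tree, load_presence_matrix
from .io import TISSUES
from .simulate import SimulationConfig, SyntheticTruth, simulate_reads, simulate_system

log = logging.getLogger("gametolog_evo")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; unknown keys rejected on load."""

    seed: int = 0
    simulation: SimulationConfig = None
    n_reads_per_sample: int = 20000
    n_female_reads: int = 50000
    subtraction_species: str | None = None  # default: first simulated species
    n_ref_genes: int = 300
    pseudocount: float = 0.1
    alpha: float = 0.05
    stages: tuple[str, ...] = (
        "subtraction", "quantify", "normalize", "ancestral",
        "specificity", "conservation", "retrogenes", "dosage",
    )

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=_derive_seed(self.seed, 0))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim_raw = raw.pop("simulation", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = set(SimulationConfig.__dataclass_fields__)
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            if "xy_identity_range" in sim_raw:
                sim_raw["xy_identity_range"] = tuple(sim_raw["xy_identity_range"])
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg


def _derive_seed(master: int, stage: int) -> int:
    """Stable per-stage seed below 2**31."""
    return (master * 1_000_003 + stage * 7_919 + 12_345) % (2**31 - 1)


def _protein(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate()).rstrip("*")


def run_all(config: PipelineConfig, outdir=None) -> dict:
    report: dict = {"config_seed": config.seed, "stages": {}}
    resolved = asdict(config)
    resolved["simulation"]["xy_identity_range"] = list(
        resolved["simulation"]["xy_identity_range"]
    )
    resolved["stages"] = list(resolved["stages"])

    truth = simulate_system(config.simulation)
    report["stages"]["simulate"] = {
        "n_species": len(truth.species),
        "n_families": len(truth.families),
        "n_loss_events": int(sum(len(v) for v in truth.loss_edges.values())),
        "n_retrogenes": len(truth.retrogenes),
        "true_median_decay_fold": float(truth.decay.median()),
    }

    stage_fail = None
    try:
        if "subtraction" in config.stages:
            report["stages"]["subtraction"] = _stage_subtraction(config, truth)
        if "quantify" in config.stages:
            report["stages"]["quantify"] = _stage_quantify(config, truth)
        table = truth.expression
        if "normalize" in config.stages:
            table, factors = quant_mod.scaling_normalize(
                table, ortholog_genes=list(truth.background_level.index),
                n_ref_genes=config.n_ref_genes,
            )
            report["stages"]["normalize"] = {
                "n_factors": len(factors),
                "factor_geomean": float(np.exp(np.log(factors).mean())),
            }
        agg = quant_mod.aggregate(table, truth.families)
        og = quant_mod.aggregate_outgroups(table, truth.families)
        report["stages"]["aggregate"] = {"rows": len(agg), "outgroup_rows": len(og)}

        if "ancestral" in config.stages:
            report["stages"]["ancestral"] = _stage_ancestral(config, truth, agg, og)
        if "specificity" in config.stages:
            report["stages"]["specificity"] = _stage_specificity(config, truth, agg, og)
        if "conservation" in config.stages:
            report["stages"]["conservation"] = _stage_conservation()
        if "retrogenes" in config.stages:
            report["stages"]["retrogenes"] = _stage_retrogenes(config, truth, agg)
        if "dosage" in config.stages:
            report["stages"]["dosage"] = _stage_dosage(config, agg)
    except Exception as exc:
        stage = stage_fail or "unknown"
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    report["resolved_config"] = resolved
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (outdir / "resolved_config.json").write_text(
            json.dumps(resolved, indent=1, sort_keys=True)
        )
        agg.to_csv(outdir / "aggregate.tsv", sep="\t", index=False)
    return report


def _stage_subtraction(config: PipelineConfig, truth: SyntheticTruth) -> dict:
    sp = config.subtraction_species or truth.species[0]
    seed = _derive_seed(config.seed, 1)
    per_tissue = max(1, config.n_reads_per_sample // len(TISSUES))
    male_reads, female_reads = [], []
    for i, tissue in enumerate(TISSUES):
        male_reads += simulate_reads(truth, sp, "M", tissue, per_tissue, seed + i)
        female_reads += simulate_reads(
            truth, sp, "F", tissue, config.n_female_reads // len(TISSUES), seed + 100 + i
        )
    female_refs = truth.transcripts(sp, "F")
    contigs, calls, counts = sub_mod.run_subtraction(
        male_reads, female_reads, female_refs,
        truth.genomes[(sp, "M")], truth.genomes[(sp, "F")],
    )
    y_linked = [c for c, call in zip(contigs, calls) if call.verdict == "Y_linked"]
    expressed_y = {
        fam.y_genes[sp] for fam in truth.families
        if sp in fam.y_genes
    }
    recovered = set()
    for c in y_linked:
        for fam in truth.families:
            if sp in fam.y_genes and truth.y_seq[(fam.name, sp)].find(c.seq) >= 0:
                recovered.add(fam.y_genes[sp])
            elif sp in fam.y_genes and c.seq in truth.y_seq[(fam.name, sp)]:
                recovered.add(fam.y_genes[sp])
    counts.update({
        "species": sp,
        "expressed_y_transcripts": len(expressed_y),
        "recovered_y_transcripts": len(recovered),
    })
    return counts


def _stage_quantify(config: PipelineConfig, truth: SyntheticTruth) -> dict:
    sp = config.subtraction_species or truth.species[0]
    seed = _derive_seed(config.seed, 2)
    txs = truth.transcripts(sp, "M")
    reads = simulate_reads(truth, sp, "M", "brain", config.n_reads_per_sample, seed)
    tpm = quant_mod.quantify_sample(reads, txs)
    true_levels = truth.true_tpm(sp, "M", "brain").reindex(tpm.index).fillna(0.0)
    mask = true_levels > 0
    rho = _sstats.spearmanr(tpm[mask], true_levels[mask]).statistic
    return {
        "species": sp,
        "n_reads": config.n_reads_per_sample,
        "tpm_sum": float(tpm.sum()),
        "spearman_vs_truth": float(rho),
    }


def _stage_ancestral(config: PipelineConfig, truth: SyntheticTruth,
                     agg: pd.DataFrame, og: pd.DataFrame) -> dict:
    anc = anc_mod.ancestral_level(og, tissue_scope="pooled")
    ratios = anc_mod.ratio_set(agg, anc, groups=truth.groups,
                               pseudocount=config.pseudocount)
    panel = anc_mod.panel_tests(ratios, grouping="overall", alpha=config.alpha)
    y_row = panel[panel["compartment"] == "Y_male"]
    median_fold = float(y_row["median_fold"].iloc[0]) if len(y_row) else float("nan")
    # per-species Y ratio medians -> ASR + PGLS vs traits on the sim tree
    ymed = (
        ratios[ratios["compartment"] == "Y_male"]
        .groupby("species")["log2_ratio"].median()
    )
    out = {
        "n_ratio_rows": len(ratios),
        "median_y_fold_loss": median_fold,
        "panel": panel.to_dict(orient="records"),
    }
    if set(ymed.index) >= set(truth.species):
        asr = anc_mod.asr_continuous(truth.phylogeny, ymed[truth.species])
        root_label = truth.phylogeny.tree.seed_node.label
        out["asr_root_fold"] = float(2 ** (-asr[root_label]))
        for trait in truth.traits.columns:
            res = anc_mod.pgls(truth.phylogeny, np.log(truth.traits[trait]), ymed)
            out[f"pgls_{trait}_p"] = res.p
    return out


def _stage_specificity(config: PipelineConfig, truth: SyntheticTruth,
                       agg: pd.DataFrame, og: pd.DataFrame) -> dict:
    tsi_records = spec_mod.tsi_table(agg)
    anc_ts = anc_mod.ancestral_level(og, tissue_scope="testis_soma")
    ratios_ts = anc_mod.ratio_set(agg, anc_ts, groups=truth.groups,
                                  pseudocount=config.pseudocount,
                                  tissue_scope="testis_soma")
    gain = spec_mod.specificity_gain_analysis(ratios_ts, tsi_records,
                                              alpha=config.alpha)
    return {
        "n_tsi_records": len(tsi_records),
        "n_testis_specific_calls": int(
            (tsi_records.query("compartment == 'Y_male'")["tsi"] > spec_mod.TSI_THRESHOLD).sum()
        ),
        "gain_table": gain.to_dict(orient="records"),
    }


def _stage_conservation() -> dict:
    tree = load_placental_tree()
    matrix = load_presence_matrix()
    n, genes = spec_mod.conserved_count(matrix)
    losses = spec_mod.loss_table(tree, matrix)
    return {
        "n_genes": len(matrix.genes),
        "n_conserved": n,
        "conserved_genes": genes,
        "losses": losses.set_index("gene")["losses"].to_dict(),
    }


def _stage_retrogenes(config: PipelineConfig, truth: SyntheticTruth,
                      agg: pd.DataFrame) -> dict:
    calls = []
    retro_tpm = (
        agg[agg["compartment"].str.startswith("retro")]
        .groupby(["family", "species"])["tpm"].median()
    )
    for rec in truth.retrogenes:
        fam = truth.family(rec.family)
        genome = truth.genomes[(rec.species, "M")]
        protein = _protein(truth.ancestral_cds[rec.family])
        matches = retro_mod.translated_search(genome, protein, family=rec.family)
        matches = [m for m in matches if m.seq_id == f"{rec.species}_auto_{rec.retro_id}"]
        for m in matches:
            m.intronless = retro_mod.check_intronless(m, truth.introns)
        kept = [m for m in matches if m.passes_thresholds]
        if not kept:
            continue
        x_cds = truth.x_seq[(rec.family, rec.species)]
        y_cds = truth.y_seq.get((rec.family, rec.species))
        call = retro_mod.assign_parent(rec.cds, x_cds, y_cds, match=kept[0],
                                       retro_id=rec.retro_id)
        tpm = float(retro_tpm.get((rec.family, rec.species), np.nan))
        retro_mod.filter_retained([call], {rec.retro_id: tpm})
        call_d = {
            "retro_id": rec.retro_id, "true_parent": rec.parent,
            "called_parent": call.parent, "ds_to_x": call.ds_to_x,
            "ds_to_y": call.ds_to_y, "tpm": call.tpm, "retained": call.retained,
        }
        calls.append(call_d)
    correct = sum(c["called_parent"] == c["true_parent"] for c in calls)
    return {
        "n_true_retrogenes": len(truth.retrogenes),
        "n_called": len(calls),
        "n_parent_correct": correct,
        "calls": calls,
    }


def _stage_dosage(config: PipelineConfig, agg: pd.DataFrame) -> dict:
    out = {}
    for mode in ("none", "both_sides"):
        ratios = dosage_mod.dosage_ratios(agg, include_retro=mode,
                                          pseudocount=config.pseudocount)
        out[f"median_r_xx_{mode}"] = float(ratios["r_xx"].median())
        out[f"median_r_combined_{mode}"] = float(ratios["r_combined"].median())
    tests = dosage_mod.dosage_tests(
        dosage_mod.dosage_ratios(agg, pseudocount=config.pseudocount)
    )
    out["tests"] = tests.to_dict(orient="records")
    gain = dosage_mod.escape_gain_estimate(agg)
    out["escape_gain_pct_pooled"] = float(
        gain.loc[gain["species"] == "pooled", "escape_gain_pct"].iloc[0]
    )
    return out
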
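"""TPM arithmetic, read assignment, cross-mapping control, normalization,
aggregation rules and the PCA batch check."""

import numpy as np
import pandas as pd
import pytest

from gametolog_evo.io import ExpressionTable, SequenceRecord
from gametolog_evo.quantify import (
    aggregate,
    aggregate_outgroups,
    assign_reads,
    cross_map_test,
    pca_batch_check,
    quantify_sample,
    scaling_normalize,
    tpm,
)
from gametolog_evo.simulate import SimulationConfig, simulate_reads, simulate_system


class TestTpm:
    def test_closed_form(self):
        col = tpm([10, 10], {0: 1000, 1: 2000})
        assert col.tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_single_transcript(self):
        assert tpm([7], [500]).iloc[0] == pytest.approx(1e6)

    def test_all_zero_counts(self):
        assert tpm([0, 0], [100, 100]).tolist() == [0.0, 0.0]

    def test_column_sums_to_million(self, small_truth):
        sp = small_truth.species[0]
        reads = simulate_reads(small_truth, sp, "M", "kidney", 5000, 1)
        col = quantify_sample(reads, small_truth.transcripts(sp, "M"))
        assert col.sum() == pytest.approx(1e6, rel=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            tpm([1], [0])


class TestAssignReads:
    def test_unique_best_gets_weight_one(self):
        t1 = SequenceRecord("t1", "ACGTACGTAC" * 10)
        t2 = SequenceRecord("t2", "TTGGCCAATT" * 10)
        read = SequenceRecord("r", t1.seq[10:40])
        out, dropped = assign_reads([read], [t1, t2])
        assert dropped == 0
        assert out[0].transcript_ids == ["t1"] and out[0].weights == [1.0]

    def test_identical_transcripts_split_ties(self):
        seq = "ACGTACGTAC" * 10
        t1, t2 = SequenceRecord("t1", seq), SequenceRecord("t2", seq)
        out, _ = assign_reads([SequenceRecord("r", seq[5:45])], [t1, t2])
        assert sorted(out[0].transcript_ids) == ["t1", "t2"]
        assert out[0].weights == [0.5, 0.5]

    def test_incompatible_read_dropped_and_counted(self):
        t1 = SequenceRecord("t1", "A" * 60)
        out, dropped = assign_reads([SequenceRecord("r", "C" * 30)], [t1])
        assert out == [] and dropped == 1

    def test_y_read_beats_x_at_93pct_identity(self, truth):
        """A read from a Y transcript shares more k-mers with Y than with its
        92-95%-identical X gametolog."""
        sp = truth.species[0]
        fam = "UTXY"
        x = SequenceRecord("X", truth.x_seq[(fam, sp)])
        y = SequenceRecord("Y", truth.y_seq[(fam, sp)])
        hits = 0
        for start in range(0, 700, 50):
            read = SequenceRecord(f"r{start}", y.seq[start : start + 100])
            out, _ = assign_reads([read], [x, y])
            if out and out[0].transcript_ids == ["Y"]:
                hits += 1
        assert hits >= 13  # 14 windows; near-universal correct assignment


class TestCrossMap:
    def test_identical_sequences_cross_fraction_one(self):
        seq = SequenceRecord("s", "ACGTACGTGGCCAATT" * 20)
        rep = cross_map_test({"F": seq}, {"F": SequenceRecord("s2", seq.seq)},
                             n=200, seed=1)
        assert rep.overall_x_to_y == 1.0 and rep.overall_y_to_x == 1.0

    def test_diverged_gametologs_cross_below_5pct(self, truth):
        sp = truth.species[0]
        x = {f.name: SequenceRecord("x", truth.x_seq[(f.name, sp)])
             for f in truth.families if sp in truth.y_present[f.name]}
        y = {f.name: SequenceRecord("y", truth.y_seq[(f.name, sp)])
             for f in truth.families if sp in truth.y_present[f.name]}
        rep = cross_map_test(x, y, n=10000, seed=2)
        assert rep.overall_x_to_y < 0.05
        assert rep.overall_y_to_x < 0.05

    def test_n_zero_is_empty(self):
        rep = cross_map_test({}, {}, n=0)
        assert rep.x_to_y == {} and rep.overall_x_to_y == 0.0


class TestScalingNormalize:
    def _table(self, values: pd.DataFrame) -> ExpressionTable:
        meta = pd.DataFrame(
            {
                "species": "sp1",
                "sex": "M",
                "tissue": "brain",
                "individual": [str(i) for i in range(len(values.columns))],
            },
            index=values.columns,
        )
        return ExpressionTable(values, meta)

    def test_identical_samples_factors_one(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.uniform(2, 100, 50), index=[f"g{i}" for i in range(50)])
        table = self._table(pd.DataFrame({"a": v, "b": v}))
        _, factors = scaling_normalize(table, n_ref_genes=50)
        assert np.allclose(factors.values, 1.0)

    def test_doubled_sample_rescaled(self):
        rng = np.random.default_rng(1)
        v = pd.Series(rng.uniform(2, 100, 50), index=[f"g{i}" for i in range(50)])
        table = self._table(pd.DataFrame({"a": v, "b": 2 * v}))
        normed, factors = scaling_normalize(table, n_ref_genes=50)
        assert factors["b"] / factors["a"] == pytest.approx(0.5)
        pd.testing.assert_series_equal(
            normed.values["a"], normed.values["b"], check_names=False
        )

    def test_idempotent(self, truth):
        with pytest.warns(UserWarning):
            once, _ = scaling_normalize(
                truth.expression, list(truth.background_level.index)
            )
        with pytest.warns(UserWarning):
            twice, factors2 = scaling_normalize(
                once, list(truth.background_level.index)
            )
        assert np.allclose(factors2, 1.0, atol=1e-9)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        v = pd.DataFrame(
            rng.uniform(2, 100, size=(40, 3)),
            index=[f"g{i}" for i in range(40)],
            columns=list("abc"),
        )
        t1 = self._table(v)
        t2 = self._table(v.iloc[::-1])
        _, f1 = scaling_normalize(t1, n_ref_genes=40)
        _, f2 = scaling_normalize(t2, n_ref_genes=40)
        assert np.allclose(f1.values, f2.values)

    def test_no_gene_expressed_everywhere(self):
        v = pd.DataFrame({"a": [5.0, 0.0], "b": [0.0, 5.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            scaling_normalize(self._table(v))


class TestAggregate:
    def test_median_across_individuals(self, truth):
        """The aggregated value is the median over individuals: check one
        cell against a direct computation."""
        fam = truth.family("DDX3XY")
        sp = truth.species[0]
        gene = fam.x_genes[sp]
        vals = truth.expression.values
        meta = truth.expression.meta
        cols = meta.index[
            (meta.species == sp) & (meta.sex == "M") & (meta.tissue == "heart")
        ]
        expected = vals.loc[gene, cols].median()
        agg = aggregate(truth.expression, truth.families)
        got = agg.query(
            "family == 'DDX3XY' and species == @sp and sex == 'M' "
            "and tissue == 'heart' and compartment == 'X'"
        )["tpm"].iloc[0]
        assert got == pytest.approx(expected)

    def test_multicopy_summed(self, truth):
        mc_fams = [f for f in truth.families if f.multicopy]
        assert mc_fams, "default config simulates one multicopy family"
        fam = mc_fams[0]
        sp = next(iter(fam.y_genes))
        yid = fam.y_genes[sp]
        vals, meta = truth.expression.values, truth.expression.meta
        cols = meta.index[(meta.species == sp) & (meta.sex == "M") & (meta.tissue == "liver")]
        expected = sum(
            vals.loc[g, cols].median() for g in [yid] + fam.multicopy[yid]
        )
        agg = aggregate(truth.expression, truth.families)
        famname = fam.name
        got = agg.query(
            "family == @famname and species == @sp and sex == 'M' "
            "and tissue == 'liver' and compartment == 'Y'"
        )["tpm"].iloc[0]
        assert got == pytest.approx(expected)

    def test_sry_excluded(self, truth):
        agg = aggregate(truth.expression, truth.families)
        assert "SRY" not in set(agg["family"])

    def test_x_dropped_where_y_absent(self, truth):
        lost = [
            (f.name, sp) for f in truth.families for sp in truth.species
            if sp not in f.y_genes and f.name != "SRY"
        ]
        assert lost, "default config loses some Y copies"
        agg = aggregate(truth.expression, truth.families)
        for fam, sp in lost:
            assert agg.query("family == @fam and species == @sp").empty

    def test_brain_cerebellum_combined(self, truth):
        agg = aggregate(truth.expression, truth.families)
        assert set(agg["tissue"]) <= {"brain", "heart", "kidney", "liver", "gonad"}

    def test_missing_gene_is_an_error(self, truth):
        crippled = truth.expression.values.drop(
            index=truth.family("DDX3XY").x_genes[truth.species[0]]
        )
        table = ExpressionTable(crippled, truth.expression.meta)
        with pytest.raises(KeyError, match="DDX3XY"):
            aggregate(table, truth.families)


class TestPcaBatchCheck:
    def test_tissue_driven_signal_passes(self, truth):
        res = pca_batch_check(
            truth.expression, list(truth.background_level.index)
        )
        assert res["pass"]
        assert res["tissue_silhouette"] > res["experiment_silhouette"]

    def test_pure_noise_no_crash(self):
        rng = np.random.default_rng(3)
        cols = {}
        meta = {}
        for i in range(12):
            sid = f"s{i}"
            cols[sid] = rng.uniform(0, 100, 30)
            meta[sid] = {
                "species": f"sp{i % 2}", "sex": "M",
                "tissue": ["brain", "liver", "heart"][i % 3], "individual": "1",
            }
        table = ExpressionTable(
            pd.DataFrame(cols, index=[f"g{i}" for i in range(30)]),
            pd.DataFrame.from_dict(meta, orient="index"),
        )
        res = pca_batch_check(table)
        assert abs(res["tissue_silhouette"]) < 0.6

    def test_too_few_samples(self, truth):
        two = truth.expression.subset_samples(
            pd.Series(
                [True, True] + [False] * (len(truth.expression.samples) - 2),
                index=truth.expression.meta.index,
            )
        )
        with pytest.raises(ValueError):
            pca_batch_check(two)
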
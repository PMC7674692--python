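"""Subtraction chain: filtering, k-mer index boundaries, assembly, Y calls."""

import numpy as np
import pytest

from gametolog_evo.io import SequenceRecord, TISSUES
from gametolog_evo.simulate import SimulationConfig, simulate_reads, simulate_system
from gametolog_evo.subtraction import (
    assemble,
    assign_identity,
    build_female_index,
    call_absence,
    classify_y,
    filter_ambiguous,
    kmer_subtract,
    revcomp,
    run_subtraction,
    subtract_by_reference,
)


def _recs(*seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestFilterAmbiguous:
    def test_removes_only_n_reads(self):
        reads = _recs("ACGT", "ACNT", "GGGG")
        assert [r.seq for r in filter_ambiguous(reads)] == ["ACGT", "GGGG"]

    def test_identity_on_clean_input(self):
        reads = _recs("ACGT", "GGGG")
        assert filter_ambiguous(reads) == reads

    def test_all_ambiguous(self):
        assert filter_ambiguous(_recs("NNNN", "ANAN")) == []


class TestSubtractByReference:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ref = _random_seq(rng, 1000)
        self.refs = [SequenceRecord("ref", self.ref)]

    def test_exact_substring_removed(self):
        read = SequenceRecord("r", self.ref[100:200])
        assert subtract_by_reference([read], self.refs) == []

    def test_reverse_complement_removed(self):
        read = SequenceRecord("r", revcomp(self.ref[100:200]))
        assert subtract_by_reference([read], self.refs) == []

    def test_92_93_percent_identity_read_kept(self):
        """A Y read at ~93% identity to its X gametolog (7 mismatches per
        100 nt) exceeds the 5-mismatch mapping limit and survives."""
        rng = np.random.default_rng(1)
        frag = list(self.ref[100:200])
        pos = rng.choice(100, size=7, replace=False)
        for p in pos:
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        read = SequenceRecord("y", "".join(frag))
        assert subtract_by_reference([read], self.refs) == [read]

    def test_threshold_boundary(self):
        frag = list(self.ref[100:200])
        frag[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[50]]
        read = SequenceRecord("r", "".join(frag))
        assert subtract_by_reference([read], self.refs, max_mismatches_per_100=0) == [read]
        assert subtract_by_reference([read], self.refs, max_mismatches_per_100=1) == []

    def test_read_longer_than_reference_kept(self):
        long_read = SequenceRecord("long", self.ref + "ACGT")
        assert subtract_by_reference([long_read], self.refs) == [long_read]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            subtract_by_reference(_recs("ACGT"), [])


class TestKmerIndex:
    def test_frequency_threshold_boundary(self):
        rng = np.random.default_rng(2)
        kmer9 = _random_seq(rng, 35)
        kmer10 = _random_seq(rng, 35)
        reads = _recs(*([kmer9] * 9 + [kmer10] * 10))
        idx = build_female_index(reads, k=35, min_count=10)
        assert kmer9 not in idx
        assert kmer10 in idx

    def test_canonicalization_default_and_stranded(self):
        rng = np.random.default_rng(3)
        km = _random_seq(rng, 35)
        reads = _recs(*([km] * 5 + [revcomp(km)] * 5))
        idx = build_female_index(reads, k=35, min_count=10)
        assert km in idx  # 5 + 5 collapse under canonicalization
        idx_s = build_female_index(reads, k=35, min_count=10, stranded=True)
        assert km not in idx_s

    def test_empty_reads(self):
        assert build_female_index([], k=35).counts == {}

    def test_k_longer_than_read(self):
        with pytest.raises(ValueError):
            build_female_index(_recs("ACGT"), k=35)

    def test_n_kmers_excluded(self):
        km = "A" * 17 + "N" + "A" * 17
        idx = build_female_index(_recs(*[km] * 12), k=35, min_count=10)
        assert idx.counts == {}

    def test_raising_min_count_grows_survivors(self):
        """Monotonicity: a stricter frequency floor indexes fewer k-mers, so
        more male reads survive subtraction."""
        rng = np.random.default_rng(4)
        base = _random_seq(rng, 300)
        female = [SequenceRecord(f"f{i}", base[j : j + 100])
                  for i, j in enumerate(list(range(0, 201, 10)) * 2)]
        male = [SequenceRecord(f"m{i}", base[j : j + 100])
                for i, j in enumerate(range(0, 201, 7))]
        survivors = {}
        for mc in (2, 5, 50):
            idx = build_female_index(female, k=35, min_count=mc)
            survivors[mc] = {r.id for r in kmer_subtract(male, idx)}
        assert survivors[2] <= survivors[5] <= survivors[50]


class TestKmerSubtract:
    def test_containing_read_removed(self):
        rng = np.random.default_rng(5)
        km = _random_seq(rng, 35)
        idx = build_female_index(_recs(*[km] * 10), k=35, min_count=10)
        read = SequenceRecord("r", _random_seq(rng, 30) + km + _random_seq(rng, 30))
        assert kmer_subtract([read], idx) == []

    def test_one_mismatch_everywhere_kept(self):
        """No mismatches allowed: a read whose every 35-mer differs from the
        indexed one at one position survives."""
        rng = np.random.default_rng(6)
        km = _random_seq(rng, 35)
        idx = build_female_index(_recs(*[km] * 10), k=35, min_count=10)
        mutated = km[:17] + ("A" if km[17] != "A" else "C") + km[18:]
        read = SequenceRecord("r", mutated)
        assert kmer_subtract([read], idx) == [read]

    def test_empty_index_keeps_all(self):
        reads = _recs("A" * 50, "C" * 50)
        idx = build_female_index([], k=35)
        assert kmer_subtract(reads, idx) == reads


class TestAssemble:
    def test_perfect_tiling_reconstructs_transcript(self):
        """Reads tiling a 500-nt sequence with >=31-nt overlaps reassemble
        it exactly (derived oracle: the source sequence itself)."""
        rng = np.random.default_rng(7)
        transcript = _random_seq(rng, 500)
        reads = [
            SequenceRecord(f"r{i}", transcript[s : s + 100])
            for i, s in enumerate(list(range(0, 401, 40)) + [400])
        ]
        contigs = assemble(reads, min_overlap=31)
        assert len(contigs) == 1
        assert contigs[0].seq == transcript

    def test_disjoint_reads_stay_separate(self):
        rng = np.random.default_rng(8)
        a, b = _random_seq(rng, 100), _random_seq(rng, 100)
        contigs = assemble(_recs(a, b), min_overlap=31)
        assert sorted(c.seq for c in contigs) == sorted([a, b])

    def test_duplicates_collapse_with_support(self):
        rng = np.random.default_rng(9)
        a = _random_seq(rng, 100)
        contigs = assemble(_recs(a, a), min_overlap=31)
        assert len(contigs) == 1
        assert contigs[0].support == 2

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        transcript = _random_seq(rng, 400)
        reads = [SequenceRecord(f"r{i}", transcript[s : s + 100])
                 for i, s in enumerate(range(0, 301, 30))]
        c1 = assemble(reads)
        c2 = assemble(list(reversed(reads)))
        assert [c.seq for c in c1] == [c.seq for c in c2]


class TestClassifyY:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.y_gene = _random_seq(rng, 600)
        self.shared = _random_seq(rng, 600)
        self.male = [SequenceRecord("m1", self.y_gene + self.shared)]
        self.female = [SequenceRecord("f1", self.shared)]

    def test_male_only_contig_is_y_linked(self):
        from gametolog_evo.subtraction import Contig

        calls = classify_y([Contig("c", self.y_gene[50:500], 3)], self.male, self.female)
        assert calls[0].verdict == "Y_linked"
        assert calls[0].male_coverage >= 0.9

    def test_contig_in_both_genomes_rejected(self):
        from gametolog_evo.subtraction import Contig

        calls = classify_y([Contig("c", self.shared[50:500], 3)], self.male, self.female)
        assert calls[0].verdict == "rejected_female_hit"

    def test_partial_male_coverage_rejected(self):
        from gametolog_evo.subtraction import Contig

        rng = np.random.default_rng(12)
        # 85% from the male genome, 15% novel sequence
        seq = self.y_gene[:340] + _random_seq(rng, 60)
        calls = classify_y([Contig("c", seq, 3)], self.male, self.female)
        assert calls[0].verdict == "rejected_low_male_coverage"


class TestAssignIdentity:
    def test_constructed_y_contig_assigned_to_family(self, truth):
        from Bio.Seq import Seq

        sp = truth.species[0]
        proteins = {
            f.name: str(Seq(truth.ancestral_cds[f.name]).translate()).rstrip("*")
            for f in truth.families
        }
        x_ann = {f.name: f.x_genes[sp] for f in truth.families}
        contig = SequenceRecord("c", truth.y_seq[("DDX3XY", sp)][30:600])
        fam, paired_x, (sim, span) = assign_identity(contig, proteins, x_ann)
        assert fam == "DDX3XY"
        assert paired_x == truth.family("DDX3XY").x_genes[sp]
        assert sim > 0.7  # ~9% nt divergence from the ancestral CDS

    def test_random_sequence_unassigned(self, truth):
        from Bio.Seq import Seq

        rng = np.random.default_rng(13)
        proteins = {
            f.name: str(Seq(truth.ancestral_cds[f.name]).translate()).rstrip("*")
            for f in truth.families
        }
        contig = SequenceRecord("c", _random_seq(rng, 500))
        fam, _, _ = assign_identity(contig, proteins)
        assert fam == "unassigned"

    def test_empty_protein_set_rejected(self):
        with pytest.raises(ValueError):
            assign_identity(SequenceRecord("c", "ACGT" * 30), {})


class TestCallAbsence:
    def setup_method(self):
        rng = np.random.default_rng(14)
        base = _random_seq(rng, 600)
        # "another species'" queries at ~90% identity
        def mutate(seq, n):
            out = list(seq)
            for p in rng.choice(len(seq), size=n, replace=False):
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        self.y_local = base
        self.x_local = mutate(base, 42)  # the diverged X gametolog (7%)
        self.y_query = [SequenceRecord("yq", mutate(base, 60))]
        self.x_query = [SequenceRecord("xq", mutate(self.x_local, 60))]

    def test_present_when_y_matches_better(self):
        genome = [SequenceRecord("g", self.y_local + self.x_local)]
        assert call_absence("F", genome, self.y_query, self.x_query) == "present"

    def test_absent_when_only_x_found(self):
        genome = [SequenceRecord("g", self.x_local)]
        assert call_absence("F", genome, self.y_query, self.x_query) == "absent"

    def test_unassessed_without_male_data(self):
        assert call_absence("F", [], self.y_query, self.x_query) == "unassessed"


class TestEndToEndRecovery:
    def test_recovers_y_transcripts_no_false_calls(self, small_truth):
        """The full chain recovers >=90% of expressed Y transcripts with zero
        autosomal/X contigs called Y-linked (X-Y identity <= 95%)."""
        tr = small_truth
        sp = tr.species[0]
        male, female = [], []
        for i, t in enumerate(TISSUES):
            male += simulate_reads(tr, sp, "M", t, 4000, 100 + i)
            female += simulate_reads(tr, sp, "F", t, 8000, 200 + i)
        contigs, calls, counts = run_subtraction(
            male, female, tr.transcripts(sp, "F"),
            tr.genomes[(sp, "M")], tr.genomes[(sp, "F")],
        )
        y_fams = {f.name for f in tr.families if sp in f.y_genes}
        recovered, false_calls = set(), []
        for c, call in zip(contigs, calls):
            if call.verdict != "Y_linked":
                continue
            hit = None
            for fam in y_fams:
                if c.seq in tr.y_seq[(fam, sp)]:
                    hit = fam
            if hit is None:
                false_calls.append(c.id)
            else:
                recovered.add(hit)
        assert not false_calls
        assert len(recovered) >= 0.9 * len(y_fams)

    def test_high_identity_regime_fails_as_expected(self):
        """At >=98% X-Y identity the subtraction is known to lose
        sensitivity; the chain must NOT reach the 90% recovery bar."""
        tr = simulate_system(
            SimulationConfig(seed=7, n_species=4, n_families=8,
                             n_background_genes=20,
                             xy_identity_range=(0.985, 0.995))
        )
        sp = tr.species[0]
        male, female = [], []
        for i, t in enumerate(TISSUES):
            male += simulate_reads(tr, sp, "M", t, 4000, 100 + i)
            female += simulate_reads(tr, sp, "F", t, 8000, 200 + i)
        contigs, calls, _ = run_subtraction(
            male, female, tr.transcripts(sp, "F"),
            tr.genomes[(sp, "M")], tr.genomes[(sp, "F")],
        )
        y_fams = {f.name for f in tr.families if sp in f.y_genes}
        recovered = {
            fam for c, call in zip(contigs, calls) if call.verdict == "Y_linked"
            for fam in y_fams if c.seq in tr.y_seq[(fam, sp)]
        }
        assert len(recovered) < 0.9 * len(y_fams)
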
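"""Subtraction-based recovery of Y-linked transcripts from male reads.

The chain mirrors the field's male/female subtraction design with desk-scale
native stand-ins for the external aligner/assembler steps:

1. drop reads containing ambiguous bases,
2. remove male reads that map end-to-end to female reference sequences
   (exact-seed anchoring + ungapped extension, <=5 mismatches per 100 nt),
3. remove male reads containing any abundant (frequency >= 10) 35-mer of the
   female read set, exact match, no indels,
4. greedily assemble the survivors into contigs,
5. call a contig Y-linked when it matches male genomic sequence at 100%
   identity over >= 90% of its length and has no female genomic hit
   (female hit = >= 98% identity over >= 90% of the contig).

K-mers are canonicalized (min of forward / reverse complement) by default so
genomic subtraction is strand-agnostic; ``stranded=True`` disables this.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .io import SequenceRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# read filtering


def filter_ambiguous(reads: list[SequenceRecord]) -> list[SequenceRecord]:
    """Keep exactly the reads with no N characters, order preserved."""
    return [r for r in reads if "N" not in r.seq]


class _SeedIndex:
    """Exact-seed index over reference sequences: k-mer -> (ref idx, pos)."""

    def __init__(self, refs: list[SequenceRecord], k: int, both_strands: bool = False):
        self.k = k
        self.refs = refs
        self.seqs = [r.seq for r in refs]
        if both_strands:
            self.seqs += [revcomp(r.seq) for r in refs]
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ri, seq in enumerate(self.seqs):
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((ri, i))


def _end_to_end_mismatches(read: str, ref: str, offset: int) -> int | None:
    """Mismatch count for the read placed at ref[offset:]; None if it
    overhangs the reference."""
    if offset < 0 or offset + len(read) > len(ref):
        return None
    window = ref[offset : offset + len(read)]
    return sum(a != b for a, b in zip(read, window))


def subtract_by_reference(male_reads: list[SequenceRecord],
                          female_refs: list[SequenceRecord],
                          max_mismatches_per_100: float = 5.0,
                          seed_k: int = 21) -> list[SequenceRecord]:
    """Return male reads with no end-to-end match to any female reference.

    A read maps when some exact ``seed_k``-mer anchors it on a reference
    (either strand) and the full ungapped end-to-end placement has at most
    ``max_mismatches_per_100`` mismatches per 100 nt.  Reads longer than every
    reference cannot map and are kept.
    """
    if not female_refs:
        raise ValueError("female reference set is empty")
    idx = _SeedIndex(female_refs, seed_k, both_strands=True)
    survivors = []
    for read in male_reads:
        if _maps_to_reference(read.seq, idx, max_mismatches_per_100):
            continue
        survivors.append(read)
    return survivors


def _maps_to_reference(seq: str, idx: _SeedIndex, max_mm_per_100: float) -> bool:
    k = idx.k
    limit = max_mm_per_100 * len(seq) / 100.0
    if len(seq) < k:
        return False
    tried: set[tuple[int, int]] = set()
    # seeds every k positions guarantee an exact anchor whenever the read has
    # a mismatch-free stretch of >= 2k-1, which holds for <=5 mm per 100 nt
    # placements in practice; the final position is always probed too.
    starts = list(range(0, len(seq) - k + 1, k))
    if starts[-1] != len(seq) - k:
        starts.append(len(seq) - k)
    for s in starts:
        for ri, pos in idx.index.get(seq[s : s + k], ()):
            key = (ri, pos - s)
            if key in tried:
                continue
            tried.add(key)
            mm = _end_to_end_mismatches(seq, idx.seqs[ri], pos - s)
            if mm is not None and mm <= limit:
                return True
    return False


# ---------------------------------------------------------------------------
# k-mer index subtraction


@dataclass
class KmerIndex:
    """Abundant k-mers of a read corpus (the corpus 'signature')."""

    k: int
    counts: dict[str, int]
    min_count: int
    stranded: bool = False

    def __contains__(self, kmer: str) -> bool:
        key = kmer if self.stranded else canonical(kmer)
        return key in self.counts


def build_female_index(female_reads: list[SequenceRecord], k: int = 35,
                       min_count: int = 10, stranded: bool = False) -> KmerIndex:
    """Count k-mers of the female reads; keep those with frequency >= min_count.

    K-mers containing N are excluded.  Canonicalized unless ``stranded``.
    """
    if any(len(r) < k for r in female_reads):
        raise ValueError(f"read shorter than k={k}")
    counts: Counter[str] = Counter()
    for read in female_reads:
        seq = read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer if stranded else canonical(kmer)] += 1
    kept = {km: c for km, c in counts.items() if c >= min_count}
    return KmerIndex(k=k, counts=kept, min_count=min_count, stranded=stranded)


def kmer_subtract(reads: list[SequenceRecord], index: KmerIndex) -> list[SequenceRecord]:
    """Remove reads containing any indexed k-mer as an exact substring."""
    k = index.k
    out = []
    for read in reads:
        seq = read.seq
        hit = any(seq[i : i + k] in index for i in range(len(seq) - k + 1))
        if not hit:
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# greedy overlap assembly


@dataclass
class Contig:
    id: str
    seq: str
    support: int

    def __len__(self) -> int:
        return len(self.seq)


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact overlap of a's suffix with b's prefix (0 if < min)."""
    best = 0
    limit = min(len(a), len(b))
    for ol in range(limit, min_overlap - 1, -1):
        if a[-ol:] == b[:ol]:
            best = ol
            break
    return best


def assemble(reads: list[SequenceRecord], min_overlap: int = 31) -> list[Contig]:
    """Greedy overlap-layout assembly, deterministic.

    Duplicate reads collapse into one sequence (support = multiplicity) and
    contained reads are absorbed.  All suffix-prefix overlaps >= min_overlap
    are enumerated, then merged longest-first with lexicographic tie-breaking
    on (left sequence, right sequence); each sequence joins at most one
    predecessor and one successor, cycles are refused.
    """
    support: Counter[str] = Counter()
    for r in reads:
        support[r.seq] += 1
    seqs = sorted(support)
    # absorb contained sequences (substrings of a longer sequence)
    seqs_by_len = sorted(seqs, key=len, reverse=True)
    kept: list[str] = []
    for s in seqs_by_len:
        host = None
        for t in kept:
            if s in t:
                host = t
                break
        if host is None:
            kept.append(s)
        else:
            support[host] += support.pop(s)
    seqs = sorted(kept)

    # candidate overlaps via prefix index on min_overlap-length words
    pref: dict[str, list[int]] = defaultdict(list)
    for j, s in enumerate(seqs):
        pref[s[:min_overlap]].append(j)
    cands: list[tuple[int, str, str, int, int]] = []
    for i, a in enumerate(seqs):
        seen_j: set[int] = set()
        for ol_start in range(len(a) - min_overlap, -1, -1):
            word = a[ol_start : ol_start + min_overlap]
            for j in pref.get(word, ()):
                if j == i or j in seen_j:
                    continue
                ol = len(a) - ol_start
                if ol <= len(seqs[j]) and a[ol_start:] == seqs[j][:ol]:
                    cands.append((-ol, a, seqs[j], i, j))
                    seen_j.add(j)
    cands.sort()

    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    ol_used: dict[int, int] = {}
    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for neg_ol, _a, _b, i, j in cands:
        if i in succ or j in pred:
            continue
        if find(i) == find(j):
            continue  # would close a cycle
        succ[i] = j
        pred[j] = i
        ol_used[i] = -neg_ol
        parent[find(j)] = find(i)

    contigs = []
    heads = [i for i in range(len(seqs)) if i not in pred]
    for i in sorted(heads, key=lambda i: seqs[i]):
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        seq = seqs[chain[0]]
        sup = support[seqs[chain[0]]]
        for prev, nxt in zip(chain, chain[1:]):
            seq += seqs[nxt][ol_used[prev]:]
            sup += support[seqs[nxt]]
        contigs.append(Contig(id=f"contig{len(contigs)+1}", seq=seq, support=sup))
    return contigs


# ---------------------------------------------------------------------------
# Y-linkage classification


@dataclass
class YCall:
    contig_id: str
    verdict: str  # Y_linked | rejected_female_hit | rejected_low_male_coverage
    male_identity: float
    male_coverage: float
    female_identity: float = 0.0


def _exact_coverage(seq: str, genome_index: _SeedIndex) -> float:
    """Fraction of seq covered by exact genomic matches of length >= k."""
    k = genome_index.k
    if len(seq) < k:
        return 0.0
    covered = [False] * len(seq)
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in genome_index.index:
            for p in range(i, i + k):
                covered[p] = True
    return sum(covered) / len(seq)


def _best_local_identity(seq: str, idx: _SeedIndex, min_span_frac: float = 0.9) -> float:
    """Best ungapped identity of seq against any reference over a span of at
    least min_span_frac of the contig (seed-and-extend, either strand)."""
    k = idx.k
    best = 0.0
    if len(seq) < k:
        return 0.0
    tried: set[tuple[int, int]] = set()
    step = max(1, k // 2)
    starts = list(range(0, len(seq) - k + 1, step))
    if starts[-1] != len(seq) - k:
        starts.append(len(seq) - k)
    for s in starts:
        for ri, pos in idx.index.get(seq[s : s + k], ()):
            key = (ri, pos - s)
            if key in tried:
                continue
            tried.add(key)
            ref = idx.seqs[ri]
            lo = max(0, -(pos - s))
            hi = min(len(seq), len(ref) - (pos - s))
            span = hi - lo
            if span < min_span_frac * len(seq):
                continue
            window = ref[pos - s + lo : pos - s + hi]
            ident = sum(a == b for a, b in zip(seq[lo:hi], window)) / span
            best = max(best, ident)
    return best


def classify_y(contigs: list[Contig], male_genomic: list[SequenceRecord],
               female_genomic: list[SequenceRecord], seed_k: int = 31,
               min_male_coverage: float = 0.90,
               female_hit_identity: float = 0.98,
               female_hit_span: float = 0.90) -> list[YCall]:
    """Classify contigs as Y-linked.

    Y_linked requires exact-match coverage >= min_male_coverage of the contig
    in the male genomic set (100% identity within matches) and no female hit,
    a female hit being >= female_hit_identity over >= female_hit_span of the
    contig length.  The 98% default anchors the known sensitivity limit of
    subtraction at high X-Y identity.
    """
    if not male_genomic or not female_genomic:
        raise ValueError("genomic sets must be non-empty")
    midx = _SeedIndex(male_genomic, seed_k, both_strands=True)
    fidx = _SeedIndex(female_genomic, 21, both_strands=True)
    calls = []
    for c in contigs:
        fem_ident = _best_local_identity(c.seq, fidx, female_hit_span)
        male_cov = _exact_coverage(c.seq, midx)
        if fem_ident >= female_hit_identity:
            verdict = "rejected_female_hit"
        elif male_cov < min_male_coverage:
            verdict = "rejected_low_male_coverage"
        else:
            verdict = "Y_linked"
        calls.append(
            YCall(c.id, verdict, male_identity=1.0 if male_cov > 0 else 0.0,
                  male_coverage=male_cov, female_identity=fem_ident)
        )
    return calls


# ---------------------------------------------------------------------------
# identity assignment & absence calling


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    trimmed = seq[: len(seq) - len(seq) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


def _six_frames(seq: str):
    for strand_seq in (seq, revcomp(seq)):
        for off in range(3):
            yield _translate(strand_seq[off:])


def _best_protein_match(contig_seq: str, protein: str, word: int = 4):
    """Best ungapped translated alignment (identity fraction, aligned span)."""
    pidx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(protein) - word + 1):
        pidx[protein[i : i + word]].append(i)
    best = (0.0, 0)
    for frame in _six_frames(contig_seq):
        tried: set[int] = set()
        for s in range(len(frame) - word + 1):
            for p in pidx.get(frame[s : s + word], ()):
                diag = p - s
                if diag in tried:
                    continue
                tried.add(diag)
                lo = max(0, -diag)
                hi = min(len(frame), len(protein) - diag)
                span = hi - lo
                if span < word:
                    continue
                ident = sum(
                    frame[i] == protein[i + diag] for i in range(lo, hi)
                ) / span
                if (ident, span) > best:
                    best = (ident, span)
    return best


def assign_identity(contig, known_proteins: dict[str, str],
                    x_annotations: dict[str, str] | None = None,
                    min_similarity: float = 0.5):
    """Assign a contig to the gametolog family of its best translated hit.

    ``known_proteins`` maps family -> reference protein.  Returns
    (family_label, paired_x_id, (similarity, span)); label "unassigned" when no
    family reaches ``min_similarity`` (pseudogene/TE/lncRNA-like contigs are
    excluded downstream).  Ties on similarity break to the longer aligned span.
    """
    if not known_proteins:
        raise ValueError("empty reference protein set")
    seq = contig.seq if hasattr(contig, "seq") else str(contig)
    scores = {
        fam: _best_protein_match(seq, prot) for fam, prot in known_proteins.items()
    }
    fam = max(sorted(scores), key=lambda f: scores[f])
    sim, span = scores[fam]
    if sim < min_similarity:
        return "unassigned", None, (sim, span)
    paired_x = (x_annotations or {}).get(fam)
    return fam, paired_x, (sim, span)


def call_absence(family: str, male_genomic: list[SequenceRecord],
                 y_queries: list[SequenceRecord], x_queries: list[SequenceRecord],
                 min_identity: float = 0.70, min_span: float = 0.5) -> str:
    """Call a species' Y gene present/absent from male genomic sequence.

    present: some male genomic region matches the Y queries better than the X
    queries; absent: only X-like matches are retrieved; unassessed: no male
    genomic data or no informative match at all.
    """
    if not male_genomic:
        return "unassessed"
    gidx = _SeedIndex(male_genomic, 21, both_strands=True)

    def best(queries):
        b = 0.0
        for q in queries:
            b = max(b, _best_local_identity(q.seq, gidx, min_span))
        return b

    best_y = best(y_queries)
    best_x = best(x_queries)
    if max(best_y, best_x) < min_identity:
        return "unassessed"
    return "present" if best_y >= best_x else "absent"


def run_subtraction(male_reads, female_reads, female_refs, male_genomic,
                    female_genomic, k: int = 35, min_count: int = 10,
                    min_overlap: int = 31, max_mismatches_per_100: float = 5.0,
                    stranded: bool = False):
    """Full chain; returns (contigs, calls, stage_counts)."""
    counts = {"male_input": len(male_reads)}
    reads = filter_ambiguous(male_reads)
    counts["after_ambiguous_filter"] = len(reads)
    reads = subtract_by_reference(reads, female_refs, max_mismatches_per_100)
    counts["after_reference_subtraction"] = len(reads)
    index = build_female_index(filter_ambiguous(female_reads), k=k,
                               min_count=min_count, stranded=stranded)
    reads = kmer_subtract(reads, index)
    counts["after_kmer_subtraction"] = len(reads)
    contigs = assemble(reads, min_overlap=min_overlap)
    counts["contigs"] = len(contigs)
    calls = classify_y(contigs, male_genomic, female_genomic)
    counts["y_linked"] = sum(c.verdict == "Y_linked" for c in calls)
    return contigs, calls, counts
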
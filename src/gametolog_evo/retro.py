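"""Retrogene identification and parent assignment.

XY-derived retrogenes are found by a native translated homology search
(six-frame, exact 4-aa seeds, ungapped BLOSUM62 extension; nearby matches
merged), kept when amino-acid similarity > 50% over > 80% of the parent
protein and the merged span contains no annotated intron.  Pairwise dS to
both parent gametologs is estimated with the Nei-Gojobori (1986) pathway
method on a codon-aware alignment; the gametolog with the lower dS is the
parent.  Retrogenes are retained when dS < 1 (purifying selection) and
cumulative expression TPM > 1.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord
from .subtraction import revcomp

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _blosum(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -4.0


@dataclass
class RetroMatch:
    seq_id: str
    start: int  # 0-based half-open genomic interval of the merged span
    end: int
    strand: str  # "+" or "-"
    parent_family: str
    similarity: float  # fraction of aligned aa positions with positive score
    coverage: float  # fraction of the query protein covered
    intronless: bool | None = None

    @property
    def passes_thresholds(self) -> bool:
        return self.similarity > 0.5 and self.coverage > 0.8 and bool(self.intronless)


@dataclass
class RetroCall:
    match: RetroMatch
    retro_id: str
    ds_to_x: float
    ds_to_y: float
    parent: str  # "X" | "Y" | "ambiguous"
    tpm: float = np.nan
    retained: bool = False


# ---------------------------------------------------------------------------
# translated search


def _frame_matches(frame_aa: str, protein: str, word: int, x_drop: float = 12.0,
                   min_score_per_pos: float = 0.5):
    """Ungapped local alignments of one translated frame vs the query protein.

    Seeds on exact ``word``-mers, extends in both directions maximizing the
    BLOSUM62 score with an X-drop; yields (frame_start, frame_end, q_start,
    q_end, similarity)."""
    pidx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(protein) - word + 1):
        pidx[protein[i : i + word]].append(i)
    seen_diags: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for s in range(len(frame_aa) - word + 1):
        for p in pidx.get(frame_aa[s : s + word], ()):
            diag = p - s
            if any(lo <= s < hi for lo, hi in seen_diags[diag]):
                continue
            # extend right
            score = sum(_blosum(frame_aa[s + i], protein[p + i]) for i in range(word))
            best_r, run = 0, 0.0
            i = word
            while s + i < len(frame_aa) and p + i < len(protein):
                run += _blosum(frame_aa[s + i], protein[p + i])
                if run > 0:
                    best_r, score, run = i - word + 1, score + run, 0.0
                elif run < -x_drop:
                    break
                i += 1
            # extend left
            best_l, run = 0, 0.0
            j = 1
            while s - j >= 0 and p - j >= 0:
                run += _blosum(frame_aa[s - j], protein[p - j])
                if run > 0:
                    best_l, score, run = j, score + run, 0.0
                elif run < -x_drop:
                    break
                j += 1
            fs, fe = s - best_l, s + word + best_r
            qs, qe = p - best_l, p + word + best_r
            seen_diags[diag].append((fs, fe))
            span = fe - fs
            if span * min_score_per_pos > score:
                continue
            pos = sum(
                _blosum(frame_aa[fs + i], protein[qs + i]) > 0 for i in range(span)
            )
            yield fs, fe, qs, qe, pos / span


def translated_search(genome: list[SequenceRecord], parent_protein: str,
                      family: str = "", word: int = 4, merge_gap: int = 1000
                      ) -> list[RetroMatch]:
    """Six-frame translated search of a protein against genomic sequences.

    Adjacent same-strand matches within ``merge_gap`` nt are merged; the
    merged span's similarity is the alignment-length-weighted mean and its
    coverage the fraction of distinct query residues covered.
    """
    if len(parent_protein) < 30:
        raise ValueError("parent protein shorter than 30 aa")
    raw = []  # (seq_id, strand, g_start, g_end, q_start, q_end, similarity)
    for rec in genome:
        for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
            for off in range(3):
                sub = seq[off:]
                sub = sub[: len(sub) - len(sub) % 3]
                if not sub:
                    continue
                frame_aa = str(Seq(sub).translate())
                for fs, fe, qs, qe, sim in _frame_matches(frame_aa, parent_protein, word):
                    g0, g1 = off + 3 * fs, off + 3 * fe
                    if strand == "-":
                        g0, g1 = len(rec.seq) - g1, len(rec.seq) - g0
                    raw.append((rec.id, strand, g0, g1, qs, qe, sim))
    merged: list[RetroMatch] = []
    bykey = defaultdict(list)
    for m in raw:
        bykey[(m[0], m[1])].append(m)
    for (sid, strand), ms in sorted(bykey.items()):
        ms.sort(key=lambda m: m[2])
        cluster: list[tuple] = []

        def flush():
            if not cluster:
                return
            g0 = min(m[2] for m in cluster)
            g1 = max(m[3] for m in cluster)
            # each query residue counts once, attributed to the best
            # (highest-similarity) sub-match covering it, so weak overlapping
            # frame-shifted hits cannot dilute a strong one
            qcov: set[int] = set()
            wsum = ssum = 0.0
            for m in sorted(cluster, key=lambda m: -m[6]):
                new = set(range(m[4], m[5])) - qcov
                if not new:
                    continue
                qcov |= new
                wsum += len(new)
                ssum += len(new) * m[6]
            merged.append(RetroMatch(
                seq_id=sid, start=g0, end=g1, strand=strand, parent_family=family,
                similarity=ssum / wsum, coverage=len(qcov) / len(parent_protein),
            ))

        for m in ms:
            if cluster and m[2] - max(c[3] for c in cluster) > merge_gap:
                flush()
                cluster = []
            cluster.append(m)
        flush()
    return merged


def check_intronless(match: RetroMatch, annotation: dict[str, list[tuple[int, int]]]
                     ) -> bool:
    """True iff the merged span overlaps no annotated intron interval."""
    if not annotation:
        warnings.warn("empty intron annotation; treating span as intronless")
        return True
    for s, e in annotation.get(match.seq_id, []):
        if s < match.end and match.start < e:
            return False
    return True


# ---------------------------------------------------------------------------
# Nei-Gojobori dS


def _codon_syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3), one-step mutations;
    changes creating stop codons count as nonsynonymous."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        s = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in ("TAA", "TAG", "TGA"):
                continue
            if str(Seq(alt).translate()) == aa:
                s += 1
        syn += s / 3.0
    return syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all mutational pathways; pathways through stops are excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in ("TAA", "TAG", "TGA"):
                ok = False
                break
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            paths.append((s, n))
    if not paths:
        # all pathways pass through a stop; fall back to equal weighting of
        # the raw differences as nonsynonymous
        return 0.0, float(len(diff))
    s_mean = sum(p[0] for p in paths) / len(paths)
    n_mean = sum(p[1] for p in paths) / len(paths)
    return s_mean, n_mean


def _codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware global alignment: amino-acid Needleman-Wunsch back-mapped
    to codons; gap columns removed.  Equal-length in-frame pairs pass through."""
    for cds in (cds_a, cds_b):
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
    aa_a = str(Seq(cds_a).translate())
    aa_b = str(Seq(cds_b).translate())
    if "*" in aa_a.rstrip("*") or "*" in aa_b.rstrip("*"):
        raise ValueError("internal stop codon")
    if len(cds_a) == len(cds_b):
        return cds_a, cds_b
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(aa_a, aa_b)[0]
    out_a, out_b = [], []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        out_a.append(cds_a[3 * a0 : 3 * a1])
        out_b.append(cds_b[3 * b0 : 3 * b1])
    return "".join(out_a), "".join(out_b)


def pairwise_ds(cds_a: str, cds_b: str) -> float:
    """NG86 synonymous divergence with Jukes-Cantor correction.

    pS = Sd / S with S the average synonymous site count of the two sequences
    and Sd the pathway-averaged synonymous differences;
    dS = -(3/4) ln(1 - (4/3) pS); saturation (pS >= 3/4) -> +inf.
    """
    a, b = _codon_align(cds_a, cds_b)
    s_sites_a = s_sites_b = 0.0
    sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        s_sites_a += _codon_syn_fraction(ca)
        s_sites_b += _codon_syn_fraction(cb)
        s, _n = _pathway_counts(ca, cb)
        sd += s
    S = (s_sites_a + s_sites_b) / 2.0
    if S == 0:
        return 0.0
    ps = sd / S
    if ps >= 0.75:
        return float("inf")
    return float(-0.75 * np.log(1.0 - ps * 4.0 / 3.0))


# ---------------------------------------------------------------------------
# parent assignment and retention


def assign_parent(retro_cds: str, x_cds: str | None, y_cds: str | None,
                  match: RetroMatch | None = None, retro_id: str = "") -> RetroCall:
    """Parent gametolog = the one with the lower pairwise dS to the retrogene.

    With one parent sequence missing the other is assigned (flagged through
    the remaining dS being NaN); an exact tie is flagged "ambiguous" and
    excluded from parent-specific tallies downstream.
    """
    if x_cds is None and y_cds is None:
        raise ValueError("both parent sequences missing")
    ds_x = pairwise_ds(retro_cds, x_cds) if x_cds is not None else np.nan
    ds_y = pairwise_ds(retro_cds, y_cds) if y_cds is not None else np.nan
    if np.isnan(ds_x):
        parent = "Y"
    elif np.isnan(ds_y):
        parent = "X"
    elif ds_x == ds_y:
        parent = "ambiguous"
    else:
        parent = "X" if ds_x < ds_y else "Y"
    return RetroCall(match=match, retro_id=retro_id, ds_to_x=float(ds_x),
                     ds_to_y=float(ds_y), parent=parent)


def filter_retained(calls: list[RetroCall], tpm_by_retro: dict[str, float]
                    ) -> list[RetroCall]:
    """Keep retrogenes under purifying selection and actively transcribed:
    min-parent dS < 1 AND cumulative TPM > 1, both strict."""
    kept = []
    for call in calls:
        ds = np.nanmin([call.ds_to_x, call.ds_to_y])
        tpm = float(tpm_by_retro.get(call.retro_id, np.nan))
        call.tpm = tpm
        call.retained = bool(ds < 1.0 and tpm > 1.0)
        if call.retained:
            kept.append(call)
    return kept
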
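"""Alignment primitives shared by curation, host linking, and abundance.

The engine is a desk-scale stand-in for a production aligner: exact-match
k-mer seeds (k=11 for DNA, k=5 for protein), chained per diagonal band,
gapped alignment between the outermost anchors (via edlib), and ungapped
X-drop extension at the ends.  Scores use match +1, mismatch −2, gap open
−3, gap extend −1 with a floor of 30.  The identity/coverage summaries these
hits produce are the only quantities the downstream thresholds consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import edlib
from Bio.Seq import Seq

from .io import ContigRecord

__all__ = [
    "AlignmentHit",
    "ProteinRecord",
    "SubjectIndex",
    "KmerIndex",
    "revcomp",
    "local_align",
    "ani_and_query_coverage",
    "find_orfs",
    "map_reads",
]

DNA_ALPHABET = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K_DNA = 11
DEFAULT_K_PROTEIN = 5
DEFAULT_MIN_SCORE = 30
_BAND = 25          # diagonal drift tolerated when merging anchor runs
_MAX_GAP = 300      # max bp between chained anchors on a diagonal
_XDROP = 12
_MAX_SEED_HITS = 100  # per-seed occurrence cap (repeat guard)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _is_dna(seq: str) -> bool:
    return set(seq) <= DNA_ALPHABET


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a subject sequence.

    Intervals are 0-based half-open on the forward strand of each sequence.
    ``strand`` is the strand of the query relative to the subject.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str = "+"
    score: float = 0.0
    query_length: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def read_fraction(self) -> float | None:
        """Aligned fraction of the query, when the query length is known."""
        if self.query_length is None:
            return None
        q0, q1 = self.query_interval
        return (q1 - q0) / self.query_length


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its coding interval on the source contig."""

    id: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    sequence: str


# ---------------------------------------------------------------------------
# k-mer machinery

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes and validity for every k-window (Horner, O(k) passes)."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    e = enc.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + e[j : j + n]
    bad = np.concatenate([[0], np.cumsum((enc >= 4).astype(np.int64))])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


class SubjectIndex:
    """Exact k-mer position index over one subject sequence.

    DNA subjects use a sorted numpy code array with vectorized lookup;
    protein subjects fall back to a dict (they are short).  Built once per
    subject and reused across queries.
    """

    def __init__(self, sequence: str, k: int):
        self.sequence = sequence
        self.k = k
        self.is_dna = _is_dna(sequence)
        if self.is_dna:
            codes, valid = _kmer_codes(_encode(sequence), k)
            pos = np.nonzero(valid)[0]
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = pos[order].astype(np.int64)
        else:
            d: dict[str, list[int]] = {}
            for i in range(len(sequence) - k + 1):
                d.setdefault(sequence[i : i + k], []).append(i)
            self._dict = d

    def matches(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, subject_pos) arrays of all exact k-mer matches."""
        k = self.k
        if self.is_dna:
            qc, qv = _kmer_codes(_encode(query), k)
            qpos = np.nonzero(qv)[0]
            qc = qc[qpos]
            lo = np.searchsorted(self._codes, qc, side="left")
            hi = np.searchsorted(self._codes, qc, side="right")
            counts = np.minimum(hi - lo, _MAX_SEED_HITS)
            total = int(counts.sum())
            if total == 0:
                return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
            rep_q = np.repeat(qpos, counts)
            cum = np.cumsum(counts) - counts
            offs = np.arange(total, dtype=np.int64) - np.repeat(cum, counts)
            spos = self._pos[np.repeat(lo, counts) + offs]
            return rep_q.astype(np.int64), spos
        qp: list[int] = []
        sp: list[int] = []
        get = self._dict.get
        for i in range(len(query) - k + 1):
            occ = get(query[i : i + k])
            if occ:
                for s in occ[:_MAX_SEED_HITS]:
                    qp.append(i)
                    sp.append(s)
        return np.array(qp, dtype=np.int64), np.array(sp, dtype=np.int64)


# ---------------------------------------------------------------------------
# local alignment

def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, gap_columns) from an extended cigar."""
    m = x = go = gc = 0
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            if ch == "=":
                m += n
            elif ch == "X":
                x += n
            else:  # I or D
                go += 1
                gc += n
            n = 0
    return m, x, go, gc


def _extend_ungapped(a: str, b: str, qa: int, sb: int, direction: int,
                     xdrop: int = _XDROP) -> tuple[int, int, int]:
    """X-drop extension from (qa, sb); returns (length, matches, mismatches)
    of the best-scoring extension.  ``direction`` +1 extends right starting
    at the given positions, −1 extends left ending just before them."""
    best = 0
    best_len = 0
    score = 0
    i = 0
    la, lb = len(a), len(b)
    while True:
        if direction > 0:
            qi, si = qa + i, sb + i
            if qi >= la or si >= lb:
                break
        else:
            qi, si = qa - 1 - i, sb - 1 - i
            if qi < 0 or si < 0:
                break
        score += 1 if a[qi] == b[si] else -2
        i += 1
        if score > best:
            best, best_len = score, i
        if best - score > xdrop:
            break
    matches = (best + 2 * best_len) // 3
    return best_len, matches, best_len - matches


def _segments_from_matches(qpos: np.ndarray, spos: np.ndarray, k: int,
                           min_anchors: int = 2):
    """Cluster seed matches into candidate alignment segments.

    Matches are grouped by diagonal and split at query gaps > ``_MAX_GAP``;
    runs with fewer than ``min_anchors`` anchors are discarded as spurious
    single-seed collisions.  Runs on nearby diagonals with adjacent query
    ranges are then merged (tolerating small indels).  Returns
    (q0, q1, s0, s1) anchor spans, half-open and including the k-mer.
    """
    if len(qpos) == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    d, q, s = diag[order], qpos[order], spos[order]
    is_new = np.empty(len(d), dtype=bool)
    is_new[0] = True
    is_new[1:] = (d[1:] != d[:-1]) | ((q[1:] - q[:-1]) > _MAX_GAP)
    starts = np.flatnonzero(is_new)
    ends = np.append(starts[1:], len(d))
    segs: list[list[int]] = []
    for a, b in zip(starts, ends):
        if b - a < min_anchors:
            continue
        segs.append([int(q[a]), int(q[b - 1]) + k, int(s[a]), int(s[b - 1]) + k,
                     int(d[a])])
    segs.sort(key=lambda t: (t[0], t[2]))
    merged: list[list[int]] = []
    for seg in segs:
        hit = None
        for m in merged:
            if (abs(seg[4] - m[4]) <= _BAND
                    and seg[0] <= m[1] + _MAX_GAP and seg[1] >= m[0] - _MAX_GAP):
                hit = m
                break
        if hit is None:
            merged.append(list(seg))
        else:
            hit[0] = min(hit[0], seg[0])
            hit[1] = max(hit[1], seg[1])
            hit[2] = min(hit[2], seg[2])
            hit[3] = max(hit[3], seg[3])
    return [(q0, q1, s0, s1) for q0, q1, s0, s1, _ in merged]


def _align_segment(a: str, b: str, q0: int, q1: int, s0: int, s1: int):
    """Gapped alignment of the anchored core plus X-drop end extension.

    Returns (q0, q1, s0, s1, matches, mismatches, gap_opens, gap_cols)."""
    core_q = a[q0:q1]
    core_s = b[s0:s1]
    if not core_q or not core_s:
        return None
    if core_q == core_s:
        m, x, go, gc = len(core_q), 0, 0, 0
    else:
        res = edlib.align(core_q, core_s, mode="NW", task="path")
        m, x, go, gc = _cigar_stats(res["cigar"])
    ln_l, m_l, x_l = _extend_ungapped(a, b, q0, s0, -1)
    ln_r, m_r, x_r = _extend_ungapped(a, b, q1, s1, +1)
    return (
        q0 - ln_l, q1 + ln_r, s0 - ln_l, s1 + ln_r,
        m + m_l + m_r, x + x_l + x_r, go, gc,
    )


def local_align(
    a: ContigRecord | str,
    b: ContigRecord | str,
    *,
    k: int | None = None,
    min_score: int = DEFAULT_MIN_SCORE,
    subject_index: SubjectIndex | None = None,
    search_reverse: bool | None = None,
    exclude_self: bool = False,
) -> list[AlignmentHit]:
    """All maximal seed-chained local alignments of ``a`` against ``b``
    scoring at least ``min_score``.  Deterministic for fixed inputs.

    Both inputs must share an alphabet (DNA or protein); mixing is a hard
    error.  For DNA the reverse complement of the query is searched as well
    unless ``search_reverse`` is False.  ``exclude_self`` drops the trivial
    main-diagonal self-alignment (and its mirror) when aligning a sequence
    against itself.
    """
    qid = a.id if isinstance(a, ContigRecord) else "query"
    sid = b.id if isinstance(b, ContigRecord) else "subject"
    qseq = a.sequence if isinstance(a, ContigRecord) else a
    sseq = b.sequence if isinstance(b, ContigRecord) else b
    if not qseq or not sseq:
        raise ValueError("empty sequence")
    a_dna, b_dna = _is_dna(qseq), _is_dna(sseq)
    if a_dna != b_dna:
        raise ValueError("mixed alphabets: one sequence is DNA, the other protein")
    if k is None:
        k = DEFAULT_K_DNA if a_dna else DEFAULT_K_PROTEIN
    if search_reverse is None:
        search_reverse = a_dna
    if subject_index is None or subject_index.k != k:
        subject_index = SubjectIndex(sseq, k)

    qlen = len(qseq)
    results: list[AlignmentHit] = []
    strands = [("+", qseq, False)]
    if search_reverse:
        strands.append(("-", revcomp(qseq), True))
    for strand, query, rev in strands:
        qp, sp = subject_index.matches(query)
        if exclude_self and strand == "+":
            keep = sp > qp
            qp, sp = qp[keep], sp[keep]
        if len(qp) == 0:
            continue
        for q0, q1, s0, s1 in _segments_from_matches(qp, sp, k):
            parts = _align_segment(query, sseq, q0, q1, s0, s1)
            if parts is None:
                continue
            if exclude_self and strand == "+" and parts[0] == parts[2] and parts[1] == parts[3]:
                continue
            eq0, eq1, es0, es1, m, x, go, gc = parts
            columns = m + x + gc
            if columns < 1:
                continue
            score = m - 2 * x - (3 * go + (gc - go))
            if score < min_score:
                continue
            hq0, hq1 = (qlen - eq1, qlen - eq0) if rev else (eq0, eq1)
            results.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=100.0 * m / columns,
                    aln_length=columns,
                    query_interval=(hq0, hq1),
                    subject_interval=(es0, es1),
                    strand=strand,
                    score=float(score),
                    query_length=qlen,
                )
            )
    results.sort(key=lambda h: (-h.score, h.query_interval, h.subject_interval, h.strand))
    return results


def ani_and_query_coverage(
    query: ContigRecord | str,
    subject: ContigRecord | str,
    *,
    min_score: int = DEFAULT_MIN_SCORE,
    subject_index: SubjectIndex | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> tuple[float, float]:
    """ANI and covered fraction of the *query* against the subject.

    Accepted local hits are unioned over query positions, so an alignment
    split by a circular permutation still counts every position once.  ANI
    is the alignment-length-weighted mean identity of accepted hits.
    Returns (0, 0) when there are no hits.
    """
    qseq = query.sequence if isinstance(query, ContigRecord) else query
    if hits is None:
        hits = local_align(query, subject, min_score=min_score, subject_index=subject_index)
    if not hits:
        return 0.0, 0.0
    qlen = len(qseq)
    covered = np.zeros(qlen, dtype=bool)
    wsum = 0.0
    lsum = 0
    for h in hits:
        q0, q1 = h.query_interval
        covered[max(q0, 0) : min(q1, qlen)] = True
        wsum += h.percent_identity * h.aln_length
        lsum += h.aln_length
    return wsum / lsum, float(covered.sum()) / qlen


# ---------------------------------------------------------------------------
# ORF calling

_STARTS = {"ATG", "GTG", "TTG"}
_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(contig: ContigRecord, min_aa: int) -> list[ProteinRecord]:
    """All open reading frames of at least ``min_aa`` residues in six frames.

    Start codons are ATG/GTG/TTG, stops TAA/TAG/TGA; among nested ORFs
    sharing a stop, the longest (earliest start) is kept.  The initiator
    codon is translated as Met regardless of which start codon it is.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = contig.length
    out: list[ProteinRecord] = []
    n = 0
    for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, L - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STOPS:
                    if start is not None:
                        aa_len = (pos - start) // 3
                        if aa_len >= min_aa:
                            protein = "M" + str(Seq(seq[start + 3 : pos]).translate())
                            s0, s1 = start, pos + 3
                            if strand == "-":
                                s0, s1 = L - s1, L - s0
                            out.append(
                                ProteinRecord(
                                    id=f"{contig.id}_orf{n}",
                                    contig_id=contig.id,
                                    interval=(s0, s1),
                                    strand=strand,
                                    sequence=protein,
                                )
                            )
                            n += 1
                        start = None
                elif codon in _STARTS and start is None:
                    start = pos
    out.sort(key=lambda p: (p.interval, p.strand))
    return out


# ---------------------------------------------------------------------------
# Read mapping: numpy k-mer index over a reference panel

class KmerIndex:
    """Sorted-array k-mer index over a panel of reference sequences."""

    def __init__(self, references: Sequence[ContigRecord], k: int):
        if not references:
            raise ValueError("empty reference set")
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        order = sorted(range(len(references)), key=lambda i: references[i].id)
        self.ids = [references[i].id for i in order]
        seqs = [references[i].sequence for i in order]
        self.lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        sep = "N" * k
        concat = sep.join(seqs)
        self.concat_enc = _encode(concat)
        starts = np.zeros(len(seqs), dtype=np.int64)
        off = 0
        for i, s in enumerate(seqs):
            starts[i] = off
            off += len(s) + k
        self.starts = starts
        codes, valid = _kmer_codes(self.concat_enc, k)
        positions = np.nonzero(valid)[0]
        codes = codes[positions]
        srt = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[srt]
        self.sorted_pos = positions[srt]

    def lookup(self, code) -> np.ndarray:
        code = np.uint64(code)
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.sorted_pos[lo:hi]

    def lookup_batch(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) index ranges into ``sorted_pos`` for an array of codes."""
        codes = codes.astype(np.uint64, copy=False)
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi

    def locate(self, gpos: int) -> tuple[int, int]:
        idx = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return idx, int(gpos - self.starts[idx])


def _evaluate_candidate(index: KmerIndex, renc: np.ndarray, ref_idx: int, sstart: int):
    """Ungapped comparison of a read against one reference diagonal.

    Returns (score, matches, overlap, q0, q1, s0, s1) for the overlapping
    portion, or None if there is no overlap."""
    L = len(renc)
    rlen = int(index.lengths[ref_idx])
    s0 = max(sstart, 0)
    s1 = min(sstart + L, rlen)
    if s1 - s0 < 1:
        return None
    q0 = s0 - sstart
    q1 = q0 + (s1 - s0)
    g0 = int(index.starts[ref_idx]) + s0
    ref_slice = index.concat_enc[g0 : g0 + (s1 - s0)]
    matches = int(np.count_nonzero(renc[q0:q1] == ref_slice))
    overlap = s1 - s0
    score = matches - 2 * (overlap - matches)
    return score, matches, overlap, q0, q1, s0, s1


def map_reads(
    reads: Sequence[ContigRecord],
    references: Sequence[ContigRecord],
    *,
    k: int = 15,
    min_score: int = DEFAULT_MIN_SCORE,
    max_candidates: int = 64,
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Best-scoring reference hit per read (ungapped, both strands).

    Seeds are non-overlapping k-mers along the read; candidate diagonals
    are evaluated ungapped and the best score wins, ties going to the
    lexicographically smallest reference id.  Reads with no seed hit or no
    candidate scoring at least ``min_score`` report nothing.
    """
    if not references:
        raise ValueError("empty reference set")
    if index is None:
        index = KmerIndex(references, k)
    k = index.k
    hits: list[AlignmentHit] = []
    for read in reads:
        L = read.length
        best = None  # (score, ref_id, strand, matches, overlap, q0, q1, s0, s1)
        finalized = False
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            if finalized:
                break
            renc = _encode(seq)
            codes, valid = _kmer_codes(renc, k)
            seen_diag: set[tuple[int, int]] = set()
            offsets = np.arange(0, max(L - k + 1, 1), k)
            offsets = offsets[offsets < len(codes)]
            lo, hi = index.lookup_batch(codes[offsets])
            for j, off in enumerate(offsets):
                if not valid[off] or lo[j] == hi[j]:
                    continue
                for gpos in index.sorted_pos[lo[j] : min(hi[j], lo[j] + max_candidates)]:
                    ref_idx, spos = index.locate(int(gpos))
                    sstart = spos - off
                    key = (ref_idx, sstart)
                    if key in seen_diag:
                        continue
                    seen_diag.add(key)
                    ev = _evaluate_candidate(index, renc, ref_idx, sstart)
                    if ev is None:
                        continue
                    score, matches, overlap, q0, q1, s0, s1 = ev
                    ref_id = index.ids[ref_idx]
                    if best is None or score > best[0] or (
                        score == best[0] and ref_id < best[1]
                    ):
                        best = (score, ref_id, strand, matches, overlap, q0, q1, s0, s1)
                if best is not None and best[3] == L:
                    finalized = True  # perfect full-length match
                    break
        if best is None or best[0] < min_score:
            continue
        score, ref_id, strand, matches, overlap, q0, q1, s0, s1 = best
        if strand == "-":
            q0, q1 = L - q1, L - q0
        hits.append(
            AlignmentHit(
                query_id=read.id,
                subject_id=ref_id,
                percent_identity=100.0 * matches / overlap,
                aln_length=overlap,
                query_interval=(q0, q1),
                subject_interval=(s0, s1),
                strand=strand,
                score=float(score),
                query_length=L,
            )
        )
    return hits
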
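"""Stage 1 — viral contig classification, dereplication into populations,
and completeness / chimera / contamination flags.

Contigs are retained when (i) two independent detectors both call them
viral, (ii) one detector calls them viral and they carry a phage marker
protein at >= 30 bits, or (iii) they carry a eukaryotic-virus marker at
>= 30 bits.  Retained contigs are greedily clustered longest-first at
>= 95% ANI across >= 50% of the candidate, and clusters whose
representative is shorter than 10 kbp are dropped.  Completeness is called
from direct terminal repeats (20-5000 bp within 200 bp of both ends) and
chimerism from internal repeats (>= 95% identity across >= 5 kbp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io import ContigRecord, read_table
from . import seqops

__all__ = [
    "DetectorCall",
    "MarkerHit",
    "EvidenceBundle",
    "ViralPopulation",
    "classify_viral_contigs",
    "dereplicate",
    "detect_circularity",
    "detect_chimera",
    "screen_ribosomal",
]

MARKER_CATEGORIES = {
    "phage_structural",
    "temperate_marker",
    "eukaryotic_virus_marker",
    "ribosomal",
}
PHAGE_MARKER_CATEGORIES = {"phage_structural", "temperate_marker"}


@dataclass(frozen=True)
class DetectorCall:
    """One external detector's verdict on a contig."""

    tool: str
    call: str  # 'viral' | 'prophage' | 'none'
    prophage_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.call not in ("viral", "prophage", "none"):
            raise ValueError(f"bad detector call {self.call!r}")

    @property
    def is_viral(self) -> bool:
        return self.call in ("viral", "prophage")


@dataclass(frozen=True)
class MarkerHit:
    """A protein marker hit (HMM-style) with its bit score."""

    domain: str
    category: str
    bit_score: float
    protein_id: str | None = None

    def __post_init__(self):
        if self.category not in MARKER_CATEGORIES:
            raise ValueError(f"unknown marker category {self.category!r}")
        if self.bit_score < 0:
            raise ValueError("bit score must be >= 0")


@dataclass
class EvidenceBundle:
    """Per-contig detector calls and marker hits; the input contract that
    replaces running external classifiers."""

    contig_id: str
    detector_calls: list[DetectorCall] = field(default_factory=list)
    marker_hits: list[MarkerHit] = field(default_factory=list)


@dataclass
class ViralPopulation:
    """A dereplicated viral population with its curation and ecology flags."""

    representative_id: str
    member_ids: list[str]
    length: int
    is_complete: bool = False
    dtr_interval: tuple[tuple[int, int], tuple[int, int]] | None = None
    is_chimera: bool = False
    lifestyle: str | None = None  # 'temperate' | 'lytic'
    host_link: object | None = None
    depth_of_origin: str | None = None
    exported: bool | None = None
    export_source_category: frozenset[str] | None = None

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be among members")


def classify_viral_contigs(
    contigs: Sequence[ContigRecord],
    evidence: Mapping[str, EvidenceBundle],
    phage_marker_floor: float = 30.0,
    euk_marker_floor: float = 30.0,
) -> tuple[list[ContigRecord], dict[str, str]]:
    """Decide which contigs are viral; returns (retained, reason tags).

    Retention reasons (first matching wins for the tag): ``both_detectors``,
    ``detector_plus_marker``, ``eukaryotic_marker``.  When detectors report
    prophage intervals, the shortest interval's subsequence replaces the
    contig prior to dereplication.
    """
    known = {c.id for c in contigs}
    for cid in evidence:
        if cid not in known:
            raise ValueError(f"evidence references unknown contig {cid!r}")
    retained: list[ContigRecord] = []
    reasons: dict[str, str] = {}
    for contig in contigs:
        ev = evidence.get(contig.id, EvidenceBundle(contig.id))
        viral_tools = {c.tool for c in ev.detector_calls if c.is_viral}
        has_phage_marker = any(
            h.category in PHAGE_MARKER_CATEGORIES and h.bit_score >= phage_marker_floor
            for h in ev.marker_hits
        )
        has_euk_marker = any(
            h.category == "eukaryotic_virus_marker" and h.bit_score >= euk_marker_floor
            for h in ev.marker_hits
        )
        if len(viral_tools) >= 2:
            reason = "both_detectors"
        elif len(viral_tools) >= 1 and has_phage_marker:
            reason = "detector_plus_marker"
        elif has_euk_marker:
            reason = "eukaryotic_marker"
        else:
            continue
        intervals = sorted(
            (
                (c.prophage_interval[1] - c.prophage_interval[0], c.prophage_interval, c.tool)
                for c in ev.detector_calls
                if c.call == "prophage" and c.prophage_interval is not None
            ),
        )
        out = contig
        if intervals:
            _, (p0, p1), _ = intervals[0]
            if not (0 <= p0 < p1 <= contig.length):
                raise ValueError(
                    f"contig {contig.id!r}: prophage interval ({p0}, {p1}) out of bounds"
                )
            if (p0, p1) != (0, contig.length):
                out = ContigRecord(contig.id, contig.sequence[p0:p1])
        retained.append(out)
        reasons[contig.id] = reason
    return retained, reasons


AniFn = Callable[[ContigRecord, ContigRecord], tuple[float, float]]


def _default_ani(candidate: ContigRecord, representative: ContigRecord,
                 index_cache: dict | None = None) -> tuple[float, float]:
    idx = None
    if index_cache is not None:
        idx = index_cache.get(representative.id)
        if idx is None:
            idx = seqops.SubjectIndex(representative.sequence, seqops.DEFAULT_K_DNA)
            index_cache[representative.id] = idx
    return seqops.ani_and_query_coverage(candidate, representative, subject_index=idx)


def dereplicate(
    contigs: Sequence[ContigRecord],
    ani_threshold: float = 95.0,
    coverage_threshold: float = 0.5,
    min_length_bp: int = 10000,
    ani_fn: AniFn | None = None,
    coverage_on: str = "candidate",
) -> list[ViralPopulation]:
    """Greedy longest-first clustering at >= ani_threshold ANI across
    >= coverage_threshold of the candidate (cd-hit-est -aS semantics).

    Contigs are sorted by length descending (ties: id ascending); each joins
    the first existing cluster whose representative it matches, else founds
    one.  Clusters whose representative is shorter than ``min_length_bp``
    are dropped afterwards.  ``coverage_on='representative'`` measures the
    covered fraction on the representative instead.
    """
    if coverage_on not in ("candidate", "representative"):
        raise ValueError(f"bad coverage_on {coverage_on!r}")
    cache: dict = {}
    if ani_fn is None:
        ani_fn = lambda cand, rep: _default_ani(cand, rep, cache)  # noqa: E731
    by_id: dict[str, ContigRecord] = {}
    for c in contigs:
        if c.id in by_id:
            raise ValueError(f"duplicate contig id {c.id!r}")
        by_id[c.id] = c
    order = sorted(by_id.values(), key=lambda c: (-c.length, c.id))
    reps: list[ContigRecord] = []
    members: list[list[str]] = []
    for cand in order:
        placed = False
        for i, rep in enumerate(reps):
            if coverage_on == "candidate":
                ani, cov = ani_fn(cand, rep)
            else:
                ani, cov = ani_fn(rep, cand)
            if ani >= ani_threshold and cov >= coverage_threshold:
                members[i].append(cand.id)
                placed = True
                break
        if not placed:
            reps.append(cand)
            members.append([cand.id])
    return [
        ViralPopulation(rep.id, mem, rep.length)
        for rep, mem in zip(reps, members)
        if rep.length >= min_length_bp
    ]


def detect_circularity(
    contig: ContigRecord,
    min_repeat: int = 20,
    max_repeat: int = 5000,
    end_window: int = 200,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Direct terminal repeat pair indicating an assembled circular genome.

    Returns the longest exact same-strand repeat (r1, r2) with r1 starting
    within ``end_window`` bp of the 5' end, r2 ending within ``end_window``
    bp of the 3' end, and length within [min_repeat, max_repeat]; None
    otherwise.  Completeness is ``result is not None``.
    """
    seq = contig.sequence
    L = len(seq)
    if L <= 2 * min_repeat:
        return None
    # seed: min_repeat-mers starting in the 5' window
    heads: dict[str, list[int]] = {}
    for i in range(0, min(end_window, L - min_repeat) + 1):
        heads.setdefault(seq[i : i + min_repeat], []).append(i)
    best: tuple[int, int, int] | None = None  # (length, i, p)
    p_lo = max(0, L - end_window - max_repeat)
    for p in range(p_lo, L - min_repeat + 1):
        starts = heads.get(seq[p : p + min_repeat])
        if not starts:
            continue
        for i in starts:
            if p <= i:
                continue
            if i > 0 and p > 0 and seq[i - 1] == seq[p - 1]:
                continue  # left-extendable: part of a larger repeat pair
            # maximal common extension; over-long maximal repeats are
            # rejected rather than truncated (the rule bounds the repeat)
            m = min_repeat
            limit = min(L - p, L - i)
            while m < limit and seq[i + m] == seq[p + m]:
                m += 1
            if m > max_repeat:
                continue
            if p + m < L - end_window:
                continue  # 3' copy ends too far from the end
            if best is None or m > best[0] or (m == best[0] and (i, p) < best[1:]):
                best = (m, i, p)
    if best is None:
        return None
    m, i, p = best
    return (i, i + m), (p, p + m)


def detect_chimera(
    contig: ContigRecord,
    ani_threshold: float = 95.0,
    min_repeat_bp: int = 5000,
) -> bool:
    """True iff a non-self internal repeat exists at >= ani_threshold
    identity across >= min_repeat_bp (a mis-assembly signature; flagged,
    never removed)."""
    hits = seqops.local_align(contig, contig, exclude_self=True)
    return any(
        h.percent_identity >= ani_threshold and h.aln_length >= min_repeat_bp
        for h in hits
    )


def screen_ribosomal(marker_hits: Iterable[MarkerHit]) -> list[MarkerHit]:
    """Ribosomal-protein hits other than S21 on a viral population.

    An empty list is a pass.  Violations are reported as warnings; the
    population is retained (annotations were inspected, not auto-removed).
    """
    return [
        h
        for h in marker_hits
        if h.category == "ribosomal" and "S21" not in h.domain.upper()
    ]


def parse_evidence_tables(
    detector_calls_path, marker_hits_path
) -> dict[str, EvidenceBundle]:
    """Build EvidenceBundles from the detector-call and marker-hit TSVs
    (1-based inclusive prophage coordinates converted on read)."""
    bundles: dict[str, EvidenceBundle] = {}

    def bundle(cid: str) -> EvidenceBundle:
        return bundles.setdefault(cid, EvidenceBundle(cid))

    det = read_table(detector_calls_path)
    for row in det.itertuples(index=False):
        interval = None
        if row.call == "prophage" and not pd.isna(row.prophage_start):
            interval = (int(row.prophage_start) - 1, int(row.prophage_end))
        bundle(str(row.contig_id)).detector_calls.append(
            DetectorCall(str(row.tool), str(row.call), interval)
        )
    mk = read_table(marker_hits_path)
    for row in mk.itertuples(index=False):
        bundle(str(row.contig_id)).marker_hits.append(
            MarkerHit(
                domain=str(row.domain),
                category=str(row.category),
                bit_score=float(row.bit_score),
                protein_id=str(row.protein_id) if not pd.isna(row.protein_id) else None,
            )
        )
    return bundles
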
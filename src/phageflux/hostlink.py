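"""Stage 2 — assign hosts and taxonomy to viral populations.

Four methods, ordered by confidence and priority:

1. prophage — the virus aligns to a MAG scaffold at >= 95% identity across
   >= 50% of the viral contig (union of local hits, so circular
   permutations split into two hits still count), and the scaffold's
   plurality protein taxonomy is consistent with the bin's assignment;
2. crispr — a CRISPR array whose full repeat occurs exactly in the MAG and
   at least one full-length spacer occurs exactly in the virus;
3. aai — >= 50% of the virus's proteins hit a single genus-level group at
   >= 60% amino-acid identity;
4. reference_ani — nucleotide alignment (>= 95% / >= 50%) to an annotated
   reference virus.

A virus keeps its lowest-rank (highest-confidence) link after merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .io import ContigRecord, read_table
from . import seqops
from .seqops import ProteinRecord, revcomp

__all__ = [
    "Taxonomy",
    "CrisprArray",
    "HostLink",
    "ReferenceProtein",
    "link_by_prophage",
    "detect_crispr_arrays",
    "link_by_spacer",
    "assign_taxonomy_by_aai",
    "link_by_reference_ani",
    "merge_host_links",
    "flag_novelty",
]

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class_", "order", "family", "genus")
RANK_NAMES = {"class_": "class"}

METHOD_RANKS = {1: "prophage", 2: "crispr", 3: "aai", 4: "reference_ani"}


@dataclass(frozen=True)
class Taxonomy:
    """An ordered lineage domain -> genus; any suffix may be absent,
    but a present rank implies every rank above it."""

    domain: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None

    def __post_init__(self):
        seen_gap = False
        for rank in RANKS:
            label = getattr(self, rank)
            if label == "":
                raise ValueError(f"empty label at rank {rank}")
            if label is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(f"taxonomy gap above rank {rank}: {self}")

    def to_string(self) -> str:
        parts = []
        for rank in RANKS:
            label = getattr(self, rank)
            if label is not None:
                parts.append(f"{RANK_NAMES.get(rank, rank)}:{label}")
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "Taxonomy":
        kwargs = {}
        for part in text.split(";"):
            part = part.strip()
            if not part:
                continue
            rank, _, label = part.partition(":")
            rank = rank.strip()
            if rank == "class":
                rank = "class_"
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} in {text!r}")
            kwargs[rank] = label.strip()
        return cls(**kwargs)


@dataclass(frozen=True)
class CrisprArray:
    """A CRISPR repeat with its ordered spacers, from a MAG or read set."""

    source_id: str
    repeat: str
    spacers: tuple[str, ...]
    positions: tuple[int, ...] = ()

    def __post_init__(self):
        if any(sp == self.repeat for sp in self.spacers):
            raise ValueError("spacer identical to repeat")


@dataclass(frozen=True)
class HostLink:
    """One virus-host association with its method rank and evidence."""

    virus_id: str
    mag_id: str | None
    taxonomy: Taxonomy | None
    method_rank: int
    identity: float | None = None
    coverage: float | None = None
    n_spacers: int = 0
    spacers: tuple[str, ...] = ()
    protein_fraction: float | None = None

    def __post_init__(self):
        if self.method_rank not in METHOD_RANKS:
            raise ValueError(f"bad method rank {self.method_rank}")

    @property
    def method(self) -> str:
        return METHOD_RANKS[self.method_rank]

    @property
    def evidence_key(self) -> tuple:
        """Comparable evidence strength within a rank (higher is stronger)."""
        idcov = round((self.identity or 0.0) * (self.coverage or 0.0), 9)
        if self.method_rank == 2:
            return (self.n_spacers, idcov)
        if self.method_rank == 3:
            return (round(self.protein_fraction or 0.0, 9), idcov)
        return (idcov,)

    @property
    def host_key(self) -> tuple:
        return (self.mag_id, self.taxonomy.to_string() if self.taxonomy else None)


AniFn = Callable[[ContigRecord, ContigRecord], tuple[float, float]]


def _make_ani_fn(cache: dict) -> AniFn:
    def ani(query: ContigRecord, subject: ContigRecord) -> tuple[float, float]:
        idx = cache.get(subject.id)
        if idx is None:
            idx = seqops.SubjectIndex(subject.sequence, seqops.DEFAULT_K_DNA)
            cache[subject.id] = idx
        return seqops.ani_and_query_coverage(query, subject, subject_index=idx)

    return ani


def _plurality(labels: Sequence[str | None]) -> str | None:
    """The strictly most frequent non-missing label, or None on a tie."""
    counts: dict[str, int] = {}
    for lab in labels:
        if lab is not None:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return None
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
        return None
    return ordered[0][0]


def scaffold_consistent_with_bin(
    protein_taxonomies: Sequence[Taxonomy], bin_taxonomy: Taxonomy
) -> bool:
    """Plurality vote over the scaffold's protein best-hit taxonomies.

    The genus wins if strictly more frequent than every other; when the
    genus vote is tied or absent the family vote is used instead.
    """
    genus = _plurality([t.genus for t in protein_taxonomies])
    if genus is not None and bin_taxonomy.genus is not None:
        return genus == bin_taxonomy.genus
    family = _plurality([t.family for t in protein_taxonomies])
    return family is not None and bin_taxonomy.family is not None and family == bin_taxonomy.family


def link_by_prophage(
    viruses: Sequence[ContigRecord],
    mag_scaffolds: Mapping[str, Sequence[ContigRecord]],
    bin_taxonomy: Mapping[str, Taxonomy],
    scaffold_protein_hits: Mapping[str, Sequence[Taxonomy]],
    ani_threshold: float = 95.0,
    coverage_threshold: float = 0.5,
    ani_fn: AniFn | None = None,
) -> tuple[list[HostLink], list[dict]]:
    """Rank-1 links through prophage alignments to MAG scaffolds.

    Returns (links, rejected) where rejected logs candidates whose aligned
    scaffold's plurality taxonomy disagreed with the bin's assignment.
    """
    for mag_id in mag_scaffolds:
        if mag_id not in bin_taxonomy:
            raise ValueError(f"MAG {mag_id!r} missing from bin taxonomy")
    if ani_fn is None:
        ani_fn = _make_ani_fn({})
    links: list[HostLink] = []
    rejected: list[dict] = []
    for virus in sorted(viruses, key=lambda v: v.id):
        for mag_id in sorted(mag_scaffolds):
            for scaffold in mag_scaffolds[mag_id]:
                ani, cov = ani_fn(virus, scaffold)
                if ani < ani_threshold or cov < coverage_threshold:
                    continue
                prot_tax = scaffold_protein_hits.get(scaffold.id, ())
                if scaffold_consistent_with_bin(prot_tax, bin_taxonomy[mag_id]):
                    links.append(
                        HostLink(
                            virus_id=virus.id,
                            mag_id=mag_id,
                            taxonomy=bin_taxonomy[mag_id],
                            method_rank=1,
                            identity=ani,
                            coverage=cov,
                        )
                    )
                else:
                    rejected.append(
                        {
                            "virus_id": virus.id,
                            "mag_id": mag_id,
                            "scaffold_id": scaffold.id,
                            "reason": "taxonomy_inconsistent",
                            "identity": ani,
                            "coverage": cov,
                        }
                    )
    return links, rejected


def detect_crispr_arrays(
    sequences: Sequence[ContigRecord],
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (21, 48),
    spacer_len: tuple[int, int] = (18, 72),
) -> list[CrisprArray]:
    """Maximal arrays of >= min_repeats exact repeat occurrences with
    spacers inside ``spacer_len``; overlapping candidates resolve to the
    one with more repeats.

    A simplified assembly-space detector: repeat occurrences must be exact
    copies, which recovers planted arrays; degenerate-repeat arrays are out
    of scope.
    """
    r_min, r_max = repeat_len
    s_min, s_max = spacer_len
    gap_lo, gap_hi = r_min + s_min, r_max + s_max
    out: list[CrisprArray] = []
    for rec in sequences:
        seq = rec.sequence
        if len(seq) < r_min * min_repeats:
            continue
        anchors: dict[str, list[int]] = {}
        for i in range(len(seq) - r_min + 1):
            anchors.setdefault(seq[i : i + r_min], []).append(i)
        candidates: list[tuple[int, int, int, str, tuple[str, ...]]] = []
        seen_runs: set[tuple[int, ...]] = set()
        for kmer, positions in anchors.items():
            if len(positions) < min_repeats:
                continue
            run: list[int] = [positions[0]]
            runs: list[list[int]] = []
            for p in positions[1:]:
                if gap_lo <= p - run[-1] <= gap_hi:
                    run.append(p)
                else:
                    runs.append(run)
                    run = [p]
            runs.append(run)
            for run in runs:
                if len(run) < min_repeats:
                    continue
                # extend the anchor to the maximal shared repeat; it may
                # not grow into the neighbouring occurrence
                min_gap = min(b - a for a, b in zip(run, run[1:]))
                el = 0
                while (
                    run[0] - el - 1 >= 0
                    and r_min + el < min_gap
                    and len({seq[q - el - 1] for q in run}) == 1
                ):
                    el += 1
                er = 0
                while (
                    run[-1] + r_min + er < len(seq)
                    and r_min + el + er < min_gap
                    and len({seq[q + r_min + er] for q in run}) == 1
                ):
                    er += 1
                starts = tuple(q - el for q in run)
                if starts in seen_runs:
                    continue
                seen_runs.add(starts)
                rlen = r_min + el + er
                if rlen > r_max:
                    continue
                repeat = seq[starts[0] : starts[0] + rlen]
                spacers = []
                ok = True
                for a, b in zip(starts, starts[1:]):
                    sp = seq[a + rlen : b]
                    if not (s_min <= len(sp) <= s_max) or sp == repeat:
                        ok = False
                        break
                    spacers.append(sp)
                if not ok or len(spacers) < min_repeats - 1:
                    continue
                region = (starts[0], starts[-1] + rlen)
                candidates.append(
                    (len(starts), region[0], region[1], repeat, tuple(spacers))
                )
        # overlap resolution: prefer more repeats, then leftmost
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        claimed: list[tuple[int, int]] = []
        for n, lo, hi, repeat, spacers in candidates:
            if any(lo < c_hi and hi > c_lo for c_lo, c_hi in claimed):
                continue
            claimed.append((lo, hi))
            out.append(CrisprArray(rec.id, repeat, spacers, positions=(lo,)))
    out.sort(key=lambda a: (a.source_id, a.positions))
    return out


def _contains_either_strand(haystack: str, needle: str) -> bool:
    return needle in haystack or revcomp(needle) in haystack


def link_by_spacer(
    arrays: Sequence[CrisprArray],
    mags: Mapping[str, Sequence[ContigRecord]],
    viruses: Sequence[ContigRecord],
    min_repeat_match_len: int = 23,
) -> list[HostLink]:
    """Rank-2 links: the array's full repeat occurs exactly (either strand)
    in the MAG and >= 1 full-length spacer occurs exactly in the virus.

    The blastn e-value clause on the repeat is realized as requiring the
    exact full-repeat match to be at least ``min_repeat_match_len`` bp.
    """
    links: list[HostLink] = []
    for array in arrays:
        if len(array.repeat) < min_repeat_match_len:
            continue
        matching_mags = [
            mag_id
            for mag_id in sorted(mags)
            if any(
                _contains_either_strand(sc.sequence, array.repeat)
                for sc in mags[mag_id]
            )
        ]
        if not matching_mags:
            continue
        for virus in sorted(viruses, key=lambda v: v.id):
            found = tuple(
                sp for sp in array.spacers if _contains_either_strand(virus.sequence, sp)
            )
            if not found:
                continue
            for mag_id in matching_mags:
                links.append(
                    HostLink(
                        virus_id=virus.id,
                        mag_id=mag_id,
                        taxonomy=None,
                        method_rank=2,
                        identity=100.0,
                        coverage=None,
                        n_spacers=len(found),
                        spacers=found,
                    )
                )
    return links


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference protein with the taxonomy and genome it came from."""

    id: str
    sequence: str
    taxonomy: Taxonomy | None = None
    genome_id: str | None = None


def _best_aai(protein: ProteinRecord, references: Sequence[ReferenceProtein]):
    """Best single-alignment amino-acid identity of one protein against a
    panel; returns (aai, reference) or (0, None)."""
    best_aai, best_ref = 0.0, None
    for ref in references:
        hits = seqops.local_align(
            protein.sequence, ref.sequence, search_reverse=False
        )
        if hits and hits[0].percent_identity > best_aai:
            best_aai, best_ref = hits[0].percent_identity, ref
    return best_aai, best_ref


def _aai_group_assign(
    virus_proteins: Sequence[ProteinRecord],
    references: Sequence[ReferenceProtein],
    group_of: Callable[[ReferenceProtein], str | None],
    aai_floor: float,
    fraction_floor: float,
):
    """Shared tally logic: (winning group, fraction, exemplar ref) or None.

    A group wins only if it is the unique argmax and reaches
    ``fraction_floor`` of all proteins.
    """
    if not virus_proteins:
        raise ValueError("virus has no predicted proteins")
    tallies: dict[str, int] = {}
    exemplar: dict[str, ReferenceProtein] = {}
    for prot in virus_proteins:
        aai, ref = _best_aai(prot, references)
        if ref is None or aai < aai_floor:
            continue
        group = group_of(ref)
        if group is None:
            continue
        tallies[group] = tallies.get(group, 0) + 1
        exemplar.setdefault(group, ref)
    if not tallies:
        return None
    ordered = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
        return None  # tie: no single group
    group, count = ordered[0]
    fraction = count / len(virus_proteins)
    if fraction < fraction_floor:
        return None
    return group, fraction, exemplar[group]


def assign_taxonomy_by_aai(
    virus_proteins: Sequence[ProteinRecord],
    references: Sequence[ReferenceProtein],
    aai_floor: float = 60.0,
    fraction_floor: float = 0.5,
) -> tuple[Taxonomy, float] | None:
    """Rank-3 taxonomy: >= fraction_floor of proteins best-hit a single
    genus-level group at >= aai_floor AAI.  Ties assign nothing."""
    res = _aai_group_assign(
        virus_proteins,
        references,
        lambda ref: ref.taxonomy.genus if ref.taxonomy else None,
        aai_floor,
        fraction_floor,
    )
    if res is None:
        return None
    _, fraction, ref = res
    return ref.taxonomy, fraction


def link_by_reference_ani(
    viruses: Sequence[ContigRecord],
    references: Sequence[tuple[ContigRecord, Taxonomy]],
    ani_threshold: float = 95.0,
    coverage_threshold: float = 0.5,
    ani_fn: AniFn | None = None,
) -> list[HostLink]:
    """Rank-4 links to annotated reference viruses (>= 95% ANI across
    >= 50% of the virus); the best-scoring reference's taxonomy is copied."""
    if ani_fn is None:
        ani_fn = _make_ani_fn({})
    links: list[HostLink] = []
    for virus in sorted(viruses, key=lambda v: v.id):
        best = None
        for ref, taxonomy in sorted(references, key=lambda rt: rt[0].id):
            ani, cov = ani_fn(virus, ref)
            if ani < ani_threshold or cov < coverage_threshold:
                continue
            key = round(ani * cov, 9)
            if best is None or key > best[0]:
                best = (key, ref.id, ani, cov, taxonomy)
        if best is not None:
            _, ref_id, ani, cov, taxonomy = best
            links.append(
                HostLink(
                    virus_id=virus.id,
                    mag_id=None,
                    taxonomy=taxonomy,
                    method_rank=4,
                    identity=ani,
                    coverage=cov,
                )
            )
    return links


def merge_host_links(
    links: Sequence[HostLink],
) -> tuple[dict[str, HostLink], list[HostLink], set[str]]:
    """One link per virus: lowest method rank wins; within a rank the
    strongest evidence wins.  Conflicting hosts at equal rank and equal
    evidence keep nothing and flag the virus as ambiguous.

    Returns (merged, discarded audit trail, ambiguous virus ids); the
    result is invariant to input order.
    """
    by_virus: dict[str, list[HostLink]] = {}
    for link in links:
        by_virus.setdefault(link.virus_id, []).append(link)
    merged: dict[str, HostLink] = {}
    discarded: list[HostLink] = []
    ambiguous: set[str] = set()
    for virus_id in sorted(by_virus):
        cand = sorted(
            by_virus[virus_id],
            key=lambda l: (l.method_rank, tuple(-x for x in l.evidence_key), l.host_key),
        )
        top = cand[0]
        rivals = [
            l
            for l in cand[1:]
            if l.method_rank == top.method_rank
            and l.evidence_key == top.evidence_key
            and l.host_key != top.host_key
        ]
        if rivals:
            ambiguous.add(virus_id)
            discarded.extend(cand)
        else:
            merged[virus_id] = top
            discarded.extend(cand[1:])
    return merged, discarded, ambiguous


def flag_novelty(
    virus_proteins: Sequence[ProteinRecord],
    reference_panels: Sequence[Sequence[ReferenceProtein]],
    aai_floor: float = 60.0,
    fraction_floor: float = 0.5,
) -> bool:
    """Novel iff no panel yields a broad assignment: >= fraction_floor of
    proteins at >= aai_floor AAI to a single genome-of-origin group."""
    panels = [p for p in reference_panels if p]
    if not panels:
        logger.warning("empty reference panel: every virus is trivially novel")
        return True
    for panel in panels:
        res = _aai_group_assign(
            virus_proteins,
            panel,
            lambda ref: ref.genome_id,
            aai_floor,
            fraction_floor,
        )
        if res is not None:
            return False
    return True


def parse_bin_taxonomy(path) -> dict[str, Taxonomy]:
    """mag_id -> Taxonomy from a TSV with ``taxonomy`` rank:name pairs."""
    df = read_table(path)
    return {
        str(row.mag_id): Taxonomy.from_string(str(row.taxonomy))
        for row in df.itertuples(index=False)
    }


def parse_scaffold_protein_hits(path) -> tuple[dict[str, list[Taxonomy]], dict[str, str]]:
    """(scaffold_id -> protein best-hit taxonomies, scaffold_id -> mag_id)."""
    df = read_table(path)
    hits: dict[str, list[Taxonomy]] = {}
    mag_of: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sid = str(row.scaffold_id)
        hits.setdefault(sid, []).append(Taxonomy.from_string(str(row.protein_taxonomy)))
        mag_of[sid] = str(row.mag_id)
    return hits, mag_of
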
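"""Stage 3 — temperate versus lytic classification.

A population is temperate if at least one of four non-exclusive criteria
holds; a population displaying none of them is inferred to be lytic:

- ``marker`` — a lysogeny marker (integrase, excisionase, Cro, CI
  repressor) at >= 30 bits;
- ``prophage_homology`` — >= 95% identity across >= half the viral contig
  to a detector-identified prophage region;
- ``detector_prophage`` — a detector labelled the representative itself a
  prophage;
- ``mag_embedded`` — a single contiguous alignment at >= 95% ANI to a MAG
  scaffold at least 10 kb longer than the virus (flanking host sequence).

Unlike host linking, the ``mag_embedded`` criterion demands one contiguous
alignment rather than a union of hits.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

from .io import ContigRecord
from .curation import EvidenceBundle, ViralPopulation
from .seqops import AlignmentHit
from . import seqops

__all__ = ["classify_lifestyle", "CRITERIA"]

CRITERIA = ("marker", "prophage_homology", "detector_prophage", "mag_embedded")


def classify_lifestyle(
    population: ViralPopulation,
    virus: ContigRecord | None = None,
    evidence: EvidenceBundle | None = None,
    prophage_regions: Sequence[ContigRecord] = (),
    mag_alignments: Sequence[AlignmentHit] = (),
    scaffold_lengths: Mapping[str, int] | None = None,
    temperate_marker_floor: float = 30.0,
    ani_threshold: float = 95.0,
    coverage_threshold: float = 0.5,
    flank_excess_bp: int = 10000,
    ani_fn: Callable[[ContigRecord, ContigRecord], tuple[float, float]] | None = None,
) -> tuple[str, frozenset[str]]:
    """Classify one population; returns (lifestyle, criteria hit).

    Inputs may be empty, in which case only criteria with evidence can
    fire; ``criteria == frozenset()`` is definitionally lytic.
    ``mag_alignments`` are the virus's alignments to MAG scaffolds (one hit
    per contiguous alignment, identity per hit).
    """
    hit: set[str] = set()

    if evidence is not None:
        if any(
            h.category == "temperate_marker" and h.bit_score >= temperate_marker_floor
            for h in evidence.marker_hits
        ):
            hit.add("marker")
        if any(c.call == "prophage" for c in evidence.detector_calls):
            hit.add("detector_prophage")

    if virus is not None and prophage_regions:
        if ani_fn is None:
            ani_fn = lambda q, s: seqops.ani_and_query_coverage(q, s)  # noqa: E731
        for region in prophage_regions:
            ani, cov = ani_fn(virus, region)
            if ani >= ani_threshold and cov >= coverage_threshold:
                hit.add("prophage_homology")
                break

    if mag_alignments:
        vlen = virus.length if virus is not None else population.length
        lengths = scaffold_lengths or {}
        for aln in mag_alignments:
            if aln.percent_identity < ani_threshold:
                continue
            q0, q1 = aln.query_interval
            if (q1 - q0) < coverage_threshold * vlen:
                continue
            slen = lengths.get(aln.subject_id)
            if slen is not None and slen >= vlen + flank_excess_bp:
                hit.add("mag_embedded")
                break

    lifestyle = "temperate" if hit else "lytic"
    return lifestyle, frozenset(hit)
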
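"""End-to-end orchestration: community -> curated populations -> host
links -> lifestyles -> abundances -> provenance, plus evaluation of every
planted fact against the truth ledger.

This is the programmatic equivalent of running the CLI stages in order on
one synthetic data set, holding intermediate products in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContigRecord
from . import abundance as ab
from . import curation, hostlink, lifestyle, provenance, seqops
from .curation import ViralPopulation
from .hostlink import HostLink
from .simulate import (
    SimConfig,
    SyntheticCommunity,
    build_sample_plan,
    generate_community,
    simulate_reads,
)

__all__ = ["PipelineResult", "run_pipeline", "run_end_to_end", "evaluate_against_ledger"]

VIRUS_READ_FILTER = {"min_identity": 95.0, "min_aln_bp": 45}
EXPORT_READ_FILTER = {"min_identity": 95.0, "min_read_fraction": 0.8}


@dataclass
class PipelineResult:
    populations: list[ViralPopulation] = field(default_factory=list)
    representatives: dict[str, ContigRecord] = field(default_factory=dict)
    retention_reasons: dict[str, str] = field(default_factory=dict)
    ribosomal_violations: dict[str, list] = field(default_factory=dict)
    host_links: dict[str, HostLink] = field(default_factory=dict)
    rejected_links: list[dict] = field(default_factory=list)
    ambiguous_links: set[str] = field(default_factory=set)
    prophage_links: list[HostLink] = field(default_factory=list)
    spacer_links: list[HostLink] = field(default_factory=list)
    crispr_arrays: list = field(default_factory=list)
    lifestyles: dict[str, tuple[str, frozenset]] = field(default_factory=dict)
    trap_raw: pd.DataFrame = field(default_factory=pd.DataFrame)
    trap_normalized: pd.DataFrame = field(default_factory=pd.DataFrame)
    diversity: pd.DataFrame = field(default_factory=pd.DataFrame)
    shallow_bin_coverage: pd.DataFrame = field(default_factory=pd.DataFrame)
    exported: dict[str, tuple[bool, frozenset]] = field(default_factory=dict)
    origins: dict[str, str] = field(default_factory=dict)
    presence_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _curate(community: SyntheticCommunity, result: PipelineResult) -> None:
    retained, reasons = curation.classify_viral_contigs(
        community.contigs, community.evidence
    )
    result.retention_reasons = reasons
    populations = curation.dereplicate(retained)
    retained_by_id = {c.id: c for c in retained}
    for pop in populations:
        rep = retained_by_id[pop.representative_id]
        result.representatives[pop.representative_id] = rep
        pop.dtr_interval = curation.detect_circularity(rep)
        pop.is_complete = pop.dtr_interval is not None
        pop.is_chimera = curation.detect_chimera(rep)
        ev = community.evidence.get(pop.representative_id)
        if ev is not None:
            violations = curation.screen_ribosomal(ev.marker_hits)
            if violations:
                result.ribosomal_violations[pop.representative_id] = violations
    result.populations = populations


def _link_hosts(community: SyntheticCommunity, result: PipelineResult) -> None:
    reps = [result.representatives[p.representative_id] for p in result.populations]
    scaffolds = {
        sc.id: sc for scs in community.mag_scaffolds.values() for sc in scs
    }
    scaffold_of_mag = {
        sc.id: mag for mag, scs in community.mag_scaffolds.items() for sc in scs
    }
    index_cache: dict[str, seqops.SubjectIndex] = {}
    hits_cache: dict[tuple[str, str], list] = {}

    def aligned_hits(virus: ContigRecord, scaffold: ContigRecord):
        key = (virus.id, scaffold.id)
        if key not in hits_cache:
            idx = index_cache.get(scaffold.id)
            if idx is None:
                idx = seqops.SubjectIndex(scaffold.sequence, seqops.DEFAULT_K_DNA)
                index_cache[scaffold.id] = idx
            hits_cache[key] = seqops.local_align(virus, scaffold, subject_index=idx)
        return hits_cache[key]

    def ani_fn(virus: ContigRecord, scaffold: ContigRecord):
        return seqops.ani_and_query_coverage(
            virus, scaffold, hits=aligned_hits(virus, scaffolds[scaffold.id])
        )

    prophage_links, rejected = hostlink.link_by_prophage(
        reps,
        community.mag_scaffolds,
        community.bin_taxonomy,
        community.scaffold_protein_hits,
        ani_fn=ani_fn,
    )
    arrays = hostlink.detect_crispr_arrays(list(scaffolds.values()))
    spacer_links = hostlink.link_by_spacer(arrays, community.mag_scaffolds, reps)
    merged, _discarded, ambiguous = hostlink.merge_host_links(
        prophage_links + spacer_links
    )
    result.prophage_links = prophage_links
    result.spacer_links = spacer_links
    result.rejected_links = rejected
    result.crispr_arrays = arrays
    result.host_links = merged
    result.ambiguous_links = ambiguous

    scaffold_lengths = {sid: sc.length for sid, sc in scaffolds.items()}
    for pop in result.populations:
        rep = result.representatives[pop.representative_id]
        mag_alignments = [
            h
            for sc in scaffolds.values()
            for h in aligned_hits(rep, sc)
            if h.percent_identity >= 95.0
        ]
        ls, criteria = lifestyle.classify_lifestyle(
            pop,
            virus=rep,
            evidence=community.evidence.get(pop.representative_id),
            mag_alignments=mag_alignments,
            scaffold_lengths=scaffold_lengths,
        )
        pop.lifestyle = ls
        result.lifestyles[pop.representative_id] = (ls, criteria)
        pop.host_link = result.host_links.get(pop.representative_id)


def _profile_samples(
    community: SyntheticCommunity,
    result: PipelineResult,
    rng: np.random.Generator,
) -> None:
    cfg = community.config
    ledger = community.ledger
    reps = [result.representatives[p.representative_id] for p in result.populations]
    index = seqops.KmerIndex(reps, k=15)
    rep_lengths = {r.id: r.length for r in reps}
    genomes = dict(community.viruses)
    for scs in community.mag_scaffolds.values():
        for sc in scs:
            genomes[sc.id] = sc

    trap_iqr: dict[str, dict[str, float]] = {}
    shallow_iqr: dict[str, dict[str, float]] = {}
    libraries: dict[str, int] = {}
    for sample in ledger.samples:
        sid = sample["sample_id"]
        if sample["kind"] not in ("trap", "shallow"):
            continue
        abundances = ledger.true_abundances[sid]
        if sample["kind"] == "shallow" and not abundances:
            reads: list[ContigRecord] = []
        else:
            source = genomes if sample["kind"] == "trap" else community.viruses
            reads = simulate_reads(
                source, abundances, sample["library_size"], cfg.read_len,
                cfg.error_rate, rng, sample_id=sid,
            )
        libraries[sid] = sample["library_size"]
        hits = seqops.map_reads(reads, reps, index=index) if reads else []
        if sample["kind"] == "trap":
            filtered = ab.filter_hits(hits, **VIRUS_READ_FILTER)
        else:
            filtered = ab.filter_hits(hits, **EXPORT_READ_FILTER)
        by_ref: dict[str, list] = {}
        for h in filtered:
            by_ref.setdefault(h.subject_id, []).append(h)
        column = {}
        for rid, length in rep_lengths.items():
            prof = ab.coverage_profile(rid, length, by_ref.get(rid, ()), sid)
            column[rid] = ab.iqr_coverage(prof)
        (trap_iqr if sample["kind"] == "trap" else shallow_iqr)[sid] = column

    trap_raw = pd.DataFrame(trap_iqr).sort_index()
    result.trap_raw = trap_raw
    result.trap_normalized = ab.normalize_matrix(
        trap_raw, {s: libraries[s] for s in trap_raw.columns}
    )
    result.diversity = pd.DataFrame(
        {
            sid: dict(
                zip(("shannon", "richness", "evenness"),
                    ab.diversity_indices(result.trap_normalized[sid].to_numpy()))
            )
            for sid in result.trap_normalized.columns
        }
    ).T

    shallow_raw = pd.DataFrame(shallow_iqr).sort_index()
    shallow_norm = ab.normalize_matrix(
        shallow_raw, {s: libraries[s] for s in shallow_raw.columns}
    )
    bin_of_sample = {
        s["sample_id"]: s["depth_bin"]
        for s in ledger.samples
        if s["kind"] == "shallow"
    }
    # per-bin coverage: maximum over that bin's samples
    per_bin = {}
    for b in provenance.DEPTH_BINS:
        cols = [s for s, bb in bin_of_sample.items() if bb == b and s in shallow_norm]
        per_bin[b] = (
            shallow_norm[cols].max(axis=1) if cols
            else pd.Series(0.0, index=shallow_norm.index)
        )
    bin_cov = pd.DataFrame(per_bin)
    result.shallow_bin_coverage = bin_cov
    for rid in bin_cov.index:
        coverages = bin_cov.loc[rid].to_dict()
        result.exported[rid] = provenance.flag_exported(coverages)
        result.origins[rid] = provenance.assign_depth_of_origin(coverages, rid)
    for pop in result.populations:
        rid = pop.representative_id
        pop.exported, pop.export_source_category = result.exported.get(
            rid, (False, frozenset())
        )
        pop.depth_of_origin = result.origins.get(rid)
    result.presence_summary = provenance.presence_by_origin_summary(
        result.origins, result.trap_normalized > 0
    )


def run_pipeline(
    community: SyntheticCommunity, rng: np.random.Generator
) -> PipelineResult:
    """Run curation, host linking, lifestyle, abundance and provenance on a
    generated community; ``rng`` drives read simulation."""
    result = PipelineResult()
    _curate(community, result)
    _link_hosts(community, result)
    if not community.ledger.samples:
        build_sample_plan(community.config, community, rng)
    _profile_samples(community, result, rng)
    return result


def run_end_to_end(config: SimConfig) -> tuple[SyntheticCommunity, PipelineResult]:
    """Generate a community under ``config`` and run the full pipeline;
    read simulation uses an RNG stream derived from the config seed."""
    community = generate_community(config)
    rng = np.random.default_rng((config.seed + 99_991) % 2**31)
    build_sample_plan(config, community, rng)
    result = run_pipeline(community, rng)
    return community, result


def _prf(true_set: set, predicted_set: set) -> tuple[float, float]:
    tp = len(true_set & predicted_set)
    recall = tp / len(true_set) if true_set else 1.0
    precision = tp / len(predicted_set) if predicted_set else 1.0
    return recall, precision


def evaluate_against_ledger(
    community: SyntheticCommunity, result: PipelineResult
) -> dict[str, float]:
    """Score every pipeline decision against the planted truth."""
    ledger = community.ledger
    metrics: dict[str, float] = {}

    planted_prophage = {(p["virus_id"], p["mag_id"]) for p in ledger.prophages}
    found_prophage = {(l.virus_id, l.mag_id) for l in result.prophage_links}
    r, p = _prf(planted_prophage, found_prophage)
    metrics["prophage_link_recall"], metrics["prophage_link_precision"] = r, p

    planted_spacer = {(s["virus_id"], s["mag_id"]) for s in ledger.spacer_links}
    found_spacer = {(l.virus_id, l.mag_id) for l in result.spacer_links}
    r, p = _prf(planted_spacer, found_spacer)
    metrics["spacer_link_recall"], metrics["spacer_link_precision"] = r, p

    rep_ids = {pop.representative_id for pop in result.populations}
    planted_temperate = {
        v for v, ls in ledger.lifestyle.items() if ls == "temperate" and v in rep_ids
    }
    called_temperate = {
        rid for rid, (ls, _) in result.lifestyles.items() if ls == "temperate"
    }
    r, p = _prf(planted_temperate, called_temperate)
    metrics["lifestyle_recall"], metrics["lifestyle_precision"] = r, p

    planted_circular = {v for v in ledger.dtr_lengths if v in rep_ids}
    called_complete = {pop.representative_id for pop in result.populations
                       if pop.is_complete}
    negatives = rep_ids - planted_circular
    metrics["dtr_sensitivity"] = (
        len(planted_circular & called_complete) / len(planted_circular)
        if planted_circular else 1.0
    )
    metrics["dtr_specificity"] = (
        len(negatives - called_complete) / len(negatives) if negatives else 1.0
    )

    rep_of: dict[str, str] = {}
    for pop in result.populations:
        for member in pop.member_ids:
            rep_of[member] = pop.representative_id
    total = correct = 0
    for cid, expected_rep in ledger.cluster_of.items():
        total += 1
        if rep_of.get(cid) == expected_rep:
            correct += 1
    for cid in ledger.dropped | ledger.nonviral:
        total += 1
        if cid not in rep_of:
            correct += 1
    metrics["dereplication_accuracy"] = correct / total if total else 1.0

    total = correct = 0
    for rid in rep_ids:
        expected = ledger.origin.get(rid)
        if expected is None:
            continue
        total += 1
        if result.origins.get(rid) == expected:
            correct += 1
    metrics["depth_of_origin_accuracy"] = correct / total if total else 1.0

    planted_exported = {v for v in ledger.exported if v in rep_ids}
    called_exported = {rid for rid, (flag, _) in result.exported.items() if flag}
    r, p = _prf(planted_exported, called_exported)
    metrics["export_recall"], metrics["export_precision"] = r, p
    return metrics
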
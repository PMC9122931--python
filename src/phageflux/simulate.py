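"""Synthetic communities, read sets, and flux series with planted truth.

The generator emulates every signal the pipeline detects: temperate
viruses integrated into MAG scaffolds with >= 10 kb host flanks, CRISPR
arrays whose spacers are verbatim virus substrings, circular phage genomes
with direct terminal repeats, near-identical redundant contigs and 90%
decoys around the dereplication boundary, depth-stratified shallow read
sets, and an abundance matrix with planted flux-correlated modules.  Every
planted fact is recorded in a :class:`TruthLedger` and is verifiable
against the emitted objects by :func:`verify_ledger`.

Genomes are i.i.d. uniform random DNA: the pipeline's decisions depend
only on identity, coverage and marker structure, all of which random DNA
exercises, and k-mer collisions are negligible at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ContigRecord, FluxRecord, write_fasta
from .curation import DetectorCall, EvidenceBundle, MarkerHit
from .hostlink import Taxonomy
from .seqops import ProteinRecord, revcomp

__all__ = [
    "SimConfig",
    "TruthLedger",
    "SyntheticCommunity",
    "generate_community",
    "simulate_reads",
    "generate_flux_series",
    "verify_ledger",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed reverse-translation table (no stop codons reachable)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_AA = "".join(sorted(_CODON))


@dataclass
class SimConfig:
    """Study conditions for the synthetic community and sample series."""

    seed: int
    # community
    n_hosts: int = 20
    host_scaffold_bp: int = 300_000
    n_temperate: int = 10
    n_circular: int = 10
    n_spacer_targeted: int = 5
    n_decoys: int = 5
    n_lytic_extra: int = 10
    virus_len_range: tuple[int, int] = (15_000, 60_000)
    dtr_len_range: tuple[int, int] = (100, 1_000)
    decoy_divergence: float = 0.10
    n_redundant_fragments: int = 10
    fragment_divergence: float = 0.02
    fragment_length_frac: float = 0.6
    n_short_contigs: int = 3
    short_len_range: tuple[int, int] = (5_000, 8_000)
    n_nonviral_contigs: int = 3
    n_chimeric: int = 0
    chimera_repeat_bp: int = 6_000
    n_decoy_mags: int = 2
    genes_per_virus: int = 4
    gene_len_range_aa: tuple[int, int] = (80, 180)
    crispr_repeat_len: int = 28
    crispr_spacer_len: int = 32
    detector_fn_rate: float = 0.0
    detector_fp_rate: float = 0.0
    # samples and reads
    n_trap_samples: int = 12
    n_shallow_samples: int = 8
    reads_per_sample: int = 50_000
    read_len: int = 150
    error_rate: float = 0.0
    # flux series
    n_flux_samples: int = 63
    flux_reference_mean: float = 100.0
    pulse_amplitude: float = 2.0
    n_pulse_samples: int = 9
    n_modules: int = 3
    module_size: int = 30
    module_r: tuple[float, ...] = (0.8, 0.8, 0.0)
    n_background_populations: int = 30
    within_module_noise: float = 0.5

    def validate(self) -> None:
        counts = [
            self.n_hosts, self.n_temperate, self.n_circular, self.n_spacer_targeted,
            self.n_decoys, self.n_lytic_extra, self.n_trap_samples,
            self.n_shallow_samples, self.reads_per_sample, self.n_modules,
            self.module_size, self.n_background_populations,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for p in (self.error_rate, self.decoy_divergence, self.fragment_divergence,
                  self.detector_fn_rate, self.detector_fp_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.virus_len_range[1] + 20_000 > self.host_scaffold_bp:
            raise ValueError(
                "prophage plus 10 kb flanks does not fit the host scaffold"
            )
        if self.n_temperate > self.n_hosts:
            raise ValueError("more temperate viruses than host MAGs to integrate into")
        if any(abs(r) >= 1 for r in self.module_r):
            raise ValueError("planted module correlations must lie in (-1, 1)")
        if len(self.module_r) != self.n_modules:
            raise ValueError("module_r must have one entry per module")
        if sum(1 for r in self.module_r if r != 0) > 2:
            raise ValueError(
                "at most two flux-correlated modules are supported (their "
                "residuals are anti-correlated to keep modules separable)"
            )

    @property
    def n_viruses(self) -> int:
        return (self.n_temperate + self.n_circular + self.n_spacer_targeted
                + self.n_decoys + self.n_lytic_extra)

    @classmethod
    def small(cls, seed: int) -> "SimConfig":
        """A reduced quick-look preset for smoke tests and examples; the
        class defaults are the full study conditions."""
        return cls(
            seed=seed, n_hosts=6, host_scaffold_bp=120_000, n_temperate=3,
            n_circular=3, n_spacer_targeted=2, n_decoys=2, n_lytic_extra=3,
            virus_len_range=(15_000, 30_000), n_redundant_fragments=4,
            n_short_contigs=2, n_nonviral_contigs=2, n_decoy_mags=1,
            n_trap_samples=3, n_shallow_samples=4, reads_per_sample=8_000,
            n_flux_samples=24, n_pulse_samples=4, module_size=12,
            n_background_populations=12,
        )


@dataclass
class TruthLedger:
    """Every planted fact, keyed by the emitted entity ids."""

    seed: int = 0
    prophages: list[dict] = field(default_factory=list)
    spacer_links: list[dict] = field(default_factory=list)
    decoy_spacers: list[dict] = field(default_factory=list)
    dtr_lengths: dict[str, int] = field(default_factory=dict)
    lifestyle: dict[str, str] = field(default_factory=dict)
    origin: dict[str, str] = field(default_factory=dict)
    exported: set[str] = field(default_factory=set)
    cluster_of: dict[str, str] = field(default_factory=dict)
    dropped: set[str] = field(default_factory=set)
    nonviral: set[str] = field(default_factory=set)
    genes: list[dict] = field(default_factory=list)
    decoy_of: dict[str, str] = field(default_factory=dict)
    chimeric: set[str] = field(default_factory=set)
    samples: list[dict] = field(default_factory=list)
    true_abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    module_of: dict[str, int] = field(default_factory=dict)
    module_r: tuple[float, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of every planted fact (section, entity, fact)."""
        rows: list[tuple[str, str, str]] = []
        rows.append(("meta", "seed", str(self.seed)))
        for p in self.prophages:
            rows.append(("prophage", p["virus_id"],
                         f"{p['mag_id']}:{p['scaffold_id']}:{p['start']}-{p['end']}"))
        for s in self.spacer_links:
            rows.append(("spacer_link", s["virus_id"], f"{s['mag_id']}:{s['spacer']}"))
        for s in self.decoy_spacers:
            rows.append(("decoy_spacer", s["virus_id"], f"{s['mag_id']}:{s['spacer']}"))
        for vid, d in sorted(self.dtr_lengths.items()):
            rows.append(("dtr", vid, str(d)))
        for vid, ls in sorted(self.lifestyle.items()):
            rows.append(("lifestyle", vid, ls))
        for vid, o in sorted(self.origin.items()):
            rows.append(("origin", vid, o))
        for vid in sorted(self.exported):
            rows.append(("exported", vid, "1"))
        for cid, rep in sorted(self.cluster_of.items()):
            rows.append(("cluster", cid, rep))
        for cid in sorted(self.dropped):
            rows.append(("dropped", cid, "1"))
        for g in self.genes:
            rows.append(("gene", g["virus_id"],
                         f"{g['start']}-{g['end']}:{g['strand']}:{g['protein']}"))
        for did, src in sorted(self.decoy_of.items()):
            rows.append(("decoy_of", did, src))
        for cid in sorted(self.chimeric):
            rows.append(("chimera", cid, "1"))
        for s in self.samples:
            rows.append(("sample", s["sample_id"],
                         f"{s['kind']}:{s.get('depth_bin', '')}:{s['library_size']}"))
        for pid, m in sorted(self.module_of.items()):
            rows.append(("module", pid, str(m)))
        return pd.DataFrame(rows, columns=["section", "entity", "fact"])


@dataclass
class SyntheticCommunity:
    """In-memory bundle of everything the generator plants."""

    config: SimConfig
    contigs: list[ContigRecord]
    evidence: dict[str, EvidenceBundle]
    viruses: dict[str, ContigRecord]
    mag_scaffolds: dict[str, list[ContigRecord]]
    bin_taxonomy: dict[str, Taxonomy]
    scaffold_protein_hits: dict[str, list[Taxonomy]]
    proteins: dict[str, list[ProteinRecord]]
    ledger: TruthLedger

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# phageflux simulate seed={self.config.seed}\n"
        write_fasta(self.contigs, outdir / "contigs.fasta")
        mags = [sc for scs in self.mag_scaffolds.values() for sc in scs]
        write_fasta(mags, outdir / "mag_scaffolds.fasta")
        det_rows, marker_rows = [], []
        for cid, ev in sorted(self.evidence.items()):
            for c in ev.detector_calls:
                p0, p1 = c.prophage_interval or ("", "")
                det_rows.append(
                    {"contig_id": cid, "tool": c.tool, "call": c.call,
                     "prophage_start": p0 + 1 if p0 != "" else "",
                     "prophage_end": p1 if p1 != "" else ""}
                )
            for h in ev.marker_hits:
                marker_rows.append(
                    {"protein_id": h.protein_id or "", "contig_id": cid,
                     "domain": h.domain, "category": h.category,
                     "bit_score": h.bit_score}
                )
        for name, df in (
            ("detector_calls.tsv", pd.DataFrame(det_rows)),
            ("marker_hits.tsv", pd.DataFrame(marker_rows)),
            ("truth_ledger.tsv", self.ledger.to_frame()),
        ):
            with open(outdir / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        tax_rows = [
            {"mag_id": mag, "taxonomy": tax.to_string()}
            for mag, tax in sorted(self.bin_taxonomy.items())
        ]
        scaf_rows = [
            {"scaffold_id": sid, "mag_id": mag, "protein_taxonomy": t.to_string()}
            for mag, scs in sorted(self.mag_scaffolds.items())
            for sc in scs
            for sid, t in ((sc.id, t) for t in self.scaffold_protein_hits.get(sc.id, []))
        ]
        for name, rows in (("bin_taxonomy.tsv", tax_rows),
                           ("scaffold_protein_hits.tsv", scaf_rows)):
            with open(outdir / name, "w") as fh:
                fh.write(header)
                pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence helpers

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute an exact ``divergence`` fraction of positions (each to a
    different base), giving a controlled planted identity."""
    n = len(seq)
    n_sub = int(round(divergence * n))
    positions = rng.choice(n, size=n_sub, replace=False)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return bytes(arr).decode()


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "M" + "".join(_AA[i] for i in rng.integers(0, len(_AA), n_aa - 1))


def _gene_dna(protein: str) -> str:
    # protein[0] is the initiator Met encoded by ATG
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def _build_virus(rng: np.random.Generator, vid: str, length: int,
                 cfg: SimConfig, ledger: TruthLedger):
    """Random virus genome with planted ORF-structured genes."""
    lo, hi = cfg.gene_len_range_aa
    parts: list[str] = []
    genes: list[tuple[int, int, str]] = []
    pos = 0
    spacer = max((length // max(cfg.genes_per_virus, 1)) - 3 * hi - 600, 200)
    proteins: list[ProteinRecord] = []
    for gi in range(cfg.genes_per_virus):
        gap = _random_dna(rng, spacer)
        parts.append(gap)
        pos += len(gap)
        protein = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        dna = _gene_dna(protein)
        if pos + len(dna) > length - 200:
            break
        parts.append(dna)
        genes.append((pos, pos + len(dna), protein))
        pos += len(dna)
    tail = length - pos
    if tail > 0:
        parts.append(_random_dna(rng, tail))
    seq = "".join(parts)[:length]
    for start, end, protein in genes:
        ledger.genes.append(
            {"virus_id": vid, "start": start, "end": end, "strand": "+",
             "protein": protein}
        )
        proteins.append(ProteinRecord(f"{vid}_g{start}", vid, (start, end), "+", protein))
    return ContigRecord(vid, seq), proteins


def _taxonomy_for_host(i: int) -> Taxonomy:
    return Taxonomy(
        domain="Bacteria",
        phylum=f"Phylum{i % 4:02d}",
        class_=f"Class{i % 4:02d}",
        order=f"Order{i // 4:02d}",
        family=f"Family{i // 2:02d}",
        genus=f"Genus{i:02d}",
    )


def generate_community(config: SimConfig) -> SyntheticCommunity:
    """Deterministically generate the community, evidence and truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ledger = TruthLedger(seed=config.seed, module_r=config.module_r)

    # --- viruses -----------------------------------------------------------
    viruses: dict[str, ContigRecord] = {}
    proteins: dict[str, list[ProteinRecord]] = {}
    roles: dict[str, str] = {}
    vlo, vhi = config.virus_len_range
    order = (
        ["temperate"] * config.n_temperate
        + ["circular"] * config.n_circular
        + ["spacer"] * config.n_spacer_targeted
        + ["decoy"] * config.n_decoys
        + ["lytic"] * config.n_lytic_extra
    )
    non_decoy_ids: list[str] = []
    for i, role in enumerate(order):
        vid = f"virus{i:03d}"
        roles[vid] = role
        if role == "decoy":
            continue  # built after their sources exist
        length = int(rng.integers(vlo, vhi + 1))
        if role == "circular":
            dtr_len = int(rng.integers(*config.dtr_len_range))
            core, prots = _build_virus(rng, vid, length - 2 * dtr_len, config, ledger)
            dtr = _random_dna(rng, dtr_len)
            virus = ContigRecord(vid, dtr + core.sequence + dtr)
            ledger.dtr_lengths[vid] = dtr_len
            prots = [
                ProteinRecord(p.id, vid,
                              (p.interval[0] + dtr_len, p.interval[1] + dtr_len),
                              p.strand, p.sequence)
                for p in prots
            ]
            for g in ledger.genes:
                if g["virus_id"] == vid:
                    g["start"] += dtr_len
                    g["end"] += dtr_len
        else:
            virus, prots = _build_virus(rng, vid, length, config, ledger)
        viruses[vid] = virus
        proteins[vid] = prots
        non_decoy_ids.append(vid)
        ledger.lifestyle[vid] = "temperate" if role == "temperate" else "lytic"

    decoy_sources = non_decoy_ids[: config.n_decoys]
    decoy_ids = [vid for vid, role in roles.items() if role == "decoy"]
    for vid, src in zip(decoy_ids, decoy_sources):
        viruses[vid] = ContigRecord(
            vid, _mutate(rng, viruses[src].sequence, config.decoy_divergence)
        )
        proteins[vid] = []
        ledger.decoy_of[vid] = src
        ledger.lifestyle[vid] = ledger.lifestyle[src]

    virus_ids = sorted(viruses)

    # optional planted chimeras: an internal >= 5 kb duplication
    for i, vid in enumerate(virus_ids):
        if i >= config.n_chimeric:
            break
        seq = viruses[vid].sequence
        block = seq[1000 : 1000 + config.chimera_repeat_bp]
        mid = len(seq) // 2
        viruses[vid] = ContigRecord(vid, seq[:mid] + block + seq[mid:])
        ledger.chimeric.add(vid)

    # --- MAGs: prophages, CRISPR arrays, decoy-virus carriers --------------
    mag_scaffolds: dict[str, list[ContigRecord]] = {}
    bin_taxonomy: dict[str, Taxonomy] = {}
    scaffold_protein_hits: dict[str, list[Taxonomy]] = {}
    temperate_ids = [v for v in virus_ids if roles[v] == "temperate"]
    spacer_ids = [v for v in virus_ids if roles[v] == "spacer"]
    lytic_ids = [v for v in virus_ids if roles[v] == "lytic"]
    crispr_hosts = list(range(config.n_temperate,
                              config.n_temperate + config.n_spacer_targeted))
    decoy_mag_hosts = list(range(config.n_hosts - config.n_decoy_mags, config.n_hosts))
    for h in range(config.n_hosts):
        mag_id = f"mag{h:02d}"
        scaffold_id = f"{mag_id}_s0"
        tax = _taxonomy_for_host(h)
        bin_taxonomy[mag_id] = tax
        seq = _random_dna(rng, config.host_scaffold_bp)
        if h < config.n_temperate:
            vid = temperate_ids[h]
            vseq = viruses[vid].sequence
            insert_at = (config.host_scaffold_bp - len(vseq)) // 2
            seq = seq[:insert_at] + vseq + seq[insert_at + len(vseq):]
            ledger.prophages.append(
                {"mag_id": mag_id, "scaffold_id": scaffold_id,
                 "start": insert_at, "end": insert_at + len(vseq), "virus_id": vid}
            )
        if h in crispr_hosts:
            vid = spacer_ids[h - config.n_temperate]
            vseq = viruses[vid].sequence
            sp_at = int(rng.integers(0, len(vseq) - config.crispr_spacer_len))
            spacer = vseq[sp_at : sp_at + config.crispr_spacer_len]
            decoy_src = lytic_ids[(h - config.n_temperate) % max(len(lytic_ids), 1)]
            dseq = viruses[decoy_src].sequence
            d_at = int(rng.integers(0, len(dseq) - config.crispr_spacer_len))
            decoy_spacer = _mutate_one(rng, dseq[d_at : d_at + config.crispr_spacer_len])
            repeat = _random_dna(rng, config.crispr_repeat_len)
            filler = _random_dna(rng, config.crispr_spacer_len)
            array = repeat + spacer + repeat + decoy_spacer + repeat + filler + repeat
            arr_at = int(rng.integers(1000, config.host_scaffold_bp // 8))
            seq = seq[:arr_at] + array + seq[arr_at + len(array):]
            ledger.spacer_links.append(
                {"mag_id": mag_id, "virus_id": vid, "spacer": spacer,
                 "repeat": repeat}
            )
            ledger.decoy_spacers.append(
                {"mag_id": mag_id, "virus_id": decoy_src, "spacer": decoy_spacer}
            )
        if h in decoy_mag_hosts:
            # a 90%-identity copy of a virus: must NOT produce a host link
            src = virus_ids[(h - decoy_mag_hosts[0]) % len(virus_ids)]
            degraded = _mutate(rng, viruses[src].sequence, config.decoy_divergence)
            at = config.host_scaffold_bp // 2 + 20_000
            if at + len(degraded) > len(seq):
                at = len(seq) - len(degraded) - 1000
            seq = seq[:at] + degraded + seq[at + len(degraded):]
        scaffold = ContigRecord(scaffold_id, seq)
        mag_scaffolds[mag_id] = [scaffold]
        # plurality protein hits consistent with the bin: 6 in-genus,
        # 2 from a different genus (annotation noise)
        other = _taxonomy_for_host((h + 7) % config.n_hosts)
        scaffold_protein_hits[scaffold_id] = [tax] * 6 + [other] * 2

    # --- assembly contigs fed to curation ---------------------------------
    contigs: list[ContigRecord] = [viruses[v] for v in virus_ids]
    for vid in virus_ids:
        ledger.cluster_of[vid] = vid
    frag_sources = [v for v in virus_ids if roles[v] != "decoy"][
        : config.n_redundant_fragments
    ]
    for src in frag_sources:
        fid = f"{src}_frag"
        seq = viruses[src].sequence
        flen = int(len(seq) * config.fragment_length_frac)
        start = int(rng.integers(0, len(seq) - flen))
        contigs.append(
            ContigRecord(fid, _mutate(rng, seq[start : start + flen],
                                      config.fragment_divergence))
        )
        ledger.cluster_of[fid] = src
    for i in range(config.n_short_contigs):
        sid = f"short{i:02d}"
        contigs.append(ContigRecord(sid, _random_dna(
            rng, int(rng.integers(*config.short_len_range)))))
        ledger.dropped.add(sid)
    for i in range(config.n_nonviral_contigs):
        nid = f"cellular{i:02d}"
        contigs.append(ContigRecord(nid, _random_dna(rng, 12_000)))
        ledger.nonviral.add(nid)

    # --- detector evidence, emitted from truth ----------------------------
    evidence: dict[str, EvidenceBundle] = {}
    for contig in contigs:
        cid = contig.id
        ev = EvidenceBundle(cid)
        base = cid.split("_frag")[0]
        is_viral = not cid.startswith("cellular")
        if is_viral:
            is_temperate = ledger.lifestyle.get(base, "lytic") == "temperate"
            call = "prophage" if is_temperate else "viral"
            interval = (0, contig.length) if is_temperate else None
            calls = [DetectorCall("detectorA", call, interval)]
            # lytic extras exercise retention criterion (ii): one detector
            # plus a phage marker instead of agreement of two detectors
            if roles.get(base) != "lytic":
                calls.append(DetectorCall("detectorB", call, interval))
            for c in calls:
                if config.detector_fn_rate > 0 and rng.random() < config.detector_fn_rate:
                    c = DetectorCall(c.tool, "none", None)
                ev.detector_calls.append(c)
            ev.marker_hits.append(
                MarkerHit("Phage_capsid", "phage_structural",
                          float(np.round(40 + 40 * rng.random(), 1)))
            )
            ev.marker_hits.append(
                MarkerHit("Terminase_large", "phage_structural",
                          float(np.round(35 + 30 * rng.random(), 1)))
            )
            if is_temperate:
                ev.marker_hits.append(
                    MarkerHit("Phage_integrase", "temperate_marker",
                              float(np.round(35 + 25 * rng.random(), 1)))
                )
        else:
            ev.detector_calls.append(DetectorCall("detectorA", "none"))
            ev.detector_calls.append(DetectorCall("detectorB", "none"))
            if config.detector_fp_rate > 0 and rng.random() < config.detector_fp_rate:
                ev.detector_calls[0] = DetectorCall("detectorA", "viral")
        evidence[cid] = ev

    # --- depth of origin and export truth ----------------------------------
    bins = ("surface", "DCM", "transitional", "mesopelagic")
    exported_pool = ([v for v in virus_ids if roles[v] == "circular"]
                     + [v for v in virus_ids if roles[v] == "spacer"]
                     + lytic_ids[:1])
    for j, vid in enumerate(exported_pool):
        b = bins[j % 4]
        ledger.origin[vid] = b
        ledger.exported.add(vid)
    for vid in virus_ids:
        ledger.origin.setdefault(vid, "bathypelagic")

    return SyntheticCommunity(
        config=config,
        contigs=contigs,
        evidence=evidence,
        viruses=viruses,
        mag_scaffolds=mag_scaffolds,
        bin_taxonomy=bin_taxonomy,
        scaffold_protein_hits=scaffold_protein_hits,
        proteins=proteins,
        ledger=ledger,
    )


def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    """Single-substitution decoy of a sequence."""
    p = int(rng.integers(0, len(seq)))
    old = seq[p]
    new = "ACGT".replace(old, "")[int(rng.integers(0, 3))]
    return seq[:p] + new + seq[p + 1 :]


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    genomes: Mapping[str, ContigRecord],
    abundances: Mapping[str, float],
    n_reads: int,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    sample_id: str = "S",
) -> list[ContigRecord]:
    """Draw reads multinomially with probability ∝ abundance × length,
    uniform start positions, both strands, substitution errors at
    ``error_rate``.  Read ids encode their true source as
    ``sample|genome|start|strand|serial``.
    """
    ids = sorted(genomes)
    weights = np.array([
        max(abundances.get(g, 0.0), 0.0) * genomes[g].length for g in ids
    ])
    if weights.sum() <= 0:
        raise ValueError("all-zero abundance vector")
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads: list[ContigRecord] = []
    serial = 0
    for gid, count in zip(ids, counts):
        if count == 0:
            continue
        seq = genomes[gid].sequence
        span = len(seq) - read_len
        if span < 0:
            raise ValueError(f"genome {gid} shorter than the read length")
        starts = rng.integers(0, span + 1, size=count)
        strands = rng.integers(0, 2, size=count)
        for start, flip in zip(starts, strands):
            read = seq[start : start + read_len]
            if error_rate > 0:
                n_err = rng.binomial(read_len, error_rate)
                if n_err:
                    pos = rng.choice(read_len, size=n_err, replace=False)
                    arr = list(read)
                    for p in pos:
                        arr[p] = "ACGT".replace(arr[p], "")[int(rng.integers(0, 3))]
                    read = "".join(arr)
            strand = "+"
            if flip:
                read = revcomp(read)
                strand = "-"
            reads.append(
                ContigRecord(f"{sample_id}|{gid}|{start}|{strand}|{serial}", read)
            )
            serial += 1
    return reads


def build_sample_plan(config: SimConfig, community: SyntheticCommunity,
                      rng: np.random.Generator) -> None:
    """Fill the ledger with per-sample kinds, depth bins, library sizes and
    true abundances (trap samples: all genomes; shallow samples: viruses of
    that depth bin only)."""
    ledger = community.ledger
    genome_ids = sorted(community.viruses) + sorted(
        sc.id for scs in community.mag_scaffolds.values() for sc in scs
    )
    size_cycle = (1.0, 0.8, 1.2, 0.9, 1.1)
    bins = ("surface", "DCM", "transitional", "mesopelagic")
    for t in range(config.n_trap_samples):
        sid = f"trap{t:02d}"
        lib = int(config.reads_per_sample * size_cycle[t % len(size_cycle)])
        abund = {
            g: float(np.round(rng.lognormal(mean=0.0, sigma=0.5), 4))
            for g in genome_ids
        }
        ledger.samples.append({"sample_id": sid, "kind": "trap",
                               "depth_bin": "", "library_size": lib})
        ledger.true_abundances[sid] = abund
    for s in range(config.n_shallow_samples):
        sid = f"shallow{s:02d}"
        depth_bin = bins[s % 4]
        lib = int(config.reads_per_sample * size_cycle[s % len(size_cycle)])
        abund = {
            vid: 1.0
            for vid in sorted(community.viruses)
            if ledger.origin.get(vid) == depth_bin
        }
        ledger.samples.append({"sample_id": sid, "kind": "shallow",
                               "depth_bin": depth_bin, "library_size": lib})
        ledger.true_abundances[sid] = abund


# ---------------------------------------------------------------------------
# flux series and planted modules

def generate_flux_series(
    config: SimConfig,
) -> tuple[list[FluxRecord], pd.DataFrame, TruthLedger]:
    """Flux series with designated >= 150%-of-mean pulse samples, plus an
    abundance matrix containing the planted co-abundance modules.

    Module latent profiles are constructed with sample-exact correlation to
    ln(flux) (residuals orthogonalized in-sample); members add independent
    noise.  The two flux-correlated modules share the ln-flux signal but
    carry anti-correlated residuals so that they remain separable under the
    tree cut.  Background populations are i.i.d. noise.
    """
    config.validate()
    n = config.n_flux_samples
    if n < 8:
        raise ValueError("need at least 8 samples")
    rng = np.random.default_rng(config.seed + 1)
    ledger = TruthLedger(seed=config.seed, module_r=config.module_r)

    ref = config.flux_reference_mean
    flux = np.empty(n)
    for i in range(n):
        draw = 0.7 * ref * np.exp(rng.normal(0.0, 0.35))
        while draw >= 1.5 * ref:
            draw = 0.7 * ref * np.exp(rng.normal(0.0, 0.35))
        flux[i] = draw
    pulse_idx = rng.choice(n, size=min(config.n_pulse_samples, n), replace=False)
    for i in pulse_idx:
        flux[i] = max(1.5 * ref,
                      config.pulse_amplitude * ref * np.exp(rng.normal(0.0, 0.1)))
    start = date(2014, 1, 15)
    records = []
    sample_ids = []
    for i in range(n):
        sid = f"F{i:02d}"
        sample_ids.append(sid)
        s = start + timedelta(days=14 * i)
        records.append(FluxRecord(sid, s, s + timedelta(days=13), float(flux[i])))
        ledger.samples.append({"sample_id": sid, "kind": "flux",
                               "depth_bin": "", "library_size": 0})

    x = np.log(flux)
    x = (x - x.mean()) / x.std()

    def orthonormal_residual(seed_vec: np.ndarray, against: list[np.ndarray]):
        v = seed_vec.copy()
        for u in against:
            v = v - (v @ u) / (u @ u) * u
        return (v - v.mean()) / v.std()

    g = orthonormal_residual(rng.normal(size=n), [x, np.ones(n)])
    used_antipair = 0
    profiles: dict[str, np.ndarray] = {}
    pop = 0
    for m, r in enumerate(config.module_r, start=1):
        if r != 0:
            resid = g if used_antipair == 0 else -g
            used_antipair += 1
            latent = r * x + np.sqrt(1 - r**2) * resid
        else:
            latent = orthonormal_residual(rng.normal(size=n), [x, g, np.ones(n)])
        for _ in range(config.module_size):
            pid = f"pop{pop:04d}"
            noise = rng.normal(scale=config.within_module_noise, size=n)
            profiles[pid] = latent + noise
            ledger.module_of[pid] = m
            pop += 1
    for _ in range(config.n_background_populations):
        pid = f"pop{pop:04d}"
        profiles[pid] = rng.normal(size=n)
        ledger.module_of[pid] = 0
        pop += 1

    matrix = pd.DataFrame(
        {sid: [15.0 + 3.0 * profiles[pid][i] for pid in sorted(profiles)]
         for i, sid in enumerate(sample_ids)},
        index=sorted(profiles),
    ).clip(lower=0.01)
    return records, matrix, ledger


# ---------------------------------------------------------------------------
# ledger verification

def verify_ledger(community: SyntheticCommunity) -> list[str]:
    """Check every planted fact against the emitted objects; returns a list
    of human-readable violations (empty = consistent)."""
    problems: list[str] = []
    ledger = community.ledger
    scaffolds = {
        sc.id: sc for scs in community.mag_scaffolds.values() for sc in scs
    }
    contig_ids = {c.id for c in community.contigs}
    for p in ledger.prophages:
        sc = scaffolds.get(p["scaffold_id"])
        if sc is None:
            problems.append(f"prophage scaffold {p['scaffold_id']} missing")
            continue
        virus = community.viruses.get(p["virus_id"])
        if virus is None:
            problems.append(f"prophage virus {p['virus_id']} missing")
            continue
        if sc.sequence[p["start"] : p["end"]] != virus.sequence:
            problems.append(f"prophage {p['virus_id']} not at its interval")
        if p["start"] < 10_000 or len(sc.sequence) - p["end"] < 10_000:
            problems.append(f"prophage {p['virus_id']} flanks shorter than 10 kb")
    for s in ledger.spacer_links:
        virus = community.viruses.get(s["virus_id"])
        if virus is None or s["spacer"] not in virus.sequence:
            problems.append(f"spacer for {s['virus_id']} not a virus substring")
        mag = community.mag_scaffolds.get(s["mag_id"], [])
        if not any(sc.sequence.count(s["repeat"]) >= 3 for sc in mag):
            problems.append(f"repeat for {s['mag_id']} occurs fewer than 3 times")
    for vid, d in ledger.dtr_lengths.items():
        seq = community.viruses[vid].sequence
        if seq[:d] != seq[-d:]:
            problems.append(f"DTR of {vid} is not a terminal repeat")
    for g in ledger.genes:
        virus = community.viruses.get(g["virus_id"])
        if virus is None:
            continue
        dna = virus.sequence[g["start"] : g["end"]]
        if dna != _gene_dna(g["protein"]):
            problems.append(f"gene at {g['virus_id']}:{g['start']} mismatches")
    for did, src in ledger.decoy_of.items():
        a = community.viruses[did].sequence
        b = community.viruses[src].sequence
        if len(a) != len(b):
            problems.append(f"decoy {did} length differs from source")
            continue
        ident = sum(1 for u, v in zip(a, b) if u == v) / len(a)
        if abs(ident - (1 - community.config.decoy_divergence)) > 0.005:
            problems.append(f"decoy {did} identity {ident:.3f} off target")
    for cid in ledger.cluster_of:
        if cid not in contig_ids:
            problems.append(f"cluster entry {cid} not an emitted contig")
    for vid, ls in ledger.lifestyle.items():
        ev = community.evidence.get(vid)
        if ls == "temperate" and ev is not None:
            if not any(h.category == "temperate_marker" and h.bit_score >= 30
                       for h in ev.marker_hits):
                problems.append(f"temperate {vid} lacks an integrase marker")
    return problems
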
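# Methods

This note documents the models and procedures implemented in `phageflux`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Alignment engine

All identity/coverage decisions rest on one engine (`seqops`): exact-match
k-mer seeds (k = 11 for DNA, k = 5 for protein), grouped by diagonal and
split at query gaps > 300 bp, with runs of fewer than two anchors
discarded as single-seed collisions. Runs on diagonals within ±25 whose
query ranges adjoin are merged; the anchored core is aligned globally
with edlib and the ends are extended ungapped with an X-drop of 12.
Scoring is match +1, mismatch −2, gap open −3, gap extend −1, with a
reporting floor of 30 — so a reported hit carries at least ~30 matched
positions. The engine is a desk-scale stand-in for a production aligner:
it is built for the ≥ 90%-identity homology the generator plants, and the
only quantities consumed downstream are per-hit identity, alignment
length, and intervals. Tabular hits (blastn/LAST outfmt-6 style, 1-based
inclusive coordinates) can be imported in place of the built-in engine.

ANI between two contigs is the alignment-length-weighted mean identity of
accepted hits; query coverage is the union of covered query positions
divided by query length, so an alignment split by a circular permutation
counts each position once. Coverage fractions are always measured on the
query (the viral contig, or the candidate during dereplication — the
cd-hit `-aS` convention; a config switch selects the representative
instead).

The read mapper indexes the references' 15-mers in one sorted array,
seeds each read at non-overlapping offsets, evaluates candidate diagonals
ungapped, and reports the single best-scoring reference per read (ties to
the lexicographically smallest reference id), trying the reverse
complement when the forward strand yields nothing. Indel read errors are
out of scope (the generator produces substitution errors only), so
ungapped evaluation is exact for simulated reads.

The ORF caller scans six frames for ATG/GTG/TTG → stop spans, keeps the
longest ORF per stop, and translates with the standard code (initiator
forced to Met). It is deliberately minimal: real-data users import
externally predicted protein tables; synthetic genomes are built so the
caller finds every planted gene.

## Curation

Retention requires one of: (i) both detectors call the contig viral,
(ii) at least one does and a phage-category marker scores ≥ 30 bits,
(iii) a eukaryotic-virus marker scores ≥ 30 bits. Criterion (ii) is
implemented as *at least* one detector (criterion (i) takes precedence in
the reason tags), since contigs satisfying (i) trivially satisfy the
"either detector" phrasing. When detectors report prophage intervals the
shortest interval's subsequence replaces the contig; when only one
reports an interval, that interval is used — it is the only boundary
estimate available.

Dereplication is greedy longest-first (ties by id, for determinism): each
contig joins the first existing cluster whose representative it matches
at ANI ≥ 95% over ≥ 50% of itself, else founds a cluster. The ≥ 10 kb
length filter applies to cluster representatives *after* clustering, so
short members of long-representative clusters survive inside populations.

Direct terminal repeats are exact (no mismatch allowance): the longest
maximal repeat pair with the 5′ copy starting within 200 bp of the start,
the 3′ copy ending within 200 bp of the end, and length in [20, 5000] bp.
Maximality matters at the upper bound: a pair extendable on its left
flank is skipped as part of a larger repeat, so a 5001 bp terminal repeat
is not reported via its 5000 bp sub-repeat. Chimera flagging looks for
any off-diagonal self-alignment at ≥ 95% identity over ≥ 5 kb; chimeras
are flagged, never removed. The ribosomal screen reports any
ribosomal-category marker other than S21 as a warning (the procedure is
an inspection, not an automated removal).

## Host linking

Methods are ranked 1–4 by confidence. Rank 1 (prophage) additionally
requires taxonomic consistency: over the aligned scaffold's protein
best-hit taxonomies, the genus must win a strict plurality and equal the
bin's genus; when the genus vote is tied or absent the family vote
decides. Genus-first is the stricter of the two readings of
"genus or family".

The CRISPR detector works in assembly space: arrays of ≥ 3 exact
occurrences of a repeat (21–48 bp after maximal shared extension) with
spacers of 18–72 bp between them; overlapping candidates resolve to the
one with more repeats. Read-based detection accepts a pre-filtered read
set (≥ 97% identity across ≥ 75% of the read) and treats each read as a
sequence — a simplification of read-space array assembly. Rank-2 linking
requires the full repeat to occur exactly (either strand) in the MAG and
a full spacer exactly in the virus. The published criterion couples the
repeat match to a blastn e-value ≤ 1e-10; at this database scale an exact
full-repeat match of ≥ 23 bp is far below that e-value, so the clause is
operationalized as a 23 bp minimum repeat length — removing an
aligner-statistics dependency without weakening the rule.

Rank 3 assigns a genus when ≥ 50% of the virus's proteins have best hits
at ≥ 60% AAI to a single genus; AAI of a protein pair is the identity of
its single best local alignment. A tie between genera assigns nothing
(conservative, matching the strict "single genus-level group"). Novelty
inverts the same tally with genomes-of-origin as groups, across every
supplied panel. Merging keeps the lowest rank per virus; within a rank
the strongest evidence (spacer count for rank 2, identity × coverage
otherwise) wins, and an exact tie between different hosts yields no link
plus an `ambiguous` flag.

## Lifestyle

Temperate iff any of four non-exclusive criteria: lysogeny marker
≥ 30 bits; ≥ 95% identity over ≥ half the virus to a prophage region;
a detector prophage call on the representative; or a *single contiguous*
alignment at ≥ 95% identity covering ≥ 50% of the virus to a MAG scaffold
at least 10 kb longer. The contiguity requirement distinguishes this
criterion from host-linking's union semantics on purpose: flanking host
sequence is only evidence of integration when the viral region is intact
in the scaffold. An empty criteria set is definitionally lytic, and
classification is monotone in evidence.

## Abundance

Read filters: ≥ 95% identity across ≥ 45 bp for viral references (≥ 97%
for MAGs); the water-column export filter is ≥ 95% identity across ≥ 80%
of the read. The two length conventions are exclusive by construction.
Reads contribute depth over their full aligned interval, mismatches
included.

IQR coverage uses the nearest-rank percentile convention: with depths
sorted ascending, Q1 and Q3 sit at 1-based indices ⌈0.25 n⌉ and ⌈0.75 n⌉,
and the statistic is the mean of all depth values inside the inclusive
band. This convention is deterministic and provably reproduces the
equivalence "IQR coverage > 0 ⇔ breadth > 25%" for lengths divisible by
four (with ≤ 25% of positions covered, Q3 = 0 and the band mean is 0; with
more, Q3 > 0 and the band contains a positive value). Whether other
profiling tools include or exclude the band boundaries differs; anyone
comparing against external output should check that convention first.
Normalization multiplies each sample by smallest-library/library read
count, so the smallest library's factor is exactly 1, zeros are
preserved, and within-sample ranks are unchanged. Library sizes are
inputs (a sidecar table), not recomputed. Shannon H uses natural log over
present (non-zero) populations; evenness H/ln(richness) is undefined at
richness ≤ 1 and reported as missing.

## Provenance

Export requires non-zero IQR coverage in any shallow dataset; the source
category is the exact subset of positive datasets. Depth of origin is the
argmax over bins of the bin-level normalized coverage, where a bin's
coverage is the *maximum* over its samples — robust to bins with unequal
sample counts (a config choice; mean aggregation is the alternative).
Ties resolve to the shallowest tied bin and are logged: shallow-first
biases against claiming deep origin, which is the conservative direction
for export inference. All-zero coverage ⇒ bathypelagic.

## Flux analysis

The summer-export-pulse rule compares each sample's flux to 1.5× an
externally supplied long-term reference mean (µmol C m⁻² d⁻¹); the mean
is never computed from the series itself, because the series at hand is
short relative to the reference record the rule presumes.

Modules come from a weighted correlation network: unsigned adjacency
a_ij = |pearson|^6 (the conventional unsigned soft threshold; the power
is exposed in config), TOM dissimilarity
d_ij = 1 − (Σ_k a_ik a_kj + a_ij)/(min(k_i, k_j) + 1 − a_ij), average
linkage, and a static cut at height 0.988 with a minimum module size of
10. The static cut plus the size floor stand in for the dynamic hybrid
tree cut; the approximation's visible gap is that weakly connected noise
populations can be absorbed into a module at so permissive a cut height
(TOM denominators near 1 for low-degree nodes), which dynamic pruning
would trim. Tests therefore require exact recovery of planted partitions
without background and bound the absorption rate with background present.

Each module's eigenprofile is the first principal component across
samples of its members' per-population z-scored profiles, sign-oriented
to the module mean and scaled to unit (population) variance; a summed-
member-profile variant is available for total-abundance-style tests.
Correlation is Pearson against natural-log flux (the base only rescales
the regressor and leaves r unchanged), with a two-sided p from the
t-distribution at n − 2 degrees of freedom. Members are flagged
flux-correlated only for modules with p < α = 0.05 *and* r > 0 —
positive association is the phenomenon of interest; negative modules are
reported but not flagged. No multiple-testing correction is applied
across modules by default (a config switch exists in spirit via α).

## The synthetic-data generator

Defaults are the study conditions the test suite runs under: 20 host MAGs
with 300 kb scaffolds; 40 viruses of 15–60 kb split into 10 temperate
(each integrated into a distinct MAG with ≥ 10 kb flanks and also present
free), 10 circular (planted DTRs of 100–1000 bp, inside the searchable
20–5000 bp range), 5 spacer-targeted (a 32 bp spacer copied verbatim into
a CRISPR array of a 28 bp repeat, alongside a single-mismatch decoy
spacer drawn from a lytic virus), 5 decoys at exactly 90% identity to
cluster representatives (probing the 95% dereplication boundary from
below), and 10 free lytic viruses; plus 10 redundant fragments (60%
length, 2% divergence — above the boundary, must merge), 3 short
standalone viral contigs (dropped by the 10 kb filter) and 3 cellular
contigs (never retained). Two MAGs carry 90%-identity degraded virus
copies that must not produce host links. Each virus carries 4 planted
ORF-structured genes. Samples: 12 deep-trap and 8 shallow (two per depth
bin) of 50,000 150 bp reads each, libraries varying ±20% to exercise
normalization; reads are drawn multinomially ∝ abundance × length, both
strands, substitution errors at a configurable rate (default 0 — the
noise-free regime in which planted-truth recovery is expected to be
exact). Sixteen viruses are exported, four per depth bin, with reads only
in their origin bin; the rest are bathypelagic.

The flux series has 63 samples, a lognormal baseline below a 100
µmol C m⁻² d⁻¹ reference mean, and 9 designated pulse samples at ≥ 150%
of it. Three 30-member modules are planted: module latents are built with
*sample-exact* correlation to ln flux (residuals orthogonalized
in-sample), r = (0.8, 0.8, 0) by default, members adding independent
noise of SD 0.5 (within-module r ≈ 0.8). The two flux-correlated modules
share the ln-flux signal, which alone would make them mutually correlated
at r ≈ 0.64 and indistinguishable under the 0.988 cut; their residual
components are therefore anti-correlated (g and −g), keeping the pair
separable while preserving each module's planted flux correlation. At
most two flux-correlated modules are supported for this reason. Thirty
background populations are i.i.d. noise.

Genomes are i.i.d. uniform random DNA. That is the central simplification:
the pipeline's decisions depend only on identity, coverage, and marker
structure, all of which random DNA exercises, but passing tests say
nothing about codon structure, oligomer composition, strain
microdiversity, phylogenetic signal, chimeric reads, or indel errors in
real data. Detector tables are emitted from truth with configurable
false-positive/negative rates (default 0), so decision-logic errors are
separable from detector noise. One RNG stream per run, seeded from the
config; identical seeds give byte-identical outputs, and every planted
fact is re-verifiable against the emitted objects by `verify_ledger`.

## Problem sizes and determinism

The acceptance run uses the full default community (≈ 7.5 Mb of genomes,
1,000,000 reads over 20 samples), twenty 63-sample flux series, and 1000
random depth vectors for the IQR oracle; unit tests use a reduced preset
(`SimConfig.small`) of the same structure. Greedy clustering ties break
by contig id; merged host links are sorted canonically before selection;
module labels are assigned by size then first member id — so every stage
is deterministic and invariant to input order, which the suite asserts.

## Known limitations

- The aligner offers no optimality guarantee for gapped alignments and is
  untuned for < 85% identity homology; import external hit tables there.
- CRISPR detection requires exact repeat copies; degenerate repeats and
  read-space array reconstruction are out of scope.
- The static tree cut is an approximation of dynamic hybrid cutting (see
  above); module boundaries for marginal populations differ from WGCNA's.
- Prophage-homology lifestyle evidence (criterion ii) requires an
  explicit prophage-region set; the end-to-end pipeline relies on the
  marker, detector, and embedding criteria, which planted temperate
  viruses always satisfy.
- FASTQ qualities are parsed and ignored; read QC happens upstream.
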
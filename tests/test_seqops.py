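import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phageflux.io import ContigRecord
from phageflux.seqops import (
    AlignmentHit,
    ani_and_query_coverage,
    find_orfs,
    local_align,
    map_reads,
    revcomp,
)

from conftest import mutate, random_dna


class TestLocalAlign:
    def test_self_identity_full_coverage(self, rng):
        seq = random_dna(rng, 1000)
        hits = local_align(seq, seq)
        top = hits[0]
        assert top.percent_identity == 100.0
        assert top.query_interval == (0, 1000)
        assert top.subject_interval == (0, 1000)

    def test_unrelated_random_sequences_yield_no_hit(self, rng):
        assert local_align(random_dna(rng, 500), random_dna(rng, 500)) == []

    def test_fifty_substitutions_in_1000_gives_95_percent(self, rng):
        # oracle: matches along the known gap-free correspondence = 950/1000
        a = random_dna(rng, 1000)
        b = mutate(rng, a, 0.05)
        top = local_align(b, a)[0]
        assert top.percent_identity == pytest.approx(95.0, abs=0.2)

    def test_reverse_complement_found_on_minus_strand(self, rng):
        subj = random_dna(rng, 2000)
        query = revcomp(subj[500:1500])
        top = local_align(query, subj)[0]
        assert top.strand == "-"
        assert top.subject_interval == (500, 1500)

    def test_mixed_alphabets_raise(self):
        with pytest.raises(ValueError, match="mixed alphabets"):
            local_align("ACGTACGTACGT", "MKLVWYHQERDS")

    def test_protein_alignment_identity(self, rng):
        prot = "".join(np.random.default_rng(5).choice(list("ARNDCQEGHILKMFPSTWYV"), 120))
        hits = local_align(prot, prot)
        assert hits[0].percent_identity == 100.0


class TestAniAndQueryCoverage:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 1500)
        ani, cov = ani_and_query_coverage(seq, seq)
        assert ani == 100.0 and cov == 1.0

    def test_query_contained_in_longer_subject(self, rng):
        subj = random_dna(rng, 4000)
        ani, cov = ani_and_query_coverage(subj[1000:3000], subj)
        assert ani == 100.0 and cov == 1.0

    def test_half_matching_query(self, rng):
        # first half at 96% identity, second half unrelated
        subj = random_dna(rng, 2000)
        query = mutate(rng, subj[:1000], 0.04) + random_dna(rng, 1000)
        ani, cov = ani_and_query_coverage(query, subj)
        assert ani == pytest.approx(96.0, abs=0.3)
        assert cov == pytest.approx(0.5, abs=0.01)

    def test_no_hits_returns_zeros(self, rng):
        assert ani_and_query_coverage(random_dna(rng, 400), random_dna(rng, 400)) == (0.0, 0.0)

    def test_identity_symmetric_for_equal_length_pairs(self, rng):
        a = random_dna(rng, 3000)
        b = mutate(rng, a, 0.03)
        ani_ab, _ = ani_and_query_coverage(a, b)
        ani_ba, _ = ani_and_query_coverage(b, a)
        assert abs(ani_ab - ani_ba) < 0.1

    @given(st.lists(st.tuples(st.integers(0, 990), st.integers(1, 400)),
                    min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_union_coverage_matches_position_set_oracle(self, intervals):
        # brute-force oracle: union of covered query positions
        qlen = 1000
        hits = [
            AlignmentHit("q", "s", 99.0, ln, (start, min(start + ln, qlen)),
                         (0, min(ln, qlen)), "+", 50.0, qlen)
            for start, ln in intervals
        ]
        expected = set()
        for start, ln in intervals:
            expected.update(range(start, min(start + ln, qlen)))
        _, cov = ani_and_query_coverage("A" * qlen, "A" * qlen, hits=hits)
        assert cov == pytest.approx(len(expected) / qlen)
        assert cov <= 1.0


class TestFindOrfs:
    def test_planted_91_codon_orf(self, rng):
        rng2 = np.random.default_rng(10)
        codons = [c for c in ("GCT", "CAT", "AAA", "GAA", "TGG")]
        body = "".join(codons[i % 5] for i in range(90))
        gene = "ATG" + body + "TAA"
        contig = ContigRecord("c", random_dna(rng2, 97) + gene + random_dna(rng2, 100))
        orfs = [o for o in find_orfs(contig, 50) if o.strand == "+"]
        # the ORF sharing the planted stop contains the gene; a chance
        # upstream in-frame start may lengthen it
        target = [o for o in orfs if o.interval[1] == 97 + len(gene)]
        assert len(target) == 1
        assert target[0].interval[0] <= 97
        assert len(target[0].sequence) >= 91
        assert target[0].sequence.endswith("AHKEW" * 18)

    def test_all_stop_sequence_has_no_orfs(self):
        contig = ContigRecord("stops", "TAATAGTGA" * 40)
        assert find_orfs(contig, 1) == []

    def test_reverse_strand_gene_recovered(self, rng):
        gene = "ATG" + "GAACATAAA" * 30 + "TAA"
        contig = ContigRecord("c", random_dna(rng, 80) + revcomp(gene) + random_dna(rng, 80))
        minus = [o for o in find_orfs(contig, 50) if o.strand == "-"]
        assert any(o.interval == (80, 80 + len(gene)) for o in minus)

    def test_longest_orf_kept_for_shared_stop(self):
        # two in-frame starts, one stop: the earlier start wins
        gene = "ATG" + "GCA" * 10 + "ATG" + "GCA" * 40 + "TAA"
        contig = ContigRecord("c", gene)
        plus = [o for o in find_orfs(contig, 10) if o.strand == "+"]
        assert len(plus) == 1
        assert plus[0].interval == (0, len(gene))

    def test_min_aa_must_be_positive(self):
        with pytest.raises(ValueError):
            find_orfs(ContigRecord("c", "ACGT"), 0)


class TestMapReads:
    def test_exact_substring_maps_perfectly(self, rng):
        refs = [ContigRecord(f"ref{i}", random_dna(rng, 5000)) for i in range(3)]
        read = ContigRecord("r", refs[1].sequence[2000:2100])
        (hit,) = map_reads([read], refs)
        assert hit.subject_id == "ref1"
        assert hit.percent_identity == 100.0
        assert hit.read_fraction == 1.0
        assert hit.subject_interval == (2000, 2100)

    def test_single_substitution_gives_99_percent(self, rng):
        refs = [ContigRecord("ref0", random_dna(rng, 5000))]
        seq = list(refs[0].sequence[1000:1100])
        seq[50] = "ACGT".replace(seq[50], "")[0]
        (hit,) = map_reads([ContigRecord("r", "".join(seq))], refs)
        assert hit.percent_identity == pytest.approx(99.0)

    def test_random_read_has_no_hit(self, rng):
        refs = [ContigRecord("ref0", random_dna(rng, 5000))]
        assert map_reads([ContigRecord("r", random_dna(rng, 100))], refs) == []

    def test_empty_reference_set_raises(self, rng):
        with pytest.raises(ValueError, match="empty reference"):
            map_reads([ContigRecord("r", random_dna(rng, 100))], [])

    def test_reverse_strand_read_maps(self, rng):
        refs = [ContigRecord("ref0", random_dna(rng, 5000))]
        read = ContigRecord("r", revcomp(refs[0].sequence[3000:3120]))
        (hit,) = map_reads([read], refs)
        assert hit.strand == "-"
        assert hit.subject_interval == (3000, 3120)

    def test_recovers_99_percent_of_error_free_reads(self, rng):
        # references share no k-mers (independent random sequences)
        refs = [ContigRecord(f"g{i}", random_dna(rng, 20_000)) for i in range(4)]
        reads, truth = [], []
        for i in range(400):
            src = refs[i % 4]
            start = int(rng.integers(0, src.length - 120))
            seq = src.sequence[start : start + 120]
            if i % 2:
                seq = revcomp(seq)
            reads.append(ContigRecord(f"read{i}", seq))
            truth.append(src.id)
        hits = {h.query_id: h for h in map_reads(reads, refs)}
        correct = sum(
            1
            for i, t in enumerate(truth)
            if f"read{i}" in hits
            and hits[f"read{i}"].subject_id == t
            and hits[f"read{i}"].percent_identity == 100.0
        )
        assert correct / len(truth) >= 0.99
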
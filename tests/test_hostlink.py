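import logging

import numpy as np
import pytest

from phageflux.io import ContigRecord
from phageflux.hostlink import (
    CrisprArray,
    HostLink,
    ReferenceProtein,
    Taxonomy,
    assign_taxonomy_by_aai,
    detect_crispr_arrays,
    flag_novelty,
    link_by_prophage,
    link_by_reference_ani,
    link_by_spacer,
    merge_host_links,
    scaffold_consistent_with_bin,
)
from phageflux.seqops import ProteinRecord, revcomp

from conftest import random_dna

TAX_X = Taxonomy(domain="Bacteria", phylum="P", class_="C", order="O",
                 family="FamX", genus="GenX")
TAX_Y = Taxonomy(domain="Bacteria", phylum="P", class_="C", order="O",
                 family="FamY", genus="GenY")


class TestTaxonomy:
    def test_gap_in_lineage_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            Taxonomy(domain="Bacteria", genus="G")

    def test_round_trip_string(self):
        assert Taxonomy.from_string(TAX_X.to_string()) == TAX_X


class TestPluralityConsistency:
    def test_strict_genus_majority_wins(self):
        assert scaffold_consistent_with_bin([TAX_X, TAX_X, TAX_Y], TAX_X)
        assert not scaffold_consistent_with_bin([TAX_Y, TAX_Y, TAX_X], TAX_X)

    def test_genus_tie_falls_back_to_family(self):
        # same family, tied genera: family vote decides
        tax_x2 = Taxonomy(domain="Bacteria", phylum="P", class_="C", order="O",
                          family="FamX", genus="GenX2")
        assert scaffold_consistent_with_bin([TAX_X, tax_x2], TAX_X)

    def test_no_taxonomy_is_inconsistent(self):
        assert not scaffold_consistent_with_bin([], TAX_X)


def fixed_ani(table):
    def fn(query, subject):
        return table.get((query.id, subject.id), (0.0, 0.0))

    return fn


class TestLinkByProphage:
    def _setup(self, rng):
        virus = ContigRecord("v0", random_dna(rng, 20_000))
        scaffold = ContigRecord("mag00_s0", random_dna(rng, 50_000))
        mags = {"mag00": [scaffold]}
        bins = {"mag00": TAX_X}
        return virus, scaffold, mags, bins

    def test_qualified_candidate_links(self, rng):
        virus, scaffold, mags, bins = self._setup(rng)
        links, rejected = link_by_prophage(
            [virus], mags, bins, {scaffold.id: [TAX_X] * 6 + [TAX_Y] * 2},
            ani_fn=fixed_ani({("v0", scaffold.id): (98.0, 1.0)}),
        )
        assert [(l.virus_id, l.mag_id, l.method_rank) for l in links] == [("v0", "mag00", 1)]
        assert rejected == []

    @pytest.mark.parametrize(
        "ani,cov,linked", [(95.0, 0.5, True), (94.9, 0.5, False), (98.0, 0.4, False)]
    )
    def test_identity_and_coverage_thresholds(self, rng, ani, cov, linked):
        virus, scaffold, mags, bins = self._setup(rng)
        links, _ = link_by_prophage(
            [virus], mags, bins, {scaffold.id: [TAX_X] * 5},
            ani_fn=fixed_ani({("v0", scaffold.id): (ani, cov)}),
        )
        assert bool(links) is linked

    def test_inconsistent_scaffold_taxonomy_rejected_and_logged(self, rng):
        virus, scaffold, mags, bins = self._setup(rng)
        links, rejected = link_by_prophage(
            [virus], mags, bins, {scaffold.id: [TAX_Y] * 6},
            ani_fn=fixed_ani({("v0", scaffold.id): (99.0, 1.0)}),
        )
        assert links == []
        assert rejected[0]["reason"] == "taxonomy_inconsistent"

    def test_missing_bin_taxonomy_is_an_error(self, rng):
        virus, scaffold, mags, _ = self._setup(rng)
        with pytest.raises(ValueError, match="missing from bin taxonomy"):
            link_by_prophage([virus], mags, {}, {}, ani_fn=fixed_ani({}))


class TestDetectCrisprArrays:
    def _array(self, rng, repeat, spacers):
        return repeat + "".join(s + repeat for s in spacers)

    def test_planted_array_recovered_verbatim(self, rng):
        repeat = random_dna(rng, 28)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        seq = random_dna(rng, 4_000) + self._array(rng, repeat, spacers) + random_dna(rng, 4_000)
        (arr,) = detect_crispr_arrays([ContigRecord("s", seq)])
        assert arr.repeat == repeat
        assert arr.spacers == tuple(spacers)

    def test_two_repeat_copies_are_not_an_array(self, rng):
        repeat = random_dna(rng, 28)
        seq = random_dna(rng, 2_000) + repeat + random_dna(rng, 32) + repeat + random_dna(rng, 2_000)
        assert detect_crisp_free(seq) == []

    def test_oversized_spacer_splits_the_array(self, rng):
        repeat = random_dna(rng, 28)
        good = [random_dna(rng, 32) for _ in range(2)]
        seq = (
            random_dna(rng, 2_000)
            + self._array(rng, repeat, good)          # 3 repeats, 2 good spacers
            + random_dna(rng, 80)                     # oversized gap
            + repeat
            + random_dna(rng, 2_000)
        )
        arrays = detect_crispr_arrays([ContigRecord("s", seq)])
        assert all(all(18 <= len(sp) <= 72 for sp in a.spacers) for a in arrays)
        assert all(len(a.spacers) <= 2 for a in arrays)


def detect_crisp_free(seq):
    return detect_crispr_arrays([ContigRecord("s", seq)])


class TestLinkBySpacer:
    def _community(self, rng):
        virus = ContigRecord("v0", random_dna(rng, 15_000))
        spacer = virus.sequence[5_000:5_032]
        repeat = random_dna(rng, 28)
        mag_seq = (
            random_dna(rng, 3_000)
            + repeat + spacer + repeat + random_dna(rng, 32) + repeat
            + random_dna(rng, 3_000)
        )
        mags = {"mag00": [ContigRecord("mag00_s0", mag_seq)]}
        array = CrisprArray("mag00_s0", repeat, (spacer, random_dna(rng, 32)))
        return virus, spacer, repeat, mags, array

    def test_exact_spacer_and_repeat_link(self, rng):
        virus, spacer, repeat, mags, array = self._community(rng)
        (link,) = link_by_spacer([array], mags, [virus])
        assert (link.virus_id, link.mag_id, link.method_rank) == ("v0", "mag00", 2)
        assert link.n_spacers == 1 and link.spacers == (spacer,)

    def test_single_mismatch_spacer_yields_no_link(self, rng):
        virus, spacer, repeat, mags, _ = self._community(rng)
        bad = "ACGT".replace(spacer[10], "")[0]
        decoy = spacer[:10] + bad + spacer[11:]
        array = CrisprArray("mag00_s0", repeat, (decoy,))
        assert link_by_spacer([array], mags, [virus]) == []

    def test_repeat_absent_from_all_mags_yields_no_link(self, rng):
        virus, spacer, _, mags, _ = self._community(rng)
        array = CrisprArray("x", random_dna(rng, 28), (spacer,))
        assert link_by_spacer([array], mags, [virus]) == []

    def test_short_repeat_fails_evalue_stand_in(self, rng):
        virus, spacer, _, mags, _ = self._community(rng)
        array = CrisprArray("x", random_dna(rng, 22), (spacer,))
        assert link_by_spacer([array], mags, [virus]) == []

    def test_strand_symmetric_in_the_virus(self, rng):
        virus, spacer, repeat, mags, array = self._community(rng)
        flipped = ContigRecord("v0", revcomp(virus.sequence))
        (fwd,) = link_by_spacer([array], mags, [virus])
        (rev,) = link_by_spacer([array], mags, [flipped])
        assert (fwd.virus_id, fwd.mag_id) == (rev.virus_id, rev.mag_id)


def protein(pid, seq):
    return ProteinRecord(pid, "v0", (0, 3 * len(seq)), "+", seq)


def _prot_seq(rng, n=80):
    return "M" + "".join(np.random.default_rng(rng.integers(1 << 30)).choice(
        list("ARNDCQEGHILKMFPSTWYV"), n - 1))


class TestAssignTaxonomyByAai:
    def _panel(self, rng, sequences, taxonomy):
        return [
            ReferenceProtein(f"ref{i}", s, taxonomy, genome_id=f"G_{taxonomy.genus}")
            for i, s in enumerate(sequences)
        ]

    def test_six_of_ten_matching_assigns_genus(self, rng):
        shared = [_prot_seq(rng) for _ in range(6)]
        own = [_prot_seq(rng) for _ in range(4)]
        virus_prots = [protein(f"p{i}", s) for i, s in enumerate(shared + own)]
        panel = self._panel(rng, shared, TAX_X)
        tax, fraction = assign_taxonomy_by_aai(virus_prots, panel)
        assert tax.genus == "GenX"
        assert fraction == pytest.approx(0.6)

    def test_four_of_ten_is_below_the_floor(self, rng):
        shared = [_prot_seq(rng) for _ in range(4)]
        own = [_prot_seq(rng) for _ in range(6)]
        virus_prots = [protein(f"p{i}", s) for i, s in enumerate(shared + own)]
        assert assign_taxonomy_by_aai(virus_prots, self._panel(rng, shared, TAX_X)) is None

    def test_five_five_tie_assigns_nothing(self, rng):
        to_x = [_prot_seq(rng) for _ in range(5)]
        to_y = [_prot_seq(rng) for _ in range(5)]
        virus_prots = [protein(f"p{i}", s) for i, s in enumerate(to_x + to_y)]
        panel = self._panel(rng, to_x, TAX_X) + self._panel(rng, to_y, TAX_Y)
        assert assign_taxonomy_by_aai(virus_prots, panel) is None

    def test_no_proteins_is_an_error(self):
        with pytest.raises(ValueError, match="no predicted proteins"):
            assign_taxonomy_by_aai([], [])


class TestLinkByReferenceAni:
    def test_best_reference_meeting_thresholds_wins(self, rng):
        virus = ContigRecord("v0", random_dna(rng, 15_000))
        refs = [
            (ContigRecord("refA", random_dna(rng, 15_000)), TAX_X),
            (ContigRecord("refB", random_dna(rng, 15_000)), TAX_Y),
        ]
        table = {("v0", "refA"): (97.0, 0.8), ("v0", "refB"): (96.0, 0.6)}
        (link,) = link_by_reference_ani([virus], refs, ani_fn=fixed_ani(table))
        assert link.method_rank == 4
        assert link.taxonomy == TAX_X

    def test_coverage_below_half_rejected(self, rng):
        virus = ContigRecord("v0", random_dna(rng, 15_000))
        refs = [(ContigRecord("refA", random_dna(rng, 15_000)), TAX_X)]
        links = link_by_reference_ani(
            [virus], refs, ani_fn=fixed_ani({("v0", "refA"): (97.0, 0.3)})
        )
        assert links == []


class TestMergeHostLinks:
    def test_lowest_rank_wins(self):
        l1 = HostLink("v0", "mag00", TAX_X, 1, identity=98.0, coverage=0.9)
        l3 = HostLink("v0", None, TAX_Y, 3, protein_fraction=0.8)
        merged, discarded, ambiguous = merge_host_links([l3, l1])
        assert merged["v0"] is l1
        assert discarded == [l3]
        assert ambiguous == set()

    def test_only_rank_three_kept(self):
        l3 = HostLink("v0", None, TAX_Y, 3, protein_fraction=0.8)
        merged, _, _ = merge_host_links([l3])
        assert merged["v0"] is l3

    def test_equal_evidence_conflicting_hosts_flag_ambiguous(self):
        a = HostLink("v0", "mag00", None, 2, identity=100.0, n_spacers=1, spacers=("AA",))
        b = HostLink("v0", "mag01", None, 2, identity=100.0, n_spacers=1, spacers=("AA",))
        merged, _, ambiguous = merge_host_links([a, b])
        assert "v0" not in merged
        assert ambiguous == {"v0"}

    def test_more_spacers_break_rank2_ties(self):
        a = HostLink("v0", "mag00", None, 2, identity=100.0, n_spacers=2, spacers=("A", "C"))
        b = HostLink("v0", "mag01", None, 2, identity=100.0, n_spacers=1, spacers=("A",))
        merged, _, _ = merge_host_links([a, b])
        assert merged["v0"].mag_id == "mag00"

    def test_invariant_to_input_order(self):
        links = [
            HostLink("v0", "mag00", TAX_X, 1, identity=96.0, coverage=0.7),
            HostLink("v0", "mag01", None, 2, identity=100.0, n_spacers=1),
            HostLink("v1", None, TAX_Y, 4, identity=95.5, coverage=0.9),
        ]
        base = merge_host_links(links)[0]
        for perm in ([2, 1, 0], [1, 2, 0], [2, 0, 1]):
            assert merge_host_links([links[i] for i in perm])[0] == base


class TestFlagNovelty:
    def test_strong_panel_match_is_not_novel(self, rng):
        shared = [_prot_seq(rng) for _ in range(8)]
        own = [_prot_seq(rng) for _ in range(2)]
        prots = [protein(f"p{i}", s) for i, s in enumerate(shared + own)]
        panel = [ReferenceProtein(f"r{i}", s, None, genome_id="genomeA")
                 for i, s in enumerate(shared)]
        assert flag_novelty(prots, [panel]) is False

    def test_no_match_anywhere_is_novel(self, rng):
        prots = [protein(f"p{i}", _prot_seq(rng)) for i in range(4)]
        panel = [ReferenceProtein("r", _prot_seq(rng), None, genome_id="genomeB")]
        assert flag_novelty(prots, [panel]) is True

    def test_empty_panel_is_novel_with_warning(self, rng, caplog):
        prots = [protein("p0", _prot_seq(rng))]
        with caplog.at_level(logging.WARNING):
            assert flag_novelty(prots, []) is True
        assert "empty reference panel" in caplog.text
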
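import numpy as np
import pytest

from phageflux.io import ContigRecord
from phageflux.curation import (
    DetectorCall,
    EvidenceBundle,
    MarkerHit,
    classify_viral_contigs,
    dereplicate,
    detect_chimera,
    detect_circularity,
    screen_ribosomal,
)

from conftest import mutate, random_dna


def bundle(cid, calls=(), markers=()):
    return EvidenceBundle(cid, list(calls), list(markers))


def contig(rng, cid="c0", n=12_000):
    return ContigRecord(cid, random_dna(rng, n))


class TestClassifyViralContigs:
    def test_both_detectors_viral_retained(self, rng):
        c = contig(rng)
        retained, reasons = classify_viral_contigs(
            [c],
            {c.id: bundle(c.id, [DetectorCall("A", "viral"), DetectorCall("B", "viral")])},
        )
        assert retained == [c]
        assert reasons[c.id] == "both_detectors"

    @pytest.mark.parametrize("bit,kept", [(35.0, True), (30.0, True), (29.0, False)])
    def test_single_detector_needs_marker_at_30_bits(self, rng, bit, kept):
        c = contig(rng)
        ev = bundle(
            c.id,
            [DetectorCall("A", "viral")],
            [MarkerHit("Terminase_large", "phage_structural", bit)],
        )
        retained, reasons = classify_viral_contigs([c], {c.id: ev})
        assert (len(retained) == 1) is kept
        if kept:
            assert reasons[c.id] == "detector_plus_marker"

    def test_eukaryotic_marker_alone_retains(self, rng):
        c = contig(rng)
        ev = bundle(c.id, [], [MarkerHit("NCLDV_capsid", "eukaryotic_virus_marker", 31.0)])
        retained, reasons = classify_viral_contigs([c], {c.id: ev})
        assert retained == [c]
        assert reasons[c.id] == "eukaryotic_marker"

    def test_no_evidence_not_retained(self, rng):
        c = contig(rng)
        retained, _ = classify_viral_contigs([c], {c.id: bundle(c.id)})
        assert retained == []

    def test_both_detectors_takes_precedence_over_marker_reason(self, rng):
        c = contig(rng)
        ev = bundle(
            c.id,
            [DetectorCall("A", "viral"), DetectorCall("B", "viral")],
            [MarkerHit("Phage_capsid", "phage_structural", 60.0)],
        )
        _, reasons = classify_viral_contigs([c], {c.id: ev})
        assert reasons[c.id] == "both_detectors"

    def test_removing_euk_evidence_never_changes_other_outcomes(self, rng):
        c = contig(rng)
        ev_full = bundle(
            c.id,
            [DetectorCall("A", "viral"), DetectorCall("B", "viral")],
            [MarkerHit("Pox_protein", "eukaryotic_virus_marker", 50.0)],
        )
        ev_stripped = bundle(c.id, ev_full.detector_calls, [])
        _, r1 = classify_viral_contigs([c], {c.id: ev_full})
        _, r2 = classify_viral_contigs([c], {c.id: ev_stripped})
        assert r1[c.id] == r2[c.id] == "both_detectors"

    def test_shorter_prophage_interval_replaces_contig(self, rng):
        c = contig(rng, n=20_000)
        ev = bundle(
            c.id,
            [
                DetectorCall("A", "prophage", (2_000, 18_000)),
                DetectorCall("B", "prophage", (3_000, 15_000)),
            ],
        )
        (trimmed,), _ = classify_viral_contigs([c], {c.id: ev})
        assert trimmed.sequence == c.sequence[3_000:15_000]
        assert trimmed.id == c.id

    def test_unknown_contig_in_evidence_is_an_error(self, rng):
        c = contig(rng)
        with pytest.raises(ValueError, match="unknown contig"):
            classify_viral_contigs([c], {"ghost": bundle("ghost")})


def fixed_ani(table):
    """ani_fn stub driven by (candidate_id, representative_id) pairs."""

    def fn(cand, rep):
        return table.get((cand.id, rep.id), (0.0, 0.0))

    return fn


class TestDereplicate:
    def test_identical_contigs_form_one_population(self, rng):
        seq = random_dna(rng, 20_000)
        pops = dereplicate([ContigRecord("a", seq), ContigRecord("b", seq)])
        assert len(pops) == 1
        assert pops[0].representative_id == "a"  # tie broken by id
        assert sorted(pops[0].member_ids) == ["a", "b"]

    def test_ten_percent_divergence_separates(self, rng):
        a = ContigRecord("a", random_dna(rng, 20_000))
        b = ContigRecord("b", mutate(rng, a.sequence, 0.10))
        assert len(dereplicate([a, b])) == 2

    def test_short_member_survives_inside_long_cluster(self, rng):
        a = ContigRecord("a", random_dna(rng, 20_000))
        member = ContigRecord("m", mutate(rng, a.sequence[:8_000], 0.01))
        lone = ContigRecord("z", random_dna(rng, 8_000))
        pops = dereplicate([a, member, lone])
        assert len(pops) == 1
        assert sorted(pops[0].member_ids) == ["a", "m"]

    @pytest.mark.parametrize(
        "ani,cov,merged",
        [(95.0, 0.5, True), (94.9, 0.5, False), (95.0, 0.499, False), (96.0, 0.6, True)],
    )
    def test_ani_and_coverage_boundaries(self, rng, ani, cov, merged):
        a = contig(rng, "a", 20_000)
        b = contig(rng, "b", 15_000)
        pops = dereplicate([a, b], ani_fn=fixed_ani({("b", "a"): (ani, cov)}))
        assert (len(pops) == 1) is merged

    def test_min_length_applied_to_representatives(self, rng):
        kept = contig(rng, "a", 10_000)
        dropped = contig(rng, "b", 9_999)
        pops = dereplicate([kept, dropped], ani_fn=fixed_ani({}))
        assert [p.representative_id for p in pops] == ["a"]

    def test_idempotent_on_representatives(self, rng):
        contigs = [contig(rng, f"c{i}", 12_000 + 500 * i) for i in range(4)]
        pops = dereplicate(contigs)
        reps = [c for c in contigs if c.id in {p.representative_id for p in pops}]
        again = dereplicate(reps)
        assert {p.representative_id for p in again} == {p.representative_id for p in pops}
        assert all(len(p.member_ids) == 1 for p in again)

    def test_order_invariance(self, rng):
        contigs = [contig(rng, f"c{i}", 11_000 + 997 * i) for i in range(5)]
        contigs.append(ContigRecord("dup", mutate(rng, contigs[2].sequence, 0.02)))
        expected = {
            p.representative_id: sorted(p.member_ids) for p in dereplicate(contigs)
        }
        shuffled = list(contigs)
        np.random.default_rng(3).shuffle(shuffled)
        observed = {
            p.representative_id: sorted(p.member_ids) for p in dereplicate(shuffled)
        }
        assert observed == expected


class TestDetectCircularity:
    def test_terminal_30bp_repeat_detected(self, rng):
        r = random_dna(rng, 30)
        g = ContigRecord("g", r + random_dna(rng, 20_000) + r)
        dtr = detect_circularity(g)
        assert dtr == ((0, 30), (20_030, 20_060))

    def test_19bp_repeat_below_minimum(self, rng):
        r = random_dna(rng, 19)
        g = ContigRecord("g", r + random_dna(rng, 20_000) + r)
        assert detect_circularity(g) is None

    def test_repeat_ending_250bp_from_end_rejected(self, rng):
        r = random_dna(rng, 30)
        g = ContigRecord("g", r + random_dna(rng, 20_000) + r + random_dna(rng, 250))
        assert detect_circularity(g) is None

    def test_planted_dtr_library_sensitivity_and_specificity(self):
        rng = np.random.default_rng(77)
        fp = fn = 0
        for i in range(200):
            d = int(rng.integers(20, 400))
            core = random_dna(rng, 3_000)
            r = random_dna(rng, d)
            if detect_circularity(ContigRecord(f"pos{i}", r + core + r)) is None:
                fn += 1
            if detect_circularity(ContigRecord(f"neg{i}", random_dna(rng, 3_000 + 2 * d))) is not None:
                fp += 1
        assert fn == 0  # sensitivity 1.0
        assert fp / 200 <= 0.005  # specificity >= 0.995


class TestDetectChimera:
    def _with_duplication(self, rng, block_len):
        base = random_dna(rng, 25_000)
        block = base[1_000 : 1_000 + block_len]
        # force mismatching joints so the repeat is exactly block_len
        joint = {"A": "C", "C": "G", "G": "T", "T": "A"}
        left = joint[block[-1]]
        seq = base[:18_000] + left + block + base[18_000:]
        return ContigRecord("chim", seq)

    def test_6kb_duplication_flags_chimera(self, rng):
        assert detect_chimera(self._with_duplication(rng, 6_000)) is True

    def test_4kb_duplication_below_bound(self, rng):
        assert detect_chimera(self._with_duplication(rng, 4_000)) is False

    def test_random_contig_is_clean(self, rng):
        assert detect_chimera(ContigRecord("r", random_dna(rng, 30_000))) is False


class TestScreenRibosomal:
    def test_s21_is_exempt(self):
        hits = [MarkerHit("Ribosomal_S21", "ribosomal", 45.0)]
        assert screen_ribosomal(hits) == []

    def test_other_ribosomal_protein_is_a_violation(self):
        hits = [MarkerHit("Ribosomal_L4", "ribosomal", 40.0)]
        assert [h.domain for h in screen_ribosomal(hits)] == ["Ribosomal_L4"]

    def test_no_ribosomal_hits_passes(self):
        hits = [MarkerHit("Phage_capsid", "phage_structural", 60.0)]
        assert screen_ribosomal(hits) == []
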
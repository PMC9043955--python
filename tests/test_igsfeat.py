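"""Spacer features: GC, identity, duplications, motifs, SV typing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribomine5s import (SimilarityOptions, cds_divergence, classify_sv,
                        find_tandem_duplication, gc_content,
                        pairwise_identity, scan_promoter_motifs,
                        similarity_range, sv_label)
from ribomine5s._util import random_seq, revcomp
from ribomine5s.igsfeat import load_default_signatures

RNG = np.random.default_rng(41)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGC:
    def test_extremes(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("ATAT") == 0.0

    def test_n_excluded_both_sides(self):
        assert gc_content("GCNNAT") == 50.0

    def test_all_n_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dna)
    def test_invariant_under_reverse_complement(self, s):
        assert gc_content(s) == pytest.approx(gc_content(revcomp(s)))


def _brute_force_best_alignments(a, b, opts):
    """Enumerate every global alignment of two short strings; return the
    optimal score and the identity values of all optimal alignments."""
    results = []

    def rec(i, j, cols, score, in_gap):
        if i == len(a) and j == len(b):
            matches = sum(1 for x, y in cols if x == y and x != "-")
            results.append((score, 100.0 * matches / len(cols)))
            return
        if i < len(a) and j < len(b):
            s = opts.match if a[i] == b[j] else opts.mismatch
            rec(i + 1, j + 1, cols + [(a[i], b[j])], score + s, None)
        if i < len(a):
            s = opts.gap_extend if in_gap == "a" else opts.gap_open
            rec(i + 1, j, cols + [(a[i], "-")], score + s, "a")
        if j < len(b):
            s = opts.gap_extend if in_gap == "b" else opts.gap_open
            rec(i, j + 1, cols + [("-", b[j])], score + s, "b")

    rec(0, 0, [], 0.0, None)
    best = max(s for s, _ in results)
    return best, {round(ident, 6) for s, ident in results
                  if s == pytest.approx(best)}


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_long_deletion_masked_vs_unmasked(self):
        a = random_seq(np.random.default_rng(5), 80)
        b = a[:30] + a[40:]  # 10-bp deletion
        masked = pairwise_identity(a, b, SimilarityOptions(
            mask_long_indels=True))
        unmasked = pairwise_identity(a, b, SimilarityOptions())
        assert masked == 100.0
        assert unmasked < 100.0

    @pytest.mark.parametrize("a,b", [("ACGT", "TGCA"), ("AAAC", "AC"),
                                     ("GATT", "GTT"), ("ACG", "CGT")])
    def test_matches_exhaustive_alignment_enumeration(self, a, b):
        opts = SimilarityOptions()
        best, idents = _brute_force_best_alignments(a, b, opts)
        got = pairwise_identity(a, b, opts)
        assert round(got, 6) in idents

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_symmetry_and_self_identity(self, a, b):
        opts = SimilarityOptions()
        assert pairwise_identity(a, a, opts) == 100.0
        assert pairwise_identity(a, b, opts) == \
            pytest.approx(pairwise_identity(b, a, opts))


class TestSimilarityRange:
    def test_two_identical(self):
        assert similarity_range(["ACGT", "ACGT"]) == (100.0, 100.0)

    def test_three_sequences_match_brute_force_over_pairs(self):
        seqs = [random_seq(np.random.default_rng(s), 50) for s in (1, 2, 3)]
        lo, hi = similarity_range(seqs)
        pairs = [pairwise_identity(a, b)
                 for a, b in itertools.combinations(seqs, 2)]
        assert (lo, hi) == (min(pairs), max(pairs))

    def test_single_sequence_is_undefined(self):
        assert similarity_range(["ACGT"]) is None


class TestDuplication:
    def test_exact_tandem_repeat(self):
        x = random_seq(np.random.default_rng(6), 50)
        call = find_tandem_duplication("A" * 20 + x + x + "C" * 20, min_unit=30)
        assert call.unit_length == 50
        assert call.n_copies == 2
        assert call.snps_between_copies == 0
        assert call.indels_between_copies == []

    def test_two_snps_between_copies(self):
        x = random_seq(np.random.default_rng(7), 60)
        x2 = list(x)
        for p in (20, 40):
            x2[p] = "A" if x[p] != "A" else "G"
        seq = random_seq(np.random.default_rng(8), 30) + x + "".join(x2)
        call = find_tandem_duplication(seq, min_unit=30)
        assert call.unit_length == 60
        assert call.snps_between_copies == 2

    def test_eggplant_style_anatomy(self):
        """A duplication spanning the CDS 3' end: 146-bp unit = 32 bp of
        coding region + 114 bp of spacer; copies diverge by 6 SNPs and one
        8-bp indel, all in the spacer-derived part."""
        rng = np.random.default_rng(42)
        cds = random_seq(rng, 120, 0.55)
        w = random_seq(rng, 114)
        x = cds[88:] + w
        chars = list(x)
        for p in (36, 45, 80, 95, 110, 130):
            chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
        x2 = "".join(chars[:60] + chars[68:])  # 8-bp deletion
        unit = cds + w + x2 + random_seq(rng, 100)
        call = find_tandem_duplication(unit, cds_length=120)
        assert call.unit_length == 146
        assert call.snps_between_copies == 6
        assert call.indels_between_copies == [8]
        assert call.cds_derived_length == 32
        assert call.igs_derived_length == 114
        assert call.copy_spans[0] == (88, 234)

    def test_triplicated_segment_counts_three_copies(self):
        x = random_seq(np.random.default_rng(9), 40)
        call = find_tandem_duplication("T" * 25 + x * 3 + "A" * 25,
                                       min_unit=30)
        assert call.n_copies == 3

    def test_no_repeat_returns_none_with_brute_force_oracle(self):
        for seed in (10, 11, 12):
            s = random_seq(np.random.default_rng(seed), 200)
            # oracle: no two adjacent >=30 bp windows nearly identical
            has_repeat = False
            for u in range(30, 100):
                for p in range(0, len(s) - 2 * u + 1):
                    d = sum(1 for a, b in zip(s[p:p + u], s[p + u:p + 2 * u])
                            if a != b)
                    if d / u <= 0.2:
                        has_repeat = True
            assert not has_repeat
            assert find_tandem_duplication(s, min_unit=30) is None

    def test_dispersed_repeat_is_not_tandem(self):
        x = random_seq(np.random.default_rng(13), 50)
        gap = random_seq(np.random.default_rng(14), 40)
        assert find_tandem_duplication("A" * 10 + x + gap + x + "C" * 10,
                                       min_unit=30) is None


class TestMotifs:
    def _planted_igs(self, seed=15):
        rng = np.random.default_rng(seed)
        igs = list(random_seq(rng, 210))

        def put(s, off):
            start = 210 + off if off < 0 else off
            igs[start:start + len(s)] = list(s)

        put("TTTTT", 2)
        put("TTTAATA", -30)
        put("GC", -14)
        put("GC", -12)
        put("GA", -3)
        igs[209] = "C"
        return "".join(igs)

    def test_planted_motifs_found_at_planted_offsets(self):
        hits = {h.name: h for h in scan_promoter_motifs(self._planted_igs())}
        expect = {"TATA_box": -30, "GC_minus12": -12, "GC_minus14": -14,
                  "GA_minus3": -3, "pyrimidine_minus1": -1,
                  "terminator_oligoT": 2}
        for name, off in expect.items():
            assert hits[name].found, name
            assert hits[name].offset == off
            assert hits[name].mismatches == 0

    def test_absent_motifs_verified_by_exhaustive_window_scan(self):
        rng = np.random.default_rng(16)
        while True:  # draw an IGS with no TATA-like box anywhere near -30
            igs = random_seq(rng, 210)
            window_hits = [
                off for off in range(-35, -24)
                if sum(1 for a, b in zip(igs[210 + off:210 + off + 7],
                                         "TTTAATA") if a != b) <= 1
            ]
            if not window_hits:
                break
        hit = {h.name: h for h in scan_promoter_motifs(igs)}["TATA_box"]
        assert not hit.found

    def test_short_igs_reports_reason(self):
        hit = {h.name: h for h in scan_promoter_motifs("ACGTACGTAC")}
        assert not hit["TATA_box"].found
        assert "shorter" in hit["TATA_box"].reason


class TestCdsDivergence:
    def test_self_and_two_snps(self):
        cds = random_seq(np.random.default_rng(17), 120, 0.55)
        assert cds_divergence(cds, cds) == (0, [])
        chars = list(cds)
        for p in (30, 60):
            chars[p] = "A" if cds[p] != "A" else "G"
        subs, indels = cds_divergence("".join(chars), cds)
        assert subs == 2 and indels == []


class TestStructuralVariants:
    def test_decision_table_enumerates_all_combinations(self):
        table = {
            (True, True, False): "A", (True, True, True): "A",
            (True, False, False): "B", (True, False, True): "B",
            (False, True, False): "C", (False, True, True): "D",
            (False, False, False): "unclassified",
            (False, False, True): "unclassified",
        }
        for (i1, i2, gc), label in table.items():
            assert sv_label({"indel_I": i1, "indel_II": i2,
                             "GC_DUP": gc}) == label

    def test_packaged_examples_classify_to_their_labels(self):
        sigs, rows = load_default_signatures()
        for name, row in rows.items():
            if name == "master":
                continue
            call = classify_sv(row.replace("-", ""), sigs)
            assert call.label == name[2], name

    def test_unrelated_sequence_is_rejected(self):
        with pytest.raises(ValueError, match="Petota"):
            classify_sv("A" * 200)
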
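"""Semi-global aligner, variant extraction and allele classification."""

from ampliplate.align import (
    AlleleClass,
    Scoring,
    TargetLocus,
    Variant,
    align_fragment,
    align_semiglobal,
    apply_variants,
    classify_allele,
    extract_variants,
    left_align,
    validate_amplicon_design,
)
from ampliplate.merge import revcomp

from conftest import random_dna
from oracles import (
    oracle_leftmost_deletion,
    oracle_leftmost_insertion,
    oracle_semiglobal_score,
)


class TestAlignSemiglobal:
    def test_identity(self):
        ref = "ACGTACGTGG"
        a = align_semiglobal(ref, ref)
        assert a.operations == (("match", len(ref)),)
        assert a.score == len(ref)
        assert (a.ref_start, a.ref_end) == (0, len(ref))

    def test_single_deletion_left_aligned(self, toy_locus):
        a = align_semiglobal("ACGACGT", "ACGTACGT")
        assert a.score == 7 - 5
        ops = dict(a.operations)
        assert ops.get("deletion") == 1
        locus = TargetLocus("t", "c", 0, 8, "ACGTACGT")
        (v,) = extract_variants(a, locus)
        assert (v.kind, v.amplicon_position) == ("deletion", 3)

    def test_single_substitution(self, rng):
        ref = random_dna(rng, 60)
        q = ref[:25] + "ACGT"[("ACGT".index(ref[25]) + 2) % 4] + ref[26:]
        a = align_semiglobal(q, ref)
        locus = TargetLocus("t", "c", 0, 60, ref)
        (v,) = extract_variants(a, locus)
        assert (v.kind, v.amplicon_position, v.ref_allele) == ("substitution", 25, ref[25])

    def test_truncated_fragment_uses_free_end_gaps(self, rng):
        ref = random_dna(rng, 80)
        a = align_semiglobal(ref[20:65], ref)
        assert a.score == 45
        assert (a.ref_start, a.ref_end) == (20, 65)
        assert a.operations == (("match", 45),)

    def test_matches_exhaustive_dp_on_1000_random_instances(self, rng):
        """The kernel's score equals an independently written exhaustive
        affine DP on every short random instance, for two scoring sets."""
        scorings = [Scoring(), Scoring(match=2, mismatch=-3, gap_open=-4, gap_extend=-2)]
        for trial in range(1000):
            sc = scorings[trial % 2]
            n = int(rng.integers(1, 13))
            m = int(rng.integers(1, 13))
            ref = random_dna(rng, n)
            # half the instances are mutated copies to exercise near-matches
            if trial % 3 == 0:
                q = list(ref)
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(0, len(q)))
                    q[p] = "ACGT"[int(rng.integers(0, 4))]
                qry = "".join(q)[:m] or "A"
            else:
                qry = random_dna(rng, m)
            got = align_semiglobal(qry, ref, sc).score
            want = oracle_semiglobal_score(
                ref, qry, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
            )
            assert got == want, (ref, qry, sc)

    def test_one_bp_indel_outscores_two_substitutions(self):
        # deletion representation: n-1 matches and a 1-bp gap
        ref = "ACGTTTACGTA"
        q = "ACGTTACGTA"
        a = align_semiglobal(q, ref)
        assert dict(a.operations).get("deletion") == 1
        assert a.score == 10 * 1 - 5

    def test_reverse_complement_fragment_recovered(self, toy_locus):
        a = align_fragment(revcomp(toy_locus.reference_amplicon), toy_locus)
        assert a.strand == "-"
        assert a.operations == (("match", len(toy_locus.reference_amplicon)),)


class TestVariants:
    def test_identity_has_no_variants(self, toy_locus):
        a = align_semiglobal(toy_locus.reference_amplicon, toy_locus.reference_amplicon)
        assert extract_variants(a, toy_locus) == []

    def test_homopolymer_deletion_reported_leftmost(self, toy_locus):
        ref = toy_locus.reference_amplicon  # has AAAA at 8..11
        q = ref[:10] + ref[11:]  # delete one A from inside the run
        a = align_semiglobal(q, ref)
        (v,) = extract_variants(a, toy_locus)
        assert v.kind == "deletion"
        assert v.amplicon_position == oracle_leftmost_deletion(ref, 10, 1) == 8
        assert v.roi_labels == ("gRNA",)

    def test_insertion_left_alignment_matches_placement_enumeration(self, rng):
        for _ in range(200):
            ref = random_dna(rng, 30)
            pos = int(rng.integers(1, 29))
            ins = random_dna(rng, int(rng.integers(1, 4)))
            v = left_align(Variant(pos, "insertion", "", ins), ref)
            want_pos, want_ins = oracle_leftmost_insertion(ref, pos, ins)
            assert (v.amplicon_position, v.alt_allele) == (want_pos, want_ins)
            # equivalence preserved
            assert apply_variants(ref, [v]) == ref[:pos] + ins + ref[pos:]

    def test_left_align_idempotent(self, rng):
        for _ in range(100):
            ref = random_dna(rng, 25)
            pos = int(rng.integers(1, 20))
            v = Variant(pos, "deletion", ref[pos : pos + 2], "")
            once = left_align(v, ref)
            assert left_align(once, ref) == once

    def test_roi_deletion_tagged(self, toy_locus):
        ref = toy_locus.reference_amplicon
        q = ref[:14] + ref[17:]  # 3 bp deletion inside the gRNA region
        a = align_semiglobal(q, ref)
        (v,) = extract_variants(a, toy_locus)
        assert v.kind == "deletion" and "gRNA" in v.roi_labels


class TestClassifyAllele:
    def test_rule_table_exhaustive(self, toy_locus):
        """All eight combinations of donor-match x indel x extra substitution."""
        donor = Variant(12, "substitution", "C", "T")
        extra = Variant(2, "substitution", "G", "A")
        indel = Variant(25, "deletion", toy_locus.reference_amplicon[25:27], "")
        expected = {
            (0, 0, 0): AlleleClass.WT,
            (1, 0, 0): AlleleClass.HDR,
            (0, 1, 0): AlleleClass.NHEJ_INDEL,
            (0, 0, 1): AlleleClass.SUBSTITUTION_ONLY,
            (1, 1, 0): AlleleClass.COMPLEX,
            (1, 0, 1): AlleleClass.COMPLEX,
            (0, 1, 1): AlleleClass.NHEJ_INDEL,
            (1, 1, 1): AlleleClass.COMPLEX,
        }
        for (d, i, s), want in expected.items():
            variants = []
            if d:
                variants.append(donor)
            if i:
                variants.append(indel)
            if s:
                variants.append(extra)
            assert classify_allele(variants, toy_locus) is want, (d, i, s)

    def test_every_variant_list_gets_exactly_one_class(self, toy_locus, rng):
        kinds = ["substitution", "insertion", "deletion"]
        for _ in range(50):
            variants = []
            for _ in range(int(rng.integers(0, 4))):
                kind = kinds[int(rng.integers(0, 3))]
                pos = int(rng.integers(0, 30))
                ref = toy_locus.reference_amplicon
                if kind == "substitution":
                    variants.append(
                        Variant(pos, kind, ref[pos], "ACGT"[int(rng.integers(0, 4))])
                    )
                elif kind == "deletion":
                    variants.append(Variant(pos, kind, ref[pos : pos + 2], ""))
                else:
                    variants.append(Variant(pos, kind, "", random_dna(rng, 2)))
            assert classify_allele(variants, toy_locus) in AlleleClass

    def test_no_donor_never_yields_hdr(self):
        locus = TargetLocus("t", "c", 0, 10, "ACGTACGTAA")
        v = [Variant(3, "substitution", "T", "G")]
        assert classify_allele(v, locus) is AlleleClass.SUBSTITUTION_ONLY

    def test_donor_edit_detected_despite_adjacent_indel_representation(self, toy_locus):
        """An insertion next to the donor base can be aligned in a way that
        hides the donor substitution; classification must still see it."""
        ref = toy_locus.reference_amplicon
        allele = apply_variants(
            ref,
            [
                Variant(12, "substitution", "C", "T"),  # the donor edit
                Variant(13, "insertion", "", "CG"),
            ],
        )
        a = align_semiglobal(allele, ref)
        variants = extract_variants(a, toy_locus)
        assert classify_allele(variants, toy_locus) is AlleleClass.COMPLEX


class TestDesignValidation:
    def _warnings(self, notes):
        return [n for n in notes if n.level == "warning"]

    def test_recommended_design_has_no_warnings(self):
        notes = validate_amplicon_design(0, 350, 175, 350, heterozygous_snp_declared=True)
        assert self._warnings(notes) == []

    def test_over_length_product_warned(self):
        notes = validate_amplicon_design(0, 450, 225, 450, heterozygous_snp_declared=True)
        assert any("above 400" in n.message for n in self._warnings(notes))

    def test_primer_on_edit_site_warned(self):
        notes = validate_amplicon_design(0, 350, 0, 350, heterozygous_snp_declared=True)
        assert any("<150" in n.message for n in self._warnings(notes))

    def test_false_homozygote_note_without_het_snp(self):
        notes = validate_amplicon_design(0, 350, 175, 350)
        assert any(n.level == "note" and "homozygote" in n.message for n in notes)
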
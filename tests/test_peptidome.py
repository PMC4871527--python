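import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoburden.errors import (
    CoordinateError,
    FormatError,
    ParameterError,
    ReferenceMismatchError,
    UnresolvableVariantError,
)
from neoburden.peptidome import (
    MutantProteinContext,
    apply_mutation,
    design_vaccine_peptide,
    enumerate_class1_windows,
    translate_frameshift,
)
from neoburden.records import ProteinRecord, VariantClass

from conftest import make_mutation

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_windows(mut_seq, novel, lengths=(8, 9, 10, 11)):
    """Independent oracle: every substring of each length that covers a
    novel position."""
    out = []
    for length in sorted(lengths):
        for start in range(1, len(mut_seq) - length + 2):
            if any(start <= q <= start + length - 1 for q in novel):
                out.append((length, start, mut_seq[start - 1 : start - 1 + length]))
    return out


class TestApplyMutation:
    def test_missense_substitution(self):
        protein = ProteinRecord(
            protein_id="bat1a", gene="Bat1a",
            sequence="MSFSGFFVVPSPSSSVGNAKLVERTQHWDMI",
        )
        ctx = apply_mutation(
            protein, make_mutation(position=4, ref_aa="S", alt_aa="P")
        )
        assert ctx.mut_sequence.startswith("MSFPGFFVV")
        assert ctx.novel_positions == (4,)
        assert len(ctx.mut_sequence) == len(ctx.wt_sequence)

    def test_reference_mismatch_cites_details(self, toy_protein):
        with pytest.raises(ReferenceMismatchError, match="P1.*position 5"):
            apply_mutation(
                toy_protein, make_mutation(position=5, ref_aa="W", alt_aa="V")
            )

    def test_no_novel_residue_classes_rejected(self, toy_protein):
        for vc in (VariantClass.SYNONYMOUS, VariantClass.NONSENSE):
            with pytest.raises(ParameterError, match="no novel"):
                apply_mutation(
                    toy_protein,
                    make_mutation(variant_class=vc, position=5, ref_aa="Y", alt_aa="Y"),
                )

    def test_position_out_of_range(self, toy_protein):
        with pytest.raises(CoordinateError):
            apply_mutation(
                toy_protein,
                make_mutation(position=len(toy_protein) + 1, ref_aa="A", alt_aa="V"),
            )

    def test_frameshift_with_precomputed_tail(self):
        wt = "A" * 20 + "SITLSKGDSDNSSS" + "QKLME"
        protein = ProteinRecord(protein_id="mtdh", gene="Mtdh", sequence=wt)
        mutation = make_mutation(
            variant_class=VariantClass.FRAMESHIFT,
            position=35,
            ref_aa="Q",
            alt_aa="HVTRHRQAQVKC",
        )
        ctx = apply_mutation(protein, mutation)
        assert ctx.mut_sequence.endswith("SITLSKGDSDNSSSHVTRHRQAQVKC")
        assert ctx.novel_positions == tuple(range(35, 47))
        assert len(ctx.novel_positions) == 12

    def test_frameshift_without_tail_or_cds(self, toy_protein):
        mutation = make_mutation(
            variant_class=VariantClass.FRAMESHIFT, position=5, ref_aa="Y", alt_aa=""
        )
        with pytest.raises(UnresolvableVariantError):
            apply_mutation(toy_protein, mutation)

    def test_frameshift_tail_translated_from_cds(self):
        # protein MKT, cds ATG AAA ACC GGG TAA; 1-base deletion after codon 1
        # shifts to AAA CCG GGT AA -> from codon 2: ... read the shifted frame.
        protein = ProteinRecord(
            protein_id="p", gene="g", sequence="MKTG" + "A" * 26,
            cds="ATGAAAACCGGG" + "GCA" * 26 + "TAA",
        )
        mutation = make_mutation(
            variant_class=VariantClass.FRAMESHIFT,
            position=2,
            ref_aa="K",
            alt_aa="",
            annotations={"fs_indel": "del:1"},
        )
        ctx = apply_mutation(protein, mutation)
        assert ctx.mut_sequence.startswith("M")
        assert len(ctx.novel_positions) == len(ctx.mut_sequence) - 1

    def test_inframe_deletion_junction_flanks(self, toy_protein):
        ref = toy_protein.sequence[9:11]
        mutation = make_mutation(
            variant_class=VariantClass.INFRAME_INDEL,
            position=10,
            ref_aa=ref,
            alt_aa="",
        )
        ctx = apply_mutation(toy_protein, mutation)
        assert len(ctx.mut_sequence) == len(toy_protein) - 2
        assert ctx.novel_positions == (9, 10)

    def test_inframe_insertion_marks_inserted_plus_flanks(self, toy_protein):
        mutation = make_mutation(
            variant_class=VariantClass.INFRAME_INDEL,
            position=10,
            ref_aa="",
            alt_aa="WW",
        )
        ctx = apply_mutation(toy_protein, mutation)
        assert len(ctx.mut_sequence) == len(toy_protein) + 2
        assert ctx.novel_positions == (9, 10, 11, 12)

    @given(st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_missense_is_involution(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice(list(AA), size=40))
        pos = int(rng.integers(1, 41))
        ref = seq[pos - 1]
        alt = data.draw(st.sampled_from([a for a in AA if a != ref]))
        protein = ProteinRecord(protein_id="p", gene="g", sequence=seq)
        ctx = apply_mutation(
            protein, make_mutation(position=pos, ref_aa=ref, alt_aa=alt)
        )
        back = apply_mutation(
            ProteinRecord(protein_id="p", gene="g", sequence=ctx.mut_sequence),
            make_mutation(position=pos, ref_aa=alt, alt_aa=ref),
        )
        assert back.mut_sequence == seq


class TestEnumerateWindows:
    def _interior_ctx(self):
        seq = "".join(AA[i % 20] for i in range(41))
        mut = seq[:20] + ("W" if seq[20] != "W" else "Y") + seq[21:]
        return MutantProteinContext(
            protein_id="p", wt_sequence=seq, mut_sequence=mut, novel_positions=(21,)
        )

    def test_interior_missense_yields_38_windows(self):
        windows = enumerate_class1_windows(self._interior_ctx())
        assert len(windows) == 8 + 9 + 10 + 11 == 38

    def test_first_residue_missense_yields_4_windows(self):
        seq = "".join(AA[i % 20] for i in range(30))
        mut = "W" + seq[1:]
        ctx = MutantProteinContext(
            protein_id="p", wt_sequence=seq, mut_sequence=mut, novel_positions=(1,)
        )
        windows = enumerate_class1_windows(ctx)
        assert [(w.length, w.start) for w in windows] == [
            (8, 1), (9, 1), (10, 1), (11, 1)
        ]

    def test_windows_match_slices_and_cover_novel(self):
        ctx = self._interior_ctx()
        for w in enumerate_class1_windows(ctx):
            assert w.sequence == ctx.mut_sequence[w.start - 1 : w.end]
            assert w.start <= 21 <= w.end
            # every window differs from the same-coordinate wild-type slice
            assert w.sequence != ctx.wt_sequence[w.start - 1 : w.end]

    def test_sorted_and_unique(self):
        windows = enumerate_class1_windows(self._interior_ctx())
        keys = [(w.length, w.start) for w in windows]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)

    def test_length_outside_range_requires_override(self):
        ctx = self._interior_ctx()
        with pytest.raises(ParameterError, match="override"):
            enumerate_class1_windows(ctx, lengths=(7, 9))
        assert enumerate_class1_windows(
            ctx, lengths=(7,), allow_nonstandard_lengths=True
        )

    def test_agrees_with_brute_force_on_random_mutations(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            L = int(rng.integers(12, 80))
            seq = "".join(rng.choice(list(AA), size=L))
            pos = int(rng.integers(1, L + 1))
            alt = rng.choice([a for a in AA if a != seq[pos - 1]])
            mut = seq[: pos - 1] + alt + seq[pos:]
            ctx = MutantProteinContext(
                protein_id="p", wt_sequence=seq, mut_sequence=mut,
                novel_positions=(pos,),
            )
            got = [(w.length, w.start, w.sequence) for w in enumerate_class1_windows(ctx)]
            assert got == brute_force_windows(mut, [pos])

    def test_frameshift_tail_windows_match_brute_force(self):
        wt = "A" * 20 + "SITLSKGDSDNSSS" + "QKLME"
        protein = ProteinRecord(protein_id="p", gene="g", sequence=wt)
        ctx = apply_mutation(
            protein,
            make_mutation(
                variant_class=VariantClass.FRAMESHIFT,
                position=35,
                ref_aa="Q",
                alt_aa="HVTRHRQAQVKC",
            ),
        )
        got = [(w.length, w.start, w.sequence) for w in enumerate_class1_windows(ctx)]
        assert got == brute_force_windows(ctx.mut_sequence, ctx.novel_positions)


class TestVaccineDesign:
    def test_interior_missense_gives_29mer_with_central_mutation(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AA), size=60))
        pos = 30
        alt = "W" if seq[pos - 1] != "W" else "Y"
        protein = ProteinRecord(protein_id="p", gene="g", sequence=seq)
        ctx = apply_mutation(
            protein, make_mutation(position=pos, ref_aa=seq[pos - 1], alt_aa=alt)
        )
        peptide = design_vaccine_peptide(ctx)
        assert len(peptide) == 29
        assert peptide[14] == alt

    def test_length_formula_holds_near_termini(self):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(35))
        protein = ProteinRecord(protein_id="p", gene="g", sequence=seq)
        for pos in (1, 2, 4, 18, 33, 35):
            ref = seq[pos - 1]
            alt = "W" if ref != "W" else "Y"
            ctx = apply_mutation(
                protein, make_mutation(position=pos, ref_aa=ref, alt_aa=alt)
            )
            peptide = design_vaccine_peptide(ctx)
            expected = min(pos + 14, 35) - max(1, pos - 14) + 1
            assert len(peptide) == expected

    def test_long_novel_tail_truncated_with_warning(self):
        mut = "A" * 10 + "W" * 80
        ctx = MutantProteinContext(
            protein_id="p", wt_sequence="A" * 10, mut_sequence=mut,
            novel_positions=tuple(range(11, 91)),
        )
        with pytest.warns(UserWarning, match="truncated"):
            peptide = design_vaccine_peptide(ctx)
        assert len(peptide) == 10 + 50

    def test_empty_novel_set_rejected(self):
        ctx = MutantProteinContext(
            protein_id="p", wt_sequence="A" * 10, mut_sequence="A" * 9,
            novel_positions=(),
        )
        with pytest.raises(ParameterError):
            design_vaccine_peptide(ctx)


class TestTranslateFrameshift:
    def test_one_base_deletion_after_first_codon(self):
        result = translate_frameshift("ATGGCTTAA", shift_point=1, indel="del:1")
        assert result.tail == "L"
        assert result.open_ended  # ran out of codons before any stop

    def test_immediate_stop_gives_empty_tail(self):
        # inserting T before AAT... opens the shifted frame on a TAA stop
        result = translate_frameshift("ATGAATTTG", shift_point=1, indel="ins:T")
        assert result.tail == ""
        assert not result.open_ended

    def test_no_stop_runs_to_end_open_ended(self):
        result = translate_frameshift("ATGGCAGCAGCAGCA", shift_point=1, indel="del:1")
        assert result.open_ended
        assert result.tail

    def test_ambiguous_nucleotide_rejected(self):
        with pytest.raises(FormatError, match="N"):
            translate_frameshift("ATGGCNTAA", shift_point=1, indel="del:1")

    def test_shift_beyond_cds_rejected(self):
        with pytest.raises(CoordinateError):
            translate_frameshift("ATGGCTTAA", shift_point=3, indel="del:1")

    def test_bad_indel_spec_rejected(self):
        with pytest.raises(FormatError):
            translate_frameshift("ATGGCTTAA", shift_point=1, indel="dup:2")
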
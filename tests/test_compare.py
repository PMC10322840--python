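import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ksrscan.compare import (CandidateMutation, MultipleAlignment,
                             annotate_candidates, divergence_profile,
                             donor_specific_residues, known_oncogenic_lookup,
                             load_landmark_table, read_msa, region_summary,
                             transpose_mutations, validate_landmarks)
from ksrscan.motifs import annotate
from ksrscan.seqio import SequenceRecord
from ksrscan.synthetic_data import inject_mutation, make_ksr3_divergence_set


@pytest.fixture(scope="module")
def ref_msa(msa_rows):
    return MultipleAlignment(tuple(msa_rows), tuple(msa_rows.values()))


KSR3_IDS = ["KSR3_PL", "KSR3_SK", "KSR3_NV"]


class TestReadMsa:
    def test_single_ungapped_sequence(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nMKVLY\n")
        msa = read_msa(p)
        assert msa.ids == ("a",) and msa.n_columns == 5

    def test_clustal_and_fasta_dialects_agree(self, tmp_path):
        fasta = tmp_path / "two.fasta"
        fasta.write_text(">a\nMKV-Y\n>b\nMRVLY\n")
        clustal = tmp_path / "two.aln"
        clustal.write_text(
            "CLUSTAL W (1.82) multiple sequence alignment\n\n"
            "a    MKV-Y\nb    MRVLY\n"
        )
        m1, m2 = read_msa(fasta, "fasta"), read_msa(clustal, "clustal")
        assert m1.ids == m2.ids and m1.rows == m2.rows

    def test_ragged_rows_error(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nMKV\n>b\nMK\n")
        with pytest.raises(ValueError):
            read_msa(p)

    def test_illegal_character_names_row(self):
        with pytest.raises(ValueError, match="'b'"):
            MultipleAlignment(("a", "b"), ("MKV", "M7V"))

    def test_all_gap_columns_dropped(self, tmp_path):
        p = tmp_path / "gapcol.fasta"
        p.write_text(">a\nM-KV\n>b\nM-RV\n")
        assert read_msa(p).n_columns == 3


class TestDivergenceProfile:
    def test_reference_only_set_is_all_zero(self, ref_msa):
        prof = divergence_profile(ref_msa, "BRAF", ["BRAF"])
        assert set(prof.fractions) == {0.0}
        assert prof.positions == tuple(range(1, 767))

    def test_three_row_toy_hand_computed(self):
        msa = MultipleAlignment(("ref", "s1", "s2"), ("MKV", "MRV", "M-L"))
        prof = divergence_profile(msa, "ref", ["s1", "s2"])
        assert prof.positions == (1, 2, 3)
        assert prof.fractions == (0.0, 1.0, 0.5)

    def test_gap_not_divergent_switch(self):
        msa = MultipleAlignment(("ref", "s1", "s2"), ("MKV", "MRV", "M-L"))
        prof = divergence_profile(msa, "ref", ["s1", "s2"], gaps_divergent=False)
        assert prof.fractions == (0.0, 1.0, 0.5)  # pos2: 1 of 1 compared

    def test_reference_gap_columns_skipped(self):
        msa = MultipleAlignment(("ref", "s1"), ("M-V", "MKV"))
        prof = divergence_profile(msa, "ref", ["s1"])
        assert prof.positions == (1, 2)

    def test_all_divergent_column(self):
        msa = MultipleAlignment(("ref", "s1", "s2"), ("MA", "MC", "MD"))
        assert divergence_profile(msa, "ref", ["s1", "s2"]).fractions[1] == 1.0

    def test_empty_set_error(self, ref_msa):
        with pytest.raises(ValueError):
            divergence_profile(ref_msa, "BRAF", [])

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.permutations(KSR3_IDS))
    def test_invariant_under_set_permutation(self, ref_msa, order):
        base = divergence_profile(ref_msa, "BRAF", KSR3_IDS)
        perm = divergence_profile(ref_msa, "BRAF", list(order))
        assert base.fractions == perm.fractions

    def test_fractions_bounded(self, ref_msa):
        prof = divergence_profile(ref_msa, "BRAF", KSR3_IDS)
        assert all(0.0 <= f <= 1.0 for f in prof.fractions)


class TestRegionSummary:
    def test_uniform_profile_equal_means(self, references):
        ann = annotate(references["BRAF"])
        n = len(references["BRAF"].residues)
        from ksrscan.compare import DivergenceProfile
        prof = DivergenceProfile("BRAF", tuple(range(1, n + 1)),
                                 tuple("A" * n), tuple([0.25] * n), 3)
        df = region_summary(prof, ann)
        assert np.allclose(df["mean_divergence"], 0.25)

    def test_elevated_ploop_ranks_first(self, references):
        ann = annotate(references["BRAF"])
        n = len(references["BRAF"].residues)
        a, b = ann.regions["PLOOP"]
        fracs = [0.9 if a <= p <= b else 0.05 for p in range(1, n + 1)]
        from ksrscan.compare import DivergenceProfile
        prof = DivergenceProfile("BRAF", tuple(range(1, n + 1)),
                                 tuple("A" * n), tuple(fracs), 3)
        df = region_summary(prof, ann)
        assert df.iloc[0]["region"] == "PLOOP"

    def test_ksr3_set_concentrates_in_named_regions(self):
        """The KSR3 divergence study set places the P-loop, alphaC and
        activation segment among the top-ranked regions."""
        ids, rows = make_ksr3_divergence_set(19, seed=1)
        msa = MultipleAlignment(tuple(ids), tuple(rows))
        prof = divergence_profile(msa, "BRAF_REF", ids[1:])
        ref = SequenceRecord("BRAF_REF", msa.ungapped("BRAF_REF"))
        df = region_summary(prof, annotate(ref))
        top4 = set(df.head(4)["region"])
        assert {"PLOOP", "ALPHAC", "AS"} <= top4


class TestDonorSpecificResidues:
    def test_donors_identical_to_acceptor_empty(self):
        msa = MultipleAlignment(("acc", "d1", "d2"), ("MKV", "MKV", "MKV"))
        assert donor_specific_residues(msa, ["d1", "d2"], "acc") == []

    def test_toy_four_donor_column(self):
        rows = ("G", "A", "A", "A", "C")
        msa = MultipleAlignment(("acc", "d1", "d2", "d3", "d4"), rows)
        hits = donor_specific_residues(msa, ["d1", "d2", "d3", "d4"], "acc", 0.75)
        assert hits == [(1, "G", "A")]

    def test_threshold_monotonicity(self, ref_msa):
        strict = set(donor_specific_residues(ref_msa, KSR3_IDS, "BRAF", 1.0))
        for thr in (0.8, 0.5, 0.34):
            loose = set(donor_specific_residues(ref_msa, KSR3_IDS, "BRAF", thr))
            assert strict <= loose

    def test_known_beta3_alphac_residues_found(self, ref_msa):
        hits = {p: d for p, _, d in donor_specific_residues(ref_msa, KSR3_IDS, "BRAF")}
        assert hits[485] == "R"   # beta3 leucine -> arginine
        assert hits[499] == "L"   # alphaC lysine -> leucine
        assert hits[506] == "S"   # dimerization arginine -> serine

    def test_empty_donor_set_error(self, ref_msa):
        with pytest.raises(ValueError):
            donor_specific_residues(ref_msa, [], "BRAF")


@pytest.fixture(scope="module")
def braf_candidates(ref_msa, references):
    ann = annotate(references["BRAF"])
    return annotate_candidates(
        transpose_mutations(ref_msa, KSR3_IDS, references["BRAF"], ann)
    )


class TestTransposeMutations:
    def test_expected_candidate_labels_present(self, braf_candidates):
        labels = {c.label for c in braf_candidates}
        assert {"L485R", "K499L", "R506S", "D587K", "L588V"} <= labels

    def test_deletion_at_beta3_alphac_loop(self, braf_candidates):
        dels = [c for c in braf_candidates if c.kind == "deletion"]
        assert any(c.acceptor_position == 487 and c.acceptor_residue.startswith("V")
                   for c in dels)

    def test_qlqa_segment_swap(self, braf_candidates):
        swaps = {c.acceptor_residue: c for c in braf_candidates
                 if c.kind == "segment_swap"}
        assert "QLQA" in swaps
        assert swaps["QLQA"].payload == "DIND"
        assert "DIND" in swaps["QLQA"].note or "discrepancy" in swaps["QLQA"].note

    def test_donors_equal_acceptor_give_empty(self, references):
        row = references["BRAF"].residues
        msa = MultipleAlignment(("BRAF", "d1", "d2"), (row, row, row))
        ann = annotate(references["BRAF"])
        assert transpose_mutations(msa, ["d1", "d2"], references["BRAF"], ann) == []

    def test_ploop_excluded_by_default(self, braf_candidates):
        assert all(not (464 <= c.acceptor_position <= 469) for c in braf_candidates)

    def test_round_trip_substitutions(self, references, braf_candidates):
        """Applying each substitution places the donor residue at the
        mapped position; applying it again in reverse restores the
        original sequence."""
        braf = references["BRAF"]
        subs = [c for c in braf_candidates if c.kind == "substitution"]
        assert subs
        for c in subs:
            mutant = inject_mutation(braf, c)
            assert mutant.residues[c.acceptor_position - 1] == c.payload
            back = CandidateMutation(braf.id, c.acceptor_position, c.payload,
                                     c.acceptor_residue, "substitution",
                                     c.region, c.donor_id, c.donor_position)
            restored = inject_mutation(
                SequenceRecord(braf.id, mutant.residues), back)
            assert restored.residues == braf.residues

    def test_deletion_shortens_by_run_length(self, references, braf_candidates):
        for c in (c for c in braf_candidates if c.kind == "deletion"):
            mutant = inject_mutation(references["BRAF"], c)
            assert len(mutant) == len(references["BRAF"]) - len(c.acceptor_residue)

    def test_segment_swap_round_trip(self, references, braf_candidates):
        for c in (c for c in braf_candidates if c.kind == "segment_swap"):
            mutant = inject_mutation(references["BRAF"], c)
            pos = c.acceptor_position
            assert mutant.residues[pos - 1 : pos - 1 + len(c.payload)] == c.payload

    def test_wild_type_mismatch_guard(self, references, braf_candidates):
        sub = next(c for c in braf_candidates if c.kind == "substitution")
        wrong = SequenceRecord("w", "A" * len(references["BRAF"]))
        with pytest.raises(ValueError, match="mismatch"):
            inject_mutation(wrong, sub)

    def test_hgvs_notation(self, braf_candidates):
        by_label = {c.label: c for c in braf_candidates}
        assert by_label["L485R"].hgvs == "p.Leu485Arg"


class TestKnownOncogenicLookup:
    @pytest.mark.parametrize(
        "pos,wt,var,expected",
        [
            (485, "L", "F", True),    # reported cancer variant
            (485, "L", "R", False),   # explicitly never described
            (506, "R", "E", False),   # explicitly never described
            (506, "R", "S", True),    # position-level entry
            (499, "K", "L", True),
            (588, "L", "V", True),
            (600, "V", "E", True),
            (600, "V", "W", False),   # not a reported variant at 600
            (587, "D", "K", False),   # position not in the list
        ],
    )
    def test_braf_variants(self, pos, wt, var, expected):
        c = CandidateMutation("BRAF", pos, wt, var, "substitution", "X", "d", None)
        flag, note = known_oncogenic_lookup(c)
        assert flag is expected
        assert note

    def test_non_braf_acceptor_undetermined(self):
        c = CandidateMutation("KSR1", 100, "A", "V", "substitution", "X", "d", None)
        flag, _ = known_oncogenic_lookup(c)
        assert flag is None


class TestLandmarks:
    def test_packaged_table_validates_references(self, references):
        table = load_landmark_table()
        report = validate_landmarks(table, references)
        assert len(report) > 0 and report["ok"].all()

    def test_uniform_shift_suggested(self, references):
        table = load_landmark_table()
        shifted = {"KSR3_PL": SequenceRecord(
            "KSR3_PL", "AA" + references["KSR3_PL"].residues)}
        report = validate_landmarks(table, shifted)
        assert (~report["ok"]).sum() >= len(report) - 2  # near-total failure
        assert (report["suggested_offset"] == 2).all()

    def test_single_point_mismatch(self, references):
        seq = list(references["KSR3_PL"].residues)
        seq[37 - 1] = "A"  # break C37 only
        report = validate_landmarks(
            load_landmark_table(),
            {"KSR3_PL": SequenceRecord("KSR3_PL", "".join(seq))})
        assert (~report["ok"]).sum() == 1
        assert report.loc[~report["ok"], "landmark"].item() == "C37"

    def test_numbering_offset_applied(self, references):
        table = load_landmark_table(offset=2)
        shifted = {"KSR3_PL": SequenceRecord(
            "KSR3_PL", "AA" + references["KSR3_PL"].residues)}
        assert validate_landmarks(table, shifted)["ok"].all()
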
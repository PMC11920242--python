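"""Guide design: residue enumeration, codon consequences, oracle equivalence."""

import pytest

from styscreen import synthetic_data as sd
from styscreen.library_design import (
    DesignError,
    EditorSpec,
    LibraryTable,
    TranscriptModel,
    add_controls,
    assign_ibars,
    codon_edit_outcomes,
    design_guides,
    enumerate_sty_residues,
    _has_homopolymer,
)

from oracles import brute_force_designable


class TestEnumerateResidues:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGTAC", [(2, "Y", "TAC", 3)]),
            ("ATGGCG", []),
            ("AGTACTTAT", [(1, "S", "AGT", 0), (2, "T", "ACT", 3), (3, "Y", "TAT", 6)]),
        ],
    )
    def test_genetic_code(self, cds, expected):
        t = TranscriptModel("g", "p", cds)
        assert enumerate_sty_residues(t) == expected

    def test_non_triplet_cds_rejected(self):
        with pytest.raises(DesignError):
            TranscriptModel("g", "p", "ATGT")


class TestCodonEditOutcomes:
    @pytest.mark.parametrize(
        "codon,positions,strand,new_codon,new_aa,category",
        [
            # mutation shapes observed in edited cells: Y->C (sense),
            # S->P and Y->H (antisense), plus a synonymous sense edit
            ("TAC", {2}, "sense", "TGC", "C", "missense"),
            ("TCT", {1}, "antisense", "CCT", "P", "missense"),
            ("TAT", {1}, "antisense", "CAT", "H", "missense"),
            ("ACA", {3}, "sense", "ACG", "T", "synonymous"),
            # bystander leucine->proline via antisense second-position edit
            ("CTG", {2}, "antisense", "CCG", "P", "missense"),
        ],
    )
    def test_anchored_consequences(self, codon, positions, strand, new_codon, new_aa, category):
        assert codon_edit_outcomes(codon, positions, strand) == (new_codon, new_aa, category)

    def test_invalid_edit_position(self):
        with pytest.raises(DesignError):
            codon_edit_outcomes("TAC", {1}, "sense")  # T is not editable on sense


class TestDesignGuides:
    def test_single_site_exactly_one_guide(self):
        # 60-nt CDS of TTT codons with one TAC whose A2 sits at protospacer
        # position 6 of the only NGG-adjacent 20-mer in the sequence
        cds = list("TTT" * 20)
        cds[6:9] = "TAC"
        cds[23] = "G"
        cds[24] = "G"
        t = TranscriptModel("g", "p", "".join(cds))
        guides = design_guides(t)
        assert len(guides) == 1
        (g,) = guides
        assert g.strand == "sense"
        assert g.residue == ("Y", 3)
        assert g.on_target_change == "Y3C"
        assert g.window_adenines == [6]
        # removing the PAM removes the guide
        cds[24] = "T"
        assert design_guides(TranscriptModel("g", "p", "".join(cds))) == []

    def test_oracle_equivalence_small(self, toy_transcripts):
        for t in toy_transcripts:
            got = {(g.spacer, g.strand, g.residue) for g in design_guides(t)}
            assert got == brute_force_designable(t)

    def test_pam_required(self):
        # no G/C anywhere, so neither strand can carry an NGG PAM
        t = TranscriptModel("g", "p", "ATTTATTATTATTATTATTATTATTATTAT")
        assert design_guides(t) == []

    def test_on_target_is_abe_reachable(self, toy_transcripts):
        for t in toy_transcripts:
            for g in design_guides(t):
                aa, pos = g.residue
                codon = t.cds[(pos - 1) * 3 : pos * 3]
                src = "A" if g.strand == "sense" else "T"
                assert src in codon
                assert g.on_target_change.startswith(f"{aa}{pos}")
                # destination is a different non-stop AA or recorded faithfully
                assert not g.on_target_change.endswith("*")

    def test_physical_edit_consistency(self, toy_transcripts):
        """Every reported consequence is reproduced by physically editing
        the locus: place the protospacer on its strand, convert the target
        codon's window bases, and re-translate the full CDS."""
        from styscreen.library_design import revcomp, translate_codon

        for t in toy_transcripts:
            ctx = t.context
            cs = len(t.flank5)
            for g in design_guides(t):
                strand_seq = ctx if g.strand == "sense" else revcomp(ctx)
                # spacer must sit on its strand with the PAM adjacent
                starts = [
                    i
                    for i in range(len(strand_seq) - 22)
                    if strand_seq[i : i + 20] == g.spacer
                    and strand_seq[i + 21 : i + 23] == "GG"
                ]
                assert starts, f"{g.spacer} not found with PAM on {g.strand}"
                aa, pos = g.residue
                reproduced = False
                for i in starts:
                    edited = list(strand_seq)
                    for w in g.window_adenines:
                        assert edited[i + w - 1] == "A"
                        edited[i + w - 1] = "G"
                    coding = "".join(edited) if g.strand == "sense" else revcomp("".join(edited))
                    new_codon = coding[cs + (pos - 1) * 3 : cs + pos * 3]
                    # keep only edits inside the target codon
                    ref_codon = t.cds[(pos - 1) * 3 : pos * 3]
                    merged = "".join(
                        n if (r, n) in (("A", "G"), ("T", "C")) else r
                        for r, n in zip(ref_codon, new_codon)
                    )
                    if g.on_target_change.endswith(translate_codon(merged)):
                        reproduced = True
                assert reproduced, (g.spacer, g.strand, g.residue, g.on_target_change)

    def test_bystander_recorded(self):
        # adjacent CTG (L) and TCA (S) codons: an antisense guide editing the
        # serine also converts the upstream leucine to proline
        cds = "ATG" + "CTG" + "TCA" + "GGC" * 5
        t = TranscriptModel("g", "p", cds, flank5="A" * 7 + "CC" + "A" * 11, flank3="A" * 20)
        hits = [g for g in design_guides(t) if g.residue and g.residue[0] == "S"]
        assert any("L2P" in g.bystander_changes for g in hits if g.strand == "antisense")


class TestIbarsAndControls:
    def _lib(self, n=10):
        guides = []
        ts = sd.make_toy_proteome(n_genes=1, cds_len_range=(300, 300), seed=5)
        pool = design_guides(ts[0])
        assert len(pool) >= n
        return LibraryTable(guides=pool[:n], sublibrary="sense")

    def test_assignment_cardinality_and_alphabet(self):
        lib = assign_ibars(self._lib(), n_ibars=3, length=6, seed=1)
        rows = [(g.spacer, b) for g in lib.guides for b in g.ibars]
        assert len(rows) == 30
        for g in lib.guides:
            assert len(set(g.ibars)) == 3
            for b in g.ibars:
                assert len(b) == 6 and set(b) <= set("ACGT")
                assert not _has_homopolymer(b)

    def test_deterministic_under_seed(self):
        a = assign_ibars(self._lib(), seed=7)
        b = assign_ibars(self._lib(), seed=7)
        assert [g.ibars for g in a.guides] == [g.ibars for g in b.guides]
        c = assign_ibars(self._lib(), seed=8)
        assert [g.ibars for g in a.guides] != [g.ibars for g in c.guides]

    def test_capacity_error(self):
        with pytest.raises(DesignError):
            assign_ibars(self._lib(), n_ibars=50, length=2)

    def test_controls_added_and_flagged(self):
        lib = self._lib()
        controls = ["A" * 10 + "C" * 10, "G" * 10 + "T" * 10]
        out = add_controls(lib, controls)
        assert len(out.guides) == len(lib.guides) + 2
        assert sum(g.is_control for g in out.guides) == 2

    def test_controls_identical_across_sublibraries(self):
        controls = ["ACGTACGTACGTACGTACGT"]
        sense = add_controls(self._lib(), controls)
        anti = add_controls(LibraryTable(guides=[], sublibrary="antisense"), controls)
        s = assign_ibars(sense, seed=3).guides[-1]
        a = assign_ibars(anti, seed=3).guides[-1]
        assert (s.spacer, s.ibars) == (a.spacer, a.ibars)

    def test_empty_control_list_noop(self):
        lib = self._lib()
        assert add_controls(lib, []).guides == lib.guides

    def test_duplicate_control_collision(self):
        lib = self._lib()
        with pytest.raises(DesignError):
            add_controls(lib, [lib.guides[0].spacer])


def test_library_tsv_round_trip(tmp_path):
    ts = sd.make_toy_proteome(n_genes=2, cds_len_range=(150, 300), seed=2)
    guides = [g for t in ts for g in design_guides(t)]
    lib = assign_ibars(LibraryTable(guides=guides, sublibrary="sense"), seed=1)
    path = tmp_path / "lib.tsv"
    lib.write_tsv(path)
    back = LibraryTable.read_tsv(path)
    assert [(g.spacer, g.strand, g.residue, g.ibars) for g in back.guides] == [
        (g.spacer, g.strand, g.residue, g.ibars) for g in lib.guides
    ]
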
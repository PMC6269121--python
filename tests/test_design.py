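"""Library design: k-mer enumeration, selection, mutagenesis, controls."""

import numpy as np
import pandas as pd
import pytest

import presenter as ps
from presenter.design import (
    DesignError,
    RESIDUE_CLASSES,
    library_to_frame,
    read_library_tsv,
    write_library_tsv,
)


def proteome(*seqs):
    return ps.Proteome(records=tuple((f"p{i}", s) for i, s in enumerate(seqs)))


class TestEnumerateKmers:
    def test_hand_enumeration(self):
        kmers = ps.enumerate_kmers(proteome("SIINFEKLA"), 8)
        assert set(kmers) == {"SIINFEKL", "IINFEKLA"}
        assert kmers["SIINFEKL"] == ("p0", 0)
        assert kmers["IINFEKLA"] == ("p0", 1)

    def test_deduplication(self):
        assert set(ps.enumerate_kmers(proteome("A" * 9), 8)) == {"AAAAAAAA"}

    def test_noncanonical_kmers_excluded(self):
        kmers = ps.enumerate_kmers(proteome("MSIINFEKL", "XSIINFEKL"), 8)
        assert set(kmers) == {"MSIINFEK", "SIINFEKL"}

    def test_empty_proteome_errors(self):
        with pytest.raises(DesignError):
            ps.enumerate_kmers(ps.Proteome(records=()), 8)

    def test_every_kmer_occurs_in_a_protein(self, small_proteome):
        kmers = ps.enumerate_kmers(small_proteome, 8)
        seqs = dict(small_proteome.records)
        for pep, (pid, start) in list(kmers.items())[:200]:
            assert seqs[pid][start : start + 8] == pep


class TestSelectWildtype:
    def affinities(self, binders, nonbinders):
        return {**{p: 100.0 for p in binders}, **{p: 900.0 for p in nonbinders}}

    def test_exhaustive_selection_ignores_seed(self):
        binders = [f"PEP{i:05d}" for i in range(10)]
        aff = self.affinities(binders, [])
        for seed in (0, 1, 99):
            cfg = ps.LibraryDesignConfig(n_select=10, seed=seed)
            got = {r.peptide for r in ps.select_wildtype_library(binders, aff, cfg)}
            assert got == set(binders)

    def test_nonbinders_never_selected(self):
        binders = [f"BIND{i:04d}" for i in range(10)]
        others = [f"WEAK{i:04d}" for i in range(5)]
        aff = self.affinities(binders, others)
        cfg = ps.LibraryDesignConfig(n_select=10, seed=0)
        got = {r.peptide for r in ps.select_wildtype_library(binders + others, aff, cfg)}
        assert got == set(binders)

    def test_deterministic_and_order_invariant(self):
        peps = [f"PEP{i:05d}" for i in range(40)]
        aff = self.affinities(peps, [])
        cfg = ps.LibraryDesignConfig(n_select=15, seed=7)
        a = [r.peptide for r in ps.select_wildtype_library(peps, aff, cfg)]
        b = [r.peptide for r in ps.select_wildtype_library(peps[::-1], aff, cfg)]
        assert a == b

    def test_insufficient_binders_error_names_counts(self):
        aff = self.affinities(["PEPTIDEA"], [])
        with pytest.raises(DesignError, match="1 binders.*n_select=5"):
            ps.select_wildtype_library(
                ["PEPTIDEA"], aff, ps.LibraryDesignConfig(n_select=5)
            )


class TestMutatePeptide:
    def test_known_control_pair_is_single_substitution(self):
        # the S551F pair: SNFVSAGI -> SNFVFAGI (position 5)
        rec = ps.PeptideRecord(
            "SNFVFAGI", ic50=50.0, role="mutant", partner="SNFVSAGI", mutated_position=5
        )
        assert rec.mutated_position == 5  # constructor validates Hamming-1

    def test_candidate_space_size(self):
        wt = "SIINFEKL"
        neighbours = {
            wt[:i] + aa + wt[i + 1 :]
            for i in range(8)
            for aa in "ACDEFGHIKLMNPQRSTVWY"
            if aa != wt[i]
        }
        assert len(neighbours) == 8 * 19

    def test_full_neighbourhood_forbidden_means_unmutable(self):
        wt = "SIINFEKL"
        forbidden = frozenset(
            wt[:i] + aa + wt[i + 1 :]
            for i in range(8)
            for aa in "ACDEFGHIKLMNPQRSTVWY"
        )
        cfg = ps.LibraryDesignConfig(n_select=1, exhaustive_mutation=True)
        assert ps.mutate_peptide(wt, forbidden, lambda p: 10.0, cfg) is None

    @pytest.mark.parametrize("exhaustive", [False, True])
    def test_mutant_is_admissible(self, exhaustive):
        cfg = ps.LibraryDesignConfig(
            n_select=1, seed=5, exhaustive_mutation=exhaustive
        )
        rec = ps.mutate_peptide("SIINFEKL", frozenset({"SIINFEKL"}), lambda p: 10.0, cfg)
        assert rec.partner == "SIINFEKL"
        assert sum(a != b for a, b in zip(rec.peptide, "SIINFEKL")) == 1

    def test_binding_filter_applies_to_mutants(self):
        # only mutants containing W bind; everything else fails the cut
        def ic50_of(p):
            return 10.0 if "W" in p else 900.0

        cfg = ps.LibraryDesignConfig(n_select=1, seed=0, exhaustive_mutation=True)
        rec = ps.mutate_peptide("SIINFEKL", frozenset(), ic50_of, cfg)
        assert "W" in rec.peptide and rec.ic50 < 500


class TestBuildMutantLibrary:
    def test_each_mutant_pairs_with_its_wildtype(self, small_design):
        wt_set = {r.peptide for r in small_design["wildtype"]}
        for mut in small_design["mutants"]:
            assert mut.partner in wt_set
            assert sum(a != b for a, b in zip(mut.peptide, mut.partner)) == 1

    def test_mutants_avoid_proteome_kmers(self, small_design):
        kmers = set(small_design["kmers"])
        assert all(m.peptide not in kmers for m in small_design["mutants"])

    def test_mutants_unique_and_pass_binder_filter(self, small_design):
        peps = [m.peptide for m in small_design["mutants"]]
        assert len(set(peps)) == len(peps)
        assert all(m.ic50 < 500 for m in small_design["mutants"])

    def test_reproducible_under_seed(self, small_design):
        cfg = small_design["config"]
        again, _ = ps.build_mutant_library(
            small_design["wildtype"], set(small_design["kmers"]),
            small_design["ic50_of"], cfg,
        )
        assert [m.peptide for m in again] == [m.peptide for m in small_design["mutants"]]

    def test_blocked_wildtype_excluded(self):
        # a wild type whose entire binding-competent neighbourhood is self
        wt = [ps.PeptideRecord("AAAAAAAA", ic50=10.0, role="wild_type")]
        all_neighbours = {
            "AAAAAAAA"[:i] + aa + "AAAAAAAA"[i + 1 :]
            for i in range(8)
            for aa in "ACDEFGHIKLMNPQRSTVWY"
        }
        cfg = ps.LibraryDesignConfig(n_select=1, exhaustive_mutation=True)
        mutants, unmutable = ps.build_mutant_library(
            wt, all_neighbours, lambda p: 10.0, cfg
        )
        assert mutants == [] and unmutable == ["AAAAAAAA"]


class TestControls:
    def test_default_controls_added(self, small_design):
        lib = ps.add_controls(small_design["wildtype"])
        assert len(lib) == len(small_design["wildtype"]) + 8
        roles = {r.role for r in lib[-8:]}
        assert roles == {"control_immunogenic", "control_nonimmunogenic"}

    def test_longer_control_accepted(self):
        lib = [ps.PeptideRecord("SIINFEKL", ic50=40.0)]
        out = ps.add_controls(
            lib, [ps.PeptideRecord("MSIIFFLPL", role="control_nonimmunogenic")]
        )
        assert out[-1].peptide == "MSIIFFLPL"

    def test_duplicate_control_rejected(self):
        lib = [ps.PeptideRecord("SIINFEKL", ic50=40.0)]
        with pytest.raises(DesignError):
            ps.add_controls(lib, [ps.PeptideRecord("SIINFEKL", role="control_immunogenic")])

    def test_bad_role_rejected(self):
        with pytest.raises(DesignError):
            ps.add_controls([], [ps.PeptideRecord("SIINFEKL", role="wild_type")])


class TestCharacterize:
    def test_single_pair_within_100nM(self):
        wt = [ps.PeptideRecord("SNFVSAGI", ic50=200.0)]
        mut = [
            ps.PeptideRecord(
                "SNFVFAGI", ic50=260.0, role="mutant", partner="SNFVSAGI",
                mutated_position=5,
            )
        ]
        char = ps.characterize_library(wt, mut)
        assert char.affinity_delta_histogram.iloc[0] == 1
        assert char.position_histogram[5] == 1
        # S (polar) -> F (hydrophobic)
        assert RESIDUE_CLASSES["S"] == "polar" and RESIDUE_CLASSES["F"] == "hydrophobic"
        assert char.substitution_class_matrix.loc["polar", "hydrophobic"] == 1

    def test_empty_mutant_library_all_zero(self, small_design):
        char = ps.characterize_library(small_design["wildtype"], [])
        assert char.affinity_delta_histogram.sum() == 0
        assert char.position_histogram.sum() == 0
        assert char.substitution_class_matrix.values.sum() == 0

    def test_histogram_totals_conserved(self, small_design):
        char = ps.characterize_library(
            small_design["wildtype"], small_design["mutants"]
        )
        n = len(small_design["mutants"])
        assert char.affinity_delta_histogram.sum() == n
        assert char.position_histogram.sum() == n
        assert char.substitution_class_matrix.values.sum() == n

    def test_orphan_mutant_errors(self):
        mut = [
            ps.PeptideRecord(
                "SNFVFAGI", ic50=10.0, role="mutant", partner="SNFVSAGI",
                mutated_position=5,
            )
        ]
        with pytest.raises(DesignError):
            ps.characterize_library([], mut)


class TestLibraryIO:
    def test_tsv_round_trip(self, small_design, tmp_path):
        lib = ps.add_controls(small_design["wildtype"]) + small_design["mutants"]
        path = tmp_path / "library.tsv"
        write_library_tsv(lib, path)
        back = read_library_tsv(path)
        a, b = library_to_frame(back), library_to_frame(lib)
        pd.testing.assert_frame_equal(
            a.fillna(np.nan), b.fillna(np.nan), check_dtype=False
        )
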
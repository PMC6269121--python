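"""Screen deconvolution: counting, normalisation, QC, depletion calls."""

import numpy as np
import pandas as pd
import pytest

import presenter as ps
from presenter.deconvolve import (
    DeconvolutionError,
    brute_force_count,
    read_count_tsv,
    write_comparison_tsv,
)


REF = {"A": "ATGGCTAAA", "B": "ATGGCTAAG"}  # Hamming distance 1 apart


class TestCountMinigenes:
    def test_error_free_reads_count_exactly(self):
        ct = ps.count_minigenes(["ATGGCTAAA"] * 100, {"A": "ATGGCTAAA", "C": "CCCCCCCCC"})
        assert ct.counts["A"] == 100 and ct.counts["C"] == 0
        assert ct.unmapped == 0 and ct.ambiguous == 0

    def test_mismatch_budget(self):
        read = "ATGGCTTAA"  # 1 sub vs A at position 7, 2 vs B
        assert ps.count_minigenes([read], REF, max_mismatch=0).unmapped == 1
        ct = ps.count_minigenes([read], REF, max_mismatch=1)
        assert ct.counts["A"] == 1

    def test_equidistant_read_is_ambiguous(self):
        read = "ATGGCTAAC"  # distance 1 from both A and B
        ct = ps.count_minigenes([read], REF, max_mismatch=1)
        assert ct.ambiguous == 1 and ct.counts.sum() == 0

    def test_exact_match_beats_neighbour(self):
        # a read equal to A is also within 1 of B, but distance 0 wins
        ct = ps.count_minigenes(["ATGGCTAAA"], REF, max_mismatch=1)
        assert ct.counts["A"] == 1 and ct.ambiguous == 0

    def test_count_conservation(self, rng):
        refs = {f"m{i}": "".join(rng.choice(list("ACGT"), 24)) for i in range(20)}
        reads = []
        for dna in refs.values():
            for _ in range(5):
                arr = list(dna)
                for j in rng.choice(24, rng.integers(0, 3), replace=False):
                    arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
                reads.append("".join(arr))
        ct = ps.count_minigenes(reads, refs, max_mismatch=1)
        assert ct.total_mapped + ct.unmapped + ct.ambiguous == len(reads)

    def test_agrees_with_brute_force_oracle(self, rng):
        refs = {f"m{i}": "".join(rng.choice(list("ACGT"), 15)) for i in range(60)}
        reads = []
        for dna in list(refs.values()) * 3:
            arr = list(dna)
            n_err = rng.integers(0, 3)
            for j in rng.choice(15, n_err, replace=False):
                arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
            reads.append("".join(arr))
        for mm in (0, 1):
            fast = ps.count_minigenes(reads, refs, max_mismatch=mm)
            slow = brute_force_count(reads, refs, max_mismatch=mm)
            assert fast.counts.equals(slow.counts)
            assert (fast.unmapped, fast.ambiguous) == (slow.unmapped, slow.ambiguous)

    def test_fastq_input(self, tmp_path):
        fq = tmp_path / "reads.fastq"
        fq.write_text("@r1\nATGGCTAAA\n+\nIIIIIIIII\n@r2\nTTTTTTTTT\n+\nIIIIIIIII\n")
        ct = ps.count_minigenes(fq, {"A": "ATGGCTAAA"}, max_mismatch=0)
        assert ct.counts["A"] == 1 and ct.unmapped == 1

    def test_empty_reference_errors(self):
        with pytest.raises(DeconvolutionError):
            ps.count_minigenes([], {})

    def test_empty_reads_all_zero(self):
        ct = ps.count_minigenes([], REF)
        assert ct.counts.sum() == 0 and ct.total_reads == 0


class TestRelativeAbundance:
    def test_two_even_minigenes(self):
        ab = ps.relative_abundance(
            ps.CountTable("s", pd.Series({"a": 1, "b": 1}))
        )
        assert ab.abundance["a"] == 0.5 and ab.abundance["b"] == 0.5

    def test_one_cell_per_five_million_is_2e5_percent(self):
        counts = pd.Series({"rare": 1, "rest": 5_000_000 - 1})
        ab = ps.relative_abundance(ps.CountTable("s", counts))
        assert ab.abundance["rare"] * 100 == pytest.approx(0.00002)

    def test_order_invariance(self, rng):
        counts = pd.Series(rng.integers(1, 100, 10), index=[f"m{i}" for i in range(10)])
        a = ps.relative_abundance(ps.CountTable("s", counts)).abundance
        b = ps.relative_abundance(
            ps.CountTable("s", counts[::-1])
        ).abundance
        assert a.sort_index().equals(b.sort_index())

    def test_zero_mapped_reads_error(self):
        with pytest.raises(DeconvolutionError):
            ps.relative_abundance(ps.CountTable("s", pd.Series({"a": 0})))


class TestRepresentationQC:
    def test_full_scale_library_minimum(self):
        qc = ps.qc_representation(5_000_000, 5000, 1000)
        assert qc.required == 5_000_000 and qc.passed

    @pytest.mark.parametrize("n,passed", [(4_999_999, False), (5_000_000, True)])
    def test_boundary(self, n, passed):
        assert ps.qc_representation(n, 5000, 1000).passed is passed


class TestCellsAtInjection:
    @pytest.mark.parametrize(
        "abundance,cells", [(5e-5, 250), (1.3e-4, 650), (0.0, 0)]
    )
    def test_inoculum_scaling(self, abundance, cells):
        est = ps.estimate_cells_at_injection(abundance, 5_000_000)
        assert est.cells == pytest.approx(cells)
        assert est.cells_rounded == cells

    def test_invalid_inputs(self):
        with pytest.raises(DeconvolutionError):
            ps.estimate_cells_at_injection(1.5, 100)
        with pytest.raises(DeconvolutionError):
            ps.estimate_cells_at_injection(0.5, 0)


def abundance_table(sample, mapping, total=None):
    return ps.AbundanceTable(sample, pd.Series(mapping), total_mapped=total)


class TestCompareScreens:
    def test_identity_is_all_neutral(self, rng):
        p = rng.dirichlet(np.ones(30))
        x = abundance_table("x", {f"m{i}": v for i, v in enumerate(p)}, total=10_000)
        comp = ps.compare_screens([x], [x])
        assert (comp.table["lfc"] == 0).all()
        assert (comp.table["call"] == "neutral").all()

    def test_eightfold_drop_is_called_depleted(self):
        pre = {"a": 0.2, "b": 0.4, "c": 0.4}
        post_a = 0.2 / 8
        scale = (1 - post_a) / 0.8
        post = {"a": post_a, "b": 0.4 * scale, "c": 0.4 * scale}
        comp = ps.compare_screens(
            [abundance_table("pre", pre)], [abundance_table("post", post)],
            pseudocount=1e-9,
        )
        assert comp.table.loc["a", "lfc"] == pytest.approx(-3.0, abs=0.01)
        assert comp.table.loc["a", "call"] == "depleted"
        assert (comp.table.loc[["b", "c"], "call"] == "neutral").all()

    def test_floor_guards_stochastic_dropout(self):
        # a rare minigene (below 1/10,000) vanishing entirely is NOT depletion
        pre = {"rare": 5e-5, "big": 1 - 5e-5}
        post = {"rare": 0.0, "big": 1.0}
        comp = ps.compare_screens(
            [abundance_table("pre", pre)], [abundance_table("post", post)],
            pseudocount=1e-7,
        )
        assert comp.table.loc["rare", "call"] == "neutral"
        assert comp.table.loc["rare", "lfc"] < -1

    def test_replicates_are_averaged(self):
        pre1 = abundance_table("p1", {"a": 0.3, "b": 0.7})
        pre2 = abundance_table("p2", {"a": 0.5, "b": 0.5})
        post = abundance_table("t", {"a": 0.4, "b": 0.6})
        comp = ps.compare_screens([pre1, pre2], [post], pseudocount=1e-9)
        assert comp.table.loc["a", "pre"] == pytest.approx(0.4)
        assert comp.table.loc["a", "lfc"] == pytest.approx(0.0, abs=1e-6)

    def test_library_mismatch_errors(self):
        x = abundance_table("x", {"a": 0.5, "b": 0.5})
        y = abundance_table("y", {"a": 0.5, "c": 0.5})
        with pytest.raises(DeconvolutionError):
            ps.compare_screens([x], [y])

    def test_per_animal_mode(self, rng):
        p = rng.dirichlet(np.ones(20))
        names = [f"m{i}" for i in range(20)]
        pre = abundance_table("pre", dict(zip(names, p)))
        posts = [abundance_table(f"t{j}", dict(zip(names, rng.dirichlet(np.ones(20)))))
                 for j in range(3)]
        comp = ps.compare_screens([pre], posts, pseudocount=1e-7, per_animal=True)
        assert set(comp.per_animal) == {"t0", "t1", "t2"}
        for frame in comp.per_animal.values():
            assert set(frame.columns) == set(comp.table.columns)

    def test_default_pseudocount_is_scale_aware(self):
        x = abundance_table("x", {"a": 0.5, "b": 0.5}, total=1000)
        y = abundance_table("y", {"a": 0.5, "b": 0.5}, total=4000)
        comp = ps.compare_screens([x], [y])
        assert comp.pseudocount == pytest.approx(1 / 8000)


class TestIO:
    def test_count_tsv_round_trip(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("minigene\tcount\nA\t10\nB\t5\n")
        ct = read_count_tsv(path)
        assert ct.counts["A"] == 10 and ct.counts["B"] == 5

    def test_comparison_tsv_written(self, tmp_path, rng):
        p = rng.dirichlet(np.ones(10))
        x = abundance_table("x", {f"m{i}": v for i, v in enumerate(p)})
        comp = ps.compare_screens([x], [x], pseudocount=1e-7)
        out = tmp_path / "comparison.tsv"
        write_comparison_tsv(comp, out)
        frame = pd.read_csv(out, sep="\t")
        assert set(frame.columns) == {
            "minigene", "pre", "post", "lfc", "fitted", "residual", "call"
        }
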
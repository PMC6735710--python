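from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from profalign import (
    GroupAssignment,
    Profile,
    build_profile_set,
    normalize_sum,
    progressive_align,
    read_alignment,
    read_gene_sets,
    read_groups,
    read_profile,
    read_subset,
    write_alignment,
    write_profile,
)

from .conftest import make_profile


def write_csv(path, text):
    path.write_text(text)
    return path


class TestReadProfile:
    def test_constant_matrix(self, tmp_path):
        p = write_csv(
            tmp_path / "s.csv",
            "protein_id,s1,s2,s3,s4\nA,1.0,1.0,1.0,1.0\nB,1.0,1.0,1.0,1.0\nC,1.0,1.0,1.0,1.0\n",
        )
        prof = read_profile(p)
        assert prof.sample_id == "s"
        assert prof.protein_ids == ("A", "B", "C")
        assert prof.intensities.sum() == 12.0

    def test_empty_cell_reads_as_zero(self, tmp_path):
        p = write_csv(tmp_path / "s.csv", "protein_id,s1,s2\nA,1,\nB,2,3\n")
        prof = read_profile(p)
        assert prof.intensities[0, 1] == 0.0

    def test_nan_cell_zeroed_with_warning(self, tmp_path, caplog):
        p = write_csv(tmp_path / "s.csv", "protein_id,s1,s2\nA,1,NaN\nB,2,3\n")
        with caplog.at_level("WARNING"):
            prof = read_profile(p)
        assert prof.intensities[0, 1] == 0.0
        assert any("NaN" in rec.message for rec in caplog.records)

    def test_negative_cell_error_names_cell(self, tmp_path):
        p = write_csv(tmp_path / "s.csv", "protein_id,s1,s2\nA,1,2\nB,-5,3\n")
        with pytest.raises(ValueError, match=r"'B'.*'s1'"):
            read_profile(p)

    def test_non_numeric_cell_is_error(self, tmp_path):
        p = write_csv(tmp_path / "s.csv", "protein_id,s1,s2\nA,1,x\nB,2,3\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_profile(p)

    def test_duplicate_ids_reported(self, tmp_path):
        p = write_csv(tmp_path / "s.csv", "protein_id,s1,s2\nA,1,2\nA,2,3\n")
        with pytest.raises(ValueError, match=r"duplicate.*\['A'\]"):
            read_profile(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_profile(tmp_path / "absent.csv")

    def test_tsv_and_xlsx(self, tmp_path):
        prof = make_profile("x", [[1.0, 2.0], [3.0, 4.0]])
        for ext in ("tsv", "xlsx"):
            path = write_profile(prof, tmp_path / f"x.{ext}")
            again = read_profile(path)
            assert again.protein_ids == prof.protein_ids
            np.testing.assert_array_equal(again.intensities, prof.intensities)

    def test_roundtrip_csv(self, tmp_path):
        rng = np.random.default_rng(3)
        prof = make_profile("rt", rng.random((5, 7)))
        again = read_profile(write_profile(prof, tmp_path / "rt.csv"))
        assert again.protein_ids == prof.protein_ids
        np.testing.assert_allclose(again.intensities, prof.intensities, rtol=1e-12)

    def test_gene_collapse_keeps_max_total(self, tmp_path):
        p = write_csv(
            tmp_path / "s.csv",
            "protein_id,gene,s1,s2\nA1,G1,1,1\nA2,G1,5,5\nB1,G2,2,2\n",
        )
        prof = read_profile(p, gene_column="gene")
        assert prof.protein_ids == ("G1", "G2")
        np.testing.assert_array_equal(prof.intensities, [[5, 5], [2, 2]])

    def test_explicit_slice_columns(self, tmp_path):
        p = write_csv(tmp_path / "s.csv", "protein_id,note,s1,s2\nA,hi,1,2\nB,yo,3,4\n")
        prof = read_profile(p, slice_columns=["s1", "s2"])
        assert prof.n_slices == 2


class TestProfileInvariants:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            make_profile("s", [[1.0, -1.0]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            make_profile("s", [[1.0, np.inf]])

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            make_profile("s", [[1.0], [2.0]])


class TestBuildProfileSet:
    def test_union_zero_fill(self):
        a = make_profile("a", [[1, 2], [3, 4]], ids=("A", "B"))
        b = make_profile("b", [[5, 6], [7, 8]], ids=("B", "C"))
        pset = build_profile_set([a, b])
        assert pset.protein_ids == ("A", "B", "C")
        np.testing.assert_array_equal(pset["a"].intensities, [[1, 2], [3, 4], [0, 0]])
        np.testing.assert_array_equal(pset["b"].intensities, [[0, 0], [5, 6], [7, 8]])

    def test_subset_restriction(self):
        a = make_profile("a", [[1, 2], [3, 4]], ids=("A", "B"))
        b = make_profile("b", [[5, 6], [7, 8]], ids=("B", "C"))
        pset = build_profile_set([a, b], subset=["B"])
        assert pset.protein_ids == ("B",)
        np.testing.assert_array_equal(pset["a"].intensities, [[3, 4]])
        np.testing.assert_array_equal(pset["b"].intensities, [[5, 6]])

    def test_disjoint_subset_error(self):
        a = make_profile("a", [[1, 2]], ids=("A",))
        b = make_profile("b", [[1, 2]], ids=("B",))
        with pytest.raises(ValueError, match="subset"):
            build_profile_set([a, b], subset=["Z"])

    def test_idempotent(self, small_profiles):
        pset = build_profile_set(small_profiles)
        again = build_profile_set(list(pset.profiles))
        assert again.protein_ids == pset.protein_ids
        for p, q in zip(pset, again):
            np.testing.assert_array_equal(p.intensities, q.intensities)

    def test_needs_two_profiles(self, small_profiles):
        with pytest.raises(ValueError):
            build_profile_set([small_profiles[0]])


class TestAuxFiles:
    def test_read_groups(self, tmp_path):
        p = write_csv(tmp_path / "g.tsv", "s1\tcase\ns2\tcontrol\ns3\tcontrol\n")
        g = read_groups(p)
        assert g.case_ids == {"s1"}
        assert g.control_ids == {"s2", "s3"}

    def test_read_groups_bad_label(self, tmp_path):
        p = write_csv(tmp_path / "g.tsv", "s1\tpatient\n")
        with pytest.raises(ValueError, match="case"):
            read_groups(p)

    def test_group_assignment_overlap(self):
        with pytest.raises(ValueError):
            GroupAssignment(case_ids=frozenset({"a"}), control_ids=frozenset({"a", "b"}))

    def test_read_subset(self, tmp_path):
        p = write_csv(tmp_path / "subset.txt", "# comment\nA\nB\nA\n")
        assert read_subset(p) == ("A", "B")

    def test_gmt(self, tmp_path):
        p = write_csv(tmp_path / "sets.gmt", "MICOS\tdesc\tMIC60\tMIC19\nOther\td\tX\n")
        sets = read_gene_sets(p)
        assert sets["MICOS"] == ("MIC60", "MIC19")
        assert len(sets) == 2

    def test_gmt_duplicate_name(self, tmp_path):
        p = write_csv(tmp_path / "sets.gmt", "A\td\tX\nA\td\tY\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_sets(p)

    def test_gmt_empty_set(self, tmp_path):
        p = write_csv(tmp_path / "sets.gmt", "A\td\t\n")
        with pytest.raises(ValueError, match="no members"):
            read_gene_sets(p)

    def test_empty_file(self, tmp_path):
        p = write_csv(tmp_path / "sets.gmt", "")
        with pytest.raises(ValueError, match="empty"):
            read_gene_sets(p)

    def test_two_column(self, tmp_path):
        p = write_csv(tmp_path / "sets.tsv", "S1\tA\nS1\tB\nS2\tC\n")
        sets = read_gene_sets(p)
        assert sets["S1"] == ("A", "B")
        assert sets["S2"] == ("C",)


class TestWriteAlignment:
    @pytest.fixture
    def identity_alignment(self, normalized_pair):
        # two identical samples -> no gaps
        base = normalized_pair["a"]
        twin = Profile(sample_id="b", protein_ids=base.protein_ids,
                       intensities=base.intensities.copy())
        pset = build_profile_set([base, twin])
        return pset, progressive_align(pset)

    def test_no_gap_alignment_writes_inputs(self, tmp_path, identity_alignment):
        pset, alignment = identity_alignment
        write_alignment(alignment, tmp_path)
        for sid in pset.sample_ids:
            frame = pd.read_csv(tmp_path / f"aligned_{sid}.csv", index_col="protein_id")
            np.testing.assert_allclose(
                frame.to_numpy(), pset[sid].intensities, rtol=1e-12
            )

    def test_written_width_is_aligned_length(self, tmp_path, normalized_pair):
        alignment = progressive_align(normalized_pair)
        write_alignment(alignment, tmp_path)
        for sid in normalized_pair.sample_ids:
            frame = pd.read_csv(tmp_path / f"aligned_{sid}.csv", index_col="protein_id")
            assert frame.shape[1] == alignment.length

    def test_gap_table_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        a = make_profile("a", rng.random((4, 8)))
        # b = a with two duplicated slices: forces insertions in a
        mat = np.repeat(a.intensities, [1, 1, 2, 1, 1, 2, 1, 1], axis=1)
        b = make_profile("b", mat)
        pset = build_profile_set([a, b])
        pset, _ = normalize_sum(pset)
        alignment = progressive_align(pset)
        write_alignment(alignment, tmp_path)
        loaded = read_alignment(tmp_path)
        for sid in pset.sample_ids:
            np.testing.assert_array_equal(loaded.insertions(sid), alignment.insertions(sid))
            np.testing.assert_allclose(
                loaded.matrices[sid], alignment.matrices[sid], rtol=1e-12
            )

    def test_cost_matrix_and_tree_written(self, tmp_path, normalized_pair):
        alignment = progressive_align(normalized_pair)
        write_alignment(alignment, tmp_path)
        cm = pd.read_csv(tmp_path / "cost_matrix.csv", index_col="sample_id")
        np.testing.assert_allclose(cm.to_numpy(), alignment.cost_matrix)
        assert (tmp_path / "guide_tree.newick").read_text().strip().endswith(";")
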
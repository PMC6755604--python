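"""Fingerprint containers, CSV round-trip, bit selection and filtering."""

import numpy as np
import pytest

from siftsim import (
    BitLayout,
    FingerprintDataset,
    FormatError,
    InteractionFingerprint,
    conform_fingerprint,
    filter_interactions,
    filter_residues,
    read_dataset,
    select_bits,
    write_dataset,
)
from siftsim.fingerprints import INTERACTION_TYPES, apply_filtering

from conftest import random_dataset


def make_dataset(columns_bits, activities, name="t"):
    """Dataset from a dict {column_name: tuple-of-bits}."""
    cols = list(columns_bits)
    from siftsim.fingerprints import make_layout, _make_dataset

    layout = make_layout(cols)
    matrix = np.array(list(columns_bits.values()), dtype=np.uint8).T
    fps = [
        InteractionFingerprint(f"L{i}", matrix[i], bool(a))
        for i, a in enumerate(activities)
    ]
    return _make_dataset(name, layout, fps)


class TestLayout:
    def test_bit_indexing_and_length(self):
        layout = BitLayout(("ASP86", "TYR90"))
        assert len(layout) == 18
        assert layout.index_of("ASP86", "Any") == 0
        assert layout.index_of("TYR90", "BB") == 10
        assert layout.columns[0] == "ASP86:Any"
        assert layout.columns[-1] == "TYR90:Chg"

    def test_interaction_types_must_follow_canonical_order(self):
        with pytest.raises(ValueError):
            BitLayout(("ASP86",), ("BB", "Any"))
        with pytest.raises(ValueError):
            BitLayout(("ASP86",), ("Any", "XX"))

    def test_fingerprint_rejects_non_binary_bits(self):
        with pytest.raises(ValueError, match="non-binary"):
            InteractionFingerprint("L1", np.array([0, 2, 1]), True)


class TestIO:
    def test_read_small_file(self, tmp_path):
        path = tmp_path / "fp.csv"
        path.write_text(
            "ligand_id,active,ASP86:Any,ASP86:HBA\n"
            "L1,1,1,0\nL2,0,0,1\nL3,1,1,1\n"
        )
        ds = read_dataset(path)
        assert len(ds.layout) == 2
        assert len(ds) == 3
        assert ds.layout.residues == ("ASP86",)
        assert ds.layout.interaction_types == ("Any", "HBA")
        assert ds.fingerprints[1].bits.tolist() == [0, 1]
        assert not ds.fingerprints[1].active

    def test_tab_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "fp.tsv"
        path.write_text("ligand_id\tactive\tASP86:Any\nL1\t1\t1\n")
        assert len(read_dataset(path)) == 1

    @pytest.mark.parametrize(
        "text,exc,match",
        [
            ("id,active,ASP86:Any\nL1,1,1\n", FormatError, "header"),
            ("ligand_id,active,ASP86:Foo\nL1,1,1\n", FormatError, "interaction type"),
            ("ligand_id,active,ASP86:Any\nL1,1,2\n", ValueError, "ASP86:Any"),
            ("ligand_id,active,ASP86:Any\nL1,1,1,0\n", ValueError, "expected 3 fields"),
            ("ligand_id,active,ASP86:Any\nL1,x,1\n", ValueError, "activity"),
        ],
    )
    def test_malformed_inputs(self, tmp_path, text, exc, match):
        path = tmp_path / "bad.csv"
        path.write_text(text)
        with pytest.raises(exc, match=match):
            read_dataset(path)

    def test_round_trip(self, tmp_path, rng):
        ds = random_dataset(rng, n_ligands=5, n_residues=3)
        path = tmp_path / "rt.csv"
        write_dataset(ds, path)
        back = read_dataset(path, name=ds.name)
        assert back.layout.columns == ds.layout.columns
        assert back.ligand_ids == ds.ligand_ids
        assert np.array_equal(back.bit_matrix, ds.bit_matrix)
        assert np.array_equal(back.activities, ds.activities)


class TestBitSelection:
    @pytest.mark.parametrize("scheme,expected", [("ALL", 18), ("WO1", 16), ("WO3", 12)])
    def test_bits_per_scheme(self, scheme, expected, rng):
        ds = random_dataset(rng, n_residues=2)
        assert len(select_bits(ds, scheme).layout) == expected

    def test_all_is_identity(self, rng):
        ds = random_dataset(rng)
        assert select_bits(ds, "ALL") is ds

    def test_wo3_drops_exactly_any_bb_sc(self, rng):
        ds = random_dataset(rng, n_residues=2)
        out = select_bits(ds, "WO3")
        assert out.layout.interaction_types == ("Pol", "Hyd", "HBA", "HBD", "Aro", "Chg")
        assert out.layout.residues == ds.layout.residues

    def test_unknown_scheme(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            select_bits(random_dataset(rng), "WO2")

    def test_removing_absent_types_is_noop(self, rng):
        ds = random_dataset(rng, n_residues=2)
        once = select_bits(ds, "WO3")
        again = select_bits(once, "WO3")
        assert again.layout.columns == once.layout.columns


class TestFiltering:
    def test_res_drops_fully_silent_residue(self):
        cols = {f"ALA10:{t}": (0, 1, 1) for t in INTERACTION_TYPES}
        cols.update({f"GLY20:{t}": (0, 0, 0) for t in INTERACTION_TYPES})
        ds = make_dataset(cols, [1, 0, 1])
        out = filter_residues(ds)
        assert out.layout.residues == ("ALA10",)
        assert len(out.layout) == 9

    def test_res_keeps_residue_with_single_bit(self):
        cols = {f"ALA10:{t}": (1, 1, 1) for t in INTERACTION_TYPES}
        silent = {f"GLY20:{t}": (0, 0, 0) for t in INTERACTION_TYPES}
        silent["GLY20:Aro"] = (0, 0, 1)  # one ligand, one interaction
        cols.update(silent)
        ds = make_dataset(cols, [1, 0, 1])
        out = filter_residues(ds)
        assert out.layout.residues == ("ALA10", "GLY20")
        assert len(out.layout) == 18

    def test_res_identity_when_no_silent_residue(self, rng):
        ds = random_dataset(rng, density=0.9)
        assert filter_residues(ds) is ds

    def test_ints_keeps_exactly_established_columns(self):
        bits = {"ALA10:Any": (1, 1), "ALA10:BB": (0, 1), "ALA10:SC": (0, 0),
                "ALA10:Pol": (1, 0), "ALA10:Hyd": (0, 0), "ALA10:HBA": (1, 1),
                "ALA10:HBD": (0, 0), "ALA10:Aro": (0, 0), "ALA10:Chg": (0, 0)}
        ds = make_dataset(bits, [1, 0])
        out = filter_interactions(ds)
        assert out.layout.columns == ["ALA10:Any", "ALA10:BB", "ALA10:Pol", "ALA10:HBA"]
        assert np.array_equal(out.bit_matrix, np.array([[1, 0, 1, 1], [1, 1, 0, 1]]))

    def test_ints_errors_when_everything_silent(self):
        cols = {f"ALA10:{t}": (0, 0) for t in INTERACTION_TYPES}
        ds = make_dataset(cols, [1, 0])
        with pytest.raises(ValueError):
            filter_interactions(ds)

    def test_empty_dataset_rejected(self):
        ds = FingerprintDataset("e", BitLayout(("ALA10",)), ())
        with pytest.raises(ValueError):
            filter_residues(ds)

    def test_subset_chain_and_value_preservation(self, rng):
        """columns(INTS) subseteq columns(RES) subseteq columns(input);
        retained bits, ligand order and labels untouched."""
        for _ in range(50):
            ds = random_dataset(rng, n_ligands=4, n_residues=5, density=0.15)
            res, ints = filter_residues(ds), filter_interactions(ds)
            cin, cres, cints = (set(d.layout.columns) for d in (ds, res, ints))
            assert cints <= cres <= cin
            for out in (res, ints):
                assert out.ligand_ids == ds.ligand_ids
                assert np.array_equal(out.activities, ds.activities)
                idx = [ds.layout.columns.index(c) for c in out.layout.columns]
                assert np.array_equal(out.bit_matrix, ds.bit_matrix[:, idx])

    def test_selection_and_ints_commute(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, n_ligands=4, n_residues=4, density=0.2)
            try:
                first = filter_interactions(select_bits(ds, "WO3"))
                second = select_bits(filter_interactions(ds), "WO3")
            except ValueError:
                continue  # variant emptied
            assert first.layout.columns == second.layout.columns
            assert np.array_equal(first.bit_matrix, second.bit_matrix)

    def test_selection_first_res_is_subset_of_res_first(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, n_ligands=4, n_residues=4, density=0.2)
            try:
                first = filter_residues(select_bits(ds, "WO1"))
                second = select_bits(filter_residues(ds), "WO1")
            except ValueError:
                continue
            assert set(first.layout.columns) <= set(second.layout.columns)
            idx = [second.layout.columns.index(c) for c in first.layout.columns]
            assert np.array_equal(first.bit_matrix, second.bit_matrix[:, idx])

    def test_apply_filtering_dispatch(self, rng):
        ds = random_dataset(rng)
        assert apply_filtering(ds, "NO") is ds
        with pytest.raises(ValueError, match="rule"):
            apply_filtering(ds, "BOGUS")


def test_conform_fingerprint_projects_by_name(rng):
    ds = random_dataset(rng, n_residues=3)
    ref = ds.fingerprints[0]
    sub = select_bits(ds, "WO3")
    projected = conform_fingerprint(ref, ds.layout, sub.layout)
    idx = [ds.layout.columns.index(c) for c in sub.layout.columns]
    assert np.array_equal(projected.bits, ref.bits[idx])
    with pytest.raises(ValueError, match="absent"):
        conform_fingerprint(ds.fingerprints[0], sub.layout, ds.layout)
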
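import numpy as np
import pandas as pd
import pytest

from conftest import make_pm
from taacgh.profile_io import (CloneRecord, average_duplicate_positions,
                               harmonize_clone_map, impute_missing_lowess,
                               normalize_chromosome, preprocess,
                               read_profile_matrix)


# -------------------------------------------------------------------- reading

def test_toy_roundtrip(toy_files):
    pm = read_profile_matrix(toy_files["matrix"], toy_files["clone_map"],
                             toy_files["labels"])
    assert pm.n_clones == 3 and pm.n_patients == 2
    assert list(pm.clones["clone_id"]) == ["c1", "c2", "c3"]
    assert pm.values[0, 0] == pytest.approx(0.1)
    assert list(pm.patients["label"]) == ["lumA", "basal"]


def test_out_of_order_clones_sorted_by_genome_position(toy_files, tmp_path):
    (tmp_path / "clones2.tsv").write_text(
        "clone_id\tchromosome\tarm\tposition_bp\n"
        "c1\t2\tp\t500\n"
        "c2\t1\tq\t9000\n"
        "c3\t1\tp\t100\n")
    pm = read_profile_matrix(toy_files["matrix"], tmp_path / "clones2.tsv",
                             toy_files["labels"])
    assert list(pm.clones["clone_id"]) == ["c3", "c2", "c1"]
    assert pm.values[0, 1] == pytest.approx(0.0)  # c3 row moved with its values


def test_unlabelled_patient_is_named_in_error(toy_files, tmp_path):
    (tmp_path / "labels2.tsv").write_text("patient_id\tsubtype\npA\tlumA\n")
    with pytest.raises(ValueError, match="pB"):
        read_profile_matrix(toy_files["matrix"], toy_files["clone_map"],
                            tmp_path / "labels2.tsv")


def test_unmapped_clone_reported_with_count(toy_files, tmp_path):
    (tmp_path / "clones3.tsv").write_text(
        "clone_id\tchromosome\tarm\tposition_bp\nc1\t1\tp\t1000\nc2\t1\tp\t2000\n")
    with pytest.raises(ValueError, match="1 matrix clones"):
        read_profile_matrix(toy_files["matrix"], tmp_path / "clones3.tsv",
                            toy_files["labels"])


def test_missing_file_raises(toy_files, tmp_path):
    with pytest.raises(FileNotFoundError):
        read_profile_matrix(tmp_path / "nope.tsv", toy_files["clone_map"],
                            toy_files["labels"])


def test_chromosome_dialects_normalized():
    assert normalize_chromosome("chr17") == "17"
    assert normalize_chromosome("17") == "17"
    assert normalize_chromosome("chrX") == "X"


# -------------------------------------------------------------- harmonization

def _ref(*records):
    return [CloneRecord(*r) for r in records]


def test_nearby_reference_position_updates_clone():
    # ERBB2-region clone: reported 35,065,321 on 17q, reference 37,812,853
    pm = make_pm("17", "q", [35_065_321, 40_000_000], np.zeros((2, 4)))
    ref = _ref(("cl0", "17", "q", 37_812_853), ("cl1", "17", "q", 40_000_000))
    out, rep = harmonize_clone_map(pm, ref, max_distance_bp=5_000_000)
    assert out.n_clones == 2
    assert out.clones.loc[out.clones["clone_id"] == "cl0", "position_bp"].iloc[0] \
        == 37_812_853
    assert rep.n_updated == 1 and rep.n_removed == 0


def test_chromosome_mismatch_removed_and_counted():
    pm = make_pm("17", "q", [1000, 2000], np.zeros((2, 4)))
    ref = _ref(("cl0", "3", "q", 1000), ("cl1", "17", "q", 2000))
    out, rep = harmonize_clone_map(pm, ref)
    assert list(out.clones["clone_id"]) == ["cl1"]
    assert rep.n_removed_chrom_mismatch == 1


def test_far_reference_position_removed():
    pm = make_pm("17", "q", [1_000_000, 2_000_000], np.zeros((2, 4)))
    ref = _ref(("cl0", "17", "q", 50_000_000), ("cl1", "17", "q", 2_000_000))
    out, rep = harmonize_clone_map(pm, ref)
    assert rep.n_removed_far == 1 and out.n_clones == 1


def test_absent_reference_entry_removed():
    pm = make_pm("17", "q", [1000, 2000], np.zeros((2, 4)))
    out, rep = harmonize_clone_map(pm, _ref(("cl1", "17", "q", 2000)))
    assert rep.n_removed_no_position == 1 and out.n_clones == 1


def test_order_inconsistent_clone_removed():
    pm = make_pm("17", "q", [1000, 2000, 3000, 4000], np.zeros((4, 4)))
    ref = _ref(("cl0", "17", "q", 1000), ("cl1", "17", "q", 3500),
               ("cl2", "17", "q", 3000), ("cl3", "17", "q", 4000))
    out, rep = harmonize_clone_map(pm, ref)
    assert rep.n_removed_order_inconsistent == 1
    assert "cl1" not in set(out.clones["clone_id"])
    assert list(out.clones["position_bp"]) == [1000, 3000, 4000]


def test_identity_reference_is_fixed_point_and_idempotent():
    rng = np.random.default_rng(0)
    pm = make_pm("5", "p", [100, 900, 1700, 2400], rng.normal(size=(4, 4)))
    ref = [CloneRecord(r.clone_id, r.chromosome, r.arm, int(r.position_bp))
           for r in pm.clones.itertuples()]
    out1, rep1 = harmonize_clone_map(pm, ref)
    assert rep1.n_removed == 0 and rep1.n_updated == 0
    out2, rep2 = harmonize_clone_map(out1, ref)
    assert rep2.n_removed == 0
    assert np.array_equal(out1.values, out2.values)
    assert out1.clones.equals(out2.clones)


def test_report_counts_partition_the_input():
    pm = make_pm("17", "q", [1000, 2000, 3000, 4000, 5000], np.zeros((5, 2)))
    ref = _ref(("cl0", "17", "q", 1000), ("cl1", "2", "q", 2000),
               ("cl2", "17", "q", 90_000_000), ("cl4", "17", "q", 5000))
    out, rep = harmonize_clone_map(pm, ref)
    assert rep.n_input == out.n_clones + rep.n_removed


def test_empty_reference_rejected():
    pm = make_pm("1", "p", [1000], np.zeros((1, 2)))
    with pytest.raises(ValueError):
        harmonize_clone_map(pm, [])


# -------------------------------------------------------- duplicate averaging

def test_duplicates_averaged_per_patient():
    pm = make_pm("1", "p", [1000, 1000, 2000],
                 np.array([[0.2, 1.0], [0.4, 3.0], [0.5, 0.5]]))
    out = average_duplicate_positions(pm)
    assert out.n_clones == 2
    assert out.values[0, 0] == pytest.approx(0.3)
    assert out.values[0, 1] == pytest.approx(2.0)


def test_no_duplicates_is_fixed_point():
    pm = make_pm("1", "p", [1000, 2000], np.array([[0.1, 0.2], [0.3, 0.4]]))
    out = average_duplicate_positions(pm)
    assert np.array_equal(out.values, pm.values)
    assert out.clones.equals(pm.clones.reset_index(drop=True))


def test_duplicate_with_missing_value_keeps_observed_mean():
    pm = make_pm("1", "p", [1000, 1000], np.array([[0.2, np.nan], [np.nan, 0.6]]))
    out = average_duplicate_positions(pm)
    # mean over the non-missing subset of each patient's duplicate entries
    assert out.values[0, 0] == pytest.approx(0.2)
    assert out.values[0, 1] == pytest.approx(0.6)


# ------------------------------------------------------------------ imputation

def test_imputation_leaves_complete_matrix_unchanged():
    rng = np.random.default_rng(1)
    pm = make_pm("1", "q", np.arange(10) * 1000, rng.normal(size=(10, 3)))
    out, rep = impute_missing_lowess(pm)
    assert np.array_equal(out.values, pm.values)
    assert rep.n_imputed == 0


def test_constant_profile_imputes_constant():
    vals = np.full((8, 2), 0.42)
    vals[3, 0] = np.nan
    pm = make_pm("1", "q", np.arange(8) * 1000, vals)
    out, rep = impute_missing_lowess(pm, span=0.6)
    assert out.values[3, 0] == pytest.approx(0.42, abs=1e-9)
    assert rep.n_imputed == 1


def test_linear_profile_imputed_on_the_line():
    pos = np.arange(12) * 1_000_000
    a = 3e-8
    vals = np.tile(a * pos, (2, 1)).T
    vals[5, 1] = np.nan
    pm = make_pm("1", "q", pos, vals)
    out, _ = impute_missing_lowess(pm, span=0.5)
    # local linear regression reproduces exactly linear data
    assert out.values[5, 1] == pytest.approx(a * pos[5], rel=1e-6)


def test_imputation_changes_only_missing_entries():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(15, 3))
    miss = [(2, 0), (7, 2), (11, 1)]
    for i, j in miss:
        vals[i, j] = np.nan
    pm = make_pm("1", "q", np.arange(15) * 1000, vals)
    out, rep = impute_missing_lowess(pm)
    assert rep.n_imputed == 3
    observed = ~np.isnan(vals)
    assert np.array_equal(out.values[observed], vals[observed])
    assert not np.isnan(out.values).any()


def test_too_few_observations_names_the_stratum():
    vals = np.full((4, 1), np.nan)
    vals[0, 0] = 0.1
    vals[1, 0] = 0.2
    pm = make_pm("9", "p", np.arange(4) * 1000, vals)
    with pytest.raises(ValueError, match="chromosome 9.*p0"):
        impute_missing_lowess(pm)


def test_preprocess_composes_all_stages():
    vals = np.array([[0.2, 0.1], [0.4, np.nan], [0.1, 0.3],
                     [0.0, 0.2], [np.nan, 0.1], [0.2, 0.0]])
    pm = make_pm("1", "q", [1000, 1000, 2000, 3000, 4000, 5000], vals)
    out, rep = preprocess(pm)
    assert out.n_clones == 5
    assert rep.n_duplicates_averaged == 1
    assert not np.isnan(out.values).any()
    pos = out.clones["position_bp"].to_numpy()
    assert np.all(np.diff(pos) > 0)  # strictly increasing after preprocessing
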
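import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blocksurv import (
    BlockedDataset,
    BlockStructure,
    LoadError,
    OutcomeError,
    StructureError,
    SurvivalOutcome,
    VariantParams,
    BlocksurvError,
    block_mtry,
    load_blocked_dataset,
    save_blocked_dataset,
)


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "time,status",
    [
        ([1.0, 0.0], [1, 0]),           # non-positive time
        ([1.0, 2.0], [1, 2]),           # status outside {0,1}
        ([1.0, 2.0, 3.0], [1, 0]),      # length mismatch
        ([1.0, np.nan], [1, 0]),        # non-finite time
    ],
)
def test_outcome_validation_rejects_bad_input(time, status):
    with pytest.raises(OutcomeError):
        SurvivalOutcome(np.asarray(time), np.asarray(status))


def test_outcome_counts_events():
    out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
    assert out.n == 3 and out.n_events == 2


# ---------------------------------------------------------------------------
# block structure
# ---------------------------------------------------------------------------


def test_structure_rejects_overlap_and_gap():
    with pytest.raises(StructureError, match="more than one block"):
        BlockStructure(("a", "b"), (np.array([0, 1]), np.array([1, 2])))
    with pytest.raises(StructureError, match="unassigned"):
        BlockStructure(("a", "b"), (np.array([0, 1]), np.array([3])))


def test_structure_clinical_designation():
    s = BlockStructure.from_sizes([2, 3], ["clin", "rna"], clinical_block="clin")
    assert s.clinical_index == 0
    with pytest.raises(StructureError):
        BlockStructure.from_sizes([2, 3], ["clin", "rna"], clinical_block="nope")


def test_block_of_var_roundtrip():
    s = BlockStructure.from_sizes([2, 3, 1])
    assert list(s.block_of_var) == [0, 0, 1, 1, 1, 2]


# ---------------------------------------------------------------------------
# block_mtry
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sizes,expected_k,expected_total",
    [
        ((4, 9, 16), (2, 3, 4), 9),
        ((5,), (3,), 3),
        ((1, 10000), (1, 100), 101),
    ],
)
def test_block_mtry_examples(sizes, expected_k, expected_total):
    k, total = block_mtry(BlockStructure.from_sizes(sizes))
    assert tuple(k) == expected_k
    assert total == expected_total


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=6))
def test_block_mtry_bounds_and_monotonicity(sizes):
    k, total = block_mtry(BlockStructure.from_sizes(sizes))
    assert np.all(k >= 1) and np.all(k <= np.asarray(sizes))
    assert total == k.sum()
    bigger, _ = block_mtry(BlockStructure.from_sizes([s + 3 for s in sizes]))
    assert np.all(bigger >= k)


# ---------------------------------------------------------------------------
# variant params
# ---------------------------------------------------------------------------


def test_varprob_constraint_checked_against_structure():
    s = BlockStructure.from_sizes([10, 90])
    ok = VariantParams("varprob", [0.055, 0.005])
    ok.validate_for(s)  # 10*0.055 + 90*0.005 = 1
    bad = VariantParams("varprob", [0.05, 0.005])
    with pytest.raises(BlocksurvError, match="p_m v_m"):
        bad.validate_for(s)


def test_weights_require_max_one():
    VariantParams("blockforest", [0.4, 1.0])
    with pytest.raises(BlocksurvError):
        VariantParams("splitweights", [0.4, 0.9])
    with pytest.raises(BlocksurvError):
        VariantParams("blockvarsel", [0.0, 1.0])


def test_randomblock_probs_sum_to_one():
    VariantParams("randomblock", [0.6, 0.3, 0.1])
    with pytest.raises(BlocksurvError):
        VariantParams("randomblock", [0.6, 0.3, 0.2])


def test_rsf_collapses_to_integer_mtry():
    p = VariantParams("rsf", [7])
    assert p.mtry == 7
    with pytest.raises(BlocksurvError):
        VariantParams("rsf", [2.5])


def test_variant_name_aliases():
    assert VariantParams("block_forest", [1.0]).variant == "blockforest"
    with pytest.raises(BlocksurvError):
        VariantParams("bogus", [1.0])


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _write_triple(tmp_path, matrix_rows, header="a,b,c,d,e",
                  blocks=None, outcome="time,status\n1,1\n2,0\n3,1\n4,1\n"):
    mpath = tmp_path / "m.csv"
    mpath.write_text(header + "\n" + matrix_rows)
    opath = tmp_path / "o.csv"
    opath.write_text(outcome)
    bpath = tmp_path / "b.json"
    if blocks is None:
        blocks = {"clin": ["a", "b"], "rna": ["c", "d", "e"], "clinical": "clin"}
    bpath.write_text(json.dumps(blocks))
    return mpath, opath, bpath


def test_load_blocked_dataset_basic(tmp_path):
    rows = "\n".join("1,2,3,4,5" for _ in range(4))
    m, o, b = _write_triple(tmp_path, rows)
    data = load_blocked_dataset(m, o, b)
    assert data.structure.M == 2
    assert tuple(data.structure.sizes) == (2, 3)
    assert data.structure.clinical_block == "clin"
    assert data.n == 4 and data.p == 5


def test_load_reports_missing_cell_coordinates(tmp_path):
    rows = "1,2,3,4,5\n1,,3,4,5\n1,2,3,4,5\n1,2,3,4,5"
    m, o, b = _write_triple(tmp_path, rows)
    with pytest.raises(LoadError, match=r"row 2.*'b'"):
        load_blocked_dataset(m, o, b)


def test_load_rejects_unassigned_column(tmp_path):
    rows = "\n".join("1,2,3,4,5" for _ in range(4))
    blocks = {"clin": ["a", "b"], "rna": ["c", "d"]}
    m, o, b = _write_triple(tmp_path, rows, blocks=blocks)
    with pytest.raises(StructureError, match="column 5.*unassigned"):
        load_blocked_dataset(m, o, b)


def test_load_index_ranges_and_column_reordering(tmp_path):
    rows = "\n".join("1,2,3,4,5" for _ in range(4))
    blocks = {"rna": ["3-5"], "clin": ["a", "b"]}
    m, o, b = _write_triple(tmp_path, rows, blocks=blocks)
    data = load_blocked_dataset(m, o, b)
    # config block order defines the column order of X
    assert data.structure.names == ("rna", "clin")
    assert data.var_names == ("c", "d", "e", "a", "b")


def test_load_id_based_row_alignment(tmp_path):
    mpath = tmp_path / "m.csv"
    mpath.write_text("id,a,b\ns1,1,10\ns2,2,20\ns3,3,30\n")
    opath = tmp_path / "o.csv"
    opath.write_text("id,time,status\ns3,3,1\ns1,1,1\ns2,2,0\n")
    bpath = tmp_path / "b.json"
    bpath.write_text(json.dumps({"all": ["a", "b"]}))
    data = load_blocked_dataset(mpath, opath, bpath)
    assert list(data.outcome.time) == [1.0, 2.0, 3.0]
    assert list(data.outcome.status) == [1, 0, 1]


def test_save_load_roundtrip_bit_exact(tmp_path, tiny_data):
    paths = (tmp_path / "m.csv", tmp_path / "o.csv", tmp_path / "b.json")
    save_blocked_dataset(tiny_data, *paths)
    back = load_blocked_dataset(*paths)
    np.testing.assert_array_equal(back.X, tiny_data.X)
    np.testing.assert_array_equal(back.outcome.time, tiny_data.outcome.time)
    np.testing.assert_array_equal(back.outcome.status, tiny_data.outcome.status)
    assert back.structure.names == tiny_data.structure.names
    assert back.structure.clinical_block == tiny_data.structure.clinical_block
    for a, b in zip(back.structure.columns, tiny_data.structure.columns):
        np.testing.assert_array_equal(a, b)


def test_dataset_rejects_nan_and_shape_mismatch(tiny_data):
    X = tiny_data.X.copy()
    X[3, 5] = np.nan
    with pytest.raises(LoadError, match="row 4, column 6"):
        BlockedDataset(X, tiny_data.outcome, tiny_data.structure)
    with pytest.raises(StructureError):
        BlockedDataset(tiny_data.X[:, :10], tiny_data.outcome, tiny_data.structure)


def test_subset_columns_preserves_block_order(tiny_data):
    cols = np.concatenate([tiny_data.structure.columns[0][:2],
                           tiny_data.structure.columns[2][:5]])
    sub = tiny_data.subset_columns(cols)
    assert sub.structure.names == ("clinical", "mutation")
    assert tuple(sub.structure.sizes) == (2, 5)
    assert sub.structure.clinical_block == "clinical"
    np.testing.assert_array_equal(sub.X, tiny_data.X[:, cols])
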
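"""IO round trips, masking/filtering rules, and design validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acetylpipe.simulate import printed_twelveplex_design
from acetylpipe.tables import (
    DesignError,
    FeatureTable,
    ImpurityMatrix,
    IntegrityError,
    PlexDesign,
    SchemaError,
    read_design,
    read_feature_table,
    read_impurity_matrix,
    read_results,
    write_design,
    write_feature_table,
    write_results,
)
from conftest import make_feature_table


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def _toy_tsv(tmp_path, rows, header=None):
    header = header or (
        "Feature ID\tProtein group\tPosition\tMultiplicity\t"
        "Reporter intensity corrected 126C plex1\t"
        "Reporter intensity corrected 127C plex1"
    )
    path = tmp_path / "toy.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def test_zero_intensity_is_masked_on_read(tmp_path):
    path = _toy_tsv(
        tmp_path,
        ["A_K5_m1\tA\t5\t1\t100\t0",
         "B_K9_m1\tB\t9\t1\t200\t300",
         "C_K2_m2\tC\t2\t2\t50\t60"],
    )
    t = read_feature_table(path, level="site")
    assert len(t.feature_ids) == 3
    assert t.mask.loc["A_K5_m1", ("plex1", "127C")]
    assert t.n_unmasked() == 5


def test_contaminant_rows_are_dropped(tmp_path):
    header = (
        "Feature ID\tProtein group\tPotential contaminant\t"
        "Reporter intensity corrected 126C plex1"
    )
    path = _toy_tsv(
        tmp_path,
        ["A_K5_m1\tA\t\t100", "CON_K1_m1\tCON\t+\t999", "B_K9_m1\tB\t\t200"],
        header=header,
    )
    with pytest.warns(UserWarning, match="contaminant"):
        t = read_feature_table(path, level="site")
    assert list(t.feature_ids) == ["A_K5_m1", "B_K9_m1"]


def test_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("Feature ID\tReporter intensity corrected 126C p1\nA\t1\n")
    with pytest.raises(SchemaError, match="Protein group"):
        read_feature_table(path, level="site")


def test_duplicate_feature_id_rejected(tmp_path):
    path = _toy_tsv(tmp_path, ["A_K5_m1\tA\t5\t1\t1\t2", "A_K5_m1\tA\t5\t1\t3\t4"])
    with pytest.raises(IntegrityError, match="A_K5_m1"):
        read_feature_table(path, level="site")


def test_write_read_round_trip_is_identity(tmp_path):
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 1e6, size=(8, 4))
    vals[2, 1] = np.nan
    # quantize to the declared output precision so the trip is exact
    vals = np.vectorize(lambda x: float(f"{x:.6g}") if np.isfinite(x) else x)(vals)
    t = make_feature_table(vals, ["plex1", "plex2"], ["126C", "127C"])
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_feature_table(t, p1)
    back = read_feature_table(p1, level="site")
    assert back.mask.to_numpy().tolist() == t.mask.to_numpy().tolist()
    np.testing.assert_array_equal(
        back.values.to_numpy()[~back.mask.to_numpy()],
        t.values.to_numpy()[~t.mask.to_numpy()],
    )
    write_feature_table(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_log_space_flag_survives_round_trip(tmp_path):
    t = make_feature_table([[1.5, -2.0]], ["plex1"], ["126C", "127C"],
                           log_space=True)
    path = tmp_path / "log.tsv"
    write_feature_table(t, path)
    assert path.read_text().startswith("# log_space=true")
    back = read_feature_table(path, level="site")
    assert back.log_space
    # negative log2 values are legitimate and must not be masked
    assert back.values.iloc[0, 1] == -2.0


def test_empty_table_writes_header_only(tmp_path):
    t = make_feature_table(np.empty((0, 2)), ["plex1"], ["126C", "127C"],
                           feature_ids=[], protein_groups=[])
    path = tmp_path / "empty.tsv"
    write_feature_table(t, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2  # comment + header


def test_reading_never_invents_values(tmp_path):
    path = _toy_tsv(tmp_path, ["A_K5_m1\tA\t5\t1\t100\t", "B_K9_m1\tB\t9\t1\t\t"])
    t = read_feature_table(path, level="site")
    assert t.n_unmasked() == 1  # one numeric field in the file


# ---------------------------------------------------------------------------
# Plex design
# ---------------------------------------------------------------------------

PRINTED_LABELS = [
    ("126C", "wildtype"), ("127C", "MS275_6h"), ("128C", "MS275_24h"),
    ("129C", "WT_HDAC1_CI"), ("130C", "WT_HDAC2_CI"), ("131N", "HDAC1_KO"),
    ("131C", "WT_HDAC3_CI"), ("132N", "HDAC2_KO"), ("132C", "WT_HDAC8_CI"),
    ("133N", "HDAC3_KO"), ("133C", "REF"), ("134N", "HDAC8_KO"),
]


def test_printed_twelve_label_assignment_parses_with_ref_133C(tmp_path):
    design = printed_twelveplex_design(3)
    path = tmp_path / "design.tsv"
    write_design(design, path)
    back = read_design(path)
    assert back.plexes == ["plex1", "plex2", "plex3"]
    for plex in back.plexes:
        assert back.reference_channel(plex) == "133C"
    assert dict(zip(back.table["channel"][:12], back.table["condition"][:12])) == dict(
        PRINTED_LABELS
    )
    assert "wildtype" in back.conditions and "REF" not in back.conditions


def test_two_reference_channels_in_one_plex_rejected():
    df = pd.DataFrame(
        {
            "plex": ["p1"] * 3,
            "channel": ["126C", "127C", "128C"],
            "condition": ["wildtype", "REF", "REF"],
            "replicate": [1, 1, 1],
            "is_reference": [False, True, True],
        }
    )
    with pytest.raises(DesignError, match="reference"):
        PlexDesign(df)


def test_minimal_design_parses(tmp_path):
    path = tmp_path / "mini.tsv"
    path.write_text(
        "plex\tchannel\tcondition\treplicate\tis_reference\n"
        "p1\t126C\twildtype\t1\tfalse\n"
        "p1\t133C\tREF\t1\ttrue\n"
    )
    d = read_design(path)
    assert d.plexes == ["p1"] and d.reference_channel("p1") == "133C"


def _valid_design_df():
    rows = []
    for p in ("p1", "p2"):
        for ch, cond, ref in (("126C", "wildtype", False), ("127C", "ko", False),
                              ("133C", "REF", True)):
            rows.append({"plex": p, "channel": ch, "condition": cond,
                         "replicate": 1 if p == "p1" else 2, "is_reference": ref})
    return pd.DataFrame(rows)


CORRUPTIONS = {
    "duplicate_channel": lambda df, rng: pd.concat(
        [df, df.iloc[[rng.integers(len(df))]]], ignore_index=True
    ),
    "second_reference": lambda df, rng: df.assign(
        is_reference=df["is_reference"] | (df.index == 0)
    ),
    "no_reference": lambda df, rng: df.assign(is_reference=False),
    "duplicate_condition_replicate": lambda df, rng: df.assign(
        condition=np.where(df.index == 1, "wildtype", df["condition"])
    ),
    "missing_baseline": lambda df, rng: df.assign(
        condition=df["condition"].replace("wildtype", "other")
    ),
}


@settings(max_examples=30, derandomize=True)
@given(kind=st.sampled_from(sorted(CORRUPTIONS)), seed=st.integers(0, 10_000))
def test_design_validation_rejects_every_invariant_breaking_corruption(kind, seed):
    rng = np.random.default_rng(seed)
    df = CORRUPTIONS[kind](_valid_design_df(), rng)
    with pytest.raises((DesignError, IntegrityError)):
        PlexDesign(df)


# ---------------------------------------------------------------------------
# Impurity matrix
# ---------------------------------------------------------------------------


def _impurity_csv(tmp_path, text):
    path = tmp_path / "imp.csv"
    path.write_text(text)
    return path


def test_all_zero_offsets_give_identity(tmp_path):
    path = _impurity_csv(
        tmp_path, "label,-1,+1\na,0,0\nb,0,0\nc,0,0\n"
    )
    m = read_impurity_matrix(path)
    np.testing.assert_array_equal(m.coefficients, np.eye(3))


def test_single_offset_hand_assembly(tmp_path):
    # 5% of label a's signal observed in its +1 neighbour b
    path = _impurity_csv(tmp_path, "label,-1,+1\na,0,5\nb,0,0\n")
    m = read_impurity_matrix(path)
    expected = np.array([[0.95, 0.0], [0.05, 1.0]])
    np.testing.assert_allclose(m.coefficients, expected)


def test_off_ladder_offset_discarded_with_warning(tmp_path):
    path = _impurity_csv(tmp_path, "label,-1,+1\na,3,0\nb,0,4\n")
    with pytest.warns(UserWarning, match="outside the label ladder"):
        m = read_impurity_matrix(path)
    # the discarded mass stays unaccounted: columns sum to < 1
    np.testing.assert_allclose(m.coefficients.sum(axis=0), [0.97, 0.96])


def test_negative_offset_rejected(tmp_path):
    path = _impurity_csv(tmp_path, "label,-1,+1\na,-1,0\nb,0,0\n")
    with pytest.raises(ValueError, match="negative"):
        read_impurity_matrix(path)


def test_column_sum_above_one_rejected():
    with pytest.raises(ValueError, match="sums to"):
        ImpurityMatrix(["a", "b"], np.array([[0.9, 0.0], [0.2, 1.0]]))


# ---------------------------------------------------------------------------
# Results IO
# ---------------------------------------------------------------------------


def test_results_round_trip_and_stable_ordering(tmp_path, results_frame):
    p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
    write_results(results_frame, p1)
    shuffled = results_frame.sample(frac=1, random_state=1)
    write_results(shuffled, p2)
    assert p1.read_bytes() == p2.read_bytes()  # permutation invariance
    back = read_results(p1)
    assert list(back["feature_id"]) == sorted(back["feature_id"])
    merged = back.set_index(["feature_id", "contrast"])["log2fc"]
    orig = results_frame.set_index(["feature_id", "contrast"])["log2fc"]
    np.testing.assert_allclose(merged.reindex(orig.index), orig, rtol=1e-6)


def test_empty_results_write_header_only(tmp_path):
    empty = pd.DataFrame(columns=["feature_id", "contrast", "log2fc", "t_mod",
                                  "p", "padj", "n_used", "call"])
    path = tmp_path / "empty.tsv"
    write_results(empty, path)
    assert path.read_text().strip().count("\n") == 0
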
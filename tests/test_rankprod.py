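"""Rank-product statistic, pfp estimation and fold-change summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csctargets import class_fold_changes, pfp_filter, rank_product
from csctargets.core import ConfigError
from csctargets.rankprod import DEResult

from conftest import make_study
from _oracles import oracle_exhaustive_pfp, oracle_rank_product


def _two_class_study(a_cols, b_cols):
    values = {}
    classes = {}
    for i, col in enumerate(a_cols):
        values[f"a{i}"] = col
        classes[f"a{i}"] = "sCSC"
    for i, col in enumerate(b_cols):
        values[f"b{i}"] = col
        classes[f"b{i}"] = "dCSC"
    return make_study(values, classes)


def test_gene_ranked_first_everywhere_has_rp_one():
    # g1 is up 4-fold (2 log2 units) in every comparison
    a = np.array([[10.0, 10.2], [5.0, 5.1], [6.0, 6.2], [7.0, 7.1], [4.0, 4.1]])
    b = a.copy()
    b[0] -= 2.0
    study = _two_class_study(a.T, b.T)
    de = rank_product(study, "sCSC", "dCSC", n_perm=5, seed=0)
    assert de.table.loc["g1", "RP_up"] == pytest.approx(1.0)
    assert de.table.loc["g1", "log2fc"] == pytest.approx(2.0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.integers(0, 10_000),
    st.integers(2, 6),
    st.integers(2, 3),
    st.integers(2, 3),
)
def test_rank_product_matches_bruteforce_oracle(seed, n_genes, n_a, n_b):
    rng = np.random.default_rng(seed)
    a = rng.normal(8, 1, size=(n_genes, n_a)).round(2)
    b = rng.normal(8, 1, size=(n_genes, n_b)).round(2)
    study = _two_class_study(a.T, b.T)
    de = rank_product(study, "sCSC", "dCSC", n_perm=1, seed=0)
    np.testing.assert_allclose(de.table["RP_up"], oracle_rank_product(a, b, "up"), rtol=1e-12)
    np.testing.assert_allclose(de.table["RP_down"], oracle_rank_product(a, b, "down"), rtol=1e-12)


def test_exhaustive_pfp_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    a = rng.normal(8, 1, size=(2, 2)).round(2)
    b = rng.normal(8, 1, size=(2, 2)).round(2)
    study = _two_class_study(a.T, b.T)
    de = rank_product(study, "sCSC", "dCSC", n_perm=1, seed=0, exhaustive=True)
    np.testing.assert_allclose(de.table["pfp_up"], oracle_exhaustive_pfp(a, b, "up"), rtol=1e-12)
    np.testing.assert_allclose(
        de.table["pfp_down"], oracle_exhaustive_pfp(a, b, "down"), rtol=1e-12
    )


def test_exhaustive_pfp_invariant_to_gene_relabeling():
    rng = np.random.default_rng(5)
    a = rng.normal(8, 1, size=(3, 2))
    b = rng.normal(8, 1, size=(3, 2))
    de = rank_product(_two_class_study(a.T, b.T), "sCSC", "dCSC", exhaustive=True)
    perm = [2, 0, 1]
    de_perm = rank_product(
        _two_class_study(a[perm].T, b[perm].T), "sCSC", "dCSC", exhaustive=True
    )
    np.testing.assert_allclose(
        de.table["pfp_up"].to_numpy()[perm], de_perm.table["pfp_up"].to_numpy(), rtol=1e-12
    )
    np.testing.assert_allclose(
        de.table["RP_up"].to_numpy()[perm], de_perm.table["RP_up"].to_numpy(), rtol=1e-12
    )


def test_raising_class_a_values_never_worsens_rp_up():
    rng = np.random.default_rng(1)
    a = rng.normal(8, 1, size=(6, 3))
    b = rng.normal(8, 1, size=(6, 3))
    base = rank_product(_two_class_study(a.T, b.T), "sCSC", "dCSC", n_perm=1, seed=0)
    a2 = a.copy()
    a2[2] += 1.5
    bumped = rank_product(_two_class_study(a2.T, b.T), "sCSC", "dCSC", n_perm=1, seed=0)
    assert bumped.table.loc["g3", "RP_up"] <= base.table.loc["g3", "RP_up"]


def test_pfp_seeded_reproducibility():
    rng = np.random.default_rng(2)
    a = rng.normal(8, 1, size=(40, 4))
    b = rng.normal(8, 1, size=(40, 4))
    study = _two_class_study(a.T, b.T)
    d1 = rank_product(study, "sCSC", "dCSC", n_perm=50, seed=11)
    d2 = rank_product(study, "sCSC", "dCSC", n_perm=50, seed=11)
    pd.testing.assert_frame_equal(d1.table, d2.table)


def test_rank_product_rejects_missing_class_and_bad_nperm():
    study = _two_class_study(np.ones((2, 2)), np.ones((2, 2)))
    with pytest.raises(ConfigError):
        rank_product(study, "sCSC", "tumor")
    with pytest.raises(ConfigError):
        rank_product(study, "sCSC", "dCSC", n_perm=0)


# -- pfp_filter -------------------------------------------------------------
def _de_from(pfp_up, rp_up):
    table = pd.DataFrame(
        {
            "RP_up": rp_up,
            "pfp_up": pfp_up,
            "RP_down": rp_up,
            "pfp_down": pfp_up,
            "log2fc": 0.0,
        },
        index=[f"g{i + 1}" for i in range(len(pfp_up))],
    )
    return DEResult(table, "sCSC", "dCSC", 1, 1)


def test_pfp_filter_threshold_semantics():
    de = _de_from([0.05, 0.2, 0.10], [2.0, 1.0, 3.0])
    assert pfp_filter(de, cutoff=0.1, direction="up") == ["g1", "g3"]
    assert pfp_filter(de, cutoff=1.0, direction="up") == ["g2", "g1", "g3"]
    empty = _de_from([], [])
    assert pfp_filter(empty, cutoff=0.1, direction="up") == []
    with pytest.raises(ConfigError):
        pfp_filter(de, cutoff=0.1, direction="sideways")
    with pytest.raises(ConfigError):
        pfp_filter(de, cutoff=0.0)


# -- class_fold_changes -----------------------------------------------------
def test_fold_change_identities_and_antisymmetry():
    study = make_study(
        {"a1": [5.0, 8.0], "a2": [5.0, 8.0], "n1": [5.0, 7.0], "n2": [5.0, 7.0]},
        {"a1": "sCSC", "a2": "sCSC", "n1": "normal", "n2": "normal"},
    )
    fc = class_fold_changes(study, "sCSC", ["normal"])
    assert fc.loc["g1", "log2fc_normal"] == pytest.approx(0.0)
    assert fc.loc["g1", "fc_normal"] == pytest.approx(1.0)
    assert fc.loc["g2", "log2fc_normal"] == pytest.approx(1.0)
    rev = class_fold_changes(study, "normal", ["sCSC"])
    assert rev.loc["g2", "log2fc_sCSC"] == pytest.approx(-1.0)
    with pytest.raises(ConfigError):
        class_fold_changes(study, "sCSC", ["tumor"])


def test_fold_change_recovers_planted_two_fold():
    from csctargets import StudyConfig, gen_expression_study

    cfg = StudyConfig(
        seed=6, n_genes=400, n_planted_targets=20, planted_log2fc=1.0,
        batch_shift_sd=0.0, noise_sd=0.5,
        tissue_class_sizes={"sCSC": 8, "normal": 8},
    )
    study, _, truth = gen_expression_study(cfg)
    fc = class_fold_changes(study, "sCSC", ["normal"])
    se = 3 * cfg.noise_sd * np.sqrt(2 / 8)
    planted = fc.loc[truth.planted_target_ids, "log2fc_normal"]
    assert np.all(np.abs(planted - 1.0) < se)
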
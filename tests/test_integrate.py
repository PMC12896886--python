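"""Probe mapping, EB batch adjustment, medoid/MAD pruning, PCA diagnostics."""

import numpy as np
import pandas as pd
import pytest

from csctargets import (
    BatchDesign,
    ConfoundingError,
    StudyConfig,
    combat_adjust,
    gen_expression_study,
    map_probes,
    medoid_mad_prune,
    pca_project,
)
from csctargets.core import ConfigError, DataError

from conftest import make_study


# -- map_probes -------------------------------------------------------------
def _u133_study():
    return make_study(
        {"s1": [4.0, 6.0, 2.0], "s2": [4.2, 6.2, 2.2]},
        {"s1": "tumor", "s2": "tumor"},
    )


def test_map_probes_identity():
    study = _u133_study()
    pm = pd.DataFrame({"source": ["g1", "g2", "g3"], "target": ["g1", "g2", "g3"]})
    mapped, report = map_probes(study, pm)
    pd.testing.assert_frame_equal(
        mapped.values.sort_index(), study.values.sort_index(), check_names=False
    )
    assert report.n_unmapped == 0 and report.n_collisions == 0


def test_map_probes_collision_keeps_higher_mean_source():
    study = _u133_study()
    pm = pd.DataFrame({"source": ["g1", "g2"], "target": ["T", "T"]})
    mapped, report = map_probes(study, pm)
    assert list(mapped.probe_ids) == ["T"]
    assert mapped.values.loc["T", "s1"] == 6.0  # g2 has the higher mean
    assert report.n_collisions == 1 and report.collision_losers == ["g1"]


def test_map_probes_counts_unmapped_and_rejects_empty_overlap():
    study = _u133_study()
    pm = pd.DataFrame({"source": ["g1"], "target": ["T1"]})
    mapped, report = map_probes(study, pm)
    assert report.n_unmapped == 2
    with pytest.raises(DataError):
        map_probes(study, pd.DataFrame({"source": ["zz"], "target": ["T"]}))


# -- combat_adjust ----------------------------------------------------------
def test_combat_single_batch_is_identity():
    cfg = StudyConfig(seed=0, n_genes=100, platform_of_dataset={"d1": "HuGene1.0ST"})
    study, _, _ = gen_expression_study(cfg)
    adjusted, _ = combat_adjust(study, BatchDesign.from_study(study))
    assert np.abs(adjusted.values.to_numpy() - study.values.to_numpy()).max() < 1e-8


def test_combat_removes_planted_batch_separation():
    cfg = StudyConfig(seed=5, n_genes=1000)
    study, _, _ = gen_expression_study(cfg)
    adjusted, _ = combat_adjust(study, BatchDesign.from_study(study))
    plat = study.platforms()
    p1, p2 = sorted(plat.unique())
    post = (
        adjusted.values[plat.index[plat == p1]].mean(axis=1)
        - adjusted.values[plat.index[plat == p2]].mean(axis=1)
    )
    assert post.abs().mean() < 0.05


def test_combat_preserves_planted_class_effect():
    cfg = StudyConfig(seed=5, n_genes=1000, planted_log2fc=2.0)
    study, _, truth = gen_expression_study(cfg)
    adjusted, _ = combat_adjust(study, BatchDesign.from_study(study))
    cls = study.classes()
    eff = (
        adjusted.values.loc[truth.planted_target_ids, cls.index[cls == "sCSC"]].mean(axis=1)
        - adjusted.values.loc[truth.planted_target_ids, cls.index[cls == "dCSC"]].mean(axis=1)
    ).mean()
    assert abs(eff - 2.0) / 2.0 < 0.10


def test_combat_shrinks_between_raw_estimate_and_prior_mean():
    cfg = StudyConfig(seed=2, n_genes=400)
    study, _, _ = gen_expression_study(cfg)
    _, est = combat_adjust(study, BatchDesign.from_study(study))
    for b in est.gamma_hat.columns:
        lo = np.minimum(est.gamma_hat[b], est.gamma_bar[b])
        hi = np.maximum(est.gamma_hat[b], est.gamma_bar[b])
        assert ((est.gamma_star[b] >= lo - 1e-9) & (est.gamma_star[b] <= hi + 1e-9)).all()
        assert (est.delta_sq_star[b] > 0).all()


def test_combat_shrunken_effects_track_planted_shifts():
    """EB-shrunken additive effects correlate strongly with the planted
    per-platform shifts across simulation seeds."""
    cors = []
    for seed in range(50):
        cfg = StudyConfig(
            seed=seed, n_genes=150, n_planted_targets=0, noise_sd=0.5,
            tissue_class_sizes={"normal": 10, "tumor": 10},
        )
        study, _, truth = gen_expression_study(cfg)
        _, est = combat_adjust(study, BatchDesign.from_study(study))
        p1, p2 = est.gamma_star.columns
        planted = truth.batch_shift[p1] - truth.batch_shift[p2]
        estimated = (est.gamma_star[p1] - est.gamma_star[p2]) * np.sqrt(est.var_pooled)
        cors.append(np.corrcoef(planted, estimated)[0, 1])
    assert np.mean(cors) > 0.95


def test_combat_second_pass_is_contraction():
    """Parametric EB re-shrinkage means exact idempotence does not hold; a
    second pass must still be a strong contraction and leave the batch
    separation removed."""
    cfg = StudyConfig(seed=9, n_genes=500)
    study, _, _ = gen_expression_study(cfg)
    design = BatchDesign.from_study(study)
    once, _ = combat_adjust(study, design)
    twice, _ = combat_adjust(once, design)
    first = np.abs(once.values.to_numpy() - study.values.to_numpy()).max()
    second = np.abs(twice.values.to_numpy() - once.values.to_numpy()).max()
    assert second < 0.1 * first
    plat = study.platforms()
    p1, p2 = sorted(plat.unique())
    post = (
        twice.values[plat.index[plat == p1]].mean(axis=1)
        - twice.values[plat.index[plat == p2]].mean(axis=1)
    )
    assert post.abs().mean() < 0.05


def test_combat_matches_reference_implementation():
    """Covariate-free agreement with scanpy's ComBat (independent code path)."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad

    cfg = StudyConfig(
        seed=3, n_genes=300, n_planted_targets=0,
        tissue_class_sizes={"normal": 12, "tumor": 12},
    )
    study, _, _ = gen_expression_study(cfg)
    adata = ad.AnnData(
        study.values.to_numpy().T.copy(),
        obs=pd.DataFrame({"batch": study.platforms().to_numpy()}, index=study.sample_ids),
    )
    sc.pp.combat(adata, key="batch")
    design = BatchDesign(
        study.platforms().rename("batch"),
        pd.Series("all", index=study.sample_ids, name="covariate"),
    )
    mine, _ = combat_adjust(study, design)
    assert np.abs(mine.values.to_numpy().T - adata.X).max() < 1e-3


def test_combat_rejects_confounded_covariate():
    cfg = StudyConfig(
        seed=1, n_genes=60,
        tissue_class_sizes={"sCSC": 4, "normal": 6},
        dataset_of_class={"sCSC": "d1", "normal": "d2"},
    )
    study, _, _ = gen_expression_study(cfg)
    with pytest.raises(ConfoundingError):
        combat_adjust(study, BatchDesign.from_study(study))


# -- medoid_mad_prune -------------------------------------------------------
def test_prune_identical_samples_all_retained():
    vals = {f"s{i}": [1.0, 2.0, 3.0, 4.0] for i in range(5)}
    study = make_study(vals, {f"s{i}": "normal" for i in range(5)})
    retained = medoid_mad_prune(study, study.classes())
    assert sorted(retained["normal"]) == sorted(vals)


def _outlier_study(seed):
    cfg = StudyConfig(
        seed=seed, n_genes=2000, n_planted_targets=0,
        tissue_class_sizes={"normal": 10}, outlier_fraction=0.1,
        batch_shift_sd=0.0, platform_of_dataset={"d1": "HuGene1.0ST"},
    )
    return gen_expression_study(cfg)


def test_prune_removes_exactly_the_planted_outlier():
    study, _, truth = _outlier_study(seed=0)
    retained = medoid_mad_prune(study, study.classes())["normal"]
    assert set(study.sample_ids) - set(retained) == set(truth.outlier_sample_ids)


def test_prune_order_invariant_and_contains_medoid():
    study, _, truth = _outlier_study(seed=1)
    labels = study.classes()
    retained = medoid_mad_prune(study, labels)["normal"]
    shuffled = study.subset_samples(list(study.sample_ids)[::-1])
    retained_rev = medoid_mad_prune(shuffled, shuffled.classes())["normal"]
    assert set(retained) == set(retained_rev)
    assert set(retained) <= set(study.sample_ids)


def test_prune_monotone_in_outlier_displacement():
    study, _, truth = _outlier_study(seed=2)
    outlier = truth.outlier_sample_ids[0]
    sizes = []
    for extra in (0.0, 2.0, 6.0):
        bumped = study.values.copy()
        bumped.loc[bumped.index[:500], outlier] += extra
        s = study.with_values(bumped)
        sizes.append(len(medoid_mad_prune(s, s.classes())["normal"]))
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_prune_small_groups_pass_through():
    vals = {"a": [1.0, 2.0], "b": [9.0, 9.0]}
    study = make_study(vals, {"a": "normal", "b": "normal"})
    retained = medoid_mad_prune(study, study.classes())
    assert sorted(retained["normal"]) == ["a", "b"]


# -- pca_project ------------------------------------------------------------
def test_pca_duplicate_samples_coincide():
    rng = np.random.default_rng(0)
    col = rng.normal(size=30)
    vals = {"a": col, "b": col.copy(), "c": rng.normal(size=30)}
    study = make_study(vals, {k: "normal" for k in vals})
    coords, var = pca_project(study, 2)
    assert np.allclose(coords.loc["a"], coords.loc["b"])
    assert var.sum() <= 100.0 + 1e-9
    assert np.all(np.diff(var) <= 1e-9)


def test_pca_rejects_too_many_components():
    vals = {"a": [1.0, 2.0], "b": [2.0, 1.0]}
    study = make_study(vals, {"a": "normal", "b": "normal"})
    with pytest.raises(ConfigError):
        pca_project(study, 5)


def test_pca_platform_silhouette_drops_after_adjustment():
    from sklearn.metrics import silhouette_score

    cfg = StudyConfig(seed=4, n_genes=600)
    study, _, _ = gen_expression_study(cfg)
    design = BatchDesign.from_study(study)
    adjusted, _ = combat_adjust(study, design)
    labels = study.platforms().to_numpy()
    pre, _ = pca_project(study, 2)
    post, _ = pca_project(adjusted, 2)
    sil_pre = silhouette_score(pre.to_numpy(), labels)
    sil_post = silhouette_score(post.to_numpy(), labels)
    assert sil_pre > 0
    assert sil_post < sil_pre
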
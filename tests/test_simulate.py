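"""Synthetic-data generators: determinism, bookkeeping, planted truth."""

import numpy as np
import pandas as pd
import pytest

from csctargets import (
    ConfigError,
    QPCRDesign,
    StudyConfig,
    ddct_quantify,
    gen_ct_table,
    gen_dose_response,
    gen_expression_study,
    gen_sensorgram,
    serial_dilution,
)
from csctargets.assays import one_site


def test_same_seed_reproduces_study_exactly():
    cfg = StudyConfig(seed=7, n_genes=300)
    s1, a1, t1 = gen_expression_study(cfg)
    s2, a2, t2 = gen_expression_study(StudyConfig(seed=7, n_genes=300))
    pd.testing.assert_frame_equal(s1.values, s2.values)
    pd.testing.assert_frame_equal(a1, a2)
    assert t1.planted_target_ids == t2.planted_target_ids
    s3, _, _ = gen_expression_study(StudyConfig(seed=8, n_genes=300))
    assert not s1.values.equals(s3.values)


def test_sample_sheet_bookkeeping():
    cfg = StudyConfig(seed=0, n_genes=50, n_planted_targets=5,
                      tissue_class_sizes={"sCSC": 8, "dCSC": 8})
    study, _, _ = gen_expression_study(cfg)
    assert study.n_samples == 16
    assert len(study.sample_sheet) == 16
    assert set(study.classes()) == {"sCSC", "dCSC"}


def test_planted_effect_matches_requested_log2fc():
    cfg = StudyConfig(
        seed=1, n_genes=500, n_planted_targets=20, batch_shift_sd=0.0,
        noise_sd=0.05, tissue_class_sizes={"sCSC": 8, "dCSC": 8},
    )
    study, _, truth = gen_expression_study(cfg)
    cls = study.classes()
    diff = (
        study.values.loc[truth.planted_target_ids, cls.index[cls == "sCSC"]].mean(axis=1)
        - study.values.loc[truth.planted_target_ids, cls.index[cls == "dCSC"]].mean(axis=1)
    )
    se = cfg.noise_sd * np.sqrt(2 / 8)
    assert np.all(np.abs(diff - cfg.planted_log2fc) < 3 * se + 1e-9)


def test_group_mean_estimator_unbiased_for_planted_effect():
    """Across many seeds the sCSC-vs-dCSC group-mean difference is an
    unbiased estimator of the planted effect (mean error < 0.05 log2)."""
    errors = []
    for seed in range(100):
        cfg = StudyConfig(
            seed=seed, n_genes=60, n_planted_targets=10, batch_shift_sd=0.0,
            noise_sd=0.5, tissue_class_sizes={"sCSC": 8, "dCSC": 8},
        )
        study, _, truth = gen_expression_study(cfg)
        cls = study.classes()
        diff = (
            study.values.loc[truth.planted_target_ids, cls.index[cls == "sCSC"]].mean(axis=1)
            - study.values.loc[truth.planted_target_ids, cls.index[cls == "dCSC"]].mean(axis=1)
        )
        errors.append(diff.mean() - cfg.planted_log2fc)
    assert abs(np.mean(errors)) < 0.05


def test_annotation_marks_planted_genes_membrane():
    cfg = StudyConfig(seed=3, n_genes=400, n_planted_targets=10, n_planted_decoys=10)
    _, annotation, truth = gen_expression_study(cfg)
    for g in truth.planted_target_ids + truth.planted_decoy_ids:
        assert annotation.loc[g, "membrane_status"] == "transmembrane"
    assert set(truth.planted_target_ids) <= set(truth.planted_membrane_ids)
    assert not set(truth.planted_target_ids) & set(truth.housekeeping_ids)


def test_zero_samples_in_class_rejected():
    with pytest.raises(ConfigError):
        StudyConfig(tissue_class_sizes={"sCSC": 0, "dCSC": 8}).validate()
    with pytest.raises(ConfigError):
        StudyConfig(tissue_class_sizes={"mystery": 4}).validate()
    with pytest.raises(ConfigError):
        StudyConfig(noise_sd=0.0).validate()


# -- Ct tables --------------------------------------------------------------
def _design(noise_sd=0.15, enrichment=8.0):
    lines = {"CSC1": "csc", "CSC2": "csc", "TUM1": "cancer_line", "nrm": "normal"}
    genes = ["tg1", "tg2"]
    abundance = {
        g: {ln: (enrichment if lt == "csc" else 1.0) for ln, lt in lines.items()}
        for g in genes
    }
    return QPCRDesign(
        genes=genes, housekeeping="GAPDH", lines=lines, reference_line="CSC1",
        normal_line="nrm", abundance=abundance, noise_sd=noise_sd,
    )


def test_ct_table_encodes_planted_enrichment():
    """An 8-fold planted CSC enrichment corresponds to ΔΔCt ≈ -3 for the
    normal line referenced against the CSC line."""
    ct = gen_ct_table(_design(noise_sd=0.0), seed=0)
    rq = ddct_quantify(ct)
    assert rq.ddct.loc["tg1", "nrm"] == pytest.approx(3.0)
    assert rq.rq.loc["tg1", "nrm"] == pytest.approx(1 / 8)


def test_ct_table_zero_noise_equal_abundance_gives_unit_rq():
    ct = gen_ct_table(_design(noise_sd=0.0, enrichment=1.0), seed=0)
    rq = ddct_quantify(ct)
    assert np.allclose(rq.rq.to_numpy(), 1.0)


def test_ct_table_seeded_reproducible():
    c1 = gen_ct_table(_design(), seed=5)
    c2 = gen_ct_table(_design(), seed=5)
    pd.testing.assert_frame_equal(c1.data, c2.data)


def test_ct_design_requires_housekeeping():
    d = _design()
    d.housekeeping = ""
    with pytest.raises(ConfigError):
        gen_ct_table(d, seed=0)


# -- dose-response ----------------------------------------------------------
def test_one_site_response_at_kd_is_half_bmax():
    dr = gen_dose_response("one_site", {"bmax": 6.0, "kd": 0.5}, [0.5], noise_sd=0.0)
    assert dr.response[0] == pytest.approx(3.0)


def test_serial_dilution_grid_spans_reported_range():
    grid = serial_dilution(top=30.0, factor=3.0, n=8)
    assert grid.size == 8
    assert grid[-1] == pytest.approx(30.0)
    assert grid[0] == pytest.approx(0.0137, rel=5e-3)
    assert np.all(np.diff(grid) > 0)


def test_one_site_curve_monotone_without_noise():
    grid = serial_dilution(n=10)
    dr = gen_dose_response("one_site", {"bmax": 5.0, "kd": 0.2}, grid, noise_sd=0.0)
    assert np.all(np.diff(dr.response) >= 0)


def test_dose_response_rejects_bad_params():
    with pytest.raises(ConfigError):
        gen_dose_response("one_site", {"bmax": 5.0, "kd": -1.0}, [1.0, 2.0])
    with pytest.raises(ConfigError):
        gen_dose_response("one_site", {"bmax": 5.0, "kd": 1.0}, [0.0, 2.0])


# -- sensorgrams ------------------------------------------------------------
def test_sensorgram_association_plateau():
    ka, kd, rmax = 1e5, 1e-3, 50.0
    conc = 2e-8
    sgs = gen_sensorgram(ka, kd, rmax, [conc], t_assoc=5000.0, t_dissoc=0.0, dt=50.0)
    plateau = conc * rmax / (conc + kd / ka)
    assert sgs[0].response[-1] == pytest.approx(plateau, rel=1e-3)
    # saturating concentration drives the plateau to Rmax
    sgs_hi = gen_sensorgram(ka, kd, rmax, [1e-4], t_assoc=5000.0, t_dissoc=0.0, dt=50.0)
    assert sgs_hi[0].response[-1] == pytest.approx(rmax, rel=1e-2)


def test_sensorgram_rejects_negative_times():
    with pytest.raises(ConfigError):
        gen_sensorgram(1e5, 1e-4, 100.0, [1e-9], t_assoc=-5.0)
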
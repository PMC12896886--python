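"""Synthetic multi-platform expression studies, Ct tables, dose-response
curves and sensorgrams with known ground truth.

The expression generator emulates a cross-platform target-discovery study:
several tissue classes (stem and differentiated CSC lines, normal and tumor
colon with LCM variants, cell lines), per-platform additive/multiplicative
batch effects, Gaussian residual noise on the log2 scale, a planted set of
CSC-enriched membrane genes with configurable effect size, optional
tumor-shared membrane decoys, and optional displaced outlier samples.  All
randomness flows from a single integer seed, one generator stream per
generated artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import (
    DoseResponse,
    Sensorgram,
    four_pl,
    one_site,
    sensorgram_response,
)
from .core import ConfigError, ExpressionStudy, PLATFORMS, TISSUE_CLASSES
from .funnel import ANNOTATION_COLUMNS, VITAL_ORGANS
from .qpcr import CtTable

__all__ = [
    "StudyConfig",
    "TruthSet",
    "QPCRDesign",
    "gen_expression_study",
    "gen_ct_table",
    "gen_dose_response",
    "gen_sensorgram",
]

#: Classes that share the decoys' enrichment (decoys are up in CSCs *and* here,
#: so they fail the consistency-versus-tumor filter that true targets pass).
DECOY_SHARED_CLASSES = ("tumor", "tumor_lcm", "tumor_crypt", "cell_line")


def _default_class_sizes() -> dict[str, int]:
    return {
        "sCSC": 8,
        "dCSC": 8,
        "normal": 10,
        "normal_lcm": 4,
        "tumor": 10,
        "tumor_lcm": 4,
        "cell_line": 8,
    }


def _default_platforms() -> dict[str, str]:
    return {"d1": PLATFORMS[0], "d2": PLATFORMS[1]}


@dataclass
class StudyConfig:
    """Ground-truth configuration of a simulated expression study."""

    n_genes: int = 2000
    n_planted_targets: int = 25
    n_planted_decoys: int = 0
    tissue_class_sizes: dict[str, int] = field(default_factory=_default_class_sizes)
    platform_of_dataset: dict[str, str] = field(default_factory=_default_platforms)
    dataset_of_class: dict[str, str] | None = None  # default: alternate datasets
    planted_log2fc: float = 1.5
    batch_shift_sd: float = 1.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.5
    outlier_fraction: float = 0.0
    outlier_shift: float = 4.0
    outlier_gene_fraction: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    membrane_background_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_planted_targets < 0 or self.n_planted_decoys < 0:
            raise ConfigError("counts must be nonnegative (n_genes positive)")
        if self.n_planted_targets + self.n_planted_decoys > self.n_genes:
            raise ConfigError("more planted genes than genes")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        bad = set(self.tissue_class_sizes) - set(TISSUE_CLASSES)
        if bad:
            raise ConfigError(f"unknown tissue classes: {sorted(bad)}")
        for cls, n in self.tissue_class_sizes.items():
            if n <= 0:
                raise ConfigError(f"zero samples in referenced class {cls!r}")
        if not self.platform_of_dataset:
            raise ConfigError("need at least one dataset")
        if not (0 <= self.outlier_fraction < 1):
            raise ConfigError("outlier_fraction must lie in [0, 1)")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ConfigError("batch_scale_range must be positive and ordered")


@dataclass
class TruthSet:
    """What was planted: consumed by tests and benchmark evaluation."""

    planted_target_ids: list[str]
    planted_decoy_ids: list[str]
    planted_membrane_ids: list[str]
    housekeeping_ids: list[str]
    batch_shift: pd.DataFrame      # genes × platforms, additive log2 shifts
    batch_scale: pd.DataFrame      # genes × platforms, variance factors
    outlier_sample_ids: list[str]

    def __post_init__(self):
        if not set(self.planted_target_ids) <= set(self.planted_membrane_ids):
            raise ConfigError("planted targets must be membrane genes")
        if set(self.planted_target_ids) & set(self.housekeeping_ids):
            raise ConfigError("planted targets overlap housekeeping genes")


def gen_expression_study(
    config: StudyConfig,
) -> tuple[ExpressionStudy, pd.DataFrame, TruthSet]:
    """Simulate a study; returns (study, gene annotation, truth set).

    Gene-wise baselines are Normal(baseline_mean, baseline_sd) log2 units;
    planted targets gain ``planted_log2fc`` in sCSC samples only, decoys gain
    it in sCSC and in tumor-like classes; each platform adds gene-wise
    additive shifts (SD ``batch_shift_sd``) and scales residual noise by a
    gene-wise variance factor drawn from ``batch_scale_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    planted = rng.choice(
        config.n_genes, size=config.n_planted_targets + config.n_planted_decoys, replace=False
    )
    target_ids = sorted(genes[i] for i in planted[: config.n_planted_targets])
    decoy_ids = sorted(genes[i] for i in planted[config.n_planted_targets:])
    remaining = sorted(set(genes) - set(target_ids) - set(decoy_ids))
    housekeeping_ids = remaining[:2]

    # sample sheet: every class split across datasets (round robin) unless pinned
    datasets = sorted(config.platform_of_dataset)
    rows = []
    for cls in sorted(config.tissue_class_sizes):
        for i in range(config.tissue_class_sizes[cls]):
            if config.dataset_of_class is not None and cls in config.dataset_of_class:
                ds = config.dataset_of_class[cls]
            else:
                ds = datasets[i % len(datasets)]
            rows.append(
                {
                    "sample_id": f"{cls}_{i + 1:02d}",
                    "dataset_id": ds,
                    "platform": config.platform_of_dataset[ds],
                    "tissue_class": cls,
                }
            )
    sheet = pd.DataFrame(rows)
    sample_ids = list(sheet["sample_id"])
    n_samples = len(sample_ids)
    platforms = sorted(set(config.platform_of_dataset.values()))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # class effect matrix (genes × samples)
    effect = np.zeros((config.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cls_per_sample = sheet["tissue_class"].to_numpy()
    is_cs = cls_per_sample == "sCSC"
    is_decoy_shared = np.isin(cls_per_sample, DECOY_SHARED_CLASSES)
    for g in target_ids:
        effect[gene_pos[g], is_cs] += config.planted_log2fc
    for g in decoy_ids:
        effect[gene_pos[g], is_cs | is_decoy_shared] += config.planted_log2fc

    # per-platform batch parameters
    shift = pd.DataFrame(
        rng.normal(0.0, config.batch_shift_sd, size=(config.n_genes, len(platforms))),
        index=genes,
        columns=platforms,
    )
    lo, hi = config.batch_scale_range
    scale = pd.DataFrame(
        rng.uniform(lo, hi, size=(config.n_genes, len(platforms))),
        index=genes,
        columns=platforms,
    )

    plat_per_sample = sheet["platform"].to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    values = baseline[:, None] + effect
    for p in platforms:
        m = plat_per_sample == p
        values[:, m] += shift[p].to_numpy()[:, None]
        values[:, m] += noise[:, m] * np.sqrt(scale[p].to_numpy())[:, None]

    # displaced outlier samples
    n_out = int(round(config.outlier_fraction * n_samples))
    outlier_idx = sorted(rng.choice(n_samples, size=n_out, replace=False)) if n_out else []
    outlier_ids = [sample_ids[i] for i in outlier_idx]
    n_displaced = int(round(config.outlier_gene_fraction * config.n_genes))
    for i in outlier_idx:
        displaced = rng.choice(config.n_genes, size=n_displaced, replace=False)
        values[displaced, i] += config.outlier_shift

    study = ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(genes, name="probe_id"), columns=sample_ids),
        sheet,
    )
    annotation = _gen_annotation(
        genes, target_ids, decoy_ids, config.membrane_background_rate, rng
    )
    membrane_ids = sorted(annotation.index[annotation["membrane_status"] != "none"])
    truth = TruthSet(
        planted_target_ids=target_ids,
        planted_decoy_ids=decoy_ids,
        planted_membrane_ids=membrane_ids,
        housekeeping_ids=housekeeping_ids,
        batch_shift=shift,
        batch_scale=scale,
        outlier_sample_ids=outlier_ids,
    )
    return study, annotation, truth


def _gen_annotation(
    genes, target_ids, decoy_ids, membrane_rate, rng
) -> pd.DataFrame:
    n = len(genes)
    favored = set(target_ids) | set(decoy_ids)
    membrane = rng.random(n) < membrane_rate
    ann = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=list(ANNOTATION_COLUMNS))
    ann["membrane_status"] = np.where(
        membrane, np.where(rng.random(n) < 0.2, "GPI", "transmembrane"), "none"
    )
    for organ in VITAL_ORGANS:
        ann[f"vital_{organ}"] = rng.choice(
            ["low", "medium", "high"], size=n, p=[0.6, 0.25, 0.15]
        )
    ann["shedding"] = rng.choice(["limited", "extensive", "unknown"], size=n, p=[0.5, 0.2, 0.3])
    ann["knowledge_score"] = rng.choice(
        ["favorable", "neutral", "unfavorable"], size=n, p=[0.4, 0.4, 0.2]
    )
    for col in ("immunogenicity_ok", "ectopic_expression_ok", "paralog_similarity_ok"):
        ann[col] = rng.random(n) < 0.8
    # planted genes are clean, antibody-accessible membrane targets by construction
    fav = ann.index.isin(favored)
    ann.loc[fav, "membrane_status"] = "transmembrane"
    for organ in VITAL_ORGANS:
        ann.loc[fav, f"vital_{organ}"] = "low"
    ann.loc[fav, "shedding"] = "limited"
    ann.loc[fav, "knowledge_score"] = "favorable"
    for col in ("immunogenicity_ok", "ectopic_expression_ok", "paralog_similarity_ok"):
        ann.loc[fav, col] = True
    return ann


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------
@dataclass
class QPCRDesign:
    """Design of a validation qPCR run.

    ``abundance`` maps gene -> {line: relative abundance versus the normal
    control} on the linear scale; one cycle corresponds to a 2-fold change.
    """

    genes: list[str]
    housekeeping: str
    lines: dict[str, str]          # line -> line_type (csc / cancer_line / normal)
    reference_line: str
    normal_line: str
    abundance: dict[str, dict[str, float]]
    replicates: int = 3
    noise_sd: float = 0.15         # cycles
    ct_base: float = 25.0
    ct_housekeeping: float = 20.0

    def validate(self) -> None:
        if not self.housekeeping:
            raise ConfigError("design needs a housekeeping gene")
        if self.housekeeping in self.genes:
            raise ConfigError("housekeeping gene must be separate from the targets")
        for ln in (self.reference_line, self.normal_line):
            if ln not in self.lines:
                raise ConfigError(f"line {ln!r} missing from design")
        for g in self.genes:
            missing = set(self.lines) - set(self.abundance.get(g, {}))
            if missing:
                raise ConfigError(f"gene {g!r} lacks abundances for {sorted(missing)}")

    @classmethod
    def from_truth(
        cls,
        truth: "TruthSet",
        lines: dict[str, str],
        reference_line: str,
        normal_line: str,
        enrichment: float = 8.0,
        n_genes: int = 5,
        **kwargs,
    ) -> "QPCRDesign":
        """Design a validation run for planted targets: ``enrichment``-fold
        abundance in CSC lines, parity with normal elsewhere."""
        genes = truth.planted_target_ids[:n_genes]
        abundance = {
            g: {ln: (enrichment if lt == "csc" else 1.0) for ln, lt in lines.items()}
            for g in genes
        }
        return cls(
            genes=genes,
            housekeeping=truth.housekeeping_ids[0],
            lines=lines,
            reference_line=reference_line,
            normal_line=normal_line,
            abundance=abundance,
            **kwargs,
        )


def gen_ct_table(design: QPCRDesign, seed: int = 0) -> CtTable:
    """Simulate Ct values: Ct = Ct_base - log2(relative abundance) + noise."""
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for line, line_type in design.lines.items():
        for rep in range(1, design.replicates + 1):
            rows.append(
                {
                    "gene": design.housekeeping,
                    "line": line,
                    "line_type": line_type,
                    "replicate": rep,
                    "ct": design.ct_housekeeping + rng.normal(0.0, design.noise_sd)
                    if design.noise_sd > 0
                    else design.ct_housekeeping,
                }
            )
        for gene in design.genes:
            ab = design.abundance[gene][line]
            if ab <= 0:
                raise ConfigError(f"nonpositive abundance for {gene!r} in {line!r}")
            ct_true = design.ct_base - np.log2(ab)
            for rep in range(1, design.replicates + 1):
                ct = ct_true + (rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "gene": gene,
                        "line": line,
                        "line_type": line_type,
                        "replicate": rep,
                        "ct": float(np.clip(ct, 1.0, 40.0)),
                    }
                )
    return CtTable(
        data=pd.DataFrame(rows),
        housekeeping=design.housekeeping,
        reference_line=design.reference_line,
        normal_line=design.normal_line,
    )


# ---------------------------------------------------------------------------
# dose-response curves and sensorgrams
# ---------------------------------------------------------------------------
def gen_dose_response(
    model: str,
    params: dict[str, float],
    conc_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    relative_noise: bool = True,
) -> DoseResponse:
    """Simulate a titration: response = model(conc; params) + noise.

    ``model`` is ``one_site`` (params bmax, kd) or ``four_pl`` (top, bottom,
    ic50, hill).  With ``relative_noise`` the Gaussian noise is proportional
    to the signal (sd = noise_sd × |response|), matching multiplicative assay
    error; otherwise it is additive.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0):
        raise ConfigError("concentrations must be > 0")
    if model == "one_site":
        if params["kd"] <= 0:
            raise ConfigError("KD must be > 0")
        y = one_site(conc, params["bmax"], params["kd"])
    elif model == "four_pl":
        if params["ic50"] <= 0:
            raise ConfigError("IC50 must be > 0")
        y = four_pl(conc, params["top"], params["bottom"], params["ic50"], params["hill"])
    else:
        raise ConfigError(f"unknown model {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=conc.shape)
        y = y * (1.0 + eps) if relative_noise else y + eps
    return DoseResponse(concentration=conc, response=y)


def gen_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    conc_list,
    t_assoc: float = 180.0,
    t_dissoc: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 2.0,
    relative_noise: bool = False,
) -> list[Sensorgram]:
    """Simulate one 1:1-model sensorgram per analyte concentration (molar).

    ``noise_sd`` is additive RU noise, or a fractional multiplicative level
    when ``relative_noise`` is set.
    """
    if min(ka, kd, rmax) <= 0:
        raise ConfigError("ka, kd and Rmax must be > 0")
    if t_assoc <= 0 or t_dissoc < 0 or dt <= 0:
        raise ConfigError("times must be positive")
    conc_list = [float(c) for c in conc_list]
    if any(c <= 0 for c in conc_list):
        raise ConfigError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(dt, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for conc in conc_list:
        r = sensorgram_response(t, conc, ka, kd, rmax, t_assoc)
        if noise_sd > 0:
            eps = rng.normal(0.0, noise_sd, size=r.shape)
            r = r * (1.0 + eps) if relative_noise else r + eps
        out.append(Sensorgram(time=t.copy(), response=r, concentration=conc, t_assoc=t_assoc))
    return out
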
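"""Cross-platform study integration.

Merges studies from two array architectures onto common probe identifiers,
removes platform batch effects with a parametric empirical-Bayes
location/scale adjustment (per-gene additive effects γ with a normal prior,
multiplicative variance factors δ² with an inverse-gamma prior, hyperparameters
by method of moments), prunes heterogeneous sample groups by distance from the
medoid sample, and provides a PCA projection for before/after diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .core import ConfigError, DataError, ExpressionStudy

__all__ = [
    "ProbeMapReport",
    "BatchDesign",
    "BatchEstimates",
    "ConfoundingError",
    "map_probes",
    "combat_adjust",
    "medoid_mad_prune",
    "pca_project",
]


class ConfoundingError(ValueError):
    """A covariate level lies entirely within one batch; its biological effect
    cannot be separated from the batch effect."""


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------
@dataclass
class ProbeMapReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_collisions: int
    collision_losers: list[str] = field(default_factory=list)


def map_probes(
    study: ExpressionStudy, probe_map: pd.DataFrame
) -> tuple[ExpressionStudy, ProbeMapReport]:
    """Re-express a study on the target probe-id space of a best-match map.

    ``probe_map`` needs columns ``source`` and ``target`` (an optional boolean
    ``best_match`` column restricts the pairs used).  Unmapped source probes
    are dropped and counted; when several source probes map to the same target
    the source with the highest mean expression is retained (ties broken by
    probe id for determinism).
    """
    need = {"source", "target"}
    if not need <= set(probe_map.columns):
        raise DataError("probe map needs 'source' and 'target' columns")
    pm = probe_map
    if "best_match" in pm.columns:
        pm = pm[pm["best_match"].astype(bool)]
    pm = pm.drop_duplicates(subset=["source", "target"])
    if pm["source"].duplicated().any():
        raise DataError("a source probe maps to multiple targets")

    present = pm[pm["source"].isin(study.probe_ids)]
    if present.empty:
        raise DataError("probe map shares no probes with the study")
    n_unmapped = study.values.shape[0] - present["source"].nunique()

    means = study.values.mean(axis=1)
    losers: list[str] = []
    chosen: dict[str, str] = {}
    for target, grp in present.groupby("target"):
        sources = sorted(grp["source"])
        best = max(sources, key=lambda s: (means[s], s))
        chosen[target] = best
        losers.extend(s for s in sources if s != best)

    targets = sorted(chosen)
    new_values = study.values.loc[[chosen[t] for t in targets]].copy()
    new_values.index = pd.Index(targets, name=study.values.index.name)
    report = ProbeMapReport(
        n_input=study.values.shape[0],
        n_mapped=len(targets),
        n_unmapped=n_unmapped,
        n_collisions=len(losers),
        collision_losers=losers,
    )
    return ExpressionStudy(new_values, study.sample_sheet.copy()), report


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------
@dataclass
class BatchDesign:
    """Per-sample batch label (array platform / dataset) and covariate label
    (tissue class), indexed by sample id."""

    batch: pd.Series
    covariate: pd.Series

    def __post_init__(self):
        if not self.batch.index.equals(self.covariate.index):
            raise DataError("batch and covariate labels must index the same samples")
        sizes = self.batch.value_counts()
        if (sizes < 2).any():
            raise DataError("every batch needs >= 2 samples")

    @classmethod
    def from_study(cls, study: ExpressionStudy, batch_by: str = "platform") -> "BatchDesign":
        """Build a design from the sample sheet.

        ``batch_by``: ``platform`` (default) or ``dataset`` (platform and
        dataset id combined), covering both readings of how batches were
        defined.
        """
        sheet = study.sample_sheet.set_index("sample_id").loc[study.sample_ids]
        if batch_by == "platform":
            batch = sheet["platform"]
        elif batch_by == "dataset":
            batch = sheet["platform"].str.cat(sheet["dataset_id"], sep="/")
        else:
            raise ConfigError(f"unknown batch_by {batch_by!r}")
        return cls(batch.rename("batch"), sheet["tissue_class"].rename("covariate"))


@dataclass
class BatchEstimates:
    """Per-(gene, batch) batch-effect estimates from the EB model."""

    gamma_hat: pd.DataFrame      # raw additive effects, genes × batches
    gamma_star: pd.DataFrame     # EB-shrunken additive effects
    delta_sq_hat: pd.DataFrame   # raw variance factors
    delta_sq_star: pd.DataFrame  # EB-shrunken variance factors
    gamma_bar: pd.Series         # prior means per batch
    tau_sq: pd.Series            # prior variances per batch
    grand_mean: pd.Series        # per-gene grand mean (standardization model)
    beta: pd.DataFrame           # covariate coefficients, genes × levels
    var_pooled: pd.Series        # per-gene pooled variance


def _check_confounding(batch: pd.Series, covariate: pd.Series) -> None:
    if batch.nunique() < 2:
        return
    for level, idx in covariate.groupby(covariate).groups.items():
        if batch.loc[idx].nunique() < 2:
            raise ConfoundingError(
                f"covariate level {level!r} occurs in a single batch; "
                "batch and covariate effects are confounded"
            )


def combat_adjust(
    study: ExpressionStudy,
    design: BatchDesign,
    mode: str = "parametric",
    max_iter: int = 200,
    conv: float = 1e-6,
) -> tuple[ExpressionStudy, BatchEstimates]:
    """Parametric empirical-Bayes batch-effect removal.

    Per gene, expression is standardized with a covariate-adjusted mean and a
    pooled variance; per-batch additive effects (γ) and multiplicative variance
    factors (δ²) are estimated and shrunk toward parametric priors (normal and
    inverse-gamma, method-of-moments hyperparameters); the data are then
    back-transformed with batch effects removed and covariate effects intact.
    """
    if mode != "parametric":
        raise ConfigError("only the parametric EB mode is implemented")
    sample_ids = list(study.sample_ids)
    batch = design.batch.loc[sample_ids]
    cov = design.covariate.loc[sample_ids]
    batches = sorted(batch.unique())
    y = study.values.to_numpy(dtype=float)
    genes = study.probe_ids

    if len(batches) == 1:
        est = BatchEstimates(
            gamma_hat=pd.DataFrame(0.0, index=genes, columns=batches),
            gamma_star=pd.DataFrame(0.0, index=genes, columns=batches),
            delta_sq_hat=pd.DataFrame(1.0, index=genes, columns=batches),
            delta_sq_star=pd.DataFrame(1.0, index=genes, columns=batches),
            gamma_bar=pd.Series(0.0, index=batches),
            tau_sq=pd.Series(0.0, index=batches),
            grand_mean=study.values.mean(axis=1),
            beta=pd.DataFrame(index=genes),
            var_pooled=study.values.var(axis=1, ddof=0),
        )
        return study.with_values(study.values.copy()), est

    _check_confounding(batch, cov)

    n = len(sample_ids)
    batch_dummies = pd.get_dummies(pd.Categorical(batch, categories=batches), dtype=float)
    cov_levels = sorted(cov.unique())
    cov_dummies = pd.get_dummies(
        pd.Categorical(cov, categories=cov_levels), drop_first=True, dtype=float
    )
    x = np.hstack([batch_dummies.to_numpy(), cov_dummies.to_numpy()])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ConfoundingError("model matrix is rank deficient")
    n_batch = len(batches)

    # standardization model
    b_hat, *_ = np.linalg.lstsq(x, y.T, rcond=None)  # coef × genes
    batch_sizes = batch_dummies.to_numpy().sum(axis=0)
    grand = (batch_sizes / n) @ b_hat[:n_batch]
    resid = y - (x @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand[:, None] + (x[:, n_batch:] @ b_hat[n_batch:]).T
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((y.shape[0], n_batch))
    delta_sq_hat = np.empty_like(gamma_hat)
    masks = [batch.to_numpy() == b for b in batches]
    for i, m in enumerate(masks):
        gamma_hat[:, i] = z[:, m].mean(axis=1)
        delta_sq_hat[:, i] = z[:, m].var(axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau_sq = gamma_hat.var(axis=0, ddof=1)
    gamma_star = np.empty_like(gamma_hat)
    delta_sq_star = np.empty_like(delta_sq_hat)
    for i, m in enumerate(masks):
        n_i = int(m.sum())
        d_mean = delta_sq_hat[:, i].mean()
        d_var = delta_sq_hat[:, i].var(ddof=1)
        d_var = max(d_var, 1e-12)
        a_prior = (2.0 * d_var + d_mean ** 2) / d_var
        b_prior = (d_mean * d_var + d_mean ** 3) / d_var
        g_star = gamma_hat[:, i].copy()
        d_star = delta_sq_hat[:, i].copy()
        zb = z[:, m]
        for _ in range(max_iter):
            g_new = (n_i * tau_sq[i] * gamma_hat[:, i] + d_star * gamma_bar[i]) / (
                n_i * tau_sq[i] + d_star
            )
            sum2 = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - g_star).max() / (np.abs(g_star).max() + 1e-12),
                np.abs(d_new - d_star).max() / (np.abs(d_star).max() + 1e-12),
            )
            g_star, d_star = g_new, d_new
            if change < conv:
                break
        gamma_star[:, i] = g_star
        delta_sq_star[:, i] = d_star

    z_adj = z.copy()
    for i, m in enumerate(masks):
        z_adj[:, m] = (z[:, m] - gamma_star[:, i][:, None]) / np.sqrt(
            delta_sq_star[:, i]
        )[:, None]
    y_adj = z_adj * np.sqrt(var_pooled)[:, None] + stand_mean

    out = study.values.copy()
    out.loc[:, :] = y_adj
    est = BatchEstimates(
        gamma_hat=pd.DataFrame(gamma_hat, index=genes, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=batches),
        delta_sq_hat=pd.DataFrame(delta_sq_hat, index=genes, columns=batches),
        delta_sq_star=pd.DataFrame(delta_sq_star, index=genes, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau_sq=pd.Series(tau_sq, index=batches),
        grand_mean=pd.Series(grand, index=genes),
        beta=pd.DataFrame(
            b_hat[n_batch:].T, index=genes, columns=list(cov_dummies.columns)
        ),
        var_pooled=pd.Series(var_pooled, index=genes),
    )
    return study.with_values(out), est


# ---------------------------------------------------------------------------
# medoid/MAD pruning
# ---------------------------------------------------------------------------
def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def medoid_mad_prune(
    study: ExpressionStudy,
    group_labels: pd.Series | dict,
    n_top_genes: int = 1000,
    strict: bool = False,
    center: str = "median_profile",
) -> dict[str, list[str]]:
    """Per group, retain samples within one MAD of the medoid.

    Distances are Euclidean over the ``n_top_genes`` most variable genes
    (z-scored).  Within each group of >= 3 samples the medoid minimizes total
    pairwise distance; a sample is retained when its distance to the group
    center is at most median + 1·MAD of the group's nonzero pairwise
    distances (``strict=True`` uses the bare MAD as the threshold).  The
    center defaults to the medoid's denoised profile — the gene-wise group
    median — because the raw medoid sample carries its own measurement noise
    into every distance, which at array scale swamps the one-MAD margin;
    ``center="medoid"`` uses the literal medoid sample instead.  The medoid
    is always retained; groups smaller than 3 pass through unpruned.
    """
    if center not in ("median_profile", "medoid"):
        raise ConfigError(f"unknown center {center!r}")
    labels = pd.Series(group_labels)
    x = study.values.to_numpy(dtype=float)
    variances = x.var(axis=1)
    top = np.argsort(variances, kind="stable")[::-1][: min(n_top_genes, x.shape[0])]
    sub = x[top]
    sd = sub.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(zs, columns=study.sample_ids)

    retained: dict[str, list[str]] = {}
    for group in sorted(labels.unique()):
        members = sorted(labels.index[labels == group])
        if len(members) < 3:
            retained[group] = members
            continue
        pts = zdf[members].to_numpy().T
        dmat = squareform(pdist(pts))
        medoid_idx = int(np.argmin(dmat.sum(axis=1)))
        if center == "medoid":
            d_center = dmat[medoid_idx]
        else:
            profile = np.median(pts, axis=0)
            d_center = np.linalg.norm(pts - profile, axis=1)
        pairwise = dmat[np.triu_indices(len(members), k=1)]
        nonzero = pairwise[pairwise > 0]
        if nonzero.size == 0:
            retained[group] = members
            continue
        if strict:
            threshold = _mad(nonzero)
        else:
            threshold = float(np.median(nonzero)) + _mad(nonzero)
        keep = [m for m, d in zip(members, d_center) if d <= threshold]
        if members[medoid_idx] not in keep:
            keep.append(members[medoid_idx])
        retained[group] = sorted(keep)
    return retained


# ---------------------------------------------------------------------------
# PCA diagnostics
# ---------------------------------------------------------------------------
def pca_project(study: ExpressionStudy, n_components: int = 2):
    """Centered PCA of samples; returns (coordinates, % variance explained)."""
    x = study.values.to_numpy(dtype=float).T  # samples × genes
    max_comp = min(x.shape)
    if not (1 <= n_components <= max_comp):
        raise ConfigError(f"n_components must lie in [1, {max_comp}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=study.sample_ids, columns=cols),
        100.0 * pca.explained_variance_ratio_,
    )
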
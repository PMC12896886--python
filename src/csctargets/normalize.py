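"""Cross-array intensity normalization.

Two methods operate on a probe × sample log2 matrix:

* quantile normalization — forces every sample onto the cross-sample mean of
  sorted intensity vectors, preserving within-sample rank order (ties by
  average rank);
* global rank-invariant set normalization (GRSN) — selects probes whose ranks
  are stable across samples by iteratively trimming the highest
  rank-variability probes, then corrects each array against an approximated
  common reference (the mean quantile-normalized sample) with a smooth
  monotone curve fitted on the invariant set.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .core import ConfigError, DataError, ExpressionStudy

__all__ = ["quantile_normalize", "grsn_normalize", "select_rank_invariant"]


def _quantile_normalize_matrix(x: np.ndarray) -> np.ndarray:
    n_probes = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    ranks = rankdata(x, axis=0, method="average")
    positions = np.arange(1, n_probes + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # fractional (tied) ranks interpolate between adjacent reference values,
        # i.e. tied probes share the mean of the tied reference slots
        out[:, j] = np.interp(ranks[:, j], positions, ref)
    return out


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-normalize all samples to their common mean distribution."""
    x = study.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ConfigError("quantile normalization needs >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("expression matrix contains non-finite values")
    out = study.values.astype(float)
    out.loc[:, :] = _quantile_normalize_matrix(x)
    return study.with_values(out)


def select_rank_invariant(
    x: np.ndarray, invariant_fraction: float = 0.25, n_sweep: int = 10
) -> np.ndarray:
    """Indices of the global rank-invariant probe set.

    Ranks are recomputed within the surviving probes at each sweep and the
    probes with the largest cross-sample rank variance are discarded on a
    geometric schedule until ``invariant_fraction`` of probes remains.
    """
    n_probes = x.shape[0]
    keep = np.arange(n_probes)
    for sweep in range(1, n_sweep + 1):
        target = int(round(n_probes * invariant_fraction ** (sweep / n_sweep)))
        target = max(target, 2)
        if len(keep) <= target:
            continue
        ranks = rankdata(x[keep], axis=0, method="average")
        score = ranks.var(axis=1)
        order = np.argsort(score, kind="stable")
        keep = np.sort(keep[order[:target]])
    return keep


def _monotone_curve(x_inv: np.ndarray, y_inv: np.ndarray):
    """Nondecreasing correction curve through the invariant points.

    The reference ordinates are monotone-adjusted by isotonic regression
    against the sample's intensity order; where noise breaks monotonicity the
    pool-adjacent-violators step averages neighboring points, so PAVA doubles
    as the local smoother.  Already-monotone (e.g. undistorted) data pass
    through exactly.  Returns knots for linear interpolation, with linear
    extrapolation beyond the fitted range.
    """
    order = np.argsort(x_inv, kind="stable")
    xs, ys = x_inv[order], y_inv[order]
    fitted = IsotonicRegression(increasing=True).fit_transform(
        np.arange(xs.size, dtype=float), ys
    )
    # collapse duplicate abscissae so interpolation is well defined
    xu, first = np.unique(xs, return_index=True)
    counts = np.diff(np.append(first, xs.size))
    yu = np.array([fitted[i : i + c].mean() for i, c in zip(first, counts)])
    return xu, yu


def _apply_curve(values: np.ndarray, xu: np.ndarray, yu: np.ndarray) -> np.ndarray:
    out = np.interp(values, xu, yu)
    # linear extrapolation using the end segments
    if xu.size >= 2:
        lo_slope = (yu[1] - yu[0]) / (xu[1] - xu[0])
        hi_slope = (yu[-1] - yu[-2]) / (xu[-1] - xu[-2])
        below = values < xu[0]
        above = values > xu[-1]
        out[below] = yu[0] + lo_slope * (values[below] - xu[0])
        out[above] = yu[-1] + hi_slope * (values[above] - xu[-1])
    return out


def grsn_normalize(
    study: ExpressionStudy,
    invariant_fraction: float = 0.25,
    n_sweep: int = 10,
    min_invariant: int = 10,
) -> ExpressionStudy:
    """Global rank-invariant set normalization.

    Each sample is mapped through a smooth monotone curve fitted on the
    rank-invariant probes against the approximated common reference (the mean
    of the quantile-normalized samples), removing per-array monotone intensity
    distortion while preserving within-array rank order on the invariant set.
    """
    x = study.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ConfigError("GRSN needs >= 2 samples")
    if not (0 < invariant_fraction <= 1):
        raise ConfigError("invariant_fraction must lie in (0, 1]")
    invariant = select_rank_invariant(x, invariant_fraction, n_sweep)
    if invariant.size < min_invariant:
        raise DataError(
            f"invariant set of {invariant.size} probes is too small for curve fitting"
        )
    reference = _quantile_normalize_matrix(x).mean(axis=1)

    corrected = np.empty_like(x)
    for j in range(x.shape[1]):
        xu, yu = _monotone_curve(x[invariant, j], reference[invariant])
        corrected[:, j] = _apply_curve(x[:, j], xu, yu)
    out = study.values.astype(float)
    out.loc[:, :] = corrected
    return study.with_values(out)
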
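"""Rank-product differential expression with permutation-based pfp control.

For two sample classes, every pairwise (a, b) sample comparison yields a
per-gene log2 fold change; fold changes are ranked across genes within each
comparison (rank 1 = strongest change in the direction analyzed, ties by
average rank) and the rank product is the geometric mean of a gene's ranks
over the K comparisons — small RP means consistent regulation.  Significance
is expressed as the false positive prediction (pfp): the permutation-expected
number of genes with an equal or smaller rank product, divided by the gene's
position in the observed RP ordering (an FDR-like quantity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ConfigError, DataError, ExpressionStudy

__all__ = ["DEResult", "rank_product", "pfp_filter", "class_fold_changes"]


@dataclass
class DEResult:
    """Per-gene rank products, pfp values and average log2 fold change."""

    table: pd.DataFrame  # columns RP_up, pfp_up, RP_down, pfp_down, log2fc
    class_a: str
    class_b: str
    n_pairs: int
    n_perm: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def _pair_fold_changes(a: np.ndarray, b: np.ndarray, pairs) -> np.ndarray:
    """G × K matrix of per-comparison log2 fold changes (a minus b)."""
    return np.stack([a[:, i] - b[:, j] for i, j in pairs], axis=1)


def _rp_from_fc(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(RP_up, RP_down) from a G × K fold-change matrix, average-tie ranks."""
    ranks_up = rankdata(-fc, axis=0, method="average")
    ranks_down = rankdata(fc, axis=0, method="average")
    rp_up = np.exp(np.log(ranks_up).mean(axis=1))
    rp_down = np.exp(np.log(ranks_down).mean(axis=1))
    return rp_up, rp_down


def _pfp(rp_obs: np.ndarray, rp_perm_counts: np.ndarray, n_perm: int) -> np.ndarray:
    """pfp = E_perm[# permuted RP <= observed RP] / rank position (ascending)."""
    positions = rankdata(rp_obs, method="average")
    expected_fp = rp_perm_counts / n_perm
    return expected_fp / positions


def rank_product(
    study: ExpressionStudy,
    class_a: str,
    class_b: str,
    n_perm: int = 100,
    max_pairs: int = 200,
    seed: int | None = None,
    exhaustive: bool = False,
    monotonize: bool = False,
) -> DEResult:
    """Rank-product analysis of ``class_a`` versus ``class_b``.

    All n_a × n_b pairwise sample comparisons are used (a seeded random subset
    of ``max_pairs`` when there are more).  The permutation null shuffles each
    gene's values across the pooled samples independently, ``n_perm`` times;
    ``exhaustive=True`` instead enumerates the full product of per-gene sample
    permutations (feasible only for a handful of genes and samples, used for
    oracle verification).  ``monotonize`` applies a cumulative-minimum
    step-down so pfp is nonincreasing in RP.
    """
    cls = study.classes()
    a_ids = list(cls.index[cls == class_a])
    b_ids = list(cls.index[cls == class_b])
    if not a_ids or not b_ids:
        raise ConfigError(f"class {class_a if not a_ids else class_b!r} absent from sample sheet")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ConfigError("need >= 2 samples per class")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")

    a = study.values[a_ids].to_numpy(dtype=float)
    b = study.values[b_ids].to_numpy(dtype=float)
    genes = study.probe_ids
    n_genes = len(genes)

    rng = np.random.default_rng(seed)
    pairs = list(itertools.product(range(len(a_ids)), range(len(b_ids))))
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    fc = _pair_fold_changes(a, b, pairs)
    rp_up, rp_down = _rp_from_fc(fc)
    log2fc = fc.mean(axis=1)

    pooled = np.hstack([a, b])
    n_samples = pooled.shape[1]
    n_a = len(a_ids)

    counts_up = np.zeros(n_genes)
    counts_down = np.zeros(n_genes)

    def _accumulate(perm_matrix: np.ndarray) -> None:
        pa, pb = perm_matrix[:, :n_a], perm_matrix[:, n_a:]
        pfc = _pair_fold_changes(pa, pb, pairs)
        prp_up, prp_down = _rp_from_fc(pfc)
        counts_up[:] += np.searchsorted(np.sort(prp_up), rp_up, side="right")
        counts_down[:] += np.searchsorted(np.sort(prp_down), rp_down, side="right")

    if exhaustive:
        perms = list(itertools.permutations(range(n_samples)))
        total = 0
        for combo in itertools.product(perms, repeat=n_genes):
            pm = np.stack([pooled[g, list(p)] for g, p in enumerate(combo)])
            _accumulate(pm)
            total += 1
        effective_perm = total
    else:
        for _ in range(n_perm):
            _accumulate(rng.permuted(pooled, axis=1))
        effective_perm = n_perm

    pfp_up = _pfp(rp_up, counts_up, effective_perm)
    pfp_down = _pfp(rp_down, counts_down, effective_perm)
    if monotonize:
        for arr, rp in ((pfp_up, rp_up), (pfp_down, rp_down)):
            order = np.argsort(rp, kind="stable")[::-1]
            arr[order] = np.minimum.accumulate(arr[order])

    table = pd.DataFrame(
        {
            "RP_up": rp_up,
            "pfp_up": pfp_up,
            "RP_down": rp_down,
            "pfp_down": pfp_down,
            "log2fc": log2fc,
        },
        index=genes,
    )
    return DEResult(
        table=table,
        class_a=class_a,
        class_b=class_b,
        n_pairs=len(pairs),
        n_perm=effective_perm,
        seed=seed,
    )


def pfp_filter(de: DEResult, cutoff: float = 0.1, direction: str = "up") -> list[str]:
    """Genes with pfp <= cutoff in the given direction, ordered by RP ascending."""
    if not (0 < cutoff <= 1):
        raise ConfigError("cutoff must lie in (0, 1]")
    if direction not in ("up", "down"):
        raise ConfigError(f"unknown direction {direction!r}")
    t = de.table
    hits = t[t[f"pfp_{direction}"] <= cutoff]
    return list(hits.sort_values(f"RP_{direction}", kind="stable").index)


def class_fold_changes(
    study: ExpressionStudy,
    reference_class: str = "sCSC",
    other_classes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mean log2 fold change of the reference class vs each other class.

    Returns a DataFrame with one ``log2fc_<class>`` and one ``fc_<class>``
    (linear scale) column per comparison class.
    """
    cls = study.classes()
    if other_classes is None:
        other_classes = sorted(set(cls) - {reference_class})
    for c in [reference_class, *other_classes]:
        if (cls == c).sum() == 0:
            raise ConfigError(f"class {c!r} has no samples")
    ref_mean = study.values[list(cls.index[cls == reference_class])].mean(axis=1)
    out = {}
    for c in other_classes:
        diff = ref_mean - study.values[list(cls.index[cls == c])].mean(axis=1)
        out[f"log2fc_{c}"] = diff
        out[f"fc_{c}"] = 2.0 ** diff
    return pd.DataFrame(out, index=study.probe_ids)
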
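"""Independent brute-force oracles used only by the test suite.

Everything here is written as plain loops / exhaustive enumeration / dense
grid search, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# rank product
# ---------------------------------------------------------------------------
def _avg_rank_desc(values, g):
    """Average rank of values[g] when the largest value gets rank 1."""
    greater = sum(1 for v in values if v > values[g])
    ties = sum(1 for v in values if v == values[g])
    return greater + (ties + 1) / 2.0


def oracle_rank_product(a, b, direction="up"):
    """RP per gene from explicit enumeration of every pairwise comparison.

    ``a``/``b``: gene × sample arrays for the two classes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_genes = a.shape[0]
    rps = []
    pairs = [(i, j) for i in range(a.shape[1]) for j in range(b.shape[1])]
    for g in range(n_genes):
        log_sum = 0.0
        for i, j in pairs:
            fcs = [a[h, i] - b[h, j] for h in range(n_genes)]
            if direction == "up":
                r = _avg_rank_desc(fcs, g)
            else:
                r = _avg_rank_desc([-f for f in fcs], g)
            log_sum += math.log(r)
        rps.append(math.exp(log_sum / len(pairs)))
    return np.array(rps)


def oracle_exhaustive_pfp(a, b, direction="up"):
    """pfp per gene from full enumeration of all joint within-gene sample
    permutations (feasible only for a handful of genes / samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_genes, n_a = a.shape
    pooled = np.hstack([a, b])
    n_samples = pooled.shape[1]
    rp_obs = oracle_rank_product(a, b, direction)

    # observed rank positions, average ties
    positions = []
    for g in range(n_genes):
        smaller = sum(1 for v in rp_obs if v < rp_obs[g])
        ties = sum(1 for v in rp_obs if v == rp_obs[g])
        positions.append(smaller + (ties + 1) / 2.0)

    perms = list(itertools.permutations(range(n_samples)))
    counts = [0.0] * n_genes
    total = 0
    for combo in itertools.product(perms, repeat=n_genes):
        pa = np.array([[pooled[g, combo[g][s]] for s in range(n_a)] for g in range(n_genes)])
        pb = np.array(
            [[pooled[g, combo[g][s]] for s in range(n_a, n_samples)] for g in range(n_genes)]
        )
        rp_perm = oracle_rank_product(pa, pb, direction)
        for g in range(n_genes):
            counts[g] += sum(1 for v in rp_perm if v <= rp_obs[g])
        total += 1
    return np.array([counts[g] / total / positions[g] for g in range(n_genes)])


# ---------------------------------------------------------------------------
# curve-fit oracles: dense grid search
# ---------------------------------------------------------------------------
def oracle_one_site_grid(x, y, kd_lo, kd_hi, n=4001):
    """Best (bmax, kd) on a dense log grid with closed-form bmax."""
    best = (np.inf, None, None)
    for kd in np.geomspace(kd_lo, kd_hi, n):
        f = x / (kd + x)
        bmax = float(f @ y / (f @ f))
        rss = float(np.sum((y - bmax * f) ** 2))
        if rss < best[0]:
            best = (rss, bmax, kd)
    return {"bmax": best[1], "kd": best[2], "rss": best[0]}


def oracle_4pl_grid(x, y, ic50_lo, ic50_hi, n_ic50=2001, hills=None):
    """Best 4PL on a dense IC50 × hill grid with closed-form top/bottom
    (the model is linear in (top, bottom) once IC50 and hill are fixed)."""
    hills = hills if hills is not None else np.linspace(0.25, 4.0, 16)
    best = (np.inf, None)
    for hill in hills:
        for ic50 in np.geomspace(ic50_lo, ic50_hi, n_ic50):
            w = 1.0 / (1.0 + (x / ic50) ** hill)  # weight on (top - bottom)
            design = np.column_stack([np.ones_like(x), w])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            pred = design @ coef
            rss = float(np.sum((y - pred) ** 2))
            if rss < best[0]:
                best = (rss, {"top": coef[0] + coef[1], "bottom": coef[0], "ic50": ic50, "hill": hill, "rss": rss})
    return best[1]


def oracle_sensorgram_ode(conc, ka, kd, rmax, t_grid, t_assoc):
    """1:1 binding sensorgram via numerical ODE integration (independent of
    the closed-form expressions used by the package):
    dR/dt = ka*C*(Rmax - R) - kd*R during association, C = 0 afterwards."""
    from scipy.integrate import solve_ivp

    def rhs(t, r):
        c = conc if t <= t_assoc else 0.0
        return ka * c * (rmax - r[0]) - kd * r[0]

    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), [0.0], t_eval=t_grid, rtol=1e-10, atol=1e-12,
        max_step=1.0,
    )
    return sol.y[0]
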
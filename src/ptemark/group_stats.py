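"""Group-difference inference for variance-coded effects.

Lesions after TBI land in different places in different subjects, so group
differences show up as *variance* rather than mean differences.  The core
test is therefore a one-sided variance-ratio F statistic (PTE variance over
non-PTE variance) whose null distribution is obtained by permuting group
labels; voxel maps are corrected with Benjamini-Hochberg FDR.  Lobe-level
lesion volumes use a one-sided Wilcoxon rank-sum test instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "pointwise_variance_f",
    "permutation_f_test",
    "bh_fdr",
    "ranksum_test",
    "region_tests",
]

logger = logging.getLogger(__name__)


@dataclass
class StatMap:
    """Per-voxel F ratio, permutation p-values, and FDR significance mask."""

    F: np.ndarray
    p_raw: np.ndarray
    p_fdr_mask: np.ndarray  # bool, significant at q
    q: float
    nperm: int
    seed: int | None
    exhaustive: bool  # True when all distinct labelings were enumerated
    numerator_group: str = "PTE"


def _as_2d(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 1:
        maps = maps[:, None]
    elif maps.ndim > 2:
        maps = maps.reshape(maps.shape[0], -1)
    return maps


def _variance_ratio(x: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """F(v) = s^2_A(v) / s^2_B(v) with unbiased (n-1) variances.

    Zero denominator with a positive numerator yields +inf (sentinel); a
    0/0 voxel is reported as F = 1 (no evidence either way).
    """
    va = x[is_a].var(axis=0, ddof=1)
    vb = x[~is_a].var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = va / vb
    f = np.where((vb == 0) & (va > 0), np.inf, f)
    f = np.where((vb == 0) & (va == 0), 1.0, f)
    return f


def pointwise_variance_f(
    group_a_maps: np.ndarray, group_b_maps: np.ndarray
) -> np.ndarray:
    """Observed per-voxel variance ratio, group A (PTE) in the numerator."""
    a = _as_2d(group_a_maps)
    b = _as_2d(group_b_maps)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups are on different grids")
    x = np.concatenate([a, b], axis=0)
    is_a = np.zeros(x.shape[0], dtype=bool)
    is_a[: a.shape[0]] = True
    f = _variance_ratio(x, is_a)
    n_inf = int(np.isinf(f).sum())
    if n_inf:
        logger.info("%d voxels with zero denominator variance set to +inf", n_inf)
    return f.reshape(np.asarray(group_a_maps).shape[1:] or (1,))


def _perm_variances(x2sum: np.ndarray, xsum: np.ndarray, s1: np.ndarray,
                    s2: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Vectorized F for many labelings from group-A sums s1/s2 and totals."""
    va = (s2 - s1**2 / na) / (na - 1)
    vb = ((x2sum - s2) - (xsum - s1) ** 2 / nb) / (nb - 1)
    va = np.clip(va, 0.0, None)
    vb = np.clip(vb, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = va / vb
    f = np.where((vb == 0) & (va > 0), np.inf, f)
    f = np.where((vb == 0) & (va == 0), 1.0, f)
    return f


def permutation_f_test(
    group_a_maps: np.ndarray,
    group_b_maps: np.ndarray,
    nperm: int = 1000,
    seed: int | None = 0,
    q: float = 0.05,
) -> StatMap:
    """One-sided permutation variance F-test (alternative: var_A > var_B).

    The same label permutation is applied to every voxel in a given iteration,
    preserving the spatial correlation of the maps.  Monte-Carlo p-values use
    the (1 + #{F_perm >= F_obs}) / (nperm + 1) convention, so p is never 0.
    When the number of distinct labelings C(n_A + n_B, n_A) does not exceed
    ``nperm``, all labelings are enumerated instead and
    p = #{F_perm >= F_obs} / n_labelings (the identity labeling is included,
    so p >= 1/n_labelings).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    a = _as_2d(group_a_maps)
    b = _as_2d(group_b_maps)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    x = np.concatenate([a, b], axis=0)
    x2 = x**2
    xsum = x.sum(axis=0)
    x2sum = x2.sum(axis=0)

    obs_is_a = np.zeros(n, dtype=bool)
    obs_is_a[:na] = True
    f_obs = _variance_ratio(x, obs_is_a)
    # comparison value computed with the same running-sums formula as the
    # permuted statistics, so the identity labeling ties exactly
    f_cmp = _perm_variances(x2sum, xsum, x[:na].sum(axis=0), x2[:na].sum(axis=0),
                            na, nb)

    n_labelings = math.comb(n, na)
    exhaustive = n_labelings <= nperm
    if exhaustive:
        count = np.zeros(x.shape[1], dtype=np.int64)
        for combo in combinations(range(n), na):
            sel = np.array(combo)
            s1 = x[sel].sum(axis=0)
            s2 = x2[sel].sum(axis=0)
            f_perm = _perm_variances(x2sum, xsum, s1, s2, na, nb)
            count += f_perm >= f_cmp
        p = count / n_labelings
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(x.shape[1], dtype=np.int64)
        # batched to bound memory at ~nperm_batch * n_voxels floats
        batch = max(1, min(nperm, int(5e7 // max(x.shape[1], 1)) or 1))
        done = 0
        while done < nperm:
            nb_iter = min(batch, nperm - done)
            order = np.argsort(rng.random((nb_iter, n)), axis=1)[:, :na]
            sel = np.zeros((nb_iter, n), dtype=np.float64)
            np.put_along_axis(sel, order, 1.0, axis=1)
            s1 = sel @ x
            s2 = sel @ x2
            f_perm = _perm_variances(x2sum, xsum, s1, s2, na, nb)
            count += (f_perm >= f_cmp).sum(axis=0)
            done += nb_iter
        p = (1.0 + count) / (nperm + 1.0)

    reject = bh_fdr(p, q=q)
    shape = np.asarray(group_a_maps).shape[1:] or (1,)
    return StatMap(
        F=f_obs.reshape(shape),
        p_raw=p.reshape(shape),
        p_fdr_mask=reject.reshape(shape),
        q=q,
        nperm=nperm,
        seed=seed,
        exhaustive=exhaustive,
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p <= p_(k*) with
    k* = max{k : p_(k) <= k q / m}.  Returns a boolean rejection array."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject.reshape(np.asarray(p_values).shape)


def ranksum_test(x, y, alternative: str = "x_greater") -> float:
    """One-sided Wilcoxon rank-sum p-value.

    Exact enumeration when m + n <= 12 with no ties, the tie-corrected normal
    approximation otherwise (scipy's Mann-Whitney U implementation).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"x_greater": "greater", "x_less": "less", "two_sided": "two-sided"}[
        alternative
    ]
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alt, method=method).pvalue)


def region_tests(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    roi_names: tuple[str, ...] | list[str],
    nperm: int = 1000,
    seed: int | None = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Lobe-wise group comparison table.

    Per ROI: a one-sided rank-sum p on lesion volumes (PTE > nonPTE) and a
    one-sided permutation-F p on ALFF variance (var PTE > var nonPTE), each
    BH-corrected across ROIs separately.  ``features`` must carry
    ``lesvol_<roi>`` and ``alff_<roi>`` columns; ``labels`` holds "PTE" /
    "nonPTE" per row.
    """
    labels = np.asarray(labels)
    is_pte = labels == "PTE"
    rows = []
    for name in roi_names:
        col = name.replace(" ", "_")
        les_col, alff_col = f"lesvol_{col}", f"alff_{col}"
        for c in (les_col, alff_col):
            if c not in features.columns:
                raise KeyError(f"missing feature column {c!r}")
        p_les = ranksum_test(
            features.loc[is_pte, les_col].to_numpy(),
            features.loc[~is_pte, les_col].to_numpy(),
            alternative="x_greater",
        )
        sm = permutation_f_test(
            features.loc[is_pte, alff_col].to_numpy()[:, None],
            features.loc[~is_pte, alff_col].to_numpy()[:, None],
            nperm=nperm,
            seed=seed,
        )
        rows.append({"roi": name, "p_lesion": p_les, "p_alff": float(sm.p_raw[0])})
    table = pd.DataFrame(rows)
    table["sig_lesion"] = bh_fdr(table["p_lesion"].to_numpy(), q=q)
    table["sig_alff"] = bh_fdr(table["p_alff"].to_numpy(), q=q)
    return table
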
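"""Compositional statistics: Spearman, PERMANOVA, ANOSIM, distances, PCA.

These are the tests behind the cohort comparisons: Spearman rank
correlation (with exact permutation p-values at small n), one-factor
PERMANOVA and ANOSIM on a distance matrix with seeded permutation
null distributions, and PCA scores/loadings for biplots of transformed
compound-class profiles.

Permutation p-values everywhere use the +1 correction
``p = (1 + #{perm stat >= observed}) / (1 + n_perm)`` so they are never
exactly zero and are bounded below by 1/(n_perm + 1). Ties are handled
with mid-ranks throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from scipy import stats as _sps

__all__ = [
    "SpearmanResult",
    "PermanovaResult",
    "AnosimResult",
    "spearman",
    "distance_matrix",
    "permanova",
    "anosim",
    "pca_biplot",
    "doc_class_correlations",
]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class PermanovaResult:
    f_stat: float
    r2: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class AnosimResult:
    r_stat: float
    p: float
    n_perm: int


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties allowed). For
    n <= ``exact_max_n`` the p-value is exact, from full enumeration of
    the n! orderings of y; otherwise the usual t-approximation with
    n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = rankdata(y)
        perms = np.array(list(itertools.permutations(ry)))
        rx = rankdata(x)
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 2.0 / math.factorial(n) if n <= 20 else np.finfo(float).tiny
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * _sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p=min(p, 1.0), n=n)


def distance_matrix(x, metric: str = "jaccard") -> np.ndarray:
    """Symmetric pairwise distance matrix between sample rows.

    ``jaccard`` treats rows as presence/absence (x > 0); ``bray-curtis``
    and ``euclidean`` use the values as given. Rows that are entirely
    empty have undefined jaccard/bray distances; they are assigned
    distance 1 to every other sample (and 0 to themselves) with a
    warning.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    metric = metric.lower().replace("_", "-")
    if metric == "jaccard":
        cond = pdist(arr > 0, metric="jaccard")
    elif metric == "bray-curtis":
        cond = pdist(arr, metric="braycurtis")
    elif metric == "euclidean":
        cond = pdist(arr, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = squareform(cond)
    empty = ~(arr != 0).any(axis=1)
    if empty.any() and metric in ("jaccard", "bray-curtis"):
        warnings.warn(
            f"{int(empty.sum())} empty sample row(s); distances to them set to 1",
            UserWarning,
            stacklevel=2,
        )
        for i in np.flatnonzero(empty):
            d[i, :] = 1.0
            d[:, i] = 1.0
            d[i, i] = 0.0
    else:
        d = np.nan_to_num(d, nan=0.0)
    return d


def _as_group_codes(groups) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(list(groups)))
    return codes, list(uniques)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    d: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    The pseudo-F is computed from sums of squared inter-point distances:
    SS_total = sum of squared distances / n, SS_within analogously per
    group, F = (SS_between/(g-1)) / (SS_within/(n-g)). The p-value
    permutes the group labels; with ``exhaustive=True`` every distinct
    labeling is enumerated instead (the p is then exact, without the +1
    correction since the observed labeling is one of the enumerated
    ones).
    """
    d = np.asarray(d, dtype=float)
    codes, uniques = _as_group_codes(groups)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(codes) != n:
        raise ValueError("groups must label every sample")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    g = len(uniques)
    d2 = d**2
    f_obs, r2 = _permanova_f(d2, codes, g)
    if exhaustive:
        count, total = 0, 0
        for perm in _distinct_labelings(codes):
            f_p, _ = _permanova_f(d2, perm, g)
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        n_perm = total
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            f_p, _ = _permanova_f(d2, rng.permutation(codes), g)
            count += f_p >= f_obs - 1e-12
        p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_stat=f_obs, r2=r2, p=float(p), n_perm=n_perm)


def _distinct_labelings(codes: np.ndarray):
    """Yield every distinct assignment of labels preserving group sizes."""
    n = len(codes)
    sizes = np.bincount(codes)
    if len(sizes) == 2:
        for combo in itertools.combinations(range(n), int(sizes[1])):
            perm = np.zeros(n, dtype=int)
            perm[list(combo)] = 1
            yield perm
    else:
        seen = set()
        for perm in itertools.permutations(codes):
            if perm not in seen:
                seen.add(perm)
                yield np.array(perm)


def _anosim_r(rank_d: np.ndarray, within: np.ndarray) -> float:
    m = len(rank_d)
    return float((rank_d[~within].mean() - rank_d[within].mean()) / (m / 2.0))


def anosim(
    d: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based group separation statistic.

    R = (mean rank of between-group distances − mean rank of
    within-group distances) / (M/2) with M = n(n−1)/2 and mid-ranks for
    ties; R = 1 iff every between-group distance exceeds every
    within-group distance. Permutation p as in :func:`permanova`.
    """
    d = np.asarray(d, dtype=float)
    codes, _ = _as_group_codes(groups)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    iu = np.triu_indices(n, k=1)
    rank_d = rankdata(d[iu])
    within_obs = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(rank_d, within_obs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        count += _anosim_r(rank_d, perm[iu[0]] == perm[iu[1]]) >= r_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(r_stat=r_obs, p=float(p), n_perm=n_perm)


def pca_biplot(x) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores, loadings and explained-variance fractions for a biplot.

    ``x`` is a samples x classes matrix (ideally already transformed);
    it is centered here regardless. Signs are fixed so the
    largest-magnitude element of each loading vector is positive, which
    makes biplots reproducible across LAPACK builds.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    centered = arr - arr.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: per component, largest-|loading| element positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return scores, vt.T, frac


def doc_class_correlations(profiles: pd.DataFrame, doc) -> pd.DataFrame:
    """Spearman correlation of every compound class with DOC concentration.

    ``profiles`` is a samples x classes matrix (normalized counts);
    ``doc`` the matched per-sample DOC vector (mg C/L). Returns one row
    per class (rho, p, n), ordered by decreasing |rho|. Constant classes
    get NaN rho with p = 1.
    """
    doc = np.asarray(doc, dtype=float)
    if len(doc) != len(profiles):
        raise ValueError("DOC vector length must match the profile matrix")
    rows = []
    for cls in profiles.columns:
        vals = profiles[cls].to_numpy(dtype=float)
        try:
            res = spearman(vals, doc)
            rows.append({"class": cls, "rho": res.rho, "p": res.p, "n": res.n})
        except ValueError:
            rows.append({"class": cls, "rho": np.nan, "p": 1.0, "n": len(doc)})
    out = pd.DataFrame(rows).set_index("class")
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index)
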
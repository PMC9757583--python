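"""Landscape-genetic association tests.

Associates genetic differentiation (pairwise F_ST) with landscape distance
matrices via Mantel permutation tests, and genetic diversity (expected
heterozygosity He) with habitat-node connectivity via Pearson correlation of
He against log-transformed current-flow betweenness, across a grid of
network-threshold scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DistanceMatrix, PointSet

__all__ = [
    "MantelResult",
    "GeneticData",
    "mantel_test",
    "diversity_centrality_correlation",
    "select_scale",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str


@dataclass
class GeneticData:
    """Genetic summaries for the sampled populations."""

    fst: DistanceMatrix
    he: np.ndarray
    sites: PointSet

    def __post_init__(self) -> None:
        self.he = np.asarray(self.he, dtype=float)
        if len(self.he) != self.fst.n or len(self.sites) != self.fst.n:
            raise ValueError("F_ST labels, He vector and sites must agree in length")
        if not np.array_equal(np.asarray(self.fst.labels, dtype=object),
                              np.asarray(self.sites.ids, dtype=object)):
            raise ValueError("F_ST labels must match site ids")


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0:
        raise ValueError("zero variance in a distance vector")
    return float((u @ v) / denom)


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    The statistic is the Pearson correlation of the vectorized upper
    triangles.  The null distribution jointly permutes the rows and columns
    of ``B``; the p-value uses the +1 correction
    p = (1 + #{r_perm as or more extreme}) / (1 + n_perm).

    With ``exact=True`` all n! relabelings are enumerated instead (feasible
    for small n only) and p is the exact fraction of relabelings at least as
    extreme as the observed one (the identity is included, so p > 0).
    """
    if A.n != B.n or not np.array_equal(
        np.asarray(A.labels, dtype=object), np.asarray(B.labels, dtype=object)
    ):
        raise ValueError("distance matrices must share the same labels")
    if A.n < 4:
        raise ValueError("Mantel test requires at least 4 sites")
    if A.has_infinite() or B.has_infinite():
        raise ValueError(
            "distance matrix contains infinite (disconnected) entries; "
            "exclude them before testing"
        )
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = A.n
    iu = np.triu_indices(n, k=1)
    a_vec = A.values[iu]
    r_obs = _pearson(a_vec, B.values[iu])
    if exact:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))))
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    # vectorized: permuted upper triangles of B via fancy indexing
    b_perm = B.values[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n*(n-1)/2)
    ac = a_vec - a_vec.mean()
    bc = b_perm - b_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * np.einsum("ij,ij->i", bc, bc))
    with np.errstate(invalid="ignore"):
        r_perm = (bc @ ac) / denom
    r_perm = np.nan_to_num(r_perm)
    eps = 1e-12  # count exact ties as "as extreme"
    if alternative == "greater":
        extreme = np.sum(r_perm >= r_obs - eps)
    elif alternative == "less":
        extreme = np.sum(r_perm <= r_obs + eps)
    else:
        extreme = np.sum(np.abs(r_perm) >= abs(r_obs) - eps)
    if exact:
        p = extreme / n_perm  # identity relabeling is counted, so p > 0
    else:
        p = (1 + extreme) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, alternative=alternative)


def diversity_centrality_correlation(
    he: np.ndarray, cfbc: np.ndarray, log_transform: bool = True
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of He against (log) CFBC.

    CFBC scores are natural-log transformed by default (the base only
    rescales and leaves r unchanged); they must then be strictly positive.
    """
    he = np.asarray(he, dtype=float)
    cfbc = np.asarray(cfbc, dtype=float)
    if len(he) != len(cfbc) or len(he) < 3:
        raise ValueError("he and cfbc must have equal length >= 3")
    if log_transform:
        if np.any(cfbc <= 0):
            raise ValueError("cfbc must be strictly positive under log transform")
        cfbc = np.log(cfbc)
    if np.std(he) == 0 or np.std(cfbc) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(he, cfbc)
    return float(r), float(p)


def select_scale(
    thresholded_results: dict[float, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    log_transform: bool = True,
) -> tuple[float, list[dict]]:
    """Pick the network threshold whose He–CFBC correlation is strongest.

    Among thresholds with p < ``alpha`` the one with maximal r is returned
    (ties go to the smallest threshold).  If none is significant the max-r
    threshold is returned and the table rows carry ``significant=False``
    with a warning.
    """
    if not thresholded_results:
        raise ValueError("at least one threshold is required")
    table = []
    for thr in sorted(thresholded_results):
        he, cfbc = thresholded_results[thr]
        r, p = diversity_centrality_correlation(he, cfbc, log_transform)
        table.append({"threshold": float(thr), "r": r, "p": p, "significant": p < alpha})
    sig = [row for row in table if row["significant"]]
    pool = sig if sig else table
    if not sig:
        warnings.warn("no threshold reached significance; returning the max-r threshold")
    best = max(pool, key=lambda row: (row["r"], -row["threshold"]))
    return best["threshold"], table
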
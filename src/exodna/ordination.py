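"""Community comparison: Bray-Curtis distances, NMDS and PERMANOVA.

Exocellular-DNA fractions are compared with co-occurring cellular and
viral communities by ordination of square-root-transformed proportional
count tables.  Bray-Curtis dissimilarities feed a nonmetric
multidimensional scaling (NMDS) embedding (Kruskal stress-1 reported) and
one-way PERMANOVA: Anderson's pseudo-F computed directly on the distance
matrix, with a permutation p-value from whole-sample label shuffles.
Pairwise group comparisons are corrected with the Benjamini-Hochberg
step-up procedure.

Bray-Curtis, the pseudo-F and the BH adjustment are implemented here (they
are the statistics under test); the NMDS numerical optimization is
delegated to scikit-learn's SMACOF with stress-1 recomputed via isotonic
regression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS


def sqrt_transform(comp: pd.DataFrame) -> pd.DataFrame:
    """Elementwise square root of a proportional count table (no renormalization).

    Dampens the influence of dominant taxa before distance computation.
    """
    if (comp.to_numpy() < 0).any():
        raise ValueError("proportions must be non-negative")
    return np.sqrt(comp)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y).

    0 for identical vectors, 1 for disjoint supports; requires
    non-negative inputs with at least one positive entry overall.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(comp: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between the columns (samples) of a
    taxon x sample composition table."""
    X = comp.to_numpy(dtype=float).T
    dm = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(dm, index=comp.columns, columns=comp.columns)


@dataclass
class PermanovaResult:
    """One-way PERMANOVA outcome on a distance matrix."""

    pseudo_F: float
    p_value: float
    n_permutations: int
    groups: tuple[str, ...]
    seed: int | None = None


def _pseudo_F(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and group labels.

    SS_total = (1/N) sum_{i<j} d_ij^2 ; SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2 ; F = (SS_A / (g-1)) / (SS_W / (N-g)).
    """
    N = len(labels)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = 0.0
    for g in groups:
        m = labels == g
        n_g = int(m.sum())
        ss_within += D2[np.ix_(m, m)].sum() / (2.0 * n_g)
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = N - len(groups)
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(dm: pd.DataFrame | np.ndarray, labels, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    The permutation p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``
    over whole-sample label permutations, so its minimum attainable value
    is ``1 / (n_perm + 1)``.  Deterministic under ``seed``.  Degenerate
    all-equal distance matrices report p = 1.
    """
    D = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(labels)
    if labels.size != D.shape[0]:
        raise ValueError("one label per sample required")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    D2 = D ** 2
    F_obs = _pseudo_F(D2, labels, groups)
    if not np.isfinite(F_obs) and F_obs == 0.0:
        pass
    rng = np.random.default_rng(seed)
    # Vectorized permutation null: per group, an indicator matrix over
    # permutations; within-group SS via quadratic forms m @ D2 @ m.
    perms = np.array([rng.permutation(labels.size) for _ in range(n_perm)])
    ss_total = D2.sum() / (2.0 * labels.size)
    ss_within_perm = np.zeros(n_perm)
    for g, n_g in zip(groups, counts):
        pos = np.where(labels == g)[0]
        member = np.zeros((n_perm, labels.size))
        rows = np.repeat(np.arange(n_perm), pos.size)
        member[rows, perms[:, pos].ravel()] = 1.0
        ss_within_perm += np.einsum("pi,ij,pj->p", member, D2, member) / (2.0 * n_g)
    df_among = groups.size - 1
    df_within = labels.size - groups.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F_perm = ((ss_total - ss_within_perm) / df_among) / (ss_within_perm / df_within)
    F_perm = np.nan_to_num(F_perm, nan=0.0, posinf=np.inf)

    if not np.isfinite(F_obs) or F_obs == 0.0 and np.allclose(D2, D2.flat[0]):
        p = 1.0
    else:
        p = (1.0 + np.sum(F_perm >= F_obs)) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=float(F_obs), p_value=float(p),
                           n_permutations=n_perm,
                           groups=tuple(str(g) for g in groups), seed=seed)


def pairwise_permanova(dm: pd.DataFrame, labels: pd.Series, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """PERMANOVA for every pair of groups, BH-adjusted across the pairs.

    ``labels`` is indexed by sample id.  Returns one row per group pair
    with pseudo-F, raw and adjusted p-values.
    """
    labels = labels.reindex(dm.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    rows = []
    for k, (a, b) in enumerate(itertools.combinations(groups, 2)):
        keep = labels.isin([a, b]).to_numpy()
        sub = dm.loc[keep, keep]
        res = permanova(sub, labels[keep].to_numpy(), n_perm=n_perm, seed=seed + k)
        rows.append({"group_a": a, "group_b": b, "pseudo_F": res.pseudo_F,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_list())
    return out


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    ``p_(i) * m / i`` with a running minimum from the largest p downward;
    output order matches the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out.tolist()


def kruskal_stress(dissim: np.ndarray, embedding: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against target dissimilarities.

    Fitted distances are the isotonic (monotone) regression of the
    embedding distances on the dissimilarity ranks; stress-1 =
    sqrt( sum (d - dhat)^2 / sum d^2 ).
    """
    d = pdist(embedding)
    delta = squareform(np.asarray(dissim, float), checks=False)
    iso = IsotonicRegression()
    dhat = iso.fit_transform(delta, d)
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(dm: pd.DataFrame | np.ndarray, k: int = 2, seed: int = 0,
         n_restarts: int = 4) -> tuple[pd.DataFrame, float]:
    """Nonmetric multidimensional scaling of a distance matrix.

    Runs scikit-learn's nonmetric SMACOF from ``n_restarts`` seeded random
    starts and returns the configuration with the lowest Kruskal stress-1,
    as ``(coordinates, stress)``.  Deterministic under ``seed``.
    """
    ids = dm.index if isinstance(dm, pd.DataFrame) else pd.RangeIndex(len(dm))
    D = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    best: tuple[float, np.ndarray] | None = None
    # first start from the classical (metric) solution, then random restarts
    for r in range(n_restarts):
        mds = MDS(n_components=k, metric_mds=False, metric="precomputed",
                  init="classical_mds" if r == 0 else "random",
                  n_init=1, random_state=seed + r, max_iter=500,
                  normalized_stress=False, eps=1e-9)
        X = mds.fit_transform(D)
        s = kruskal_stress(D, X)
        if best is None or s < best[0]:
            best = (s, X)
    stress, X = best
    coords = pd.DataFrame(X, index=ids, columns=[f"NMDS{i+1}" for i in range(k)])
    return coords, float(stress)
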
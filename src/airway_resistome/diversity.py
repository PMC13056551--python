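"""Alpha/beta diversity, principal-coordinate embedding and a one-factor
permutational location test.

Shannon diversity is reported in nats by default (natural log, the
convention of the usual ecology toolkits); ``base=2`` is available.
Beta diversity is Bray–Curtis dissimilarity
``d(u, v) = sum |u_i - v_i| / sum (u_i + v_i)``.
The permutational test is the one-factor special case (no covariates):
a pseudo-F from between/within sums of squared distances with a
permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import FeatureTable

__all__ = [
    "DistanceMatrix",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "PCoAResult",
    "permanova_oneway",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample identifiers."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (zero entries contribute 0)."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero profile")
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of extreme abundance ratios
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def alpha_diversity(table: FeatureTable, base: float | None = None) -> pd.Series:
    """Per-sample Shannon diversity over a feature table."""
    return pd.Series(
        {s: shannon(table.values.loc[s].to_numpy(), base=base) for s in table.samples},
        name="shannon",
    )


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity between two non-negative abundance profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must have the same length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero profiles")
    return float(np.abs(u - v).sum() / denom)


def bray_curtis_matrix(table: FeatureTable) -> DistanceMatrix:
    mat = table.values.to_numpy(dtype=float)
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(mat[i], mat[j])
    return DistanceMatrix(d, table.samples)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    negative_eigenvalues: np.ndarray  # dropped (magnitudes reported)
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns the top-``k``
    coordinates scaled by the square root of their eigenvalues.  Negative
    eigenvalues (non-Euclidean input) are dropped and reported.  When the
    input distances are Euclidean the full-rank embedding reproduces them.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    dm = d.values
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals)) * 1e-10 if evals.size else 0.0
    pos = evals > tol
    pos_vals = evals[pos]
    neg_vals = evals[evals < -tol]
    if k > pos_vals.size:
        k = int(pos_vals.size)  # truncated: fewer positive axes than requested
    coords = evecs[:, pos][:, :k] * np.sqrt(pos_vals[:k])
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    total = pos_vals.sum()
    return PCoAResult(
        coordinates=frame,
        eigenvalues=pos_vals,
        negative_eigenvalues=neg_vals,
        proportion_explained=pos_vals / total if total > 0 else pos_vals,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ssb = sst - ssw
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def permanova_oneway(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "sampled",
) -> tuple[float, float]:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    Returns ``(pseudo_F, p)`` with ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``
    for seeded Monte-Carlo permutations (``method="sampled"``), or the exact
    fraction over every label permutation for ``method="exhaustive"``
    (feasible only at small n).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(d.ids):
        raise ValueError("labels must match the distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if groups.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = d.values**2
    f_obs = _pseudo_f(d2, codes, groups.size)
    if method == "exhaustive":
        import itertools

        hits = 0
        total = 0
        for perm in itertools.permutations(codes):
            total += 1
            if _pseudo_f(d2, np.asarray(perm), groups.size) >= f_obs - 1e-12:
                hits += 1
        return f_obs, hits / total
    if method != "sampled":
        raise ValueError("method must be 'sampled' or 'exhaustive'")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, groups.size) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)
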
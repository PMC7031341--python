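"""Community diversity and multivariate statistics.

Alpha diversity is the effective number of species exp(H), with Shannon's H
in nats; beta diversity is Bray-Curtis dissimilarity on absolute abundances.
Group structure is tested by one-way PERMANOVA (pseudo-F partition of the
squared-dissimilarity sums, label permutation), homogeneity of multivariate
dispersion by distances to group centroids in principal-coordinate space
(real/imaginary split for negative eigenvalues), and ordination by PCA on
log10-transformed abundances where below-LOD zeros are first replaced by 1
(log10 1 = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import DesignError
from .permstats import PermTestResult, _anova_f_rows, _group_indices

__all__ = [
    "shannon",
    "effective_species",
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "dispersion",
    "DispersionResult",
    "log_transform",
    "pca",
    "OrdinationResult",
]


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats); zero entries contribute 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    s = p.sum()
    if s <= 0:
        raise ValueError("proportions must sum to a positive value")
    p = p / s
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def effective_species(h: float) -> float:
    """Effective number of species exp(H): equally-abundant-taxon equivalent."""
    if h < 0:
        raise ValueError("Shannon diversity cannot be negative")
    return float(np.exp(h))


def alpha_diversity(abundances: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon H and effective species number.

    ``abundances`` has samples as rows and taxa as columns; rows are
    normalized internally, so absolute or relative values give identical
    diversity (scale invariance of H).
    """
    rows = []
    for sid, row in abundances.iterrows():
        h = shannon(row.to_numpy())
        rows.append((sid, h, effective_species(h)))
    return pd.DataFrame(rows, columns=["sample_id", "shannon", "effective_species"]).set_index(
        "sample_id"
    )


def bray_curtis(abundances: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d(x,y) = sum|x-y| / sum(x+y), samples as rows."""
    x = abundances.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = abundances.index[x.sum(axis=1) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {sorted(map(str, zero))}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          ids=[str(i) for i in abundances.index])


def _ss_within(d2: np.ndarray, member_idx: list[np.ndarray]) -> float:
    return sum(d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix)) for ix in member_idx)


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """One-way PERMANOVA (ADONIS) on a dissimilarity matrix.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) with
    SS_total = sum_{i<j} d_ij^2 / N and SS_within summed per group. The
    p-value counts the observed configuration among the permutations:
    p = (#{F_perm >= F_obs} + 1) / (B + 1), floor 1/(B+1).
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    groups = np.asarray(grouping)
    if groups.size != n:
        raise DesignError("grouping length must match the distance matrix")
    _, levels, idx = _group_indices(groups)
    a = len(levels)
    if a >= n:
        raise DesignError("need replication within groups")
    d2 = d ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(member_idx):
        ss_w = _ss_within(d2, member_idx)
        ss_b = ss_total - ss_w
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    observed = pseudo_f(idx)
    rng = np.random.default_rng(seed)
    sizes = [len(ix) for ix in idx]
    # permuting labels == permuting sample indices and re-slicing by group
    perms = rng.permuted(np.tile(np.arange(n), (n_permutations, 1)), axis=1)
    exceed = 0
    splits = np.cumsum(sizes)[:-1]
    order = np.concatenate(idx)  # group-blocked positions
    for row in perms:
        member = np.split(row[order], splits)
        if pseudo_f(member) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermTestResult("pseudo-F", float(observed), n_permutations, exceed, p,
                          seed if isinstance(seed, int) else None)


@dataclass(frozen=True)
class DispersionResult:
    """Homogeneity-of-dispersion test (betadisper-style)."""

    distances: pd.Series  # per-sample distance to its group centroid
    grouping: pd.Series
    statistic: float  # one-way F on the distances
    n_permutations: int
    exceed_count: int
    p: float


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates with negative eigenvalues kept as imaginary axes.

    Returns (real_coords, imag_coords): Gower-centred eigendecomposition,
    axes scaled by sqrt(|eigenvalue|); axes with negative eigenvalues span
    the 'imaginary' space whose squared distances subtract (Anderson's
    convention for semi-metric dissimilarities like Bray-Curtis).
    """
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    tol = 1e-9 * max(1.0, np.abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def dispersion(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Compare distances to group centroids in principal-coordinate space.

    Squared distance to the centroid is ||real||^2 - ||imag||^2 (clipped at
    zero when the imaginary part dominates numerically); the group effect on
    the distances is a one-way F whose null distribution is obtained by
    permuting the distances across samples, observed configuration counted.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    ids = list(dm.ids) if isinstance(dm, DistanceMatrix) else list(range(d.shape[0]))
    groups = np.asarray(grouping)
    _, levels, idx = _group_indices(groups)
    real, imag = _pcoa_coords(d)
    dist = np.empty(d.shape[0])
    for ix in idx:
        cr = real[ix].mean(axis=0)
        ci = imag[ix].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[ix] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[ix] - ci) ** 2).sum(axis=1)
        dist[ix] = np.sqrt(np.clip(d2, 0.0, None))

    observed = float(_anova_f_rows(dist[None, :], idx)[0])
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(dist, (n_permutations, 1)), axis=1)
    stats = _anova_f_rows(perm, idx)
    exceed = int(np.count_nonzero(stats >= observed))
    p = (exceed + 1) / (n_permutations + 1)
    return DispersionResult(
        distances=pd.Series(dist, index=ids, name="dist_to_centroid"),
        grouping=pd.Series(groups, index=ids, name="group"),
        statistic=observed,
        n_permutations=n_permutations,
        exceed_count=exceed,
        p=p,
    )


def log_transform(abundances: pd.DataFrame | np.ndarray):
    """log10 with the below-LOD rule: zeros are replaced by 1 (log10 1 = 0)."""
    x = abundances.to_numpy(dtype=float) if isinstance(abundances, pd.DataFrame) else np.asarray(
        abundances, dtype=float
    )
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    out = np.log10(np.where(x == 0, 1.0, x))
    if isinstance(abundances, pd.DataFrame):
        return pd.DataFrame(out, index=abundances.index, columns=abundances.columns)
    return out


@dataclass(frozen=True)
class OrdinationResult:
    """PCA ordination: per-sample scores, loadings, explained variance."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray
    proportion_explained: np.ndarray


def pca(data: pd.DataFrame, scale: bool = False) -> OrdinationResult:
    """Principal component analysis by SVD of the centred data matrix.

    Samples are rows. Centring always; unit-variance scaling only on request
    (``scale=True``). Constant columns are dropped with a warning. Component
    signs are fixed so each loading vector's largest-magnitude entry is
    positive, making the ordination deterministic.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise DesignError("PCA needs at least 2 samples and 2 variables")
    x = data.astype(float)
    sd = x.std(ddof=1)
    const = sd[sd == 0].index
    if len(const):
        warnings.warn(f"dropping constant column(s): {sorted(map(str, const))}", stacklevel=2)
        x = x.drop(columns=const)
        sd = sd.drop(const)
    centred = x - x.mean()
    if scale:
        centred = centred / sd
    u, s, vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
    # sign convention: dominant loading entry positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    n = centred.shape[0]
    var = s ** 2 / (n - 1)
    comp = [f"PC{i+1}" for i in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(u * s, index=x.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=x.columns, columns=comp),
        explained_variance=var,
        proportion_explained=var / var.sum(),
    )
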
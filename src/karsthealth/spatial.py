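"""Bivariate spatial association on the analysis grid.

Global bivariate Moran's I measures how one standardised variable at a cell
co-varies with the neighbourhood average (spatial lag) of another:

    I = (1/n) * sum_i z_x,i * sum_j w_ij z_y,j

with row-standardised weights and population-sd z-scores (Anselin's
formulation).  Significance comes from a Monte-Carlo permutation test, and
the local decomposition (LISA) classifies each cell into High-High,
High-Low, Low-High or Low-Low by the signs of z_x and the lag of z_y,
masked by a per-cell conditional permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .grid import Grid

LISA_CLASSES = ("not significant", "High-High", "High-Low",
                "Low-High", "Low-Low")


@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix over a subset of grid cells.

    ``ids`` are the grid cell ids included (missing-data cells are dropped
    before neighbour construction); ``matrix`` is indexed by position within
    ``ids``.  Cells left with no neighbours (islands) keep an empty row and
    are reported in ``islands``.
    """

    ids: np.ndarray
    matrix: sparse.csr_matrix
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return self.ids.size

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    @property
    def islands(self) -> np.ndarray:
        deg = np.asarray((self.matrix != 0).sum(axis=1)).ravel()
        return np.where(deg == 0)[0]

    def neighbors(self, pos: int) -> np.ndarray:
        return self.matrix.indices[
            self.matrix.indptr[pos]:self.matrix.indptr[pos + 1]]


def build_weights(grid: Grid, scheme: str = "queen",
                  row_standardize: bool = True,
                  valid_mask: np.ndarray | None = None,
                  knn: int = 8) -> SpatialWeights:
    """Contiguity (queen/rook) or k-nearest-neighbour weights on the fishnet.

    Queen adjacency joins cells sharing an edge or a corner (up to 8
    neighbours); rook requires a shared edge.  ``valid_mask`` drops cells
    (e.g. with missing values) *before* neighbours are built, so islands
    created by the removal keep empty rows.
    """
    if scheme not in ("queen", "rook", "knn"):
        raise ValueError(f"unknown weights scheme {scheme!r}")
    if valid_mask is None:
        valid_mask = np.ones(grid.n_cells, dtype=bool)
    ids = np.where(valid_mask)[0]
    n = ids.size
    pos = -np.ones(grid.n_cells, dtype=np.int64)
    pos[ids] = np.arange(n)
    r, c = np.divmod(ids, grid.n_cols)

    rows, cols = [], []
    if scheme in ("queen", "rook"):
        if scheme == "queen":
            offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                       (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
            nb = rr[ok] * grid.n_cols + cc[ok]
            keep = pos[nb] >= 0
            rows.append(np.arange(n)[ok][keep])
            cols.append(pos[nb[keep]])
    else:
        centers = grid.cell_centers()[ids]
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        k = min(knn, n - 1)
        nbrs = np.argsort(d2, axis=1)[:, :k]
        rows.append(np.repeat(np.arange(n), k))
        cols.append(nbrs.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    if row_standardize:
        deg = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        w = sparse.diags(inv) @ w
    return SpatialWeights(ids=ids, matrix=w.tocsr(), scheme=scheme,
                          row_standardized=row_standardize)


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()  # population sd
    if sd == 0:
        raise ValueError("variable has zero variance")
    return (v - v.mean()) / sd


def bivariate_moran(x: np.ndarray, y: np.ndarray, w: SpatialWeights) -> float:
    """Global bivariate Moran's I of x against the spatial lag of y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != w.n or y.size != w.n:
        raise ValueError("x and y must match the weight matrix cell set")
    if x.size < 2:
        raise ValueError("need at least two cells")
    zx, zy = _zscore(x), _zscore(y)
    return float(zx @ (w.matrix @ zy) / w.n)


def _pseudo_p(i_obs: float, perm_stats: np.ndarray) -> float:
    """One-sided pseudo p in the direction of the observed sign, +1/+1 rule."""
    if i_obs >= 0:
        extreme = int((perm_stats >= i_obs).sum())
    else:
        extreme = int((perm_stats <= i_obs).sum())
    return (extreme + 1) / (perm_stats.size + 1)


@dataclass
class MoranResult:
    i_obs: float
    permutations: int
    #: one-sided pseudo-p in the direction of the observed sign (the
    #: convention of common spatial-analysis GUIs; floor 1/(permutations+1))
    pseudo_p: float
    z_value: float
    seed: int | None = None
    perm_stats: np.ndarray | None = field(default=None, repr=False)

    @property
    def pseudo_p_two_sided(self) -> float:
        """Sign-agnostic pseudo-p.

        The directional ``pseudo_p`` picks its tail after seeing the sign of
        the statistic, which roughly doubles the null rejection rate at any
        nominal level; doubling it (capped at 1) restores a valid,
        slightly conservative test.  Use this one for calibrated inference.
        """
        return min(1.0, 2.0 * self.pseudo_p)


def moran_permutation_test(x: np.ndarray, y: np.ndarray, w: SpatialWeights,
                           n_perm: int = 999, seed: int | None = None
                           ) -> MoranResult:
    """Monte-Carlo test of bivariate Moran's I.

    y is permuted uniformly over locations (x and W fixed); the pseudo
    p-value is one-sided in the direction of the observed statistic with the
    (extreme + 1)/(permutations + 1) correction, so 0.001 is the floor at
    999 permutations.  The z-value is taken against the permutation
    distribution's mean and sd.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    i_obs = bivariate_moran(x, y, w)
    zx, zy = _zscore(x), _zscore(y)
    perms = np.stack([rng.permutation(zy) for _ in range(n_perm)])
    lags = w.matrix @ perms.T  # (n, n_perm)
    stats = (zx @ lags) / w.n
    sd = stats.std()
    z_value = (i_obs - stats.mean()) / sd if sd > 0 else np.inf
    return MoranResult(i_obs=i_obs, permutations=n_perm,
                       pseudo_p=_pseudo_p(i_obs, stats),
                       z_value=float(z_value), seed=seed, perm_stats=stats)


@dataclass
class LISAResult:
    local_i: np.ndarray
    pseudo_p: np.ndarray
    #: index into LISA_CLASSES per cell
    cluster: np.ndarray
    alpha: float
    permutations: int
    seed: int | None = None

    def cluster_labels(self) -> list[str]:
        return [LISA_CLASSES[c] for c in self.cluster]


def bivariate_lisa(x: np.ndarray, y: np.ndarray, w: SpatialWeights,
                   n_perm: int = 999, alpha: float = 0.05,
                   seed: int | None = None) -> LISAResult:
    """Local bivariate Moran statistics with conditional permutation.

    I_i = z_x,i * lag_i(z_y).  For each cell the neighbours' z_y values are
    resampled (without replacement) from all *other* cells; the cluster class
    comes from the signs of z_x,i and the observed lag, masked to "not
    significant" where the conditional pseudo p exceeds ``alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    zx, zy = _zscore(np.asarray(x, float)), _zscore(np.asarray(y, float))
    n = w.n
    if zx.size != n or zy.size != n:
        raise ValueError("x and y must match the weight matrix cell set")
    rng = np.random.default_rng(seed)
    lag = w.matrix @ zy
    local_i = zx * lag
    pseudo_p = np.ones(n)
    for i in range(n):
        nbrs = w.neighbors(i)
        k = nbrs.size
        if k == 0:
            continue
        wts = w.matrix.data[w.matrix.indptr[i]:w.matrix.indptr[i + 1]]
        others = np.delete(zy, i)
        draw = _sample_without_replacement(rng, n_perm, others.size, k)
        perm_lag = (others[draw] * wts).sum(axis=1)
        perm_stats = zx[i] * perm_lag
        pseudo_p[i] = _pseudo_p(local_i[i], perm_stats)
    cluster = np.zeros(n, dtype=np.int64)
    hi_x, hi_lag = zx > 0, lag > 0
    cluster[hi_x & hi_lag] = 1   # High-High
    cluster[hi_x & ~hi_lag] = 2  # High-Low
    cluster[~hi_x & hi_lag] = 3  # Low-High
    cluster[~hi_x & ~hi_lag] = 4  # Low-Low
    cluster[pseudo_p > alpha] = 0
    return LISAResult(local_i=local_i, pseudo_p=pseudo_p, cluster=cluster,
                      alpha=alpha, permutations=n_perm, seed=seed)


def _sample_without_replacement(rng: np.random.Generator, n_draws: int,
                                pool: int, k: int) -> np.ndarray:
    """(n_draws, k) index matrix, each row distinct indices into 0..pool-1.

    Rejection sampling on duplicate rows — efficient because k is small
    (neighbourhood size) relative to the pool.
    """
    if k > pool:
        raise ValueError("cannot draw more neighbours than the pool holds")
    draw = rng.integers(0, pool, size=(n_draws, k))
    while True:
        dup = (np.sort(draw, axis=1)[:, 1:] == np.sort(draw, axis=1)[:, :-1]
               ).any(axis=1) if k > 1 else np.zeros(n_draws, dtype=bool)
        if not dup.any():
            return draw
        draw[dup] = rng.integers(0, pool, size=(int(dup.sum()), k))
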
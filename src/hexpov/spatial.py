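"""Spatial autocorrelation inference on regional index values.

Implements the Cliff–Ord global Moran's I with both normality-assumption
and permutation inference, the Moran scatter decomposition into HH/LL/LH/HL
quadrants, Anselin's local Moran's I (LISA) with conditional permutation,
and significance-based cluster typing.

Conventions follow the Geoda workflow widely used in regional science:
row-standardized contiguity weights, one-sided pseudo p-values from 999
random permutations by default, and explicit exclusion of island regions
(regions with no neighbors) from inference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpatialWeights",
    "MoranGlobalResult",
    "LisaResult",
    "row_standardize",
    "global_morans_i",
    "moran_scatter",
    "local_morans_i",
    "classify_lisa",
    "read_gal",
    "write_gal",
    "read_edgelist_csv",
    "write_edgelist_csv",
]

#: Default number of random permutations for pseudo p-values.
DEFAULT_N_PERM = 999


class ZeroVarianceError(ValueError):
    """Raised when the analysed values are constant across regions."""


@dataclass
class SpatialWeights:
    """Sparse spatial weights: per-region neighbor lists with weights.

    Parameters
    ----------
    region_ids
        Ordered region identifiers, one per row.
    neighbors
        For each region, integer indices (into ``region_ids``) of its
        neighbors. Self-neighbors are forbidden.
    weights
        Non-negative weights aligned with ``neighbors``.
    standardized
        True once each non-island row has been scaled to sum to one.
    """

    region_ids: list
    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.region_ids = list(self.region_ids)
        n = len(self.region_ids)
        if len(self.neighbors) != n or len(self.weights) != n:
            raise ValueError("neighbors/weights must have one entry per region")
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if nb.shape != w.shape:
                raise ValueError(f"row {i}: neighbor/weight length mismatch")
            if np.any(nb == i):
                raise ValueError(f"row {i}: self-neighbor not allowed")
            if nb.size and (nb.min() < 0 or nb.max() >= n):
                raise ValueError(f"row {i}: neighbor index out of range")
            if np.any(w < 0):
                raise ValueError(f"row {i}: negative weight")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def islands(self) -> np.ndarray:
        """Indices of regions with no neighbors."""
        return np.array([i for i, nb in enumerate(self.neighbors) if nb.size == 0], dtype=int)

    def to_dense(self) -> np.ndarray:
        """Dense n-by-n weight matrix (mainly for oracles and small n)."""
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = w
        return W

    def subset(self, keep: Sequence[int]) -> "SpatialWeights":
        """Weights restricted to ``keep`` (indices), reindexed."""
        keep = np.asarray(keep, dtype=int)
        pos = {int(old): new for new, old in enumerate(keep)}
        nbs, wts = [], []
        for i in keep:
            nb, w = self.neighbors[i], self.weights[i]
            mask = np.isin(nb, keep)
            nbs.append(np.array([pos[int(j)] for j in nb[mask]], dtype=int))
            wts.append(w[mask])
        return SpatialWeights(
            [self.region_ids[i] for i in keep], nbs, wts, standardized=self.standardized
        )


def row_standardize(W: SpatialWeights) -> SpatialWeights:
    """Scale each non-island row's weights to sum to one.

    Islands are left untouched. Idempotent: standardizing an already
    standardized matrix returns bit-equal weights.
    """
    if len(W.islands) == W.n:
        raise ValueError("cannot row-standardize: every region is an island")
    new_weights = []
    for w in W.weights:
        s = w.sum()
        new_weights.append(w / s if s > 0 else w.copy())
    return SpatialWeights(W.region_ids, [nb.copy() for nb in W.neighbors], new_weights,
                          standardized=True)


# ---------------------------------------------------------------------------
# weights I/O — GAL dialect and edge list
# ---------------------------------------------------------------------------

def write_gal(W: SpatialWeights, path: str | Path) -> None:
    """Write binary adjacency in GAL-dialect text (ids, neighbor counts, ids)."""
    lines = [str(W.n)]
    for i, nb in enumerate(W.neighbors):
        lines.append(f"{W.region_ids[i]} {nb.size}")
        lines.append(" ".join(str(W.region_ids[j]) for j in nb))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> SpatialWeights:
    """Read a GAL-dialect file written by :func:`write_gal` (binary weights)."""
    tokens_by_line = [ln.split() for ln in Path(path).read_text().splitlines()]
    header = tokens_by_line[0]
    n = int(header[-1]) if len(header) > 1 else int(header[0])  # Geoda headers may carry extras
    ids: list[str] = []
    raw_neighbors: list[list[str]] = []
    li = 1
    for _ in range(n):
        rid, count = tokens_by_line[li][0], int(tokens_by_line[li][1])
        li += 1
        nbrs: list[str] = []
        while len(nbrs) < count:
            nbrs.extend(tokens_by_line[li])
            li += 1
        if count == 0 and li < len(tokens_by_line) and not tokens_by_line[li]:
            li += 1  # blank line for islands
        ids.append(rid)
        raw_neighbors.append(nbrs[:count])
    pos = {rid: i for i, rid in enumerate(ids)}
    neighbors = [np.array([pos[r] for r in nbrs], dtype=int) for nbrs in raw_neighbors]
    weights = [np.ones(len(nbrs)) for nbrs in raw_neighbors]
    return SpatialWeights(ids, neighbors, weights, standardized=False)


def write_edgelist_csv(W: SpatialWeights, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_i", "region_j", "weight"])
        for i, (nb, w) in enumerate(zip(W.neighbors, W.weights)):
            for j, wij in zip(nb, w):
                writer.writerow([W.region_ids[i], W.region_ids[int(j)], repr(float(wij))])


def read_edgelist_csv(path: str | Path, region_ids: Sequence | None = None) -> SpatialWeights:
    """Read an edge list (region_i, region_j, weight).

    ``region_ids`` fixes the row order (and admits islands that appear in no
    edge); when omitted the order of first appearance is used.
    """
    df = pd.read_csv(path, dtype={"region_i": str, "region_j": str})
    if region_ids is None:
        seen: dict[str, None] = {}
        for col in ("region_i", "region_j"):
            for r in df[col]:
                seen.setdefault(r, None)
        region_ids = list(seen)
    else:
        region_ids = [str(r) for r in region_ids]
    pos = {r: i for i, r in enumerate(region_ids)}
    nbs: list[list[int]] = [[] for _ in region_ids]
    wts: list[list[float]] = [[] for _ in region_ids]
    for ri, rj, w in zip(df["region_i"], df["region_j"], df["weight"]):
        nbs[pos[ri]].append(pos[rj])
        wts[pos[ri]].append(float(w))
    return SpatialWeights(region_ids, [np.array(x, dtype=int) for x in nbs],
                          [np.array(x) for x in wts], standardized=False)


# ---------------------------------------------------------------------------
# global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranGlobalResult:
    """Global Moran's I with analytic (normality) and permutation inference.

    ``p_perm`` is the one-sided pseudo p-value in the direction of the
    observed deviation from the null expectation -1/(n-1), following the
    Geoda convention; ``p_perm_two_sided`` is its two-sided companion.
    """

    I: float
    expected_I: float
    variance_normal: float
    z_normal: float
    p_normal: float
    p_perm: float
    p_perm_two_sided: float
    n_perm: int
    seed: int | None
    n: int


def _prepare(values: np.ndarray, W: SpatialWeights):
    """Drop islands, validate, and return (x, W_used, island_ids)."""
    x = np.asarray(values, dtype=float)
    if x.shape != (W.n,):
        raise ValueError(f"values must have length {W.n}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    islands = W.islands
    if islands.size:
        keep = np.setdiff1d(np.arange(W.n), islands)
        W = W.subset(keep)
        x = x[keep]
    if x.size < 3:
        raise ValueError("need at least 3 non-island regions")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("values are constant across regions")
    return x, W, islands


def _moran_stat(z: np.ndarray, Wd: np.ndarray, s0: float) -> float:
    n = z.size
    return float(n / s0 * (z @ Wd @ z) / (z @ z))


def global_morans_i(
    values: Sequence[float],
    W: SpatialWeights,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> MoranGlobalResult:
    """Global Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2.

    ``z_i`` are mean deviations. The analytic z-score uses the classical
    variance under the normality assumption; the permutation p-value
    randomly reassigns the values over regions ``n_perm`` times.
    """
    x, Wu, _ = _prepare(np.asarray(values), W)
    n = x.size
    Wd = Wu.to_dense()
    s0 = Wd.sum()
    z = x - x.mean()
    I = _moran_stat(z, Wd, s0)

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((Wd + Wd.T) ** 2).sum()
    s2 = ((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum()
    e_i2 = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n - 1) * (n + 1) * s0 * s0)
    var = e_i2 - e_i * e_i
    if var > 0:
        z_norm = (I - e_i) / np.sqrt(var)
        # one-sided in the direction of the observed deviation
        p_norm = float(stats.norm.sf(z_norm) if I >= e_i else stats.norm.cdf(z_norm))
    else:  # degenerate at very small n; permutation inference still applies
        z_norm, p_norm = float("nan"), float("nan")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])  # n_perm x n
    I_perm = n / s0 * np.einsum("pi,ij,pj->p", perms, Wd, perms) / (z @ z)
    if I >= e_i:
        extreme_one = np.count_nonzero(I_perm >= I)
    else:
        extreme_one = np.count_nonzero(I_perm <= I)
    extreme_two = np.count_nonzero(np.abs(I_perm - e_i) >= abs(I - e_i))
    p_perm = (extreme_one + 1) / (n_perm + 1)
    p_two = (extreme_two + 1) / (n_perm + 1)
    return MoranGlobalResult(I=I, expected_I=e_i, variance_normal=float(var),
                             z_normal=float(z_norm), p_normal=p_norm,
                             p_perm=float(p_perm), p_perm_two_sided=float(p_two),
                             n_perm=n_perm, seed=seed, n=n)


# ---------------------------------------------------------------------------
# Moran scatter & LISA
# ---------------------------------------------------------------------------

def _standardize_values(x: np.ndarray) -> np.ndarray:
    """Mean 0, unit sample sd (denominator n, matching the LISA moment m2)."""
    z = x - x.mean()
    sd = np.sqrt((z @ z) / z.size)
    return z / sd


def _quadrant(z: np.ndarray, lag: np.ndarray) -> np.ndarray:
    """HH/LL/LH/HL from the signs of z and its spatial lag.

    Exact zeros are assigned to the positive side (documented tie rule;
    only measure-zero inputs are affected).
    """
    hi_z = z >= 0
    hi_lag = lag >= 0
    out = np.empty(z.size, dtype=object)
    out[hi_z & hi_lag] = "HH"
    out[~hi_z & ~hi_lag] = "LL"
    out[~hi_z & hi_lag] = "LH"
    out[hi_z & ~hi_lag] = "HL"
    return out


def moran_scatter(values: Sequence[float], W: SpatialWeights) -> pd.DataFrame:
    """Per-region standardized value, spatial lag, and scatter quadrant.

    Islands are excluded and reported with quadrant ``"island"`` and NaN
    coordinates. Requires row-standardized weights.
    """
    if not W.standardized:
        raise ValueError("moran_scatter requires row-standardized weights")
    x, Wu, islands = _prepare(np.asarray(values), W)
    z = _standardize_values(x)
    lag = Wu.to_dense() @ z
    quad = _quadrant(z, lag)
    rows = pd.DataFrame({"region_id": Wu.region_ids, "z": z, "lag": lag, "quadrant": quad})
    if islands.size:
        island_rows = pd.DataFrame({
            "region_id": [W.region_ids[i] for i in islands],
            "z": np.nan, "lag": np.nan, "quadrant": "island",
        })
        rows = pd.concat([rows, island_rows], ignore_index=True)
    return rows.sort_values("region_id", kind="stable").reset_index(drop=True)


@dataclass
class LisaResult:
    """Local Moran's I for one region with conditional-permutation inference."""

    region_id: object
    local_I: float
    quadrant: str
    p_perm: float
    significant: bool
    excluded: bool = False


def local_morans_i(
    values: Sequence[float],
    W: SpatialWeights,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    level: float = 0.05,
) -> list[LisaResult]:
    """Anselin's local Moran's I with conditional permutation.

    local_I_i = (z_i / m2) * sum_j w_ij z_j, with m2 = sum_k z_k^2 / n so
    that sum_i local_I_i = n * global I under row-standardized weights.
    The pseudo p-value holds region i's value fixed and permutes the
    remaining values onto its neighbors; one-sided by the observed sign.
    """
    if not W.standardized:
        raise ValueError("local_morans_i requires row-standardized weights")
    x, Wu, islands = _prepare(np.asarray(values), W)
    n = x.size
    zdev = x - x.mean()
    m2 = (zdev @ zdev) / n
    lag = Wu.to_dense() @ zdev
    local = zdev / m2 * lag
    zstd = _standardize_values(x)
    quad = _quadrant(zstd, Wu.to_dense() @ zstd)

    rng = np.random.default_rng(seed)
    results: list[LisaResult] = []
    for i in range(n):
        nb = Wu.neighbors[i]
        w = Wu.weights[i]
        k = nb.size
        others = np.delete(zdev, i)
        # n_perm random draws of k values (without replacement) from the others
        idx = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :k]
        perm_lag = others[idx] @ w
        perm_local = zdev[i] / m2 * perm_lag
        if local[i] >= 0:
            extreme = np.count_nonzero(perm_local >= local[i])
        else:
            extreme = np.count_nonzero(perm_local <= local[i])
        p = (extreme + 1) / (n_perm + 1)
        results.append(LisaResult(region_id=Wu.region_ids[i], local_I=float(local[i]),
                                  quadrant=str(quad[i]), p_perm=float(p),
                                  significant=bool(p < level)))
    for i in islands:
        results.append(LisaResult(region_id=W.region_ids[i], local_I=float("nan"),
                                  quadrant="island", p_perm=float("nan"),
                                  significant=False, excluded=True))
    try:
        results.sort(key=lambda r: r.region_id)
    except TypeError:
        results.sort(key=lambda r: str(r.region_id))
    return results


def classify_lisa(lisa: list[LisaResult], level: float = 0.05) -> pd.DataFrame:
    """Cluster table: significant regions labeled by quadrant, rest not-significant."""
    rows = []
    for r in lisa:
        if r.excluded:
            label = "island"
        elif r.p_perm < level:
            label = r.quadrant
        else:
            label = "not-significant"
        rows.append({"region_id": r.region_id, "local_I": r.local_I,
                     "quadrant": r.quadrant, "p_perm": r.p_perm, "label": label})
    return (pd.DataFrame(rows)
            .sort_values("region_id", kind="stable")
            .reset_index(drop=True))
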
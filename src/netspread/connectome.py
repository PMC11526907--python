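"""Connectome container, directional graph Laplacians, and seed vectors.

The central object is a weighted directed adjacency matrix ``W`` over labeled
brain regions, with ``W[i, j]`` the projection strength from region ``i`` to
region ``j``.  Two Laplacians are derived from it: an *anterograde* Laplacian,
under which diffusing mass moves along the edge direction (soma to axon
terminal), and a *retrograde* Laplacian, under which mass moves against it.
Both conserve total mass under ``dx/dt = -c L x``.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Connectome",
    "SeedVector",
    "build_laplacians",
    "euclidean_surrogate",
    "seed_vector",
]

_HEMIS = {"ipsi", "contra", "none"}


@dataclass
class Connectome:
    """Weighted directed region-to-region connectivity.

    Parameters
    ----------
    region_ids : list of str
        Unique region labels, one per row/column of ``W``.
    W : ndarray, shape (N, N)
        Nonnegative adjacency; ``W[i, j]`` is the projection strength from
        region ``i`` to region ``j``. Zero diagonal.
    hemisphere : list of str, optional
        Per-region tag in ``{"ipsi", "contra", "none"}``.
    coords : ndarray, shape (N, 3), optional
        Region centroids in micrometres.
    base_ids : list of str, optional
        Anatomical label shared by hemispheric twins; defaults to
        ``region_ids`` when absent.
    """

    region_ids: list[str]
    W: np.ndarray
    hemisphere: list[str] | None = None
    coords: np.ndarray | None = None
    base_ids: list[str] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        n = len(self.region_ids)
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if len(set(self.region_ids)) != n:
            raise ValueError("region_ids are not unique")
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} regions")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite entries")
        neg = np.argwhere(self.W < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative weight W[{self.region_ids[i]!r}, {self.region_ids[j]!r}]"
                f" = {self.W[i, j]}"
            )
        diag = np.flatnonzero(np.diag(self.W) != 0)
        if diag.size:
            i = diag[0]
            raise ValueError(f"nonzero diagonal at region {self.region_ids[i]!r}")
        if self.hemisphere is not None:
            if len(self.hemisphere) != n:
                raise ValueError("hemisphere length mismatch")
            bad = set(self.hemisphere) - _HEMIS
            if bad:
                raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(f"coords shape {self.coords.shape}, expected ({n}, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("coords contain non-finite entries")
        if self.base_ids is not None and len(self.base_ids) != n:
            raise ValueError("base_ids length mismatch")
        self._index = {r: i for i, r in enumerate(self.region_ids)}

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def anatomical_ids(self) -> list[str]:
        return list(self.base_ids) if self.base_ids is not None else list(self.region_ids)

    def index(self, region_id: str) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            near = difflib.get_close_matches(region_id, self.region_ids, n=3)
            hint = f"; nearest matches: {near}" if near else ""
            raise KeyError(f"unknown region {region_id!r}{hint}") from None

    def density(self) -> float:
        n = self.n
        return float(np.count_nonzero(self.W) / (n * (n - 1)))


@dataclass
class SeedVector:
    """One-hot unit mass placed at a single seed region."""

    x0: np.ndarray
    seed_region: str

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        if np.any(self.x0 < 0):
            raise ValueError("seed vector must be nonnegative")
        if not np.isclose(self.x0.sum(), 1.0):
            raise ValueError("seed vector must sum to 1")


def build_laplacians(conn: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(L_antero, L_retro)`` for a connectome.

    ``L_antero = D_out - W.T`` with ``D_out`` the diagonal of row sums and
    ``L_retro = D_in - W`` with ``D_in`` the diagonal of column sums.  Under
    ``dx/dt = -c L x`` mass flows along edge direction (anterograde) or
    against it (retrograde); every column of each Laplacian sums to zero, so
    total mass is conserved.
    """
    W = conn.W
    L_antero = np.diag(W.sum(axis=1)) - W.T
    L_retro = np.diag(W.sum(axis=0)) - W
    return L_antero, L_retro


def euclidean_surrogate(
    coords: np.ndarray,
    region_ids: list[str] | None = None,
    kernel: str = "inverse",
    d0: float | None = None,
) -> Connectome:
    """Distance-based surrogate network over region centroids.

    The default kernel assigns ``W[i, j] = 1 / d(i, j)``; ``kernel="exp"``
    uses ``exp(-d / d0)`` with ``d0`` defaulting to the mean pairwise
    distance.  The result is a symmetric :class:`Connectome` usable by the
    same diffusion machinery as a structural connectome.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an N x 3 array")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    if region_ids is None:
        region_ids = [f"R{i:03d}" for i in range(n)]
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    dup = np.argwhere((d == 0) & off)
    if dup.size:
        i, j = dup[0]
        raise ValueError(
            f"duplicate coordinates for distinct regions {region_ids[i]!r} and"
            f" {region_ids[j]!r} (infinite weight)"
        )
    W = np.zeros_like(d)
    if kernel == "inverse":
        W[off] = 1.0 / d[off]
    elif kernel == "exp":
        if d0 is None:
            d0 = float(d[off].mean())
        W[off] = np.exp(-d[off] / d0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return Connectome(region_ids=list(region_ids), W=W, coords=coords)


def seed_vector(conn: Connectome, seed_region: str) -> SeedVector:
    """One-hot unit vector at ``seed_region``."""
    i = conn.index(seed_region)
    x0 = np.zeros(conn.n)
    x0[i] = 1.0
    return SeedVector(x0=x0, seed_region=seed_region)
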
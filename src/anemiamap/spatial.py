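"""Region adjacency graphs and the intrinsic CAR (ICAR) prior.

The ICAR prior models spatially structured region effects u over an areal
adjacency graph: conditionally, each region's effect is normal around the
mean of its neighbours' effects with variance tau2 / m_j, where m_j is the
neighbour count.  The joint density is improper (invariant to a constant
shift); it becomes proper on the sum-to-zero subspace, where it has rank
J - 1.  Connectivity of the graph is therefore required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import guinea

__all__ = [
    "AdjacencyGraph",
    "read_adjacency",
    "guinea_graph",
    "icar_conditional",
    "icar_log_density_unnormalized",
    "icar_pairwise_ss",
    "sample_icar",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, loop-free, connected region adjacency.

    Attributes
    ----------
    labels
        Region names; all index arrays refer to this order.
    neighbors
        Per-region tuple of neighbouring region indices (sorted).
    """

    labels: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        J = len(self.labels)
        if len(self.neighbors) != J:
            raise ValueError("neighbors list length != number of labels")
        for j, nb in enumerate(self.neighbors):
            if j in nb:
                raise ValueError(f"self-loop at region {self.labels[j]!r}")
            if not nb:
                raise ValueError(f"isolated region {self.labels[j]!r}")
            for r in nb:
                if j not in self.neighbors[r]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.labels[j]!r} lists "
                        f"{self.labels[r]!r} but not vice versa"
                    )
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("adjacency graph is not connected")

    @property
    def J(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> np.ndarray:
        """Neighbour count per region."""
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as (j, r) with j < r."""
        return [(j, r) for j, nb in enumerate(self.neighbors) for r in nb if j < r]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.J))
        g.add_edges_from(self.edges)
        return g

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = diag(m) - A; the ICAR precision is L / tau2."""
        L = np.diag(self.m.astype(float))
        for j, r in self.edges:
            L[j, r] = L[r, j] = -1.0
        return L

    @classmethod
    def from_edges(cls, labels, edges) -> "AdjacencyGraph":
        idx = {lab: j for j, lab in enumerate(labels)}
        nb: list[set[int]] = [set() for _ in labels]
        for a, b in edges:
            ja, jb = idx[a], idx[b]
            nb[ja].add(jb)
            nb[jb].add(ja)
        return cls(labels=tuple(labels), neighbors=tuple(tuple(sorted(s)) for s in nb))


def read_adjacency(path: str | Path) -> AdjacencyGraph:
    """Read a region adjacency file.

    Two plain-text dialects are accepted:

    * a neighbours list, one ``label: neighbor, neighbor, ...`` line per
      region (entries must be symmetric; an asymmetric pair is an error), or
    * a CSV 0/1 adjacency matrix with region labels as header and first
      column.
    """
    path = Path(path)
    text = path.read_text().strip()
    first = text.splitlines()[0]
    if ":" in first:
        labels, nb_names = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lab, _, rest = line.partition(":")
            labels.append(lab.strip())
            nb_names.append([s.strip() for s in rest.split(",") if s.strip()])
        idx = {lab: j for j, lab in enumerate(labels)}
        neighbors = []
        for lab, names in zip(labels, nb_names):
            unknown = [n for n in names if n not in idx]
            if unknown:
                raise ValueError(f"unknown neighbor label(s) {unknown} for {lab!r}")
            neighbors.append(tuple(sorted(idx[n] for n in names)))
        return AdjacencyGraph(labels=tuple(labels), neighbors=tuple(neighbors))
    import pandas as pd

    mat = pd.read_csv(path, index_col=0)
    labels = tuple(str(c) for c in mat.columns)
    A = mat.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency matrix must be square and symmetric")
    neighbors = tuple(tuple(np.flatnonzero(row).tolist()) for row in A)
    return AdjacencyGraph(labels=labels, neighbors=neighbors)


def guinea_graph() -> AdjacencyGraph:
    """The bundled first-order contiguity graph of Guinea's eight regions."""
    return AdjacencyGraph.from_edges(guinea.REGIONS, guinea.ADJACENCY)


def icar_conditional(
    u: np.ndarray, j: int, g: AdjacencyGraph, tau2: float
) -> tuple[float, float]:
    """Full conditional of u_j given the rest: N(neighbour mean, tau2/m_j)."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    nb = g.neighbors[j]
    mean = float(np.mean([u[r] for r in nb]))
    return mean, tau2 / len(nb)


def icar_pairwise_ss(u: np.ndarray, g: AdjacencyGraph) -> float:
    """Sum of squared differences over adjacent pairs, sum_{j~r, j<r} (u_j-u_r)^2."""
    u = np.asarray(u, dtype=float)
    return float(sum((u[j] - u[r]) ** 2 for j, r in g.edges))


def icar_log_density_unnormalized(u: np.ndarray, g: AdjacencyGraph, tau2: float) -> float:
    """Joint ICAR log density up to a constant.

    Equals ``-(1/(2 tau2)) * pairwise_ss(u) + ((J-1)/2) log(1/tau2)``; the
    (J-1)/2 exponent reflects the rank deficiency of the pairwise-difference
    precision (one null direction: the constant vector).  The full
    conditionals derived from this joint are exactly
    :func:`icar_conditional`.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    J = g.J
    return -icar_pairwise_ss(u, g) / (2.0 * tau2) + (J - 1) / 2.0 * np.log(1.0 / tau2)


def sample_icar(g: AdjacencyGraph, tau2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw u from the sum-to-zero-constrained ICAR with scale tau2.

    The constrained distribution is the singular Gaussian with covariance
    ``tau2 * pinv(L)`` supported on the sum-to-zero subspace; sampling is by
    spectral decomposition of the Laplacian, drawing independently along the
    eigenvectors with nonzero eigenvalue (variance tau2/lambda).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    if tau2 == 0:
        return np.zeros(g.J)
    lam, V = np.linalg.eigh(g.laplacian())
    pos = lam > 1e-10
    z = rng.standard_normal(int(pos.sum()))
    u = V[:, pos] @ (z * np.sqrt(tau2 / lam[pos]))
    return u - u.mean()
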
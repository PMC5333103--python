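"""Raw and centrality-adjusted network distances.

An edge with confidence ``S`` has raw distance ``1000/S``, so the most
confident interactions (S = 1000) are one unit apart and weak ones are
far. The raw distance between any two genes is the weighted shortest
path (Dijkstra) over those edge distances. Because hub genes sit close
to everything, a raw distance understates how surprising proximity to a
hub is; the adjusted distance therefore normalizes each pair's raw
distance by the endpoints' mean raw distances to the whole network,
damping that centrality bias.

All computation is restricted to the largest connected component:
infinite distances to off-component genes would poison the means, so
off-component genes carry no distances and are reported as unranked
downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph

from .exceptions import DataError
from .network import GeneNetwork

ADJUST_MODES = ("geometric", "arithmetic", "product")


def edge_distance(score) -> float:
    """Raw distance of a single edge: 1000 / S, strictly decreasing in S."""
    s = float(score)
    if not 0.0 < s <= 1000.0:
        raise DataError(f"confidence score {score} outside (0, 1000]")
    return 1000.0 / s


@dataclass
class DistanceMatrix:
    """All-pairs raw shortest-path distances over the largest component.

    `genes` fixes row/column order (network first-appearance order
    restricted to the component); `excluded` lists off-component genes.
    The matrix is symmetric with zero diagonal; every finite
    off-diagonal entry is >= 1 because a single edge costs at least
    1000/1000.
    """

    genes: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]


@dataclass
class CentralityProfile:
    """Per-gene mean raw distance mu_a = (1/N) * sum_j D_aj.

    The self term D_aa = 0 is included in the sum and the divisor is N,
    so mu is a (downward-biased by 1/N) average distance to the network:
    small mu marks central, hub-like genes.
    """

    genes: list[str]
    mu: np.ndarray
    n: int


@dataclass
class AdjustedDistanceMatrix:
    """Centrality-adjusted distances; same layout as DistanceMatrix."""

    genes: list[str]
    values: np.ndarray
    mode: str = "geometric"
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]


def all_pairs_raw_distance(network: GeneNetwork) -> DistanceMatrix:
    """Dijkstra from every gene over 1000/S edge distances.

    Restricted to the largest connected component; genes outside it are
    recorded in ``excluded``. Requires at least 2 genes in the
    component.
    """
    if network.n_genes < 2:
        raise DataError("network must contain at least 2 genes")
    inside, outside = network.largest_component_genes()
    if len(inside) < 2:
        raise DataError("largest connected component has fewer than 2 genes")
    graph = network.to_distance_csgraph()
    idx = np.array([network.index_of(g) for g in inside])
    sub = graph[idx][:, idx]
    dist = csgraph.dijkstra(sub, directed=False)
    # per-source Dijkstra accumulates path sums in different orders, so
    # d_ab and d_ba can differ in the last ulp; take the smaller sum
    dist = np.minimum(dist, dist.T)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(genes=inside, values=dist, excluded=outside)


def mean_distances(dm: DistanceMatrix) -> CentralityProfile:
    """Row means of the raw distance matrix (self term included, divisor N)."""
    if not np.all(np.isfinite(dm.values)):
        raise DataError("distance matrix contains non-finite entries")
    mu = dm.values.mean(axis=1)
    return CentralityProfile(genes=list(dm.genes), mu=mu, n=dm.n)


def adjust_distance(dm: DistanceMatrix,
                    cp: CentralityProfile | None = None,
                    mode: str = "geometric") -> AdjustedDistanceMatrix:
    """Normalize raw distances by the endpoints' mean raw distances.

    Modes
    -----
    geometric (default)
        ``Dhat_ab = D_ab / sqrt(mu_a * mu_b)`` — dimensionless and
        invariant under uniform rescaling of all raw distances.
    arithmetic
        ``Dhat_ab = 2 * D_ab / (mu_a + mu_b)`` — also scale-invariant.
    product
        ``Dhat_ab = D_ab**2 / (mu_a * mu_b)`` — scale-invariant via the
        squared numerator; penalizes long distances more sharply.
    """
    if mode not in ADJUST_MODES:
        raise DataError(f"unknown adjustment mode {mode!r}; "
                        f"expected one of {ADJUST_MODES}")
    if cp is None:
        cp = mean_distances(dm)
    if list(cp.genes) != list(dm.genes):
        raise DataError("centrality profile does not match distance matrix")
    mu = cp.mu
    if np.any(mu <= 0):
        raise DataError("zero mean distance encountered; "
                        "is the component a single gene?")
    d = dm.values
    if mode == "geometric":
        adj = d / np.sqrt(np.outer(mu, mu))
    elif mode == "arithmetic":
        adj = 2.0 * d / np.add.outer(mu, mu)
    else:  # product
        adj = d ** 2 / np.outer(mu, mu)
    np.fill_diagonal(adj, 0.0)
    return AdjustedDistanceMatrix(genes=list(dm.genes), values=adj,
                                  mode=mode, excluded=list(dm.excluded))


# ---------------------------------------------------------------------
# on-disk cache
# ---------------------------------------------------------------------

def edge_list_hash(network: GeneNetwork) -> str:
    """SHA-256 of the canonical edge list; keys the distance cache."""
    h = hashlib.sha256()
    for line in network.canonical_edge_lines():
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()


def save_distance_cache(dm: DistanceMatrix, path,
                        network: GeneNetwork | None = None,
                        mode: str = "geometric") -> None:
    """Persist raw distances as float32 (.npz) with a gene-order sidecar.

    The adjusted matrix is cheap relative to Dijkstra, so only raw
    distances are stored; mu and the adjusted matrix are recomputed at
    load time from the float32 values, keeping everything derived from
    one cache mutually consistent.
    """
    meta = {
        "mode": mode,
        "edge_hash": edge_list_hash(network) if network is not None else None,
    }
    np.savez_compressed(
        path,
        values=dm.values.astype(np.float32),
        genes=np.array(dm.genes, dtype=object),
        excluded=np.array(dm.excluded, dtype=object),
        meta=np.array(json.dumps(meta)),
    )


def load_distance_cache(path) -> tuple[DistanceMatrix, dict]:
    """Load a cache written by :func:`save_distance_cache`."""
    with np.load(path, allow_pickle=True) as npz:
        values = np.asarray(npz["values"], dtype=np.float64)
        genes = [str(g) for g in npz["genes"]]
        excluded = [str(g) for g in npz["excluded"]]
        meta = json.loads(str(npz["meta"]))
    dm = DistanceMatrix(genes=genes, values=values, excluded=excluded)
    return dm, meta
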
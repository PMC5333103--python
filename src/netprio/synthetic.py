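"""Seeded synthetic networks with planted disease modules.

The generator emulates the structure the prioritization method
exploits: a sparse Erdős–Rényi background of low-confidence
associations with one or more planted modules — gene subsets that are
both more densely connected and connected at higher confidence than
the background. Module members serve as ground-truth "disease genes".
A ``cohesion`` dial interpolates between a module indistinguishable
from background (0) and the fully planted module (1), giving a null
condition for calibration tests. A separate hub fixture wires one gene
to everything at high confidence to exercise the centrality
adjustment.

Confidence scores are drawn from a normal distribution, rounded to
integers and clamped to [1, 1000]. Generated networks are always
returned connected: if the Bernoulli draw leaves isolated components,
a low-confidence spanning backbone chains them to the main component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import DataError
from .network import DiseaseGeneSet, GeneNetwork

BACKBONE_SCORE = 100  # low-confidence spanning edges added for connectivity


@dataclass
class SyntheticScenario:
    """Parameters of a planted-module network.

    Defaults give a 300-gene background (edge probability 0.02,
    confidence ~N(200, 50)) with one 15-gene module (edge probability
    0.8, confidence ~N(900, 50)) — a compact, high-confidence disease
    module on a weak background. ``cohesion`` in [0, 1] linearly
    interpolates module edge probability and confidence between the
    background values (0, the null) and the stated module values (1).
    """

    n_genes: int = 300
    background_edge_p: float = 0.02
    background_score_mean: float = 200.0
    background_score_sd: float = 50.0
    module_sizes: tuple[int, ...] = (15,)
    module_edge_p: float = 0.8
    module_score_mean: float = 900.0
    module_score_sd: float = 50.0
    cohesion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.module_sizes, list):
            self.module_sizes = tuple(self.module_sizes)
        if sum(self.module_sizes) > self.n_genes:
            raise DataError("modules larger than the network")
        if not 0.0 <= self.cohesion <= 1.0:
            raise DataError("cohesion must lie in [0, 1]")
        if self.n_genes < 2:
            raise DataError("need at least 2 genes")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)


def _draw_scores(rng, size, mean, sd):
    s = np.rint(rng.normal(mean, sd, size=size))
    return np.clip(s, 1, 1000).astype(int)


def _gene_names(n):
    width = max(4, len(str(n)))
    return [f"g{str(i + 1).zfill(width)}" for i in range(n)]


def generate_scenario(sc: SyntheticScenario
                      ) -> tuple[GeneNetwork, list[DiseaseGeneSet]]:
    """Draw one network and its ground-truth module gene sets.

    Deterministic for a fixed scenario (the seed lives inside it).
    Module members are sampled without replacement; within-module pairs
    use the cohesion-interpolated edge probability and confidence,
    everything else the background values.
    """
    rng = np.random.default_rng(sc.seed)
    n = sc.n_genes
    genes = _gene_names(n)

    # assign module members
    perm = rng.permutation(n)
    modules, start = [], 0
    for size in sc.module_sizes:
        modules.append(np.sort(perm[start:start + size]))
        start += size
    in_module = np.full(n, -1)
    for m, members in enumerate(modules):
        in_module[members] = m

    c = sc.cohesion
    p_mod = sc.background_edge_p + c * (sc.module_edge_p - sc.background_edge_p)
    mean_mod = (sc.background_score_mean
                + c * (sc.module_score_mean - sc.background_score_mean))
    sd_mod = sc.background_score_sd + c * (sc.module_score_sd
                                           - sc.background_score_sd)

    iu, ju = np.triu_indices(n, k=1)
    same = (in_module[iu] >= 0) & (in_module[iu] == in_module[ju])
    p = np.where(same, p_mod, sc.background_edge_p)
    present = rng.random(iu.size) < p
    scores = np.where(
        same,
        _draw_scores(rng, iu.size, mean_mod, sd_mod),
        _draw_scores(rng, iu.size, sc.background_score_mean,
                     sc.background_score_sd),
    )

    net = GeneNetwork(genes=genes)
    for i, j, s in zip(iu[present], ju[present], scores[present]):
        net.add_edge(genes[i], genes[j], int(s))

    _ensure_connected(net)

    gene_sets = [
        DiseaseGeneSet(f"module_{m + 1}",
                       frozenset(genes[i] for i in members))
        for m, members in enumerate(modules)
    ]
    return net, gene_sets


def _ensure_connected(net: GeneNetwork) -> None:
    """Chain stray components to the main one with low-confidence edges."""
    labels = net.component_labels()
    if labels.size and labels.max() > 0:
        genes = net.genes
        counts = np.bincount(labels)
        main = int(np.argmax(counts))
        anchor = genes[int(np.flatnonzero(labels == main)[0])]
        for comp in range(len(counts)):
            if comp == main:
                continue
            rep = genes[int(np.flatnonzero(labels == comp)[0])]
            net.add_edge(anchor, rep, BACKBONE_SCORE)


def hub_fixture(n_leaves: int = 30, n_module: int = 8, seed: int = 0,
                hub_score: int = 1000, module_score: int = 500,
                satellite_score: int = 700,
                n_satellites: int | None = None
                ) -> tuple[GeneNetwork, DiseaseGeneSet, str]:
    """Deterministic hub-and-module network for centrality tests.

    One ``hub`` gene is wired to every leaf at uniform high confidence,
    so raw shortest paths route through it and its mean raw distance is
    the smallest in the network. A module of `n_module` leaves forms a
    clique at `module_score`; `n_satellites` further leaves (default:
    half the remainder) each hang off one module gene at
    `satellite_score` — peripheral genes whose closeness to the module
    the raw distance underrates and the adjustment restores. The
    module is the ground-truth disease set. Returns
    (network, disease set, hub gene id).
    """
    if n_leaves < 3 or n_module < 3:
        raise DataError("need n_leaves >= 3 and n_module >= 3")
    if n_module > n_leaves:
        raise DataError("module larger than the leaf set")
    rng = np.random.default_rng(seed)
    leaves = _gene_names(n_leaves)
    hub = "hub"
    net = GeneNetwork(genes=[hub] + leaves)
    for leaf in leaves:
        net.add_edge(hub, leaf, hub_score)
    members = sorted(rng.choice(n_leaves, size=n_module, replace=False))
    module = [leaves[i] for i in members]
    for i in range(n_module):
        for j in range(i + 1, n_module):
            net.add_edge(module[i], module[j], module_score)
    others = [l for l in leaves if l not in set(module)]
    if n_satellites is None:
        n_satellites = len(others) // 2
    if n_satellites > len(others):
        raise DataError("more satellites than non-module leaves")
    for idx, leaf in enumerate(others[:n_satellites]):
        anchor = module[int(rng.integers(n_module))]
        net.add_edge(leaf, anchor, satellite_score)
    ds = DiseaseGeneSet("hub_module", frozenset(module))
    return net, ds, hub
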
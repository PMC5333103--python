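"""Model/Results facade over the prioritization pipeline.

:class:`GenePrioritizer` is built from a :class:`~netprio.network.GeneNetwork`
and holds everything disease-independent (shortest-path distances,
centralities, the adjusted matrix — computed lazily and reused across
fits). ``fit(disease_genes)`` returns a
:class:`PrioritizationResults` carrying the weights, converted
precision scores, the ranked table and a ``summary()``; cross-validated
evaluation hangs off the same objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError
from .network import (DiseaseGeneSet, GeneNetwork, load_network,
                      make_disease_set, write_ranking)
from .distance import (all_pairs_raw_distance, mean_distances,
                       adjust_distance)
from .prioritize import disease_weights, convert_scores, prioritize_disease
from . import evaluate as _evaluate


class GenePrioritizer:
    """Network-distance disease-gene prioritization model.

    Parameters
    ----------
    network : GeneNetwork
        Weighted functional-association network.
    normalization : {'geometric', 'arithmetic', 'product'}
        Form of the centrality adjustment applied to raw shortest-path
        distances.
    weight_mode : {'difference', 'ratio'}
        How the all-genes and disease-genes mean-distance components
        combine into the gene weight.
    inclusive_threshold : bool
        Whether the precision conversion counts a gene's own weight at
        its threshold (the default).
    use_adjusted : bool
        Set False to run the method on raw distances (the baseline the
        adjustment is compared against).
    """

    def __init__(self, network: GeneNetwork, *, normalization="geometric",
                 weight_mode="difference", inclusive_threshold=True,
                 use_adjusted=True):
        self.network = network
        self.normalization = normalization
        self.weight_mode = weight_mode
        self.inclusive_threshold = inclusive_threshold
        self.use_adjusted = use_adjusted
        self._dm = None
        self._cp = None
        self._adm = None

    @classmethod
    def from_edgelist(cls, path, min_score: int = 1, **kwargs):
        """Build from a STRING-style edge-list file."""
        return cls(load_network(path, min_score=min_score), **kwargs)

    # -- lazy disease-independent state --------------------------------
    @property
    def distances_(self):
        if self._dm is None:
            self._dm = all_pairs_raw_distance(self.network)
        return self._dm

    @property
    def centrality_(self):
        if self._cp is None:
            self._cp = mean_distances(self.distances_)
        return self._cp

    @property
    def adjusted_(self):
        if self._adm is None:
            self._adm = adjust_distance(self.distances_, self.centrality_,
                                        mode=self.normalization)
        return self._adm

    @property
    def scoring_matrix_(self):
        return self.adjusted_ if self.use_adjusted else self.distances_

    def attach_distances(self, dm):
        """Inject a precomputed raw distance matrix (e.g. from a cache)."""
        if set(dm.genes) - set(self.network.genes) and self.network.n_genes:
            raise DataError("cached distance matrix does not match network")
        self._dm = dm
        self._cp = None
        self._adm = None

    # -- fitting --------------------------------------------------------
    def _as_disease_set(self, disease_genes, disease_id):
        if isinstance(disease_genes, DiseaseGeneSet):
            return disease_genes
        ds = make_disease_set(disease_id, disease_genes, self.network)
        if ds is None:
            raise DataError(
                f"disease {disease_id}: fewer than 2 genes in the network"
            )
        return ds

    def fit(self, disease_genes, disease_id: str = "disease"):
        """Prioritize all genes for one disease gene set."""
        ds = self._as_disease_set(disease_genes, disease_id)
        table = prioritize_disease(self.scoring_matrix_, ds,
                                   weight_mode=self.weight_mode,
                                   inclusive=self.inclusive_threshold)
        wv = disease_weights(self.scoring_matrix_, ds,
                             weight_mode=self.weight_mode)
        scores = convert_scores(wv, ds, inclusive=self.inclusive_threshold)
        return PrioritizationResults(self, ds, wv, scores, table)

    def loocv(self, disease_genes, disease_id: str = "disease"):
        """Leave-one-out evaluation for one disease."""
        ds = self._as_disease_set(disease_genes, disease_id)
        return _evaluate.loocv(self.scoring_matrix_, ds,
                               weight_mode=self.weight_mode)


class PrioritizationResults:
    """Fitted prioritization for one disease.

    Attributes
    ----------
    table : pandas.DataFrame
        Ranked genes: rank, gene, weight, score, is_known, unranked.
    weights : WeightVector
        Per-gene weights and their two mean-distance components.
    scores : PrecisionScores
        Converted precision scores and the threshold table.
    """

    def __init__(self, model, disease_set, weights, scores, table):
        self.model = model
        self.disease_set = disease_set
        self.weights = weights
        self.scores = scores
        self.table = table

    @property
    def disease_id(self):
        return self.disease_set.disease_id

    def top(self, n: int = 10, novel_only: bool = False) -> pd.DataFrame:
        """Top-n rows, optionally restricted to non-known genes."""
        t = self.table
        if novel_only:
            t = t[~t["is_known"]]
        return t.head(n)

    def rank_of(self, gene: str) -> int:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise DataError(f"gene {gene!r} not in ranking")
        return int(row["rank"].iloc[0])

    def save(self, path) -> None:
        write_ranking(self.table, path)

    def summary(self, n_top: int = 10) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        ds = self.disease_set
        t = self.table
        ranked = t[~t["unranked"]]
        known = ranked[ranked["is_known"]]
        lines = [
            "Gene prioritization results",
            "=" * 60,
            f"Disease:              {ds.disease_id}",
            f"Known disease genes:  {ds.k}",
            f"Genes ranked:         {len(ranked)}"
            + (f" (+{int(t['unranked'].sum())} unranked off-component)"
               if t["unranked"].any() else ""),
            f"Distance:             "
            f"{'adjusted (' + self.model.normalization + ')' if self.model.use_adjusted else 'raw'}",
            f"Weight mode:          {self.model.weight_mode}",
            f"Median rank of known: {known['rank'].median():.1f}",
            "",
            f"Top {n_top} genes",
            "-" * 60,
        ]
        head = ranked.head(n_top)
        lines.append(f"{'rank':>4}  {'gene':<12} {'weight':>10} "
                     f"{'score':>8}  known")
        for _, r in head.iterrows():
            lines.append(f"{int(r['rank']):>4}  {r['gene']:<12} "
                         f"{r['weight']:>10.4f} {r['score']:>8.4f}  "
                         f"{'yes' if r['is_known'] else 'no'}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PrioritizationResults {self.disease_id}: "
                f"{len(self.table)} genes, K={self.disease_set.k}>")
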
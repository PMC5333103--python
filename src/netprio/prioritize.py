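"""Disease-specific gene weights, ranking, and precision score conversion.

Given an adjusted distance matrix and a set of K known disease genes,
each gene i gets a weight

    w_i = (1/N) sum_j Dhat_ij  -  (1/K) sum_{j in disease} Dhat_ij,

the gap between its mean adjusted distance to the whole network and to
the disease genes. A positive w_i says the gene sits closer to the
disease genes than to a typical gene — the guilt-by-association signal.
Genes are ranked by descending w_i (ties broken by ascending gene id).

Because w values live on a disease-specific scale, they are converted
into precisions: at each distinct weight threshold w (inclusive), with
P genes weighing at least w of which TP are disease genes, the
precision TP/P estimates the probability that a gene scoring at least w
is a disease gene — a quantity comparable across diseases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .network import DiseaseGeneSet, GeneNetwork
from .distance import (AdjustedDistanceMatrix, DistanceMatrix,
                       all_pairs_raw_distance, adjust_distance)

WEIGHT_MODES = ("difference", "ratio")


@dataclass
class WeightVector:
    """Per-gene disease weights plus their two mean-distance components."""

    disease_id: str
    genes: list[str]
    weights: np.ndarray
    component_all: np.ndarray
    component_disease: np.ndarray
    weight_mode: str = "difference"

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    def weight_of(self, gene: str) -> float:
        return float(self.weights[self._index[gene]])


@dataclass
class PrecisionScores:
    """Converted per-gene scores plus the threshold table behind them."""

    genes: list[str]
    scores: np.ndarray
    thresholds: pd.DataFrame  # columns: weight, P, TP, precision


def disease_weights(adm, ds: DiseaseGeneSet,
                    weight_mode: str = "difference") -> WeightVector:
    """Compute w for every gene in the (component-restricted) matrix.

    `adm` may be an :class:`AdjustedDistanceMatrix` or a raw
    :class:`DistanceMatrix` (the raw-distance variant of the method);
    anything exposing ``genes`` and a square ``values`` array works.
    Disease genes outside the matrix are ignored; at least one must
    remain (leave-one-out training sets may have K = 1).
    """
    if weight_mode not in WEIGHT_MODES:
        raise DataError(f"unknown weight mode {weight_mode!r}")
    genes = list(adm.genes)
    didx = [adm.index_of(g) for g in sorted(ds.genes) if g in adm._index]
    if not didx:
        raise DataError(
            f"disease {ds.disease_id}: no disease genes in the network component"
        )
    d = adm.values
    comp_all = d.mean(axis=1)
    comp_dis = d[:, didx].mean(axis=1)
    if weight_mode == "difference":
        w = comp_all - comp_dis
    else:  # ratio: >1 means relatively closer to disease genes
        with np.errstate(divide="ignore"):
            w = np.where(comp_dis > 0, comp_all / np.maximum(comp_dis, 1e-300),
                         np.inf)
    return WeightVector(
        disease_id=ds.disease_id, genes=genes, weights=w,
        component_all=comp_all, component_disease=comp_dis,
        weight_mode=weight_mode,
    )


def rank_genes(wv: WeightVector, excluded=()) -> pd.DataFrame:
    """Rank by descending weight, ties by ascending gene id.

    Off-component genes (`excluded`) are appended after all ranked
    genes, in id order, flagged ``unranked`` with NaN weight.
    """
    order = sorted(range(len(wv.genes)),
                   key=lambda i: (-wv.weights[i], wv.genes[i]))
    rows = [(r + 1, wv.genes[i], wv.weights[i], False)
            for r, i in enumerate(order)]
    base = len(rows)
    for j, g in enumerate(sorted(excluded)):
        rows.append((base + j + 1, g, np.nan, True))
    return pd.DataFrame(rows, columns=["rank", "gene", "weight", "unranked"])


def convert_scores(wv: WeightVector, ds: DiseaseGeneSet,
                   inclusive: bool = True,
                   isotonic: bool = False) -> PrecisionScores:
    """Convert weights to precision scores TP/P at each weight threshold.

    At threshold w: P counts genes with weight >= w (inclusive, the
    default — an exclusive reading would leave the top gene with an
    undefined 0/0 precision), TP counts disease genes among them. Each
    gene's converted score is the precision at its own weight. Tied
    weights share one threshold and hence one score. With
    ``isotonic=True`` precision is replaced by its running maximum from
    the strictest threshold down (off by default; the plain stepwise
    TP/P is the reference behaviour).
    """
    w = wv.weights
    is_dis = np.array([g in ds.genes for g in wv.genes])
    if not is_dis.any():
        raise DataError(f"disease {ds.disease_id}: empty disease set")
    distinct = np.unique(w)[::-1]  # descending
    w_sorted = np.sort(w)          # ascending, for counting
    wd_sorted = np.sort(w[is_dis])
    if inclusive:
        # count of values >= t
        P = len(w) - np.searchsorted(w_sorted, distinct, side="left")
        TP = len(wd_sorted) - np.searchsorted(wd_sorted, distinct, side="left")
    else:
        P = len(w) - np.searchsorted(w_sorted, distinct, side="right")
        TP = len(wd_sorted) - np.searchsorted(wd_sorted, distinct, side="right")
    with np.errstate(invalid="ignore"):
        prec = np.where(P > 0, TP / np.maximum(P, 1), 0.0)
    if isotonic:
        prec = np.maximum.accumulate(prec)
    thresholds = pd.DataFrame(
        {"weight": distinct, "P": P, "TP": TP, "precision": prec}
    )
    # map each gene's weight to its threshold's precision
    pos = np.searchsorted(-distinct, -w)  # distinct is descending
    scores = prec[pos]
    return PrecisionScores(genes=list(wv.genes), scores=scores,
                           thresholds=thresholds)


def prioritize_disease(adm, ds: DiseaseGeneSet,
                       weight_mode: str = "difference",
                       inclusive: bool = True) -> pd.DataFrame:
    """Full ranked table: rank, gene, weight, score, is_known, unranked.

    Deterministic composition of :func:`disease_weights`,
    :func:`rank_genes` and :func:`convert_scores`. Known disease genes
    are not excluded from their own ranking; off-component genes appear
    at the bottom flagged ``unranked`` with NaN weight and score.
    """
    wv = disease_weights(adm, ds, weight_mode=weight_mode)
    ps = convert_scores(wv, ds, inclusive=inclusive)
    score_of = dict(zip(ps.genes, ps.scores))
    table = rank_genes(wv, excluded=getattr(adm, "excluded", ()))
    table["score"] = [score_of.get(g, np.nan) for g in table["gene"]]
    table["is_known"] = [g in ds.genes for g in table["gene"]]
    return table[["rank", "gene", "weight", "score", "is_known", "unranked"]]


def prioritize_from_network(network: GeneNetwork, ds: DiseaseGeneSet,
                            mode: str = "geometric",
                            weight_mode: str = "difference",
                            inclusive: bool = True,
                            use_adjusted: bool = True) -> pd.DataFrame:
    """Convenience path: network -> distances -> (adjusted) -> ranking."""
    dm = all_pairs_raw_distance(network)
    adm = adjust_distance(dm, mode=mode) if use_adjusted else dm
    return prioritize_disease(adm, ds, weight_mode=weight_mode,
                              inclusive=inclusive)
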
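"""Leave-one-out evaluation of network-distance gene prioritization.

The protocol: for each known disease gene, retrain the weights on the
remaining K-1 genes, record the held-out gene's weight and genome-wide
rank; every non-disease gene is scored once against the full K-gene
set. The resulting labeled score list feeds a stepwise precision-recall
curve (thresholds at distinct scores, precision TP/(TP+FP), recall
TP/K), its trapezoidal area over recall (AUPRC), and the maximum F1
over thresholds (F-max). Top-k true-positive rates and rank ratios
summarise how useful the top of the ranking would be to an
experimentalist who can only assay a handful of candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .network import DiseaseGeneSet, GeneNetwork
from .distance import all_pairs_raw_distance, adjust_distance
from .prioritize import disease_weights, convert_scores

DEFAULT_TOP_KS = (50, 100, 150, 200)


@dataclass
class LoocvResult:
    """Labeled LOOCV scores for one disease.

    `table` has one row per network-component gene: columns ``gene``,
    ``score`` (held-out weight for disease genes, full-set weight for
    the rest), ``label`` (1 = known disease gene), ``rank`` and
    ``rank_ratio`` (held-out genome-wide rank, NaN for negatives).
    """

    disease_id: str
    table: pd.DataFrame
    n_genes: int
    k: int

    @property
    def prevalence(self) -> float:
        return self.k / self.n_genes


@dataclass
class PRCurve:
    """Stepwise precision-recall curve with AUPRC and F-max.

    Points sit at distinct score thresholds in descending order; an
    anchor at recall 0 with the first point's precision starts the
    trapezoidal integration so a perfect ranking integrates to 1.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    fmax: float

    def plot(self, ax=None, **kwargs):
        """Draw the curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = np.concatenate([[0.0], self.recall])
        p = np.concatenate([[self.precision[0]], self.precision])
        ax.plot(r, p, drawstyle="steps-post", **kwargs)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        return ax


def _held_out_rank(weights: np.ndarray, genes: list[str], i: int) -> int:
    """1-based rank of gene i under descending weight, id tie-break."""
    wi, gi = weights[i], genes[i]
    better = int(np.sum(weights > wi))
    ties_before = sum(1 for j in np.flatnonzero(weights == wi)
                      if genes[j] < gi)
    return better + ties_before + 1


def loocv(adm, ds: DiseaseGeneSet,
          weight_mode: str = "difference") -> LoocvResult:
    """Leave-one-out cross-validation for one disease.

    Each disease gene is scored by weights trained on the other K-1;
    non-disease genes are scored once with the full set (rescoring all
    negatives per fold would be quadratic and changes nothing about the
    relative ordering question the protocol asks).
    """
    in_matrix = sorted(g for g in ds.genes if g in adm._index)
    k = len(in_matrix)
    if k < 2:
        raise DataError(
            f"disease {ds.disease_id}: LOOCV needs at least 2 disease genes "
            f"in the network (got {k})"
        )
    genes = list(adm.genes)
    full = disease_weights(adm, ds, weight_mode=weight_mode)
    n = len(genes)
    scores = full.weights.astype(float).copy()
    labels = np.zeros(n, dtype=int)
    ranks = np.full(n, np.nan)
    for g in in_matrix:
        i = adm.index_of(g)
        labels[i] = 1
        fold = disease_weights(adm, ds.without(g), weight_mode=weight_mode)
        scores[i] = fold.weights[i]
        ranks[i] = _held_out_rank(fold.weights, genes, i)
    table = pd.DataFrame({
        "gene": genes,
        "score": scores,
        "label": labels,
        "rank": ranks,
        "rank_ratio": ranks / n,
    })
    return LoocvResult(disease_id=ds.disease_id, table=table,
                       n_genes=n, k=k)


def pr_curve(scores, labels) -> PRCurve:
    """Stepwise PR curve over distinct score thresholds (descending).

    Tied scores enter together at one threshold. AUPRC integrates
    precision over recall by trapezoid, anchored at (recall 0, first
    precision); F-max sweeps all thresholds, endpoints included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be 1-D arrays of equal length")
    npos = int(labels.sum())
    if npos == 0 or npos == len(labels):
        raise DataError("PR curve needs at least one positive and one negative")
    distinct = np.unique(scores)[::-1]
    s_sorted = np.sort(scores)
    sp_sorted = np.sort(scores[labels == 1])
    P = len(scores) - np.searchsorted(s_sorted, distinct, side="left")
    TP = npos - np.searchsorted(sp_sorted, distinct, side="left")
    precision = TP / P
    recall = TP / npos
    # trapezoid over recall, anchored at recall 0
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(p, r))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return PRCurve(thresholds=distinct, precision=precision, recall=recall,
                   auc=auc, fmax=float(f1.max()))


def loocv_pr(result: LoocvResult) -> PRCurve:
    """PR curve of a LOOCV score set."""
    return pr_curve(result.table["score"].to_numpy(),
                    result.table["label"].to_numpy())


def convert_loocv_scores(result: LoocvResult) -> pd.DataFrame:
    """Map LOOCV weights to stepwise precisions for cross-disease pooling.

    Precision at each distinct LOOCV score s (inclusive threshold):
    TP/P over the labeled LOOCV list itself. Returns the result table
    with a ``converted`` column added.
    """
    t = result.table
    scores = t["score"].to_numpy()
    labels = t["label"].to_numpy()
    distinct = np.unique(scores)[::-1]
    s_sorted = np.sort(scores)
    sp_sorted = np.sort(scores[labels == 1])
    P = len(scores) - np.searchsorted(s_sorted, distinct, side="left")
    TP = labels.sum() - np.searchsorted(sp_sorted, distinct, side="left")
    prec = TP / P
    pos = np.searchsorted(-distinct, -scores)
    out = t.copy()
    out["converted"] = prec[pos]
    return out


def tpr_at_k(result: LoocvResult, ks=DEFAULT_TOP_KS,
             mode: str = "precision") -> pd.DataFrame:
    """True-positive rate among the top-k LOOCV-scored genes.

    ``precision`` mode (default) divides the positives found in the
    top k by k — how much of a k-gene assay budget would hit; the
    ``recall`` variant divides by K instead. Ties are broken by gene
    id, matching the ranking convention.
    """
    if mode not in ("precision", "recall"):
        raise DataError(f"unknown TPR mode {mode!r}")
    t = result.table
    order = np.lexsort((t["gene"].to_numpy(), -t["score"].to_numpy()))
    labels = t["label"].to_numpy()[order]
    rows = []
    for k in ks:
        if not 0 < k <= len(labels):
            raise DataError(f"k={k} outside 1..{len(labels)}")
        hits = int(labels[:k].sum())
        denom = k if mode == "precision" else result.k
        rows.append((k, hits / denom))
    return pd.DataFrame(rows, columns=["k", "tpr"])


def rank_ratio(ranking: pd.DataFrame, gene: str) -> float:
    """Rank of `gene` divided by the number of ranked genes; lower is better."""
    ranked = ranking[~ranking.get("unranked", pd.Series(False, index=ranking.index))]
    row = ranked[ranked["gene"] == gene]
    if row.empty:
        raise DataError(f"gene {gene!r} not present in the ranking")
    return float(row["rank"].iloc[0]) / len(ranked)


def pooled_pr(score_sets) -> PRCurve:
    """One PR curve over (score, label) pairs pooled across diseases.

    `score_sets` is an iterable of (scores, labels) pairs — use
    converted precision scores, which are comparable across diseases,
    not raw weights. Needs at least two diseases.
    """
    pairs = list(score_sets)
    if len(pairs) < 2:
        raise DataError("pooling needs at least 2 diseases")
    scores = np.concatenate([np.asarray(s, dtype=float) for s, _ in pairs])
    labels = np.concatenate([np.asarray(l, dtype=int) for _, l in pairs])
    return pr_curve(scores, labels)


def _size_stratum(k: int) -> str:
    if k <= 10:
        return "<=10"
    if k <= 50:
        return "11-50"
    if k <= 100:
        return "51-100"
    return ">100"


def mean_pairwise_disease_distance(dm, ds: DiseaseGeneSet) -> float:
    """Mean raw distance over the K*(K-1)/2 disease gene pairs."""
    idx = [dm.index_of(g) for g in sorted(ds.genes) if g in dm._index]
    if len(idx) < 2:
        raise DataError(f"disease {ds.disease_id}: fewer than 2 genes in matrix")
    sub = dm.values[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def compare_raw_vs_adjusted(network: GeneNetwork, gene_sets,
                            mode: str = "geometric",
                            weight_mode: str = "difference") -> pd.DataFrame:
    """Per-disease F-max with raw vs adjusted distances.

    Runs the full LOOCV pipeline twice per disease and also reports the
    mean pairwise raw distance among its genes (diseases whose genes
    are compact in the network are where the adjustment helps) and the
    disease-size stratum.
    """
    dm = all_pairs_raw_distance(network)
    adm = adjust_distance(dm, mode=mode)
    rows = []
    for ds in gene_sets:
        pr_raw = loocv_pr(loocv(dm, ds, weight_mode=weight_mode))
        pr_adj = loocv_pr(loocv(adm, ds, weight_mode=weight_mode))
        rows.append({
            "disease_id": ds.disease_id,
            "k": ds.k,
            "stratum": _size_stratum(ds.k),
            "fmax_raw": pr_raw.fmax,
            "fmax_adjusted": pr_adj.fmax,
            "auprc_raw": pr_raw.auc,
            "auprc_adjusted": pr_adj.auc,
            "mean_disease_distance": mean_pairwise_disease_distance(dm, ds),
        })
    return pd.DataFrame(rows)
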
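"""Post-GWAS SNP prioritization against a ranked candidate gene list.

A SNP is flagged as pointing at a novel candidate when (i) its
association p-value clears genome-wide significance (strictly below
5e-8 by default), (ii) its host gene is NOT already a known disease
gene, and (iii) the host gene sits within the top `top_n` (default
500) of the network-distance ranking. Known disease genes count toward
the rank threshold — the rank is the gene's literal position in the
genome-wide ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DiseaseGeneSet, SnpRecord

GENOME_WIDE_SIGNIFICANCE = 5e-8
DEFAULT_TOP_N = 500

RESULT_COLUMNS = ["snp_id", "host_gene", "p_value", "passes_p_threshold",
                  "host_is_known", "host_rank", "flagged_novel"]


@dataclass
class SnpPrioritizationResult:
    """Per-SNP flags; `table` columns follow RESULT_COLUMNS."""

    table: pd.DataFrame
    p_threshold: float
    top_n: int

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged_novel"]]


def prioritize_snps(snps, ranking: pd.DataFrame, known: DiseaseGeneSet,
                    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
                    top_n: int = DEFAULT_TOP_N) -> SnpPrioritizationResult:
    """Flag SNPs whose host genes are high-ranking novel candidates.

    `ranking` is a prioritization table with ``gene`` and ``rank``
    columns (unranked genes, if flagged, never satisfy the rank
    condition). SNPs whose host gene is absent from the ranking get a
    missing ``host_rank`` and are never flagged. An empty SNP list
    yields an empty result.
    """
    ranked = ranking
    if "unranked" in ranking.columns:
        ranked = ranking[~ranking["unranked"]]
    rank_of = dict(zip(ranked["gene"], ranked["rank"].astype(int)))
    rows = []
    for snp in snps:
        if not isinstance(snp, SnpRecord):
            snp = SnpRecord(*snp)
        passes = snp.p_value < p_threshold
        is_known = snp.host_gene in known.genes
        rank = rank_of.get(snp.host_gene)
        flagged = bool(passes and not is_known
                       and rank is not None and rank <= top_n)
        rows.append((snp.snp_id, snp.host_gene, snp.p_value, passes,
                     is_known, np.nan if rank is None else rank, flagged))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SnpPrioritizationResult(table=table, p_threshold=p_threshold,
                                   top_n=top_n)
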
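"""Gene functional-association networks and the text formats around them.

The central container is :class:`GeneNetwork`: an undirected graph over
opaque gene identifiers whose edges carry an integer confidence score
``S`` in ``(0, 1000]`` — the dialect of STRING ``protein.links`` files,
where a larger score means higher confidence that the two genes act
together. Edges are canonicalized (lexicographically smaller id first),
self-loops are dropped, and duplicate rows are merged keeping the
maximum score.

Also here: disease gene sets (2-column TSV or GMT lines), SNP tables,
and the ranked-output TSV writer/reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .exceptions import DataError, NetworkParseError

logger = logging.getLogger(__name__)

#: STRING confidence-tier presets usable as ``min_score``.
STRING_SCORE_TIERS = {
    "low": 150,       # low confidence or better
    "medium": 400,    # medium confidence or better
    "high": 700,      # high confidence or better
    "highest": 900,   # highest confidence
}

RANKING_COLUMNS = ["rank", "gene", "weight", "score", "is_known", "unranked"]


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class GeneNetwork:
    """Undirected weighted gene network with integer confidence scores.

    Parameters
    ----------
    genes : iterable of str, optional
        Gene identifiers in desired order; genes appearing in `edges`
        are appended in first-appearance order if missing.
    edges : iterable of (str, str, int), optional
        Edge triples. Pairs are canonicalized, self-loops rejected,
        duplicates merged keeping the maximum score.
    """

    def __init__(self, genes=(), edges=()):
        self._genes: list[str] = []
        self._index: dict[str, int] = {}
        self._edges: dict[tuple[str, str], int] = {}
        for g in genes:
            self.add_gene(g)
        for a, b, s in edges:
            self.add_edge(a, b, s)

    # -- construction -------------------------------------------------
    def add_gene(self, gene: str) -> None:
        if gene not in self._index:
            self._index[gene] = len(self._genes)
            self._genes.append(gene)

    def add_edge(self, a: str, b: str, score: int) -> None:
        score = int(score)
        if not 0 < score <= 1000:
            raise DataError(f"confidence score {score} outside (0, 1000]")
        if a == b:
            raise DataError(f"self-loop on gene {a!r}")
        self.add_gene(a)
        self.add_gene(b)
        key = _canonical(a, b)
        prev = self._edges.get(key)
        if prev is None or score > prev:
            self._edges[key] = score

    # -- basic queries -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return dict(self._edges)

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def degree(self, gene: str) -> int:
        return sum(1 for (a, b) in self._edges if gene in (a, b))

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self._genes}
        for a, b in self._edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    # -- structure -----------------------------------------------------
    def to_distance_csgraph(self) -> sparse.csr_matrix:
        """Sparse symmetric matrix of raw edge distances 1000/S."""
        n = self.n_genes
        if not self._edges:
            return sparse.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (a, b), s in self._edges.items():
            i, j = self._index[a], self._index[b]
            d = 1000.0 / s
            rows += [i, j]
            cols += [j, i]
            vals += [d, d]
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def component_labels(self) -> np.ndarray:
        n_comp, labels = csgraph.connected_components(
            self.to_distance_csgraph(), directed=False
        )
        return labels

    def largest_component_genes(self) -> tuple[list[str], list[str]]:
        """Split genes into (largest-component members, the rest).

        Ties between equally large components are broken in favour of
        the component containing the earliest-loaded gene. Order within
        each list follows network gene order.
        """
        labels = self.component_labels()
        counts = np.bincount(labels)
        best = int(np.flatnonzero(counts == counts.max())[0])
        inside = [g for g, l in zip(self._genes, labels) if l == best]
        outside = [g for g, l in zip(self._genes, labels) if l != best]
        return inside, outside

    def canonical_edge_lines(self) -> list[str]:
        """Sorted ``a\\tb\\tS`` lines; a stable fingerprint of the graph."""
        return [f"{a}\t{b}\t{s}" for (a, b), s in sorted(self._edges.items())]

    def __eq__(self, other):
        return (
            isinstance(other, GeneNetwork)
            and self._edges == other._edges
            and set(self._genes) == set(other._genes)
        )


@dataclass(frozen=True)
class DiseaseGeneSet:
    """A named set of known disease genes (post network intersection)."""

    disease_id: str
    genes: frozenset[str]

    @property
    def k(self) -> int:
        return len(self.genes)

    def without(self, gene: str) -> "DiseaseGeneSet":
        return DiseaseGeneSet(self.disease_id, self.genes - {gene})


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS SNP mapped to a host gene with its association p-value."""

    snp_id: str
    host_gene: str
    p_value: float

    def __post_init__(self):
        if not self.host_gene:
            raise DataError(f"SNP {self.snp_id}: empty host gene")
        if not 0.0 < self.p_value <= 1.0:
            raise DataError(
                f"SNP {self.snp_id}: p-value {self.p_value} outside (0, 1]"
            )


# ---------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------

def _is_int(token: str) -> bool:
    return token.lstrip("+-").isdigit() and token.lstrip("+-") != ""


def load_network(path, min_score: int = 1) -> GeneNetwork:
    """Read a STRING ``protein.links``-style edge list.

    Whitespace- or tab-delimited with at least three columns
    (geneA, geneB, integer confidence score in (0, 1000]). A single
    header line is auto-detected by a non-integer third field. Edges
    with score below `min_score` are discarded after duplicate rows are
    merged (max score wins); their endpoint genes are still registered.
    Self-loop rows register the gene but add no edge.

    Raises
    ------
    NetworkParseError
        Empty file, a line with fewer than three fields, a non-integer
        score, or a score outside (0, 1000].
    """
    net = GeneNetwork()
    merged: dict[tuple[str, str], int] = {}
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and len(fields) >= 3 and not _is_int(fields[2]):
                continue  # header
            if len(fields) < 3:
                raise NetworkParseError(
                    f"expected >=3 fields, got {len(fields)}",
                    path=path, line=lineno,
                )
            a, b, s_tok = fields[0], fields[1], fields[2]
            if not _is_int(s_tok):
                raise NetworkParseError(
                    f"non-integer confidence score {s_tok!r}",
                    path=path, line=lineno,
                )
            s = int(s_tok)
            if not 0 < s <= 1000:
                raise NetworkParseError(
                    f"confidence score {s} outside (0, 1000]",
                    path=path, line=lineno,
                )
            n_data_lines += 1
            net.add_gene(a)
            net.add_gene(b)
            if a == b:
                continue
            key = _canonical(a, b)
            if merged.get(key, 0) < s:
                merged[key] = s
    if n_data_lines == 0:
        raise NetworkParseError("no edges found", path=path)
    for (a, b), s in merged.items():
        if s >= min_score:
            net.add_edge(a, b, s)
    return net


def write_network(net: GeneNetwork, path) -> None:
    """Write the canonical edge list as a 3-column TSV with header."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for line in net.canonical_edge_lines():
            fh.write(line + "\n")


def make_disease_set(disease_id, genes, network: GeneNetwork,
                     min_size: int = 2) -> DiseaseGeneSet | None:
    """Intersect a raw gene list with the network; None if < min_size survive.

    A warning is logged with the number of genes dropped for being
    absent from the network, and another if the whole disease is
    discarded for falling below the minimum size.
    """
    genes = set(genes)
    kept = frozenset(g for g in genes if g in network)
    dropped = len(genes) - len(kept)
    if dropped:
        logger.warning(
            "disease %s: dropped %d gene(s) not present in the network",
            disease_id, dropped,
        )
    if len(kept) < min_size:
        logger.warning(
            "disease %s: only %d gene(s) left after network intersection "
            "(minimum %d); disease excluded",
            disease_id, len(kept), min_size,
        )
        return None
    return DiseaseGeneSet(disease_id, kept)


def load_gene_sets(path, network: GeneNetwork,
                   min_size: int = 2) -> list[DiseaseGeneSet]:
    """Read disease gene sets from 2-column TSV or GMT lines.

    Format is detected from the first non-empty line: exactly two
    tab-separated fields means (disease_id, gene_id) TSV; three or more
    means GMT (disease_id, description, gene, gene, ...). Gene sets are
    intersected with the network; diseases with fewer than `min_size`
    surviving genes are dropped with a warning.

    Raises
    ------
    NetworkParseError
        Unknown/mixed format or empty file.
    DataError
        Every disease was dropped.
    """
    raw: dict[str, list[str]] = {}
    fmt = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fmt is None:
                if len(fields) == 2:
                    fmt = "tsv"
                elif len(fields) >= 3:
                    fmt = "gmt"
                else:
                    raise NetworkParseError(
                        "unrecognized gene-set format (need 2-column TSV "
                        "or GMT lines)", path=path, line=lineno,
                    )
            if fmt == "tsv":
                if len(fields) != 2:
                    raise NetworkParseError(
                        f"expected 2 tab-separated fields, got {len(fields)}",
                        path=path, line=lineno,
                    )
                did, gene = fields
                raw.setdefault(did, []).append(gene)
            else:
                if len(fields) < 3:
                    raise NetworkParseError(
                        f"GMT line needs >=3 fields, got {len(fields)}",
                        path=path, line=lineno,
                    )
                did = fields[0]
                raw.setdefault(did, []).extend(fields[2:])
    if not raw:
        raise NetworkParseError("no gene sets found", path=path)
    out = []
    for did, genes in raw.items():
        ds = make_disease_set(did, genes, network, min_size=min_size)
        if ds is not None:
            out.append(ds)
    if not out:
        raise DataError(
            f"{path}: every disease dropped after network intersection"
        )
    return out


def load_snps(path) -> list[SnpRecord]:
    """Read a 3-column SNP table (snp_id, host_gene, p_value).

    Tab- or whitespace-delimited; a single header line is auto-detected
    by a non-numeric third field. A SNP mapping to several host genes
    appears as several rows.
    """
    records = []
    with open(path) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise NetworkParseError(
                    f"expected >=3 fields, got {len(fields)}",
                    path=path, line=lineno,
                )
            if lineno == 1:
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header
            try:
                p = float(fields[2])
            except ValueError:
                raise NetworkParseError(
                    f"non-numeric p-value {fields[2]!r}",
                    path=path, line=lineno,
                ) from None
            try:
                records.append(SnpRecord(fields[0], fields[1], p))
            except DataError as err:
                raise NetworkParseError(str(err), path=path, line=lineno) from None
    return records


# ---------------------------------------------------------------------
# ranking output
# ---------------------------------------------------------------------

def write_ranking(table: pd.DataFrame, path) -> None:
    """Write a ranked gene table as TSV (floats to 6 decimal places)."""
    cols = [c for c in RANKING_COLUMNS if c in table.columns]
    table = table[cols]
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ranking(path) -> pd.DataFrame:
    """Read back a ranking TSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("is_known", "unranked"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
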
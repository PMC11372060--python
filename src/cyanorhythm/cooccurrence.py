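"""Phylogenetic-profiling co-occurrence network.

Given a genome x protein boolean presence/absence matrix, the analysis
restricts the genome universe to those containing an anchor protein, runs a
right-sided Fisher's exact test for joint presence on every unordered protein
pair, corrects the p-values with Benjamini-Hochberg (FDR 1e-2 by default),
and keeps network edges whose adjusted p-value is at or below the threshold.
Node degree is the number of retained incident edges.

"Right-sided" means enrichment of joint presence: with a = both-present
count and fixed margins, p = P(X >= a) under the hypergeometric null.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParseError

FDR_DEFAULT = 0.01


def read_presence_matrix(path, delimiter: str = ",") -> pd.DataFrame:
    """Boolean genome-by-protein matrix from delimited text (genomes as rows,
    proteins as columns, header row and index column)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ParseError("duplicate genome or protein ids")
    try:
        return validate_presence_matrix(df)
    except DomainError as exc:
        raise ParseError(str(exc)) from exc


def validate_presence_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DomainError("duplicate genome or protein ids")
    values = df.to_numpy()
    if not np.isin(values, [0, 1, True, False]).all():
        raise DomainError("presence matrix must be boolean (0/1)")
    return df.astype(bool)


def fisher_right(table) -> float:
    """Right-tail Fisher's exact p for a 2x2 table [[a, b], [c, d]] with
    a = both present: P(X >= a) under the hypergeometric null with fixed
    margins.  A zero row or column margin gives p = 1."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DomainError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise DomainError("counts must be integers")
    if np.any(t < 0):
        raise DomainError("counts must be nonnegative")
    a, b, c, d = (int(round(float(v))) for v in t.ravel())
    n_total = a + b + c + d
    if n_total == 0 or min(a + b, a + c, c + d, b + d) == 0:
        return 1.0  # a zero margin fixes the table; the tail is the whole support
    # survival function is computed in log space internally by scipy
    return float(hypergeom.sf(a - 1, n_total, a + b, a + c))


def pairwise_cooccurrence(matrix: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """Right-sided Fisher p for every unordered protein pair within the
    universe of genomes containing the anchor.  The anchor's self-pair is
    excluded (as is every self-pair); pairs involving the anchor itself are
    degenerate (p = 1) since the anchor is present in every universe genome."""
    matrix = validate_presence_matrix(matrix)
    if anchor not in matrix.columns:
        raise KeyError(f"anchor protein {anchor!r} not in matrix")
    universe = matrix.loc[matrix[anchor]]
    proteins = list(matrix.columns)
    rows = []
    n = len(universe)
    for i, p1 in enumerate(proteins):
        for p2 in proteins[i + 1 :]:
            x1 = universe[p1].to_numpy()
            x2 = universe[p2].to_numpy()
            a = int(np.sum(x1 & x2))
            b = int(np.sum(x1 & ~x2))
            c = int(np.sum(~x1 & x2))
            d = n - a - b - c
            rows.append((p1, p2, fisher_right([[a, b], [c, d]])))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "p_raw"])


def bh_adjust(pvals, q: float = FDR_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)
    and discovery flags (adjusted p <= q)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


@dataclass
class CooccurNetwork:
    """Edge table (with raw and adjusted p) plus retained-edge node degrees."""

    edges: pd.DataFrame  # protein_a, protein_b, p_raw, p_adj, significant
    degrees: dict[str, int]
    threshold: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.degrees)
        g.add_edges_from(
            self.retained[["protein_a", "protein_b"]].itertuples(index=False, name=None)
        )
        return g


def build_network(pairs: pd.DataFrame, threshold: float = FDR_DEFAULT,
                  p_column: str = "p_adj") -> CooccurNetwork:
    """Retain edges with ``p_column`` <= threshold; degree = retained incident
    edges (nodes with no retained edge have degree 0)."""
    edges = pairs.copy()
    edges["significant"] = edges[p_column] <= threshold
    nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        edges.loc[edges["significant"], ["protein_a", "protein_b"]]
        .itertuples(index=False, name=None)
    )
    return CooccurNetwork(
        edges=edges, degrees={node: int(g.degree(node)) for node in nodes},
        threshold=threshold,
    )


def cooccurrence_network(
    matrix: pd.DataFrame,
    anchor: str,
    q: float = FDR_DEFAULT,
    threshold: float | None = None,
    use_raw: bool = False,
) -> CooccurNetwork:
    """Full analysis: anchor-restricted pairwise Fisher tests, BH correction,
    thresholded network.  ``use_raw=True`` thresholds raw instead of adjusted
    p-values (adjusted is the default reading of the edge rule)."""
    pairs = pairwise_cooccurrence(matrix, anchor)
    adjusted, _ = bh_adjust(pairs["p_raw"].to_numpy(), q=q)
    pairs["p_adj"] = adjusted
    thr = q if threshold is None else threshold
    return build_network(pairs, threshold=thr, p_column="p_raw" if use_raw else "p_adj")
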
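"""Phylogenetic-profiling co-occurrence network from a presence matrix.

Thirty genomes all carry an anchor protein; three proteins (X, Y, Z) share
one presence profile across half of them, three others are random.  Each
protein pair gets a right-sided Fisher's exact p (enrichment of joint
presence in the anchor-restricted universe), Benjamini-Hochberg correction
at FDR 0.01 decides the network edges, and node degree counts retained
edges — the shared-profile triple comes out as a 3-clique.
"""

import numpy as np
import pandas as pd

from cyanorhythm import cooccurrence_network

rng = np.random.default_rng(0)
profile = (np.arange(30) < 15).astype(int)
matrix = pd.DataFrame(
    np.column_stack(
        [np.ones(30, int), profile, profile, profile, rng.integers(0, 2, (30, 3))]
    ),
    index=[f"genome{i:02d}" for i in range(30)],
    columns=["anchor", "X", "Y", "Z", "R1", "R2", "R3"],
)

net = cooccurrence_network(matrix, anchor="anchor", q=0.01)
print("retained edges (BH-adjusted p <= 0.01):")
for row in net.retained.itertuples(index=False):
    print(f"  {row.protein_a} -- {row.protein_b}: p_raw={row.p_raw:.2e}, p_adj={row.p_adj:.2e}")
print("node degrees:", {k: v for k, v in net.degrees.items() if v > 0})
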
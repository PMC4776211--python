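"""Genome completeness from conserved single-copy gene families.

Protein families are derived by Markov clustering (MCL) of a similarity
graph: the column-stochastic adjacency matrix is alternately squared
(expansion) and raised elementwise to an inflation power with column
renormalization, until convergence; clusters are the connected attractor
systems. Families present in exactly one copy in every reference genome
act as completeness markers: the fraction of them represented in a target
gene set (and, among those, the fraction present as a single gene)
estimates how complete the recovered genome is.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def mcl_cluster(
    similarity_edges,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> list[set]:
    """Markov clustering of a weighted undirected similarity graph.

    ``similarity_edges`` is an iterable of (a, b, weight) triples (or a
    DataFrame with those columns). Self-loops are added with weight equal
    to the node's maximum incident weight, a standard regularization.
    Returns the clusters as a partition of the node set (list of sets,
    ordered by smallest member).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if isinstance(similarity_edges, pd.DataFrame):
        edges = list(similarity_edges.itertuples(index=False, name=None))
    else:
        edges = list(similarity_edges)
    if not edges:
        return []
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, w in edges:
        if w < 0:
            raise ValueError("similarity weights must be non-negative")
        i, j = idx[a], idx[b]
        if i == j:
            continue
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        delta = np.abs(inflated - M).max()
        M = inflated
        if delta < tol:
            break

    # attractor systems: connect i-j when either steady-state entry is nonzero
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(M > prune)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = sorted(nx.connected_components(g), key=min)
    return [{nodes[i] for i in comp} for comp in comps]


@dataclass
class FamilyTable:
    """Gene-family copy counts per genome.

    ``counts`` is families x genomes (non-negative integers); every family
    must have at least one nonzero entry.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("family counts must be non-negative")
        if len(self.counts) and (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every family needs >= 1 nonzero entry")

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)


def single_copy_families(families: FamilyTable, reference_genomes) -> list[str]:
    """Families present in exactly one copy in every reference genome."""
    refs = list(reference_genomes)
    unknown = set(refs) - set(families.genomes)
    if unknown:
        raise ValueError(f"unknown reference genome(s): {sorted(unknown)}")
    sub = families.counts[refs]
    mask = (sub == 1).all(axis=1)
    return list(families.counts.index[mask])


@dataclass
class CompletenessReport:
    n_families_considered: int
    fraction_represented: float
    fraction_single_copy: float


def completeness(
    single_copy_ids, target_gene_families: dict[str, str] | pd.Series
) -> CompletenessReport:
    """Completeness of a target gene set against single-copy marker families.

    ``target_gene_families`` maps target gene id -> family id.
    fraction_represented is the share of marker families with >= 1 target
    gene; fraction_single_copy is, among represented families, the share
    with exactly one.
    """
    markers = list(single_copy_ids)
    if not markers:
        raise ValueError("single_copy_ids must be non-empty")
    fam = pd.Series(dict(target_gene_families) if isinstance(target_gene_families, dict) else target_gene_families)
    per_family = fam.value_counts()
    counts = per_family.reindex(markers).fillna(0).astype(int)
    represented = counts[counts >= 1]
    frac_rep = len(represented) / len(markers)
    frac_single = float((represented == 1).mean()) if len(represented) else 0.0
    return CompletenessReport(
        n_families_considered=len(markers),
        fraction_represented=frac_rep,
        fraction_single_copy=frac_single,
    )
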
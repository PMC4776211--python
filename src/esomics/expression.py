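"""Expression analysis: normalization, Rank Product, GSEA, clustering.

Transcript read counts and balanced protein spectral counts are analyzed
on two levels. Community level: each sample is scaled to a fixed library
size of one million, and organismal groups are summarized as fractions of
the community. Organism level: within one organism's features, samples are
rescaled so the organism's totals are identical across samples, removing
abundance differences before expression comparisons.

Differential expression uses the Rank Product: the geometric mean of a
feature's fold-change ranks over all between-condition sample pairs, with
significance from permutations of the rank columns, combined with a
fold-change cutoff. Gene-set level shifts use classic (unweighted) GSEA
with a gene-set permutation null. Sample structure is explored by
average-linkage clustering on an uncentered Pearson correlation distance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

LIBRARY_SIZE = 1_000_000.0


@dataclass
class CountMatrix:
    """Features x samples abundance table with sample/feature annotations.

    Parameters
    ----------
    values : DataFrame
        Non-negative counts (transcript reads or balanced spectral counts),
        features as rows, samples as columns.
    conditions : Series
        Condition label per sample (e.g. streamer / floating); must cover
        every sample column.
    organisms, groups : Series or None
        Optional per-feature organism and functional-group labels.
    kind : {"transcript", "protein"}
    normalization : {"raw", "community", "organism"}
        State advances only raw -> community -> organism.
    """

    values: pd.DataFrame
    conditions: pd.Series
    organisms: pd.Series | None = None
    groups: pd.Series | None = None
    kind: str = "transcript"
    normalization: str = "raw"

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.kind not in ("transcript", "protein"):
            raise ValueError("kind must be 'transcript' or 'protein'")
        if self.normalization not in ("raw", "community", "organism"):
            raise ValueError("unknown normalization state")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition].index
        return [s for s in self.values.columns if s in set(sel)]


def normalize_community(matrix: CountMatrix) -> CountMatrix:
    """Scale every sample to a total of exactly one million.

    Each value is divided by its sample total and multiplied by 1,000,000;
    idempotent on already community-normalized input.
    """
    if matrix.normalization == "organism":
        raise ValueError("cannot community-normalize an organism-normalized matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    values = matrix.values / totals * LIBRARY_SIZE
    return replace(matrix, values=values, normalization="community")


def normalize_organism(matrix: CountMatrix, organism: str) -> CountMatrix:
    """Make one organism's per-sample totals identical across samples.

    Within the organism's feature rows, each sample is rescaled so the
    organism's totals all equal the mean of the input totals; other
    organisms' rows are untouched.
    """
    if matrix.organisms is None:
        raise ValueError("matrix has no organism labels")
    if matrix.normalization == "organism":
        raise ValueError("matrix is already organism-normalized")
    rows = matrix.organisms[matrix.organisms == organism].index
    rows = [f for f in matrix.values.index if f in set(rows)]
    if not rows:
        raise ValueError(f"organism {organism!r} has no features")
    sub = matrix.values.loc[rows]
    totals = sub.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"organism {organism!r} absent in sample(s): {list(zero.index)}"
        )
    target = totals.mean()
    values = matrix.values.copy()
    values.loc[rows] = sub * (target / totals)
    return replace(matrix, values=values, normalization="organism")


def filter_complete(matrix: CountMatrix) -> CountMatrix:
    """Keep features quantified (value > 0) in every sample."""
    mask = (matrix.values > 0).all(axis=1)
    if not mask.any():
        warnings.warn("no feature is quantified in all samples", stacklevel=2)
    out = replace(matrix, values=matrix.values[mask])
    if matrix.organisms is not None:
        out.organisms = matrix.organisms.reindex(out.values.index)
    if matrix.groups is not None:
        out.groups = matrix.groups.reindex(out.values.index)
    return out


def unique_mapped(total_counts: pd.DataFrame, unique_counts: pd.DataFrame) -> pd.DataFrame:
    """Restrict counts to uniquely mapping evidence.

    ``unique_counts`` must be elementwise <= ``total_counts`` (a read or
    spectrum cannot be unique without being counted); the returned table is
    exactly the unique evidence, so no feature's count ever increases.
    """
    t = total_counts.reindex_like(unique_counts)
    if ((unique_counts - t) > 0).any().any():
        raise ValueError("unique counts exceed total counts")
    return unique_counts.copy()


# ---------------------------------------------------------------------------
# Rank Product
# ---------------------------------------------------------------------------


def _rank_columns(ratios: np.ndarray, ascending: bool) -> np.ndarray:
    """Column-wise ranks (1 = first) with average tie ranks."""
    sign = 1.0 if ascending else -1.0
    return np.column_stack(
        [rankdata(sign * ratios[:, k], method="average") for k in range(ratios.shape[1])]
    )


def _null_rp_exhaustive(G: int) -> np.ndarray:
    """All G! single-column rank assignments (K = 1): null RP = the rank."""
    perms = np.array(list(itertools.permutations(range(1, G + 1))), dtype=float)
    return perms.ravel()


def _null_rp_montecarlo(
    A: np.ndarray, B: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Null RPs from ``n_perm`` permutations of feature labels per sample.

    Each permutation independently shuffles the feature labels within every
    sample column and recomputes the cross-condition ratio ranks. Shuffling
    whole sample columns (rather than the derived ratio-rank columns)
    preserves the dependence between ratio columns that share a sample, so
    the null matches the statistic's correlation structure and the
    resulting p-values are calibrated.
    """
    G = A.shape[0]
    null_up = np.empty(n_perm * G)
    null_down = np.empty(n_perm * G)
    for p in range(n_perm):
        Ap = np.column_stack([A[rng.permutation(G), i] for i in range(A.shape[1])])
        Bp = np.column_stack([B[rng.permutation(G), j] for j in range(B.shape[1])])
        ratios = np.column_stack(
            [Ap[:, i] / Bp[:, j] for i in range(Ap.shape[1]) for j in range(Bp.shape[1])]
        )
        up = _rank_columns(ratios, ascending=False)
        down = _rank_columns(ratios, ascending=True)
        null_up[p * G : (p + 1) * G] = np.exp(np.log(up).mean(axis=1))
        null_down[p * G : (p + 1) * G] = np.exp(np.log(down).mean(axis=1))
    return null_up, null_down


def _p_from_null(observed: np.ndarray, null_sorted: np.ndarray, n_datasets: int) -> np.ndarray:
    """p = E(null RP <= observed) / G, with E the mean count per null dataset."""
    G = len(observed)
    # geometric means come back a few ulps under their exact value
    # (exp(log 5) < 5); a relative nudge keeps exact ties counted as <=
    counts = np.searchsorted(null_sorted, observed * (1.0 + 1e-9), side="right")
    p = counts / n_datasets / G
    return np.clip(p, 1.0 / (n_datasets * G), 1.0)


def rank_product(
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    n_perm: int = 200,
    seed: int | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    exhaustive_limit: int = 9,
) -> pd.DataFrame:
    """Rank Product differential expression between two conditions.

    All nA x nB cross-condition ratio columns are formed; within each
    column features are ranked by descending ratio (average tie ranks) and
    RP_up is the geometric mean of a feature's ranks (RP_down analogously
    on ascending order). The null distribution comes from ``n_perm``
    independent permutations of the feature labels within each sample
    column (ratios and ranks recomputed per permutation);
    p = E(null RP <= observed) / G. When K = 1 and G! <= 10^6 (G <= 9) the
    rank permutations are enumerated exhaustively instead (for K = 1 the
    two null constructions coincide).

    A feature is flagged significant when its A:B mean ratio exceeds
    ``fc_threshold`` (or is below its reciprocal) and min(p_up, p_down) is
    at or below ``p_threshold``. Benjamini-Hochberg columns are emitted for
    transparency; the significance rule itself is the joint
    fold-change/p-value criterion.
    """
    a_cols = matrix.samples_of(condition_a)
    b_cols = matrix.samples_of(condition_b)
    if not a_cols or not b_cols:
        raise ValueError("both conditions need at least one sample")
    X = matrix.values
    G = len(X)
    if G < 2:
        raise ValueError("need at least 2 features")
    if (X[a_cols + b_cols].to_numpy() <= 0).any():
        raise ValueError(
            "rank_product requires a complete-case matrix (all values > 0); "
            "apply filter_complete first"
        )
    A = X[a_cols].to_numpy(dtype=float)
    B = X[b_cols].to_numpy(dtype=float)
    K = A.shape[1] * B.shape[1]
    ratios = np.column_stack(
        [A[:, i] / B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    ranks_up = _rank_columns(ratios, ascending=False)
    ranks_down = _rank_columns(ratios, ascending=True)
    rp_up = np.exp(np.log(ranks_up).mean(axis=1))
    rp_down = np.exp(np.log(ranks_down).mean(axis=1))

    if K == 1 and G <= exhaustive_limit and math.factorial(G) <= 10**6:
        null = np.sort(_null_rp_exhaustive(G))
        n_datasets = math.factorial(G)
        p_up = _p_from_null(rp_up, null, n_datasets)
        p_down = _p_from_null(rp_down, null, n_datasets)
    else:
        rng = np.random.default_rng(seed)
        null_up, null_down = _null_rp_montecarlo(A, B, n_perm, rng)
        p_up = _p_from_null(rp_up, np.sort(null_up), n_perm)
        p_down = _p_from_null(rp_down, np.sort(null_down), n_perm)

    ratio = A.mean(axis=1) / B.mean(axis=1)
    p_min = np.minimum(p_up, p_down)
    significant = ((ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)) & (
        p_min <= p_threshold
    )
    return pd.DataFrame(
        {
            "feature_id": X.index,
            "ratio": ratio,
            "rp_up": rp_up,
            "rp_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "fdr_up": _bh(p_up),
            "fdr_down": _bh(p_down),
            "significant": significant,
        }
    ).reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# GSEA (classic, gene-set permutation)
# ---------------------------------------------------------------------------


def enrichment_score(ranked_ids, gene_set) -> float:
    """Classic (unweighted) running-sum enrichment score.

    Walking the ranked list, the sum gains 1/|S| at each gene-set member
    and loses 1/(N - |S|) at every other gene; the ES is the deviation of
    maximum magnitude (signed).
    """
    members = set(gene_set)
    N = len(ranked_ids)
    S = sum(1 for g in ranked_ids if g in members)
    if S == 0 or S == N:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    hit, miss = 1.0 / S, 1.0 / (N - S)
    running = 0.0
    best = 0.0
    for g in ranked_ids:
        running += hit if g in members else -miss
        if abs(running) > abs(best):
            best = running
    return best


def _es_for_size(is_hit: np.ndarray) -> float:
    """ES from a boolean hit vector along the ranking (vectorized)."""
    N = len(is_hit)
    S = int(is_hit.sum())
    steps = np.where(is_hit, 1.0 / S, -1.0 / (N - S))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    matrix: CountMatrix,
    gene_sets: dict[str, list[str]],
    condition_a: str,
    condition_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 2,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classic GSEA with a gene-set permutation null.

    Features are ranked by the log2 ratio of class means (condition A over
    condition B), descending. Each set's null is ``n_perm`` random gene
    sets of the same size; NES divides ES by the mean |null ES| of the
    matching sign, the nominal p is one-sided on that sign, and the FDR q
    compares each |NES| against the pooled sign-normalized null over all
    sets, then is made monotone non-increasing in |NES|. Sets smaller than
    ``min_size`` (after intersection with the matrix features) or covering
    the whole ranking are skipped with a warning.
    """
    a_cols = matrix.samples_of(condition_a)
    b_cols = matrix.samples_of(condition_b)
    if not a_cols or not b_cols:
        raise ValueError("both conditions need at least one sample")
    mean_a = matrix.values[a_cols].mean(axis=1)
    mean_b = matrix.values[b_cols].mean(axis=1)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError("class means must be positive; apply filter_complete first")
    metric = np.log2(mean_a / mean_b)
    order = metric.sort_values(ascending=False, kind="mergesort")
    ranked = list(order.index)
    pos = {g: i for i, g in enumerate(ranked)}
    N = len(ranked)
    rng = np.random.default_rng(seed)

    usable: list[tuple[str, np.ndarray, int]] = []
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in pos]
        size = len(set(members))
        if size < min_size or size >= N:
            warnings.warn(f"gene set {name!r} skipped (size {size} of {N})", stacklevel=2)
            continue
        is_hit = np.zeros(N, dtype=bool)
        for g in set(members):
            is_hit[pos[g]] = True
        usable.append((name, is_hit, size))

    # shared null per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for _, _, size in usable:
        if size in null_by_size:
            continue
        null = np.empty(n_perm)
        for p in range(n_perm):
            hit = np.zeros(N, dtype=bool)
            hit[rng.choice(N, size=size, replace=False)] = True
            null[p] = _es_for_size(hit)
        null_by_size[size] = null

    rows = []
    pooled_null_nes: list[np.ndarray] = []
    for name, is_hit, size in usable:
        es = _es_for_size(is_hit)
        null = null_by_size[size]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            nes = np.nan
            p_nom = 1.0 / (n_perm + 1)
        else:
            denom = np.abs(same_sign).mean()
            nes = es / denom
            p_nom = max(
                (np.abs(same_sign) >= abs(es)).sum() / len(same_sign),
                1.0 / (n_perm + 1),
            )
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        norm_null = np.concatenate(
            [
                pos_null / pos_null.mean() if len(pos_null) else pos_null,
                neg_null / np.abs(neg_null).mean() if len(neg_null) else neg_null,
            ]
        )
        pooled_null_nes.append(norm_null)
        rows.append((name, size, es, nes, p_nom))

    if not rows:
        return pd.DataFrame(
            columns=["gene_set", "size", "es", "nes", "p_nominal", "fdr_q", "direction", "significant"]
        )
    df = pd.DataFrame(rows, columns=["gene_set", "size", "es", "nes", "p_nominal"])
    pooled = np.abs(np.concatenate(pooled_null_nes))
    obs_abs = np.abs(df["nes"].to_numpy())
    qs = np.empty(len(df))
    for i, v in enumerate(obs_abs):
        frac_null = (pooled >= v).mean() if len(pooled) else 1.0
        frac_obs = (obs_abs >= v).mean()
        qs[i] = min(frac_null / frac_obs, 1.0) if frac_obs > 0 else 1.0
    # enforce q monotone non-increasing in |NES|: walking down the
    # |NES|-descending order, q may only grow (raising, never lowering)
    order_idx = np.argsort(-obs_abs, kind="mergesort")
    qs[order_idx] = np.maximum.accumulate(qs[order_idx])
    df["fdr_q"] = qs
    df["direction"] = np.where(df["es"] >= 0, f"up_in_{condition_a}", f"up_in_{condition_b}")
    df["significant"] = df["fdr_q"] <= fdr_threshold
    return df


# ---------------------------------------------------------------------------
# Hierarchical clustering & community structure
# ---------------------------------------------------------------------------


def uncentered_pearson_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise d(x, y) = 1 - sum(x*y) / sqrt(sum(x^2) * sum(y^2)) over columns."""
    norms = np.sqrt((X**2).sum(axis=0))
    if (norms == 0).any():
        raise ValueError("column with all-zero profile")
    Xn = X / norms
    D = 1.0 - Xn.T @ Xn
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


@dataclass
class HclusterResult:
    newick: str
    linkage: np.ndarray
    distance: pd.DataFrame
    cophenetic_r: float
    leaves: list[str] = field(default_factory=list)


def _to_newick(node, labels: list[str], parent_dist: float) -> str:
    length = max((parent_dist - node.dist) / 2.0, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def hcluster(matrix: CountMatrix, pseudo: float = 1e-6) -> HclusterResult:
    """Average-linkage clustering of samples on uncentered Pearson distance.

    Each feature row is first converted to percentages (summing to 100),
    then ``pseudo`` (default 0.000001) is added to every value so zeros do
    not collapse the correlation. Samples are processed in lexicographic
    order for a deterministic leaf layout.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cols = sorted(matrix.values.columns)
    X = matrix.values[cols].to_numpy(dtype=float)
    row_sums = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, X / row_sums * 100.0, 0.0)
    pct = pct + pseudo
    D = uncentered_pearson_distance(pct)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    coph, _ = sch.cophenet(Z, squareform(D, checks=False))
    tree = sch.to_tree(Z)
    newick = _to_newick(tree, cols, tree.dist)
    newick = newick.rsplit(":", 1)[0] + ";"  # the root carries no branch length
    leaves = [cols[i] for i in sch.leaves_list(Z)]
    return HclusterResult(
        newick=newick,
        linkage=Z,
        distance=pd.DataFrame(D, index=cols, columns=cols),
        cophenetic_r=float(coph),
        leaves=leaves,
    )


def community_summary(
    matrix: CountMatrix, organism_groups: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-sample fraction of the community attributed to each organismal group.

    fraction(group, sample) = sum of the group's counts / sum of all
    counts in the sample; fractions sum to 1 per sample. Every feature
    must be mapped to a group.
    """
    mapping = pd.Series(dict(organism_groups) if isinstance(organism_groups, dict) else organism_groups)
    unmapped = [f for f in matrix.values.index if f not in mapping.index]
    if unmapped:
        raise ValueError(f"unmapped feature(s): {unmapped[:10]}")
    groups = mapping.reindex(matrix.values.index)
    totals = matrix.values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total")
    frac = matrix.values.groupby(groups).sum() / totals
    return frac.sort_index()
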
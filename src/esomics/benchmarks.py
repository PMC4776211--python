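"""End-to-end benchmark measurements on study-condition synthetic data.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and measures recovery/calibration metrics against the
generator's ground truth. They are the single source for the acceptance
checks and the reproduction script, so the numbers those report are always
recomputed, never stored.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from . import families as fam
from . import proteomics as prot
from . import refine as ref
from . import synthetic as syn
from .composition import tnf
from .esom import TetranucleotideESOM, assign_bmus, select_bins
from .expression import (
    CountMatrix,
    enrichment_score,
    filter_complete,
    gsea,
    hcluster,
    normalize_community,
    rank_product,
)


def bin_recovery(
    seed: int = 1,
    n_genomes: int = 3,
    n_per_genome: int = 300,
    divergence: float = 0.8,
    epochs: int = 20,
) -> dict:
    """Target-genome recovery on a seeded 3-genome mixture.

    Trains the ESOM on contigs >= 3 kbp, projects 1-3 kbp contigs, extracts
    bins from the U-matrix, identifies the target bin from taxonomy hits
    (not truth), expands it via assembly-graph neighbors and taxon hits,
    screens contaminants, and scores the kept set against the generator's
    truth. Also reports the F1 of the raw composition bin alone.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    models = syn.simulate_community(n_genomes, divergence, int(seeds[0]))
    contigs, truth = syn.simulate_contigs(models, n_per_genome, chimera_rate=0.0, seed=int(seeds[1]))
    target = next(m.genome_id for m in models if m.is_target)
    graph = syn.simulate_assembly_graph(truth, seed=int(seeds[2]))
    hits = syn.simulate_hit_table(truth, target, seed=int(seeds[3]))

    train = tnf(contigs, min_len=3000)
    short = {c: s for c, s in contigs.items() if 1000 <= len(s) < 3000}
    project = tnf(short, min_len=1000) if short else None
    som = TetranucleotideESOM(epochs=epochs, random_state=seed).fit(train)
    assignments = assign_bmus(som, train, project)
    bins = select_bins(som, assignments, umatrix_percentile=30)

    fungal = ref.taxon_set(hits, 1e-10, "Fungi")
    best_bin, best_score = None, (-1, -1)
    for label in bins.bins:
        members = bins.contigs_in_bin(label)
        score = (len(set(members) & fungal), len(members))
        if score > best_score:
            best_bin, best_score = label, score
    set1 = set(bins.contigs_in_bin(best_bin)) if best_bin else set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        set2 = ref.graph_neighbors(graph, set1, 2)
    candidates = ref.candidate_union(set1, set2, fungal)
    kept, _ = ref.screen_contaminants(
        candidates["contig_id"], hits, ["Leptospirillum", "Sulfobacillus", "Archaea"]
    )

    target_contigs = {c for c, g in truth.contig_genome.items() if g == target}

    def prf(predicted: set[str]) -> tuple[float, float, float]:
        tp = len(predicted & target_contigs)
        precision = tp / len(predicted) if predicted else 0.0
        recall = tp / len(target_contigs)
        f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
        return precision, recall, f1

    precision, recall, f1 = prf(kept)
    _, _, f1_bin_only = prf(set1)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "f1_bin_only": f1_bin_only,
        "n_contigs": len(contigs),
        "n_kept": len(kept),
    }


def chimera_splitting(
    seed: int = 1,
    n_clean: int = 270,
    n_chimeric: int = 30,
    depth: float = 20.0,
    insert_mean: float = 200.0,
    insert_sd: float = 20.0,
) -> dict:
    """Breakpoint detection on planted chimeras among clean contigs.

    A split is correct when the contig is cut and some cut site falls
    within one insert length of the true junction; any cut on a clean
    contig counts as a false split.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    models = syn.simulate_community(3, 0.8, int(seeds[0]))
    per_genome_clean, per_genome_chim = n_clean // 3, n_chimeric // 3
    clean, truth_clean = syn.simulate_contigs(
        models, per_genome_clean, chimera_rate=0.0, seed=int(seeds[1])
    )
    chim, truth_chim = syn.simulate_contigs(
        models, per_genome_chim, chimera_rate=1 - 1e-12, seed=int(seeds[2])
    )
    chim = {f"chim_{c}": s for c, s in chim.items()}
    truth = syn.SyntheticTruth(
        contig_genome={**truth_clean.contig_genome,
                       **{f"chim_{c}": g for c, g in truth_chim.contig_genome.items()}},
        junctions={f"chim_{c}": j for c, j in truth_chim.junctions.items()},
    )
    contigs = {**clean, **chim}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        placements = syn.simulate_read_pairs(
            contigs, depth, insert_mean, insert_sd, truth=truth, seed=seed
        )
    lengths = {c: len(s) for c, s in contigs.items()}
    supports = ref.fragment_support(placements, lengths)
    margin = int(insert_mean + 3 * insert_sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = ref.split_misassemblies(supports, margin, min_piece=250)
    cuts: dict[str, list[int]] = {}
    for r in records:
        cuts.setdefault(r.contig_id, r.cut_sites)
    n_correct = sum(
        1
        for cid, j in truth.junctions.items()
        if any(abs(c - j) <= insert_mean for c in cuts.get(cid, []))
    )
    false_splits = sum(bool(cuts.get(cid)) for cid in clean)
    return {
        "n_chimeras": len(truth.junctions),
        "n_split_near_junction": n_correct,
        "n_false_splits": false_splits,
    }


def rank_product_calibration(
    seed: int = 1, n_features: int = 2000, n_perm: int = 200
) -> dict:
    """Type-I error of the RP permutation test on all-null features, plus
    exactness of the exhaustive mode against full enumeration at G=4."""
    matrix, _ = syn.simulate_count_matrix(
        n_features, (3, 2), de_fraction=0.0, fold_change=4.0, dispersion=0.1, seed=seed
    )
    full = filter_complete(normalize_community(matrix))
    res = rank_product(full, "streamer", "floating", n_perm=n_perm, seed=seed)
    type1_up = float((res["p_up"] <= 0.01).mean())
    type1_down = float((res["p_down"] <= 0.01).mean())

    # exhaustive-vs-enumeration equality at G=4, K=1
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        {"a1": rng.uniform(1, 100, 4), "b1": rng.uniform(1, 100, 4)}
    )
    toy = CountMatrix(values=values, conditions=pd.Series({"a1": "A", "b1": "B"}))
    toy_res = rank_product(toy, "A", "B").set_index("feature_id")
    from scipy.stats import rankdata

    obs = rankdata(-(values["a1"] / values["b1"]))
    exact = True
    for f in range(4):
        counts = [
            sum(r <= obs[f] for r in perm)
            for perm in itertools.permutations(range(1, 5))
        ]
        if abs(toy_res.loc[f, "p_up"] - np.mean(counts) / 4) > 1e-12:
            exact = False
    return {
        "type1_error_up": type1_up,
        "type1_error_down": type1_down,
        "exhaustive_matches_enumeration": exact,
        "n_features": len(full.features),
    }


def rank_product_power(
    seed: int = 1, n_features: int = 2000, n_perm: int = 200
) -> dict:
    """Recall of planted fold-change-4 features under the joint rule
    (ratio > 2 or < 0.5, and permutation p <= 0.01)."""
    matrix, truth = syn.simulate_count_matrix(
        n_features, (3, 2), de_fraction=0.05, fold_change=4.0, dispersion=0.1, seed=seed
    )
    full = filter_complete(normalize_community(matrix))
    res = rank_product(full, "streamer", "floating", n_perm=n_perm, seed=seed)
    sig = set(res.loc[res["significant"], "feature_id"])
    planted = set(truth.de_features["feature_id"]) & set(full.features)
    nulls = set(full.features) - set(truth.de_features["feature_id"])
    return {
        "recall": len(sig & planted) / len(planted),
        "false_positive_rate": len(sig & nulls) / len(nulls),
        "n_planted": len(planted),
    }


def gsea_checks(seed: int = 1) -> dict:
    """Toy-instance correctness of the classic enrichment statistic."""
    rng = np.random.default_rng(seed)
    n = 10
    values = pd.DataFrame(
        {
            "a1": rng.uniform(1, 100, n), "a2": rng.uniform(1, 100, n),
            "b1": rng.uniform(1, 100, n), "b2": rng.uniform(1, 100, n),
        },
        index=[f"g{i}" for i in range(n)],
    )
    matrix = CountMatrix(
        values=values,
        conditions=pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
    )
    members = {"g1", "g4", "g7"}
    res = gsea(matrix, {"s": sorted(members)}, "A", "B", n_perm=200, seed=seed)
    mean_a = values[["a1", "a2"]].mean(axis=1)
    mean_b = values[["b1", "b2"]].mean(axis=1)
    ranked = list(np.log2(mean_a / mean_b).sort_values(ascending=False).index)
    S, N = len(members), n
    running, best = 0.0, 0.0
    for g in ranked:
        running += 1.0 / S if g in members else -1.0 / (N - S)
        if abs(running) > abs(best):
            best = running
    es_error = abs(float(res.iloc[0]["es"]) - best)

    singleton_es = enrichment_score(ranked, {ranked[0]})

    big = CountMatrix(
        values=pd.DataFrame(
            {c: rng.uniform(1, 100, 60) for c in ("a1", "a2", "b1", "b2")},
            index=[f"f{i}" for i in range(60)],
        ),
        conditions=pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
    )
    sets = {
        f"set{k}": [f"f{i}" for i in np.random.default_rng(seed + k).choice(60, 8, replace=False)]
        for k in range(8)
    }
    many = gsea(big, sets, "A", "B", n_perm=200, seed=seed)
    ordered = many.reindex(many["nes"].abs().sort_values(ascending=False).index)
    monotone = bool((np.diff(ordered["fdr_q"]) >= -1e-12).all())
    return {
        "es_abs_error_vs_bruteforce": es_error,
        "singleton_top_es": float(singleton_es),
        "fdr_monotone_in_abs_nes": monotone,
    }


def proteomics_checks(seed: int = 1, n_spectra: int = 3000) -> dict:
    """Peptide FDR threshold vs exhaustive sweep, protein-level decoy rate
    after parsimony, and balanced-count conservation."""
    psms, _ = syn.simulate_psm_table(
        40, shared_fraction=0.2, n_spectra=n_spectra, decoy_ratio=1.0, seed=seed
    )
    filtered, report = prot.peptide_fdr_filter(psms, 0.01)
    achieved_fdr = float(report["fdr"].max())

    best = psms.sort_values("score", ascending=False).drop_duplicates(["run", "peptide"])
    order = best.sort_values("score", ascending=False)
    thr_oracle = None
    scores = order["score"].to_numpy()
    decoy = order["is_decoy"].to_numpy(bool)
    for i in range(len(order)):
        d = int(decoy[: i + 1].sum())
        t = int((~decoy[: i + 1]).sum())
        if t > 0 and d / t <= 0.01:
            thr_oracle = scores[i]
    threshold_matches = bool(np.isclose(report["threshold"].iloc[0], thr_oracle))

    protein_fdr = prot.protein_level_fdr(filtered)
    targets = filtered[~filtered["is_decoy"]]
    groups = prot.infer_protein_groups(targets)
    counts, tally = prot.balanced_counts(groups, targets)
    conservation_error = abs(
        counts.to_numpy().sum() - (tally["n_spectra"] - tally["n_dropped"])
    )
    return {
        "peptide_fdr": achieved_fdr,
        "threshold_matches_sweep": threshold_matches,
        "protein_decoy_rate": float(protein_fdr),
        "balanced_count_conservation_error": float(conservation_error),
    }


def normalization_clustering(seed: int = 1) -> dict:
    """Library-size normalization exactness and recovery of a planted
    two-group sample structure by uncentered-Pearson UPGMA."""
    matrix, _ = syn.simulate_count_matrix(300, (3, 3), 0.0, 2.0, 0.1, seed=seed)
    norm = normalize_community(matrix)
    colsum_error = float((norm.values.sum(axis=0) - 1e6).abs().max())

    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(10, 100, 50), rng.uniform(10, 100, 50)
    cols = {}
    for i in range(3):
        cols[f"g1_{i}"] = p1 * rng.uniform(0.9, 1.1, 50)
        cols[f"g2_{i}"] = p2 * rng.uniform(0.9, 1.1, 50)
    planted = CountMatrix(
        values=pd.DataFrame(cols), conditions=pd.Series({c: "x" for c in cols})
    )
    res = hcluster(planted)
    import scipy.cluster.hierarchy as sch

    two = sch.fcluster(res.linkage, 2, criterion="maxclust")
    samples = sorted(planted.values.columns)
    parts = {}
    for c, k in zip(samples, two):
        parts.setdefault(k, set()).add(c.split("_")[0])
    bipartition_ok = sorted(map(sorted, parts.values())) == [["g1"], ["g2"]]

    # naive agglomeration oracle on the same distance matrix
    active = [frozenset([s]) for s in samples]
    coph_oracle: dict[frozenset, float] = {}
    while len(active) > 1:
        best = None
        for c1, c2 in itertools.combinations(sorted(active, key=sorted), 2):
            d = float(np.mean([res.distance.loc[x, y] for x in c1 for y in c2]))
            if best is None or d < best[0] - 1e-15:
                best = (d, c1, c2)
        h, c1, c2 = best
        for x in c1:
            for y in c2:
                coph_oracle[frozenset([x, y])] = h
        active.remove(c1)
        active.remove(c2)
        active.append(c1 | c2)
    import scipy.cluster.hierarchy as sch2
    from scipy.spatial.distance import squareform

    impl = squareform(sch2.cophenet(res.linkage))
    idx = {s: i for i, s in enumerate(samples)}
    oracle_error = max(
        abs(impl[idx[min(p)], idx[max(p)]] - h) for p, h in coph_oracle.items()
    )
    return {
        "max_colsum_error": colsum_error,
        "bipartition_recovered": bool(bipartition_ok),
        "upgma_vs_naive_oracle_error": float(oracle_error),
    }


def completeness_checks(seed: int = 1) -> dict:
    """Single-copy-family accounting and MCL planted-partition recovery."""
    table, full_map = syn.simulate_family_table(seed=seed)
    single = fam.single_copy_families(table, table.genomes)
    full = fam.completeness(single, full_map)

    table2, partial_map = syn.simulate_family_table(
        target_missing_fraction=0.10, seed=seed
    )
    single2 = fam.single_copy_families(table2, table2.genomes)
    partial = fam.completeness(single2, partial_map)

    rng = np.random.default_rng(seed)
    sizes = [10, 10, 10]
    labels = np.repeat(np.arange(3), sizes)
    edges = []
    for i, j in itertools.combinations(range(30), 2):
        p = 0.9 if labels[i] == labels[j] else 0.02
        if rng.random() < p:
            edges.append((f"n{i}", f"n{j}", 1.0))
    clusters = fam.mcl_cluster(edges, inflation=2.0)
    blocks_ok = len(clusters) == 3 and all(
        len({int(labels[int(n[1:])]) for n in c}) == 1 for c in clusters
    )
    return {
        "full_fraction_represented": full.fraction_represented,
        "full_fraction_single_copy": full.fraction_single_copy,
        "partial_fraction_represented": partial.fraction_represented,
        "mcl_recovers_planted_blocks": bool(blocks_ok),
    }


def pipeline_determinism(seed: int = 1, preset: str = "demo", workdir=None) -> dict:
    """Checksum equality of two identically configured pipeline runs."""
    import tempfile
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig.from_dict({"simulate": {"preset": preset}, "seed": seed})
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="esomics_det_"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = run_pipeline(cfg, base / "run1")
        m2 = run_pipeline(cfg, base / "run2")
    return {
        "manifests_identical": m1["stages"] == m2["stages"],
        "n_stages": len(m1["stages"]),
    }
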
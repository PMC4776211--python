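"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator emulates one class of study input so every downstream stage
is testable without any external download:

* genome models — order-3 Markov chains over nucleotides, so that
  tetranucleotide composition is exactly the signal the binner must
  recover; one model is flagged as the dominant "fungal" target;
* contigs — Markov-generated sequences, optionally chimeric (two genomes
  joined at one recorded junction);
* read-pair placements — proper-pair fragments sampled only within
  single-genome segments, so chimera junctions have zero spanning support;
* two-condition count matrices — negative-binomial counts with planted
  fold-change structure and lognormal library-size variation;
* peptide-spectrum tables — target/decoy evidence with shared peptides.

All generators are byte-deterministic for a fixed seed and emit 0-based
half-open coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = "ACGT"

#: placements table columns (the documented TSV dialect): one row per read,
#: mates share a fragment id and are suffixed /1 and /2; frag_start/frag_end
#: give the 0-based half-open fragment (outer) interval on the contig.
PLACEMENT_COLUMNS = ["read_id", "contig_id", "frag_start", "frag_end", "proper_pair"]

#: PSM table columns; ``proteins`` is a semicolon-joined matched-protein list.
PSM_COLUMNS = ["spectrum_id", "run", "peptide", "score", "is_decoy", "proteins"]


@dataclass
class GenomeModel:
    """Order-3 Markov nucleotide model for one synthetic genome."""

    genome_id: str
    transition_weights: np.ndarray  # (64, 4); each row sums to 1
    is_target: bool = False
    order: int = 3

    def __post_init__(self):
        w = np.asarray(self.transition_weights, dtype=float)
        if w.shape != (64, 4):
            raise ValueError("transition_weights must have shape (64, 4)")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each conditional distribution must sum to 1")
        self.transition_weights = w


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data.

    contig_genome maps every contig to the genome its first (or only)
    segment came from; junctions maps each chimeric contig to its 0-based
    junction offset and the second genome; de_features lists planted
    differentially expressed features; peptide_proteins maps peptides to
    their true source proteins.
    """

    contig_genome: dict[str, str] = field(default_factory=dict)
    junctions: dict[str, int] = field(default_factory=dict)
    junction_partner: dict[str, str] = field(default_factory=dict)
    de_features: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptide_proteins: dict[str, list[str]] = field(default_factory=dict)


def simulate_community(
    n_genomes: int, divergence: float, seed: int | None = None
) -> list[GenomeModel]:
    """Draw ``n_genomes`` order-3 Markov models around a shared base table.

    ``divergence`` in [0, 1] linearly mixes a shared base transition table
    with an independent Dirichlet jitter per genome, so pairwise distance
    between tables grows with divergence and is exactly zero at 0. The
    first genome is flagged as the target.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(4, 5.0), size=64)
    models = []
    for g in range(n_genomes):
        jitter = rng.dirichlet(np.ones(4), size=64)
        table = (1.0 - divergence) * base + divergence * jitter
        models.append(
            GenomeModel(
                genome_id=f"genome_{g:02d}",
                transition_weights=table,
                is_target=(g == 0),
            )
        )
    return models


def _markov_sequence(table: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Sample a sequence of ``length`` bases from an order-3 chain."""
    cum = np.cumsum(table, axis=1)
    start = rng.integers(0, 4, size=3)
    out = list(start)
    ctx = int(start[0] * 16 + start[1] * 4 + start[2])
    u = rng.random(max(length - 3, 0))
    for i in range(length - 3):
        nxt = int(np.searchsorted(cum[ctx], u[i], side="right"))
        nxt = min(nxt, 3)
        out.append(nxt)
        ctx = (ctx * 4 + nxt) % 64
    return "".join(_BASES[b] for b in out[:length])


def _default_length_law(rng: np.random.Generator) -> int:
    # log-uniform 1-10 kbp: populates both the >3 kbp training class and
    # the 1-3 kbp projection class
    return int(np.exp(rng.uniform(np.log(1000), np.log(10000))))


def simulate_contigs(
    models: list[GenomeModel],
    n_per_genome: int,
    length_law=None,
    chimera_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate contigs per genome; a ``chimera_rate`` fraction are chimeric.

    A chimeric contig concatenates sequence from its own genome and one
    other genome at a single junction, recorded 0-based in the truth table.
    ``length_law`` is a callable ``rng -> length`` (lengths must be
    >= 500 bp); the default is log-uniform over 1-10 kbp.
    """
    if not models:
        raise ValueError("models must be non-empty")
    if not 0.0 <= chimera_rate < 1.0:
        raise ValueError("chimera_rate must lie in [0, 1)")
    law = length_law or _default_length_law
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    truth = SyntheticTruth()
    for gi, model in enumerate(models):
        for ci in range(n_per_genome):
            cid = f"{model.genome_id}_c{ci:04d}"
            length = int(law(rng))
            if length < 500:
                raise ValueError("length_law produced a contig below 500 bp")
            if len(models) > 1 and rng.random() < chimera_rate:
                partner_idx = int(rng.integers(0, len(models) - 1))
                if partner_idx >= gi:
                    partner_idx += 1
                partner = models[partner_idx]
                junction = int(rng.integers(int(0.3 * length), int(0.7 * length)))
                seq = _markov_sequence(model.transition_weights, junction, rng)
                seq += _markov_sequence(
                    partner.transition_weights, length - junction, rng
                )
                truth.junctions[cid] = junction
                truth.junction_partner[cid] = partner.genome_id
            else:
                seq = _markov_sequence(model.transition_weights, length, rng)
            contigs[cid] = seq
            truth.contig_genome[cid] = model.genome_id
    return contigs, truth


def simulate_read_pairs(
    contigs: dict[str, str],
    depth: float,
    insert_mean: float = 200.0,
    insert_sd: float = 20.0,
    read_len: int = 50,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample proper-pair fragment placements at the given fragment depth.

    Fragments are drawn only within single-genome segments of chimeric
    contigs, so recorded junctions have zero spanning fragments by
    construction. Returns the placements table (two rows per fragment, one
    per mate) with 0-based half-open fragment coordinates.
    """
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed 2 * read_len")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    junctions = truth.junctions if truth is not None else {}
    rows = []
    frag_no = 0
    min_span = insert_mean + 4 * insert_sd
    for cid, seq in contigs.items():
        length = len(seq)
        if cid in junctions:
            j = junctions[cid]
            segments = [(0, j), (j, length)]
        else:
            segments = [(0, length)]
        for s0, s1 in segments:
            seg_len = s1 - s0
            if seg_len < min_span:
                warnings.warn(
                    f"segment {cid}:{s0}-{s1} shorter than insert span; skipped",
                    stacklevel=2,
                )
                continue
            n_frags = int(round(depth * seg_len / insert_mean))
            if n_frags == 0:
                continue
            lens = rng.normal(insert_mean, insert_sd, size=n_frags)
            lens = np.clip(np.rint(lens), 2 * read_len, seg_len).astype(int)
            starts = rng.integers(0, seg_len - lens + 1) + s0
            for fs, fl in zip(starts, lens):
                frag = f"frag{frag_no:07d}"
                frag_no += 1
                for mate in (1, 2):
                    rows.append((f"{frag}/{mate}", cid, int(fs), int(fs + fl), 1))
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def simulate_count_matrix(
    n_features: int,
    n_per_condition: tuple[int, int] = (3, 2),
    de_fraction: float = 0.05,
    fold_change: float = 4.0,
    dispersion: float = 0.1,
    lib_sizes=None,
    seed: int | None = None,
    conditions: tuple[str, str] = ("streamer", "floating"),
):
    """Two-condition negative-binomial count matrix with planted DE features.

    ``de_fraction`` of features receive the planted fold change in the
    first condition — half up-regulated, half down-regulated. Library-size
    factors default to lognormal draws (sigma 0.4) around 1 so that the
    per-million normalization matters. Returns (CountMatrix, truth) where
    truth.de_features has columns feature_id, direction.
    """
    from .expression import CountMatrix

    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    nA, nB = n_per_condition
    n_samples = nA + nB
    rng = np.random.default_rng(seed)
    if lib_sizes is None:
        lib = rng.lognormal(mean=0.0, sigma=0.4, size=n_samples)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        if lib.shape != (n_samples,):
            raise ValueError("lib_sizes must have one entry per sample")
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_features)
    n_de = int(round(de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    n_up = n_de // 2 + n_de % 2
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]

    mu = np.tile(base[:, None], (1, n_samples))
    mu[up_idx, :nA] *= fold_change
    mu[down_idx, :nA] /= fold_change
    mu *= lib[None, :]

    if dispersion > 0:
        size = 1.0 / dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    feature_ids = [f"feat_{i:05d}" for i in range(n_features)]
    sample_ids = [f"{conditions[0]}_{i + 1}" for i in range(nA)] + [
        f"{conditions[1]}_{i + 1}" for i in range(nB)
    ]
    cond = pd.Series(
        [conditions[0]] * nA + [conditions[1]] * nB, index=sample_ids, name="condition"
    )
    values = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
    matrix = CountMatrix(values=values, conditions=cond, kind="transcript")

    direction = np.array([""] * n_features, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    truth = SyntheticTruth(
        de_features=pd.DataFrame(
            {
                "feature_id": np.array(feature_ids, dtype=object)[de_idx],
                "direction": direction[de_idx],
            }
        ).reset_index(drop=True)
    )
    return matrix, truth


def simulate_assembly_graph(
    truth: SyntheticTruth,
    intra_degree: float = 2.0,
    cross_edges: int = 0,
    seed: int | None = None,
):
    """Contig-adjacency graph with edges mostly within genomes.

    Each contig gets on average ``intra_degree`` edges to random contigs of
    the same genome (mimicking de Bruijn graph contiguity), plus
    ``cross_edges`` random between-genome edges as noise. Returns a
    networkx Graph over all contig ids.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    by_genome: dict[str, list[str]] = {}
    for cid, gid in truth.contig_genome.items():
        by_genome.setdefault(gid, []).append(cid)
    g = nx.Graph()
    g.add_nodes_from(truth.contig_genome)
    for gid, members in sorted(by_genome.items()):
        if len(members) < 2:
            continue
        n_edges = int(round(intra_degree * len(members) / 2))
        for _ in range(n_edges):
            a, b = rng.choice(members, size=2, replace=False)
            if a != b:
                g.add_edge(str(a), str(b))
    all_ids = sorted(truth.contig_genome)
    for _ in range(cross_edges):
        a, b = rng.choice(all_ids, size=2, replace=False)
        if truth.contig_genome[str(a)] != truth.contig_genome[str(b)]:
            g.add_edge(str(a), str(b))
    return g


def simulate_hit_table(
    truth: SyntheticTruth,
    target_genome: str,
    target_clade: str = "Fungi",
    other_taxa: tuple[str, ...] = ("Leptospirillum", "Sulfobacillus", "Archaea"),
    hit_rate: float = 0.6,
    e_lo: float = 1e-40,
    e_hi: float = 1e-11,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-contig best-BLAST-style protein hit table.

    A ``hit_rate`` fraction of contigs carry one protein hit: contigs of
    the target genome hit the target clade, others hit one of
    ``other_taxa``; e-values are log-uniform in [e_lo, e_hi].
    """
    from .refine import HIT_COLUMNS

    rng = np.random.default_rng(seed)
    rows = []
    for cid, gid in sorted(truth.contig_genome.items()):
        if rng.random() > hit_rate:
            continue
        taxon = (
            target_clade if gid == target_genome else str(rng.choice(list(other_taxa)))
        )
        e_val = float(np.exp(rng.uniform(np.log(e_lo), np.log(e_hi))))
        rows.append((cid, f"{cid}_p1", taxon, e_val, float(rng.uniform(50, 500))))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def simulate_gene_sets(
    feature_ids,
    truth: SyntheticTruth,
    n_sets: int = 10,
    set_size: int = 20,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Gene sets for enrichment testing: one set concentrated in planted
    up-regulated features, one in down-regulated, the rest random."""
    rng = np.random.default_rng(seed)
    features = list(feature_ids)
    sets: dict[str, list[str]] = {}
    de = truth.de_features
    if len(de):
        up = de.loc[de["direction"] == "up", "feature_id"].tolist()
        down = de.loc[de["direction"] == "down", "feature_id"].tolist()
        if len(up) >= 2:
            k = min(set_size, len(up))
            sets["planted_up"] = sorted(rng.choice(up, size=k, replace=False))
        if len(down) >= 2:
            k = min(set_size, len(down))
            sets["planted_down"] = sorted(rng.choice(down, size=k, replace=False))
    for i in range(n_sets - len(sets)):
        sets[f"random_{i:02d}"] = sorted(
            rng.choice(features, size=min(set_size, len(features)), replace=False)
        )
    return sets


def simulate_family_table(
    n_families: int = 200,
    n_reference_genomes: int = 10,
    single_copy_fraction: float = 0.5,
    target_missing_fraction: float = 0.0,
    target_duplicated_fraction: float = 0.0,
    seed: int | None = None,
):
    """Gene-family copy-number table plus a target-genome gene->family map.

    ``single_copy_fraction`` of families are single copy in every
    reference genome; the rest get at least one non-1 count. The target
    gene map covers every single-copy family except a
    ``target_missing_fraction`` share, and duplicates a
    ``target_duplicated_fraction`` share.
    """
    from .families import FamilyTable

    rng = np.random.default_rng(seed)
    genomes = [f"ref_{i:02d}" for i in range(n_reference_genomes)]
    fam_ids = [f"fam_{i:04d}" for i in range(n_families)]
    n_single = int(round(single_copy_fraction * n_families))
    counts = np.ones((n_families, n_reference_genomes), dtype=int)
    for i in range(n_single, n_families):
        j = int(rng.integers(n_reference_genomes))
        counts[i, j] = int(rng.choice([0, 2, 3]))
    table = FamilyTable(pd.DataFrame(counts, index=fam_ids, columns=genomes))

    single_ids = fam_ids[:n_single]
    n_missing = int(round(target_missing_fraction * n_single))
    n_dup = int(round(target_duplicated_fraction * n_single))
    drop = set(rng.choice(single_ids, size=n_missing, replace=False)) if n_missing else set()
    remaining = [f for f in single_ids if f not in drop]
    dup = set(rng.choice(remaining, size=min(n_dup, len(remaining)), replace=False)) if n_dup else set()
    gene_map: dict[str, str] = {}
    g = 0
    for fam in remaining:
        gene_map[f"gene_{g:05d}"] = fam
        g += 1
        if fam in dup:
            gene_map[f"gene_{g:05d}"] = fam
            g += 1
    return table, gene_map


def simulate_psm_table(
    n_proteins: int,
    peptides_per_protein: int = 5,
    shared_fraction: float = 0.1,
    n_spectra: int = 1000,
    decoy_ratio: float = 1.0,
    seed: int | None = None,
    n_runs: int = 1,
    score_separation: float = 3.0,
    decoy_spectrum_fraction: float = 0.2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Target/decoy peptide-spectrum match table with shared peptides.

    Target spectra score Normal(10 + score_separation, 1), decoy spectra
    Normal(10, 1), so targets stochastically dominate. ``shared_fraction``
    of target peptides also map to a second protein. Decoy proteins number
    ``decoy_ratio * n_proteins`` (concatenated-database convention).
    """
    if decoy_ratio <= 0:
        raise ValueError("decoy_ratio must be positive")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    peptide_map: dict[str, list[str]] = {}
    k = 0
    for p in proteins:
        for _ in range(peptides_per_protein):
            peptide_map[f"pep{k:05d}"] = [p]
            k += 1
    target_peptides = list(peptide_map)
    n_shared = int(round(shared_fraction * len(target_peptides)))
    if n_shared and n_proteins >= 2:
        for pep in rng.choice(target_peptides, size=n_shared, replace=False):
            owner = peptide_map[pep][0]
            others = [p for p in proteins if p != owner]
            peptide_map[pep].append(str(rng.choice(others)))

    n_decoy_prot = max(1, int(round(decoy_ratio * n_proteins)))
    decoy_map: dict[str, list[str]] = {}
    for d in range(n_decoy_prot):
        for _ in range(peptides_per_protein):
            decoy_map[f"dpep{len(decoy_map):05d}"] = [f"DECOY_P{d:04d}"]
    decoy_peptides = list(decoy_map)

    rows = []
    for run in range(n_runs):
        run_id = f"run_{run + 1}"
        for s in range(n_spectra):
            sid = f"{run_id}_sp{s:06d}"
            if rng.random() < decoy_spectrum_fraction:
                pep = str(rng.choice(decoy_peptides))
                score = rng.normal(10.0, 1.0)
                rows.append((sid, run_id, pep, score, True, ";".join(decoy_map[pep])))
            else:
                pep = str(rng.choice(target_peptides))
                score = rng.normal(10.0 + score_separation, 1.0)
                rows.append((sid, run_id, pep, score, False, ";".join(peptide_map[pep])))
    psms = pd.DataFrame(rows, columns=PSM_COLUMNS)
    truth = SyntheticTruth(peptide_proteins={**peptide_map, **decoy_map})
    return psms, truth
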
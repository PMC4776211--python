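"""Bin refinement: contig-set union, read recruitment, misassembly splitting.

A composition bin is expanded into a candidate set by combining (1) the
bin itself, (2) assembly-graph neighbors within a small edge radius, and
(3) contigs whose best protein hit falls in the target clade. Reads
mapping to candidates (plus mates) are recruited for reassembly, known
contaminants are screened out by best-hit taxonomy, and chimeric contigs
are split where no proper-pair fragment spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

HIT_COLUMNS = ["contig_id", "query_protein_id", "subject_taxon", "e_value", "bit_score"]


def graph_neighbors(
    graph: nx.Graph, seed_contigs, max_edges: int = 2
) -> set[str]:
    """Contigs within ``max_edges`` assembly-graph edges of the seed set.

    BFS ball of the given radius, including the seeds themselves. Seeds
    absent from the graph are collected in a warning (they still appear in
    the result — absence from the graph is not evidence against them).
    """
    if max_edges < 0:
        raise ValueError("max_edges must be >= 0")
    seeds = set(seed_contigs)
    missing = seeds - set(graph.nodes)
    if missing:
        warnings.warn(
            f"{len(missing)} seed contig(s) absent from assembly graph", stacklevel=2
        )
    out = set(seeds)
    for s in seeds & set(graph.nodes):
        out.update(nx.single_source_shortest_path_length(graph, s, cutoff=max_edges))
    return out


def _best_hits_per_protein(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per (contig, protein): lowest e-value, then highest bit score."""
    ordered = hits.sort_values(
        ["e_value", "bit_score"], ascending=[True, False], kind="mergesort"
    )
    return ordered.drop_duplicates(["contig_id", "query_protein_id"], keep="first")


def taxon_set(
    hits: pd.DataFrame, e_max: float = 1e-10, target_clade: str = "Fungi"
) -> set[str]:
    """Contigs with >= 1 protein whose best hit is in the target clade at e <= e_max."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if hits.empty:
        return set()
    best = _best_hits_per_protein(hits)
    sel = (best["subject_taxon"] == target_clade) & (best["e_value"] <= e_max)
    return set(best.loc[sel, "contig_id"])


def candidate_union(set1, set2, set3) -> pd.DataFrame:
    """Union of the three candidate sources with per-contig provenance flags.

    Columns: contig_id, in_esom_bin, graph_neighbor, taxonomic_hit.
    """
    s1, s2, s3 = set(set1), set(set2), set(set3)
    ids = sorted(s1 | s2 | s3)
    return pd.DataFrame(
        {
            "contig_id": ids,
            "in_esom_bin": [c in s1 for c in ids],
            "graph_neighbor": [c in s2 for c in ids],
            "taxonomic_hit": [c in s3 for c in ids],
        }
    )


def _mate_id(read_id: str) -> str:
    if read_id.endswith("/1"):
        return read_id[:-2] + "/2"
    if read_id.endswith("/2"):
        return read_id[:-2] + "/1"
    return read_id


def recruit_reads(placements: pd.DataFrame, candidate_contigs) -> set[str]:
    """Every read mapping to a candidate contig, plus its mate.

    Mates are recruited regardless of where (or whether) they map. Mate
    identity follows the ``/1``/``/2`` read-id suffix convention. Result is
    a set (no duplicates).
    """
    candidates = set(candidate_contigs)
    known = set(placements["contig_id"].unique())
    unknown = candidates - known
    if unknown and not placements.empty:
        warnings.warn(
            f"{len(unknown)} candidate contig(s) have no placements", stacklevel=2
        )
    hit = placements.loc[placements["contig_id"].isin(candidates), "read_id"]
    recruited: set[str] = set()
    for rid in hit:
        recruited.add(rid)
        recruited.add(_mate_id(rid))
    return recruited


@dataclass
class FragmentSupport:
    """Proper-pair fragment intervals (0-based half-open) on one contig."""

    contig_id: str
    length: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for a, b in self.intervals:
            if not (0 <= a <= b <= self.length):
                raise ValueError(f"interval ({a}, {b}) outside [0, {self.length}]")

    def coverage(self) -> np.ndarray:
        """Per-position spanning-fragment coverage via interval union."""
        diff = np.zeros(self.length + 1, dtype=np.int64)
        for a, b in self.intervals:
            diff[a] += 1
            diff[b] -= 1
        return np.cumsum(diff[:-1])


def fragment_support(
    placements: pd.DataFrame, contig_lengths: dict[str, int]
) -> dict[str, FragmentSupport]:
    """Build per-contig FragmentSupport from a placements table.

    Only proper pairs contribute; mates of one fragment share an interval,
    which is counted once.
    """
    proper = placements[placements["proper_pair"].astype(bool)]
    supports = {
        cid: FragmentSupport(cid, length) for cid, length in contig_lengths.items()
    }
    seen: set[tuple[str, int, int, str]] = set()
    for row in proper.itertuples(index=False):
        cid = row.contig_id
        if cid not in supports:
            warnings.warn(f"placement on unknown contig {cid}", stacklevel=2)
            continue
        frag = row.read_id[:-2] if row.read_id[-2:] in ("/1", "/2") else row.read_id
        key = (cid, int(row.frag_start), int(row.frag_end), frag)
        if key in seen:
            continue
        seen.add(key)
        supports[cid].intervals.append((int(row.frag_start), int(row.frag_end)))
    return supports


@dataclass
class SplitRecord:
    """One output piece of a (possibly split) contig."""

    contig_id: str
    piece_id: str
    start: int
    end: int
    cut_sites: list[int]


def split_misassemblies(
    supports: dict[str, FragmentSupport],
    margin: int,
    min_piece: int = 500,
) -> list[SplitRecord]:
    """Split contigs at interior regions with zero spanning-fragment coverage.

    Maximal zero-coverage runs lying strictly inside ``[margin,
    length - margin]`` are treated as misassembly evidence; the contig is
    cut at each run's midpoint. Pieces shorter than ``min_piece`` are
    discarded. Contigs with no interior zero run pass through unchanged.
    Contig ends cannot be spanned by fragments, hence the margin, which
    should be about insert_mean + 3 * insert_sd.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    out: list[SplitRecord] = []
    for cid in sorted(supports):
        sup = supports[cid]
        L = sup.length
        if margin >= L / 2:
            warnings.warn(f"margin {margin} >= half of contig {cid}; skipped", stacklevel=2)
            out.append(SplitRecord(cid, cid, 0, L, []))
            continue
        cov = sup.coverage()
        zero = cov == 0
        # maximal zero runs strictly inside [margin, L - margin]
        cuts: list[int] = []
        boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)))
        run_starts = [0] if zero[0] else []
        run_starts += [int(b) + 1 for b in boundaries if not zero[b]]
        for rs in run_starts:
            re_ = rs
            while re_ < L and zero[re_]:
                re_ += 1
            if rs >= margin and re_ <= L - margin:
                cuts.append((rs + re_) // 2)
        if not cuts:
            out.append(SplitRecord(cid, cid, 0, L, []))
            continue
        edges = [0] + cuts + [L]
        kept = 0
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < min_piece:
                continue
            out.append(SplitRecord(cid, f"{cid}_s{kept}", a, b, cuts))
            kept += 1
    return out


def apply_splits(
    records: list[SplitRecord], contigs: dict[str, str]
) -> dict[str, str]:
    """Materialize split pieces as sequences."""
    return {r.piece_id: contigs[r.contig_id][r.start : r.end] for r in records}


def screen_contaminants(
    candidates, hits: pd.DataFrame, contaminant_taxa
) -> tuple[set[str], pd.DataFrame]:
    """Drop candidates whose best contig-level hit is a contaminant taxon.

    The best hit per contig is the row with the lowest e-value (ties by
    highest bit score). Returns (kept set, removal report) where the report
    has columns contig_id, subject_taxon, e_value.
    """
    contaminants = set(contaminant_taxa)
    if not contaminants:
        raise ValueError("contaminant_taxa must be non-empty")
    candidates = set(candidates)
    removed_rows = []
    if not hits.empty:
        best = hits.sort_values(
            ["e_value", "bit_score"], ascending=[True, False], kind="mergesort"
        ).drop_duplicates("contig_id", keep="first")
        for row in best.itertuples(index=False):
            if row.contig_id in candidates and row.subject_taxon in contaminants:
                removed_rows.append((row.contig_id, row.subject_taxon, row.e_value))
    report = pd.DataFrame(removed_rows, columns=["contig_id", "subject_taxon", "e_value"])
    kept = candidates - set(report["contig_id"])
    return kept, report
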
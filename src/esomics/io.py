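"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; assembly graphs are accepted as GFA (S/L
lines) or a two-column edge-list TSV; everything tabular is plain TSV with
a fixed, documented column order so outputs are byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import PLACEMENT_COLUMNS, PSM_COLUMNS
from .expression import CountMatrix


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_assembly_graph(path) -> nx.Graph:
    """Assembly graph from GFA 1 (S and L lines) or an edge-list TSV.

    Orientation is dropped: edges mean contig adjacency. Self-loops are
    ignored.
    """
    path = Path(path)
    g = nx.Graph()
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith(("H\t", "S\t", "L\t")):
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "S":
                    g.add_node(parts[1])
                elif parts[0] == "L":
                    a, b = parts[1], parts[3]
                    if a != b:
                        g.add_edge(a, b)
        else:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                a, b = line.split("\t")[:2]
                a, b = a.strip(), b.strip()
                g.add_node(a)
                g.add_node(b)
                if a != b:
                    g.add_edge(a, b)
    return g


def write_gfa(graph: nx.Graph, path, lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for node in sorted(graph.nodes):
            ln = (lengths or {}).get(node)
            seq = "*" if ln is None else "*"
            tag = f"\tLN:i:{ln}" if ln is not None else ""
            fh.write(f"S\t{node}\t{seq}{tag}\n")
        for a, b in sorted(map(lambda e: tuple(sorted(e)), graph.edges)):
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\n")


def read_placements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig_id": str})
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placements table missing columns: {sorted(missing)}")
    return df[PLACEMENT_COLUMNS]


def write_placements(df: pd.DataFrame, path) -> None:
    df[PLACEMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sam_placements(path) -> pd.DataFrame:
    """Placements from a SAM file of paired-end alignments (via pysam).

    Only primary, mapped, proper-pair reads contribute; the fragment
    interval is taken from the leftmost mate's position and the template
    length.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mate = "/1" if aln.is_read1 else "/2"
            proper = int(aln.is_proper_pair)
            tlen = aln.template_length
            if tlen > 0:
                frag_start, frag_end = aln.reference_start, aln.reference_start + tlen
            elif tlen < 0 and aln.next_reference_start >= 0:
                frag_start, frag_end = aln.next_reference_start, aln.next_reference_start - tlen
            else:
                frag_start, frag_end = aln.reference_start, aln.reference_end
            rows.append(
                (aln.query_name + mate, aln.reference_name, frag_start, frag_end, proper)
            )
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def read_hits(path) -> pd.DataFrame:
    from .refine import HIT_COLUMNS

    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df[HIT_COLUMNS]


def read_psms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df[PSM_COLUMNS]


def write_psms(df: pd.DataFrame, path) -> None:
    df[PSM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets in GMT format: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_count_matrix(values_path, samples_path, features_path=None, kind="transcript") -> CountMatrix:
    """Count matrix TSV (features x samples) plus sidecar annotation TSVs.

    ``samples_path``: columns sample_id, condition. ``features_path``
    (optional): columns feature_id, organism[, group].
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    organisms = groups = None
    if features_path is not None:
        feats = pd.read_csv(features_path, sep="\t", index_col="feature_id")
        if "organism" in feats:
            organisms = feats["organism"]
        if "group" in feats:
            groups = feats["group"]
    return CountMatrix(
        values=values,
        conditions=samples["condition"],
        organisms=organisms,
        groups=groups,
        kind=kind,
    )


def write_count_matrix(matrix: CountMatrix, values_path, samples_path=None) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="feature_id")
    if samples_path is not None:
        matrix.conditions.rename("condition").to_frame().to_csv(
            samples_path, sep="\t", index_label="sample_id"
        )


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
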
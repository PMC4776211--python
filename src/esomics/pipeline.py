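"""End-to-end pipeline orchestration with strict config and manifests.

Stages run in dependency order (simulate -> bin -> refine -> completeness
-> proteo -> express) on files in a run directory. Every random operation
receives an explicit seed derived from the config seed; re-running with an
identical config reproduces byte-identical outputs, which the manifest
(sha256 per artifact) makes checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    families as comp,
    esom as esom_mod,
    expression as expr,
    io as eio,
    proteomics as prot,
    refine as ref,
    synthetic as syn,
    composition as tnf_mod,
)

log = logging.getLogger("esomics")

STAGES = ["simulate", "bin", "refine", "completeness", "proteo", "express"]

#: full config schema: section -> {key: default}. Unknown keys are rejected.
SCHEMA: dict[str, dict] = {
    "seed": 1,
    "out_dir": "run",
    "stages": {s: True for s in STAGES},
    "simulate": {
        "preset": "demo",
        "n_genomes": 3,
        "divergence": 0.8,
        "n_per_genome": 300,
        "chimera_rate": 0.1,
        "depth": 20.0,
        "insert_mean": 200.0,
        "insert_sd": 20.0,
        "read_len": 50,
        "n_features": 2000,
        "n_per_condition": [3, 2],
        "de_fraction": 0.05,
        "fold_change": 4.0,
        "dispersion": 0.1,
        "n_proteins": 50,
        "n_spectra": 2000,
        "decoy_ratio": 1.0,
    },
    "bin": {
        "min_train_len": 3000,
        "project_min_len": 1000,
        "rows": 50,
        "cols": 82,
        "epochs": 20,
        "lr_start": 0.5,
        "lr_end": 0.1,
        "radius_end": 1.0,
        "umatrix_percentile": 30.0,
        "mask": None,
    },
    "refine": {
        "max_edges": 2,
        "e_max": 1e-10,
        "target_clade": "Fungi",
        "contaminants": ["Leptospirillum", "Sulfobacillus", "Archaea"],
        "min_piece": 500,
    },
    "completeness": {"inflation": 2.0},
    "proteo": {"fdr": 0.01, "split_policy": "proportional"},
    "express": {
        "condition_a": "streamer",
        "condition_b": "floating",
        "n_perm": 200,
        "fc_threshold": 2.0,
        "p_threshold": 0.01,
        "gsea_n_perm": 200,
        "gsea_fdr": 0.05,
    },
}

PRESETS = {
    "tiny": {
        "n_per_genome": 20,
        "n_features": 200,
        "n_proteins": 10,
        "n_spectra": 300,
        "depth": 10.0,
    },
    "demo": {},
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, given: dict) -> "PipelineConfig":
        merged = {}
        unknown = set(given) - set(SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key, default in SCHEMA.items():
            value = given.get(key, default)
            if isinstance(default, dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                bad = set(value) - set(default)
                if bad:
                    raise ConfigError(f"unknown key(s) in {key!r}: {sorted(bad)}")
                value = {**default, **value}
            merged[key] = value
        cfg = cls(merged)
        preset = cfg.data["simulate"]["preset"]
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}")
        overrides = {
            k: v for k, v in PRESETS[preset].items()
            if k not in given.get("simulate", {})
        }
        cfg.data["simulate"].update(overrides)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.data[key]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_fixtures(preset: str = "tiny", seed: int = 1, out_dir=None) -> dict:
    """Generate a complete in-memory synthetic dataset (optionally written).

    ``tiny`` is sized for unit tests (<= 60 contigs, <= 200 features);
    ``demo`` reproduces the full study-scale conditions.
    """
    if preset not in PRESETS:
        raise ConfigError(f"preset must be one of {sorted(PRESETS)}")
    cfg = PipelineConfig.from_dict({"simulate": {"preset": preset}, "seed": seed})
    sim = cfg["simulate"]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    models = syn.simulate_community(sim["n_genomes"], sim["divergence"], int(seeds[0]))
    contigs, truth = syn.simulate_contigs(
        models, sim["n_per_genome"], chimera_rate=sim["chimera_rate"], seed=int(seeds[1])
    )
    placements = syn.simulate_read_pairs(
        contigs,
        depth=sim["depth"],
        insert_mean=sim["insert_mean"],
        insert_sd=sim["insert_sd"],
        read_len=sim["read_len"],
        truth=truth,
        seed=int(seeds[2]),
    )
    graph = syn.simulate_assembly_graph(truth, seed=int(seeds[3]))
    target = next(m.genome_id for m in models if m.is_target)
    hits = syn.simulate_hit_table(truth, target, seed=int(seeds[4]))
    counts, de_truth = syn.simulate_count_matrix(
        sim["n_features"],
        tuple(sim["n_per_condition"]),
        sim["de_fraction"],
        sim["fold_change"],
        sim["dispersion"],
        seed=int(seeds[5]),
    )
    gene_sets = syn.simulate_gene_sets(counts.features, de_truth, seed=int(seeds[6]))
    psms, psm_truth = syn.simulate_psm_table(
        sim["n_proteins"],
        n_spectra=sim["n_spectra"],
        decoy_ratio=sim["decoy_ratio"],
        seed=int(seeds[7]),
    )
    family_table, gene_map = syn.simulate_family_table(seed=seed)

    fixtures = {
        "models": models,
        "contigs": contigs,
        "truth": truth,
        "placements": placements,
        "graph": graph,
        "hits": hits,
        "target_genome": target,
        "counts": counts,
        "de_truth": de_truth,
        "gene_sets": gene_sets,
        "psms": psms,
        "psm_truth": psm_truth,
        "family_table": family_table,
        "target_gene_families": gene_map,
        "insert_mean": sim["insert_mean"],
        "insert_sd": sim["insert_sd"],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_fasta(contigs, out / "contigs.fasta")
        eio.write_placements(placements, out / "placements.tsv")
        eio.write_gfa(graph, out / "assembly.gfa")
        eio.write_tsv(hits, out / "hits.tsv")
        eio.write_count_matrix(counts, out / "counts.tsv", out / "samples.tsv")
        eio.write_gmt(gene_sets, out / "gene_sets.gmt")
        eio.write_psms(psms, out / "psms.tsv")
        family_table.counts.to_csv(out / "family_table.tsv", sep="\t", index_label="family_id")
        pd.Series(gene_map, name="family_id").to_csv(
            out / "target_gene_families.tsv", sep="\t", index_label="gene_id"
        )
        truth_df = pd.DataFrame(
            {
                "contig_id": sorted(truth.contig_genome),
                "genome_id": [truth.contig_genome[c] for c in sorted(truth.contig_genome)],
                "junction": [truth.junctions.get(c, -1) for c in sorted(truth.contig_genome)],
            }
        )
        eio.write_tsv(truth_df, out / "truth_contigs.tsv")
        eio.write_tsv(de_truth.de_features, out / "truth_de.tsv")
    return fixtures


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the enabled stages; returns the manifest dict.

    The manifest lists, per stage, every artifact with its sha256 and the
    config digest, so two runs with an identical config can be compared
    checksum-for-checksum.
    """
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {"config_digest": config.digest(), "stages": {}}
    stages = config["stages"]
    seed = int(config["seed"])
    artifacts: dict[str, list[Path]] = {}
    try:
        fixtures = None
        if stages.get("simulate"):
            log.info("stage simulate")
            fixtures = make_fixtures(config["simulate"]["preset"], seed, out_dir=out / "simulate")
            # apply any explicit simulate overrides by regenerating via config
            artifacts["simulate"] = sorted((out / "simulate").glob("*"))
        if stages.get("bin"):
            log.info("stage bin")
            if fixtures is None:
                raise ConfigError("bin stage requires simulate outputs (stage simulate)")
            bdir = out / "bin"
            bdir.mkdir(exist_ok=True)
            bc = config["bin"]
            contigs = fixtures["contigs"]
            train = tnf_mod.tnf(contigs, min_len=bc["min_train_len"])
            short = {
                c: s for c, s in contigs.items()
                if bc["project_min_len"] <= len(s) < bc["min_train_len"]
            }
            project = tnf_mod.tnf(short, min_len=bc["project_min_len"]) if short else None
            som = esom_mod.TetranucleotideESOM(
                rows=bc["rows"],
                cols=bc["cols"],
                epochs=bc["epochs"],
                lr_start=bc["lr_start"],
                lr_end=bc["lr_end"],
                radius_end=bc["radius_end"],
                random_state=seed,
            ).fit(train)
            assignments = esom_mod.assign_bmus(som, train, project)
            bins = esom_mod.select_bins(som, assignments, bc["umatrix_percentile"])
            eio.write_tsv(bins.table, bdir / "bins.tsv")
            pd.DataFrame(som.codebook_).to_csv(bdir / "codebook.tsv", sep="\t", index=False)
            pd.DataFrame(som.umatrix()).to_csv(bdir / "umatrix.tsv", sep="\t", index=False)
            fixtures["bins"] = bins
            fixtures["esom"] = som
            artifacts["bin"] = sorted(bdir.glob("*"))
        if stages.get("refine"):
            log.info("stage refine")
            if fixtures is None or "bins" not in fixtures:
                raise ConfigError("refine stage requires bin outputs (stage bin)")
            rdir = out / "refine"
            rdir.mkdir(exist_ok=True)
            rc = config["refine"]
            bins = fixtures["bins"]
            truth = fixtures["truth"]
            target = fixtures["target_genome"]
            # the bin with the most target-genome contigs plays the "large
            # obvious fungal bin" selected for refinement
            best_bin, best_n = None, -1
            for label in bins.bins:
                members = bins.contigs_in_bin(label)
                n_target = sum(truth.contig_genome[c] == target for c in members)
                if n_target > best_n:
                    best_bin, best_n = label, n_target
            set1 = set(bins.contigs_in_bin(best_bin)) if best_bin else set()
            set2 = ref.graph_neighbors(fixtures["graph"], set1, rc["max_edges"])
            set3 = ref.taxon_set(fixtures["hits"], rc["e_max"], rc["target_clade"])
            candidates = ref.candidate_union(set1, set2, set3)
            kept, removal = ref.screen_contaminants(
                candidates["contig_id"], fixtures["hits"], rc["contaminants"]
            )
            recruited = ref.recruit_reads(fixtures["placements"], kept)
            lengths = {c: len(s) for c, s in fixtures["contigs"].items()}
            supports = ref.fragment_support(fixtures["placements"], lengths)
            margin = int(fixtures["insert_mean"] + 3 * fixtures["insert_sd"])
            splits = ref.split_misassemblies(supports, margin, rc["min_piece"])
            eio.write_tsv(candidates, rdir / "candidates.tsv")
            eio.write_tsv(removal, rdir / "removals.tsv")
            (rdir / "recruited_reads.txt").write_text("\n".join(sorted(recruited)) + "\n")
            pieces = ref.apply_splits(splits, fixtures["contigs"])
            eio.write_fasta(pieces, rdir / "split_contigs.fasta")
            bed = pd.DataFrame(
                sorted({(r.contig_id, c) for r in splits for c in r.cut_sites}),
                columns=["contig_id", "cut"],
            )
            bed["start"], bed["end"] = bed["cut"], bed["cut"] + 1
            eio.write_tsv(bed[["contig_id", "start", "end"]], rdir / "cut_sites.bed")
            fixtures["kept"] = kept
            artifacts["refine"] = sorted(rdir.glob("*"))
        if stages.get("completeness"):
            log.info("stage completeness")
            if fixtures is None:
                raise ConfigError("completeness stage requires simulate outputs")
            cdir = out / "completeness"
            cdir.mkdir(exist_ok=True)
            table = fixtures["family_table"]
            single = comp.single_copy_families(table, table.genomes)
            report = comp.completeness(single, fixtures["target_gene_families"])
            (cdir / "completeness.json").write_text(
                json.dumps(
                    {
                        "n_families_considered": report.n_families_considered,
                        "fraction_represented": report.fraction_represented,
                        "fraction_single_copy": report.fraction_single_copy,
                    },
                    indent=2,
                )
                + "\n"
            )
            artifacts["completeness"] = sorted(cdir.glob("*"))
        if stages.get("proteo"):
            log.info("stage proteo")
            if fixtures is None:
                raise ConfigError("proteo stage requires simulate outputs")
            pdir = out / "proteo"
            pdir.mkdir(exist_ok=True)
            pc = config["proteo"]
            filtered, fdr_report = prot.peptide_fdr_filter(fixtures["psms"], pc["fdr"])
            groups = prot.infer_protein_groups(filtered)
            counts, bal_report = prot.balanced_counts(
                groups, filtered, split_policy=pc["split_policy"]
            )
            eio.write_tsv(fdr_report, pdir / "fdr_thresholds.tsv")
            grp_df = pd.DataFrame(
                {
                    "group_id": [g.group_id for g in groups],
                    "proteins": [";".join(g.proteins) for g in groups],
                    "n_peptides": [len(g.peptides) for g in groups],
                    "n_unique": [len(g.unique_peptides) for g in groups],
                }
            )
            eio.write_tsv(grp_df, pdir / "protein_groups.tsv")
            counts.to_csv(pdir / "balanced_counts.tsv", sep="\t", index_label="group_id")
            artifacts["proteo"] = sorted(pdir.glob("*"))
        if stages.get("express"):
            log.info("stage express")
            if fixtures is None:
                raise ConfigError("express stage requires simulate outputs")
            edir = out / "express"
            edir.mkdir(exist_ok=True)
            ec = config["express"]
            counts = fixtures["counts"]
            norm = expr.normalize_community(counts)
            complete = expr.filter_complete(counts)
            de = expr.rank_product(
                complete,
                ec["condition_a"],
                ec["condition_b"],
                n_perm=ec["n_perm"],
                seed=seed,
                fc_threshold=ec["fc_threshold"],
                p_threshold=ec["p_threshold"],
            )
            gsea_res = expr.gsea(
                complete,
                fixtures["gene_sets"],
                ec["condition_a"],
                ec["condition_b"],
                n_perm=ec["gsea_n_perm"],
                seed=seed,
                fdr_threshold=ec["gsea_fdr"],
            )
            clust = expr.hcluster(norm)
            eio.write_count_matrix(norm, edir / "community_normalized.tsv")
            eio.write_tsv(de, edir / "rank_product.tsv")
            eio.write_tsv(gsea_res, edir / "gsea.tsv")
            (edir / "dendrogram.nwk").write_text(clust.newick + "\n")
            artifacts["express"] = sorted(edir.glob("*"))
    finally:
        log.removeHandler(fh)
        fh.close()
    for stage, files in artifacts.items():
        manifest["stages"][stage] = {
            f.name: _sha256(f) for f in files if f.is_file()
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
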
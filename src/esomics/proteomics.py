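"""Peptide FDR filtering, parsimony protein inference, balanced counts.

Spectra are matched against a concatenated target/decoy database upstream;
here each run is filtered individually to a peptide-level FDR (decoy
peptides / target peptides at a score threshold), proteins are inferred by
parsimony rules (merge indistinguishable proteins, drop subset and
subsumable proteins, require two peptides with at least one unique), and
abundance is quantified by balanced spectral counting: a protein group
receives its unique spectra in full plus a share of every non-unique
spectrum, split between the matching groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NoDecoysError(ValueError):
    """FDR is inestimable without decoy matches."""


def _peptide_best(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse spectra to peptides by best (highest) score, per run."""
    best = (
        psms.sort_values("score", ascending=False, kind="mergesort")
        .drop_duplicates(["run", "peptide"], keep="first")
    )
    return best[["run", "peptide", "score", "is_decoy"]]


def peptide_fdr_filter(
    psms: pd.DataFrame, fdr_target: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter each run individually to a peptide-level decoy FDR.

    Per run, spectra are collapsed to peptides by best score and the score
    threshold is swept downward; at each candidate threshold t,
    FDR(t) = #decoy peptides with score >= t / #target peptides with
    score >= t. The loosest (lowest) threshold with FDR <= ``fdr_target``
    is chosen, and all spectra whose peptide passes are retained.

    Returns (filtered PSM table, threshold report) where the report has one
    row per run: run, threshold, n_target_peptides, n_decoy_peptides, fdr.
    """
    if not 0 < fdr_target < 1:
        raise ValueError("fdr_target must lie in (0, 1)")
    if not psms["is_decoy"].any():
        raise NoDecoysError("no decoy PSMs; FDR cannot be estimated")
    kept_frames = []
    report_rows = []
    for run, run_psms in psms.groupby("run", sort=True):
        peptides = _peptide_best(run_psms)
        order = peptides.sort_values("score", ascending=False, kind="mergesort")
        scores = order["score"].to_numpy()
        decoy = order["is_decoy"].to_numpy(dtype=bool)
        n_decoy = np.cumsum(decoy)
        n_target = np.cumsum(~decoy)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1), np.inf)
        ok = np.flatnonzero((fdr <= fdr_target) & (n_target > 0))
        if len(ok) == 0:
            threshold = np.inf
            passing: set[str] = set()
            t_cnt = d_cnt = 0
            achieved = 0.0
        else:
            cut = ok.max()  # loosest threshold still meeting the target
            threshold = scores[cut]
            # passing decoys stay in the output: they carry the evidence
            # for the downstream protein-level FDR estimate
            passing = set(order["peptide"].iloc[: cut + 1])
            t_cnt = int(n_target[cut])
            d_cnt = int(n_decoy[cut])
            achieved = float(fdr[cut])
        kept = run_psms[run_psms["peptide"].isin(passing)]
        kept_frames.append(kept)
        report_rows.append((run, threshold, t_cnt, d_cnt, achieved))
    filtered = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else psms.iloc[0:0].copy()
    )
    report = pd.DataFrame(
        report_rows,
        columns=["run", "threshold", "n_target_peptides", "n_decoy_peptides", "fdr"],
    )
    return filtered, report


@dataclass
class ProteinGroup:
    """Parsimony-inferred protein group with its peptide evidence."""

    group_id: str
    proteins: tuple[str, ...]
    peptides: frozenset[str]
    unique_peptides: frozenset[str] = frozenset()
    balanced_counts: dict[str, float] = field(default_factory=dict)


def _split_proteins(cell: str) -> tuple[str, ...]:
    return tuple(cell.split(";"))


def infer_protein_groups(
    filtered_psms: pd.DataFrame,
    min_peptides: int = 2,
    min_unique: int = 1,
    include_decoys: bool = False,
) -> list[ProteinGroup]:
    """Parsimony protein inference from FDR-filtered PSMs.

    Rules, iterated to a fixpoint (uniqueness is recomputed after every
    removal round):

    1. proteins with identical peptide sets merge into one group;
    2. a group whose peptide set is a proper subset of another's is removed;
    3. a subsumable group — peptide set covered by the union of >= 2 other
       retained groups, with no unique peptide — is removed;
    4. groups with fewer than ``min_peptides`` peptides or fewer than
       ``min_unique`` unique peptides are removed.

    Decoy PSMs are excluded from grouping unless ``include_decoys`` is set
    (which the protein-level FDR check uses: decoy groups surviving all
    rules estimate the false-group rate).
    """
    psms = filtered_psms
    if not include_decoys and "is_decoy" in psms.columns:
        psms = psms[~psms["is_decoy"].astype(bool)]
    pep_sets: dict[str, set[str]] = {}
    for row in psms.itertuples(index=False):
        for prot in _split_proteins(row.proteins):
            pep_sets.setdefault(prot, set()).add(row.peptide)

    # rule 1: merge indistinguishable proteins
    by_set: dict[frozenset, list[str]] = {}
    for prot, peps in pep_sets.items():
        by_set.setdefault(frozenset(peps), []).append(prot)
    groups = [
        (tuple(sorted(prots)), peps) for peps, prots in by_set.items()
    ]
    groups.sort(key=lambda g: g[0])

    retained = list(range(len(groups)))
    changed = True
    while changed:
        changed = False
        # unique peptides relative to the currently retained groups
        pep_owner_count: dict[str, int] = {}
        for gi in retained:
            for pep in groups[gi][1]:
                pep_owner_count[pep] = pep_owner_count.get(pep, 0) + 1
        uniques = {
            gi: {p for p in groups[gi][1] if pep_owner_count[p] == 1}
            for gi in retained
        }
        drop: set[int] = set()
        for gi in retained:
            peps = groups[gi][1]
            # rule 2: proper subset of another retained group
            for gj in retained:
                if gi != gj and peps < groups[gj][1]:
                    drop.add(gi)
                    break
            if gi in drop:
                continue
            # rule 3: subsumable — covered by >= 2 others, no unique peptide
            if not uniques[gi]:
                covering = [
                    gj
                    for gj in retained
                    if gj != gi and gj not in drop and groups[gj][1] & peps
                ]
                if len(covering) >= 2:
                    union = set().union(*(groups[gj][1] for gj in covering))
                    if peps <= union:
                        drop.add(gi)
                        continue
            # rule 4: evidence thresholds
            if len(peps) < min_peptides or len(uniques[gi]) < min_unique:
                drop.add(gi)
        if drop:
            retained = [gi for gi in retained if gi not in drop]
            changed = True

    # final uniqueness among survivors
    pep_owner_count = {}
    for gi in retained:
        for pep in groups[gi][1]:
            pep_owner_count[pep] = pep_owner_count.get(pep, 0) + 1
    out = []
    for k, gi in enumerate(retained):
        prots, peps = groups[gi]
        out.append(
            ProteinGroup(
                group_id=f"grp_{k:04d}",
                proteins=prots,
                peptides=frozenset(peps),
                unique_peptides=frozenset(
                    p for p in peps if pep_owner_count[p] == 1
                ),
            )
        )
    return out


def protein_level_fdr(
    psms: pd.DataFrame, min_peptides: int = 2, min_unique: int = 1
) -> float:
    """Decoy protein-group rate after applying the parsimony rules to all PSMs.

    Groups containing only decoy proteins count as decoy groups; the rate
    is decoy groups / target groups (concatenated-decoy convention).
    """
    groups = infer_protein_groups(psms, min_peptides, min_unique, include_decoys=True)
    n_decoy = sum(all(p.startswith("DECOY_") for p in g.proteins) for g in groups)
    n_target = len(groups) - n_decoy
    return n_decoy / n_target if n_target else float("inf")


def balanced_counts(
    groups: list[ProteinGroup],
    filtered_psms: pd.DataFrame,
    split_policy: str = "proportional",
    sample_col: str = "run",
) -> tuple[pd.DataFrame, dict]:
    """Balanced spectral counts per group and sample.

    Each retained group receives its unique spectra in full. A spectrum
    shared between several retained groups is split: with the
    ``proportional`` policy the share is w(group) / sum of w over matching
    groups, where w is the group's unique-spectrum count in that sample
    (equal split when all w are zero); the ``equal`` policy always splits
    evenly. Totals are conserved exactly: summed balanced counts equal the
    number of spectra assigned to any retained group. Spectra matching no
    retained group are dropped and tallied in the report.
    """
    if split_policy not in ("proportional", "equal"):
        raise ValueError("split_policy must be 'proportional' or 'equal'")
    prot_to_group: dict[str, str] = {}
    for g in groups:
        for prot in g.proteins:
            prot_to_group[prot] = g.group_id
    samples = sorted(filtered_psms[sample_col].unique())
    counts = pd.DataFrame(
        0.0, index=[g.group_id for g in groups], columns=samples
    )
    dropped = 0
    # first pass: unique-spectrum counts per group/sample
    spectrum_groups: list[tuple[str, list[str]]] = []
    for row in filtered_psms.itertuples(index=False):
        gids = sorted(
            {prot_to_group[p] for p in _split_proteins(row.proteins) if p in prot_to_group}
        )
        spectrum_groups.append((getattr(row, sample_col), gids))
    unique_w = pd.DataFrame(0.0, index=counts.index, columns=samples)
    for sample, gids in spectrum_groups:
        if len(gids) == 1:
            unique_w.loc[gids[0], sample] += 1.0
    # second pass: assign
    for sample, gids in spectrum_groups:
        if not gids:
            dropped += 1
            continue
        if len(gids) == 1:
            counts.loc[gids[0], sample] += 1.0
            continue
        if split_policy == "proportional":
            w = np.array([unique_w.loc[g, sample] for g in gids])
            if w.sum() == 0:
                w = np.ones(len(gids))
        else:
            w = np.ones(len(gids))
        w = w / w.sum()
        for g, share in zip(gids, w):
            counts.loc[g, sample] += share
    report = {"n_spectra": len(spectrum_groups), "n_dropped": dropped}
    for g in groups:
        g.balanced_counts = counts.loc[g.group_id].to_dict()
    return counts, report
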
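"""Decoy FDR filtering, parsimony inference, balanced spectral counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from esomics import synthetic as syn
from esomics.proteomics import (
    NoDecoysError,
    balanced_counts,
    infer_protein_groups,
    peptide_fdr_filter,
    protein_level_fdr,
)


def make_psms(rows):
    return pd.DataFrame(rows, columns=syn.PSM_COLUMNS)


def sweep_oracle(peptide_scores, decoy_flags, target=0.01):
    """Exhaustive threshold sweep over peptide-level best scores."""
    order = sorted(zip(peptide_scores, decoy_flags), key=lambda t: -t[0])
    best = None
    for i in range(len(order)):
        thr = order[i][0]
        d = sum(1 for s, f in order if s >= thr and f)
        t = sum(1 for s, f in order if s >= thr and not f)
        if t > 0 and d / t <= target:
            best = thr
    return best


class TestPeptideFdrFilter:
    def test_well_separated_scores_keep_every_target(self):
        rows = [(f"s{i}", "r1", f"p{i}", 20.0 + i, False, f"P{i}") for i in range(10)]
        rows += [(f"d{i}", "r1", f"dp{i}", 1.0 + i, True, f"DECOY_P{i}") for i in range(5)]
        filtered, report = peptide_fdr_filter(make_psms(rows), 0.01)
        assert len(filtered[~filtered["is_decoy"]]) == 10
        assert report.iloc[0]["fdr"] == 0.0

    def test_all_decoys_give_empty_result(self):
        rows = [(f"d{i}", "r1", f"dp{i}", float(i), True, "DECOY_P0") for i in range(5)]
        filtered, _ = peptide_fdr_filter(make_psms(rows), 0.01)
        assert len(filtered[~filtered["is_decoy"]]) == 0

    def test_no_decoys_is_an_error(self):
        rows = [("s1", "r1", "p1", 5.0, False, "P1")]
        with pytest.raises(NoDecoysError):
            peptide_fdr_filter(make_psms(rows), 0.01)

    def test_threshold_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            decoy = bool(rng.random() < 0.4)
            score = float(rng.normal(8 if decoy else 11, 2))
            pep = f"{'d' if decoy else 't'}pep{i}"
            prot = f"{'DECOY_' if decoy else ''}P{i % 37}"
            rows.append((f"s{i}", "r1", pep, score, decoy, prot))
        psms = make_psms(rows)
        fdr_target = 0.05
        _, report = peptide_fdr_filter(psms, fdr_target)
        best = psms.sort_values("score", ascending=False).drop_duplicates(
            ["run", "peptide"]
        )
        oracle = sweep_oracle(best["score"].tolist(), best["is_decoy"].tolist(), fdr_target)
        assert report.iloc[0]["threshold"] == oracle

    def test_runs_filtered_individually(self):
        rows = [("s1", "rA", "p1", 10.0, False, "P1"), ("d1", "rA", "dp1", 1.0, True, "D1")]
        rows += [("s2", "rB", "p2", 3.0, False, "P2"), ("d2", "rB", "dp2", 9.0, True, "D2")]
        filtered, report = peptide_fdr_filter(make_psms(rows), 0.5)
        assert set(report["run"]) == {"rA", "rB"}
        # in rB the decoy outranks the target, so nothing can pass at 50%
        kept_runs = set(filtered.loc[~filtered["is_decoy"], "run"])
        assert kept_runs == {"rA"}

    def test_monotone_in_fdr_target(self):
        psms, _ = syn.simulate_psm_table(20, n_spectra=800, seed=5, score_separation=1.5)
        prev = None
        for target in (0.2, 0.1, 0.05, 0.01):
            filtered, _ = peptide_fdr_filter(psms, target)
            kept = set(filtered["spectrum_id"])
            if prev is not None:
                assert kept <= prev
            prev = kept


def groups_by_proteins(groups):
    return {g.proteins: set(g.peptides) for g in groups}


class TestParsimonyInference:
    def test_indistinguishable_proteins_merge(self):
        rows = [
            ("s1", "r1", "a", 9.0, False, "P1;P2"),
            ("s2", "r1", "b", 9.0, False, "P1;P2"),
        ]
        groups = infer_protein_groups(make_psms(rows))
        assert [g.proteins for g in groups] == [("P1", "P2")]
        assert groups[0].peptides == {"a", "b"}

    def test_subset_protein_removed(self):
        rows = [
            ("s1", "r1", "a", 9.0, False, "P1;P3"),
            ("s2", "r1", "b", 9.0, False, "P1"),
        ]
        groups = infer_protein_groups(make_psms(rows))
        assert [g.proteins for g in groups] == [("P1",)]

    def test_two_peptide_one_unique_rule(self):
        rows = [("s1", "r1", "a", 9.0, False, "P1")]  # one peptide only
        assert infer_protein_groups(make_psms(rows)) == []

    def test_subsumable_group_removed(self):
        # P3's peptides {a, b} are covered by P1 (unique a, c) and P2
        # (unique b, d); P3 has no unique peptide
        rows = [
            ("s1", "r1", "a", 9.0, False, "P1;P3"),
            ("s2", "r1", "c", 9.0, False, "P1"),
            ("s3", "r1", "b", 9.0, False, "P2;P3"),
            ("s4", "r1", "d", 9.0, False, "P2"),
        ]
        groups = infer_protein_groups(make_psms(rows))
        assert sorted(g.proteins for g in groups) == [("P1",), ("P2",)]

    def test_matches_brute_force_rule_applier(self):
        """Random 50-protein incidence matrix versus an independent
        re-application of merge/subset/subsumable/evidence rules."""
        rng = np.random.default_rng(12)
        n_prot, n_pep = 50, 120
        incidence = rng.random((n_prot, n_pep)) < 0.06
        rows = []
        for j in range(n_pep):
            owners = [f"P{i:02d}" for i in range(n_prot) if incidence[i, j]]
            if owners:
                rows.append((f"s{j}", "r1", f"pep{j}", 10.0, False, ";".join(owners)))
        groups = infer_protein_groups(make_psms(rows))

        # oracle: iterate the rules with plain set algebra until stable
        pep_sets = {}
        for i in range(n_prot):
            peps = {f"pep{j}" for j in range(n_pep) if incidence[i, j]
                    and any(incidence[:, j])}
            if peps:
                pep_sets[f"P{i:02d}"] = frozenset(peps)
        merged = {}
        for p, s in pep_sets.items():
            merged.setdefault(s, []).append(p)
        alive = {tuple(sorted(ps)): set(s) for s, ps in merged.items()}
        while True:
            uniq = {}
            for g, s in alive.items():
                others = set().union(*(t for h, t in alive.items() if h != g)) if len(alive) > 1 else set()
                uniq[g] = s - others
            doomed = set()
            for g, s in alive.items():
                if any(g != h and s < t for h, t in alive.items()):
                    doomed.add(g)
                    continue
                if not uniq[g]:
                    covering = [h for h, t in alive.items() if h != g and t & s]
                    if len(covering) >= 2 and s <= set().union(*(alive[h] for h in covering)):
                        doomed.add(g)
                        continue
                if len(s) < 2 or len(uniq[g]) < 1:
                    doomed.add(g)
            if not doomed:
                break
            for g in doomed:
                del alive[g]
        assert {g.proteins for g in groups} == set(alive)


class TestBalancedCounts:
    def _two_group_psms(self):
        rows = []
        # grp P1 unique spectra: 3; grp P2 unique: 1; 1 shared spectrum
        for i in range(3):
            rows.append((f"u{i}", "r1", f"pa{i}", 9.0, False, "P1"))
        rows.append(("v0", "r1", "pb0", 9.0, False, "P2"))
        rows.append(("v1", "r1", "pb1", 9.0, False, "P2"))
        rows.append(("w0", "r1", "pa3", 9.0, False, "P1"))
        rows.append(("sh", "r1", "shared", 9.0, False, "P1;P2"))
        return make_psms(rows)

    def test_proportional_split_follows_unique_evidence(self):
        psms = self._two_group_psms()
        groups = infer_protein_groups(psms)
        counts, _ = balanced_counts(groups, psms)
        gid = {g.proteins[0]: g.group_id for g in groups}
        # unique weights: P1 has 4 unique spectra, P2 has 2 -> shared splits 2/3 : 1/3
        assert counts.loc[gid["P1"], "r1"] == pytest.approx(4 + 2 / 3)
        assert counts.loc[gid["P2"], "r1"] == pytest.approx(2 + 1 / 3)

    def test_three_to_one_unique_evidence_splits_shared_075_025(self):
        # unique spectra 3 (P1) vs 1 (P2): the shared spectrum splits
        # w/(sum w) = 0.75 / 0.25
        rows = [
            ("u1", "r1", "a1", 9.0, False, "P1"),
            ("u2", "r1", "a2", 9.0, False, "P1"),
            ("u3", "r1", "a3", 9.0, False, "P1"),
            ("v1", "r1", "b1", 9.0, False, "P2"),
            ("sh", "r1", "s", 9.0, False, "P1;P2"),
        ]
        psms = make_psms(rows)
        groups = infer_protein_groups(psms)
        counts, _ = balanced_counts(groups, psms)
        gid = {g.proteins[0]: g.group_id for g in groups}
        assert counts.loc[gid["P1"], "r1"] == pytest.approx(3.75)
        assert counts.loc[gid["P2"], "r1"] == pytest.approx(1.25)

    def test_equal_split_policy(self):
        psms = self._two_group_psms()
        groups = infer_protein_groups(psms)
        counts, _ = balanced_counts(groups, psms, split_policy="equal")
        assert counts.to_numpy().sum() == pytest.approx(7.0)
        gid = {g.proteins[0]: g.group_id for g in groups}
        assert counts.loc[gid["P1"], "r1"] == pytest.approx(4.5)

    def test_totals_conserved_to_machine_precision(self):
        psms, _ = syn.simulate_psm_table(
            25, shared_fraction=0.3, n_spectra=1500, seed=7
        )
        filtered, _ = peptide_fdr_filter(psms, 0.01)
        targets = filtered[~filtered["is_decoy"]]
        groups = infer_protein_groups(targets)
        counts, report = balanced_counts(groups, targets)
        assigned = report["n_spectra"] - report["n_dropped"]
        assert counts.to_numpy().sum() == pytest.approx(assigned, abs=1e-9)


def test_protein_level_decoy_rate_below_one_percent():
    psms, _ = syn.simulate_psm_table(40, n_spectra=3000, decoy_ratio=1.0, seed=13)
    filtered, _ = peptide_fdr_filter(psms, 0.01)
    assert protein_level_fdr(filtered) < 0.01
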
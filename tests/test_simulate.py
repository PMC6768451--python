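"""Tests for the synthetic clone-pair generator."""

import math

import numpy as np
import pytest

from clonescan import filter as filt
from clonescan import selection as sel
from clonescan import simulate as sim


class TestTranscriptomes:
    def test_omega_zero_no_nonsynonymous(self):
        cfg = sim.SimulationConfig(n_genes=15, omega=0.0, ks_target=0.1, seed=2)
        _, _, _, truth = sim.simulate_transcriptomes(cfg)
        assert all(d.cls == "syn" for d in truth.fixed_diffs)

    def test_determinism_same_seed(self):
        cfg = sim.SimulationConfig(n_genes=8, seed=5)
        out1 = sim.simulate_transcriptomes(cfg)
        out2 = sim.simulate_transcriptomes(cfg)
        assert out1[0] == out2[0] and out1[1] == out2[1] and out1[2] == out2[2]
        assert out1[3].fixed_diffs == out2[3].fixed_diffs
        assert out1[3].het_sites == out2[3].het_sites

    def test_different_seed_differs(self):
        a = sim.simulate_transcriptomes(sim.SimulationConfig(n_genes=5, seed=1))
        b = sim.simulate_transcriptomes(sim.SimulationConfig(n_genes=5, seed=2))
        assert a[0] != b[0]

    def test_equal_lengths_across_sets(self, small_sim):
        _, ancestral, clone_a, clone_b, _ = small_sim
        for g in ancestral:
            assert len(ancestral[g]) == len(clone_a[g]) == len(clone_b[g])

    def test_cds_starts_with_atg_no_internal_stops(self, small_sim):
        _, ancestral, clone_a, clone_b, truth = small_sim
        for seqs in (ancestral, clone_a, clone_b):
            for g, (start, end) in truth.cds_ranges.items():
                cds = seqs[g][start:end]
                assert cds.startswith("ATG")
                assert sel.is_stop(cds[-3:])
                internal = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
                assert not any(sel.is_stop(c) for c in internal)

    def test_conservation_truth_equals_sequence_diff(self, small_sim):
        _, _, clone_a, clone_b, truth = small_sim
        n_diff = sum(
            1 for g in clone_a for x, y in zip(clone_a[g], clone_b[g]) if x != y
        )
        assert n_diff == len(truth.fixed_diffs)

    def test_planted_positions_inside_cds(self, small_sim):
        _, _, _, _, truth = small_sim
        for d in truth.fixed_diffs:
            start, end = truth.cds_ranges[d.gene]
            assert start <= d.pos < end

    def test_het_never_on_own_fixed_difference(self, small_sim):
        _, _, _, _, truth = small_sim
        fixed = {(d.gene, d.pos) for d in truth.fixed_diffs}
        for clone in ("A", "B"):
            assert not fixed & {(g, p) for g, p, _ in truth.het_sites[clone]}

    def test_ng86_reclassification_consistency(self, small_sim):
        """Planted classes agree 100% with the selection module's tables."""
        _, _, clone_a, clone_b, truth = small_sim
        for d in truth.fixed_diffs:
            start, _ = truth.cds_ranges[d.gene]
            off = d.pos - start
            c0 = off - off % 3
            codon_a = clone_a[d.gene][start + c0:start + c0 + 3]
            codon_b = clone_b[d.gene][start + c0:start + c0 + 3]
            expected = "syn" if sel.ng86_difference_counts(codon_a, codon_b).Nn == 0 else "nonsyn"
            assert expected == d.cls

    def test_poisson_mean_of_planted_synonymous(self):
        cfg = sim.SimulationConfig(n_genes=200, ks_target=0.05, omega=0.2, seed=7)
        anc, _, _, truth = sim.simulate_transcriptomes(cfg)
        S = []
        for g, (start, end) in truth.cds_ranges.items():
            S.append(sel.ng86_site_counts(anc[g][start:end - 3]).S)
        syn_counts = {g: 0 for g in truth.omega_true}
        for d in truth.fixed_diffs:
            if d.cls == "syn":
                syn_counts[d.gene] += 1
        mean_syn = np.mean(list(syn_counts.values()))
        expected = 0.05 * np.mean(S)
        se = math.sqrt(expected / cfg.n_genes)  # Poisson SE of the mean
        assert abs(mean_syn - expected) <= 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            sim.SimulationConfig(ks_target=0.0)
        with pytest.raises(ValueError):
            sim.SimulationConfig(het_rate=1.5)
        with pytest.raises(ValueError):
            sim.SimulationConfig(omega=-0.1)
        with pytest.raises(ValueError):
            sim.SimulationConfig(omega_mixture=((0.5, 0.2), (0.4, 1.0)))

    def test_omega_mixture_assigns_stated_values(self):
        cfg = sim.SimulationConfig(
            n_genes=50, omega_mixture=((0.8, 0.2), (0.2, 5.0)), seed=3
        )
        _, _, _, truth = sim.simulate_transcriptomes(cfg)
        assert set(truth.omega_true.values()) <= {0.2, 5.0}


class TestInjectContaminants:
    def test_noop_when_zero(self, small_sim):
        cfg0 = sim.SimulationConfig(n_genes=5, n_contaminants=0, n_rrna=0, seed=1)
        _, a, b, truth = sim.simulate_transcriptomes(cfg0)
        mixed, contam_db, rrna_db = sim.inject_contaminants({"A": a, "B": b}, cfg0, truth)
        assert mixed["A"] == a and mixed["B"] == b and not contam_db and not rrna_db

    def test_exact_contaminant_count_flagged(self):
        cfg = sim.SimulationConfig(n_genes=5, n_contaminants=50, n_rrna=0, seed=4)
        _, a, b, truth = sim.simulate_transcriptomes(cfg)
        mixed, contam_db, _ = sim.inject_contaminants({"A": a, "B": b}, cfg, truth)
        assert len(truth.contaminant_ids) == 50
        assert set(truth.contaminant_ids) <= set(mixed["A"])

    def test_all_contaminants_removed_by_filter(self, small_sim):
        cfg, ancestral, clone_a, clone_b, truth = small_sim
        mixed, contam_db, rrna_db = sim.inject_contaminants(
            {"A": clone_a, "B": clone_b}, cfg, truth
        )
        decisions = filt.contaminant_filter(mixed["A"], ancestral, contam_db)
        removed = {d.contig for d in decisions if not d.kept}
        survivors = {n: s for n, s in mixed["A"].items() if n not in removed}
        rrna_removed = {
            d.contig for d in filt.rrna_filter(survivors, rrna_db) if not d.kept
        }
        gone = removed | rrna_removed
        assert set(truth.contaminant_ids) <= gone
        assert set(truth.rrna_ids) <= gone
        kept_genes = set(mixed["A"]) - gone
        assert len(kept_genes & set(clone_a)) >= 0.99 * len(clone_a)


class TestPileups:
    def test_error_free_sites_match_reference(self):
        cfg = sim.SimulationConfig(
            n_genes=4, error_rate=0.0, het_rate=0.0, ks_target=1e-9,
            n_contaminants=0, n_rrna=0, seed=6,
        )
        _, a, b, truth = sim.simulate_transcriptomes(cfg)
        assert not truth.fixed_diffs
        piles = sim.simulate_pileups(a, b, truth, cfg)
        t = piles["B_on_A"]
        for base in "ACGT":
            rows = t[t["ref"] == base]
            others = [c for c in "ACGT" if c != base]
            assert (rows[others].to_numpy() == 0).all()

    def test_depth_mean_matches_coverage(self, small_sim):
        cfg, _, clone_a, clone_b, truth = small_sim
        t = sim.simulate_pileups(clone_a, clone_b, truth, cfg)["A_on_A"]
        depth = t[["A", "C", "G", "T"]].sum(axis=1) + t["ins"] + t["del"]
        assert len(depth) >= 10**4
        se = math.sqrt(cfg.coverage / len(depth))
        assert abs(depth.mean() - cfg.coverage) <= 3 * se

    def test_het_allele_fraction_half(self):
        cfg = sim.SimulationConfig(
            n_genes=60, het_rate=0.01, coverage=50.0, error_rate=0.0,
            n_contaminants=0, n_rrna=0, seed=13,
        )
        _, a, b, truth = sim.simulate_transcriptomes(cfg)
        t = sim.simulate_pileups(a, b, truth, cfg)["A_on_A"]
        t = t.set_index(["gene", "pos"])
        alt_reads = total = 0
        for g, p, alt in truth.het_sites["A"]:
            row = t.loc[(g, p)]
            alt_reads += row[alt]
            total += row[list("ACGT")].sum()
        frac = alt_reads / total
        se = math.sqrt(0.25 / total)
        assert abs(frac - 0.5) <= 3 * se

    def test_pileup_determinism(self, small_sim):
        cfg, _, clone_a, clone_b, truth = small_sim
        t1 = sim.simulate_pileups(clone_a, clone_b, truth, cfg)["A_on_B"]
        t2 = sim.simulate_pileups(clone_a, clone_b, truth, cfg)["A_on_B"]
        assert t1.equals(t2)


class TestCounts:
    def test_fold_one_no_de_truth(self):
        cfg = sim.SimulationConfig(n_genes=100, fold_change=1.0, de_fraction=0.5, seed=3)
        truth = sim.SimulationTruth()
        sim.simulate_counts(cfg, truth)
        assert not any(truth.de_flags.values())

    def test_de_fold_recovered_in_condition_means(self):
        cfg = sim.SimulationConfig(
            n_genes=500, de_fraction=1.0, fold_change=4.0, nb_dispersion=0.05,
            n_replicates_per_condition=4, seed=17,
        )
        truth = sim.SimulationTruth()
        counts, conds = sim.simulate_counts(cfg, truth)
        conds = np.array(conds)
        lib = np.array([truth.library_factors[s] for s in counts.columns])
        m1 = counts.loc[:, conds == "cond1"].mean(axis=1) / lib[conds == "cond1"].mean()
        m2 = counts.loc[:, conds == "cond2"].mean(axis=1) / lib[conds == "cond2"].mean()
        ratios = (m2 / m1).to_numpy()
        se = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean() - 4.0) <= 3 * se

    def test_counts_determinism(self):
        cfg = sim.SimulationConfig(n_genes=50, seed=9)
        c1, _ = sim.simulate_counts(cfg)
        c2, _ = sim.simulate_counts(cfg)
        assert c1.equals(c2)

    def test_counts_are_nonnegative_integers(self):
        cfg = sim.SimulationConfig(n_genes=30, seed=9)
        counts, conditions = sim.simulate_counts(cfg)
        assert (counts.to_numpy() >= 0).all()
        assert counts.shape == (30, 2 * cfg.n_replicates_per_condition)
        assert len(conditions) == counts.shape[1]
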
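"""Unit and property tests for ORF finding, NG86 counting and Ka/Ks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonescan import selection as sel
from clonescan._genetics import BASES, SENSE_CODONS
from Bio.Seq import Seq


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def _aa(codon):
    return str(Seq(codon).translate())


def oracle_site_counts(codon):
    """Brute-force NG86 site counts: enumerate all 9 single-base mutants."""
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if _aa(mut) != "*" and _aa(mut) == _aa(codon):
                syn += 1 / 3
    return syn, 3.0 - syn


def oracle_pair_diffs(c1, c2):
    """Brute-force pathway enumeration with stop-path exclusion."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths, ok_paths = [], []
    for order in itertools.permutations(diff):
        cur, syn, non, bad = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                non += 1
            if nxt != c2 and _aa(nxt) == "*":
                bad = True
            cur = nxt
        all_paths.append((syn, non))
        if not bad:
            ok_paths.append((syn, non))
    use = ok_paths or all_paths
    return sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use)


def random_cds(rng, n_codons):
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


# --------------------------------------------------------------------------
# ORFs
# --------------------------------------------------------------------------

class TestFindOrfs:
    def test_canonical_orf_spans_atg_to_stop(self, rng):
        body = random_cds(rng, 120)
        transcript = "ATG" + body + "TAA"
        orfs = sel.find_orfs(transcript, min_len_codons=100)
        assert orfs and orfs[0].n_codons == 122
        assert orfs[0].start == 0 and orfs[0].end == len(transcript)
        assert not orfs[0].partial5

    def test_partial_5prime_without_atg(self, rng):
        # 150 stop-free codons, no ATG anywhere in frame 0
        codons = [c for c in SENSE_CODONS if c != "ATG"]
        body = "".join(codons[i % len(codons)] for i in rng.integers(0, len(codons), 150))
        orfs = sel.find_orfs(body, min_len_codons=100, allow_partial=True)
        assert orfs and orfs[0].partial5

    def test_short_orf_filtered(self, rng):
        transcript = "ATG" + random_cds(rng, 48) + "TAA"
        assert sel.find_orfs(transcript, min_len_codons=100) == []

    def test_no_partial_requires_atg(self, rng):
        codons = [c for c in SENSE_CODONS if c != "ATG"]
        body = "".join(codons[i] for i in rng.integers(0, len(codons), 150))
        assert sel.find_orfs(body, min_len_codons=100, allow_partial=False) == []


class TestApplyFixedVariants:
    def test_empty_variants_identity(self):
        assert sel.apply_fixed_variants("ATGAAA", []) == "ATGAAA"

    def test_single_variant_single_position(self):
        out = sel.apply_fixed_variants("ATGAAA", [(4, "A", "G")])
        assert out == "ATGAGA"
        assert sum(a != b for a, b in zip(out, "ATGAAA")) == 1

    def test_involution_restores_original(self):
        variants = [(1, "T", "C"), (5, "A", "T")]
        fwd = sel.apply_fixed_variants("ATGAAA", variants)
        back = sel.apply_fixed_variants(fwd, [(p, alt, ref) for p, ref, alt in variants])
        assert back == "ATGAAA"

    def test_positions_outside_cds_ignored(self):
        assert sel.apply_fixed_variants("ATGAAA", [(99, "A", "G")], cds_start=0) == "ATGAAA"

    def test_allele_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            sel.apply_fixed_variants("ATGAAA", [(0, "C", "G")])


# --------------------------------------------------------------------------
# NG86 site counts
# --------------------------------------------------------------------------

class TestSiteCounts:
    def test_atg_fully_nonsynonymous(self):
        sc = sel.ng86_site_counts("ATG")
        assert sc.S == 0.0 and sc.N == 3.0

    def test_ttt_one_third_synonymous(self):
        sc = sel.ng86_site_counts("TTT")
        assert math.isclose(sc.S, 1 / 3) and math.isclose(sc.N, 8 / 3)

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_matches_bruteforce_oracle_per_codon(self, codon):
        s, n = oracle_site_counts(codon)
        sc = sel.ng86_site_counts(codon)
        assert math.isclose(sc.S, s, abs_tol=1e-12)
        assert math.isclose(sc.N, n, abs_tol=1e-12)

    @given(st.integers(0, 2**32 - 1), st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_site_conservation(self, seed, n_codons):
        cds = random_cds(np.random.default_rng(seed), n_codons)
        sc = sel.ng86_site_counts(cds)
        assert math.isclose(sc.S + sc.N, 3 * n_codons, abs_tol=1e-9)

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            sel.ng86_site_counts("ATGA")


# --------------------------------------------------------------------------
# NG86 difference counts
# --------------------------------------------------------------------------

class TestDifferenceCounts:
    def test_identical_zero(self):
        dc = sel.ng86_difference_counts("ATGAAA", "ATGAAA")
        assert dc.Ns == 0.0 and dc.Nn == 0.0

    def test_single_synonymous_step(self):
        dc = sel.ng86_difference_counts("TTT", "TTC")
        assert dc.Ns == 1.0 and dc.Nn == 0.0

    def test_two_step_pathway_average(self):
        # TTT->GTT->GTA: (1 syn, 1 non); TTT->TTA->GTA: (0 syn, 2 non); average
        dc = sel.ng86_difference_counts("TTT", "GTA")
        assert math.isclose(dc.Ns, 0.5) and math.isclose(dc.Nn, 1.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_pathway_oracle(self, seed):
        r = np.random.default_rng(seed)
        c1 = SENSE_CODONS[r.integers(len(SENSE_CODONS))]
        c2 = SENSE_CODONS[r.integers(len(SENSE_CODONS))]
        s, n = oracle_pair_diffs(c1, c2)
        dc = sel.ng86_difference_counts(c1, c2)
        assert math.isclose(dc.Ns, s, abs_tol=1e-12)
        assert math.isclose(dc.Nn, n, abs_tol=1e-12)

    def test_total_steps_equal_differing_positions(self, rng):
        a = random_cds(rng, 50)
        b = random_cds(rng, 50)
        d = sum(
            1 for i in range(0, 150, 3)
            if a[i:i + 3] != b[i:i + 3]
            for j in range(3) if a[i + j] != b[i + j]
        )
        dc = sel.ng86_difference_counts(a, b)
        assert math.isclose(dc.Ns + dc.Nn, d, abs_tol=1e-9)


# --------------------------------------------------------------------------
# Ka/Ks and classification
# --------------------------------------------------------------------------

class TestKaKs:
    def test_identical_pair_unclassified(self):
        rec = sel.kaks_estimate("ATGAAATTTCCC", "ATGAAATTTCCC")
        assert rec.Ka == 0.0 and rec.Ks == 0.0
        assert math.isnan(rec.ratio)
        assert rec.selection_class == "unclassified"

    def test_jukes_cantor_closed_form(self):
        assert sel.jukes_cantor(0.0) == 0.0
        assert math.isclose(sel.jukes_cantor(0.06), -0.75 * math.log(1 - 0.08))

    def test_jukes_cantor_monotone(self):
        ps = np.linspace(0, 0.74, 200)
        ds = [sel.jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_jukes_cantor_undefined(self):
        with pytest.raises(ValueError):
            sel.jukes_cantor(0.75)

    def test_fisher_p_one_without_substitutions(self):
        from scipy.stats import fisher_exact

        assert fisher_exact([[0, 10], [0, 20]])[1] == 1.0

    def test_classification_partition(self, rng):
        records = []
        for _ in range(30):
            a = random_cds(rng, 60)
            b = "".join(
                (BASES[(BASES.index(x) + 1) % 4] if rng.random() < 0.05 else x) for x in a
            )
            records.append(sel.kaks_estimate(a, b))
        counts = sel.classify_selection(records)
        assert sum(counts.values()) == len(records)

    def test_bitwise_deterministic(self, rng):
        a = random_cds(rng, 100)
        b = random_cds(rng, 100)
        r1 = sel.kaks_estimate(a, b)
        r2 = sel.kaks_estimate(a, b)
        assert r1 == r2


class TestDistanceAndDating:
    def test_p_distance_identical(self):
        assert sel.p_distance("ACGT", "ACGT") == 0.0

    def test_p_distance_six_percent(self):
        a = "A" * 100
        b = "C" * 6 + "A" * 94
        assert sel.p_distance(a, b) == 0.06

    def test_p_distance_all_gaps_errors(self):
        with pytest.raises(ValueError):
            sel.p_distance("--", "AC")

    def test_divergence_time_worked_example(self):
        assert sel.divergence_time(0.06, 0.02) == pytest.approx(3.0)

    def test_divergence_time_zero(self):
        assert sel.divergence_time(0.0, 0.02) == 0.0

    def test_divergence_time_arithmetic(self):
        assert sel.divergence_time(0.04, 0.02) == pytest.approx(2.0)

    def test_divergence_time_bad_rate(self):
        with pytest.raises(ValueError):
            sel.divergence_time(0.06, 0.0)
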
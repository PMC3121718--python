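"""Promoter motif scanning, interaction matrix, and TRE enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from lesionlink.synthetic_data import generate_promoters
from lesionlink.tre import (HNF4_CONSENSUS, Motif, PromoterMotifAnalysis,
                            build_interaction_matrix, read_motifs,
                            scan_promoter, tre_enrichment)

HNF4 = Motif(name="HNF-4", consensus="AGGTCAaAGGTCA", strand="forward")


class TestScanPromoter:
    def test_hnf4_consensus_matches_itself_once_forward(self):
        count, positions = scan_promoter("AGGTCAAAGGTCA", HNF4)
        assert count == 1
        assert positions == [0]

    def test_empty_sequence(self):
        assert scan_promoter("", HNF4) == (0, [])

    def test_reverse_complement_needs_both_strands(self):
        rc = reverse_complement("AGGTCAAAGGTCA")
        assert scan_promoter(rc, HNF4)[0] == 0
        both = Motif(name="HNF-4", consensus=HNF4_CONSENSUS, strand="both")
        assert scan_promoter(rc, both)[0] == 1

    def test_lowercase_and_case_insensitive(self):
        assert scan_promoter("aggtcaaaggtca", HNF4)[0] == 1

    def test_overlapping_matches_counted(self):
        m = Motif(name="AA", consensus="AA", strand="forward")
        count, positions = scan_promoter("AAAA", m)
        assert count == 3
        assert positions == [0, 1, 2]

    def test_sequence_n_never_matches_non_n_position(self):
        m = Motif(name="x", consensus="ANA", strand="forward")
        assert scan_promoter("ANA", m)[0] == 1     # motif N matches anything
        m2 = Motif(name="y", consensus="AAA", strand="forward")
        assert scan_promoter("ANA", m2)[0] == 0

    def test_degenerate_codes(self):
        m = Motif(name="gata", consensus="WGATAR", strand="forward")
        assert scan_promoter("TGATAG", m)[0] == 1
        assert scan_promoter("CGATAG", m)[0] == 0

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            scan_promoter("ACGU", HNF4)
        with pytest.raises(ValueError):
            Motif(name="bad", consensus="ACGX")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_both_strand_count_invariant_under_revcomp(self, seed):
        r = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[r.integers(0, 4, size=60)])
        m = Motif(name="e", consensus="CANNTG", strand="both")
        assert scan_promoter(seq, m)[0] == scan_promoter(reverse_complement(seq), m)[0]


class TestPWM:
    def _pwm_for(self, seq):
        pwm = np.full((4, len(seq)), 0.01)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, c in enumerate(seq):
            pwm[idx[c], j] = 0.97
        return pwm

    def test_pwm_hit_and_threshold(self):
        pwm = self._pwm_for("ACGT")
        m = Motif(name="p", pwm=pwm, threshold=4.0, strand="forward")
        assert scan_promoter("TTACGTTT", m)[0] == 1
        strict = Motif(name="p", pwm=pwm, threshold=100.0, strand="forward")
        assert scan_promoter("TTACGTTT", strict)[0] == 0

    def test_pwm_both_strands(self):
        pwm = self._pwm_for("AACCG")
        m = Motif(name="p", pwm=pwm, threshold=5.0, strand="both")
        assert scan_promoter("CGGTT", m)[0] == 1   # reverse complement of AACCG

    def test_pwm_window_with_n_never_hits(self):
        pwm = self._pwm_for("ACGT")
        m = Motif(name="p", pwm=pwm, threshold=-100.0, strand="forward")
        assert scan_promoter("ACNT", m)[0] == 0

    def test_pwm_columns_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Motif(name="bad", pwm=np.full((4, 3), 0.3), threshold=0)


class TestInteractionMatrix:
    def test_low_prevalence_motif_dropped(self, rng):
        promoters = generate_promoters([f"g{i}" for i in range(100)], rng,
                                       length=200)
        promoters["g0"] = promoters["g0"][:100] + "AGGTCAAAGGTCA" + promoters["g0"][113:]
        hnf4 = Motif(name="HNF-4", consensus=HNF4_CONSENSUS)
        ebox = Motif(name="EBOX", consensus="CANNTG")
        mat = build_interaction_matrix(promoters, [hnf4, ebox])
        assert "HNF-4" in mat.dropped                 # 1/100 <= 5%
        assert mat.prevalence["HNF-4"] == pytest.approx(0.01)

    def test_ubiquitous_motif_retained(self, rng):
        promoters = {f"g{i}": "AGGTCAAAGGTCA" + "C" * 50 for i in range(10)}
        mat = build_interaction_matrix(promoters, [Motif(name="HNF-4",
                                                         consensus=HNF4_CONSENSUS)])
        assert mat.prevalence["HNF-4"] == 1.0
        assert list(mat.hits.columns) == ["HNF-4"]
        assert set(mat.hits["HNF-4"]) == {1}

    def test_planted_sixty_percent_prevalence(self, rng):
        genes = [f"g{i}" for i in range(60)]
        promoters = generate_promoters(genes, rng, length=2000,
                                       plant_motif=HNF4_CONSENSUS, plant_frac=0.6)
        mat = build_interaction_matrix(promoters,
                                       [Motif(name="HNF-4", consensus=HNF4_CONSENSUS)])
        assert mat.prevalence["HNF-4"] == pytest.approx(0.6, abs=0.05)
        assert mat.promoter_length == 2000

    def test_missing_promoter_warns(self, rng):
        promoters = generate_promoters(["g0", "g1"], rng, length=50)
        with pytest.warns(UserWarning):
            mat = build_interaction_matrix(promoters,
                                           [Motif(name="E", consensus="CANNTG")],
                                           genes=["g0", "g1", "g_missing"])
        assert mat.skipped_genes == ["g_missing"]


def fisher_oracle(k, n, K, M):
    """One-sided Fisher p for a 2x2 table by exact-fraction enumeration."""
    hits, misses = k + K, (n - k) + (M - K)
    N = hits + misses
    total = comb(N, n)
    return float(sum(Fraction(comb(hits, j) * comb(misses, n - j), total)
                     for j in range(k, min(hits, n) + 1)))


class TestTREEnrichment:
    def _hits_frame(self, cand_hits, cand_n, ref_hits, ref_n):
        genes = [f"c{i}" for i in range(cand_n)] + [f"r{i}" for i in range(ref_n)]
        col = ([1] * cand_hits + [0] * (cand_n - cand_hits)
               + [1] * ref_hits + [0] * (ref_n - ref_hits))
        return pd.DataFrame({"M": col}, index=genes)

    def test_equal_frequencies_not_significant(self):
        hits = self._hits_frame(6, 12, 100, 200)
        res = tre_enrichment(hits, [f"c{i}" for i in range(12)],
                             [f"r{i}" for i in range(200)])
        assert res["p_value"].iloc[0] > 0.4
        assert not res["significant"].iloc[0]

    def test_matches_fisher_enumeration_oracle(self):
        hits = self._hits_frame(9, 12, 50, 200)
        res = tre_enrichment(hits, [f"c{i}" for i in range(12)],
                             [f"r{i}" for i in range(200)])
        assert res["p_value"].iloc[0] == pytest.approx(
            fisher_oracle(9, 12, 50, 200), rel=1e-10)

    def test_absent_motif_p_one(self):
        hits = self._hits_frame(0, 10, 0, 50)
        res = tre_enrichment(hits, [f"c{i}" for i in range(10)],
                             [f"r{i}" for i in range(50)])
        assert res["p_value"].iloc[0] == 1.0

    def test_planted_enrichment_always_detected(self):
        """0.6 frequency in 60 candidates vs 0.1 in 940 reference promoters."""
        detected = 0
        seeds = 60
        for seed in range(seeds):
            r = np.random.default_rng(seed)
            cand = (r.uniform(size=60) < 0.6).astype(int)
            ref = (r.uniform(size=940) < 0.1).astype(int)
            genes = [f"c{i}" for i in range(60)] + [f"r{i}" for i in range(940)]
            hits = pd.DataFrame({"M": np.concatenate([cand, ref])}, index=genes)
            res = tre_enrichment(hits, genes[:60], genes[60:])
            detected += bool(res["significant"].iloc[0])
        assert detected / seeds >= 0.99

    def test_label_permutation_null_is_flat(self):
        """Permuting candidate labels gives no excess of small p-values."""
        rng = np.random.default_rng(5)
        base = (rng.uniform(size=300) < 0.3).astype(int)
        genes = [f"g{i}" for i in range(300)]
        hits = pd.DataFrame({"M": base}, index=genes)
        small = 0
        reps = 300
        for _ in range(reps):
            cand = list(rng.choice(genes, size=30, replace=False))
            res = tre_enrichment(hits, cand, genes)
            small += res["p_value"].iloc[0] < 0.05
        assert small / reps <= 0.08


class TestMotifIO:
    def test_read_consensus_and_pwm(self, tmp_path):
        path = tmp_path / "motifs.txt"
        path.write_text(
            "HNF-4\tAGGTCAaAGGTCA\tforward\n"
            ">MYPWM threshold=3.5 strand=both\n"
            "A 0.7 0.1\n"
            "C 0.1 0.7\n"
            "G 0.1 0.1\n"
            "T 0.1 0.1\n")
        motifs = read_motifs(path)
        assert motifs[0].consensus == "AGGTCAAAGGTCA"
        assert motifs[0].strand == "forward"
        assert motifs[1].pwm.shape == (4, 2)
        assert motifs[1].threshold == 3.5

    def test_estimator_end_to_end(self, rng):
        universe = [f"g{i}" for i in range(200)]
        promoters = generate_promoters(universe, rng, length=300)
        cands = universe[:20]
        planted = generate_promoters(cands, rng, length=300,
                                     plant_motif=HNF4_CONSENSUS, plant_frac=0.7)
        promoters.update(planted)
        pma = PromoterMotifAnalysis().fit(
            promoters, [Motif(name="HNF-4", consensus=HNF4_CONSENSUS),
                        Motif(name="EBOX", consensus="CANNTG")],
            cands, reference_genes=universe)
        assert "HNF-4" in pma.significant_
        assert "EBOX" not in pma.significant_
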
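"""Alignment, site counts, Jin-Nei / Kimura corrections, distance tables."""

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitopair as mp
from mitopair.distances import (
    KIMURA_MAX_P,
    AlignedPair,
    PairCounts,
    align_pair,
    gene_distance_table,
    group_averages,
    jin_nei_gamma,
    kimura_protein,
    pair_counts,
)


def exhaustive_best_score(a, b, match=1.0, mismatch=-1.0, open_=-5.0, ext=-1.0):
    """Best global affine-gap score by recursive enumeration of alignments.

    The first base of a gap run costs ``open_``, each later base ``ext`` —
    the same convention as the production aligner, implemented independently.
    """

    @lru_cache(maxsize=None)
    def go(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1, 0))
        if j < len(b):
            best = max(best, (ext if state == 1 else open_) + go(i, j + 1, 1))
        if i < len(a):
            best = max(best, (ext if state == 2 else open_) + go(i + 1, j, 2))
        return best

    return go(0, 0, 0)


class TestAlignPair:
    def test_identical_sequences_align_gapless(self):
        pair = align_pair("ACGTACGT", "ACGTACGT")
        assert pair.a == pair.b == "ACGTACGT"

    def test_single_gap_example(self):
        pair = align_pair("ACGT", "ACT")
        assert "-" in pair.b
        assert len(pair.a) == 4

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_matches_exhaustive_oracle(self, a, b):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score, aligner.extend_gap_score = -5, -1
        assert aligner.score(a, b) == pytest.approx(exhaustive_best_score(a, b))

    def test_mismatched_length_pair_rejected(self):
        with pytest.raises(ValueError):
            AlignedPair("ACGT", "ACG")


class TestPairCounts:
    def test_identical_pair_all_zero(self):
        c = pair_counts(AlignedPair("A" * 100, "A" * 100))
        assert (c.p, c.P, c.Q) == (0.0, 0.0, 0.0)
        assert c.n == 100

    def test_hand_built_ten_columns(self):
        # one transition (A->G), one transversion (C->A), eight identities
        a = "ACGTACGTAC"
        b = "GAGTACGTAC"
        c = pair_counts(AlignedPair(a, b))
        assert c.P == pytest.approx(0.1)
        assert c.Q == pytest.approx(0.1)
        assert c.p == pytest.approx(0.2)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        c = pair_counts(AlignedPair("AC-GN", "ACTGA"))
        assert c.n == 3  # gap and N columns dropped

    def test_all_gap_columns_raise(self):
        with pytest.raises(ValueError):
            pair_counts(AlignedPair("---", "AAA"))

    def test_transitions_and_transversions_partition_differences(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = "".join(rng.choice(list("ACGT"), size=500))
        c = pair_counts(AlignedPair(a, b))
        assert c.P + c.Q == pytest.approx(c.p)


class TestJinNei:
    def test_zero_divergence(self):
        assert jin_nei_gamma(PairCounts(100, 0.0, 0.0, 0.0)) == 0.0

    def test_closed_form_example(self):
        # (1/2) (1/0.75 + 0.5/0.9 - 1.5) = 0.194444...
        d = jin_nei_gamma(PairCounts(1000, 0.15, 0.10, 0.05), a=1.0)
        assert d == pytest.approx(19.4444, abs=5e-3)

    def test_gamma_shape_changes_correction(self):
        c = PairCounts(1000, 0.3, 0.2, 0.1)
        assert jin_nei_gamma(c, a=0.5) > jin_nei_gamma(c, a=1.0) > 0

    def test_too_divergent_is_nan(self):
        assert math.isnan(jin_nei_gamma(PairCounts(10, 0.8, 0.45, 0.35)))
        assert math.isnan(jin_nei_gamma(PairCounts(10, 0.9, 0.4, 0.5)))

    def test_invalid_shape_raises(self):
        with pytest.raises(ValueError):
            jin_nei_gamma(PairCounts(10, 0.1, 0.05, 0.05), a=0.0)

    @given(st.floats(0.0, 0.35), st.floats(0.0, 0.35))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_correction_dominates_p_distance(self, P, Q):
        c = PairCounts(1000, P + Q, P, Q)
        d = jin_nei_gamma(c)
        if not math.isnan(d):
            assert d >= 100.0 * c.p - 1e-9


class TestKimuraProtein:
    def test_zero(self):
        assert kimura_protein(PairCounts(10, 0.0, 0, 0)) == 0.0

    def test_closed_form_example(self):
        # -ln(1 - 0.2 - 0.2*0.04) = -ln(0.792)
        d = kimura_protein(PairCounts(100, 0.2, 0, 0))
        assert d == pytest.approx(23.3190, abs=5e-3)

    def test_divergence_threshold(self):
        assert KIMURA_MAX_P == pytest.approx(0.854101966, abs=1e-8)
        assert math.isnan(kimura_protein(PairCounts(100, KIMURA_MAX_P + 1e-6, 0, 0)))
        assert math.isfinite(kimura_protein(PairCounts(100, KIMURA_MAX_P - 1e-6, 0, 0)))

    @given(st.floats(0.0, 0.8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_correction_dominates_p_distance(self, p):
        assert kimura_protein(PairCounts(100, p, 0, 0)) >= 100.0 * p - 1e-9


class TestGeneDistanceTable:
    def test_genome_vs_itself_is_zero(self, sim_genome):
        g, _ = sim_genome
        tab = gene_distance_table(g, g).set_index("label")
        assert (tab["p_distance"].fillna(0) == 0).all()
        assert (tab["jn_distance"].fillna(0) == 0).all()

    def test_symmetry(self, sim_pair):
        f, m, _ = sim_pair
        ab = gene_distance_table(f, m).set_index("label")["jn_distance"]
        ba = gene_distance_table(m, f).set_index("label")["jn_distance"]
        assert np.allclose(ab.fillna(-1), ba.fillna(-1), atol=1e-9)

    def test_pair_distances_scale_with_divergence(self, sim_pair):
        f, m, _ = sim_pair
        tab = gene_distance_table(f, m).set_index("label")
        assert tab.loc["All coding DNA", "jn_distance"] > \
            tab.loc["All coding DNA", "p_distance"]
        assert tab.loc["PCGs", "kimura_aa"] > 0

    def test_missing_gene_flagged_absent(self, sim_genome):
        g, _ = sim_genome
        feats = [f for f in g.features if f.name != "atp8"]
        g2 = mp.AnnotatedGenome("noatp8", g.sequence, feats)
        tab = gene_distance_table(g, g2).set_index("label")
        assert math.isnan(tab.loc["atp8", "jn_distance"])

    def test_estimator_recovery_at_three_distances(self):
        for d in (0.05, 0.2, 0.5):
            est = []
            for s in range(30):
                cfg = mp.SimConfig(
                    seed=1000 + s,
                    divergence=mp.DivergenceSpec(expected_distance=d),
                )
                _, counts = mp.make_aligned_pair(cfg, n=4000)
                est.append(jin_nei_gamma(counts) / 100.0)
            est = np.array(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - d) < 3 * max(se, 1e-4)


class TestGroupAverages:
    def test_singleton_group_is_the_row(self, distance_table):
        out = group_averages(distance_table[["nt_all_coding"]],
                             {"solo": ["Meretrix lamarckii"]})
        assert out.iloc[0, 0] == pytest.approx(49.65)

    def test_empty_group_raises(self, distance_table):
        with pytest.raises(ValueError):
            group_averages(distance_table[["nt_all_coding"]], {"none": []})

    def test_missing_cells_skipped(self, distance_table):
        # atp8 is unannotated for several mussels: the mean divides by the
        # number of present values only
        members = list(distance_table.index[
            distance_table["group"] == "Amarsipobranchia"])
        out = group_averages(distance_table[["nt_atp8"]],
                             {"Amarsipobranchia": members})
        present = distance_table.loc[members, "nt_atp8"].dropna()
        assert out.iloc[0, 0] == pytest.approx(present.mean())
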
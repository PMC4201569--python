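import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcpintron.evodist import (
    SaturatedDistance,
    average_distance,
    chimera_screen,
    global_percent_similarity,
    nei_gojobori_dnds,
    pairwise_distance,
    percent_similarity,
)
from spcpintron.seqio import SequenceRecord


def _mutate(seq: str, n_ts: int, n_tv: int) -> str:
    """Apply transitions then transversions at distinct leading positions."""
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for i in range(n_ts):
        out[i] = ts_map[out[i]]
    for i in range(n_ts, n_ts + n_tv):
        out[i] = tv_map[out[i]]
    return "".join(out)


BASE = ("ACGT" * 50)  # 200 nt, balanced composition


class TestClosedFormDistances:
    @pytest.mark.parametrize("model", ["p", "F81", "K80", "K80G", "HKY85"])
    def test_identical_sequences_have_zero_distance(self, model):
        d = pairwise_distance(BASE, BASE, model=model, alpha=1.0)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_k80_formula_value(self):
        # P=0.1, Q=0.05 -> -1/2 ln(0.75) - 1/4 ln(0.9)
        seq = _mutate(BASE, 20, 10)
        assert pairwise_distance(BASE, seq, model="K80") == pytest.approx(
            0.17018, abs=5e-5
        )

    def test_k80_gamma_formula_value(self):
        seq = _mutate(BASE, 20, 10)
        assert pairwise_distance(
            BASE, seq, model="K80G", alpha=1.0
        ) == pytest.approx(0.19444, abs=5e-5)

    def test_f81_equal_frequencies_reduces_to_jc(self):
        seq = _mutate(BASE, 20, 10)  # p = 0.15, pi_i = 1/4 -> B = 3/4
        expected = -0.75 * math.log(1 - 4 * 0.15 / 3)
        assert pairwise_distance(BASE, seq, model="F81") == pytest.approx(
            expected, abs=1e-3
        )

    def test_gamma_needs_positive_alpha(self):
        with pytest.raises(ValueError):
            pairwise_distance(BASE, BASE, model="K80G", alpha=0.0)
        with pytest.raises(ValueError):
            pairwise_distance(BASE, BASE, model="K80G")

    def test_saturation_flagged(self):
        # maximal transition divergence: every site changed by a transition
        seq = _mutate(BASE, 140, 0)
        with pytest.raises(SaturatedDistance):
            pairwise_distance(BASE, seq, model="K80")

    def test_gaps_and_ambiguity_excluded_pairwise(self):
        a = "ACGTN-ACGT"
        b = "ACGTAAACGA"
        # comparable columns: 8 (N and gap dropped), one mismatch
        assert pairwise_distance(a, b, model="p") == pytest.approx(1 / 8)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_corrections_never_below_p_distance(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(
            c if rng.random() > 0.15 else str(rng.choice(list("ACGT")))
            for c in a
        )
        p = pairwise_distance(a, b, model="p")
        for model, kw in (("F81", {}), ("K80", {}), ("K80G", {"alpha": 2.0})):
            try:
                d = pairwise_distance(a, b, model=model, **kw)
            except SaturatedDistance:
                continue
            assert d >= p - 1e-9

    def test_k80_gamma_converges_to_k80_for_large_alpha(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=400))
            b = "".join(
                c if rng.random() > 0.1 else str(rng.choice(list("ACGT")))
                for c in a
            )
            k80 = pairwise_distance(a, b, model="K80")
            k80g = pairwise_distance(a, b, model="K80G", alpha=1e6)
            assert abs(k80g - k80) < 1e-6

    def test_hky_equals_k80_under_equal_frequencies(self):
        seq = _mutate(BASE, 20, 10)  # BASE has exactly equal base frequencies
        k80 = pairwise_distance(BASE, seq, model="K80")
        hky = pairwise_distance(BASE, seq, model="HKY85")
        assert hky == pytest.approx(k80, abs=2e-3)


class TestAverageDistance:
    def test_identical_pair_average_zero(self):
        recs = [SequenceRecord("a", BASE), SequenceRecord("b", BASE)]
        res = average_distance(recs, model="K80")
        assert res.average == 0.0

    def test_three_sequence_mean_matches_hand_computed_pairs(self):
        s1 = BASE
        s2 = _mutate(BASE, 8, 4)
        s3 = _mutate(BASE, 0, 12)
        recs = [SequenceRecord(x, s) for x, s in zip("abc", (s1, s2, s3))]
        res = average_distance(recs, model="K80")
        expected = np.mean(
            [
                pairwise_distance(x, y, model="K80")
                for x, y in ((s1, s2), (s1, s3), (s2, s3))
            ]
        )
        assert res.average == pytest.approx(float(expected))
        assert np.allclose(res.matrix, res.matrix.T)
        assert np.all(np.diag(res.matrix) == 0)


class TestPercentSimilarity:
    def test_identity_is_100(self):
        assert percent_similarity(BASE, BASE) == 100.0

    def test_nine_of_ten_comparable_columns(self):
        assert percent_similarity("ACGTACGTA-", "ACGTACGTT-") == pytest.approx(
            88.8889, abs=1e-3
        )
        assert percent_similarity("ACGTACGTAC", "ACGTACGTTC") == 90.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError):
            percent_similarity("---", "AAA"[0:3].replace("A", "-"))

    def test_global_variant_handles_unaligned_input(self):
        assert global_percent_similarity("ACGTACGT", "ACGTACGT") == 100.0


class TestNeiGojobori:
    def test_identical_cds_has_no_substitutions(self):
        r = nei_gojobori_dnds("ATGAAACCC", "ATGAAACCC")
        assert r.Sd == 0 and r.Nd == 0
        assert r.ratio is None  # dS == 0

    def test_single_synonymous_change(self):
        r = nei_gojobori_dnds("ATGAAA", "ATGAAG")
        assert r.Sd == 1 and r.Nd == 0
        assert r.dN == 0
        assert r.ratio == 0
        # site counts: ATG contributes 0 syn sites, AAA/AAG 1/3 each
        assert r.S_sites == pytest.approx(1 / 3)
        assert r.N_sites == pytest.approx(6 - 1 / 3)

    def test_symmetry(self):
        a = "ATGAAAGCCTGGTTTCAA"
        b = "ATGAAGGCATGGTTCCAG"
        r1 = nei_gojobori_dnds(a, b)
        r2 = nei_gojobori_dnds(b, a)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.Nd == pytest.approx(r2.Nd)
        assert r1.S_sites == pytest.approx(r2.S_sites)

    def test_sites_sum_to_three_per_codon(self):
        a = "ATGAAAGCCTGGTTTCAA"
        r = nei_gojobori_dnds(a, a)
        assert r.S_sites + r.N_sites == pytest.approx(len(a))

    def test_multi_hit_codon_path_averaging(self):
        # TTT (Phe) vs TTA (Leu) single nonsyn; plus AAA->GAG double hit:
        # paths AAA->GAA(Glu)->GAG(Glu): nonsyn+syn; AAA->AAG(Lys)->GAG: syn+nonsyn
        r = nei_gojobori_dnds("AAA", "GAG")
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(1.0)

    def test_gapped_codons_skipped(self):
        r = nei_gojobori_dnds("ATG---AAA", "ATGCCCAAA")
        assert r.S_sites + r.N_sites == pytest.approx(6)


class TestChimeraScreen:
    def _refs(self, rng, length=300, divergence=0.1):
        a = "".join(rng.choice(list("ACGT"), size=length))
        b = "".join(
            c if rng.random() > divergence else str(rng.choice(list("ACGT")))
            for c in a
        )
        return (
            SequenceRecord("refA", a),
            SequenceRecord("refB", b),
        )

    def test_clone_identical_to_reference_is_clean(self):
        rng = np.random.default_rng(0)
        ra, rb = self._refs(rng)
        clone = SequenceRecord("clone", ra.residues)
        (call,) = chimera_screen([clone], [ra, rb])
        assert not call.chimeric

    def test_constructed_recombinant_detected_near_breakpoint(self):
        rng = np.random.default_rng(1)
        ra, rb = self._refs(rng)
        half = 150
        clone = SequenceRecord("rec", ra.residues[:half] + rb.residues[half:])
        (call,) = chimera_screen([clone], [ra, rb])
        assert call.chimeric
        assert call.parents == ("refA", "refB")
        assert abs(call.breakpoint - half) <= 30

    def test_star_phylogeny_clone_not_flagged(self):
        rng = np.random.default_rng(2)
        centre = "".join(rng.choice(list("ACGT"), size=300))

        def radiate(seed):
            r = np.random.default_rng(seed)
            return "".join(
                c if r.random() > 0.05 else str(r.choice(list("ACGT")))
                for c in centre
            )

        refs = [SequenceRecord(f"r{i}", radiate(i)) for i in range(4)]
        clone = SequenceRecord("c", radiate(99))
        (call,) = chimera_screen([clone], refs)
        assert not call.chimeric
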
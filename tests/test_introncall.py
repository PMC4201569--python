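import numpy as np
import pytest

from spcpintron import simdata
from spcpintron.introncall import (
    IntronCallParams,
    JunctionWindow,
    UnpairableError,
    align_pair,
    call_introns,
    call_orthology,
    junction_consensus,
    phase_and_context,
    splice,
    star_msa,
)
from spcpintron.seqio import CodingAnnotation, SequenceRecord

from oracles import gotoh_global, valid_insertion_placements


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignPair:
    def test_identical_sequences_have_no_insertions(self):
        rng = np.random.default_rng(0)
        s = _rand_dna(rng, 150)
        aln = align_pair(SequenceRecord("g", s), SequenceRecord("c", s))
        assert aln.insertions() == []
        assert aln.identity() == 1.0

    def test_single_constructed_insertion_recovered(self):
        rng = np.random.default_rng(1)
        x, y = _rand_dna(rng, 80), _rand_dna(rng, 60)
        intron = _rand_dna(rng, 61)
        genomic = x + intron + y
        aln = align_pair(SequenceRecord("g", genomic), SequenceRecord("c", x + y))
        ins = aln.insertions()
        assert len(ins) == 1
        s, e, cpos = ins[0]
        assert e - s == 61
        # excising the reported span reproduces the cDNA
        assert genomic[:s] + genomic[e:] == x + y

    def test_score_matches_independent_affine_dp(self):
        """The library alignment must be optimal under its own scoring —
        checked against a hand-written Gotoh DP on small inputs."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            c = _rand_dna(rng, 90)
            g = c[:40] + _rand_dna(rng, 70) + c[40:]
            p = IntronCallParams()
            aln = align_pair(SequenceRecord("g", g), SequenceRecord("c", c), p)
            expected = gotoh_global(
                g, c, match=p.match_score, mismatch=p.mismatch_score,
                gap_open=p.open_gap_score, gap_extend=p.extend_gap_score,
            )
            assert aln.score == pytest.approx(expected)

    def test_unrelated_sequences_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(UnpairableError):
            align_pair(
                SequenceRecord("g", _rand_dna(rng, 200)),
                SequenceRecord("c", _rand_dna(rng, 150)),
            )

    def test_cdna_found_inside_longer_flanked_cassette(self):
        rng = np.random.default_rng(4)
        cds = _rand_dna(rng, 120)
        genomic = _rand_dna(rng, 300) + cds + _rand_dna(rng, 250)
        aln = align_pair(SequenceRecord("g", genomic), SequenceRecord("c", cds))
        assert aln.insertions() == []  # flanks are not insertions


class TestCallIntrons:
    def test_zero_insertions_gives_no_calls(self):
        rng = np.random.default_rng(5)
        s = _rand_dna(rng, 120)
        aln = align_pair(SequenceRecord("g", s), SequenceRecord("c", s))
        assert call_introns(aln).introns == []

    def test_constructed_phase0_intron_with_boundary_enumeration_oracle(self):
        """The documented 68-nt toy: cdna ATGCAG|GGTTTCTAA, intron
        gc + 56*t + cag inserted at offset 6."""
        cdna = "ATGCAGGGTTTCTAA"
        genomic = "ATGCAG" + "gc" + "t" * 56 + "cag" + "GGTTTCTAA"
        toy = IntronCallParams(min_intron_len=50, min_anchors=1, kmer=6)
        aln = align_pair(SequenceRecord("g", genomic), SequenceRecord("c", cdna), toy)
        res = call_introns(aln, CodingAnnotation(0, 15), toy)
        assert len(res.introns) == 1
        ic = res.introns[0]
        assert (ic.genomic_start, ic.genomic_end) == (6, 67)
        assert ic.cds_insert_pos == 6
        assert ic.phase == 0
        # oracle: among all equivalent excisions, [6, 67) must be valid
        assert (6, 67) in valid_insertion_placements(genomic.upper(), cdna, 61)

    def test_boundary_sliding_prefers_best_consensus_leftmost(self):
        """An intron flanked by a repeated base can slide; the caller must
        pick the placement maximizing the gy...sag consensus, leftmost on
        ties — verified against exhaustive placement enumeration."""
        cdna = "ATGCCCGGGTTTAAACCCTTTGGGACGT"
        # intron gtaaa...cag inserted after position 12; 'a' repeats allow sliding
        intron = "gt" + "a" * 55 + "cag"
        genomic = cdna[:12] + intron + cdna[12:]
        aln = align_pair(
            SequenceRecord("g", genomic), SequenceRecord("c", cdna),
            IntronCallParams(min_anchors=1),
        )
        res = call_introns(aln, params=IntronCallParams(min_intron_len=50, min_anchors=1))
        (ic,) = res.introns
        placements = valid_insertion_placements(genomic.upper(), cdna, len(intron))

        def score(s, e):
            g = genomic.upper()
            donor = sum(p == b or (p, b) == ("Y", "C") or (p, b) == ("Y", "T")
                        for p, b in zip("GY", g[s:s + 2]))
            acc = sum(p == b or (p, b) == ("S", "C") or (p, b) == ("S", "G")
                      for p, b in zip("SAG", g[e - 3:e]))
            return donor + acc

        best = max(score(s, e) for s, e in placements)
        expected = min((s, e) for s, e in placements if score(s, e) == best)
        assert (ic.genomic_start, ic.genomic_end) == expected
        assert ic.consensus_score == best

    def test_short_insertion_reported_as_indel(self):
        cdna = "ATGCCCGGGTTTAAACCCTTTGGGACGTACGTACGTACGTGGCCTTAA"
        genomic = cdna[:20] + "GCCGCC" + cdna[20:]
        aln = align_pair(
            SequenceRecord("g", genomic), SequenceRecord("c", cdna),
            IntronCallParams(min_anchors=1),
        )
        res = call_introns(aln, params=IntronCallParams(min_intron_len=50, min_anchors=1))
        assert res.introns == []
        assert len(res.indels) == 1
        s, e = res.indels[0]
        assert e - s == 6

    def test_splicing_invariant_on_simulated_pairs(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        for g in long_dataset.genomic:
            aln = align_pair(g, cdna[g.id])
            res = call_introns(aln)
            spliced = splice(g.upper, res.introns)
            assert cdna[g.id].upper in spliced

    def test_recovers_truth_coordinates(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        for g in long_dataset.genomic:
            res = call_introns(align_pair(g, cdna[g.id]))
            truth = long_dataset.truth.for_taxon(g.id)
            assert [(ic.genomic_start, ic.genomic_end) for ic in res.introns] \
                == [(t.genomic_start, t.genomic_end) for t in truth]
            assert [ic.phase for ic in res.introns] == [t.phase for t in truth]


class TestPhaseAndContext:
    def test_codon_boundary_insertion_is_phase_zero(self, short_dataset):
        cdna = {r.id: r for r in short_dataset.cdna}
        g = next(r for r in short_dataset.genomic if r.id == "Smicro")
        res = call_introns(align_pair(g, cdna["Smicro"]))
        (ic,) = res.introns
        ann = CodingAnnotation(
            0, len(cdna["Smicro"].residues),
            signal_len_aa=short_dataset.config.signal_len_aa,
            transit_len_aa=short_dataset.config.transit_len_aa,
        )
        phase, host_aa, mature = phase_and_context(ic, ann)
        assert phase == 0
        assert host_aa == ("K", "A")  # between lysine and alanine codons
        assert mature == (42, 43)

    def test_phase1_glycine_at_mature_33(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        g = next(r for r in long_dataset.genomic if r.id == "Dstok28")
        res = call_introns(align_pair(g, cdna["Dstok28"]))
        intron2 = res.introns[1]
        ann = CodingAnnotation(
            0, len(cdna["Dstok28"].residues),
            signal_len_aa=24, transit_len_aa=28,
        )
        phase, host_aa, mature = phase_and_context(intron2, ann)
        assert phase == 1
        assert host_aa == "G"
        assert mature == 33

    def test_out_of_cds_position_rejected(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        g = long_dataset.genomic[0]
        (ic, _) = call_introns(align_pair(g, cdna[g.id])).introns
        ann = CodingAnnotation(0, 30)
        with pytest.raises(ValueError):
            phase_and_context(ic, ann, cds_len=30)


class TestJunctionConsensus:
    def test_single_window_is_its_own_consensus(self):
        w = JunctionWindow("donor", "AAG", "gt")
        donor, acceptor = junction_consensus([w])
        assert donor == "AAG|gt"
        assert acceptor is None

    def test_two_donor_example(self):
        donor, _ = junction_consensus(
            [JunctionWindow("donor", "AAG", "GT"),
             JunctionWindow("donor", "CTG", "GC")]
        )
        assert donor == "MWG|gy"

    def test_order_independence_and_idempotence(self):
        ws = [
            JunctionWindow("donor", "CTG", "gt"),
            JunctionWindow("donor", "CAG", "gc"),
            JunctionWindow("donor", "AAG", "gt"),
        ]
        d1, _ = junction_consensus(ws)
        d2, _ = junction_consensus(list(reversed(ws)))
        assert d1 == d2 == "MWG|gy"
        # feeding the consensus back in changes nothing
        cons = JunctionWindow("donor", d1.split("|")[0], d1.split("|")[1])
        d3, _ = junction_consensus([cons])
        assert d3 == d1

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            junction_consensus([])


class TestOrthology:
    def test_intron_vs_itself_is_orthologous(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        g = long_dataset.genomic[0]
        res = call_introns(align_pair(g, cdna[g.id]))
        ic = res.introns[0]
        other = call_introns(align_pair(g, cdna[g.id])).introns[0]
        msa = {g.id: cdna[g.id].residues}
        oc = call_orthology(ic, other, msa)
        # same taxon alignment row; identical intron
        assert oc.same_position and oc.junction_compatible
        assert oc.intron_identity == 1.0
        assert oc.orthologous

    def test_descendants_of_one_gain_are_orthologous(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        calls = {
            g.id: call_introns(align_pair(g, cdna[g.id])).introns
            for g in long_dataset.genomic
        }
        msa = star_msa(long_dataset.cdna)
        a = calls["Dstok28"][0]
        b = calls["Dstrig102"][0]
        oc = call_orthology(a, b, msa)
        assert oc.orthologous

    def test_different_introns_not_orthologous(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        calls = call_introns(
            align_pair(long_dataset.genomic[0], cdna[long_dataset.genomic[0].id])
        ).introns
        msa = star_msa(long_dataset.cdna)
        oc = call_orthology(calls[0], calls[1], msa)
        assert not oc.same_position
        assert not oc.orthologous

    def test_missing_taxon_is_error(self, long_dataset):
        cdna = {r.id: r for r in long_dataset.cdna}
        calls = call_introns(
            align_pair(long_dataset.genomic[0], cdna[long_dataset.genomic[0].id])
        ).introns
        with pytest.raises(ValueError, match="missing"):
            call_orthology(calls[0], calls[1], {"nobody": "ACGT"})
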
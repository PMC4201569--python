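import numpy as np
import pytest

from spcpintron import simdata
from spcpintron.evodist import nei_gojobori_dnds
from spcpintron.phylo import Tree
from spcpintron.seqio import iupac_matches, translate
from spcpintron.simdata import (
    GainEvent,
    build_root_cds,
    default_long_config,
    default_short_config,
    emit_dataset,
    plant_intron,
    simulate_cds_evolution,
)


class TestSimulateCdsEvolution:
    def test_zero_length_branches_leave_tips_identical(self):
        root = build_root_cds(np.random.default_rng(0), 100, {})
        tips = simulate_cds_evolution(root, "(a:0,b:0);", seed=1)
        assert tips["a"] == tips["b"] == root

    def test_omega_zero_means_no_nonsynonymous_change(self):
        root = build_root_cds(np.random.default_rng(1), 200, {})
        tips = simulate_cds_evolution(root, "(a:0.1,b:0.1);", omega=0.0, seed=2)
        pa = translate_str(tips["a"])
        pb = translate_str(tips["b"])
        assert pa == pb
        assert tips["a"] != tips["b"]  # synonymous change did happen

    def test_no_stops_introduced(self):
        root = build_root_cds(np.random.default_rng(2), 150, {})
        tips = simulate_cds_evolution(root, "(a:0.3,b:0.3);", seed=3)
        for s in tips.values():
            translate_str(s)  # raises on internal stop

    def test_deterministic_per_seed(self):
        root = build_root_cds(np.random.default_rng(3), 120, {})
        t1 = simulate_cds_evolution(root, "(a:0.05,b:0.05);", seed=7)
        t2 = simulate_cds_evolution(root, "(a:0.05,b:0.05);", seed=7)
        assert t1 == t2

    def test_stop_in_root_rejected(self):
        with pytest.raises(ValueError):
            simulate_cds_evolution("ATGTAAAAATAA", "(a:0.1,b:0.1);")


def translate_str(cds: str) -> str:
    from spcpintron.seqio import SequenceRecord

    return translate(SequenceRecord("x", cds)).residues


class TestPlantIntron:
    def test_same_intron_inserted_at_motif_in_all_tips(self):
        rng = np.random.default_rng(5)
        root = build_root_cds(rng, 120, {60: "AAG", 61: "GCC"})
        ev = GainEvent(
            branch="a", intron_id="i", length_range=(60, 80),
            insert_offset=183,
        )
        seqs, coords = plant_intron({"a": root, "b": root}, ev, seed=1)
        for taxon in ("a", "b"):
            s, e, cpos, phase = coords[taxon]
            assert phase == 0
            assert seqs[taxon][:s] + seqs[taxon][e:] == root
            intron = seqs[taxon][s:e]
            assert intron[:2] == "gt" and intron[-3:] == "cag"
            assert 60 <= len(intron) <= 80

    def test_missing_motif_reports_candidates(self):
        ev = GainEvent(branch="a", intron_id="i", length_range=(60, 80),
                       target_motif="MAGG")
        with pytest.raises(ValueError, match="absent|candidates"):
            plant_intron({"a": "ATGTTTTTTTTTTTTTGA"}, ev)


class TestEmitDataset:
    def test_same_config_and_seed_byte_identical(self, tmp_path):
        d1 = emit_dataset(default_long_config(3))
        d2 = emit_dataset(default_long_config(3))
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for name in ("genomic.fasta", "cdna.fasta", "proteins.fasta",
                     "tree.nwk", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_intron_lengths_within_study_ranges(self, long_dataset):
        for t in long_dataset.truth.introns:
            lo, hi = {"intron1": (209, 264), "intron2": (297, 412)}[t.intron_id]
            assert lo <= t.length <= hi

    def test_splicing_truth_invariant(self, long_dataset, short_dataset):
        for ds in (long_dataset, short_dataset):
            cdna = {r.id: r.residues for r in ds.cdna}
            for g in ds.genomic:
                spliced = g.residues
                for t in sorted(ds.truth.for_taxon(g.id),
                                key=lambda x: -x.genomic_start):
                    spliced = spliced[: t.genomic_start] + spliced[t.genomic_end :]
                assert cdna[g.id] in spliced.upper()

    def test_gain_branch_controls_which_tips_carry_intron(self, short_dataset):
        carriers = {t.taxon for t in short_dataset.truth.introns}
        assert carriers == {"Smicro"}

    def test_exon_architecture_of_long_config(self, long_dataset):
        """Tips without signal-peptide indels reproduce the 127/126/845
        exon layout."""
        for g in long_dataset.genomic:
            truth = sorted(long_dataset.truth.for_taxon(g.id),
                           key=lambda t: t.genomic_start)
            i1, i2 = truth
            cds_len = len(next(r for r in long_dataset.cdna if r.id == g.id).residues)
            exon2 = i2.cds_insert_pos - i1.cds_insert_pos
            exon3 = cds_len - i2.cds_insert_pos
            assert exon2 == 126
            assert exon3 == 845
            if cds_len == 1098:  # no net indel
                assert i1.cds_insert_pos == 127

    def test_junction_fourmers_match_configured_motifs(self, long_dataset):
        cdna = {r.id: r.residues for r in long_dataset.cdna}
        motifs = {"intron1": "MWGG", "intron2": "MAGG"}
        for t in long_dataset.truth.introns:
            four = cdna[t.taxon][t.cds_insert_pos - 3 : t.cds_insert_pos + 1]
            assert iupac_matches(motifs[t.intron_id], four)

    def test_proteins_are_translations_of_cdna(self, long_dataset):
        for cds, prot in zip(long_dataset.cdna, long_dataset.proteins):
            assert translate(cds).residues == prot.residues

    def test_tandem_array_copies(self):
        cfg = default_long_config(5)
        cfg.copies_per_array = 2
        ds = emit_dataset(cfg)
        for g in ds.genomic:
            per_copy = {t.copy for t in ds.truth.for_taxon(g.id, copy=0)} | {
                t.copy for t in ds.truth.for_taxon(g.id, copy=1)
            }
            assert per_copy == {0, 1}
            # both copies spliceable at truth coordinates
            spliced = g.residues
            rows = [t for t in ds.truth.introns if t.taxon == g.id]
            for t in sorted(rows, key=lambda x: -x.genomic_start):
                spliced = spliced[: t.genomic_start] + spliced[t.genomic_end :]
            assert ds.config is cfg

    def test_invalid_gain_branch_rejected(self):
        cfg = default_long_config(0)
        with pytest.raises(ValueError, match="not on tree"):
            simdata.SyntheticConfig(
                tree=cfg.tree, root_cds=cfg.root_cds,
                gain_events=[GainEvent(branch="nope", intron_id="x",
                                       length_range=(100, 120))],
            )


class TestStudyConditions:
    def test_realized_divergence_matches_study_levels(self):
        """Between-lineage cassette and CDS similarity and dN/dS of the
        default generator sit at the levels the defaults encode."""
        from spcpintron.evodist import global_percent_similarity
        from spcpintron.introncall import star_msa

        sims_cass, sims_cds, ratios = [], [], []
        for seed in (21, 22, 23):
            ds = emit_dataset(default_long_config(seed))
            genomic = {r.id: r for r in ds.genomic}
            cdna = {r.id: r for r in ds.cdna}
            for a, b in (("Dstok28", "Dstrig102"), ("Dstok28", "HIAp"),
                         ("Ap1", "Dstrig102"), ("Ap1", "HIAp")):
                sims_cass.append(global_percent_similarity(
                    genomic[a].residues, genomic[b].residues))
                sims_cds.append(global_percent_similarity(
                    cdna[a].residues, cdna[b].residues))
                msa = star_msa([cdna[a], cdna[b]])
                r = nei_gojobori_dnds(msa[a], msa[b])
                if r.ratio is not None:
                    ratios.append(r.ratio)
        assert np.mean(sims_cass) == pytest.approx(93.4, abs=1.0)
        assert np.mean(sims_cds) == pytest.approx(96.6, abs=0.7)
        assert np.mean(ratios) == pytest.approx(0.14, abs=0.03)

    def test_short_config_exons(self, short_dataset):
        (t,) = short_dataset.truth.for_taxon("Smicro")
        assert t.cds_insert_pos == 282
        assert t.phase == 0
        assert 108 <= t.length <= 117
        cds_len = len(next(r for r in short_dataset.cdna
                           if r.id == "Smicro").residues)
        assert cds_len - t.cds_insert_pos == 330

    def test_gain_loss_recovery_on_emitted_tree(self, short_dataset):
        """End-to-end: the emitted presence/absence pattern implies one
        gain on the configured branch."""
        from spcpintron.phylo import CharacterMatrix, gain_loss_accounting

        tree = Tree.from_newick(short_dataset.truth.tree)
        carriers = {t.taxon for t in short_dataset.truth.introns}
        m = CharacterMatrix(
            tree.tip_labels(), ["i"],
            {t: ["1" if t in carriers else "0"] for t in tree.tip_labels()},
        )
        res = gain_loss_accounting(tree, m)
        assert res.min_gains == len(short_dataset.config.gain_events)
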
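"""Synthetic-cohort generator: determinism, Mendelian structure, read and
variant statistics, subclone mixture law."""

import math

import numpy as np
import pandas as pd
import pytest

from famseq.capture import TargetRegion
from famseq.linkage import AFFECTED, DiseaseModel, marker_qc
from famseq.readqc import demultiplex, mark_duplicates
from famseq.syndata import (DeletionSpec, PedigreeSpec, SimConfig, TraitModel,
                            TruthSet, default_barcodes, generate_cohort,
                            inject_variants, pooled_fastq,
                            simulate_gene_models, simulate_marker_panel,
                            simulate_pedigree, simulate_reads,
                            simulate_reference_and_genemodel,
                            simulate_subclone_counts, substream)

RNG = lambda s=0: np.random.default_rng(s)

SMALL = dict(region_length=40_000, n_exons=8, mean_depth=30.0, n_families=2)


class TestPedigree:
    def test_full_penetrance_affected_are_carriers(self):
        ped, carriers = simulate_pedigree(PedigreeSpec(3, 2), TraitModel(), RNG(1))
        for iid in ped.members:
            if ped[iid].affection == AFFECTED:
                assert carriers[iid]

    def test_mosaic_fraction_zero_no_carrier_offspring(self):
        trait = TraitModel(mosaic_founder=True, mosaic_fraction=0.0)
        ped, carriers = simulate_pedigree(PedigreeSpec(2, 200), trait, RNG(2))
        assert not any(carriers[i] for i in ped.nonfounders)

    def test_transmission_is_fair_over_many_meioses(self):
        """10,000 meioses from a het carrier: fraction within 3 SE of 1/2."""
        ped, carriers = simulate_pedigree(PedigreeSpec(2, 10_000), TraitModel(),
                                          RNG(3))
        frac = np.mean([carriers[i] for i in ped.nonfounders])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_carrier_bookkeeping_consistent(self):
        """Every non-de-novo carrier child has a constitutional carrier parent."""
        ped, carriers = simulate_pedigree(PedigreeSpec(4, 2), TraitModel(), RNG(4))
        for iid in ped.nonfounders:
            if carriers[iid]:
                ind = ped[iid]
                assert carriers[ind.father] or carriers[ind.mother]

    def test_de_novo_mutation_in_second_generation(self):
        trait = TraitModel(de_novo=True)
        ped, carriers = simulate_pedigree(PedigreeSpec(3, 2), trait, RNG(5))
        assert not carriers["G1-1"] and not carriers["G1-2"]
        assert any(carriers[i] for i in ped.members if i.startswith("G2"))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(PedigreeSpec(1, 2), TraitModel(), RNG(0))
        with pytest.raises(ValueError):
            simulate_pedigree(PedigreeSpec(3, 0), TraitModel(), RNG(0))


class TestReferenceAndGeneModel:
    def test_fifteen_exons(self):
        seq, gene = simulate_reference_and_genemodel(200_000, 15, RNG(0))
        assert gene.n_exons == 15
        assert len(seq) == 200_000

    def test_single_exon_valid(self):
        _, gene = simulate_reference_and_genemodel(10_000, 1, RNG(0))
        assert gene.n_exons == 1

    def test_cds_length_is_concatenated_exon_length(self):
        seq, gene = simulate_reference_and_genemodel(100_000, 10, RNG(1))
        assert gene.cds_length == sum(e - s + 1 for s, e in gene.exons)
        assert gene.cds_length % 3 == 0
        assert len(gene.cds_sequence(seq)) == gene.cds_length

    def test_exons_ordered_disjoint(self):
        _, gene = simulate_reference_and_genemodel(150_000, 12, RNG(2))
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            assert e1 < s2

    def test_unplaceable_exons_raise(self):
        with pytest.raises(ValueError, match="place"):
            simulate_reference_and_genemodel(2_000, 15, RNG(0))


class TestReads:
    CFG = SimConfig(region_length=30_000, mean_depth=50.0, duplicate_rate=0.0,
                    off_target_fraction=0.0)
    TARGETS = [TargetRegion("chrSim", 5_001, 15_000)]

    def test_no_duplicates_all_unique(self):
        reads = simulate_reads("s", self.TARGETS, self.CFG, RNG(0))
        keys = list(zip(reads["contig"], reads["start"], reads["strand"]))
        assert len(keys) == len(set(keys))

    def test_zero_off_target_fraction(self):
        reads = simulate_reads("s", self.TARGETS, self.CFG, RNG(1))
        ends = reads["start"] + reads["length"] - 1
        on = (reads["start"] <= 15_000) & (ends >= 5_001)
        assert on.all()

    def test_off_target_rate_close_to_config(self):
        import dataclasses
        cfg = dataclasses.replace(self.CFG, off_target_fraction=0.39)
        reads = simulate_reads("s", self.TARGETS, cfg, RNG(2))
        ends = reads["start"] + reads["length"] - 1
        on = (reads["start"] <= 15_000) & (ends >= 5_001)
        assert abs((~on).mean() - 0.39) < 0.02

    def test_het_deletion_halves_depth(self):
        """Coverage over the deleted span is ~half, within 3 SE of thinning."""
        import dataclasses
        cfg = dataclasses.replace(self.CFG, mean_depth=100.0)
        deletion = DeletionSpec(7_001, 10_000)
        reads = simulate_reads("s", self.TARGETS, cfg, RNG(3), deletion=deletion)
        ends = reads["start"] + reads["length"] - 1

        def overlap_count(lo, hi):
            return int(((reads["start"] <= hi) & (ends >= lo)).sum())

        in_del = overlap_count(7_001, 10_000)
        control = overlap_count(11_001, 14_000)
        ratio = in_del / control
        n0 = 2 * control  # pre-thinning expectation over the span
        se = math.sqrt(0.25 / n0) * 2  # ratio SE, thinning dominates
        assert abs(ratio - 0.5) < 3 * se + 0.02

    def test_duplicates_at_configured_rate(self):
        import dataclasses
        cfg = dataclasses.replace(self.CFG, duplicate_rate=0.3)
        reads = mark_duplicates(simulate_reads("s", self.TARGETS, cfg, RNG(4)))
        assert abs(reads["duplicate"].mean() - 0.3) < 0.03

    def test_nonpositive_depth_rejected(self):
        import dataclasses
        cfg = dataclasses.replace(self.CFG, mean_depth=0.0)
        with pytest.raises(ValueError):
            simulate_reads("s", self.TARGETS, cfg, RNG(0))


class TestInjectVariants:
    def _setup(self, seed=0):
        rng = RNG(seed)
        seq, gene = simulate_reference_and_genemodel(80_000, 10, rng)
        carriers = {"FA": {"FA.a1": True, "FA.a2": True, "FA.u": False}}
        return seq, gene, carriers, rng

    def test_zero_background_only_causal(self):
        seq, gene, carriers, rng = self._setup()
        calls, catalog, truth = inject_variants(
            carriers, gene, seq, rng, n_known_per_family=0,
            n_novel_per_individual=0.0)
        assert catalog == set()
        assert len(calls["FA"]["FA.a1"]) == 1
        assert calls["FA"]["FA.u"] == []
        assert calls["FA"]["FA.a1"][0].key == (
            truth.causal["FA"].contig, truth.causal["FA"].pos,
            truth.causal["FA"].ref, truth.causal["FA"].alt)

    def test_causal_in_every_carrier_call_set(self):
        seq, gene, carriers, rng = self._setup(1)
        calls, _, truth = inject_variants(carriers, gene, seq, rng)
        key = (truth.causal["FA"].contig, truth.causal["FA"].pos,
               truth.causal["FA"].ref, truth.causal["FA"].alt)
        for iid, is_carrier in carriers["FA"].items():
            present = key in {c.key for c in calls["FA"][iid]}
            assert present == is_carrier

    @pytest.mark.parametrize("klass", ["frameshift", "nonsense", "splice-acceptor"])
    def test_truth_class_matches_request(self, klass):
        seq, gene, carriers, rng = self._setup(2)
        _, _, truth = inject_variants(carriers, gene, seq, rng, classes=[klass],
                                      n_known_per_family=0,
                                      n_novel_per_individual=0.0)
        assert truth.causal["FA"].consequence == klass

    def test_gene_outside_contig_rejected(self):
        seq, gene, carriers, rng = self._setup(3)
        with pytest.raises(ValueError):
            inject_variants(carriers, gene, seq[: gene.start], rng)

    def test_truth_round_trips_through_json(self, tmp_path):
        seq, gene, carriers, rng = self._setup(4)
        _, _, truth = inject_variants(carriers, gene, seq, rng)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthSet.from_json(path)
        assert back.causal == truth.causal
        assert back.carriers == truth.carriers


class TestSubcloneCounts:
    def test_f_zero_is_fair_coin(self):
        ks = simulate_subclone_counts(52, 0.0, RNG(0), size=5000)
        se = math.sqrt(0.25 / (52 * 5000))
        assert abs(ks.mean() / 52 - 0.5) < 3 * se * 52 / 52 + 0.01

    def test_f_one_always_n(self):
        ks = simulate_subclone_counts(52, 1.0, RNG(1), size=200)
        assert (ks == 52).all()

    def test_mixture_law_mean(self):
        """f=0.69, n=52: mean k/n -> (1+f)/2 = 0.845 within 3 SE."""
        reps = 10_000
        ks = simulate_subclone_counts(52, 0.69, RNG(2), size=reps)
        p = 0.845
        se = math.sqrt(p * (1 - p) / (52 * reps))
        assert abs(ks.mean() / 52 - p) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_subclone_counts(0, 0.5, RNG(0))
        with pytest.raises(ValueError):
            simulate_subclone_counts(10, 1.5, RNG(0))


class TestMarkerPanelSimulation:
    def test_mendelian_consistency_and_qc_survival(self):
        ped, carriers = simulate_pedigree(PedigreeSpec(3, 2), TraitModel(), RNG(6))
        panel, causal_bp = simulate_marker_panel(ped, carriers, RNG(7))
        kept, report = marker_qc(panel, ped)
        assert report["n_blanked"].sum() == 0    # genotypes are consistent
        assert len(kept) > 0

    def test_carrier_map_enforced(self):
        ped, carriers = simulate_pedigree(PedigreeSpec(3, 2), TraitModel(), RNG(8))
        panel, causal_bp = simulate_marker_panel(ped, carriers, RNG(9))
        # the disease allele is not in the marker table, but carriers exist
        assert any(carriers.values())
        assert panel.genotypes.notna().all().all()


class TestDeterminismAndConfig:
    def test_identical_seed_identical_cohort(self):
        cfg1 = SimConfig(seed=5, **SMALL)
        cfg2 = SimConfig(seed=5, **SMALL)
        c1, c2 = generate_cohort(cfg1), generate_cohort(cfg2)
        pd.testing.assert_frame_equal(c1.reads, c2.reads)
        assert c1.refseq == c2.refseq
        assert c1.truth.causal == c2.truth.causal
        assert c1.subclone_counts == c2.subclone_counts

    def test_different_seed_differs(self):
        c1 = generate_cohort(SimConfig(seed=5, **SMALL))
        c2 = generate_cohort(SimConfig(seed=6, **SMALL))
        assert not c1.reads.equals(c2.reads)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, deletion=DeletionSpec(100, 200), **SMALL)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg

    @pytest.mark.parametrize("field,value", [
        ("duplicate_rate", 1.5),
        ("off_target_fraction", -0.1),
        ("loh_fraction", 2.0),
        ("region_length", 10),
        ("mean_depth", -1.0),
    ])
    def test_invalid_config_rejected(self, field, value):
        cfg = SimConfig()
        setattr(cfg, field, value)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_substreams_independent(self):
        a1 = substream(1, "reads", "s1").integers(0, 1000, 5)
        a2 = substream(1, "reads", "s1").integers(0, 1000, 5)
        b = substream(1, "reads", "s2").integers(0, 1000, 5)
        assert (a1 == a2).all()
        assert not (a1 == b).all()


class TestBarcodesAndFastq:
    def test_partition_conserves_reads(self, tmp_path):
        cfg = SimConfig(seed=2, region_length=20_000, n_exons=4, mean_depth=5.0)
        rng = substream(2, "ref")
        seq, gene = simulate_reference_and_genemodel(20_000, 4, rng,
                                                     contig=cfg.contig)
        targets = [TargetRegion(cfg.contig, s, e) for s, e in gene.exons]
        frames = [simulate_reads(s, targets, cfg, substream(2, "r", s))
                  for s in ("s1", "s2", "s3")]
        reads = pd.concat(frames, ignore_index=True)
        barcodes = default_barcodes(["s1", "s2", "s3"], 3)
        path = tmp_path / "pool.fastq"
        pooled_fastq(reads, barcodes, seq, path)
        from Bio import SeqIO
        assigned, unassigned = demultiplex(SeqIO.parse(str(path), "fastq"),
                                           barcodes)
        per_sample = reads.groupby("sample").size().to_dict()
        assert {s: len(v) for s, v in assigned.items()} == per_sample
        assert len(unassigned) == 0

    def test_barcodes_distinct_fixed_length(self):
        bcs = default_barcodes([f"s{i}" for i in range(12)], 3)
        assert len(set(bcs.values())) == 12
        assert all(len(b) == 3 for b in bcs.values())
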
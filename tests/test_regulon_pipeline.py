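import math

import numpy as np
import pytest

from regulonscout import (AnnotatedGenome, Gene, build_regulon_matrix,
                          mean_intergenic_distance, motif_from_consensus,
                          predict_operons, revise_operons, search_operon_promoters)
from regulonscout.regulon_pipeline import ABSENT, operons_to_tsv
from regulonscout._dna import reverse_complement
from tests.conftest import random_toy_genome

SITE = "TGTTCAGTCGAACA"


def genome_with_sites(gene_specs, site_positions, length=6000, seed=0):
    """Background contig with genes and consensus sites written at positions."""
    rng = np.random.default_rng(seed)
    arr = list("".join("ACGT"[i] for i in rng.integers(0, 4, length)))
    genes = []
    for gid, start, end, strand in gene_specs:
        cds = ("ATG" + "GCA" * ((end - start - 6) // 3) + "TAA")
        if strand == "-":
            cds = reverse_complement(cds)
        arr[start:end] = list(cds)
        genes.append(Gene(gid, "c1", start, end, strand, None))
    for pos in site_positions:
        arr[pos:pos + len(SITE)] = list(SITE)
    return AnnotatedGenome("t", [("c1", "".join(arr))], genes)


class TestPredictOperons:
    def test_toy_genome_distance_rule(self, toy_genome):
        # distances 50 and 20, mean 35: only the 20 bp gap merges, but the
        # strand switch between g2 and g3 splits regardless
        ops = predict_operons(toy_genome)
        assert [o.gene_ids for o in ops] == [["g1"], ["g2"], ["g3"]]

    def test_overlapping_same_strand_genes_merge(self):
        genome = AnnotatedGenome("t", [("c1", "A" * 2000)],
                                 [Gene("a", "c1", 0, 100, "+"),
                                  Gene("b", "c1", 90, 200, "+"),
                                  Gene("c", "c1", 800, 900, "+")])
        ops = predict_operons(genome)  # mean of (-10, 600) = 295
        assert [o.gene_ids for o in ops] == [["a", "b"], ["c"]]

    def test_strand_switch_always_splits(self):
        genome = AnnotatedGenome("t", [("c1", "A" * 2000)],
                                 [Gene("a", "c1", 0, 100, "+"),
                                  Gene("b", "c1", 101, 200, "-"),
                                  Gene("c", "c1", 1000, 1100, "-")])
        ops = predict_operons(genome)
        # a|b split by strand despite a 1 bp gap; b|c split by distance
        assert [o.gene_ids for o in ops] == [["a"], ["b"], ["c"]]

    def test_minus_strand_operon_lead_is_rightmost_gene(self):
        genome = AnnotatedGenome("t", [("c1", "A" * 2000)],
                                 [Gene("a", "c1", 0, 100, "-"),
                                  Gene("b", "c1", 110, 200, "-"),
                                  Gene("c", "c1", 1500, 1600, "+")])
        ops = predict_operons(genome)
        assert ops[0].gene_ids == ["b", "a"]
        assert ops[0].lead_gene_id == "b"

    def test_matches_brute_force_oracle_on_random_genomes(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            genome = random_toy_genome(rng, n_contigs=int(rng.integers(1, 3)))
            ops = predict_operons(genome)
            mean = mean_intergenic_distance(genome)
            expected = []
            for cid, _ in genome.contigs:
                genes = genome.genes_on(cid)
                run = []
                for g in genes:
                    if run and g.strand == run[-1].strand and mean is not None \
                            and g.start - run[-1].end < mean:
                        run.append(g)
                    else:
                        if run:
                            expected.append(run)
                        run = [g]
                if run:
                    expected.append(run)
            expected_ids = [[g.gene_id for g in (r if r[0].strand == "+" else r[::-1])]
                            for r in expected]
            assert [o.gene_ids for o in ops] == expected_ids
            # gene conservation
            assert sorted(g for o in ops for g in o.gene_ids) == \
                   sorted(g.gene_id for g in genome.genes)


class TestSearchOperonPromoters:
    def test_planted_consensus_reported_at_its_offset(self, verruco_motif):
        genome = genome_with_sites([("a", 1000, 1300, "+")], [1000 - 80])
        ops = search_operon_promoters(genome, predict_operons(genome), verruco_motif)
        (op,) = [o for o in ops if o.lead_gene_id == "a"]
        assert op.best_hit is not None
        assert op.best_hit.score == pytest.approx(verruco_motif.max_score)
        assert op.best_hit.offset == -80
        assert op.best_hit.position == 920

    def test_minus_strand_lead_site_mapped_to_genomic_coordinates(self, verruco_motif):
        genome = genome_with_sites([("a", 1000, 1300, "-")], [])
        # plant at reading offset -80: genomic start = tls - (-80) - 14 + 1
        tls = 1299
        gstart = tls + 80 - 14 + 1
        contig = list(genome.contigs[0][1])
        contig[gstart:gstart + 14] = list(reverse_complement(SITE))
        genome = AnnotatedGenome("t", [("c1", "".join(contig))], genome.genes)
        ops = search_operon_promoters(genome, predict_operons(genome), verruco_motif)
        (op,) = [o for o in ops if o.lead_gene_id == "a"]
        assert op.best_hit.offset == -80
        assert op.best_hit.position == gstart
        assert op.best_hit.score == pytest.approx(verruco_motif.max_score)

    def test_site_before_non_lead_member_does_not_change_operon_hit(self, verruco_motif):
        # far-away gene z raises the genome mean so that a-b merge
        genome = genome_with_sites(
            [("a", 1000, 1300, "+"), ("b", 1310, 1600, "+"), ("z", 5000, 5300, "+")],
            [1310 - 60])
        ops = search_operon_promoters(genome, predict_operons(genome), verruco_motif)
        (op,) = [o for o in ops if "a" in o.gene_ids]
        assert op.gene_ids == ["a", "b"]
        assert op.best_hit is None or op.best_hit.score < verruco_motif.max_score

    def test_window_fully_clamped_away_leaves_no_hit(self, verruco_motif):
        genome = AnnotatedGenome("t", [("c1", "A" * 400)],
                                 [Gene("a", "c1", 0, 300, "+")])
        ops = search_operon_promoters(genome, predict_operons(genome), verruco_motif,
                                      upstream=250, downstream=0)
        assert ops[0].best_hit is None


class TestReviseOperons:
    def make_three_gene_operon(self, site_positions):
        # far-away gene z raises the genome mean so that a-b-c form one operon
        return genome_with_sites(
            [("a", 1000, 1300, "+"), ("b", 1310, 1600, "+"), ("c", 1610, 1900, "+"),
             ("z", 5000, 5300, "+")],
            site_positions)

    def test_internal_site_splits_before_its_gene(self, verruco_motif):
        genome = self.make_three_gene_operon([1310 - 60])
        ops = predict_operons(genome)
        assert ["a", "b", "c"] in [o.gene_ids for o in ops]
        revised = revise_operons(genome, ops, verruco_motif)
        sets = [o.gene_ids for o in revised]
        assert ["a"] in sets and ["b", "c"] in sets

    def test_site_before_lead_gene_only_does_not_split(self, verruco_motif):
        genome = self.make_three_gene_operon([1000 - 60])
        revised = revise_operons(genome, predict_operons(genome), verruco_motif)
        assert ["a", "b", "c"] in [o.gene_ids for o in revised]

    def test_two_internal_sites_reach_three_operons_at_fixpoint(self, verruco_motif):
        genome = self.make_three_gene_operon([1310 - 60, 1610 - 60])
        revised = revise_operons(genome, predict_operons(genome), verruco_motif)
        sets = sorted(o.gene_ids[0] for o in revised if o.gene_ids[0] in "abc")
        assert [o.gene_ids for o in revised if "a" in o.gene_ids] == [["a"]]
        assert ["b"] in [o.gene_ids for o in revised]
        assert ["c"] in [o.gene_ids for o in revised]

    def test_revision_is_idempotent_and_conserves_genes(self, verruco_motif):
        genome = self.make_three_gene_operon([1310 - 60])
        once = revise_operons(genome, predict_operons(genome), verruco_motif)
        twice = revise_operons(genome, once, verruco_motif)
        assert [o.gene_ids for o in once] == [o.gene_ids for o in twice]
        assert sorted(g for o in once for g in o.gene_ids) == \
               sorted(g.gene_id for g in genome.genes)


@pytest.fixture(scope="module")
def analysis(default_community):
    genomes, truth = default_community
    from regulonscout import build_motif
    motif = build_motif(list(truth.sites[truth.sites.role == "primary"].sequence))
    matrix = build_regulon_matrix(genomes, genomes[0], motif, tf_gene_id="sp01_lexA")
    return genomes, truth, motif, matrix


class TestRegulonMatrix:
    def test_core_regulon_rows_score_high_in_all_species(self, analysis):
        genomes, truth, motif, matrix = analysis
        for fam in ["lexA", "recA", "imuA", "imuB", "dnaE2"]:
            for sp in matrix.species:
                v = matrix.cell(f"sp01_{fam}", sp)
                assert v != ABSENT
                assert v >= 0.5  # sites near the analysis maximum

    def test_normalization_endpoints(self, analysis):
        _, _, _, matrix = analysis
        vals = matrix.normalized.values
        vals = vals[~np.isnan(vals)]
        assert vals.max() == pytest.approx(1.0)
        assert vals.min() == pytest.approx(0.0)

    def test_deleted_ortholog_yields_absent_cell(self, default_community):
        from regulonscout import CommunityConfig, build_motif, generate_community
        cfg = CommunityConfig(seed=4, family_absence={"sp02": {"fam003"}})
        genomes, truth = generate_community(cfg)
        motif = build_motif(list(truth.sites[truth.sites.role == "primary"].sequence))
        matrix = build_regulon_matrix(genomes, genomes[0], motif, "sp01_lexA")
        assert matrix.cell("sp01_fam003", "sp02") == ABSENT
        assert matrix.cell("sp01_fam003", "sp03") != ABSENT

    def test_species_without_tf_ortholog_is_excluded_and_flagged(self, default_community):
        from regulonscout import CommunityConfig, build_motif, generate_community
        cfg = CommunityConfig(seed=4, family_absence={"sp03": {"lexA"}})
        genomes, truth = generate_community(cfg)
        motif = build_motif(list(truth.sites[truth.sites.role == "primary"].sequence))
        matrix = build_regulon_matrix(genomes, genomes[0], motif, "sp01_lexA")
        assert matrix.excluded_species == ["sp03"]
        assert "sp03" not in matrix.species

    def test_missing_tf_gene_in_reference_is_an_error(self, analysis):
        genomes, _, motif, _ = analysis
        with pytest.raises(ValueError):
            build_regulon_matrix(genomes, genomes[0], motif, "sp01_nothere")

    def test_tsv_serialisation_round_trips_shape(self, analysis):
        _, _, _, matrix = analysis
        lines = matrix.to_tsv().strip().splitlines()
        assert len(lines) == 1 + len(matrix.group_ids)
        assert lines[0].split("\t")[1:] == matrix.species


def test_end_to_end_regulon_recovery_over_seeds():
    """Precision and recall of planted regulon recovery average >= 0.9."""
    from regulonscout import (CommunityConfig, build_motif, evaluate_recovery,
                              generate_community)
    precisions, recalls = [], []
    for seed in range(10):
        genomes, truth = generate_community(CommunityConfig(seed=seed))
        motif = build_motif(list(truth.sites[truth.sites.role == "primary"].sequence))
        matrix = build_regulon_matrix(genomes, genomes[0], motif, "sp01_lexA")
        pred = {(sp, gid.split("_", 1)[1])
                for sp, gid in matrix.regulated_pairs(0.5 * motif.max_score)}
        score = evaluate_recovery(pred, truth)
        precisions.append(score.precision)
        recalls.append(score.recall)
    assert np.mean(precisions) >= 0.9
    assert np.mean(recalls) >= 0.9


def test_operons_tsv_contains_all_operons(toy_genome):
    ops = predict_operons(toy_genome)
    text = operons_to_tsv(ops)
    assert len(text.strip().splitlines()) == len(ops) + 1
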
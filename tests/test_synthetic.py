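"""Generator determinism, truth round-trips, and spectrum calibration."""

import math

import numpy as np
import pytest

from vntrkit.motifs import MotifConfig, build_catalog, segment_vntr
from vntrkit.popgen import hwe_test, tajimas_d
from vntrkit.projection import (
    GeneModel,
    GenomicInterval,
    classify_orf,
    liftover_interval,
    parse_paf,
    project_and_translate,
    translate_cds,
)
from vntrkit.synthetic import (
    DomainSpec,
    GrammarConfig,
    SFSConfig,
    gen_alignment_fixture,
    gen_vntr_cohort,
    sim_diploids,
    sim_hapmatrix,
    sim_ld_blocks,
    spectrum_weights,
)

MOTIFS = ("TTSTTSAP", "TTSTTSGP", "TTSATSAP", "TTSTTPAP", "TISTTSAP",
          "TTSTTSVP", "STSTTSAP", "TTSTASAP", "TTSTTSSP", "TTSTTSAA")
CYS = "CDWRCTQLGCDNHKCEWHQGRCCQEC"
TEMPLATE = (
    DomainSpec("cys", "cysD1", exemplar=CYS),
    DomainSpec("TR", "TR1", motif_count_choices=(8, 12)),
    DomainSpec("cys", "cysD1", exemplar=CYS, copy_choices=(1, 2)),
    DomainSpec("TR", "TR2", motif_count_choices=(15, 20)),
)


def grammar(seed=1, n=20, mu=0.0, allow_stops=False):
    return GrammarConfig(MOTIFS, TEMPLATE, cohort_size=n, seed=seed,
                         mutation_rate=mu, allow_stops=allow_stops)


class TestVntrCohort:
    def test_zero_mutation_catalog_recovery(self):
        cohort = gen_vntr_cohort(grammar(mu=0.0))
        cat = build_catalog(cohort.motif_lists)
        assert set(cat.motifs) == set(MOTIFS)

    def test_truth_tables_describe_sequences(self):
        cohort = gen_vntr_cohort(grammar(seed=4))
        for hap, arch in cohort.architectures.items():
            assert "M" + "".join(seq for *_, seq in arch) == cohort.proteins[hap]
            assert translate_cds(cohort.cds[hap]).rstrip("*") == cohort.proteins[hap]
            # TR domain sequences are exactly the concatenated truth motifs
            trs = [seq for kind, _, seq in arch if kind == "TR"]
            assert trs == ["".join(d) for d in cohort.per_domain_motifs[hap]]

    def test_determinism(self):
        a = gen_vntr_cohort(grammar(seed=7))
        b = gen_vntr_cohort(grammar(seed=7))
        assert a.cds == b.cds and a.proteins == b.proteins

    def test_mutation_budget_bounds_hamming_distance(self):
        mu = 0.02
        cohort = gen_vntr_cohort(grammar(seed=9, n=30, mu=mu))
        budget = math.ceil(mu * 24)
        for motifs in cohort.motif_lists.values():
            for m in motifs:
                best = min(sum(a != b for a, b in zip(m, g)) for g in MOTIFS)
                assert best <= budget

    def test_nonsense_suppression_keeps_orfs_complete(self):
        cohort = gen_vntr_cohort(grammar(seed=2, n=20, mu=0.05))
        for hap, cds in cohort.cds.items():
            assert classify_orf(translate_cds(cds)) == "complete"

    def test_segmentation_round_trip_on_truth_domains(self):
        cohort = gen_vntr_cohort(grammar(seed=3, mu=0.02))
        cfg = MotifConfig(8)
        for hap, arch in cohort.architectures.items():
            for kind, _, seq in arch:
                if kind == "TR":
                    seg = segment_vntr(seq, cfg)
                    assert seg.reconstruct() == seq and seg.remainder == ""


class TestAlignmentFixture:
    REF = "".join("ACGT"[i % 4] for i in range(600))
    MODEL = GeneModel("g", [GenomicInterval("ref", 30, 120),
                            GenomicInterval("ref", 200, 500)])

    def test_empty_edit_list_identity(self):
        fx = gen_alignment_fixture(self.REF, self.MODEL, [])
        assert fx.contig_seq == self.REF
        assert fx.alignment.cigar == [(600, "=")]
        assert [(t.start, t.end) for t in fx.truth_intervals] == [(30, 120), (200, 500)]

    def test_insertion_expands_exon(self):
        fx = gen_alignment_fixture(self.REF, self.MODEL, [(300, "ins", 24)])
        assert fx.truth_intervals[1].end - fx.truth_intervals[1].start == 324
        for exon, truth in zip(self.MODEL.exons, fx.truth_intervals):
            got = liftover_interval(fx.alignment, exon)
            assert (got.start, got.end) == (truth.start, truth.end)

    def test_deletion_spanning_exon_edge_snaps(self):
        fx = gen_alignment_fixture(self.REF, self.MODEL, [(190, "del", 20)])
        truth = fx.truth_intervals[1]
        got = liftover_interval(fx.alignment, self.MODEL.exons[1])
        assert (got.start, got.end) == (truth.start, truth.end)
        assert truth.end - truth.start == 290  # 10 leading bases lost

    def test_random_edit_lists_agree_with_liftover(self, rng):
        for trial in range(30):
            edits = []
            cursor = 10
            while cursor < 550 and len(edits) < 5:
                kind = "ins" if rng.integers(2) else "del"
                length = int(rng.integers(1, 30))
                edits.append((cursor, kind, length))
                cursor += (length if kind == "del" else 0) + int(rng.integers(20, 120))
            fx = gen_alignment_fixture(self.REF, self.MODEL, edits, seed=trial)
            (rec,) = parse_paf([fx.paf_line])
            assert rec.cigar == fx.alignment.cigar
            for exon, truth in zip(self.MODEL.exons, fx.truth_intervals):
                if truth is None:
                    continue
                got = liftover_interval(fx.alignment, exon)
                assert (got.start, got.end) == (truth.start, truth.end)

    def test_known_insertion_lengthens_protein(self):
        # 24-bp in-frame insertion inside the (single) coding exon adds 8 aa
        cds = "ATG" + "ACTAGTACTCCT" * 20 + "TAA"
        model = GeneModel("g", [GenomicInterval("ref", 0, len(cds))])
        insert_nt = "ACT" * 8
        fx = gen_alignment_fixture(cds, model, [(63, "ins", 24)], seed=0)
        contig = fx.contig_seq[:63] + insert_nt + fx.contig_seq[63 + 24:]
        ref_protein = translate_cds(cds).rstrip("*")
        p = project_and_translate(contig, fx.alignment, model)
        assert p.status == "complete"
        assert p.length_aa == len(ref_protein) + 8

    def test_overlapping_edits_rejected(self):
        with pytest.raises(ValueError):
            gen_alignment_fixture(self.REF, self.MODEL, [(100, "del", 50), (120, "ins", 5)])


class TestSfsSimulator:
    def test_determinism(self):
        cfg = SFSConfig(20, 30, 10_000, seed=5)
        a, b = sim_hapmatrix(cfg), sim_hapmatrix(cfg)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.site_positions, b.site_positions)

    def test_spectrum_shapes_goodness_of_fit(self):
        """Empirical allele-count histogram matches the sampling law."""
        from vntrkit.popgen import contingency_chisq
        from scipy.stats import chisquare

        n = 12
        for spectrum in ("neutral", "rare_excess", "common_excess"):
            cfg = SFSConfig(n, 5_000, 100_000, seed=8, spectrum=spectrum)
            m = sim_hapmatrix(cfg)
            counts = (m.alleles == 1).sum(axis=0)
            hist = np.bincount(counts, minlength=n)[1:n]
            expected = spectrum_weights(n, spectrum) * 5_000
            support = expected > 0
            assert hist[~support].sum() == 0
            assert chisquare(hist[support], expected[support]).pvalue > 0.01

    def test_mean_d_signs_small(self):
        means = {}
        for spectrum in ("neutral", "rare_excess", "common_excess"):
            ds = []
            for rep in range(60):
                cfg = SFSConfig(30, 40, 50_000, seed=100 + rep, spectrum=spectrum)
                d = tajimas_d(sim_hapmatrix(cfg)).D
                ds.append(d)
            means[spectrum] = np.mean(ds)
        assert means["rare_excess"] < means["neutral"] < means["common_excess"]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SFSConfig(10, 100, 50, seed=1)
        with pytest.raises(ValueError):
            SFSConfig(10, 5, 50, seed=1, spectrum="bogus")


class TestLdBlockSimulator:
    def test_perfect_within_block_correlation_k2(self):
        from vntrkit.ld import ld_pair

        m, truth = sim_ld_blocks([(5, 2)], n_haplotypes=100, seed=2)
        lo, hi = truth[0]
        for i in range(lo, hi + 1):
            for j in range(i + 1, hi + 1):
                assert abs(ld_pair(m, i, j).D_prime) == pytest.approx(1.0)

    def test_k3_gives_dprime_one_with_r2_below_one(self):
        from vntrkit.ld import ld_pair

        m, truth = sim_ld_blocks([(6, 3)], n_haplotypes=150, seed=6)
        lo, hi = truth[0]
        stats = [ld_pair(m, i, j) for i in range(lo, hi + 1)
                 for j in range(i + 1, hi + 1)]
        assert all(abs(s.D_prime) == pytest.approx(1.0, abs=1e-9) for s in stats)
        assert any(s.r_squared < 0.99 for s in stats)

    def test_truth_indices_and_determinism(self):
        a, ta = sim_ld_blocks([(4, 2), (5, 3)], n_haplotypes=80, seed=9)
        b, tb = sim_ld_blocks([(4, 2), (5, 3)], n_haplotypes=80, seed=9)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert ta == tb
        assert ta[0][0] == 3  # default 3 leading spacer sites


class TestDiploidSimulator:
    def hap_half(self, n=400, seed=3):
        # exactly balanced columns: allele-1 frequency is 0.5 at every site
        rng = np.random.default_rng(seed)
        A = np.zeros((n, 5), dtype=np.int8)
        for s in range(5):
            A[rng.choice(n, size=n // 2, replace=False), s] = 1
        from vntrkit.popgen import HaplotypeMatrix
        return HaplotypeMatrix("c", np.arange(5), A)

    def test_f_minus_one_all_heterozygotes(self):
        m = self.hap_half()
        g = sim_diploids(m, -1.0, seed=1)
        assert set(np.unique(g)) == {1}

    def test_f_zero_calibration_quick(self):
        m = self.hap_half(n=1_000, seed=4)
        rejections = 0
        for rep in range(100):
            g = sim_diploids(m, 0.0, seed=rep)
            counts = (int((g[:, 0] == 0).sum()), int((g[:, 0] == 1).sum()),
                      int((g[:, 0] == 2).sum()))
            if hwe_test(counts).p_value < 0.05:
                rejections += 1
        assert 0 <= rejections <= 12  # ~ alpha = 0.05

    def test_invalid_f(self):
        with pytest.raises(ValueError):
            sim_diploids(self.hap_half(), 1.5, seed=0)
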
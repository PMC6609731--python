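"""Compartment partition, enrichment chi-square, exon fractions, densities."""

import numpy as np
import pytest
from scipy import stats

from mitoirg4.compartment_stats import (
    assign_motifs,
    chisq_enrichment,
    exon_fraction,
    expected_counts,
    ir_sc_density,
    partition_compartments,
)
from mitoirg4.g4scan import G4Motif, STRICT, detect_motifs
from mitoirg4.genome_io import Feature, FeatureSet, GenomeRecord
from mitoirg4.ir_detect import IRAnnotation, find_inverted_repeat
from mitoirg4.synthetic_data import SyntheticSpec, generate_genome


def _genome(n=1000):
    return GenomeRecord("g", "A" * n)


def _fs(*features):
    return FeatureSet(genome_id="g", features=list(features))


class TestPartition:
    def test_single_exon_lengths(self):
        fs = _fs(Feature("exon", "cox1.e1", 100, 400, "+", gene="cox1"))
        part = partition_compartments(_genome(), fs)
        assert part.lengths == {"exon": 300, "intron": 0, "intergenic": 700}

    def test_overlapping_exons_unioned(self):
        fs = _fs(
            Feature("exon", "cox1.e1", 0, 100, "+", gene="cox1"),
            Feature("exon", "cox2.e1", 50, 150, "+", gene="cox2"),
        )
        part = partition_compartments(_genome(), fs)
        assert part.lengths["exon"] == 150

    def test_no_conserved_genes_all_intergenic(self):
        fs = _fs(Feature("exon", "orf1.e1", 0, 100, "+", gene="orf1"))
        part = partition_compartments(_genome(), fs)
        assert part.lengths == {"exon": 0, "intron": 0, "intergenic": 1000}

    def test_exon_priority_over_intron(self):
        fs = _fs(
            Feature("exon", "cox1.e1", 0, 100, "+", gene="cox1"),
            Feature("intron", "cob.i1", 50, 200, "+", gene="cob"),
        )
        part = partition_compartments(_genome(), fs)
        assert part.lengths["exon"] == 100 and part.lengths["intron"] == 100

    def test_partition_always_tiles(self, standard_synthetic):
        genome, feats, _ = standard_synthetic
        part = partition_compartments(genome, feats)
        assert sum(part.lengths.values()) == genome.length


class TestAssignAndExpected:
    def test_midpoint_rule(self):
        fs = _fs(Feature("exon", "cox1.e1", 0, 30, "+", gene="cox1"))
        part = partition_compartments(_genome(), fs)
        # motif [10,35): midpoint 22 -> exon; [25,55): midpoint 40 -> intergenic
        obs = assign_motifs([G4Motif(10, 35, 2.0), G4Motif(25, 55, 2.0)], part)
        assert obs == {"exon": 1, "intron": 0, "intergenic": 1}

    def test_no_motifs(self):
        part = partition_compartments(_genome(), _fs())
        assert assign_motifs([], part) == {"exon": 0, "intron": 0, "intergenic": 0}

    def test_expected_proportional_and_sums_exactly(self):
        fs = _fs(
            Feature("exon", "cox1.e1", 0, 500, "+", gene="cox1"),
            Feature("intron", "cox1.i1", 500, 800, "+", gene="cox1"),
        )
        part = partition_compartments(_genome(), fs)
        exp = expected_counts(10, part)
        assert exp == {"exon": 5.0, "intron": 3.0, "intergenic": 2.0}
        assert sum(expected_counts(7, part).values()) == pytest.approx(7, abs=1e-12)

    def test_zero_motifs_zero_expected(self):
        part = partition_compartments(_genome(), _fs())
        assert sum(expected_counts(0, part).values()) == 0


class TestChisq:
    def test_perfect_fit(self):
        res = chisq_enrichment(
            {"a": 10, "b": 10, "c": 10}, {"a": 10.0, "b": 10.0, "c": 10.0}
        )
        assert res.chi2 == pytest.approx(0) and res.p == pytest.approx(1) and res.df == 2

    def test_hand_computed_statistic(self):
        res = chisq_enrichment({"a": 30, "b": 0, "c": 0}, {"a": 10.0, "b": 10.0, "c": 10.0})
        assert res.chi2 == pytest.approx(60)  # 400/10 + 10 + 10

    def test_degenerate_nothing_to_test(self):
        with pytest.raises(ValueError, match="nothing to test"):
            chisq_enrichment({"a": 0, "b": 0}, {"a": 0.0, "b": 0.0})

    def test_observed_without_expectation_is_error(self):
        with pytest.raises(ValueError):
            chisq_enrichment({"a": 5, "b": 5}, {"a": 10.0, "b": 0.0})

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            chisq_enrichment({"a": 5, "b": 5}, {"a": 8.0, "b": 8.0})

    def test_small_expected_warns(self):
        with pytest.warns(UserWarning, match="expected count < 5"):
            chisq_enrichment({"a": 3, "b": 1}, {"a": 2.0, "b": 2.0})

    @pytest.mark.filterwarnings("ignore:expected count")
    def test_matches_textbook_formula_on_random_tables(self):
        """chi2 = sum (O-E)^2/E and p = upper chi2 tail, df = k-1."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            probs = rng.dirichlet(np.ones(k))
            n = int(rng.integers(20, 200))
            obs = rng.multinomial(n, probs)
            exp = n * probs
            keys = [str(i) for i in range(k)]
            res = chisq_enrichment(dict(zip(keys, obs)), dict(zip(keys, exp)))
            chi2_manual = float(((obs - exp) ** 2 / exp).sum())
            p_manual = float(stats.chi2.sf(chi2_manual, k - 1))
            assert res.chi2 == pytest.approx(chi2_manual, abs=1e-9)
            assert res.p == pytest.approx(p_manual, abs=1e-9)


def _simple_ir(L=1000, arm=200, s1=300):
    return IRAnnotation(
        arm1=(s1, s1 + arm), arm2=(L - arm, L),
        sc1=(0, s1), sc2=(s1 + arm, L - arm), identity=1.0, genome_length=L,
    )


class TestExonFraction:
    def test_extreme_cases(self):
        ir = _simple_ir()
        fs = _fs(Feature("exon", "cox1.e1", 300, 500, "+", gene="cox1"))  # fills arm1
        part = partition_compartments(_genome(), fs)
        out = exon_fraction(part, ir)
        assert out == {"IR": pytest.approx(100.0), "SC": pytest.approx(0.0)}

    def test_planted_coverage_recovered(self):
        # 20% of arm1 exonic, 10% of SC exonic
        ir = _simple_ir(L=10_000, arm=2_000, s1=3_000)
        fs = _fs(
            Feature("exon", "cox2.e1", 3_000, 3_400, "+", gene="cox2"),  # 400/2000 IR
            Feature("exon", "cox1.e1", 0, 300, "+", gene="cox1"),  # SC1
            Feature("exon", "cox3.e1", 5_000, 5_300, "+", gene="cox3"),  # SC2
        )
        part = partition_compartments(_genome(10_000), fs)
        out = exon_fraction(part, ir)
        assert out["IR"] == pytest.approx(20.0)
        assert out["SC"] == pytest.approx(100 * 600 / 6000)


class TestIrScDensity:
    def test_no_motifs(self):
        out = ir_sc_density([], _simple_ir())
        assert out == {"density_IR": 0.0, "density_SC": 0.0}

    def test_arithmetic(self):
        ir = IRAnnotation(
            arm1=(0, 20_000), arm2=(70_000, 90_000),
            sc1=(20_000, 70_000), sc2=(90_000, 90_000),
            identity=1.0, genome_length=90_000,
        )
        motifs = [G4Motif(i * 100, i * 100 + 30, 2.0) for i in range(10)]  # in arm1
        motifs += [G4Motif(30_000 + i * 100, 30_030 + i * 100, 2.0) for i in range(5)]
        out = ir_sc_density(motifs, ir)
        assert out["density_IR"] == pytest.approx(0.5)
        assert out["density_SC"] == pytest.approx(0.1)

    def test_motifs_only_in_ir(self, standard_synthetic):
        genome, feats, truth = standard_synthetic
        spec = SyntheticSpec(
            genome_length=80_000, ir_arm_length=20_000, genes=(),
            g4_rate_per_kb_region={"IR": 1.0, "SC": 0.0}, seed=31,
        )
        g, _, tr = generate_genome(spec)
        motifs = detect_motifs(g, STRICT)
        out = ir_sc_density(motifs, tr.ir)
        assert out["density_SC"] == 0.0 and out["density_IR"] > 0

    def test_arm_label_invariance_under_symmetric_motifs(self):
        ir = _simple_ir(L=10_000, arm=2_000, s1=3_000)
        swapped = IRAnnotation(
            arm1=ir.arm2, arm2=ir.arm1, sc1=ir.sc1, sc2=ir.sc2,
            identity=1.0, genome_length=10_000,
        )
        # motifs mirrored into both arms: same density whichever arm is copy 1
        motifs = [G4Motif(3_100, 3_130, 2.0), G4Motif(8_870, 8_900, -2.0)]
        a = ir_sc_density(motifs, ir)
        b = ir_sc_density(motifs, swapped)
        assert a == b
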
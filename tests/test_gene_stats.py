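import numpy as np
import pytest

from annotkit.formats_io import GeneModel, GenomicInterval, RepeatFeature
from annotkit.gene_stats import (
    gene_space_fractions,
    intron_intervals,
    repeat_overlap_classify,
    summarize_genes,
    top_fraction_introns,
)


def gene(gene_id, seq_id, exon_coords, cds_coords=None, aed=None,
         has_start=True, has_stop=True):
    exons = tuple(GenomicInterval(seq_id, s, e) for s, e in exon_coords)
    cds = tuple(
        GenomicInterval(seq_id, s, e)
        for s, e in (exon_coords if cds_coords is None else cds_coords)
    )
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(seq_id, exons[0].start, exons[-1].end),
        exons=exons,
        cds=cds,
        aed=aed,
        has_start=has_start,
        has_stop=has_stop,
    )


def repeat(seq_id, start, end, repeat_class="LTR/Gypsy"):
    return RepeatFeature(
        interval=GenomicInterval(seq_id, start, end),
        repeat_name="r",
        repeat_class=repeat_class,
    )


class TestIntronIntervals:
    def test_gap_between_exons(self):
        m = gene("g", "c", [(0, 100), (200, 300)])
        (iv,) = intron_intervals(m)
        assert (iv.start, iv.end) == (100, 200)

    def test_single_exon_no_introns(self):
        assert intron_intervals(gene("g", "c", [(0, 100)])) == []

    def test_span_conservation_random_models(self, rng):
        for _ in range(30):
            pos = 0
            coords = []
            for _ in range(int(rng.integers(1, 8))):
                length = int(rng.integers(50, 400))
                coords.append((pos, pos + length))
                pos += length + int(rng.integers(1, 500))
            m = gene("g", "c", coords)
            introns = intron_intervals(m)
            assert len(introns) == len(coords) - 1
            assert m.exon_bp + sum(i.length for i in introns) == m.span


class TestSummarizeGenes:
    def test_counts_and_means(self):
        models = [
            gene("g1", "c", [(0, 100), (200, 300)]),
            gene("g2", "c", [(0, 50), (100, 150), (200, 250), (300, 350)]),
        ]
        s = summarize_genes(models)
        assert s.n_genes == 2 and s.n_exons == 6 and s.n_introns == 4
        assert s.mean_exons_per_gene == 3.0

    def test_completeness_partition(self):
        models = [
            gene("f", "c", [(0, 10)], has_start=True, has_stop=True),
            gene("t5", "c", [(0, 10)], has_start=False, has_stop=True),
            gene("t3", "c", [(0, 10)], has_start=True, has_stop=False),
            gene("tb", "c", [(0, 10)], has_start=False, has_stop=False),
        ]
        s = summarize_genes(models)
        assert (s.n_full_length, s.n_trunc_5, s.n_trunc_3, s.n_trunc_both) == (
            1, 1, 1, 1,
        )
        assert sum(
            (s.n_full_length, s.n_trunc_5, s.n_trunc_3, s.n_trunc_both)
        ) == s.n_genes

    def test_aed_fraction_uses_half_cutoff(self):
        models = [
            gene("a", "c", [(0, 10)], aed=0.2),
            gene("b", "c", [(0, 10)], aed=0.5),
            gene("d", "c", [(0, 10)], aed=0.9),
            gene("e", "c", [(0, 10)], aed=0.49),
        ]
        assert summarize_genes(models).aed_below_cutoff_fraction == 0.5

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            s = summarize_genes([])
        assert s.n_genes == 0

    def test_recovers_planted_truth_exactly(self, sim_genome):
        truth = sim_genome.stats_truth
        s = summarize_genes(sim_genome.models)
        assert s.n_genes == truth["n_genes"]
        assert s.n_exons == truth["n_exons"]
        assert s.n_introns == truth["n_introns"]
        assert s.n_full_length == truth["n_full_length"]
        assert s.mean_intron_len_bp == pytest.approx(truth["mean_intron_len_bp"])
        assert s.max_intron_len_bp == truth["max_intron_len_bp"]
        assert s.intron_total_bp == truth["intron_total_bp"]


class TestTopFractionIntrons:
    def test_top_decile(self):
        coords = []
        pos = 0
        for length in range(10, 101, 10):  # introns 10..100
            coords.append((pos, pos + 5))
            pos += 5 + length
        coords.append((pos, pos + 5))
        m = gene("g", "c", coords)
        assert top_fraction_introns([m], 0.1) == [100]
        assert sorted(top_fraction_introns([m], 1.0)) == list(range(10, 101, 10))

    def test_matches_full_sort_oracle(self, rng):
        models = []
        all_introns = []
        for g in range(20):
            pos = 0
            coords = []
            n = int(rng.integers(2, 6))
            for i in range(n):
                coords.append((pos, pos + 30))
                pos += 30
                if i < n - 1:
                    gap = int(rng.integers(20, 800))
                    all_introns.append(gap)
                    pos += gap
            models.append(gene(f"g{g}", "c", coords))
        frac = 0.25
        expected = sorted(all_introns, reverse=True)[
            : int(np.ceil(frac * len(all_introns)))
        ]
        assert top_fraction_introns(models, frac) == expected

    def test_no_introns(self):
        assert top_fraction_introns([gene("g", "c", [(0, 10)])]) == []


class TestRepeatOverlapClassify:
    def test_boundary_inclusive_at_exactly_twenty_percent(self):
        m = gene("g", "c", [(0, 300)])
        calls = repeat_overlap_classify([m], [repeat("c", 0, 60)])
        assert calls[0].overlap_fraction == pytest.approx(0.20)
        assert calls[0].is_repeat_associated

    def test_just_below_threshold(self):
        m = gene("g", "c", [(0, 300)])
        (call,) = repeat_overlap_classify([m], [repeat("c", 0, 59)])
        assert call.overlap_fraction == pytest.approx(59 / 300)
        assert not call.is_repeat_associated

    def test_union_semantics_two_repeats_same_bases(self):
        m = gene("g", "c", [(0, 300)])
        (call,) = repeat_overlap_classify(
            [m], [repeat("c", 0, 100), repeat("c", 0, 100)]
        )
        assert call.overlap_fraction == pytest.approx(100 / 300)

    def test_dominant_family_by_bp_with_lexicographic_ties(self):
        m = gene("g", "c", [(0, 300)])
        calls = repeat_overlap_classify(
            [m],
            [
                repeat("c", 0, 50, "LTR/Gypsy"),
                repeat("c", 100, 200, "LINE/L1"),
            ],
        )
        assert calls[0].dominant_family == "L1"
        tie = repeat_overlap_classify(
            [m], [repeat("c", 0, 50, "LTR/Gypsy"), repeat("c", 100, 150, "LTR/Copia")]
        )
        assert tie[0].dominant_family == "Copia"

    def test_zero_cds_flagged(self):
        m = gene("g", "c", [(0, 100)], cds_coords=[])
        (call,) = repeat_overlap_classify([m], [repeat("c", 0, 100)])
        assert call.flagged_no_cds and call.overlap_fraction == 0.0

    def test_raising_threshold_is_monotone(self, rng):
        models = [gene(f"g{i}", "c", [(i * 400, i * 400 + 300)]) for i in range(20)]
        repeats = [
            repeat("c", int(i * 400), int(i * 400 + rng.integers(0, 300) + 1))
            for i in range(20)
        ]
        assoc = {}
        for thr in (0.1, 0.3, 0.6):
            calls = repeat_overlap_classify(models, repeats, threshold=thr)
            assoc[thr] = {c.gene_id for c in calls if c.is_repeat_associated}
        assert assoc[0.6] <= assoc[0.3] <= assoc[0.1]

    def test_planted_calibration_genes(self, sim_genome):
        calls = {
            c.gene_id: c
            for c in repeat_overlap_classify(sim_genome.models, sim_genome.repeats)
        }
        for row in sim_genome.calibration_truth.itertuples():
            call = calls[row.gene_id]
            assert call.overlap_fraction == pytest.approx(row.overlap_fraction)
            assert call.is_repeat_associated == row.is_repeat_associated


class TestGeneSpace:
    def test_simple_fraction(self):
        m = gene("g", "c", [(0, 100), (200, 300)])  # 200 exon, 100 intron
        intron_bp, exon_bp, frac = gene_space_fractions([m])
        assert (intron_bp, exon_bp) == (100, 200)
        assert frac == pytest.approx(1 / 3)

    def test_single_exon_set(self):
        assert gene_space_fractions([gene("g", "c", [(0, 50)])])[2] == 0.0

    def test_fractions_partition_gene_space(self, rng):
        models = []
        for g in range(15):
            pos = int(g * 10_000)
            coords = []
            for i in range(int(rng.integers(1, 6))):
                coords.append((pos, pos + int(rng.integers(30, 200))))
                pos = coords[-1][1] + int(rng.integers(1, 300))
            models.append(gene(f"g{g}", "c", coords))
        intron_bp, exon_bp, frac = gene_space_fractions(models)
        span = sum(m.span for m in models)
        assert intron_bp + exon_bp == span
        assert frac == pytest.approx(intron_bp / span)
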
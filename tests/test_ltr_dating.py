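import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annotkit.ltr_dating import (
    JCParams,
    LtrElement,
    SaturationError,
    alignment_score,
    classify_flank_motif,
    classify_superfamily,
    date_element,
    insertion_time,
    jc_distance,
    load_ltr_library,
    deduplicate_library,
    pairwise_identity,
    summarize_ages,
)
from annotkit.formats_io import SequenceRecord, write_fasta, write_table
from oracles import gotoh_endsfree_score


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = "".join(rng.choice(list("ACGT"), 100))
        assert pairwise_identity(s, s) == 1.0

    def test_single_substitution(self, rng):
        s = list("".join(rng.choice(list("ACGT"), 100)))
        t = s.copy()
        t[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[50]]
        assert pairwise_identity("".join(s), "".join(t)) == pytest.approx(0.99)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), 80))
        b = "".join(rng.choice(list("ACGT"), 70))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_ambiguity_codes_never_match(self):
        # N aligned to N is counted as a mismatch, not an identity
        assert pairwise_identity("ACGNACGT", "ACGNACGT") == pytest.approx(7 / 8)

    def test_score_matches_dp_oracle_on_random_pairs(self, rng):
        """Optimal score agrees with an independent Gotoh dynamic program
        under the same scoring (match +1, mismatch -1, gap -4/-1 affine,
        free terminal gaps)."""
        for _ in range(40):
            n1 = int(rng.integers(5, 51))
            n2 = int(rng.integers(5, 51))
            a = "".join(rng.choice(list("ACGT"), n1))
            b = "".join(rng.choice(list("ACGT"), n2))
            # mutate b from a sometimes so similar pairs are covered too
            if rng.random() < 0.5:
                chars = list(a)
                for i in range(len(chars)):
                    if rng.random() < 0.15:
                        chars[i] = "ACGT"[rng.integers(0, 4)]
                b = "".join(chars)
            assert alignment_score(a, b) == pytest.approx(
                gotoh_endsfree_score(a, b)
            ), (a, b)


class TestJcDistance:
    def test_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_against_arbitrary_precision(self):
        import mpmath

        mpmath.mp.dps = 40
        for p in [0.01, 0.05, 0.10, 0.25, 0.5, 0.74]:
            exact = float(-mpmath.mpf(3) / 4 * mpmath.log(1 - mpmath.mpf(4) * p / 3))
            assert jc_distance(p) == pytest.approx(exact, rel=1e-12)

    def test_known_value(self):
        assert jc_distance(0.10) == pytest.approx(0.1073256, abs=5e-8)

    def test_boundary(self):
        assert math.isfinite(jc_distance(0.74999))
        with pytest.raises(SaturationError):
            jc_distance(0.75)
        with pytest.raises(ValueError):
            jc_distance(-0.01)

    @given(st.floats(min_value=0.0, max_value=3.0))
    @settings(derandomize=True, max_examples=60)
    def test_inverts_expected_difference_map(self, d0):
        """jc_distance is the exact inverse of q(d) = (3/4)(1 - exp(-4d/3))."""
        q = 0.75 * (1.0 - math.exp(-4.0 * d0 / 3.0))
        assert jc_distance(q) == pytest.approx(d0, rel=1e-10, abs=1e-10)

    @given(
        st.floats(min_value=0.0, max_value=0.7),
        st.floats(min_value=1e-4, max_value=0.049),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, p, dp):
        assert jc_distance(p + dp) > jc_distance(p)


class TestInsertionTime:
    def test_zero_distance(self):
        assert insertion_time(0.0) == 0.0

    def test_closed_form(self):
        t = insertion_time(0.1073256, JCParams(mu=1.57e-8))
        assert t / 1e6 == pytest.approx(3.418, abs=2e-3)

    def test_mu_scaling(self):
        d = 0.2
        assert insertion_time(d, JCParams(mu=2e-8)) == pytest.approx(
            insertion_time(d, JCParams(mu=1e-8)) / 2
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(-0.1)


class TestDateElement:
    def test_identical_ltrs_age_zero(self):
        el = LtrElement("e", "ACGTACGTAC" * 10, "ACGTACGTAC" * 10)
        est = date_element(el)
        assert est.t_mya == 0.0 and not est.saturated

    def test_planted_one_percent_divergence(self, rng):
        """100 substitutions in 10 kb -> p = 0.01 -> T ~ 0.3206 MYA."""
        s = "".join(rng.choice(list("ACGT"), 10000))
        t = list(s)
        pos = rng.choice(10000, size=100, replace=False)
        for i in pos:
            t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
        est = date_element(LtrElement("e", s, "".join(t)))
        assert est.p == pytest.approx(0.01)
        assert est.t_mya == pytest.approx(0.3206, abs=2e-3)

    def test_unalignable_pair_is_saturated_not_dated(self, rng):
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(rng.choice(list("ACGT"), 500))
        est = date_element(LtrElement("e", a, b))
        assert est.saturated and math.isnan(est.t_mya)

    def test_lower_identity_means_older(self, rng):
        s = "".join(rng.choice(list("ACGT"), 2000))
        ages = []
        for nmut in (10, 40, 120):
            t = list(s)
            for i in rng.choice(2000, size=nmut, replace=False):
                t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
            ages.append(date_element(LtrElement("e", s, "".join(t))).t_mya)
        assert ages == sorted(ages) and ages[0] < ages[-1]


class TestClassification:
    @pytest.mark.parametrize(
        "l5,l3,expected",
        [
            ("TGAAACA", "TGTTTCA", "TGCA"),
            ("CAAAATG", "TGTTTCA", "other"),
            ("TGA", "TGTTTCA", "unknown"),
        ],
    )
    def test_flank_motif(self, l5, l3, expected):
        assert classify_flank_motif(LtrElement("e", l5, l3)) == expected

    @pytest.mark.parametrize(
        "order,expected",
        [
            ("PR-INT-RT", "Copia"),
            ("PR-RT-INT", "Gypsy"),
            ("pr_int_rt", "Copia"),
            ("", "unknown"),
            (None, "unknown"),
            ("RT-PR-INT", "unknown"),
        ],
    )
    def test_superfamily(self, order, expected):
        assert classify_superfamily(order) == expected


class TestSummarizeAges:
    def _est(self, eid, mya):
        from annotkit.ltr_dating import AgeEstimate

        return AgeEstimate(eid, 1.0, 0.0, 0.0, mya * 1e6, mya)

    def test_mean_median_even_n(self):
        ests = [self._est(f"e{i}", a) for i, a in enumerate([1, 2, 3, 4])]
        (s,) = summarize_ages(ests)
        assert s.stratum == "all" and s.n == 4
        assert s.mean_mya == 2.5 and s.median_mya == 2.5

    def test_histogram_conserves_n(self):
        ests = [self._est(f"e{i}", a) for i, a in enumerate([0.1, 0.6, 0.7, 2.4])]
        strata = {e.element_id: ("A" if i < 2 else "B") for i, e in enumerate(ests)}
        for s in summarize_ages(ests, strata, bin_width_mya=0.5):
            assert sum(c for _, _, c in s.histogram) == s.n
            edges = [h[0] for h in s.histogram] + [s.histogram[-1][1]]
            assert edges == sorted(edges)  # contiguous from 0
            assert s.histogram[0][0] == 0.0

    def test_saturated_excluded(self):
        from annotkit.ltr_dating import AgeEstimate

        sat = AgeEstimate("bad", 0.1, 0.9, math.nan, math.nan, math.nan, True)
        (s,) = summarize_ages([self._est("e", 1.0), sat])
        assert s.n == 1


class TestLibraryIngestion:
    def test_paired_fasta_with_metadata(self, tmp_path):
        recs = [
            SequenceRecord("el1_5LTR", "TGAAACCCAACA"),
            SequenceRecord("el1_3LTR", "TGAAACCCAACA"),
            SequenceRecord("el2_5LTR", "CCCCGGGGAAAA"),
            SequenceRecord("el2_3LTR", "CCCCGGGGAAAA"),
        ]
        fa = tmp_path / "lib.fa"
        write_fasta(recs, fa)
        meta = tmp_path / "meta.tsv"
        write_table(
            [
                {"element_id": "el1", "domain_order": "PR-INT-RT"},
                {"element_id": "el2", "domain_order": "PR-RT-INT"},
            ],
            meta,
        )
        elements = load_ltr_library(fa, meta)
        assert [e.superfamily for e in elements] == ["Copia", "Gypsy"]
        assert elements[0].flank_motif == "TGCA"

    def test_orphan_records_rejected_with_report(self, tmp_path):
        fa = tmp_path / "lib.fa"
        write_fasta(
            [
                SequenceRecord("el1_5LTR", "ACGTACGT"),
                SequenceRecord("stray", "ACGT"),
            ],
            fa,
        )
        with pytest.raises(ValueError, match="stray"):
            load_ltr_library(fa)

    def test_deduplication_by_identity_and_coverage(self, rng):
        s = "".join(rng.choice(list("ACGT"), 300))
        near = list(s)
        for i in rng.choice(300, size=10, replace=False):  # ~97% identity
            near[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[i]]
        existing = [LtrElement("old", s, s)]
        new = [
            LtrElement("dup", "".join(near), "".join(near)),
            LtrElement("novel", "".join(rng.choice(list("ACGT"), 300)), s[:50]),
        ]
        kept, dups = deduplicate_library(new, existing)
        assert [e.element_id for e in kept] == ["novel"]
        assert dups == [("dup", "old")]
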
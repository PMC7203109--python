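"""Depletion statistics: normalization, imputation, t test, RBR-ID score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbrid import (
    Condition,
    compute_peptide_stats,
    condition_means,
    depletion_ratio,
    global_imputation_floor,
    normalize_run_intensities,
    peptide_pvalue,
    rbr_score,
    significant_peptides,
)
from rbrid.stats import PeptideStat
from conftest import make_record

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestNormalization:
    def test_single_run_sum_normalization(self, design_2x2):
        records = [
            make_record("AAAAAK", {"p1": 2, "p2": 1, "m1": 1, "m2": 1}),
            make_record("CCCCCK", {"p1": 3, "p2": 1, "m1": 1, "m2": 1}),
            make_record("DDDDDK", {"p1": 5, "p2": 1, "m1": 1, "m2": 1}),
        ]
        normed = normalize_run_intensities(records, design_2x2)
        assert [r.intensities["p1"] for r in normed] == [0.2, 0.3, 0.5]

    def test_runs_normalized_independently(self, design_2x2, rng):
        records = [
            make_record(
                "".join(rng.choice(list("ACDEFGHIK"), 8)) + "R",
                {run: float(v) for run, v in zip(design_2x2.run_ids, rng.uniform(0.1, 10, 4))},
            )
            for _ in range(20)
        ]
        normed = normalize_run_intensities(records, design_2x2)
        for run in design_2x2.run_ids:
            total = sum(r.intensities[run] for r in normed)
            assert total == pytest.approx(1.0, abs=1e-9)
            # within-run ratios preserved
            i, j = 0, 1
            before = records[i].intensities[run] / records[j].intensities[run]
            after = normed[i].intensities[run] / normed[j].intensities[run]
            assert after == pytest.approx(before, rel=1e-12)

    def test_zero_total_run_errors(self, design_2x2):
        records = [make_record("AAAAAK", {"p1": 0, "p2": 1, "m1": 1, "m2": 1})]
        with pytest.raises(ValueError, match="p1"):
            normalize_run_intensities(records, design_2x2)


class TestConditionMeans:
    def test_plain_mean(self, design_2x2):
        rec = make_record("AAAAAK", {"p1": 0.1, "p2": 0.3, "m1": 0.2, "m2": 0.2})
        mean_plus, mean_minus, imp_plus, imp_minus = condition_means(rec, design_2x2, 0.005)
        assert mean_plus == pytest.approx(0.2)
        assert not imp_plus and not imp_minus

    def test_all_zero_condition_imputed_to_half_minimum(self, design_2x2):
        rec = make_record("AAAAAK", {"p1": 0, "p2": 0, "m1": 0.2, "m2": 0.2})
        mean_plus, _, imp_plus, imp_minus = condition_means(rec, design_2x2, 0.5 * 0.01)
        assert mean_plus == pytest.approx(0.005)
        assert imp_plus and not imp_minus

    def test_partial_zeros_count_as_measured(self, design_2x2):
        rec = make_record("AAAAAK", {"p1": 0, "p2": 0.4, "m1": 0.2, "m2": 0.2})
        mean_plus, _, imp_plus, _ = condition_means(rec, design_2x2, 0.005)
        assert mean_plus == pytest.approx(0.2)
        assert not imp_plus

    def test_global_floor_spans_peptides_and_conditions(self, design_2x2):
        records = [
            make_record("AAAAAK", {"p1": 0.5, "p2": 0.5, "m1": 0.02, "m2": 0.02}),
            make_record("CCCCCK", {"p1": 0.1, "p2": 0.1, "m1": 0.9, "m2": 0.9}),
        ]
        # smallest positive condition mean is 0.02 (-4SU of first peptide)
        assert global_imputation_floor(records, design_2x2) == pytest.approx(0.01)

    def test_all_zero_dataset_errors(self, design_2x2):
        records = [make_record("AAAAAK", {r: 0 for r in design_2x2.run_ids})]
        with pytest.raises(ValueError, match="imputation floor"):
            global_imputation_floor(records, design_2x2)


class TestDepletionRatio:
    def test_equal_means_give_zero(self):
        assert depletion_ratio(0.3, 0.3) == 0.0

    def test_twofold_depletion(self):
        assert depletion_ratio(1.0, 2.0) == pytest.approx(-1.0)

    @given(a=positive, b=positive)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert depletion_ratio(a, b) == pytest.approx(-depletion_ratio(b, a), rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            depletion_ratio(0.0, 1.0)


class TestPValue:
    def test_identical_groups_p_one(self):
        assert peptide_pvalue([0.2, 0.3], [0.2, 0.3]) == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        # pooled variance 1, se = sqrt(2/3), t = -3.674235, df = 4
        p = peptide_pvalue([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.021311641128756713, rel=1e-9)

    @given(
        a=st.lists(positive, min_size=3, max_size=6),
        b=st.lists(positive, min_size=3, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_two_sided_symmetry(self, a, b):
        assert peptide_pvalue(a, b) == pytest.approx(peptide_pvalue(b, a), rel=1e-9)

    def test_degenerate_equal_constant_groups(self):
        assert peptide_pvalue([1, 1, 1], [1, 1, 1]) == 1.0

    def test_degenerate_distinct_constant_groups_floored(self):
        assert peptide_pvalue([1, 1, 1], [2, 2, 2]) == pytest.approx(1e-15)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            peptide_pvalue([1], [1, 2])


class TestRbrScore:
    def test_zero_at_p_one(self):
        assert rbr_score(-3.7, 1.0) == 0.0

    def test_zero_at_unit_ratio(self):
        assert rbr_score(0.0, 0.001) == 0.0

    def test_round_number_evaluation(self):
        # 2-fold depletion at p = 0.01: 1 * (-2)^2 = 4
        assert rbr_score(-1.0, 0.01) == pytest.approx(4.0)

    @given(ratio=st.floats(-5, 5, allow_nan=False), p=st.floats(1e-12, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_sign_opposes_ratio(self, ratio, p):
        score = rbr_score(ratio, p)
        assert np.sign(score) == -np.sign(ratio) or score == 0

    def test_monotone_in_depletion_and_confidence(self):
        assert rbr_score(-2, 0.01) > rbr_score(-1, 0.01)
        assert rbr_score(-1, 0.001) > rbr_score(-1, 0.01)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rbr_score(-1.0, 0.0)


class TestSignificance:
    @staticmethod
    def stat(p, ratio):
        return PeptideStat("AAAAAK", ["P1"], 1, 1, False, False, ratio, p, 0.0)

    def test_depleted_below_alpha_kept(self):
        assert len(significant_peptides([self.stat(0.05, -0.5)])) == 1

    def test_enriched_excluded(self):
        assert significant_peptides([self.stat(0.05, +0.5)]) == []

    def test_boundary_alpha_excluded(self):
        assert significant_peptides([self.stat(0.1, -0.5)]) == []

    def test_flag_set_on_all_stats(self):
        stats = [self.stat(0.05, -0.5), self.stat(0.5, -0.5)]
        significant_peptides(stats)
        assert [s.significant for s in stats] == [True, False]


class TestFullStats:
    def test_run_rescaling_invariance(self, design_2x2, rng):
        """Score is unchanged when one run's raw intensities are rescaled."""
        records = [
            make_record(
                "".join(rng.choice(list("ACDEFGHIK"), 7)) + "R",
                {run: float(v) for run, v in zip(design_2x2.run_ids, rng.uniform(0.5, 5, 4))},
            )
            for _ in range(10)
        ]
        scaled = [
            make_record(
                r.peptide_seq,
                {run: v * (7.3 if run == "p1" else 1.0) for run, v in r.intensities.items()},
            )
            for r in records
        ]
        stats_a = compute_peptide_stats(
            normalize_run_intensities(records, design_2x2), design_2x2
        )
        stats_b = compute_peptide_stats(
            normalize_run_intensities(scaled, design_2x2), design_2x2
        )
        for a, b in zip(stats_a, stats_b):
            assert a.score == pytest.approx(b.score, rel=1e-9)

    def test_undetected_everywhere_dropped(self, design_2x2):
        records = [
            make_record("AAAAAK", {r: 1.0 for r in design_2x2.run_ids}),
            make_record("CCCCCK", {r: 0.0 for r in design_2x2.run_ids}),
        ]
        stats = compute_peptide_stats(
            normalize_run_intensities(records, design_2x2), design_2x2
        )
        assert [s.peptide_seq for s in stats] == ["AAAAAK"]

    def test_worked_fixture_matches_brute_force(self, design_3x3):
        """Full pipeline on 5 peptides equals an independent naive recomputation."""
        import math

        from scipy import stats as sps

        raw = {
            "AAAAAK": [2.0, 3.0, 2.5, 5.0, 6.0, 5.5],
            "CCCCCK": [1.0, 1.2, 0.9, 1.1, 1.0, 1.2],
            "DDDDDK": [0.0, 0.0, 0.0, 2.0, 2.5, 2.2],
            "EEEEEK": [4.0, 4.5, 4.2, 0.0, 0.0, 0.0],
            "FFFFFK": [3.0, 0.0, 2.0, 3.5, 3.0, 2.8],
        }
        runs = design_3x3.run_ids  # p1 p2 p3 m1 m2 m3
        records = [make_record(s, dict(zip(runs, v))) for s, v in raw.items()]
        stats = compute_peptide_stats(
            normalize_run_intensities(records, design_3x3), design_3x3
        )

        # --- independent brute force, plain loops ---
        totals = [sum(raw[s][j] for s in raw) for j in range(6)]
        norm = {s: [v / t for v, t in zip(vals, totals)] for s, vals in raw.items()}
        cond_means = {}
        for s, vals in norm.items():
            cond_means[s] = [sum(vals[:3]) / 3, sum(vals[3:]) / 3]
        floor = 0.5 * min(m for pair in cond_means.values() for m in pair if m > 0)
        for s, (mp, mm) in cond_means.items():
            cond_means[s] = [mp if mp > 0 else floor, mm if mm > 0 else floor]
        expected = {}
        for s, vals in norm.items():
            mp, mm = cond_means[s]
            ratio = math.log2(mp / mm)
            p = sps.ttest_ind(vals[:3], vals[3:], equal_var=True).pvalue
            p = min(max(p, 1e-15), 1.0)
            expected[s] = (ratio, p, -ratio * math.log10(p) ** 2)

        assert len(stats) == 5
        for s_obj in stats:
            ratio, p, score = expected[s_obj.peptide_seq]
            assert s_obj.log2_ratio == pytest.approx(ratio, rel=1e-9)
            assert s_obj.p_value == pytest.approx(p, rel=1e-9)
            assert s_obj.score == pytest.approx(score, rel=1e-9)

    def test_imputation_flags_in_full_pipeline(self, design_3x3):
        raw = {
            "AAAAAK": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            "DDDDDK": [0.0, 0.0, 0.0, 2.0, 2.5, 2.2],
        }
        records = [
            make_record(s, dict(zip(design_3x3.run_ids, v))) for s, v in raw.items()
        ]
        stats = compute_peptide_stats(
            normalize_run_intensities(records, design_3x3), design_3x3
        )
        by_seq = {s.peptide_seq: s for s in stats}
        assert by_seq["DDDDDK"].imputed_plus and not by_seq["DDDDDK"].imputed_minus
        assert by_seq["DDDDDK"].log2_ratio < 0
        assert np.isfinite(by_seq["DDDDDK"].score)
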
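"""Specificity score closed forms and SRT calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flicurate.model import FlicurateError
from flicurate.simulate import FixtureSpec, make_expression
from flicurate.srt import (
    ExpressionMatrix,
    TumorSrtParams,
    call_tissue_srt,
    call_tumor_srt,
    expression_ratios,
    lr_tumor_specific,
    specificity_score,
)


class TestRatios:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ((8, 0, 0, 0), (1, 0, 0, 0)),
            ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
            ((4, 2, 1, 1), (0.5, 0.25, 0.125, 0.125)),
        ],
    )
    def test_direct_division(self, x, expected):
        assert np.allclose(expression_ratios(x), expected)

    def test_all_zero_returns_zeros(self):
        assert expression_ratios([0, 0, 0]).sum() == 0

    def test_negative_rejected(self):
        with pytest.raises(FlicurateError):
            expression_ratios([1, -1])


class TestSpecificityScore:
    def test_point_mass_scores_log2_n(self):
        assert specificity_score([1, 0, 0, 0]) == pytest.approx(2.0, abs=1e-9)

    def test_uniform_scores_zero(self):
        assert specificity_score([0.25] * 4) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_skewed_case(self):
        """p = (1/2, 1/4, 1/8, 1/8): entropy = 1/2·1 + 1/4·2 + 2·(1/8·3)
        = 1.75 bits, so S = 2 − 1.75 = 0.25."""
        assert specificity_score([0.5, 0.25, 0.125, 0.125]) == pytest.approx(0.25, abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(FlicurateError):
            specificity_score([0.5, 0.4])

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_scale_invariance(self, x):
        x = np.asarray(x)
        if x.sum() <= 0:
            return
        p = expression_ratios(x)
        s = specificity_score(p)
        assert -1e-9 <= s <= math.log2(len(x)) + 1e-9
        p_scaled = expression_ratios(3.7 * x)
        assert specificity_score(p_scaled) == pytest.approx(s, abs=1e-9)


class TestTissueSrt:
    @staticmethod
    def matrix(rows: dict[str, list[float]], n_types: int) -> pd.DataFrame:
        cols = [f"tis{i}" for i in range(n_types)]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def test_single_tissue_of_22_is_srt(self):
        """Expression confined to 1 of 22 tissues: S = log2(22) ≈ 4.459 > 1
        and the ratio clause passes with p_(2) = 0."""
        m = self.matrix({"t": [9.0] + [0.0] * 21}, 22)
        (r,) = call_tissue_srt(m)
        assert r.score == pytest.approx(math.log2(22), abs=1e-9)
        assert r.is_tissue_srt and r.top_tissue == "tis0"

    def test_uniform_is_not_srt(self):
        (r,) = call_tissue_srt(self.matrix({"t": [5.0] * 22}, 22))
        assert r.score == pytest.approx(0.0, abs=1e-9)
        assert not r.is_tissue_srt

    def test_ratio_clause_rejects_60_40(self):
        """p = (0.6, 0.4, 0, ...): 0.6 < 2·0.4, so not tissue-specific no
        matter the score."""
        m = self.matrix({"t": [6.0, 4.0] + [0.0] * 20}, 22)
        (r,) = call_tissue_srt(m)
        assert not r.is_tissue_srt

    def test_unexpressed_scores_nan_not_zero(self):
        (r,) = call_tissue_srt(self.matrix({"t": [0.0] * 22}, 22))
        assert math.isnan(r.score) and not r.is_tissue_srt and not r.expressed

    def test_fewer_than_two_types_rejected(self):
        with pytest.raises(FlicurateError):
            call_tissue_srt(self.matrix({"t": [1.0]}, 1))


def build_matrix(tumor_vals, normal_vals, adjacent_vals=None, normal_groups=None):
    """One-transcript ExpressionMatrix builder for tumor-SRT tests."""
    cols, vals, meta = [], [], []
    for i, v in enumerate(tumor_vals):
        cols.append(f"T{i}")
        vals.append(v)
        meta.append(("CT1", "tumor"))
    groups = normal_groups or [f"tis{i}" for i in range(len(normal_vals))]
    for i, v in enumerate(normal_vals):
        cols.append(f"N{i}")
        vals.append(v)
        meta.append((groups[i], "normal"))
    for i, v in enumerate(adjacent_vals or []):
        cols.append(f"A{i}")
        vals.append(v)
        meta.append(("CT1", "adjacent_normal"))
    values = pd.DataFrame([vals], index=["t1"], columns=cols)
    meta_df = pd.DataFrame(meta, index=pd.Index(cols, name="sample_id"),
                           columns=["group", "cohort"])
    return ExpressionMatrix(values, meta_df)


def split(m: ExpressionMatrix):
    return (m.subset_cohort("tumor"), m.subset_cohort("normal"),
            m.subset_cohort("adjacent_normal"))


class TestTumorSrt:
    def test_fold_on_median_vs_max_normal(self):
        """Median tumor 5.0 vs max normal 0.4 is 12.5-fold >= 10: passes A;
        all tumor samples expressed: passes B."""
        m = build_matrix([5.0] * 10, [0.4, 0.1, 0.2])
        tumor, normal, adj = split(m)
        hits, calls = call_tumor_srt(tumor, normal, None)
        assert hits == {("t1", "CT1")}
        (call,) = [c for c in calls if c.passes]
        assert call.fold == pytest.approx(12.5)

    def test_just_under_10_fold_fails(self):
        m = build_matrix([3.9] * 10, [0.4, 0.1])
        tumor, normal, _ = split(m)
        hits, _ = call_tumor_srt(tumor, normal, None)
        assert hits == set()

    def test_exactly_5pct_prevalence_fails_strict(self):
        """5 of 100 tumor samples above 0.5 TPM is exactly 5%, not >5%."""
        tumor_vals = [5.0] * 5 + [0.0] * 95
        m = build_matrix(tumor_vals, [0.0, 0.0])
        tumor, normal, _ = split(m)
        hits, calls = call_tumor_srt(tumor, normal, None)
        assert hits == set()
        # 6 of 100 passes B but the median is still 0, so A fails too;
        # check B in isolation via the evaluation record
        assert calls[0].frac_expressed == pytest.approx(0.05)

    def test_testis_excluded_from_normal_maximum(self):
        """Expression only in testis among normals: the normal max is 0 and
        any positive tumor median passes A."""
        m = build_matrix([2.0] * 10, [8.0, 0.0, 0.0], normal_groups=["testis", "a", "b"])
        tumor, normal, _ = split(m)
        hits, _ = call_tumor_srt(tumor, normal, None)
        assert hits == {("t1", "CT1")}

    def test_adjacent_normals_pooled_into_maximum(self):
        m = build_matrix([5.0] * 10, [0.1, 0.1], adjacent_vals=[2.0])
        tumor, normal, adj = split(m)
        hits_pooled, _ = call_tumor_srt(tumor, normal, adj)
        assert hits_pooled == set()  # 5.0 < 10 × 2.0
        hits_without, _ = call_tumor_srt(tumor, normal, None)
        assert hits_without == {("t1", "CT1")}

    def test_no_normals_is_error(self):
        m = build_matrix([5.0] * 4, [1.0], normal_groups=["testis"])
        tumor, normal, _ = split(m)
        with pytest.raises(FlicurateError):
            call_tumor_srt(tumor, normal, None)

    def test_monotone_in_fold_and_prevalence(self):
        m = build_matrix([5.0] * 6 + [0.0] * 4, [0.4, 0.2])
        tumor, normal, _ = split(m)
        loose, _ = call_tumor_srt(tumor, normal, None, TumorSrtParams(fold=10))
        tight, _ = call_tumor_srt(tumor, normal, None, TumorSrtParams(fold=15))
        assert tight <= loose
        tight2, _ = call_tumor_srt(
            tumor, normal, None, TumorSrtParams(fold=10, frac_expressed=0.7)
        )
        assert tight2 <= loose

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TumorSrtParams(fold=1.0)
        with pytest.raises(ValueError):
            TumorSrtParams(frac_expressed=0.0)


class TestPlantedRecovery:
    @staticmethod
    def run_calls(spec: FixtureSpec):
        ids = [f"tx{i:03d}" for i in range(40)]
        matrix, truth = make_expression(spec, ids)
        tumor = matrix.subset_cohort("tumor")
        gtex = matrix.subset_cohort("normal")
        adj = matrix.subset_cohort("adjacent_normal")
        hits, _ = call_tumor_srt(tumor, gtex, adj)
        called_tumor = {tid for tid, _ct in hits}
        tissue = call_tissue_srt(gtex.aggregate_by_group())
        called_tissue = {r.transcript_id for r in tissue if r.is_tissue_srt}
        return called_tumor, called_tissue, truth

    def test_noise_free_recovery_is_exact(self):
        spec = FixtureSpec(seed=5, noise_sigma=0.0, dropout=0.0)
        called_tumor, called_tissue, truth = self.run_calls(spec)
        assert called_tumor == set(truth["tumor_srt"])
        assert called_tissue == set(truth["tissue_srt"])

    def test_planted_cancer_type_is_recovered(self):
        spec = FixtureSpec(seed=6, noise_sigma=0.0, dropout=0.0)
        ids = [f"tx{i:03d}" for i in range(40)]
        matrix, truth = make_expression(spec, ids)
        hits, _ = call_tumor_srt(
            matrix.subset_cohort("tumor"),
            matrix.subset_cohort("normal"),
            matrix.subset_cohort("adjacent_normal"),
        )
        assert hits == {(tid, ct) for tid, ct in truth["tumor_srt"].items()}


class TestLrTumorSpecific:
    def test_set_difference_over_cohorts(self):
        from helpers import make_transcript

        cohorts = {"s1": "tumor", "s2": "tumor", "s3": "normal"}
        only_tumor = make_transcript("a", [(0, 10), (20, 30)], samples={"s1", "s2"})
        mixed = make_transcript("b", [(0, 10), (20, 30)], samples={"s1", "s3"})
        assert lr_tumor_specific([only_tumor, mixed], cohorts) == {"a"}
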
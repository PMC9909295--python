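from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import overall_oracle, rule_table_oracle
from conftest import toy_count_matrix
from toleromics import (
    ClassificationConfig,
    ResponseQuad,
    Stimulus,
    Subcategory,
    TimepointCall,
    Tolerance,
    classify_sequence,
    classify_timepoint,
    compute_rpm,
    foster_nt_criterion,
    is_sustained_expression,
    overall_call,
    ratio_indices,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestRatioIndices:
    def test_worked_example(self):
        idx = ratio_indices(ResponseQuad(10, 50, 12, 13))
        assert idx.i_primary == pytest.approx(5.0)
        assert idx.i_residual == pytest.approx(1.2)
        assert idx.i_secondary == pytest.approx(13 / 12)
        assert idx.i_sec_vs_prim == pytest.approx(0.26)
        assert idx.i_sec_vs_base == pytest.approx(1.3)

    def test_flat_quad_gives_unit_indices(self):
        idx = ratio_indices(ResponseQuad(7.5, 7.5, 7.5, 7.5))
        assert (
            idx.i_primary == idx.i_residual == idx.i_secondary
            == idx.i_sec_vs_prim == idx.i_sec_vs_base == 1.0
        )

    @given(b=positive, p=positive, r=positive, s=positive)
    def test_secondary_over_baseline_factorizes(self, b, p, r, s):
        idx = ratio_indices(ResponseQuad(b, p, r, s))
        assert idx.i_sec_vs_base == pytest.approx(
            idx.i_secondary * idx.i_residual, rel=1e-12
        )

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ResponseQuad(0.0, 1.0, 1.0, 1.0)


class TestClassifyTimepoint:
    @pytest.mark.parametrize(
        "quad, expected",
        [
            ((10, 50, 12, 13), TimepointCall.UNINDUCIBLE),
            ((10, 50, 10, 55), TimepointCall.NORMOINDUCIBLE),
            ((10, 15, 100, 250), TimepointCall.HYPERINDUCIBLE_2),
            ((10, 50, 10, 500), TimepointCall.HYPERINDUCIBLE),
            ((10, 100, 10, 25), TimepointCall.HYPOINDUCIBLE),
            ((10, 15, 100, 150), TimepointCall.LATE),
            ((10, 15, 12, 50), TimepointCall.DE_NOVO),
            ((10, 15, 12, 14), TimepointCall.UNRESPONSIVE),
        ],
    )
    def test_rule_forced_examples(self, quad, expected):
        assert classify_timepoint(ResponseQuad(*quad)) is expected

    def test_exhaustive_grid_matches_independent_oracle(self):
        grid = [1.0, 3.0, 9.0, 27.0, 81.0]
        for b, p, r, s in itertools.product(grid, repeat=4):
            got = classify_timepoint(ResponseQuad(b, p, r, s))
            assert got.value == rule_table_oracle(b, p, r, s), (b, p, r, s)

    @given(b=positive, p=positive, r=positive, s=positive)
    def test_total_function_on_positive_quads(self, b, p, r, s):
        assert classify_timepoint(ResponseQuad(b, p, r, s)) in TimepointCall

    @given(b=positive, p=positive, r=positive, s=positive,
           c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, b, p, r, s, c):
        base = classify_timepoint(ResponseQuad(b, p, r, s))
        scaled = classify_timepoint(ResponseQuad(b * c, p * c, r * c, s * c))
        assert base is scaled

    def test_raising_threshold_never_turns_uninducible_responsive(self):
        responsive = {
            TimepointCall.HYPOINDUCIBLE,
            TimepointCall.NORMOINDUCIBLE,
            TimepointCall.HYPERINDUCIBLE,
        }
        rng = np.random.default_rng(42)
        quads = 10.0 ** rng.uniform(-1, 3, size=(300, 4))
        for q in quads:
            quad = ResponseQuad(*q)
            previous = classify_timepoint(quad, ClassificationConfig(fold_threshold=1.5))
            for theta in (2.0, 3.0, 5.0, 10.0):
                current = classify_timepoint(
                    quad, ClassificationConfig(fold_threshold=theta)
                )
                if previous is TimepointCall.UNINDUCIBLE:
                    assert current not in responsive
                previous = current


class TestOverallCall:
    # quads that force a given timepoint call deterministically
    FORCING_QUAD = {
        TimepointCall.UNINDUCIBLE: (10, 50, 12, 13),
        TimepointCall.HYPOINDUCIBLE: (10, 100, 10, 25),
        TimepointCall.NORMOINDUCIBLE: (10, 50, 10, 55),
        TimepointCall.HYPERINDUCIBLE: (10, 50, 10, 500),
        TimepointCall.LATE: (10, 15, 100, 150),
        TimepointCall.HYPERINDUCIBLE_2: (10, 15, 100, 250),
        TimepointCall.DE_NOVO: (10, 15, 12, 50),
        TimepointCall.UNRESPONSIVE: (10, 15, 12, 14),
    }

    def test_uninducible_plus_late_is_tolerizeable(self):
        q1 = ResponseQuad(*self.FORCING_QUAD[TimepointCall.UNINDUCIBLE])
        q4 = ResponseQuad(*self.FORCING_QUAD[TimepointCall.LATE])
        call = overall_call(TimepointCall.UNINDUCIBLE, TimepointCall.LATE, q1, q4)
        assert call.overall is Tolerance.T
        assert call.subcategory is Subcategory.NONE

    def test_any_secondary_response_makes_non_tolerizeable(self):
        q1 = ResponseQuad(*self.FORCING_QUAD[TimepointCall.UNRESPONSIVE])
        q4 = ResponseQuad(*self.FORCING_QUAD[TimepointCall.HYPOINDUCIBLE])
        call = overall_call(TimepointCall.UNRESPONSIVE, TimepointCall.HYPOINDUCIBLE, q1, q4)
        assert call.overall is Tolerance.NT

    def test_doubly_unresponsive_is_unclassified_for_tolerance(self):
        q = ResponseQuad(*self.FORCING_QUAD[TimepointCall.UNRESPONSIVE])
        call = overall_call(TimepointCall.UNRESPONSIVE, TimepointCall.UNRESPONSIVE, q, q)
        assert call.overall is Tolerance.UNCLASSIFIED
        assert call.subcategory is Subcategory.NONE

    def test_all_64_call_pairs_match_verbal_definitions(self):
        for c1, c4 in itertools.product(TimepointCall, repeat=2):
            q1 = ResponseQuad(*self.FORCING_QUAD[c1])
            q4 = ResponseQuad(*self.FORCING_QUAD[c4])
            got = overall_call(c1, c4, q1, q4)
            assert got.overall.value == overall_oracle(c1.value, c4.value)

    def test_t_and_nt_disjoint_by_construction(self):
        overalls = {
            overall_call(
                c1, c4,
                ResponseQuad(*self.FORCING_QUAD[c1]),
                ResponseQuad(*self.FORCING_QUAD[c4]),
            ).overall
            for c1, c4 in itertools.product(TimepointCall, repeat=2)
        }
        assert overalls == {Tolerance.T, Tolerance.NT, Tolerance.UNCLASSIFIED}


class TestSustainedExpression:
    def _quads(self, baseline=10, residual_1h=100, secondary_1h=110,
               residual_4h=20, secondary_4h=95):
        q1 = ResponseQuad(baseline, 80, residual_1h, secondary_1h)
        q4 = ResponseQuad(baseline, 80, residual_4h, secondary_4h)
        return q1, q4

    def test_all_three_criteria_satisfied(self):
        assert is_sustained_expression(*self._quads()) is True

    def test_slow_decay_without_agonist_violates_criterion_ii(self):
        assert is_sustained_expression(*self._quads(residual_4h=60)) is False

    def test_further_upregulation_violates_criterion_iii(self):
        assert is_sustained_expression(*self._quads(secondary_4h=210)) is False

    def test_lenient_mode_accepts_residual_only_elevation(self):
        q1, q4 = self._quads(secondary_1h=15)  # secondary at 1 h not elevated
        strict = ClassificationConfig(se_requires_both_1h=True)
        lenient = ClassificationConfig(se_requires_both_1h=False)
        assert is_sustained_expression(q1, q4, strict) is False
        assert is_sustained_expression(q1, q4, lenient) is True


class TestClassifySequence:
    def test_degenerate_sequence_without_agonists_classifies_nothing(self):
        rng = np.random.default_rng(0)
        values = rng.integers(50, 5000, size=(30, 18))
        rpm = compute_rpm(toy_count_matrix(values))
        table = classify_sequence(rpm, Stimulus.NONE, Stimulus.NONE)
        assert (table["overall"] == Tolerance.UNCLASSIFIED.value).all()
        assert table.attrs["coverage"] == 0.0

    def test_gene_order_permutation_permutes_rows_identically(self):
        rng = np.random.default_rng(1)
        values = rng.integers(50, 5000, size=(40, 18))
        rpm = compute_rpm(toy_count_matrix(values))
        base = classify_sequence(rpm, Stimulus.L, Stimulus.L)
        perm = rng.permutation(40)
        rpm_perm = compute_rpm(
            toy_count_matrix(values[perm])
        )
        rpm_perm.rpm.index = rpm.rpm.index[perm]
        shuffled = classify_sequence(rpm_perm, Stimulus.L, Stimulus.L)
        assert base.loc[shuffled.index, "call_1h"].tolist() == shuffled["call_1h"].tolist()
        assert base.loc[shuffled.index, "overall"].tolist() == shuffled["overall"].tolist()

    def test_missing_condition_named_in_error(self):
        rng = np.random.default_rng(2)
        values = rng.integers(50, 5000, size=(10, 18))
        rpm = compute_rpm(toy_count_matrix(values))
        dropped = [l for l in rpm.rpm.columns if "L->L@4h" not in l]
        rpm.rpm = rpm.rpm[dropped]
        rpm.conditions = {l: rpm.conditions[l] for l in dropped}
        with pytest.raises(ValueError, match="L->L@4h"):
            classify_sequence(rpm, Stimulus.L, Stimulus.L)

    def test_archetype_construction_labels_recovered(self, classified_simulation):
        """Pure-archetype genes come back as their construction labels."""
        from toleromics.synthetic import EXPECTED_CALLS, Archetype

        _, _, tab1, _, truth = classified_simulation
        merged = tab1.join(truth)
        for arch, (c1, c4, overall, sub) in EXPECTED_CALLS.items():
            rows = merged[merged["archetype"] == arch.value]
            if arch is Archetype.LOW_EXPRESSED or rows.empty:
                continue  # removed by the abundance filter
            frac_overall = (rows["overall"] == overall.value).mean()
            assert frac_overall >= 0.95, arch
            frac_sub = (rows["subcategory"] == sub.value).mean()
            assert frac_sub >= 0.95, arch


class TestFosterCriterion:
    def _rpm_with_ratio(self, secondary_scale: float):
        # baseline 10, primary 100 (inducible), residual 40, secondary scaled
        cm = toy_count_matrix(np.full((1, 18), 10, dtype=int))
        df = cm.counts.astype(float)
        for lib, cond in cm.conditions.items():
            if cond.first is Stimulus.NONE and cond.second is Stimulus.L:
                df[lib] = 100
            elif cond.first is Stimulus.L and cond.second is Stimulus.NONE:
                df[lib] = 40
            elif cond.first is Stimulus.L and cond.second is Stimulus.L:
                df[lib] = 100 * secondary_scale
        cm.counts = df.round().astype(int)
        # equal library totals: pad with a balancing gene
        pad = df.max().max() * 2 - df.sum(axis=0)
        cm.counts.loc["PAD"] = pad.round().astype(int)
        return compute_rpm(cm)

    def test_equal_expression_is_included_boundary(self):
        rpm = self._rpm_with_ratio(1.0)
        assert "G0" in foster_nt_criterion(rpm, Stimulus.L, Stimulus.L)

    def test_slightly_lower_expression_is_excluded(self):
        rpm = self._rpm_with_ratio(0.99)
        assert "G0" not in foster_nt_criterion(rpm, Stimulus.L, Stimulus.L)

    def test_foster_set_strictly_contains_nh_among_inducible_genes(
        self, classified_simulation
    ):
        """High residual expression inflates the single-ratio NT definition."""
        rpm1, _, tab1, _, _ = classified_simulation
        foster = foster_nt_criterion(rpm1, Stimulus.L, Stimulus.L) & set(tab1.index)
        inducible_4h = set(tab1.index[tab1["i_primary_4h"] > 2.0])
        nh = set(tab1.index[tab1["subcategory"] == Subcategory.NH.value])
        assert (nh & inducible_4h) <= foster
        assert len(foster) > len(nh & inducible_4h)
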
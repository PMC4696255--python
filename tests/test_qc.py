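"""QC cascade: hand-enumerated ledger, rule predicates, precedence,
denominator conventions, conservation and ordering properties."""

import numpy as np
import pytest

from arraycascade import ArraySimConfig, FlaggedMatrix, QcConfig, run_qc, simulate_arrays
from arraycascade.errors import ConfigError, PipelineError
from arraycascade.qc import (
    StageRecord,
    drop_controls,
    drop_unreliable_probesets,
    mask_outliers,
    mask_poor_and_negative,
)

NAN = float("nan")


def _matrix(values, flags, is_control=None, groups=3):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    arrays = [f"A{i}" for i in range(groups)] + [f"B{i}" for i in range(k - groups)]
    return FlaggedMatrix(
        probe_ids=[f"p{i}" for i in range(n)],
        array_ids=arrays,
        intensities=values,
        flags=np.array([list(f) for f in flags], dtype=object),
        is_control=np.zeros(n, dtype=bool) if is_control is None else np.array(is_control),
        group_of={a: ("g1" if a.startswith("A") else "g2") for a in arrays},
    )


class TestDropControls:
    def test_counts_and_removes(self):
        m = _matrix(np.full((10, 6), 5.0), ["GGGGGG"] * 10,
                    is_control=[True] * 3 + [False] * 7)
        out, rec = drop_controls(m)
        assert out.n_probes == 7 and rec.n_removed == 3
        assert rec.denominator == 10

    def test_no_controls_is_identity(self):
        m = _matrix(np.full((4, 6), 5.0), ["GGGGGG"] * 4)
        out, rec = drop_controls(m)
        assert out.probe_ids == m.probe_ids and rec.n_removed == 0


class TestMaskPoorAndNegative:
    @pytest.mark.parametrize(
        "flag,value,expect_poor,expect_neg",
        [
            ("L", 5.0, 1, 0),   # poor flag, positive value
            ("G", -2.0, 0, 1),  # good flag, negative value
            ("L", -2.0, 1, 0),  # both: counted once, as poor (precedence)
            ("G", 5.0, 0, 0),   # clean
        ],
    )
    def test_precedence_enumeration(self, flag, value, expect_poor, expect_neg):
        vals = np.full((1, 6), 5.0)
        vals[0, 0] = value
        flags = [flag + "GGGGG"]
        out, poor, neg = mask_poor_and_negative(_matrix(vals, flags))
        assert poor.n_removed == expect_poor
        assert neg.n_removed == expect_neg
        if expect_poor or expect_neg:
            assert np.isnan(out.intensities[0, 0])

    def test_masked_cells_become_missing_not_removed(self):
        vals = np.full((2, 6), 5.0)
        vals[0, 1] = -1.0
        out, _, neg = mask_poor_and_negative(_matrix(vals, ["GGGGGG"] * 2))
        assert out.n_probes == 2 and neg.n_removed == 1


class TestProbesetRules:
    def test_rule_a_fires_on_half_missing_in_one_group(self):
        vals = np.full((1, 6), 5.0)
        vals[0, 0] = vals[0, 1] = NAN
        out, rec_a, _ = drop_unreliable_probesets(_matrix(vals, ["GGGGGG"]))
        assert out.n_probes == 0 and rec_a.n_removed == 1

    def test_mixed_flags_retained_when_one_group_reliable(self):
        # flags (G,G,L | L,L,L), all values positive: group 1 has 2/3 good
        # and 3/3 above threshold -> retained
        out, rec_a, rec_b = drop_unreliable_probesets(
            _matrix(np.full((1, 6), 5.0), ["GGLLLL"])
        )
        assert out.n_probes == 1 and rec_a.n_removed == 0 and rec_b.n_removed == 0

    def test_rule_b_fires_when_no_group_reliable(self):
        out, _, rec_b = drop_unreliable_probesets(
            _matrix(np.full((1, 6), 5.0), ["LLGLLG"])  # 1/3 good in both groups
        )
        assert out.n_probes == 0 and rec_b.n_removed == 1

    def test_rule_a_sees_earlier_masking(self):
        # all flags good but one group fully masked to missing earlier
        vals = np.full((1, 6), 5.0)
        vals[0, :3] = NAN
        _, rec_a, _ = drop_unreliable_probesets(_matrix(vals, ["GGGGGG"]))
        assert rec_a.n_removed == 1

    def test_values_at_threshold_not_above(self):
        out, _, rec_b = drop_unreliable_probesets(
            _matrix(np.zeros((1, 6)), ["GGGGGG"])
        )
        assert rec_b.n_removed == 1


class TestMaskOutliers:
    @pytest.mark.parametrize(
        "group_vals,n_masked",
        [
            ((10, 10, 41), 1),  # 41/10 = 4.1 > 4
            ((10, 10, 40), 0),  # exactly fourfold: retained (strict)
            ((10, 10, 10), 0),  # all equal
        ],
    )
    def test_fourfold_rule(self, group_vals, n_masked):
        vals = np.array([[*group_vals, 10.0, 10.0, 10.0]])
        out, rec = mask_outliers(_matrix(vals, ["GGGGGG"]))
        assert rec.n_removed == n_masked

    def test_low_outlier_masked(self):
        vals = np.array([[10.0, 10.0, 2.0, 10.0, 10.0, 10.0]])
        _, rec = mask_outliers(_matrix(vals, ["GGGGGG"]))
        assert rec.n_removed == 1  # median/2 = 5 > 4

    def test_single_observed_value_skipped(self):
        vals = np.array([[10.0, NAN, NAN, 10.0, 10.0, 10.0]])
        _, rec = mask_outliers(_matrix(vals, ["GGGGGG"]))
        assert rec.n_removed == 0


class TestRunQcLedger:
    def test_hand_fixture_matches_hand_enumeration(self, hand_qc_matrix):
        filtered, rep = run_qc(hand_qc_matrix)
        assert rep["control_probes"].n_removed == 1
        assert rep["poor_flag_values"].n_removed == 7
        assert rep["negative_values"].n_removed == 1
        assert rep["group_missingness"].n_removed == 3
        assert rep["group_reliability"].n_removed == 1
        assert rep["outlier_values"].n_removed == 1
        assert rep.probes_remaining == 7
        assert rep.probesets_with_missing == 4
        assert rep.n_missing_values_remaining == 4
        assert set(filtered.probe_ids) == {"P02", "P03", "P04", "P06", "P08",
                                           "P09", "P11"}
        # denominator conventions on this fixture
        assert rep["poor_flag_values"].denominator == 72          # raw cells
        assert rep["group_reliability"].denominator == 11         # post-control
        assert rep["outlier_values"].denominator == 42            # post-filter cells

    def test_ledger_conservation(self, small_sim):
        m, _ = small_sim
        _, rep = run_qc(m)
        assert rep.probes_remaining == (
            rep.probes_in
            - rep["control_probes"].n_removed
            - rep["group_missingness"].n_removed
            - rep["group_reliability"].n_removed
        )

    def test_idempotent_on_own_output(self):
        # outlier-free corruption: rerunning the cascade on its own output
        # (controls gone, masking applied) must remove nothing further.
        # With outlier corruption strict idempotence cannot hold: masking
        # an outlier late in pass 1 can push a probe over rule A's
        # missingness threshold for pass 2.
        m, _ = simulate_arrays(
            ArraySimConfig(n_probes=2_000, n_control=150, seed=13,
                           frac_outlier=0.0)
        )
        once, _ = run_qc(m)
        twice, rep2 = run_qc(once)
        assert rep2["control_probes"].n_removed == 0
        assert rep2["group_missingness"].n_removed == 0
        assert rep2["group_reliability"].n_removed == 0
        assert rep2["outlier_values"].n_removed == 0
        assert twice.probe_ids == once.probe_ids

    def test_threshold_monotonicity(self, small_sim):
        m, _ = small_sim
        _, loose = run_qc(m, QcConfig(outlier_fold=8.0))
        _, tight = run_qc(m, QcConfig(outlier_fold=4.0))
        assert tight["outlier_values"].n_removed >= loose["outlier_values"].n_removed
        _, strict = run_qc(m, QcConfig(group_missing_frac=0.3))
        assert strict["group_missingness"].n_removed >= \
            run_qc(m)[1]["group_missingness"].n_removed

    def test_masking_before_rule_a_changes_outcome(self):
        # P10-style probe: poor flags on 2/3 of group 1, values all present
        vals = np.full((2, 6), 5.0)
        m = _matrix(vals, ["LLGGGG", "GGGGGG"])
        # canonical order: mask first -> rule A fires
        masked, _, _ = mask_poor_and_negative(m)
        _, rec_a, _ = drop_unreliable_probesets(masked)
        assert rec_a.n_removed == 1
        # swapped order: rule A sees no missing values -> survives
        _, rec_a_swapped, _ = drop_unreliable_probesets(m)
        assert rec_a_swapped.n_removed == 0

    def test_all_controls_aborts_with_stage_name(self):
        m = _matrix(np.full((3, 6), 5.0), ["GGGGGG"] * 3, is_control=[True] * 3)
        with pytest.raises(PipelineError, match="control"):
            run_qc(m)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            QcConfig(outlier_fold=0.5)
        with pytest.raises(ConfigError):
            QcConfig(group_missing_frac=0.0)


class TestPercentConventions:
    @pytest.mark.parametrize(
        "n,den,expected",
        [
            (7177, 35_129 - 1_280, 21.2),   # probe-set rule vs post-control probes
            (1603, 35_129 * 6, 0.8),        # negative values vs raw cells
            (1300, 35_129 * 6, 0.6),        # poor-flag values vs raw cells
            (1235, 26_452 * 6, 0.8),        # residual missing vs final cells
            (427, 26_469 * 6, 0.3),         # outliers vs post-filter cells
        ],
    )
    def test_one_decimal_percentages(self, n, den, expected):
        assert StageRecord("s", "values", n, den).percent_removed == expected
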
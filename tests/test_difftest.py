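import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from diaquant import (Comparison, adjust_bh, compartment_overlap,
                      flag_regulated, precursor_tests, rollup_to_protein)
from diaquant.difftest import OverlapReport
from diaquant.errors import ConfigError, IntegrityError

from test_preprocess import matrix_from
from conftest import make_design


def bh_stepup(p):
    """Independent brute-force BH step-up (textbook definition)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adj[i] = running_min
    return adj


@pytest.fixture
def design_3v3():
    return make_design({"B": 3, "V": 3})


def run_tests(arr, design, proteins=None, **kw):
    m = matrix_from(arr, design, proteins=proteins)
    comps = [Comparison("V", "B")]
    return precursor_tests(m, comps, **kw)


class TestPrecursorTests:
    def test_identical_groups_give_zero_fc_unit_p(self, design_3v3):
        out = run_tests([[1, 2, 3, 1, 2, 3]], design_3v3)
        assert out.loc[0, "log2fc"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_matches_pooled_t_oracle(self, design_3v3):
        rng = np.random.default_rng(10)
        arr = rng.normal(10, 1, size=(120, 6))
        out = run_tests(arr, design_3v3)
        t_ref, p_ref = sps.ttest_ind(arr[:, 3:], arr[:, :3], axis=1,
                                     equal_var=True)
        assert np.allclose(out["p"], p_ref, atol=1e-10)
        assert np.allclose(out["log2fc"],
                           arr[:, 3:].mean(axis=1) - arr[:, :3].mean(axis=1),
                           atol=1e-12)

    def test_zero_variance_unequal_means_is_degenerate(self, design_3v3):
        out = run_tests([[4, 4, 4, 5, 5, 5]], design_3v3)
        assert out.loc[0, "log2fc"] == 1.0
        assert out.loc[0, "p"] == 0.0
        assert bool(out.loc[0, "degenerate"])

    def test_sign_convention_and_flip(self, design_3v3):
        arr = [[1.0, 1.0, 1.0, 3.0, 3.0, 3.0]]
        fwd = run_tests(arr, design_3v3)
        rev = run_tests(arr, design_3v3, flip_sign=True)
        assert fwd.loc[0, "log2fc"] == 2.0
        assert rev.loc[0, "log2fc"] == -2.0

    def test_incomplete_matrix_rejected(self, design_3v3):
        m = matrix_from([[1, 2, 3, np.nan, 2, 3]], design_3v3)
        with pytest.raises(ConfigError, match="complete"):
            precursor_tests(m, [Comparison("V", "B")])

    def test_single_run_group_rejected(self):
        design = make_design({"B": 3, "X": 1})
        m = matrix_from([[1, 2, 3, 4]], design)
        with pytest.raises(ConfigError, match=">= 2 runs"):
            precursor_tests(m, [Comparison("X", "B")])


class TestRollup:
    def test_single_precursor_is_identity(self):
        stats = pd.DataFrame({
            "precursor_id": ["pre1"], "protein_group": ["P1"],
            "comparison": ["V_vs_B"], "log2fc": [1.7], "p": [0.03]})
        out = rollup_to_protein(stats)
        assert out.loc[0, "log2fc"] == 1.7
        assert out.loc[0, "p"] == 0.03
        assert out.loc[0, "n_precursors"] == 1

    def test_arithmetic_mean_of_metrics(self):
        stats = pd.DataFrame({
            "precursor_id": ["a", "b"], "protein_group": ["P1", "P1"],
            "comparison": ["V_vs_B"] * 2,
            "log2fc": [1.0, 2.0], "p": [0.02, 0.04]})
        out = rollup_to_protein(stats)
        assert out.loc[0, "log2fc"] == pytest.approx(1.5)
        assert out.loc[0, "p"] == pytest.approx(0.03)

    def test_matches_independent_accumulation_and_order_invariance(self):
        rng = np.random.default_rng(11)
        stats = pd.DataFrame({
            "precursor_id": [f"pre{i}" for i in range(5)],
            "protein_group": ["P1"] * 5,
            "comparison": ["V_vs_B"] * 5,
            "log2fc": rng.normal(size=5), "p": rng.random(5)})
        acc_fc = acc_p = 0.0
        for _, row in stats.iterrows():
            acc_fc += row["log2fc"]
            acc_p += row["p"]
        out = rollup_to_protein(stats)
        shuffled = rollup_to_protein(stats.sample(frac=1, random_state=1))
        assert abs(out.loc[0, "log2fc"] - acc_fc / 5) < 1e-12
        assert abs(out.loc[0, "p"] - acc_p / 5) < 1e-12
        assert out.loc[0, "log2fc"] == pytest.approx(
            shuffled.loc[0, "log2fc"], rel=1e-12)


class TestAdjustBH:
    @staticmethod
    def _frame(ps, comparison="V_vs_B"):
        return pd.DataFrame({
            "protein_group": [f"P{i}" for i in range(len(ps))],
            "comparison": comparison, "n_precursors": 1,
            "log2fc": 0.0, "p": ps})

    @pytest.mark.parametrize("ps,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.07], [0.07]),
    ])
    def test_hand_worked_step_up_values(self, ps, expected):
        out = adjust_bh(self._frame(ps))
        assert np.allclose(out["p_adj"], expected, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            ps = rng.random(rng.integers(1, 40))
            out = adjust_bh(self._frame(ps))
            assert np.allclose(out["p_adj"], bh_stepup(ps), atol=1e-12)

    def test_families_are_per_comparison(self):
        a = self._frame([0.01, 0.5], "V_vs_B")
        b = self._frame([0.03], "TH_vs_B")
        out = adjust_bh(pd.concat([a, b], ignore_index=True))
        by = out.set_index(["comparison", "protein_group"])["p_adj"]
        assert by[("V_vs_B", "P0")] == pytest.approx(0.02)
        assert by[("TH_vs_B", "P0")] == pytest.approx(0.03)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(IntegrityError):
            adjust_bh(self._frame([0.5, 1.5]))


class TestFlagRegulated:
    @pytest.mark.parametrize("lfc,p_adj,expected", [
        (1.0, 0.05, True),     # both boundaries inclusive
        (0.99, 0.001, False),  # below the fold-change threshold
        (-3.0, 0.01, True),    # absolute value of the fold change
        (2.0, 0.051, False),
    ])
    def test_threshold_boundaries(self, lfc, p_adj, expected):
        stats = pd.DataFrame({"protein_group": ["P1"],
                              "comparison": ["V_vs_B"],
                              "log2fc": [lfc], "p": [0.01],
                              "p_adj": [p_adj]})
        out = flag_regulated(stats)
        assert bool(out.loc[0, "regulated"]) is expected
        assert bool(out.loc[0, "significant"]) is expected

    def test_negative_thresholds_rejected(self):
        stats = pd.DataFrame({"protein_group": ["P1"],
                              "comparison": ["V_vs_B"],
                              "log2fc": [1.0], "p": [0.01], "p_adj": [0.01]})
        with pytest.raises(ConfigError):
            flag_regulated(stats, lfc_threshold=-1)


class TestCompartmentOverlap:
    def test_study_partition_arithmetic(self):
        report = OverlapReport(a_only=5629, b_only=495, shared=3748)
        assert report.total == 9872
        assert report.a_only_pct == 57

    def test_disjoint_singletons(self):
        report = compartment_overlap({"x"}, {"y"})
        assert report.shared == 0
        assert report.a_only_pct == 50 and report.b_only_pct == 50

    def test_identical_sets_fully_shared(self):
        report = compartment_overlap({"x", "y"}, {"x", "y"})
        assert report.shared_pct == 100 and report.a_only == 0

    def test_empty_sets_allowed(self):
        report = compartment_overlap(set(), set())
        assert report.total == 0
        assert np.isnan(report.shared_pct)
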
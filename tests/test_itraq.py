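"""Unit and property tests for reporter-ratio quantification and DEP calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from netpharm import itraq
from netpharm.itraq import (
    ConfigurationError,
    DepThresholds,
    call_deps,
    compute_peptide_ratios,
    correct_isotope_overlap,
    normalize_ratios,
    rollup_protein,
    run_quant_pipeline,
    test_differential as differential_p,
    validate_purity_matrix,
)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def _spectrum(areas, pep="p1", acc="P1", batch=1):
    return pd.DataFrame(
        {
            "peptide_id": [pep],
            "protein_acc": [acc],
            "batch": [batch],
            "area_114": [areas[0]],
            "area_115": [areas[1]],
            "area_116": [areas[2]],
            "area_117": [areas[3]],
            "protein_score": [10.0],
            "unused_score": [5.0],
        }
    )


class TestPeptideRatios:
    @pytest.mark.parametrize(
        "areas, expected",
        [
            ((50.0, 100.0, 50.0, 25.0), (2.0, 1.0, 0.5)),
            ((70.0, 70.0, 70.0, 70.0), (1.0, 1.0, 1.0)),
        ],
    )
    def test_direct_division(self, areas, expected):
        out = compute_peptide_ratios(_spectrum(areas))
        assert tuple(out[["ratio_115", "ratio_116", "ratio_117"]].iloc[0]) == expected

    def test_zero_reference_excluded_not_fatal(self):
        df = pd.concat(
            [_spectrum((0.0, 1.0, 1.0, 1.0)), _spectrum((10.0, 20.0, 10.0, 5.0), pep="p2")],
            ignore_index=True,
        )
        out = compute_peptide_ratios(df)
        assert list(out["peptide_id"]) == ["p2"]


class TestIsotopeCorrection:
    def test_identity_passthrough(self):
        areas = np.array([10.0, 20.0, 30.0, 40.0])
        assert np.allclose(correct_isotope_overlap(areas, np.eye(4)), areas)

    def test_recovers_truth_after_forward_leakage(self):
        # 10% of channel 115's signal leaks into channel 114
        m = np.eye(4)
        m[0, 1], m[1, 1] = 0.10, 0.90
        true = np.array([100.0, 200.0, 50.0, 25.0])
        observed = m @ true
        assert np.allclose(correct_isotope_overlap(observed, m), true, atol=1e-10)

    def test_bad_column_sums_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.5
        with pytest.raises(ConfigurationError, match="sum to 1"):
            validate_purity_matrix(m)

    def test_negative_correction_clipped(self):
        m = np.eye(4)
        m[0, 1], m[1, 1] = 0.5, 0.5
        observed = np.array([1.0, 10.0, 1.0, 1.0])  # inconsistent with m, x<0
        out = correct_isotope_overlap(observed, m)
        assert (out >= 0).all()


class TestRollupAndNormalize:
    def test_mean_of_peptides(self, toy_spectra):
        ratios = compute_peptide_ratios(toy_spectra)
        rolled = rollup_protein(ratios)
        # independent spreadsheet-style recomputation over the 3-row fixture
        expected = {
            "ratio_115": (200 / 100 + 600 / 200 + 25 / 50) / 3,
            "ratio_116": (100 / 100 + 200 / 200 + 50 / 50) / 3,
            "ratio_117": (50 / 100 + 100 / 200 + 100 / 50) / 3,
        }
        for col, val in expected.items():
            assert rolled[col].iloc[0] == pytest.approx(val)
        assert rolled["n_peptides"].iloc[0] == 3

    def test_single_peptide_passthrough(self):
        ratios = compute_peptide_ratios(_spectrum((50.0, 100.0, 50.0, 25.0)))
        rolled = rollup_protein(ratios)
        assert tuple(rolled[["ratio_115", "ratio_116", "ratio_117"]].iloc[0]) == (
            2.0, 1.0, 0.5,
        )

    def test_median_normalization_example(self):
        rollup = pd.DataFrame(
            {
                "protein_acc": ["A", "B", "C"],
                "batch": [1, 1, 1],
                "ratio_115": [1.0, 2.0, 4.0],
                "ratio_116": [1.0, 2.0, 4.0],
                "ratio_117": [1.0, 2.0, 4.0],
            }
        )
        out = normalize_ratios(rollup)
        assert list(out["ratio_115"]) == [0.5, 1.0, 2.0]
        assert np.median(out["ratio_116"]) == 1.0

    def test_single_protein_normalizes_to_one(self):
        rollup = pd.DataFrame(
            {"protein_acc": ["A"], "batch": [1],
             "ratio_115": [2.0], "ratio_116": [3.0], "ratio_117": [0.5]}
        )
        out = normalize_ratios(rollup)
        assert list(out[["ratio_115", "ratio_116", "ratio_117"]].iloc[0]) == [1, 1, 1]

    def test_normalization_idempotent(self, small_itraq):
        _, spectra, _ = small_itraq
        rolled = rollup_protein(compute_peptide_ratios(spectra))
        once = normalize_ratios(rolled)
        twice = normalize_ratios(once)
        assert np.allclose(
            once[itraq.RATIO_COLUMNS].to_numpy(),
            twice[itraq.RATIO_COLUMNS].to_numpy(),
            atol=1e-12,
        )

    def test_empty_batch_is_error(self):
        with pytest.raises(ConfigurationError):
            normalize_ratios(pd.DataFrame(columns=["batch", *itraq.RATIO_COLUMNS]))


class TestDifferentialTest:
    def test_matches_closed_form_oracle(self):
        ratios = [2.0, 2.1, 1.9, 2.05]
        expected = oracles.t_test_p_closed_form([math.log2(r) for r in ratios])
        assert differential_p(np.array(ratios)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_doubling_shifts_log_mean(self):
        ratios = np.array([1.1, 1.3, 0.9, 1.2, 1.05])
        doubled = 2 * ratios
        p1 = differential_p(ratios)
        p2 = differential_p(doubled)
        expected = oracles.t_test_p_closed_form([math.log2(r) for r in doubled])
        assert p2 == pytest.approx(expected, abs=1e-10)
        assert p2 < p1  # mean log2 moved from ~0 to ~1 at equal spread

    def test_zero_variance_not_testable(self):
        assert math.isnan(differential_p(np.array([1.0, 1.0, 1.0])))
        assert math.isnan(differential_p(np.array([2.0])))


def _summary_row(acc="P1", ratio=2.0, p=0.01, n_pep=3, score=5.0, cons=0.9):
    return {
        "protein_acc": acc,
        "mean_ratio": ratio,
        "p_value": p,
        "n_peptides": n_pep,
        "unused_score": score,
        "consensus_fraction": cons,
    }


class TestCallDeps:
    def test_dead_zone_never_called(self):
        summary = pd.DataFrame([_summary_row(ratio=1.0, p=1e-9)])
        assert call_deps(summary).empty

    @pytest.mark.parametrize("ratio", [1.2, 0.8])
    def test_boundary_ratio_excluded_by_strict_inequality(self, ratio):
        summary = pd.DataFrame([_summary_row(ratio=ratio, p=0.01)])
        assert call_deps(summary).empty

    @pytest.mark.parametrize(
        "override, called",
        [
            ({}, True),
            ({"p_value": 0.06}, False),
            ({"n_peptides": 1}, False),
            ({"unused_score": 2.0}, False),     # strict: exactly 2 fails
            ({"n_peptides": 2}, True),          # non-strict: exactly 2 passes
            ({"consensus_fraction": 25 / 30}, False),
            ({"ratio": 0.5}, True),
        ],
    )
    def test_each_filter_bites(self, override, called):
        row = _summary_row()
        row.update({("mean_ratio" if k == "ratio" else k): v
                    for k, v in override.items()})
        deps = call_deps(pd.DataFrame([row]))
        assert (len(deps) == 1) is called

    def test_sorted_by_abs_log2_ratio(self):
        summary = pd.DataFrame(
            [_summary_row("A", 1.5), _summary_row("B", 0.25), _summary_row("C", 3.0)]
        )
        assert list(call_deps(summary)["protein_acc"]) == ["B", "C", "A"]

    def test_threshold_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            DepThresholds(up=0.9)
        with pytest.raises(ConfigurationError):
            DepThresholds(alpha=1.5)


class TestPipelineInvariances:
    def test_row_order_never_matters(self, small_itraq):
        _, spectra, _ = small_itraq
        summary1, deps1 = run_quant_pipeline(spectra)
        shuffled = spectra.sample(frac=1.0, random_state=5).reset_index(drop=True)
        summary2, deps2 = run_quant_pipeline(shuffled)
        pd.testing.assert_frame_equal(summary1, summary2)
        pd.testing.assert_frame_equal(deps1, deps2)

    def test_common_channel_scaling_changes_nothing(self, small_itraq):
        _, spectra, _ = small_itraq
        scaled = spectra.copy()
        scaled[itraq.AREA_COLUMNS] *= 7.3
        _, deps1 = run_quant_pipeline(spectra)
        _, deps2 = run_quant_pipeline(scaled)
        pd.testing.assert_frame_equal(deps1, deps2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=0.95))
    def test_normalization_median_is_one(self, q):
        # any synthetic batch: post-normalization per-channel median == 1
        rng = np.random.default_rng(int(q * 1000))
        rollup = pd.DataFrame(
            {
                "protein_acc": [f"P{i}" for i in range(9)],
                "batch": [1] * 9,
                "ratio_115": rng.lognormal(0, q, 9),
                "ratio_116": rng.lognormal(0, q, 9),
                "ratio_117": rng.lognormal(0, q, 9),
            }
        )
        out = normalize_ratios(rollup)
        for col in itraq.RATIO_COLUMNS:
            assert np.median(out[col]) == pytest.approx(1.0, abs=1e-12)
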
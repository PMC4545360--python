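"""Unit tests of the SAM statistic, permutation null and call thresholds."""

import math
import statistics

import numpy as np
import pytest

from egwas_meta import ExperimentMatrix, SamConfig
from egwas_meta.sam import (
    call_probes,
    choose_s0,
    permutation_null,
    pooled_standard_errors,
    run_sam,
    sam_d_scores,
    sam_qc,
)

from conftest import make_matrix


def scalar_d_oracle(control, case, s0):
    """Independent scalar evaluation of d = diff / (pooled SE + s0)."""
    n1, n2 = len(control), len(case)
    diff = statistics.fmean(case) - statistics.fmean(control)
    ss1 = sum((x - statistics.fmean(control)) ** 2 for x in control)
    ss2 = sum((x - statistics.fmean(case)) ** 2 for x in case)
    s = math.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * (ss1 + ss2))
    return diff / (s + s0)


@pytest.mark.parametrize(
    "control,case,s0",
    [
        ([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], 1.0),  # zero dispersion: d = 1 exactly
        ([5.0, 5.5, 6.0], [7.0, 7.5, 8.3], 0.2),
        ([0.0, 1.0, 2.0, 3.0], [1.0, 0.0, 2.0], 0.05),
        ([8.1, 8.0, 7.9], [8.0, 8.1, 7.9], 0.1),
    ],
)
def test_d_score_matches_scalar_oracle(control, case, s0):
    matrix = make_matrix(np.array(control)[None, :], np.array(case)[None, :])
    d = sam_d_scores(matrix, s0)
    assert d[0] == pytest.approx(scalar_d_oracle(control, case, s0), abs=1e-12)


def test_d_score_zero_dispersion_example():
    matrix = make_matrix([[1.0, 1.0, 1.0]], [[2.0, 2.0, 2.0]])
    assert sam_d_scores(matrix, 1.0)[0] == pytest.approx(1.0)


def test_d_zero_numerator():
    matrix = make_matrix([[3.0, 4.0, 5.0]], [[3.0, 4.0, 5.0]])
    # identical values in both groups and s0 > 0 -> d = 0
    assert sam_d_scores(matrix, 0.5)[0] == pytest.approx(0.0)


def test_d_antisymmetry_under_group_swap():
    rng = np.random.default_rng(3)
    ctrl, case = rng.normal(size=(30, 3)), rng.normal(size=(30, 4))
    d_fwd = sam_d_scores(make_matrix(ctrl, case), 0.1)
    d_rev = sam_d_scores(make_matrix(case, ctrl), 0.1)
    np.testing.assert_allclose(d_fwd, -d_rev, atol=1e-12)


def test_d_invariant_under_within_group_reordering():
    rng = np.random.default_rng(4)
    ctrl, case = rng.normal(size=(25, 4)), rng.normal(size=(25, 3))
    d1 = sam_d_scores(make_matrix(ctrl, case), 0.2)
    d2 = sam_d_scores(make_matrix(ctrl[:, ::-1], case[:, [2, 0, 1]]), 0.2)
    np.testing.assert_allclose(d1, d2, atol=1e-12)


def test_undefined_probe_flagged_not_propagated():
    # constant probe in both groups with s0 = 0 has no defined score
    ctrl = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
    case = np.array([[1.0, 1.0, 1.0], [4.0, 5.0, 6.0]])
    matrix = make_matrix(ctrl, case)
    d = sam_d_scores(matrix, 0.0)
    assert np.isnan(d[0]) and np.isfinite(d[1])
    config = SamConfig(n_permutations=30, seed=0)
    null = permutation_null(matrix, config, 0.0)
    result = call_probes(matrix, d, null, config, s0=0.0)
    assert result.call[0] == "null" and not result.defined[0]


def test_missing_cells_complete_case_and_dropout():
    ctrl = np.array([[1.0, np.nan, 2.0, 1.5], [1.0, 1.1, 0.9, 1.2]])
    case = np.array([[2.0, 2.5, np.nan, 2.2], [np.nan, np.nan, np.nan, 2.0]])
    diff, s, _, _, usable = pooled_standard_errors(
        np.hstack([ctrl, case]),
        np.array([False] * 4 + [True] * 4),
        np.array([True] * 4 + [False] * 4),
    )
    assert usable[0] and not usable[1]  # probe 2: single case observation
    assert diff[0] == pytest.approx(
        statistics.fmean([2.0, 2.5, 2.2]) - statistics.fmean([1.0, 2.0, 1.5])
    )


@pytest.mark.parametrize("mode,expect", [(0.0, "min"), (1.0, "max"), (0.5, "median")])
def test_choose_s0_quantile_endpoints_and_median(mode, expect):
    rng = np.random.default_rng(5)
    matrix = make_matrix(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
    _, s, _, _, _ = pooled_standard_errors(matrix.values, matrix.case_mask, matrix.control_mask)
    oracle = {"min": min(s), "max": max(s), "median": sorted(s)[2]}[expect]
    assert choose_s0(matrix, mode) == pytest.approx(oracle)


def test_choose_s0_auto_deterministic(null_matrix_3v3):
    s0a = choose_s0(null_matrix_3v3, "auto")
    s0b = choose_s0(null_matrix_3v3, "auto")
    assert s0a == s0b and s0a >= 0


def test_s0_monotone_shrinkage(null_matrix_3v3):
    s0 = 0.1
    d1 = np.abs(sam_d_scores(null_matrix_3v3, s0))
    d2 = np.abs(sam_d_scores(null_matrix_3v3, 2 * s0))
    assert np.all(d2 <= d1 + 1e-12)


def test_permutation_null_3v3_enumerates_20(null_matrix_3v3):
    null = permutation_null(null_matrix_3v3, SamConfig(seed=1), s0=0.1)
    assert null.exhaustive and null.n_permutations == 20


def test_permutation_null_seed_independent_when_exhaustive(null_matrix_3v3):
    n1 = permutation_null(null_matrix_3v3, SamConfig(seed=1), s0=0.1)
    n2 = permutation_null(null_matrix_3v3, SamConfig(seed=999), s0=0.1)
    np.testing.assert_array_equal(n1.sorted_scores, n2.sorted_scores)


def test_permutation_null_symmetric_for_exchangeable_data(null_matrix_3v3):
    null = permutation_null(null_matrix_3v3, SamConfig(seed=1), s0=0.1)
    dbar = null.expected_order_stats
    # expected order statistics mirror about 0 within Monte-Carlo error
    assert np.abs(dbar + dbar[::-1]).max() < 0.2


def test_null_data_yields_no_calls_over_seeds():
    n_calls = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        matrix = make_matrix(rng.normal(8, 0.5, (300, 3)), rng.normal(8, 0.5, (300, 3)))
        result = run_sam(matrix, SamConfig(target_fdr=0.05, seed=seed))
        n_calls += int(np.sum(result.call != "null"))
    assert n_calls / (5 * 300) < 0.02


def test_strong_effect_recovered_with_planted_sign():
    rng = np.random.default_rng(42)
    m = 300
    ctrl = rng.normal(8, 0.3, (m, 3))
    case = rng.normal(8, 0.3, (m, 3))
    up, down = slice(0, 15), slice(15, 30)  # 10% of probes planted
    case[up] += 3.0
    case[down] -= 3.0
    result = run_sam(make_matrix(ctrl, case), SamConfig(target_fdr=0.05, seed=0))
    recovered_up = np.mean(result.call[up] == "positive")
    recovered_down = np.mean(result.call[down] == "negative")
    assert recovered_up >= 0.8 and recovered_down >= 0.8
    false_calls = np.mean(result.call[30:] != "null")
    assert false_calls < 0.1


def test_call_sign_consistency(null_matrix_3v3):
    config = SamConfig(seed=2)
    result = run_sam(null_matrix_3v3, config)
    d = result.d
    assert np.all(d[result.call == "positive"] > 0) if np.any(result.call == "positive") else True
    assert np.all(d[result.call == "negative"] < 0) if np.any(result.call == "negative") else True
    assert np.all((result.q_value >= 0) & (result.q_value <= 1))


def test_qc_passes_on_exchangeable_data(null_matrix_3v3):
    config = SamConfig(seed=1)
    s0 = choose_s0(null_matrix_3v3, "auto")
    d = sam_d_scores(null_matrix_3v3, s0)
    null = permutation_null(null_matrix_3v3, config, s0)
    qc = sam_qc(null_matrix_3v3, d, null)
    assert qc.passed
    assert qc.observed.size == int(np.isfinite(d).sum())


def test_qc_fails_on_constant_matrix():
    values = np.full((50, 6), 5.0)
    matrix = ExperimentMatrix(
        probe_ids=[f"p{i}" for i in range(50)],
        values=values,
        groups=np.array(["control"] * 3 + ["case"] * 3, dtype=object),
    )
    config = SamConfig(seed=1)
    d = sam_d_scores(matrix, 0.0)
    null = permutation_null(matrix, config, 0.0)
    assert not sam_qc(matrix, d, null).passed


def test_matrix_validation_errors():
    with pytest.raises(ValueError, match="replicates"):
        make_matrix(np.zeros((5, 2)), np.zeros((5, 3)))
    with pytest.raises(ValueError, match="group labels"):
        ExperimentMatrix(
            probe_ids=["a"], values=np.zeros((1, 6)),
            groups=np.array(["control"] * 3 + ["treated"] * 3, dtype=object),
        )
    with pytest.raises(ValueError, match="duplicated probe"):
        ExperimentMatrix(
            probe_ids=["a", "a"], values=np.zeros((2, 6)),
            groups=np.array(["control"] * 3 + ["case"] * 3, dtype=object),
        )


def test_sam_config_validation():
    with pytest.raises(ValueError):
        SamConfig(target_fdr=0.0)
    with pytest.raises(ValueError):
        SamConfig(n_permutations=0)
    with pytest.raises(ValueError):
        SamConfig(s0_quantile=1.5)
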
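"""Bland-Altman machinery: variance decomposition, bootstrap, Wilcoxon."""

import numpy as np
import pytest

from microrep.exams import pair_exams
from microrep.repeatability import (PairedSeries, UndefinedStatisticError,
                                    adjust_pvalues, bland_altman, cor_by_eye,
                                    global_series, mixed_sensitivity_cor,
                                    paired_wilcoxon, pointwise_series,
                                    round_cor_convention)
from microrep.synthetic import NoiseModel, simulate_cohort
from microrep.exams import make_pairs


def series_from_diffs(diffs, units=None, level="pointwise"):
    diffs = np.asarray(diffs, float)
    units = np.zeros(len(diffs)) if units is None else np.asarray(units)
    return PairedSeries(units, np.zeros(len(diffs)), diffs, level=level)


def anova_variance_components(diffs, units):
    """Independent oracle: balanced one-way random-effects ANOVA estimator.

    For n groups of equal size m: MS_within estimates s_e^2 and
    (MS_between - MS_within)/m estimates s_b^2.
    """
    diffs, units = np.asarray(diffs, float), np.asarray(units)
    groups = [diffs[units == u] for u in np.unique(units)]
    m = len(groups[0])
    assert all(len(g) == m for g in groups), "oracle assumes balance"
    grand = diffs.mean()
    ms_between = m * sum((g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (len(diffs) - len(groups))
    return max((ms_between - ms_within) / m, 0.0), ms_within


def test_constant_differences_zero_cor():
    res = bland_altman(series_from_diffs([2.0] * 10), method="naive", n_boot=0)
    assert res.bias == 2.0
    assert res.cor == 0.0
    assert (res.loa_lower, res.loa_upper) == (2.0, 2.0)


def test_single_unit_naive_hand_computed():
    res = bland_altman(series_from_diffs([-1.0, 0.0, 1.0]), method="naive", n_boot=0)
    assert res.bias == pytest.approx(0.0)
    assert res.sd_diff == pytest.approx(1.0)
    assert res.cor == pytest.approx(1.96)
    assert (res.loa_lower, res.loa_upper) == (pytest.approx(-1.96), pytest.approx(1.96))


def test_single_unit_mixed_rejected():
    with pytest.raises(ValueError, match="mixed method requires"):
        bland_altman(series_from_diffs([1.0, 2.0]), method="mixed", n_boot=0)


def test_mixed_equals_naive_with_one_observation_per_unit():
    rng = np.random.default_rng(3)
    diffs = rng.normal(0.5, 2.0, 40)
    units = np.arange(40)
    naive = bland_altman(series_from_diffs(diffs, units), "naive", n_boot=0)
    mixed = bland_altman(series_from_diffs(diffs, units), "mixed", n_boot=0)
    assert mixed.bias == pytest.approx(naive.bias, abs=1e-6)
    assert mixed.sd_diff == pytest.approx(naive.sd_diff, rel=0.02)


def test_mixed_matches_anova_oracle():
    """REML variance decomposition agrees with the closed-form balanced
    one-way ANOVA estimator on clustered differences."""
    rng = np.random.default_rng(7)
    n_units, m = 13, 68
    units = np.repeat(np.arange(n_units), m)
    diffs = (np.repeat(rng.normal(0, 1.5, n_units), m)
             + rng.normal(0.2, 3.0, n_units * m))
    res = bland_altman(series_from_diffs(diffs, units), "mixed", n_boot=0)
    var_b, var_e = anova_variance_components(diffs, units)
    assert res.var_between == pytest.approx(var_b, rel=0.05, abs=0.05)
    assert res.var_within == pytest.approx(var_e, rel=0.02)
    assert res.sd_diff == pytest.approx(np.sqrt(var_b + var_e), rel=0.02)
    assert res.sd_diff ** 2 == pytest.approx(res.var_between + res.var_within)


def test_parameter_recovery_known_variance_components():
    """Simulated d_il = mu + b_i + e_il recovers sqrt(s_b^2 + s_e^2)."""
    sigma_b, sigma_e = 1.5, 3.0
    truth = np.hypot(sigma_b, sigma_e)
    ests = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        units = np.repeat(np.arange(13), 68)
        d = np.repeat(rng.normal(0, sigma_b, 13), 68) + rng.normal(0, sigma_e, 13 * 68)
        ests.append(bland_altman(series_from_diffs(d, units), "mixed", n_boot=0).sd_diff)
    assert np.mean(ests) == pytest.approx(truth, rel=0.10)


def test_bootstrap_cis_contain_estimate_and_shrink():
    def width(n_units, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(0.3, 2.0, n_units)
        res = bland_altman(series_from_diffs(diffs, np.arange(n_units), "global"),
                           "naive", n_boot=300, seed=seed)
        assert res.ci_bias[0] <= res.bias <= res.ci_bias[1]
        assert res.ci_loa_lower[0] <= res.loa_lower <= res.ci_loa_lower[1]
        assert res.ci_loa_upper[0] <= res.loa_upper <= res.ci_loa_upper[1]
        return res.ci_bias[1] - res.ci_bias[0]

    assert width(100, 1) < width(13, 1)


def test_bootstrap_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        bland_altman(series_from_diffs([0.0, 1.0, 2.0]), "naive", n_boot=10)


def test_cor_invariant_to_relabeling_and_swap():
    rng = np.random.default_rng(11)
    units = np.repeat(np.arange(6), 10)
    a, b = rng.normal(10, 3, 60), rng.normal(10, 3, 60)
    s = PairedSeries(units, a, b)
    res = bland_altman(s, "mixed", n_boot=0)
    relabeled = PairedSeries(units[::-1], a[::-1], b[::-1])
    res2 = bland_altman(relabeled, "mixed", n_boot=0)
    assert res2.cor == pytest.approx(res.cor, rel=1e-6)
    swapped = bland_altman(PairedSeries(units, b, a), "mixed", n_boot=0)
    assert swapped.cor == pytest.approx(res.cor, rel=1e-6)
    assert swapped.bias == pytest.approx(-res.bias, abs=1e-8)


def test_cor_by_eye_identical_exams_zero(grid, make_exam):
    pairs = [pair_exams(make_exam(8.0, patient_id=p, eye=e, test_index=2),
                        make_exam(8.0, patient_id=p, eye=e, test_index=3))
             for p in ("A", "B") for e in ("right", "left")]
    for index in ("pointwise", "mean_sensitivity", "volume_sensitivity"):
        for res in cor_by_eye(pairs, index, grid, n_boot=0).values():
            assert res.cor == 0.0


def test_cor_by_eye_global_uses_naive(grid):
    exams = simulate_cohort(13, "mid", NoiseModel(), design="triplicate",
                            seed=5, grid=grid, eyes=("right",))
    pairs = make_pairs(exams)
    res = cor_by_eye(pairs, "mean_sensitivity", grid, n_boot=0)
    assert set(res) == {"right"}
    assert res["right"].method == "naive"
    assert res["right"].n_obs == 13
    ptw = cor_by_eye(pairs, "pointwise", grid, n_boot=0)["right"]
    assert ptw.method == "mixed"
    assert ptw.n_obs == 13 * 68


def test_missing_eye_omitted_with_warning(grid, make_exam, caplog):
    pairs = [pair_exams(make_exam(8.0, patient_id=p, test_index=2),
                        make_exam(9.0, patient_id=p, test_index=3))
             for p in ("A", "B")]
    with caplog.at_level("WARNING"):
        res = cor_by_eye(pairs, "mean_sensitivity", grid, n_boot=0)
    assert set(res) == {"right"}
    assert "left" in caplog.text


@pytest.mark.parametrize("cor, expected", [(9.5, 9.0), (9.0, 9.0), (0.7, 0.0)])
def test_round_cor_convention(cor, expected):
    assert round_cor_convention(cor) == expected


def test_round_cor_warns_on_degenerate(caplog):
    with caplog.at_level("WARNING"):
        round_cor_convention(0.7)
    assert "0" in caplog.text


def test_wilcoxon_undefined_on_equal_samples():
    with pytest.raises(UndefinedStatisticError):
        paired_wilcoxon([1.0, 2.0], [1.0, 2.0])


def test_wilcoxon_exact_small_sample():
    a = np.arange(1.0, 7.0)
    res = paired_wilcoxon(a, a + 10.0)
    assert res.p_raw == pytest.approx(0.03125)
    assert res.n == 6


def test_holm_adjustment_hand_computed():
    adj = adjust_pvalues([0.001, 0.02, 0.04, 0.2], "holm")
    assert adj == pytest.approx([0.004, 0.06, 0.08, 0.2])


def test_mixed_sensitivity_mode_agrees_roughly(grid):
    """The secondary sensitivity-response formulation implies a difference
    sd of sqrt(2) x residual sd, close to the difference-based estimate when
    the latent field is flat (no censoring distortion)."""
    exams = simulate_cohort(13, "flat", NoiseModel(), design="triplicate",
                            seed=2, grid=grid, eyes=("right",),
                            inter_eye_offset_sd_db=0.0)
    pairs = make_pairs(exams)
    primary = bland_altman(pointwise_series(pairs, grid), "mixed", n_boot=0)
    secondary = mixed_sensitivity_cor(pairs, grid)
    assert secondary["cor"] == pytest.approx(primary.cor, rel=0.10)
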
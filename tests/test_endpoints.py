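"""Binomial endpoint false positives and change classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microrep.endpoints import (EndpointSpec, classify_global,
                                classify_pointwise, concordance,
                                endpoint_false_positive_prob,
                                monte_carlo_endpoint_check)
from microrep.exams import pair_exams


def brute_force_tail(n, k, p):
    """Oracle: direct summation of binomial pmf terms."""
    return sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


@pytest.mark.parametrize("n, k, p", [(68, 5, 0.05), (36, 5, 0.05),
                                     (16, 5, 0.05), (10, 3, 0.2), (5, 5, 1.0)])
def test_analytic_matches_brute_force(n, k, p):
    assert endpoint_false_positive_prob(n, k, p) == pytest.approx(
        brute_force_tail(n, k, p), abs=1e-12)


def test_certain_per_point_exceedance():
    assert endpoint_false_positive_prob(5, 5, 1.0) == 1.0


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        endpoint_false_positive_prob(68, 5, 1.5)
    with pytest.raises(ValueError):
        endpoint_false_positive_prob(5, 6, 0.05)


@settings(max_examples=40, derandomize=True)
@given(n=st.integers(10, 100), k=st.integers(1, 5),
       p=st.floats(0.01, 0.5))
def test_tail_monotonicity(n, k, p):
    base = endpoint_false_positive_prob(n, k, p)
    assert endpoint_false_positive_prob(n + 10, k, p) >= base
    assert endpoint_false_positive_prob(n, k + 1, p) <= base
    assert endpoint_false_positive_prob(n, k, min(p + 0.1, 1.0)) >= base


def test_monte_carlo_agrees_with_analytic():
    p_true = endpoint_false_positive_prob(68, 5, 0.05)
    n_sim = 100_000
    est = monte_carlo_endpoint_check(68, 5, 0.05, n_sim, seed=12)
    se = math.sqrt(p_true * (1 - p_true) / n_sim)
    assert abs(est - p_true) < 3 * se


@pytest.mark.parametrize("args, expected", [((16, 5, 0.0, 1000), 0.0),
                                            ((5, 5, 1.0, 1000), 1.0)])
def test_monte_carlo_degenerate(args, expected):
    assert monte_carlo_endpoint_check(*args, seed=0) == expected


def _pair_with_diffs(make_exam, gains=0, declines=0, delta=7.0):
    base = np.full(68, 15.0)
    after = base.copy()
    after[:gains] += delta
    after[gains:gains + declines] -= delta
    return pair_exams(make_exam(base), make_exam(after, test_index=3))


def test_no_change_classification(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam))
    assert c.no_change and not c.subthreshold
    assert c.single_label == "none"


def test_five_gains_is_gain_significant(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam, gains=5))
    assert c.gain_significant and c.n_gain == 5
    assert not c.decline_significant and not c.mixed
    assert c.single_label == "gain"


def test_five_declines_is_decline_significant(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam, declines=5))
    assert c.decline_significant and c.n_decline == 5
    assert c.single_label == "decline"


def test_two_gains_five_declines_mixed_response(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam, gains=2, declines=5,
                                            delta=8.0))
    assert c.decline_significant and c.mixed
    assert (c.n_gain, c.n_decline) == (2, 5)
    assert not c.gain_significant
    assert c.single_label == "decline"  # precedence decline > mixed


def test_subthreshold_classification(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam, gains=1, declines=2))
    assert c.subthreshold and not c.mixed
    assert c.single_label == "subthreshold"


def test_boundary_change_counts(make_exam):
    c = classify_pointwise(_pair_with_diffs(make_exam, gains=5, delta=7.0))
    assert c.gain_significant  # >= is inclusive


def test_reversal_swaps_gain_and_decline(grid, make_exam):
    rng = np.random.default_rng(4)
    a = rng.uniform(8, 28, 68)
    b = a + rng.normal(0, 6, 68)
    pair = pair_exams(make_exam(np.round(a)), make_exam(np.round(np.clip(b, 0, 36)),
                                                        test_index=3))
    c = classify_pointwise(pair)
    r = classify_pointwise(pair.reversed())
    assert (c.n_gain, c.n_decline) == (r.n_decline, r.n_gain)


def test_region_subset_restricts_counting(grid, make_exam):
    # gains placed on peripheral loci only: central regions see no change
    base = np.full(68, 15.0)
    after = base.copy()
    peripheral = [i for i, l in enumerate(grid.loci)
                  if grid.region_labels[l.locus_id] == "peripheral"][:6]
    after[peripheral] += 9.0
    pair = pair_exams(make_exam(base), make_exam(after, test_index=3))
    assert classify_pointwise(pair, EndpointSpec(region="all68"), grid).gain_significant
    c16 = classify_pointwise(pair, EndpointSpec(region="central16"), grid)
    assert c16.no_change


@pytest.mark.parametrize("delta, expected", [(-1.3, "significant_decline"),
                                             (0.0, "within_variability"),
                                             (400.0, "significant_gain"),
                                             (1.3, "significant_gain")])
def test_classify_global(delta, expected):
    cutoff = 1.3 if abs(delta) < 100 else 324.2
    assert classify_global(delta, cutoff).category == expected


def test_classify_global_rejects_nonpositive_cutoff():
    with pytest.raises(ValueError):
        classify_global(1.0, 0.0)


def test_concordance_all_identical():
    rows = [{"pointwise": "decline", "ms": "decline", "vol": "decline"}] * 5
    assert concordance(rows)["agreement_fraction"] == 1.0


def test_concordance_constructed_fraction():
    concordant = [{"p": "within", "m": "within", "v": "within"}] * 7
    discordant = [{"p": "gain", "m": "within", "v": "within"}] * 3
    res = concordance(concordant + discordant)
    assert res["n_pairs"] == 10
    assert res["agreement_fraction"] == pytest.approx(0.7)


def test_concordance_excludes_incomplete_pairs(caplog):
    rows = [{"p": "gain", "m": "gain"}, {"p": "gain", "m": "gain", "v": "gain"}]
    with caplog.at_level("WARNING"):
        res = concordance(rows)
    assert res["n_pairs"] == 1
    assert "excluded" in caplog.text
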
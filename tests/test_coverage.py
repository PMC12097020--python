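"""Panel coverage math, exhaustive/greedy search, bank screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covpanel import (
    ConfigurationError,
    CoverageThresholds,
    InputError,
    PositivityMatrix,
    cohort_summary,
    coverage,
    enumerate_panels,
    greedy_panel,
    rank_sum_pvalue,
    recommend_panel,
    screen_target_bank,
)


def _pm(arr, antigens):
    flags = pd.DataFrame(np.asarray(arr, dtype=int), columns=antigens)
    flags.index = [f"c{i}" for i in range(len(flags))]
    return PositivityMatrix(flags=flags)


def bitset_best_panel(flags: pd.DataFrame, k: int):
    """Independent brute-force max-coverage oracle using Python int bitsets."""
    bits = {}
    for a in flags.columns:
        b = 0
        for i, v in enumerate(flags[a]):
            if v:
                b |= 1 << i
        bits[a] = b
    best_panel, best_count = None, -1
    for combo in itertools.combinations(sorted(flags.columns), k):
        union = 0
        for a in combo:
            union |= bits[a]
        c = union.bit_count()
        if c > best_count:
            best_panel, best_count = combo, c
    return best_panel, best_count / len(flags)


# --- coverage ---------------------------------------------------------------

def test_coverage_hand_counts_on_toy_matrix(t6):
    assert coverage(t6, ["a"]).coverage == pytest.approx(3 / 6)
    assert coverage(t6, ["a", "b"]).coverage == pytest.approx(4 / 6)
    assert coverage(t6, ["a", "b", "c"]).coverage == pytest.approx(5 / 6)


def test_coverage_all_positive_antigen(t6):
    P = _pm(np.ones((4, 1)), ["a"])
    assert coverage(P, ["a"]).coverage == 1.0


def test_empty_panel_rejected(t6):
    with pytest.raises(InputError):
        coverage(t6, [])


def test_unknown_antigen_rejected(t6):
    with pytest.raises(InputError, match="not in the positivity matrix"):
        coverage(t6, ["a", "zz"])


def test_marginals_recorded(t6):
    r = coverage(t6, ["a", "b"])
    assert r.marginals == {"a": pytest.approx(0.5), "b": pytest.approx(2 / 6)}
    assert r.covered_cells == 4 and r.n_cells == 6


# --- enumeration ------------------------------------------------------------

def test_enumerate_pairs_on_toy_matrix(t6):
    ranked = enumerate_panels(t6, 2)
    assert [r.panel for r in ranked] == [("a", "b"), ("a", "c"), ("b", "c")]
    assert [r.coverage for r in ranked] == pytest.approx([4 / 6, 4 / 6, 4 / 6])


def test_enumerate_singles_ranking(t6):
    ranked = enumerate_panels(t6, 1)
    assert [r.panel for r in ranked] == [("a",), ("b",), ("c",)]
    assert ranked[0].coverage == pytest.approx(3 / 6)
    assert ranked[1].coverage == ranked[2].coverage == pytest.approx(2 / 6)


def test_enumerate_full_bank_single_result(t6):
    ranked = enumerate_panels(t6, 3)
    assert len(ranked) == 1
    assert ranked[0].coverage == coverage(t6, ["a", "b", "c"]).coverage


def test_enumerate_result_count_is_binomial():
    rng = np.random.default_rng(0)
    P = _pm(rng.random((50, 6)) < 0.4, list("abcdef"))
    assert len(enumerate_panels(P, 2)) == 15
    assert len(enumerate_panels(P, 3)) == 20


def test_panel_size_cap_refused_without_override():
    rng = np.random.default_rng(0)
    P = _pm(rng.random((20, 5)) < 0.5, list("abcde"))
    with pytest.raises(ConfigurationError, match="cap"):
        enumerate_panels(P, 4)
    assert len(enumerate_panels(P, 4, allow_large=True)) == 5


def test_enumeration_matches_bitset_oracle():
    rng = np.random.default_rng(42)
    antigens = [f"A{i}" for i in range(9)]
    for _ in range(10):
        P = _pm(rng.random((200, 9)) < rng.uniform(0.05, 0.6), antigens)
        for k in (1, 2, 3):
            oracle_panel, oracle_cov = bitset_best_panel(P.flags, k)
            best = enumerate_panels(P, k)[0]
            assert best.panel == oracle_panel
            assert best.coverage == pytest.approx(oracle_cov, abs=0)


# --- greedy -----------------------------------------------------------------

def test_greedy_trace_on_toy_matrix(t6):
    r = greedy_panel(t6, 2)
    assert r.panel == ("a", "b")  # a first (3 new), then b on the lexicographic tie
    assert r.coverage == pytest.approx(4 / 6)


def test_greedy_k1_equals_best_single(t6):
    assert greedy_panel(t6, 1).panel == enumerate_panels(t6, 1)[0].panel


def test_greedy_meets_classic_guarantee():
    rng = np.random.default_rng(7)
    antigens = [f"A{i}" for i in range(9)]
    bound = 1 - 1 / np.e
    for _ in range(25):
        P = _pm(rng.random((300, 9)) < rng.uniform(0.05, 0.5), antigens)
        opt = enumerate_panels(P, 3)[0].coverage
        assert greedy_panel(P, 3).coverage >= bound * opt - 1e-12


# --- properties (random matrices) -------------------------------------------

@st.composite
def positivity_matrices(draw):
    n = draw(st.integers(3, 40))
    m = draw(st.integers(2, 6))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, 1), min_size=m, max_size=m),
            min_size=n, max_size=n,
        )
    )
    return _pm(rows, [f"A{i}" for i in range(m)])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(positivity_matrices(), st.data())
def test_coverage_monotone_under_panel_growth(P, data):
    ants = P.antigens
    small = data.draw(st.lists(st.sampled_from(ants), min_size=1, unique=True))
    extra = data.draw(st.lists(st.sampled_from(ants), min_size=0, unique=True))
    big = sorted(set(small) | set(extra))
    assert coverage(P, small).coverage <= coverage(P, big).coverage + 1e-12


@settings(max_examples=60, derandomize=True, deadline=None)
@given(positivity_matrices(), st.data())
def test_coverage_bounds_and_inclusion_exclusion(P, data):
    ants = P.antigens
    panel = data.draw(st.lists(st.sampled_from(ants), min_size=1, unique=True))
    r = coverage(P, panel)
    assert max(r.marginals.values()) <= r.coverage + 1e-12
    assert r.coverage <= min(1.0, sum(r.marginals.values())) + 1e-12
    if len(r.panel) == 2:
        a, b = r.panel
        both = (P.flags[a] & P.flags[b]).sum() / P.n_cells
        assert r.coverage == pytest.approx(r.marginals[a] + r.marginals[b] - both)


# --- recommendation ---------------------------------------------------------

def test_recommend_smallest_k_meeting_threshold():
    # best pair covers 0.85: recommended at k=2 under the 0.80 bar
    rng = np.random.default_rng(1)
    n = 2000
    flags = np.zeros((n, 3), dtype=int)
    flags[: int(0.85 * n), 0] = 1  # antigen A0 covers 85%
    P = _pm(flags, ["A0", "A1", "A2"])
    rec = recommend_panel(P, CoverageThresholds({2: 0.80, 3: 0.90}))
    assert rec.k == 2 and rec.met and "A0" in rec.panel


def test_recommend_toy_matrix_fails_both_bars(t6):
    rec = recommend_panel(t6, CoverageThresholds({2: 0.80, 3: 0.90}))
    assert rec.k == 3 and not rec.met
    assert rec.panel == ("a", "b", "c")
    assert rec.coverage == pytest.approx(5 / 6)


def test_recommend_dominated_by_single_antigen_ties_canonically():
    flags = np.zeros((10, 4), dtype=int)
    flags[:, 1] = 1  # only "b" positive, everywhere
    P = _pm(flags, ["a", "b", "c", "d"])
    rec = recommend_panel(P, CoverageThresholds({2: 0.80, 3: 0.90}))
    assert rec.met and rec.k == 2 and rec.coverage == 1.0
    assert rec.panel == ("a", "b")  # lexicographically first pair containing b


def test_recommend_missing_threshold_is_configuration_error(t6):
    with pytest.raises(ConfigurationError, match="threshold"):
        recommend_panel(t6, CoverageThresholds({2: 0.8}), k_min=2, k_max=3)


# --- cohort summary ----------------------------------------------------------

def _results_for(P):
    return enumerate_panels(P, 2)


def test_cohort_summary_mean_and_sample_sd():
    flags1 = np.zeros((10, 2), dtype=int)
    flags1[:8, 0] = 1  # pair coverage 0.8
    flags2 = np.zeros((10, 2), dtype=int)
    flags2[:9, 0] = 1  # pair coverage 0.9
    res = {
        "P1": _results_for(_pm(flags1, ["a", "b"])),
        "P2": _results_for(_pm(flags2, ["a", "b"])),
    }
    df = cohort_summary(res)
    assert df.loc[0, "mean_coverage"] == pytest.approx(0.85)
    assert df.loc[0, "sd_coverage"] == pytest.approx(0.070710678, abs=1e-9)


def test_cohort_summary_single_patient_degenerate(t6):
    df = cohort_summary({"P1": _results_for(t6)})
    assert (df["sd_coverage"] == 0).all()
    assert df["degenerate_n"].all()


def test_cohort_summary_patient_order_invariant(t6):
    res = {"P1": _results_for(t6), "P2": _results_for(t6)}
    df1 = cohort_summary(res)
    df2 = cohort_summary(dict(reversed(list(res.items()))))
    pd.testing.assert_frame_equal(df1, df2)


def test_cohort_summary_mismatched_panels_rejected(t6):
    P2 = _pm(np.ones((4, 2)), ["a", "x"])
    with pytest.raises(InputError, match="differ"):
        cohort_summary({"P1": _results_for(t6), "P2": _results_for(P2)})


# --- target-bank screening ---------------------------------------------------

def _catalog(rate=0.9, stable=True, tumor=(5, 6, 7, 8), normal=(1, 2, 3, 4)):
    return pd.DataFrame(
        [
            {
                "antigen": "X",
                "expression_rate": rate,
                "stability_flag": stable,
                "tumor_expr": list(tumor),
                "normal_expr": list(normal),
            }
        ]
    )


def test_low_expression_rate_excluded_regardless():
    pool = screen_target_bank(_catalog(rate=0.65))
    assert pool.empty


def test_unstable_antigen_excluded():
    pool = screen_target_bank(_catalog(stable=False))
    assert pool.empty


def test_no_tumor_elevation_excluded():
    pool = screen_target_bank(_catalog(tumor=(1, 2, 3), normal=(1.5, 2.5, 3.5)))
    assert pool.empty


def test_separated_groups_retained():
    pool = screen_target_bank(_catalog())
    assert list(pool["antigen"]) == ["X"]
    assert pool.loc[0, "rank_sum_p"] == pytest.approx(1 / 70)  # C(8,4) exact


def test_exact_rank_sum_boundary_case():
    """tumor=(5,6,7) vs normal=(1,2,3): exact one-sided p = 1/20 = 0.05,
    which strict p < alpha excludes at alpha = 0.05."""
    assert rank_sum_pvalue([5, 6, 7], [1, 2, 3]) == pytest.approx(0.05)
    pool = screen_target_bank(_catalog(tumor=(5, 6, 7), normal=(1, 2, 3)), alpha=0.05)
    assert pool.empty
    pool = screen_target_bank(_catalog(tumor=(5, 6, 7), normal=(1, 2, 3)), alpha=0.051)
    assert not pool.empty


def test_large_samples_use_tie_corrected_normal_approximation():
    rng = np.random.default_rng(0)
    tumor = np.round(rng.normal(2.0, 1.0, 60), 1)  # rounding induces ties
    normal = np.round(rng.normal(0.0, 1.0, 60), 1)
    p = rank_sum_pvalue(tumor, normal)
    assert p < 1e-6


def test_empty_expression_vector_rejected():
    with pytest.raises(InputError):
        rank_sum_pvalue([], [1, 2])
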
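import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipidiff.diffstats import (
    ComparisonSpec,
    DegenerateDataError,
    classify_volcano,
    fold_change,
    run_comparison,
    student_t,
    unique_significant_union,
)
from lipidiff.io_preprocess import IntensityTable, filter_by_grade
from lipidiff.synthetic_data import default_paper_like_spec, generate_dataset


def test_identical_groups_give_null_result():
    t, p = student_t([1, 2, 3], [1, 2, 3])
    assert (t, p) == (0.0, 1.0)
    assert fold_change([1, 2, 3], [1, 2, 3]) == 1.0


def test_pooled_variance_example():
    """Hand-computed pooled t: |t| = 10/(2*sqrt(2/3)), df = 4."""
    t, p = student_t([10, 12, 14], [20, 22, 24], variant="student")
    assert t == pytest.approx(-10 / (2 * math.sqrt(2 / 3)), abs=1e-12)
    assert t == pytest.approx(-6.123724, abs=1e-6)
    assert p == pytest.approx(0.00363, abs=5e-5)
    # cross-check against the reference implementation
    ref = stats.ttest_ind([10, 12, 14], [20, 22, 24])
    assert (t, p) == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)


@pytest.mark.parametrize("variant", ["student", "welch"])
def test_group_swap_symmetry(variant):
    a, b = [10.0, 12.0, 14.0, 13.0], [20.0, 22.0, 24.0]
    t1, p1 = student_t(a, b, variant)
    t2, p2 = student_t(b, a, variant)
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
    assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


def test_welch_matches_reference():
    a, b = [1.0, 5.0, 9.0, 2.0], [4.0, 4.5, 5.0]
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert student_t(a, b, "welch") == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)


def test_student_equals_welch_equal_n_equal_var():
    a = [1.0, 2.0, 3.0, 4.0]
    b = [11.0, 12.0, 13.0, 14.0]  # same spread, shifted
    ts, _ = student_t(a, b, "student")
    tw, _ = student_t(a, b, "welch")
    assert ts == pytest.approx(tw, abs=1e-12)


def test_degenerate_inputs():
    with pytest.raises(DegenerateDataError, match="group1"):
        student_t([1.0], [1, 2, 3])
    # constant data, equal means: total behavior
    assert student_t([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)
    with pytest.raises(DegenerateDataError):
        student_t([5, 5, 5], [7, 7, 7])
    with pytest.raises(DegenerateDataError):
        fold_change([1, 2], [0, 0])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(1.0, 1e6), min_size=2, max_size=6),
    st.lists(st.floats(1.0, 1e6), min_size=2, max_size=6),
    st.floats(0.01, 100.0),
)
def test_scale_invariance(a, b, c):
    """Multiplying all intensities by a common constant changes nothing."""
    try:
        t1, p1 = student_t(a, b)
    except DegenerateDataError:
        return
    a2, b2 = [c * x for x in a], [c * x for x in b]
    t2, p2 = student_t(a2, b2)
    assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-9)
    assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)
    assert fold_change(a, b) == pytest.approx(fold_change(a2, b2), rel=1e-9)


def _exact_permutation_p(a, b):
    """Exhaustive two-sample permutation p for |mean difference|."""
    pooled = list(a) + list(b)
    n1 = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp1 = [pooled[i] for i in idx]
        grp2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(np.mean(grp1) - np.mean(grp2)) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def test_t_ranks_like_exact_permutation_test():
    """On tiny monotone shifts, t p-values order lipids like the exact test."""
    base = np.array([3.1, 4.7, 5.2, 4.0])
    ctrl = np.array([4.2, 3.6, 4.9, 4.4])
    shifts = [0.5, 1.5, 3.0, 6.0]
    t_ps = [student_t(base + s, ctrl)[1] for s in shifts]
    perm_ps = [_exact_permutation_p(base + s, ctrl) for s in shifts]
    order = np.argsort(t_ps)
    assert list(np.array(perm_ps)[order]) == sorted(perm_ps)


@pytest.mark.parametrize(
    "p,fc,expected",
    [
        (0.004, 0.25, "down"),
        (0.5, 8.0, "not_significant"),  # fails the p gate
        (0.01, 1.5, "not_significant"),  # |log2 1.5| < 1, inside exclusion band
        (0.01, 4.46, "up"),
        (0.05, 0.1, "not_significant"),  # p threshold is strict
    ],
)
def test_classify_volcano(p, fc, expected):
    assert classify_volcano(p, fc) == expected


def test_volcano_direction_swaps_with_groups(toy_table):
    table = filter_by_grade(toy_table, {"A", "B"})
    fwd = run_comparison(table, ComparisonSpec("tumor", "ctrl"))
    rev = run_comparison(table, ComparisonSpec("ctrl", "tumor"))
    for f, r in zip(fwd, rev):
        assert f.p_value == pytest.approx(r.p_value)
        assert f.fold_change == pytest.approx(1 / r.fold_change)
        swap = {"up": "down", "down": "up", "not_significant": "not_significant"}
        assert r.call == swap[f.call]


def test_run_comparison_cardinality_and_order():
    table, _, _ = generate_dataset(default_paper_like_spec(seed=2))
    table = filter_by_grade(table, {"A", "B"})
    comps = [ComparisonSpec("cSCC", "Healthy"), ComparisonSpec("BCC", "Healthy"),
             ComparisonSpec("cSCC", "BCC")]
    all_results = [run_comparison(table, c) for c in comps]
    assert all(len(r) == 168 for r in all_results)
    assert [r.lipid for r in all_results[0]] == table.lipids
    for r in all_results[0]:
        assert r.log2_fc == pytest.approx(math.log2(r.fold_change))


def test_run_comparison_zero_variance_errors(toy_samples):
    t = IntensityTable(
        lipids=["LPC(16:0)"],
        grades=["A"],
        intensities=np.array([[1.0, 1.0, 1.0, 2.0, 2.0]]),
        missing_mask=np.zeros((1, 5), dtype=bool),
        samples=toy_samples,
    )
    with pytest.raises(DegenerateDataError, match="LPC"):
        run_comparison(t, ComparisonSpec("tumor", "ctrl"))


def test_planted_down_class_all_called_down():
    """Strong planted negative effects are all recovered as 'down'."""
    table, _, _ = generate_dataset(default_paper_like_spec(seed=4))
    table = filter_by_grade(table, {"A", "B"})
    for comp in (ComparisonSpec("cSCC", "Healthy"), ComparisonSpec("BCC", "Healthy")):
        results = run_comparison(table, comp)
        dg = [r for r in results if r.class_code == "DG"]
        assert dg and all(r.call == "down" for r in dg)


class _R:
    def __init__(self, lipid, p):
        self.lipid, self.p_value = lipid, p


def test_unique_significant_union():
    lists = [
        [_R("a", 0.01), _R("b", 0.02), _R("c", 0.5)],
        [_R("c", 0.03), _R("a", 0.9)],
        [_R("d", 0.8)],
    ]
    assert unique_significant_union(lists, 0.05) == 3
    same = [[_R("a", 0.01), _R("b", 0.02)]] * 3
    assert unique_significant_union(same, 0.05) == 2
    assert unique_significant_union([], 0.05) == 0
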
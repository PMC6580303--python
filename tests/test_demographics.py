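import numpy as np
import pytest
from scipy import stats

from strandphen import demographics as dm
from strandphen.data_io import (OTTER_TALLY_CELLS_1997_2017,
                                records_from_counts)


def _male_maturity_table():
    """Male maturity-by-cause counts summed over the published triennia."""
    counts = {}
    for (b, sex, mat, cause), n in OTTER_TALLY_CELLS_1997_2017.items():
        if sex == "M":
            counts[(mat, cause)] = counts.get((mat, cause), 0) + n
    return counts


def test_published_male_table_and_statistic():
    counts = _male_maturity_table()
    records = []
    for (mat, cause), n in counts.items():
        records.extend(records_from_counts({("M", mat): n}, cause=cause))
    table = dm.build_contingency(records, "age_class", "cause",
                                 row_levels=("mature", "immature"),
                                 col_levels=("shark", "other"))
    assert table.cells.tolist() == [[58, 67], [28, 71]]
    res = dm.chi_squared(table, yates=True)
    assert round(res.value, 2) == 6.92 and res.df == 1 and res.p_value < 0.01


@pytest.mark.parametrize("cells,yates,expected", [
    ([[10, 10], [10, 10]], True, 0.0),
    ([[10, 10], [10, 10]], False, 0.0),
    ([[20, 5], [5, 20]], True, 15.68),
])
def test_chi_squared_known_values(cells, yates, expected):
    res = dm.chi_squared(np.array(cells), yates=yates)
    assert round(res.value, 2) == expected
    if expected == 0.0:
        assert res.p_value == pytest.approx(1.0)


def test_chi_squared_matches_scipy_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        cells = rng.integers(1, 40, size=(2, 2))
        for yates in (True, False):
            ours = dm.chi_squared(cells, yates=yates)
            ref_stat, ref_p, ref_df, _ = stats.chi2_contingency(
                cells, correction=yates)
            assert ours.value == pytest.approx(ref_stat, rel=1e-10)
            assert ours.p_value == pytest.approx(ref_p, rel=1e-10)
            assert ours.df == ref_df
        assert dm.chi_squared(cells, True).value <= \
            dm.chi_squared(cells, False).value + 1e-12


def test_chi_squared_symmetries():
    cells = np.array([[12, 7], [3, 30]])
    base = dm.chi_squared(cells).value
    for variant in (cells[::-1], cells[:, ::-1], cells.T):
        assert dm.chi_squared(variant).value == pytest.approx(base)


def test_chi_squared_errors():
    with pytest.raises(ValueError):
        dm.chi_squared(np.array([[0, 0], [5, 5]]))
    with pytest.raises(ValueError):
        dm.build_contingency([], "sex", "cause")


def test_rank_sum_frozen_example_and_mirror():
    res = dm.wilcoxon([1, 2, 3], [4, 5, 6], mode="rank_sum")
    assert res.value == 0.0 and res.p_value == pytest.approx(0.1)
    assert dm.wilcoxon([4, 5, 6], [1, 2, 3]).value == 9.0


def test_exact_rank_sum_matches_independent_oracle():
    """Exact p-values agree with scipy's exact Mann-Whitney on tie-free data."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        n1, n2 = rng.integers(2, 6, size=2)
        # half-integer offset keeps the pooled sample tie-free: scipy's exact
        # null distribution assumes no ties
        x = rng.permutation(np.arange(1, 40, dtype=float))[:n1]
        y = rng.permutation(np.arange(1, 40, dtype=float))[:n2] + 0.5
        ours = dm.wilcoxon(x, y, mode="rank_sum")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.value == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


def test_exact_signed_rank_matches_independent_oracle():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(3, 9))
        x = rng.normal(size=n) * 10
        y = x + rng.choice([-3, -1, 2, 4], size=n) + rng.normal(size=n)
        ours = dm.wilcoxon(x, y, mode="signed_rank_paired")
        ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.value == pytest.approx(ref.statistic) or \
            ours.value == pytest.approx(n * (n + 1) / 2 - ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


def test_signed_rank_degenerate_and_errors():
    res = dm.wilcoxon([1, 2, 3], [1, 2, 3], mode="signed_rank_paired")
    assert res.p_value == 1.0
    with pytest.raises(ValueError):
        dm.wilcoxon([1, 2], [1, 2, 3], mode="signed_rank_paired")
    with pytest.raises(ValueError):
        dm.wilcoxon([], [1], mode="rank_sum")


def test_large_sample_modes_use_normal_approximation():
    rng = np.random.default_rng(13)
    x, y = rng.normal(size=30), rng.normal(0.8, size=30)
    res = dm.wilcoxon(x, y, mode="rank_sum")
    ref = stats.mannwhitneyu(x, y, alternative="two-sided")
    assert res.method == "normal_approx"
    assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_median_converges_to_observed_proportion():
    records = records_from_counts({("M", "mature"): 70, ("F", "mature"): 30})
    cfg = dm.BootstrapConfig(n_replicates=10_000, seed=3)
    s = dm.bootstrap_bias(records, cfg, grouping="pooled")
    assert abs(s.median - 0.70) < 0.02
    assert s.ci_lower <= s.median <= s.ci_upper


def test_bootstrap_deterministic_and_groupings(rec):
    records = [rec(year=1998, sex="M"), rec(year=1998, sex="F"),
               rec(year=2004, sex="M"), rec(year=2004, sex="M"),
               rec(year=2010, sex="F")]
    cfg = dm.BootstrapConfig(n_replicates=200, seed=5)
    for grouping in ("pooled", "per_bin"):
        a = dm.bootstrap_bias(records, cfg, grouping=grouping)
        b = dm.bootstrap_bias(records, cfg, grouping=grouping)
        assert (a.median, a.ci_lower, a.ci_upper) == (b.median, b.ci_lower, b.ci_upper)


def test_bootstrap_all_male_stratum():
    records = records_from_counts({("M", "mature"): 12})
    s = dm.bootstrap_bias(records, dm.BootstrapConfig(seed=0), grouping="pooled")
    assert (s.median, s.ci_lower, s.ci_upper) == (1.0, 1.0, 1.0)


def test_bootstrap_errors(rec):
    with pytest.raises(ValueError):
        dm.bootstrap_bias([], dm.BootstrapConfig())
    with pytest.raises(ValueError):
        dm.bootstrap_bias([rec(sex="unknown")], dm.BootstrapConfig())


def test_observed_bias_by_bin(rec):
    records = [rec(year=1998, sex="M"), rec(year=1998, sex="F"),
               rec(year=2004, sex="M")]
    assert dm.observed_bias_by_bin(records) == {0: 0.5, 2: 1.0}
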